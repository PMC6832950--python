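"""From masked pixels to histogram tensors.

Instead of feeding raw imagery to the network, every (county, year) is
summarised as a tensor of shape t x 32 x 11: for each of t composite
periods and each of 11 bands, the distribution of crop-masked pixel
values inside the county is reduced to a 32-bin normalized histogram
over fixed band limits.  This keeps sub-county heterogeneity (unlike a
zonal mean) while making the input size independent of county area.

The stages here mirror the ingestion workflow of the original cloud
pipeline: crop masking, daily-to-8-day weather alignment, empirical
limit estimation, histogramming, tensor assembly and label joining.
Each band is histogrammed on its own native grid; bands are never
co-registered or resampled against each other.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import shapely

from .bands import BandSpec, ENVIRONMENT_GROUPS, REFLECTANCE_GROUP
from .calendar import CompositeCalendar, TimeNode, truncate_calendar
from .geo import Raster

__all__ = [
    "BU_AC_TO_KG_HA",
    "CountyScene",
    "HistogramTensor",
    "YieldRecord",
    "TensorDataset",
    "DropReport",
    "mask_pixels",
    "county_cell_selection",
    "aggregate_daily",
    "estimate_limits",
    "histogram32",
    "build_tensor",
    "truncate",
    "assemble_dataset",
    "convert_yield",
]

#: bushels/acre -> kg/ha for soybean (60 lb test weight):
#: 60 lb * 0.45359237 kg/lb / 0.40468564 ha/acre = 67.25 kg/ha per bu/ac
BU_AC_TO_KG_HA = 67.25


@dataclass(frozen=True)
class YieldRecord:
    county_id: str
    year: int
    yield_kg_ha: float

    def __post_init__(self) -> None:
        if self.yield_kg_ha <= 0:
            raise ValueError(f"yield must be positive, got {self.yield_kg_ha} "
                             f"for ({self.county_id}, {self.year})")


def convert_yield(value: float, unit: str) -> float:
    """Convert a yield value to kg/ha.  Accepts 'kg/ha' or 'bu/ac'."""
    if unit == "kg/ha":
        return float(value)
    if unit == "bu/ac":
        return float(value) * BU_AC_TO_KG_HA
    raise ValueError(f"unknown yield unit {unit!r} (expected 'kg/ha' or 'bu/ac')")


@dataclass
class CountyScene:
    """All masked pixel values for one county-year.

    ``pixels[band][p]`` is the 1-D array of crop pixels of band *band* in
    composite period index *p* (may be empty, e.g. a cloudless-data gap or
    a county with no crop pixels at all).
    """

    county_id: str
    year: int
    pixels: dict[str, list[np.ndarray]]

    def masked_count(self) -> int:
        return int(sum(int(a.size) for arrays in self.pixels.values() for a in arrays))


@dataclass
class HistogramTensor:
    """Model input for one county-year: (t, n_bins, n_bands) histograms."""

    county_id: str
    year: int
    values: np.ndarray
    calendar: CompositeCalendar
    band_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        t, _, m = self.values.shape
        if t != len(self.calendar):
            raise ValueError("tensor time axis does not match calendar")
        if m != len(self.band_order):
            raise ValueError("tensor band axis does not match band order")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def has_any_pixels(self) -> bool:
        return bool(np.any(self.values))

    def restrict_bands(self, names: list[str]) -> "HistogramTensor":
        idx = []
        for n in names:
            if n not in self.band_order:
                raise KeyError(f"unknown band {n!r}")
            idx.append(self.band_order.index(n))
        return HistogramTensor(self.county_id, self.year, self.values[:, :, idx],
                               self.calendar, tuple(names))


def county_cell_selection(grid: Raster, crop_mask: Raster, polygon) -> np.ndarray:
    """Boolean selection over ``grid`` cells: center inside the polygon AND
    crop-mask positive at that center (nearest-cell sampling of the mask;
    the band grid itself is never resampled)."""
    xs, ys = grid.cell_centers()
    sel = np.zeros(grid.shape, dtype=bool)
    # restrict the point-in-polygon test to the polygon's bounding box
    minx, miny, maxx, maxy = polygon.bounds
    box = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
    if box.any():
        inside = shapely.contains_xy(polygon, xs[box], ys[box])
        sel[box] = inside
    if sel.any():
        mask_vals = crop_mask.sample_nearest(xs[sel], ys[sel], fill=0.0)
        keep = mask_vals > 0
        idx = np.flatnonzero(sel.ravel())
        sel.ravel()[idx[~keep]] = False
    return sel


def mask_pixels(band_raster: Raster, crop_mask: Raster, polygon) -> np.ndarray:
    """Values of band cells whose centers fall inside the county polygon and
    on positive crop mask.  Disjoint extents yield an empty array."""
    sel = county_cell_selection(band_raster, crop_mask, polygon)
    return band_raster.data[sel].astype(np.float64, copy=False).ravel()


def aggregate_daily(daily: np.ndarray, calendar: CompositeCalendar) -> np.ndarray:
    """Mean of daily values over each 8-day composite window.

    ``daily`` is indexed by day-of-year - 1 (length >= last period end) and
    may contain NaN for missing days; a window whose days are all missing
    yields NaN, which propagates downstream as "no pixels" for that period.
    """
    daily = np.asarray(daily, dtype=np.float64)
    out = np.empty(len(calendar))
    for i, (s, e) in enumerate(calendar.periods):
        window = daily[s - 1 : e]
        if window.size == 0 or np.all(np.isnan(window)):
            out[i] = np.nan
        else:
            out[i] = np.nanmean(window)
    return out


def estimate_limits(
    pooled: np.ndarray | list[np.ndarray],
    quantiles: tuple[float, float] = (0.005, 0.995),
) -> tuple[float, float]:
    """Empirical histogram limits from a pooled pixel sample.

    Pools pixels across all counties, periods and years of a band and
    returns the lower/upper sample quantiles.  The packaged band defaults
    can override this with the published constants.
    """
    if isinstance(pooled, (list, tuple)):
        pooled = np.concatenate([np.asarray(a).ravel() for a in pooled]) if pooled else np.array([])
    pooled = np.asarray(pooled, dtype=float).ravel()
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("cannot estimate limits from an empty pixel pool")
    lo, hi = np.quantile(pooled, quantiles)
    return float(lo), float(hi)


def histogram32(pixels: np.ndarray, limits: tuple[float, float], n_bins: int = 32) -> np.ndarray:
    """Normalized clamped histogram over n_bins equal-width bins.

    Bins are half-open [edge_i, edge_{i+1}) with the last bin closed at the
    upper limit.  Out-of-range values are clamped into the boundary bins so
    no probability mass is discarded.  An empty pixel set gives the
    all-zero vector (distinguishing "no data" from any real distribution).
    """
    lo, hi = limits
    if not lo < hi:
        raise ValueError(f"limits must satisfy min < max, got {limits}")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    pixels = pixels[~np.isnan(pixels)]
    if pixels.size == 0:
        return np.zeros(n_bins)
    width = (hi - lo) / n_bins
    idx = np.floor((pixels - lo) / width).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return counts / pixels.size


def build_tensor(
    scene: CountyScene,
    bands: list[BandSpec],
    calendar: CompositeCalendar,
) -> HistogramTensor:
    """Assemble the (t, n_bins, n_bands) histogram tensor for one scene.

    Requires every configured band to be present in the scene; periods or
    bands with no masked pixels produce all-zero histogram slices.
    """
    t = len(calendar)
    n_bins = bands[0].n_bins
    values = np.zeros((t, n_bins, len(bands)))
    for b, spec in enumerate(bands):
        if spec.name not in scene.pixels:
            raise KeyError(f"scene ({scene.county_id}, {scene.year}) is missing band {spec.name!r}")
        per_period = scene.pixels[spec.name]
        if len(per_period) != t:
            raise ValueError(
                f"band {spec.name!r}: {len(per_period)} periods, calendar has {t}"
            )
        for p in range(t):
            values[p, :, b] = histogram32(per_period[p], spec.limits, spec.n_bins)
    return HistogramTensor(scene.county_id, scene.year, values, calendar,
                           tuple(s.name for s in bands))


def truncate(tensor: HistogramTensor, node: TimeNode) -> HistogramTensor:
    """Restrict a tensor to composite periods starting on or before the
    node date, updating its calendar consistently."""
    cal = truncate_calendar(tensor.calendar, node.month, node.day)
    return HistogramTensor(tensor.county_id, tensor.year,
                           tensor.values[: len(cal)], cal, tensor.band_order)


@dataclass
class DropReport:
    """Audit of county-years removed during dataset assembly."""

    no_crop_pixels: list[tuple[str, int]] = field(default_factory=list)
    no_label: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.no_crop_pixels) + len(self.no_label)

    def summary(self) -> str:
        return (f"{len(self.no_crop_pixels)} abandoned: no crop pixels; "
                f"{len(self.no_label)} abandoned: no label")


@dataclass
class TensorDataset:
    """Labelled histogram tensors sharing one calendar and band order."""

    tensors: list[HistogramTensor]
    records: list[YieldRecord]
    band_order: tuple[str, ...]
    groups: dict[str, str]  # band name -> feature group

    def __post_init__(self) -> None:
        if len(self.tensors) != len(self.records):
            raise ValueError("tensors and records must align")
        for tr in self.tensors:
            if tr.band_order != self.band_order:
                raise ValueError("all tensors must share the dataset band order")

    def __len__(self) -> int:
        return len(self.tensors)

    @property
    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    def stack(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): X of shape (N, t, n_bins, n_bands), y in kg/ha."""
        X = np.stack([tr.values for tr in self.tensors])
        y = np.array([r.yield_kg_ha for r in self.records])
        return X, y

    def subset(self, indices: list[int]) -> "TensorDataset":
        return TensorDataset([self.tensors[i] for i in indices],
                             [self.records[i] for i in indices],
                             self.band_order, self.groups)

    def filter_years(self, keep) -> "TensorDataset":
        idx = [i for i, r in enumerate(self.records) if keep(r.year)]
        return self.subset(idx)

    def restrict_bands(self, names: list[str]) -> "TensorDataset":
        tensors = [tr.restrict_bands(names) for tr in self.tensors]
        groups = {n: self.groups[n] for n in names}
        return TensorDataset(tensors, list(self.records), tuple(names), groups)

    def truncate(self, node: TimeNode) -> "TensorDataset":
        return TensorDataset([truncate(tr, node) for tr in self.tensors],
                             list(self.records), self.band_order, self.groups)


def assemble_dataset(
    tensors: list[HistogramTensor],
    yields: list[YieldRecord] | "object",
    bands: list[BandSpec],
    unit: str = "kg/ha",
) -> tuple[TensorDataset, DropReport]:
    """Join tensors with yield labels, applying the two exclusion rules:
    county-years with zero crop pixels in every period/band are excluded,
    and tensors without a matching yield record are abandoned.  Yields are
    converted to kg/ha.  Duplicate (county, year) labels are an error.
    """
    if unit not in ("kg/ha", "bu/ac"):
        raise ValueError(f"unknown yield unit {unit!r}")
    label_map: dict[tuple[str, int], float] = {}
    for rec in yields:
        key = (rec.county_id, rec.year)
        if key in label_map:
            raise ValueError(f"duplicate yield record for {key}")
        label_map[key] = convert_yield(rec.yield_kg_ha, unit) if unit == "bu/ac" else rec.yield_kg_ha
    report = DropReport()
    kept_t: list[HistogramTensor] = []
    kept_r: list[YieldRecord] = []
    for tr in tensors:
        key = (tr.county_id, tr.year)
        if not tr.has_any_pixels():
            report.no_crop_pixels.append(key)
            continue
        if key not in label_map:
            report.no_label.append(key)
            continue
        kept_t.append(tr)
        kept_r.append(YieldRecord(tr.county_id, tr.year, label_map[key]))
    groups = {s.name: s.group for s in bands}
    order = tuple(s.name for s in bands)
    return TensorDataset(kept_t, kept_r, order, groups), report
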
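"""Synthetic multi-year county archives with a known yield process.

The simulator stands in for the satellite/weather/crop-statistics stack:
it lays rectangular counties on a shared grid and generates, per year,

* seven reflectance-like bands on a fine grid as 8-day composites whose
  seasonal shape is a double-logistic phenology curve scaled by a latent
  county-year *greenness* factor g,
* two land-surface-temperature bands on a >= 2x coarser grid, carrying a
  seasonal cycle plus a latent county-year *heat anomaly* h,
* two daily weather bands (precipitation, vapour pressure) on the coarse
  grid, also linked to h,
* an annual binary crop mask on the fine grid (Bernoulli per cell), and
* county yields produced by a known linear link:

      yield = b0 + b_g * G - b_s * S + eps,   eps ~ N(0, sd_county)

  where G = g * sum_p dl(mid-DOY of period p) is the integrated greenness
  and S = max(h, 0) the heat-stress covariate.  G, S and eps are recorded
  in a truth table so estimators can be validated against the generating
  process.

Two spatial resolutions are deliberate: the downstream histogram workflow
must never need co-registration between bands.  All randomness derives
from one integer seed; identical configs reproduce identical archives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry as sgeom

from .bands import BandSpec, default_bands
from .calendar import CompositeCalendar, composite_calendar
from .geo import Raster, write_geotiff, write_county_polygons
from .tensorize import CountyScene

__all__ = ["PhenologyParams", "YieldLink", "NoiseSpec", "SimConfig",
           "RegionArchive", "simulate_region", "degenerate_county"]


def double_logistic(d, t_on: float, t_off: float, k_on: float, k_off: float):
    """Canonical green-up/senescence curve in [0, 1] over day-of-year d."""
    d = np.asarray(d, dtype=float)
    return 1.0 / (1.0 + np.exp(-k_on * (d - t_on))) / (1.0 + np.exp(k_off * (d - t_off)))


def _seasonal(d):
    """Smooth 0..1 annual temperature cycle peaking in late July."""
    d = np.asarray(d, dtype=float)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (d - 205.0) / 365.0))


@dataclass(frozen=True)
class PhenologyParams:
    green_up_day: float = 165.0
    senescence_day: float = 270.0
    slope_on: float = 0.09
    slope_off: float = 0.08
    timing_jitter_sd: float = 3.0  # county-year jitter on both transition days
    greenness_sd: float = 0.15  # sd of the latent multiplier g around 1.0


#: per-band response to the phenology curve: value = base + amp * g * dl(d)
_BAND_CURVES: dict[str, tuple[float, float]] = {
    "sr_b1": (600.0, -350.0),   # red: absorbed by canopy
    "sr_b2": (1200.0, 2200.0),  # NIR: strong canopy rise
    "sr_b3": (300.0, -150.0),   # blue
    "sr_b4": (500.0, 300.0),    # green
    "sr_b5": (1500.0, 800.0),   # NIR2
    "sr_b6": (1800.0, -600.0),  # SWIR: leaf water lowers it
    "sr_b7": (1200.0, -500.0),  # SWIR2
}


@dataclass(frozen=True)
class YieldLink:
    """Linear map from (integrated greenness, heat stress) to kg/ha."""

    intercept: float = 400.0
    greenness: float = 200.0
    stress: float = 250.0

    def apply(self, G, S):
        return self.intercept + self.greenness * np.asarray(G) - self.stress * np.asarray(S)


@dataclass(frozen=True)
class NoiseSpec:
    reflectance_sd: float = 60.0
    temperature_sd: float = 40.0
    pressure_sd: float = 80.0
    county_yield_sd: float = 120.0


@dataclass(frozen=True)
class SimConfig:
    n_counties: int = 150
    years: tuple[int, ...] = tuple(range(2003, 2011))
    grid_cells_per_county: tuple[int, int] = (8, 12)  # county side length range, fine cells
    crop_fraction: float = 0.6
    phenology: PhenologyParams = PhenologyParams()
    yield_link: YieldLink = YieldLink()
    noise: NoiseSpec = NoiseSpec()
    season: tuple[tuple[int, int], tuple[int, int]] = ((4, 1), (12, 31))
    fine_cell: float = 500.0
    coarse_factor: int = 2  # coarse cell = coarse_factor * fine_cell (>= 2)
    heat_anomaly_sd: float = 1.0
    n_zero_crop_counties: int = 0  # trailing counties given an all-zero mask (filter fixtures)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 0:
            raise ValueError("n_counties must be >= 0")
        lo, hi = self.grid_cells_per_county
        if lo < 1 or hi < lo:
            raise ValueError("grid_cells_per_county must be a positive range")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must be in (0, 1]")
        if self.coarse_factor < 2:
            raise ValueError("coarse grid must be at least 2x coarser than the fine grid")
        if self.n_counties and not self.years:
            raise ValueError("years must be non-empty")


def _county_ids(n: int) -> list[str]:
    return [f"C{i:03d}" for i in range(1, n + 1)]


class RegionArchive:
    """Simulated region: rasters are generated deterministically on demand.

    Latent county-year variables, crop masks, yields and the truth table
    are materialised eagerly (they are small); composite and daily raster
    arrays are recomputed from the latents and seeded per-(band, year)
    noise streams whenever requested, so an archive of 150 counties x 8
    years stays small in memory.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.bands = default_bands()
        cfg = config
        n = cfg.n_counties
        self.county_ids = _county_ids(n)
        self.calendars: dict[int, CompositeCalendar] = {
            y: composite_calendar(y, *cfg.season) for y in cfg.years
        } if n else {}

        # ---- layout: counties on a tiled fine grid
        side_hi = cfg.grid_cells_per_county[1]
        self._margin = 2
        self._tile = side_hi + 2 * self._margin
        k = max(1, math.ceil(math.sqrt(max(n, 1))))
        self._k = k
        nf = k * self._tile
        nf += nf % (2 * cfg.coarse_factor)  # even coverage by coarse cells
        self.fine_shape = (nf, nf)
        self.fine_origin = (0.0, nf * cfg.fine_cell)
        nc = nf // cfg.coarse_factor
        self.coarse_shape = (nc, nc)
        self.coarse_cell = cfg.fine_cell * cfg.coarse_factor

        rng = np.random.default_rng(cfg.seed)
        lo, hi = cfg.grid_cells_per_county
        self._rects: dict[str, tuple[int, int, int, int]] = {}  # row0, col0, h, w
        self.polygons: dict[str, sgeom.Polygon] = {}
        for i, cid in enumerate(self.county_ids):
            r, q = divmod(i, k)
            h = int(rng.integers(lo, hi + 1))
            w = int(rng.integers(lo, hi + 1))
            r0 = r * self._tile + self._margin
            c0 = q * self._tile + self._margin
            self._rects[cid] = (r0, c0, h, w)
            x0, ytop = self.fine_origin
            cx = x0 + c0 * cfg.fine_cell
            cy = ytop - r0 * cfg.fine_cell
            self.polygons[cid] = sgeom.box(cx, cy - h * cfg.fine_cell,
                                           cx + w * cfg.fine_cell, cy)

        # ---- latents and truth
        ph = cfg.phenology
        rows = []
        self._latents: dict[tuple[str, int], tuple[float, float, float, float]] = {}
        for y in cfg.years:
            for cid in self.county_ids:
                g = 1.0 + ph.greenness_sd * rng.standard_normal()
                h_anom = cfg.heat_anomaly_sd * rng.standard_normal()
                jit_on = ph.timing_jitter_sd * rng.standard_normal()
                jit_off = ph.timing_jitter_sd * rng.standard_normal()
                self._latents[(cid, y)] = (g, h_anom, jit_on, jit_off)
                mids = self._period_mid_doys(y)
                curve_sum = float(np.sum(double_logistic(
                    mids, ph.green_up_day + jit_on, ph.senescence_day + jit_off,
                    ph.slope_on, ph.slope_off)))
                G = g * curve_sum
                S = max(h_anom, 0.0)
                eps = cfg.noise.county_yield_sd * rng.standard_normal()
                rows.append((cid, y, G, S, eps,
                             float(cfg.yield_link.apply(G, S)) + eps))
        self.truth = pd.DataFrame(
            rows, columns=["county_id", "year", "greenness", "stress", "noise", "yield_kg_ha"]
        )
        self.yields = self.truth[["county_id", "year", "yield_kg_ha"]].copy()

        # ---- annual crop masks (fine grid)
        self._masks: dict[int, np.ndarray] = {}
        zero_crop = set(self.county_ids[n - cfg.n_zero_crop_counties:]) if cfg.n_zero_crop_counties else set()
        self.zero_crop_counties = sorted(zero_crop)
        for y in cfg.years:
            m = np.zeros(self.fine_shape, dtype=np.uint8)
            for cid, (r0, c0, hh, ww) in self._rects.items():
                if cid in zero_crop:
                    continue
                patch = rng.random((hh, ww)) < cfg.crop_fraction
                if not patch.any():  # crop_fraction > 0 guarantees crop presence
                    patch[hh // 2, ww // 2] = True
                m[r0:r0 + hh, c0:c0 + ww] = patch
            self._masks[y] = m

    # ------------------------------------------------------------------
    def _period_mid_doys(self, year: int) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e in self.calendars[year].periods])

    def _band_index(self, name: str) -> int:
        return [b.name for b in self.bands].index(name)

    def _noise_rng(self, name: str, year: int) -> np.random.Generator:
        return np.random.default_rng([self.config.seed % (2**31), year, self._band_index(name), 911])

    def _county_field(self, year: int, values: dict[str, float], coarse: bool) -> np.ndarray:
        """Piecewise-constant field: per-county value inside its rectangle."""
        shape = self.coarse_shape if coarse else self.fine_shape
        f = self.config.coarse_factor if coarse else 1
        out = np.zeros(shape, dtype=np.float64)
        for cid, (r0, c0, hh, ww) in self._rects.items():
            sl = (slice(r0 // f, -(-(r0 + hh) // f)), slice(c0 // f, -(-(c0 + ww) // f)))
            out[sl] = values[cid]
        return out

    def mask_raster(self, year: int) -> Raster:
        return Raster(self._masks[year], self.fine_origin, self.config.fine_cell)

    def composite_stack(self, band: str, year: int) -> np.ndarray:
        """(t, ny, nx) composite values of one 8-day band for one year."""
        cfg = self.config
        ph = cfg.phenology
        mids = self._period_mid_doys(year)
        rng = self._noise_rng(band, year)
        if band in _BAND_CURVES:
            base, amp = _BAND_CURVES[band]
            gs = {}
            dls = {}
            for cid in self.county_ids:
                g, _, jon, joff = self._latents[(cid, year)]
                gs[cid] = g
                dls[cid] = double_logistic(mids, ph.green_up_day + jon,
                                           ph.senescence_day + joff, ph.slope_on, ph.slope_off)
            gfield = self._county_field(year, gs, coarse=False)
            out = np.empty((len(mids),) + self.fine_shape, dtype=np.float32)
            for p in range(len(mids)):
                dlfield = self._county_field(year, {c: dls[c][p] for c in self.county_ids}, coarse=False)
                out[p] = base + amp * gfield * dlfield
            out += cfg.noise.reflectance_sd * rng.standard_normal(out.shape).astype(np.float32)
            return out
        if band in ("lst_day", "lst_night"):
            base, season_amp, h_coef = (
                (14200.0, 600.0, 150.0) if band == "lst_day" else (13600.0, 400.0, 80.0)
            )
            hfield = self._county_field(
                year, {c: self._latents[(c, year)][1] for c in self.county_ids}, coarse=True)
            out = np.empty((len(mids),) + self.coarse_shape, dtype=np.float32)
            for p, d in enumerate(mids):
                out[p] = base + season_amp * _seasonal(d) + h_coef * hfield
            out += cfg.noise.temperature_sd * rng.standard_normal(out.shape).astype(np.float32)
            return out
        raise KeyError(f"{band!r} is not an 8-day composite band")

    def daily_stack(self, band: str, year: int) -> np.ndarray:
        """(n_days, ny, nx) daily values of one weather band for one year."""
        cfg = self.config
        n_days = composite_calendar(year, (1, 1), (12, 31)).periods[-1][1]
        days = np.arange(1, n_days + 1, dtype=float)
        rng = self._noise_rng(band, year)
        hfield = self._county_field(
            year, {c: self._latents[(c, year)][1] for c in self.county_ids}, coarse=True)
        shape = (n_days,) + self.coarse_shape
        if band == "precipitation":
            # intermittent rain; hot anomalies dry the county out
            wet = rng.random(shape) < 0.35
            scale = np.clip(3.5 * (1.0 - 0.25 * hfield), 0.3, None)
            amounts = rng.exponential(1.0, shape).astype(np.float32) * scale.astype(np.float32)
            return np.where(wet, amounts, 0.0).astype(np.float32)
        if band == "vapor_pressure":
            season = _seasonal(days)[:, None, None].astype(np.float32)
            out = 1000.0 + 900.0 * season - 100.0 * hfield.astype(np.float32)
            out = out + cfg.noise.pressure_sd * rng.standard_normal(shape).astype(np.float32)
            return np.clip(out, 1.0, None)
        raise KeyError(f"{band!r} is not a daily band")

    def raster(self, band: str, year: int, period: int) -> Raster:
        """Single-period composite raster (weather bands: 8-day mean)."""
        spec = next(b for b in self.bands if b.name == band)
        if spec.cadence == "daily":
            arr = self.daily_stack(band, year)
            s, e = self.calendars[year].periods[period]
            data = arr[s - 1:e].mean(axis=0)
            return Raster(data, self.fine_origin, self.coarse_cell)
        data = self.composite_stack(band, year)[period]
        cell = self.config.fine_cell if band in _BAND_CURVES else self.coarse_cell
        return Raster(data, self.fine_origin, cell)

    # ------------------------------------------------------------------
    def write(self, out_dir: str | Path) -> None:
        """Write GeoTIFF rasters, GeoJSON polygons and CSV tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for y in self.config.years:
            for band in [b.name for b in self.bands]:
                cal = self.calendars[y]
                for p in range(len(cal)):
                    write_geotiff(out / f"{band}_{y}_{p:02d}.tif", self.raster(band, y, p))
            write_geotiff(out / f"crop_mask_{y}.tif", self.mask_raster(y))
        write_county_polygons(out / "counties.geojson", self.polygons)
        yields = self.yields.copy()
        yields["unit"] = "kg/ha"
        yields.rename(columns={"yield_kg_ha": "yield"}).to_csv(out / "yields.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def simulate_region(config: SimConfig) -> RegionArchive:
    """Generate a synthetic archive; ``n_counties == 0`` gives empty outputs."""
    return RegionArchive(config)


def degenerate_county(config: SimConfig, county_id: str = "C000") -> CountyScene:
    """A county-year scene with zero crop pixels in every band and period —
    the fixture for the no-crop-pixels exclusion rule."""
    year = config.years[0] if config.years else 2003
    cal = composite_calendar(year, *config.season)
    empty = [np.empty(0) for _ in range(len(cal))]
    return CountyScene(county_id, year, {b.name: list(empty) for b in default_bands()})
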
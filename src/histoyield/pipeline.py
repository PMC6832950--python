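"""End-to-end tensorization of a region archive.

Glues the stages together: per county-year, select masked cells once per
grid, slice every composite period, aggregate daily weather to the 8-day
calendar, histogram each (period, band) and join yields.  Works on the
in-memory synthetic archive and on directories of GeoTIFFs alike.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .bands import BandSpec, default_bands
from .calendar import CompositeCalendar
from .geo import Raster, read_geotiff, read_county_polygons
from .simulate import RegionArchive
from .tensorize import (CountyScene, DropReport, HistogramTensor, TensorDataset,
                        YieldRecord, aggregate_daily, assemble_dataset,
                        build_tensor, county_cell_selection)

__all__ = ["extract_scene", "tensorize_archive", "tensorize_rasters"]


def _scene_from_stacks(
    county_id: str,
    year: int,
    stacks: dict[str, np.ndarray],  # band -> (t, ny, nx) per-period values
    selections: dict[str, np.ndarray],  # band -> boolean cell selection
    calendar: CompositeCalendar,
    bands: list[BandSpec],
) -> CountyScene:
    pixels: dict[str, list[np.ndarray]] = {}
    for spec in bands:
        sel = selections[spec.name]
        arr = stacks[spec.name]
        per_period = []
        for p in range(len(calendar)):
            vals = arr[p][sel]
            per_period.append(vals[~np.isnan(vals)].astype(np.float64))
        pixels[spec.name] = per_period
    return CountyScene(county_id, year, pixels)


def extract_scene(archive: RegionArchive, county_id: str, year: int,
                  bands: list[BandSpec] | None = None) -> CountyScene:
    """Masked pixel collections for one county-year of a synthetic archive."""
    bands = bands if bands is not None else archive.bands
    cal = archive.calendars[year]
    stacks, selections = _archive_stacks(archive, year, bands, [county_id])
    return _scene_from_stacks(county_id, year, stacks, selections[county_id], cal, bands)


def _archive_stacks(archive: RegionArchive, year: int, bands: list[BandSpec],
                    county_ids: list[str]):
    """Per-band period stacks plus per-county masked-cell selections."""
    cal = archive.calendars[year]
    mask = archive.mask_raster(year)
    stacks: dict[str, np.ndarray] = {}
    grids: dict[str, Raster] = {}
    for spec in bands:
        if spec.cadence == "daily":
            daily = archive.daily_stack(spec.name, year)
            t = len(cal)
            # aggregate every cell's daily series to the composite calendar
            flat = daily.reshape(daily.shape[0], -1)
            agg = np.empty((t, flat.shape[1]))
            for p, (s, e) in enumerate(cal.periods):
                agg[p] = flat[s - 1:e].mean(axis=0)
            stacks[spec.name] = agg.reshape((t,) + daily.shape[1:])
            grids[spec.name] = Raster(daily[0], archive.fine_origin, archive.coarse_cell)
        else:
            arr = archive.composite_stack(spec.name, year)
            stacks[spec.name] = arr
            cell = archive.config.fine_cell if arr.shape[1:] == archive.fine_shape else archive.coarse_cell
            grids[spec.name] = Raster(arr[0], archive.fine_origin, cell)
    selections: dict[str, dict[str, np.ndarray]] = {}
    for cid in county_ids:
        poly = archive.polygons[cid]
        sel_by_grid: dict[float, np.ndarray] = {}
        per_band = {}
        for spec in bands:
            grid = grids[spec.name]
            if grid.cell not in sel_by_grid:
                sel_by_grid[grid.cell] = county_cell_selection(grid, mask, poly)
            per_band[spec.name] = sel_by_grid[grid.cell]
        selections[cid] = per_band
    return stacks, selections


def tensorize_archive(
    archive: RegionArchive,
    bands: list[BandSpec] | None = None,
    unit: str = "kg/ha",
    yields: list[YieldRecord] | None = None,
) -> tuple[TensorDataset, DropReport]:
    """Histogram-tensorize every county-year of an archive and join labels.

    ``yields`` defaults to the archive's own yield table; passing a subset
    exercises the no-label exclusion rule.
    """
    bands = bands if bands is not None else archive.bands
    if yields is None:
        yields = [YieldRecord(r.county_id, int(r.year), float(r.yield_kg_ha))
                  for r in archive.yields.itertuples()]
    tensors: list[HistogramTensor] = []
    for year in archive.config.years:
        cal = archive.calendars[year]
        stacks, selections = _archive_stacks(archive, year, bands, archive.county_ids)
        for cid in archive.county_ids:
            scene = _scene_from_stacks(cid, year, stacks, selections[cid], cal, bands)
            tensors.append(build_tensor(scene, bands, cal))
    return assemble_dataset(tensors, yields, bands, unit=unit)


def tensorize_rasters(
    raster_dir: str | Path,
    counties_path: str | Path,
    yields: list[YieldRecord],
    years: list[int],
    calendars: dict[int, CompositeCalendar],
    bands: list[BandSpec] | None = None,
    unit: str = "kg/ha",
) -> tuple[TensorDataset, DropReport]:
    """File-based tensorization: reads `{band}_{year}_{period:02d}.tif` plus
    `crop_mask_{year}.tif` from a directory and county polygons from GeoJSON."""
    bands = bands if bands is not None else default_bands()
    raster_dir = Path(raster_dir)
    polygons = read_county_polygons(counties_path)
    tensors: list[HistogramTensor] = []
    for year in years:
        cal = calendars[year]
        mask = read_geotiff(raster_dir / f"crop_mask_{year}.tif")
        stacks: dict[str, np.ndarray] = {}
        grids: dict[str, Raster] = {}
        for spec in bands:
            per = [read_geotiff(raster_dir / f"{spec.name}_{year}_{p:02d}.tif")
                   for p in range(len(cal))]
            stacks[spec.name] = np.stack([r.data for r in per]).astype(np.float64)
            grids[spec.name] = per[0]
        for cid, poly in polygons.items():
            sel_by_cell: dict[float, np.ndarray] = {}
            per_band = {}
            for spec in bands:
                g = grids[spec.name]
                if g.cell not in sel_by_cell:
                    sel_by_cell[g.cell] = county_cell_selection(g, mask, poly)
                per_band[spec.name] = sel_by_cell[g.cell]
            scene = _scene_from_stacks(cid, year, stacks, per_band, cal, bands)
            tensors.append(build_tensor(scene, bands, cal))
    return assemble_dataset(tensors, yields, bands, unit=unit)
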
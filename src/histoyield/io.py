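"""Tabular and container I/O: yield tables, tensor stores, run configs.

The tensor store is a single HDF5 file per dataset holding the stacked
tensors with county ids, years, labels, the composite calendar and the
band order; a version attribute guards against silently reading a
container written by an incompatible layout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bands import BandSpec, default_bands
from .calendar import CompositeCalendar
from .tensorize import HistogramTensor, TensorDataset, YieldRecord, convert_yield

__all__ = ["read_yield_table", "write_tensors", "read_tensors", "RunConfig"]

STORE_VERSION = 1
_REQUIRED_COLS = ("county_id", "year", "yield")


def read_yield_table(path: str | Path, unit: str | None = None) -> list[YieldRecord]:
    """Read a county-year yield CSV and convert to kg/ha.

    Columns: county_id, year, yield and optionally unit ('kg/ha' or
    'bu/ac'); an explicit ``unit`` argument overrides the column.  Rows
    with missing columns, non-positive yields or duplicate (county, year)
    keys raise with the offending row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    seen: set[tuple[str, int]] = set()
    records: list[YieldRecord] = []
    has_unit = "unit" in df.columns
    for pos in range(len(df)):  # row numbers are 1-based and skip the header
        row = df.iloc[pos]
        i = pos + 2
        row_unit = unit if unit is not None else (row["unit"] if has_unit else "kg/ha")
        value = row["yield"]
        if pd.isna(value) or float(value) <= 0:
            raise ValueError(f"{path} row {i}: yield must be positive, got {value!r}")
        key = (str(row["county_id"]), int(row["year"]))
        if key in seen:
            raise ValueError(f"{path} row {i}: duplicate (county, year) {key}")
        seen.add(key)
        records.append(YieldRecord(key[0], key[1], convert_yield(float(value), row_unit)))
    return records


def _calendar_to_json(cal: CompositeCalendar) -> str:
    return json.dumps({"year": cal.year, "periods": list(map(list, cal.periods)),
                       "season": list(cal.season)})


def _calendar_from_json(s: str) -> CompositeCalendar:
    d = json.loads(s)
    return CompositeCalendar(d["year"], tuple(map(tuple, d["periods"])), tuple(d["season"]))


def write_tensors(path: str | Path, dataset: TensorDataset) -> None:
    """Write a labelled tensor dataset to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = STORE_VERSION
        f.attrs["band_order"] = json.dumps(list(dataset.band_order))
        f.attrs["groups"] = json.dumps(dataset.groups)
        if len(dataset):
            X = np.stack([t.values for t in dataset.tensors])
            f.create_dataset("values", data=X, compression="gzip", compression_opts=4)
            f.create_dataset("county_id",
                             data=np.array([r.county_id for r in dataset.records], dtype="S32"))
            f.create_dataset("year", data=np.array([r.year for r in dataset.records]))
            f.create_dataset("yield_kg_ha",
                             data=np.array([r.yield_kg_ha for r in dataset.records]))
            f.attrs["calendars"] = json.dumps(
                {str(t.calendar.year): json.loads(_calendar_to_json(t.calendar))
                 for t in dataset.tensors})


def read_tensors(path: str | Path) -> TensorDataset:
    """Read a tensor dataset; bit-exact round trip of :func:`write_tensors`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != STORE_VERSION:
            raise ValueError(f"{path}: tensor store version {version!r}, expected {STORE_VERSION}")
        band_order = tuple(json.loads(f.attrs["band_order"]))
        groups = json.loads(f.attrs["groups"])
        if "values" not in f:
            return TensorDataset([], [], band_order, groups)
        X = f["values"][...]
        cids = [c.decode() for c in f["county_id"][...]]
        years = f["year"][...].astype(int)
        yields = f["yield_kg_ha"][...]
        calendars = {int(k): CompositeCalendar(v["year"], tuple(map(tuple, v["periods"])),
                                               tuple(v["season"]))
                     for k, v in json.loads(f.attrs["calendars"]).items()}
    tensors, records = [], []
    for i in range(len(X)):
        cal = calendars[int(years[i])]
        tensors.append(HistogramTensor(cids[i], int(years[i]), X[i], cal, band_order))
        records.append(YieldRecord(cids[i], int(years[i]), float(yields[i])))
    return TensorDataset(tensors, records, band_order, groups)


@dataclass
class RunConfig:
    """Run configuration: paths, season, nodes, model settings, seeds.

    Round-trips losslessly through YAML; CLI flags override file values,
    which override the defaults here.
    """

    rasters: str = "rasters"
    counties: str = "counties.geojson"
    yields: str = "yields.csv"
    out: str = "out"
    unit: str = "kg/ha"
    season: tuple[tuple[int, int], tuple[int, int]] = ((4, 1), (12, 31))
    nodes: tuple[str, ...] = ("DEC-27",)
    architecture: str = "cnn_lstm"
    epochs: int = 100
    batch_size: int = 16
    seeds: tuple[int, ...] = (0,)
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        # normalise YAML lists back to tuples for lossless round trips
        cfg.season = tuple(tuple(p) for p in cfg.season)
        cfg.nodes = tuple(cfg.nodes)
        cfg.seeds = tuple(cfg.seeds)
        return cfg
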
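"""Rolling-origin evaluation, metrics, model comparison and ablation.

The forecast protocol: to predict year y at a time node d, train only on
years before y with all tensors truncated at d, then predict every
labelled county of year y.  Repeating over evaluation years gives
per-year RMSE / R-squared / per-county percent error and a five-year (or
k-year) average — the quantity models are compared on.

R-squared here is the squared Pearson correlation between predicted and
observed yields (how well predictions reconstruct the spatial ranking),
switchable to the 1 - SSE/SST definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import ENVIRONMENT_GROUPS, REFLECTANCE_GROUP
from .calendar import TimeNode
from .nn.networks import ModelConfig
from .nn.training import predict as _predict
from .nn.training import train as _train
from .tensorize import TensorDataset

__all__ = ["rmse", "percent_error", "r_squared", "YearResult", "EvalReport",
           "rolling_origin", "mean_baseline_report", "compare_models", "ablation",
           "feature_group_bands"]


def rmse(predicted, observed) -> float:
    """Root-mean-squared error (same units as the inputs, kg/ha here)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError(f"need equal non-empty lengths, got {p.shape} vs {o.shape}")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def percent_error(predicted, observed):
    """Signed percent error per sample: 100 * (pred - obs) / obs."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    if np.any(o == 0):
        raise ValueError("observed yield of 0 has no percent error")
    return 100.0 * (p - o) / o


def r_squared(predicted, observed, definition: str = "correlation") -> float:
    """R^2 between predictions and observations.

    ``correlation``: squared Pearson correlation (affine-invariant).
    ``variance_explained``: 1 - SSE/SST.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("need at least 2 paired samples")
    if np.var(o) == 0:
        raise ValueError("observed values have zero variance")
    if definition == "correlation":
        if np.var(p) == 0:
            return 0.0
        r = np.corrcoef(p, o)[0, 1]
        return float(r * r)
    if definition == "variance_explained":
        return float(1.0 - np.sum((o - p) ** 2) / np.sum((o - o.mean()) ** 2))
    raise ValueError(f"unknown R^2 definition {definition!r}")


@dataclass
class YearResult:
    year: int
    rmse: float
    r2: float
    pe: pd.DataFrame  # columns: county_id, observed, predicted, pe_percent


@dataclass
class EvalReport:
    """Per-year and averaged metrics for one (model, time node) pair."""

    model: str
    node: str
    years: list[YearResult]

    @property
    def avg_rmse(self) -> float:
        return float(np.mean([y.rmse for y in self.years]))

    @property
    def avg_r2(self) -> float:
        return float(np.mean([y.r2 for y in self.years]))

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.model, self.node, y.year, y.rmse, y.r2) for y in self.years]
        rows.append((self.model, self.node, "avg", self.avg_rmse, self.avg_r2))
        return pd.DataFrame(rows, columns=["model", "node", "year", "rmse", "r2"])


def _check_disjoint(train_ds: TensorDataset, eval_ds: TensorDataset) -> None:
    tr = {(r.county_id, r.year) for r in train_ds.records}
    ev = {(r.county_id, r.year) for r in eval_ds.records}
    if tr & ev:
        raise AssertionError(f"evaluation leaked into training: {sorted(tr & ev)[:3]}")


def rolling_origin(
    dataset: TensorDataset,
    eval_years: list[int],
    node: TimeNode,
    config: ModelConfig,
    model_label: str | None = None,
) -> EvalReport:
    """Train-before / predict-after evaluation for one architecture at one
    time node.  Every evaluation year gets its own freshly trained model."""
    truncated = dataset.truncate(node)
    results = []
    for year in sorted(eval_years):
        train_ds = truncated.filter_years(lambda y: y < year)
        eval_ds = truncated.filter_years(lambda y: y == year)
        if len(train_ds) == 0:
            raise ValueError(f"no training years precede evaluation year {year}")
        if len(eval_ds) == 0:
            raise ValueError(f"evaluation year {year} has no labelled counties")
        _check_disjoint(train_ds, eval_ds)
        model = _train(train_ds, config)
        pred = _predict(model, eval_ds)
        obs = np.array([r.yield_kg_ha for r in eval_ds.records])
        pe = pd.DataFrame({
            "county_id": [r.county_id for r in eval_ds.records],
            "observed": obs,
            "predicted": pred,
            "pe_percent": percent_error(pred, obs),
        })
        results.append(YearResult(year, rmse(pred, obs), r_squared(pred, obs), pe))
    return EvalReport(model_label or config.architecture, node.label, results)


def mean_baseline_report(dataset: TensorDataset, eval_years: list[int],
                         node: TimeNode) -> EvalReport:
    """Predict every county of the evaluation year with the mean training
    yield — the no-skill reference."""
    results = []
    for year in sorted(eval_years):
        train_ds = dataset.filter_years(lambda y: y < year)
        eval_ds = dataset.filter_years(lambda y: y == year)
        if len(train_ds) == 0 or len(eval_ds) == 0:
            raise ValueError(f"evaluation year {year} lacks training or evaluation data")
        mean_yield = float(np.mean([r.yield_kg_ha for r in train_ds.records]))
        obs = np.array([r.yield_kg_ha for r in eval_ds.records])
        pred = np.full_like(obs, mean_yield)
        pe = pd.DataFrame({
            "county_id": [r.county_id for r in eval_ds.records],
            "observed": obs, "predicted": pred,
            "pe_percent": percent_error(pred, obs),
        })
        results.append(YearResult(year, rmse(pred, obs), float("nan"), pe))
    return EvalReport("training_mean", node.label, results)


def compare_models(reports: dict[str, EvalReport], reference: str = "cnn_lstm") -> pd.DataFrame:
    """Percent RMSE reduction of the reference model against each baseline:
    100 * (baseline_avg - reference_avg) / baseline_avg."""
    ref = reports[reference]
    years = [y.year for y in ref.years]
    rows = []
    for name, rep in reports.items():
        if [y.year for y in rep.years] != years:
            raise ValueError(f"report {name!r} covers different years than {reference!r}")
        if rep.node != ref.node:
            raise ValueError(f"report {name!r} is for node {rep.node}, expected {ref.node}")
        if name == reference:
            continue
        rows.append({
            "baseline": name,
            "baseline_avg_rmse": rep.avg_rmse,
            f"{reference}_avg_rmse": ref.avg_rmse,
            "rmse_reduction_percent": 100.0 * (rep.avg_rmse - ref.avg_rmse) / rep.avg_rmse,
        })
    return pd.DataFrame(rows)


def feature_group_bands(dataset: TensorDataset, group: str) -> list[str]:
    """Band names of a feature group: 'reflectance' (7 optical bands) or
    'environment' (2 temperature + 2 weather bands)."""
    if group == REFLECTANCE_GROUP:
        return [n for n in dataset.band_order if dataset.groups[n] == REFLECTANCE_GROUP]
    if group == "environment":
        return [n for n in dataset.band_order if dataset.groups[n] in ENVIRONMENT_GROUPS]
    raise ValueError(f"unknown feature group {group!r}")


def ablation(
    dataset: TensorDataset,
    eval_years: list[int],
    node: TimeNode,
    config: ModelConfig,
    groups: tuple[str, str] = ("reflectance", "environment"),
) -> dict[str, EvalReport]:
    """Retrain with one feature family at a time and evaluate side by side
    (drop-one-group feature importance)."""
    out = {}
    for group in groups:
        names = feature_group_bands(dataset, group)
        if not names:
            raise ValueError(f"feature group {group!r} selects no bands")
        sub = dataset.restrict_bands(names)
        out[group] = rolling_origin(sub, eval_years, node, config,
                                    model_label=f"{config.architecture}[{group}]")
    return out
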
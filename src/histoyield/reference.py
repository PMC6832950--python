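"""Published benchmark results of the original CONUS soybean evaluation.

The method was developed on 2003-2015 MODIS/Daymet data over 15 U.S.
soybean states, with rolling-origin evaluation over 2011-2015.  The
tables below are the reported per-year RMSE values (kg/ha) for the three
architectures, end-of-season (DEC-27) and at each in-season time node.
They are shipped so users can place their own runs next to the reported
numbers and so the comparison arithmetic (average rows, percent RMSE
reductions between architectures, in-season increments) can be
recomputed from first principles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "END_OF_SEASON_RMSE",
    "IN_SEASON_RMSE",
    "NODE_LABELS",
    "EVAL_YEARS",
    "end_of_season_table",
    "in_season_table",
    "reported_avg_rmse",
    "node_column_mean",
    "rmse_reduction_percent",
    "in_season_increment_percent",
]

EVAL_YEARS = (2011, 2012, 2013, 2014, 2015)

NODE_LABELS = ("JUN-2", "JUL-4", "AUG-5", "AUG-13", "AUG-21", "AUG-29",
               "SEP-14", "OCT-16", "NOV-17", "DEC-27")

#: end-of-season RMSE (kg/ha) per year and model
END_OF_SEASON_RMSE: dict[str, tuple[float, ...]] = {
    "cnn": (337.60, 345.67, 357.10, 351.72, 404.85),
    "lstm": (372.57, 384.67, 359.12, 357.10, 341.63),
    "cnn_lstm": (312.72, 349.03, 338.27, 307.34, 338.94),
}

#: reported five-year average RMSE per model (end of season)
REPORTED_AVG_RMSE = {"cnn": 359.12, "lstm": 363.15, "cnn_lstm": 329.53}

#: in-season RMSE (kg/ha): model -> year -> value per node (NODE_LABELS order)
IN_SEASON_RMSE: dict[str, dict[int, tuple[float, ...]]] = {
    "cnn": {
        2011: (558.85, 526.57, 395.44, 434.44, 408.89, 355.76, 347.01, 346.34, 334.91, 337.60),
        2012: (599.21, 560.20, 471.43, 371.90, 386.69, 370.55, 350.38, 353.74, 363.15, 345.67),
        2013: (507.74, 455.29, 453.94, 397.45, 355.08, 351.72, 342.31, 321.46, 341.63, 357.10),
        2014: (504.38, 480.17, 412.92, 381.98, 349.03, 346.34, 343.65, 319.44, 323.48, 351.72),
        2015: (563.56, 494.97, 440.49, 384.00, 373.24, 363.83, 423.68, 400.82, 410.90, 404.85),
    },
    "lstm": {
        2011: (538.68, 497.66, 405.52, 411.58, 412.92, 393.42, 379.97, 391.40, 375.93, 372.57),
        2012: (618.04, 594.50, 509.09, 442.51, 418.30, 412.92, 374.59, 415.61, 375.93, 384.67),
        2013: (524.56, 429.06, 390.73, 386.02, 367.19, 340.29, 332.89, 373.91, 338.94, 359.12),
        2014: (468.74, 430.41, 365.17, 361.81, 357.77, 322.80, 357.77, 322.13, 340.29, 357.10),
        2015: (501.02, 492.28, 433.10, 357.77, 396.78, 393.42, 341.63, 377.95, 334.24, 341.63),
    },
    "cnn_lstm": {
        2011: (511.11, 484.21, 388.71, 396.11, 351.72, 340.96, 342.31, 348.36, 335.58, 312.72),
        2012: (597.86, 574.99, 449.91, 435.11, 377.28, 359.79, 343.65, 353.74, 347.01, 349.03),
        2013: (496.98, 445.87, 385.35, 358.45, 337.60, 347.01, 320.79, 305.32, 316.75, 338.27),
        2014: (464.03, 435.11, 377.95, 343.65, 321.46, 311.37, 305.32, 298.59, 305.99, 307.34),
        2015: (494.29, 459.32, 400.14, 393.42, 379.97, 389.38, 379.97, 340.96, 412.92, 338.94),
    },
}

#: reported five-year average RMSE of the full model at AUG-21 (the earliest
#: node whose accuracy was judged comparable to end of season)
REPORTED_AUG21_CNN_LSTM_AVG = 353.74


def end_of_season_table() -> pd.DataFrame:
    """Per-year end-of-season RMSE with the average row appended."""
    df = pd.DataFrame(END_OF_SEASON_RMSE, index=list(EVAL_YEARS))
    df.loc["avg"] = df.mean()
    return df


def in_season_table(model: str) -> pd.DataFrame:
    """Per-year in-season RMSE of one model, columns = time nodes."""
    data = IN_SEASON_RMSE[model]
    return pd.DataFrame([data[y] for y in EVAL_YEARS],
                        index=list(EVAL_YEARS), columns=list(NODE_LABELS))


def reported_avg_rmse(model: str) -> float:
    return REPORTED_AVG_RMSE[model]


def node_column_mean(model: str, node: str) -> float:
    """Five-year mean RMSE of one model at one time node, recomputed from
    the per-year table."""
    col = in_season_table(model)[node]
    return float(np.mean(col))


def rmse_reduction_percent(baseline_avg: float, model_avg: float) -> float:
    """Percent RMSE reduction of a model relative to a baseline."""
    return 100.0 * (baseline_avg - model_avg) / baseline_avg


def in_season_increment_percent(in_season_avg: float, end_of_season_avg: float) -> float:
    """Percent RMSE increase of an in-season forecast over end of season."""
    return 100.0 * (in_season_avg - end_of_season_avg) / end_of_season_avg
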
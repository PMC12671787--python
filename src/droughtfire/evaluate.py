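"""Observed fire-occurrence probability and probability-forecast scoring.

The observed fire probability (FP) of a grid cell over a period is the
fraction of years with at least one fire record falling in the cell.
Model skill is scored on a held-out period with

* AUC — area under the ROC curve, computed from the Mann-Whitney U statistic
  with midrank tie handling, plus its normal-approximation p-value,
* Brier score — mean squared difference between forecast probability and the
  binary outcome,
* the training model's AICc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .synthetic import GridSpec

logger = logging.getLogger(__name__)

__all__ = ["load_fire_records", "estimate_fp", "roc_auc", "brier",
           "EvalReport", "evaluate_holdout"]


def load_fire_records(path) -> pd.DataFrame:
    """Read a fire-record CSV (lon, lat, year[, month, day]), dropping and
    counting records without coordinates."""
    records = pd.read_csv(path)
    n0 = len(records)
    records = records.dropna(subset=["lon", "lat"]).reset_index(drop=True)
    dropped = n0 - len(records)
    if dropped:
        logger.info("dropped %d fire records without coordinates", dropped)
    records.attrs["n_dropped_no_coords"] = dropped
    return records


def _bin_records(records: pd.DataFrame, grid: GridSpec) -> tuple[np.ndarray, int]:
    """Cell index per record using half-open cells [west, east) x [south, north);
    returns (cell ids with -1 for out-of-grid, dropped count)."""
    ix = np.floor((records["lon"].to_numpy(float) - grid.lon0) / grid.cell_size).astype(int)
    iy = np.floor((records["lat"].to_numpy(float) - grid.lat0) / grid.cell_size).astype(int)
    inside = (ix >= 0) & (ix < grid.n_lon) & (iy >= 0) & (iy < grid.n_lat)
    cell = np.where(inside, ix * grid.n_lat + iy, -1)
    return cell, int((~inside).sum())


def estimate_fp(records: pd.DataFrame, grid: GridSpec, years) -> pd.DataFrame:
    """Observed FP per cell: years with >= 1 fire divided by period length.

    ``years`` is the iterable of years making up the period; records outside
    it or outside the grid extent are dropped (counted in
    ``result.attrs['n_dropped_outside']``).
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("period is empty")
    cell, n_outside = _bin_records(records, grid)
    keep = (cell >= 0) & records["year"].isin(years).to_numpy()
    if n_outside:
        logger.info("dropped %d fire records outside the grid extent", n_outside)
    pairs = set(zip(cell[keep], records.loc[keep, "year"]))
    n_fire_years = np.zeros(grid.n_cells, dtype=int)
    for c, _ in pairs:
        n_fire_years[c] += 1
    out = pd.DataFrame({
        "cell_id": grid.cells["cell_id"].to_numpy(),
        "n_years": len(years),
        "n_fire_years": n_fire_years,
        "fp": n_fire_years / len(years),
    })
    out.attrs["n_dropped_outside"] = n_outside
    return out


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUC from the Mann-Whitney U statistic (midrank ties) and its
    normal-approximation two-sided p-value."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must be aligned")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute AUC")
    res = mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (pos.size * neg.size)
    return auc, float(res.pvalue)


def brier(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Mean squared difference between forecast probability and binary outcome."""
    p = np.asarray(probabilities, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if p.shape != o.shape:
        raise ValueError("probabilities and outcomes must be aligned")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - o) ** 2))


@dataclass(frozen=True)
class EvalReport:
    auc: float | None
    p_value: float | None
    brier: float
    aicc: float
    train_period: tuple[int, int]
    test_period: tuple[int, int]
    note: str = ""


def evaluate_holdout(
    predicted_fp: np.ndarray,
    model_aicc: float,
    records: pd.DataFrame,
    grid: GridSpec,
    train_period: tuple[int, int],
    test_period: tuple[int, int],
) -> EvalReport:
    """Score train-period model probabilities against held-out fire years.

    The test label of a cell is binary: at least one fire inside it during
    the (short) test window.  If the test labels are degenerate (all one
    class), AUC is omitted from the report with a reason, and only the Brier
    score and training AICc are kept.
    """
    if not (train_period[1] < test_period[0] or test_period[1] < train_period[0]):
        raise ValueError("train and test periods must be disjoint")
    test_years = range(test_period[0], test_period[1] + 1)
    fp_test = estimate_fp(records, grid, test_years)
    labels = (fp_test["n_fire_years"].to_numpy() > 0).astype(int)
    predicted_fp = np.asarray(predicted_fp, dtype=float)
    b = brier(predicted_fp, labels)
    if labels.min() == labels.max():
        return EvalReport(auc=None, p_value=None, brier=b, aicc=model_aicc,
                          train_period=train_period, test_period=test_period,
                          note="degenerate test labels: AUC omitted")
    auc, p = roc_auc(labels, predicted_fp)
    return EvalReport(auc=auc, p_value=p, brier=b, aicc=model_aicc,
                      train_period=train_period, test_period=test_period)
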
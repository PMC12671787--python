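"""Future projection: ensemble averaging, model application, regional deltas.

Fitted models are applied to future drought characteristics per climate
scenario and period: future MDN/MDD/MDS/MDI are projected through the
*historical* PCA and min-max parameters (so the component space and predictor
scale are frozen at the training fit), static covariates are held at their
historical values, and the local logistic coefficients give a future fire
probability per cell.  Changes are summarized per region over forest-masked
cells, in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import MinMaxNormalizer, PcaModel
from .gwlr import GwlrModel, GlrModel
from .synthetic import GridSpec

__all__ = ["ensemble_mean", "project_fp", "delta_fp", "ProjectionResult"]

_KEY = ["cell_id", "year", "month"]


def ensemble_mean(members: list[pd.DataFrame]) -> pd.DataFrame:
    """Multi-model ensemble: per-cell-per-month mean of tas and pr.

    All members must cover identical (cell, year, month) keys; a mismatched
    member is reported by its position and model tag.
    """
    if not members:
        raise ValueError("ensemble requires at least one member")
    ref = members[0].sort_values(_KEY).reset_index(drop=True)
    ref_key = ref[_KEY]
    tas = np.zeros(len(ref))
    pr = np.zeros(len(ref))
    for i, mem in enumerate(members):
        mem = mem.sort_values(_KEY).reset_index(drop=True)
        if len(mem) != len(ref) or not mem[_KEY].equals(ref_key):
            tag = mem["model"].iloc[0] if "model" in mem.columns and len(mem) else "?"
            raise ValueError(f"ensemble member {i} ('{tag}') grid/time coverage "
                             "differs from the first member")
        tas += mem["tas"].to_numpy(float)
        pr += mem["pr"].to_numpy(float)
    out = ref.copy()
    out["tas"] = tas / len(members)
    out["pr"] = pr / len(members)
    if "model" in out.columns:
        out["model"] = "MME"
    return out


def project_fp(
    model: GwlrModel | GlrModel,
    future_chars: pd.DataFrame,
    static_covariates: pd.DataFrame,
    pca: PcaModel,
    norm: MinMaxNormalizer,
) -> np.ndarray:
    """Future fire probability per cell from future drought characteristics.

    ``future_chars`` holds mdn/mdd/mds/mdi per cell (rows aligned with the
    model's calibration cells); ``static_covariates`` holds the historical
    static predictors in *unnormalized* units.  Both are pushed through the
    stored PCA and min-max parameters — identical inputs to the historical
    ones therefore reproduce the fitted historical probabilities exactly.
    """
    scores = pca.transform(future_chars)
    scores.index = static_covariates.index
    table = pd.concat([static_covariates, scores], axis=1)
    missing = set(norm.params) - set(table.columns)
    if missing:
        raise ValueError(f"normalization parameters cover absent variables: {sorted(missing)}")
    normed = norm.transform(table, clip=True)
    X = normed[model.predictors].to_numpy(dtype=float)
    return model.predict(X)


@dataclass(frozen=True)
class ProjectionResult:
    per_cell: pd.DataFrame       # cell_id, region, forest_fraction, fp_hist, fp_future, delta
    regional: pd.DataFrame       # region, n_cells, mean_delta_pp (percentage points)
    empty_regions: list[str]     # regions with no forest-masked cells


def delta_fp(
    fp_future: np.ndarray,
    fp_hist: np.ndarray,
    grid: GridSpec,
    forest_mask_threshold: float = 0.5,
) -> ProjectionResult:
    """Per-cell probability change and forest-masked regional means.

    Regional means are taken only over cells whose forest_fraction is at
    least ``forest_mask_threshold`` and are reported in percentage points;
    regions with no qualifying cell are flagged (NaN mean).
    """
    fp_future = np.asarray(fp_future, dtype=float)
    fp_hist = np.asarray(fp_hist, dtype=float)
    if fp_future.shape != fp_hist.shape or fp_future.shape != (grid.n_cells,):
        raise ValueError("probability arrays must align with the grid cells")
    per_cell = grid.cells[["cell_id", "region", "forest_fraction"]].copy()
    per_cell["fp_hist"] = fp_hist
    per_cell["fp_future"] = fp_future
    per_cell["delta"] = fp_future - fp_hist

    masked = per_cell[per_cell["forest_fraction"] >= forest_mask_threshold]
    rows = []
    empty = []
    for region in sorted(per_cell["region"].unique()):
        sub = masked[masked["region"] == region]
        if len(sub) == 0:
            empty.append(region)
            rows.append({"region": region, "n_cells": 0, "mean_delta_pp": np.nan})
        else:
            rows.append({"region": region, "n_cells": len(sub),
                         "mean_delta_pp": 100.0 * sub["delta"].mean()})
    return ProjectionResult(per_cell=per_cell, regional=pd.DataFrame(rows),
                            empty_regions=empty)
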
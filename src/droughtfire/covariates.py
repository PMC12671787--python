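"""Predictor assembly: terrain metrics, min-max normalization, VIF, PCA.

The four run-theory drought characteristics (MDN, MDD, MDS, MDI) are nearly
collinear (duration and severity especially), which destabilizes regression
coefficients.  The standard remedy used here is to replace them with the
leading principal components of their correlation matrix, retaining enough
components to explain at least 90% of the variance, and to carry the fitted
standardization and loading matrix forward so future-period characteristics
are projected into exactly the same component space.

All predictors (static covariates and PC scores alike) are min-max scaled to
[0, 1] on the training sample; stored parameters are reapplied, with
clipping, to future data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = ["surface_roughness", "network_density", "MinMaxNormalizer",
           "minmax_fit_apply", "vif", "PcaModel"]

DROUGHT_CHARS = ("mdn", "mdd", "mds", "mdi")


def surface_roughness(elevations: np.ndarray) -> float:
    """Terrain roughness R = Zmax - Zmin (m) over the elevation samples of a cell."""
    elev = np.asarray(elevations, dtype=float)
    if elev.size == 0:
        raise ValueError("surface_roughness needs at least one elevation sample")
    return float(np.max(elev) - np.min(elev))


def network_density(length_km: float, area_km2: float) -> float:
    """Road/river network density delta = L / F in km per km^2."""
    if area_km2 <= 0.0:
        raise ValueError(f"cell area must be positive, got {area_km2}")
    if length_km < 0.0:
        raise ValueError(f"network length must be non-negative, got {length_km}")
    return length_km / area_km2


@dataclass
class MinMaxNormalizer:
    """Per-variable min-max scaling x* = (x - xmin) / (xmax - xmin).

    Extremes come from the training (historical) sample; applying the stored
    parameters to future data clips the result to [0, 1] so the logistic
    linear predictor stays inside the trained domain.
    """

    params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def fit(self, table: pd.DataFrame, columns: list[str] | None = None) -> "MinMaxNormalizer":
        cols = columns if columns is not None else list(table.columns)
        for c in cols:
            x = table[c].to_numpy(dtype=float)
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                raise ValueError(f"variable '{c}' is constant; min-max undefined")
            self.params[c] = (lo, hi)
        return self

    def transform(self, table: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        out = table.copy()
        for c, (lo, hi) in self.params.items():
            if c not in out.columns:
                raise ValueError(f"variable '{c}' missing from table")
            x = (out[c].to_numpy(dtype=float) - lo) / (hi - lo)
            out[c] = np.clip(x, 0.0, 1.0) if clip else x
        return out

    def to_json(self) -> str:
        return json.dumps({"params": self.params}, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MinMaxNormalizer":
        data = json.loads(text)
        return cls(params={k: tuple(v) for k, v in data["params"].items()})


def minmax_fit_apply(
    x: np.ndarray,
    params: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Normalize one variable; fit extremes when ``params`` is None.

    With stored params, outputs are clipped to [0, 1] (future data may exceed
    the training extremes).
    """
    x = np.asarray(x, dtype=float)
    if params is None:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError("constant variable; min-max normalization undefined")
        return (x - lo) / (hi - lo), (lo, hi)
    lo, hi = params
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0), (lo, hi)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1 / (1 - R^2_j) per predictor.

    Each predictor is regressed (with intercept) on all the others.  Exact
    linear dependence is reported as ``inf`` rather than raising.  Values
    >= 10 signal severe multicollinearity.
    """
    cols = list(design.columns)
    n, p = design.shape
    if n < p + 2:
        raise ValueError(f"need >= {p + 2} rows for {p} predictors, got {n}")
    X = np.column_stack([np.ones(n), design.to_numpy(dtype=float)])
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, c in enumerate(cols):
            v = variance_inflation_factor(X, j + 1)
            out[c] = np.inf if (not np.isfinite(v) or v > 1e12) else float(v)
    return pd.Series(out, name="vif")


@dataclass
class PcaModel:
    """PCA of drought characteristics on the correlation matrix.

    Variables are standardized with the stored training means/SDs before
    projection, so future-period characteristics land in the same component
    space.  Loading columns are orthonormal eigenvectors sorted by
    decreasing variance; each column's largest-magnitude entry is made
    positive (eigenvector sign is arbitrary, so a fixed convention is used).
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (n_vars, n_vars), columns = components
    variance_proportion: np.ndarray  # percent, per component
    n_retained: int

    @classmethod
    def fit(cls, table: pd.DataFrame, variables: list[str] | None = None,
            cumulative_target: float = 90.0) -> "PcaModel":
        cols = variables if variables is not None else list(table.columns)
        if table.shape[0] < 5:
            raise ValueError("PCA needs at least 5 rows")
        X = table[cols].to_numpy(dtype=float)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0.0):
            bad = [c for c, s in zip(cols, sds) if s == 0.0]
            raise ValueError(f"constant variable(s) {bad}: PCA undefined")
        Z = (X - means) / sds
        corr = (Z.T @ Z) / (Z.shape[0] - 1)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        # sign convention: largest-|entry| of each column positive
        for j in range(eigvec.shape[1]):
            k = np.argmax(np.abs(eigvec[:, j]))
            if eigvec[k, j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        prop = 100.0 * eigval / eigval.sum()
        cum = np.cumsum(prop)
        n_retained = int(np.searchsorted(cum, cumulative_target) + 1)
        n_retained = min(n_retained, len(cols))
        return cls(variables=list(cols), means=means, sds=sds, loadings=eigvec,
                   variance_proportion=prop, n_retained=n_retained)

    def transform(self, table: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
        missing = set(self.variables) - set(table.columns)
        if missing:
            raise ValueError(f"variable mismatch: missing {sorted(missing)}")
        r = self.n_retained if n_components is None else n_components
        Z = (table[self.variables].to_numpy(dtype=float) - self.means) / self.sds
        scores = Z @ self.loadings[:, :r]
        return pd.DataFrame(scores, columns=[f"pc{j + 1}" for j in range(r)],
                            index=table.index)

    def inverse_transform_standardized(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct the standardized variables from full-rank scores."""
        return np.asarray(scores) @ self.loadings.T

    def to_json(self) -> str:
        return json.dumps({
            "variables": self.variables,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_proportion": self.variance_proportion.tolist(),
            "n_retained": self.n_retained,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        d = json.loads(text)
        return cls(variables=d["variables"], means=np.array(d["means"]),
                   sds=np.array(d["sds"]), loadings=np.array(d["loadings"]),
                   variance_proportion=np.array(d["variance_proportion"]),
                   n_retained=int(d["n_retained"]))
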
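"""Global and geographically weighted logistic regression (GLR / GWLR).

Fire occurrence probability per grid cell is modelled as binomial: the number
of fire-years out of the years observed, with logit link.  The global model
(GLR) has one coefficient vector; the geographically weighted model (GWLR)
refits the binomial likelihood at every location with observations
down-weighted by an adaptive bi-square kernel, yielding spatially varying
coefficient surfaces.  Bandwidth (a nearest-neighbour count) is selected by
minimizing the small-sample-corrected AIC (AICc), with the effective number
of parameters taken as the trace of the hat-like projection matrix of the
final IRLS step at each location (GWR4-style convention).

With all kernel weights forced to one, every local fit collapses onto the
global fit — the central correctness anchor, exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

__all__ = ["great_circle_distance", "pairwise_distances", "bisquare_weights",
           "aicc", "GlrModel", "GwlrModel", "fit_glr", "fit_gwlr",
           "select_bandwidth", "predict"]

EARTH_RADIUS_KM = 6371.0
_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 100
_RIDGE = 1e-8


def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine distance in km (Earth radius 6371 km).  Vectorized."""
    lat1a, lat2a = np.asarray(lat1, dtype=float), np.asarray(lat2, dtype=float)
    if np.any(np.abs(lat1a) > 90) or np.any(np.abs(lat2a) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.deg2rad(lat1a), np.deg2rad(lat2a)
    dphi = p2 - p1
    dlmb = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Symmetric great-circle distance matrix for an (m, 2) lon/lat array."""
    coords = np.asarray(coords, dtype=float)
    lon, lat = coords[:, 0], coords[:, 1]
    return great_circle_distance(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def bisquare_weights(distances: np.ndarray, bandwidth_neighbors: int) -> np.ndarray:
    """Adaptive bi-square kernel weights from a distance matrix.

    For each row i, the bandwidth b_i is the distance to its N-th nearest
    point (the point itself, at distance 0, counts as the first), and
    w_ij = (1 - (d_ij / b_i)^2)^2 for d_ij < b_i, else 0.  The diagonal is
    always 1.
    """
    d_in = np.asarray(distances, dtype=float)
    d = np.atleast_2d(d_in)
    m = d.shape[1]
    n = int(bandwidth_neighbors)
    if n < 2:
        raise ValueError(f"bandwidth must cover >= 2 neighbours, got {n}")
    if n > m:
        raise ValueError(f"bandwidth {n} exceeds sample size {m}")
    b = np.sort(d, axis=1)[:, n - 1]
    if np.any(b <= 0.0):
        raise ValueError("bandwidth distance is zero (duplicate coordinates?)")
    ratio = d / b[:, None]
    w = np.where(ratio < 1.0, (1.0 - ratio**2) ** 2, 0.0)
    return w[0] if d_in.ndim == 1 else w


def aicc(log_likelihood: float, k: float, m: int) -> tuple[float, float]:
    """AIC = -2 ln L + 2k and its small-sample correction AICc."""
    if m <= k + 1:
        raise ValueError(f"AICc requires m > k + 1 (m={m}, k={k})")
    aic = -2.0 * log_likelihood + 2.0 * k
    return aic, aic + 2.0 * k * (k + 1.0) / (m - k - 1.0)


def _binom_loglik(succ, trials, p):
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(gammaln(trials + 1) - gammaln(succ + 1)
                        - gammaln(trials - succ + 1)
                        + succ * np.log(p) + (trials - succ) * np.log(1.0 - p)))


def _irls(X1, succ, trials, obs_weights=None, tol=_IRLS_TOL,
          max_iter=_IRLS_MAX_ITER):
    """Weighted binomial IRLS on a design that already includes the intercept.

    ``obs_weights`` multiply each observation's likelihood contribution
    (kernel weights).  Returns (beta, converged, ridged, work_weights).
    """
    m, p1 = X1.shape
    w_obs = np.ones(m) if obs_weights is None else np.asarray(obs_weights, float)
    beta = np.zeros(p1)
    # start from the weighted empirical logit of the pooled rate
    rate = np.sum(w_obs * succ) / max(np.sum(w_obs * trials), 1e-12)
    rate = min(max(rate, 1e-6), 1.0 - 1e-6)
    beta[0] = np.log(rate / (1.0 - rate))
    converged = False
    ridged = False
    work = None
    for _ in range(max_iter):
        eta = X1 @ beta
        mu = expit(eta)
        var = np.clip(trials * mu * (1.0 - mu), 1e-12, None)
        work = w_obs * var
        z = eta + (succ - trials * mu) / var
        XtW = X1.T * work
        A = XtW @ X1
        b = XtW @ z
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            new = np.linalg.solve(A + _RIDGE * np.eye(p1), b)
            ridged = True
        if not np.all(np.isfinite(new)):
            new = np.linalg.solve(A + _RIDGE * np.eye(p1), b)
            ridged = True
        # near-singular designs: jitter rather than crash
        if np.linalg.cond(A) > 1e12:
            new = np.linalg.solve(A + _RIDGE * np.eye(p1), b)
            ridged = True
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    return beta, converged, ridged, work


@dataclass
class GlrModel:
    """Global logistic regression fit (spatially invariant coefficients)."""

    predictors: list[str]
    coef: np.ndarray          # intercept first
    log_likelihood: float
    deviance: float
    aic: float
    aicc: float
    k: int
    m: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        X1 = _with_intercept(X, len(self.predictors))
        return expit(X1 @ self.coef)


@dataclass
class GwlrModel:
    """Geographically weighted logistic regression fit.

    Stores the calibration data so that predictions at new locations can
    re-estimate local coefficients by a kernel-weighted fit.
    """

    predictors: list[str]
    coords: np.ndarray        # (m, 2) lon/lat of calibration locations
    coef: np.ndarray          # (m, p+1) local coefficients, intercept first
    bandwidth: int            # adaptive neighbour count (0 = uniform weights)
    log_likelihood: float
    k_effective: float
    m: int
    aic: float
    aicc: float
    converged: np.ndarray     # per-location flag
    ridged: np.ndarray        # per-location numerical-guard flag
    train_X: np.ndarray = field(repr=False, default=None)
    train_succ: np.ndarray = field(repr=False, default=None)
    train_trials: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray, coords: np.ndarray | None = None) -> np.ndarray:
        """Probabilities at the calibration locations (default) or new ones.

        A new location gets local coefficients re-estimated by a
        kernel-weighted fit over the calibration observations.
        """
        X1 = _with_intercept(X, len(self.predictors))
        if coords is None:
            if X1.shape[0] != self.m:
                raise ValueError("covariate rows do not match calibration locations")
            return expit(np.sum(X1 * self.coef, axis=1))
        coords = np.asarray(coords, dtype=float)
        out = np.empty(coords.shape[0])
        train_X1 = _with_intercept(self.train_X, len(self.predictors))
        for i, (lon, lat) in enumerate(coords):
            match = np.flatnonzero(
                (self.coords[:, 0] == lon) & (self.coords[:, 1] == lat))
            if match.size:
                beta = self.coef[match[0]]
            else:
                d = great_circle_distance(lon, lat,
                                          self.coords[:, 0], self.coords[:, 1])
                if self.bandwidth == 0:
                    w = np.ones(self.m)
                else:
                    b = np.sort(d)[self.bandwidth - 1]
                    ratio = d / max(b, 1e-12)
                    w = np.where(ratio < 1.0, (1.0 - ratio**2) ** 2, 0.0)
                beta, _, _, _ = _irls(train_X1, self.train_succ,
                                      self.train_trials, obs_weights=w)
            out[i] = expit(X1[i] @ beta)
        return out


def _with_intercept(X: np.ndarray, n_predictors: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != n_predictors:
        raise ValueError(f"expected {n_predictors} predictor columns, got {X.shape[1]}")
    return np.column_stack([np.ones(X.shape[0]), X])


def _validate_response(succ, trials):
    succ = np.asarray(succ, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if succ.shape != trials.shape:
        raise ValueError("successes and trials must be aligned")
    if np.any(succ < 0) or np.any(succ > trials):
        raise ValueError("need 0 <= successes <= trials")
    return succ, trials


def fit_glr(X: np.ndarray, successes, trials, predictors: list[str] | None = None) -> GlrModel:
    """Fit the global binomial logistic model by IRLS.

    ``trials`` of all ones gives plain Bernoulli logistic regression.  A
    response with no variation (all-0 or all-1 rates) is rejected; complete
    separation surfaces as a non-convergence flag, not an exception.
    """
    succ, tri = _validate_response(successes, trials)
    rates = succ / np.clip(tri, 1e-12, None)
    if np.all(rates == 0.0) or np.all(rates == 1.0):
        raise ValueError("response has no variation (all zero or all one)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = predictors if predictors is not None else [f"x{j}" for j in range(X.shape[1])]
    X1 = _with_intercept(X, len(names))
    beta, converged, _, _ = _irls(X1, succ, tri)
    p = expit(X1 @ beta)
    ll = _binom_loglik(succ, tri, p)
    ll_sat = _binom_loglik(succ, tri, rates)
    k = X1.shape[1]
    m = X1.shape[0]
    aic = -2.0 * ll + 2.0 * k
    aicc_v = aicc(ll, k, m)[1] if m > k + 1 else np.nan
    return GlrModel(predictors=names, coef=beta, log_likelihood=ll,
                    deviance=2.0 * (ll_sat - ll), aic=aic, aicc=aicc_v,
                    k=k, m=m, converged=converged)


def fit_gwlr(
    X: np.ndarray,
    successes,
    trials,
    coords: np.ndarray,
    bandwidth_neighbors: int | None,
    predictors: list[str] | None = None,
) -> GwlrModel:
    """Fit a GWLR model at every calibration location.

    ``bandwidth_neighbors=None`` is the infinite-bandwidth mode: all kernel
    weights are one, so every local fit equals the global fit (useful as a
    correctness check and for homogeneous data).

    The model log-likelihood sums each observation's binomial contribution
    evaluated at its own location's local fit.  The effective parameter count
    is the trace of the projection ("hat") matrix of the final local IRLS
    steps; AIC/AICc follow from it.
    """
    succ, tri = _validate_response(successes, trials)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = predictors if predictors is not None else [f"x{j}" for j in range(X.shape[1])]
    X1 = _with_intercept(X, len(names))
    m, p1 = X1.shape
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (m, 2):
        raise ValueError("coords must be an (m, 2) lon/lat array")

    if bandwidth_neighbors is None:
        W = np.ones((m, m))
        bw = 0
    else:
        bw = int(bandwidth_neighbors)
        if bw < p1 + 1:
            raise ValueError(f"bandwidth {bw} below predictor count + 2 ({p1 + 1})")
        W = bisquare_weights(pairwise_distances(coords), bw)

    coef = np.empty((m, p1))
    converged = np.zeros(m, dtype=bool)
    ridged = np.zeros(m, dtype=bool)
    trace_s = 0.0
    for i in range(m):
        w = W[i]
        beta, conv, rid, work = _fit_local(X1, succ, tri, w, bw, m, coords, i)
        coef[i] = beta
        converged[i] = conv
        ridged[i] = rid
        # hat-matrix diagonal: x_i (X' V X)^-1 x_i * v_ii at the final step
        XtV = X1.T * work
        A = XtV @ X1
        try:
            ai = np.linalg.solve(A, X1[i])
        except np.linalg.LinAlgError:
            ai = np.linalg.solve(A + _RIDGE * np.eye(p1), X1[i])
        trace_s += float(X1[i] @ ai) * work[i]

    p_own = expit(np.sum(X1 * coef, axis=1))
    ll = _binom_loglik(succ, tri, p_own)
    k_eff = min(trace_s, m - 2.0)  # guard AICc's m > k + 1 domain
    aic, aicc_v = aicc(ll, k_eff, m)
    return GwlrModel(predictors=names, coords=coords, coef=coef, bandwidth=bw,
                     log_likelihood=ll, k_effective=k_eff, m=m,
                     aic=aic, aicc=aicc_v, converged=converged, ridged=ridged,
                     train_X=X, train_succ=succ, train_trials=tri)


def _fit_local(X1, succ, tri, w, bw, m, coords, i):
    """One local IRLS fit; on a singular design, enlarge the bandwidth
    until the local problem is well posed."""
    beta, conv, rid, work = _irls(X1, succ, tri, obs_weights=w)
    if np.all(np.isfinite(beta)) and work is not None:
        return beta, conv, rid, work
    d = great_circle_distance(coords[i, 0], coords[i, 1], coords[:, 0], coords[:, 1])
    for wider in range(max(bw, X1.shape[1] + 1) + 1, m + 1):
        b = np.sort(d)[wider - 1]
        w2 = np.where(d / max(b, 1e-12) < 1.0, (1.0 - (d / b) ** 2) ** 2, 0.0)
        beta, conv, _, work = _irls(X1, succ, tri, obs_weights=w2)
        if np.all(np.isfinite(beta)):
            return beta, conv, True, work
    raise np.linalg.LinAlgError(f"location {i}: no non-singular bandwidth found")


def select_bandwidth(
    X: np.ndarray,
    successes,
    trials,
    coords: np.ndarray,
    lo: int | None = None,
    hi: int | None = None,
    method: str = "golden",
    predictors: list[str] | None = None,
) -> tuple[int, list[tuple[int, float]]]:
    """AICc-minimizing adaptive bandwidth (integer neighbour count).

    Golden-section search over the integer range [lo, hi] assuming a unimodal
    AICc profile; ``method='grid'`` evaluates every candidate for non-unimodal
    profiles.  Ties break to the smaller bandwidth; the full evaluation trace
    is returned for logging.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    p1 = X.shape[1] + 1
    lo = (p1 + 1) if lo is None else int(lo)
    hi = m if hi is None else int(hi)
    if lo > hi:
        raise ValueError(f"empty bandwidth range [{lo}, {hi}]")

    cache: dict[int, float] = {}

    def score(bw: int) -> float:
        if bw not in cache:
            cache[bw] = fit_gwlr(X, successes, trials, coords, bw,
                                 predictors=predictors).aicc
        return cache[bw]

    score(lo)
    score(hi)
    if method == "grid" or hi - lo <= 4:
        for bw in range(lo, hi + 1):
            score(bw)
    elif method == "golden":
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = int(round(b - phi * (b - a)))
        d = int(round(a + phi * (b - a)))
        while b - a > 4:
            if score(c) <= score(d):
                b = d
            else:
                a = c
            c = int(round(b - phi * (b - a)))
            d = int(round(a + phi * (b - a)))
            c, d = min(c, d), max(c, d)
            if c == d:
                d = min(d + 1, b)
        for bw in range(a, b + 1):
            score(bw)
    else:
        raise ValueError(f"unknown method '{method}'")

    best = min(cache, key=lambda bw: (cache[bw], bw))
    trace = sorted(cache.items())
    return best, trace


def predict(model: GlrModel | GwlrModel, X: np.ndarray,
            coords: np.ndarray | None = None) -> np.ndarray:
    """Probabilities from either model type (dispatch helper)."""
    if isinstance(model, GlrModel):
        return model.predict(X)
    return model.predict(X, coords=coords)
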
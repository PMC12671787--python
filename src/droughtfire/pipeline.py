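"""End-to-end orchestration of the synthetic drought-to-fire analysis.

Stage order (mirrors the CLI subcommands):

1. simulate — grid, static covariates, historical + scenario climate
2. spei     — multi-scale SPEI per climate series
3. drought  — run-theory characteristics per (scale, threshold, period)
4. features — PCA of drought characteristics, min-max normalization, and the
              synthetic ground truth + fire records (which, in the synthetic
              world, depend on the drought features)
5. fit      — global and geographically weighted logistic models
6. evaluate — held-out AUC / Brier / AICc
7. project  — future probabilities, ensemble and regional deltas

Each stage is a pure function of the config and prior-stage outputs, so the
whole run is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic, spei as spei_mod, droughts, covariates as cov_mod
from . import gwlr, evaluate as eval_mod, projection
from .config import RunConfig

STATIC_PREDICTORS = ["elevation", "slope", "tree_cover", "roughness",
                     "road_density", "river_density", "population_density"]
DROUGHT_CHARS = ["mdn", "mdd", "mds", "mdi"]


@dataclass
class PipelineResult:
    config: RunConfig
    grid: synthetic.GridSpec = None
    covariates: pd.DataFrame = None
    climate_hist: pd.DataFrame = None
    climate_future: dict[str, pd.DataFrame] = field(default_factory=dict)
    spei_hist: pd.DataFrame = None
    spei_future: dict[str, pd.DataFrame] = field(default_factory=dict)
    chars_hist: pd.DataFrame = None
    chars_future: dict[str, pd.DataFrame] = field(default_factory=dict)
    pca: cov_mod.PcaModel = None
    norm: cov_mod.MinMaxNormalizer = None
    features: pd.DataFrame = None
    truth: synthetic.TrueModel = None
    fp_true: np.ndarray = None
    fire_records: pd.DataFrame = None
    fp_grid: pd.DataFrame = None
    glr: gwlr.GlrModel = None
    model: gwlr.GwlrModel = None
    bandwidth_trace: list = field(default_factory=list)
    report: eval_mod.EvalReport = None
    projections: dict[tuple[str, str], projection.ProjectionResult] = field(default_factory=dict)


def stage_simulate(cfg: RunConfig) -> PipelineResult:
    res = PipelineResult(config=cfg)
    res.grid = synthetic.gen_grid(cfg.n_lon, cfg.n_lat, cfg.seed)
    res.covariates = synthetic.gen_covariates(res.grid, cfg.seed)
    hist_years = cfg.test_period.end - cfg.start_year + 1
    res.climate_hist = synthetic.gen_climate(
        res.grid, hist_years, trend=0.0, seed=cfg.seed,
        start_year=cfg.start_year, scenario="historical")
    for scen in cfg.scenarios:
        members = [
            synthetic.gen_climate(
                res.grid, cfg.future_years, trend=scen.trend,
                seed=cfg.seed + 1000 * (j + 1), start_year=cfg.future_start,
                scenario=scen.name, model=f"gcm{j + 1}")
            for j in range(cfg.n_ensemble_members)
        ]
        res.climate_future[scen.name] = projection.ensemble_mean(members)
    return res


def stage_spei(res: PipelineResult) -> PipelineResult:
    cfg = res.config
    scales = tuple(cfg.scales)
    res.spei_hist = spei_mod.compute_spei(res.climate_hist, scales=scales)
    for name, clim in res.climate_future.items():
        if cfg.calibration == "historical":
            # standardize future series against the historical-period fit by
            # concatenating and restricting the calibration window
            both = pd.concat([res.climate_hist, clim], ignore_index=True)
            sp = spei_mod.compute_spei(
                both, scales=scales,
                calibration_years=(cfg.train_period.start, cfg.train_period.end))
            sp = sp[sp["year"] >= cfg.future_start].reset_index(drop=True)
        else:
            sp = spei_mod.compute_spei(clim, scales=scales)
        res.spei_future[name] = sp
    return res


def stage_drought(res: PipelineResult) -> PipelineResult:
    cfg = res.config
    thresholds = tuple(cfg.thresholds)
    res.chars_hist = droughts.drought_characteristics(
        res.spei_hist, thresholds=thresholds,
        periods={"train": (cfg.train_period.start, cfg.train_period.end)},
        min_duration=cfg.min_duration)
    future_periods = {k: (p.start, p.end) for k, p in cfg.future_periods.items()}
    for name, sp in res.spei_future.items():
        res.chars_future[name] = droughts.drought_characteristics(
            sp, thresholds=thresholds, periods=future_periods,
            min_duration=cfg.min_duration)
    return res


def _chars_matrix(chars: pd.DataFrame, scale: int, threshold: float,
                  period: str) -> pd.DataFrame:
    sub = chars[(chars["scale"] == scale) & (chars["threshold"] == threshold)
                & (chars["period"] == period)]
    return (sub.sort_values("cell_id").set_index("cell_id")[DROUGHT_CHARS])


def stage_features(res: PipelineResult) -> PipelineResult:
    cfg = res.config
    chars = _chars_matrix(res.chars_hist, cfg.model_scale, cfg.model_threshold, "train")
    res.pca = cov_mod.PcaModel.fit(chars, variables=DROUGHT_CHARS)
    scores = res.pca.transform(chars)
    static = res.covariates.sort_values("cell_id").set_index("cell_id")[STATIC_PREDICTORS]
    table = pd.concat([static, scores.set_axis(static.index)], axis=1)
    res.norm = cov_mod.MinMaxNormalizer().fit(table)
    res.features = res.norm.transform(table)

    predictors = STATIC_PREDICTORS + list(scores.columns)
    res.truth = synthetic.gen_true_model(
        res.grid, predictors, seed=cfg.seed, drought_predictor="pc1",
        drought_amplitude=cfg.drought_amplitude, intercept=-1.0)
    res.fp_true = res.truth.probability(res.features)
    total_years = cfg.test_period.end - cfg.start_year + 1
    res.fire_records = synthetic.gen_fire_records(
        res.grid, res.fp_true, total_years, seed=cfg.seed,
        start_year=cfg.start_year)
    return res


def stage_fit(res: PipelineResult) -> PipelineResult:
    cfg = res.config
    train_years = range(cfg.train_period.start, cfg.train_period.end + 1)
    res.fp_grid = eval_mod.estimate_fp(res.fire_records, res.grid, train_years)
    X = res.features.to_numpy(dtype=float)
    predictors = list(res.features.columns)
    coords = res.grid.cells[["lon", "lat"]].to_numpy(dtype=float)
    if cfg.response == "binomial":
        succ = res.fp_grid["n_fire_years"].to_numpy(dtype=float)
        trials = res.fp_grid["n_years"].to_numpy(dtype=float)
    else:
        succ = (res.fp_grid["n_fire_years"].to_numpy() > 0).astype(float)
        trials = np.ones(res.grid.n_cells)
    res.glr = gwlr.fit_glr(X, succ, trials, predictors=predictors)
    if cfg.bandwidth == "global":
        res.model = gwlr.fit_gwlr(X, succ, trials, coords, None, predictors=predictors)
    elif cfg.bandwidth == "auto":
        bw, trace = gwlr.select_bandwidth(X, succ, trials, coords,
                                          predictors=predictors)
        res.bandwidth_trace = trace
        res.model = gwlr.fit_gwlr(X, succ, trials, coords, bw, predictors=predictors)
    else:
        res.model = gwlr.fit_gwlr(X, succ, trials, coords, int(cfg.bandwidth),
                                  predictors=predictors)
    return res


def stage_evaluate(res: PipelineResult) -> PipelineResult:
    cfg = res.config
    predicted = res.model.predict(res.features.to_numpy(dtype=float))
    res.report = eval_mod.evaluate_holdout(
        predicted, res.model.aicc, res.fire_records, res.grid,
        train_period=(cfg.train_period.start, cfg.train_period.end),
        test_period=(cfg.test_period.start, cfg.test_period.end))
    return res


def stage_project(res: PipelineResult) -> PipelineResult:
    cfg = res.config
    static = res.covariates.sort_values("cell_id").set_index("cell_id")[STATIC_PREDICTORS]
    fp_hist = res.model.predict(res.features.to_numpy(dtype=float))
    for scen_name, chars in res.chars_future.items():
        for period in cfg.future_periods:
            fut = _chars_matrix(chars, cfg.model_scale, cfg.model_threshold, period)
            fp_future = projection.project_fp(res.model, fut, static,
                                              res.pca, res.norm)
            res.projections[(scen_name, period)] = projection.delta_fp(
                fp_future, fp_hist, res.grid,
                forest_mask_threshold=cfg.forest_mask_threshold)
    return res


_STAGES = [stage_spei, stage_drought, stage_features, stage_fit,
           stage_evaluate, stage_project]


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage in order and return the populated result bundle."""
    res = stage_simulate(cfg)
    for stage in _STAGES:
        res = stage(res)
    return res
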
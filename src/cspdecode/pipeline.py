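"""End-to-end decoding pipelines: preprocess -> CSP -> features -> selection
-> classification.

A :class:`PipelineConfig` names one feature extractor (classic CSP
log-variance, CSP-Wavelet, CSP-WPD or CSP-FB), an optional sparse selector
(LASSO or LOG, with the regularization weight picked by stratified 10-fold
CV over a 2^[-5..5] grid), and optionally the secondary threshold-ensemble
stage.  Everything fitted from data — spatial filters, feature
standardization, the selector weights and the FLDA models — is learned on
the training epochs only and applied frozen to the test epochs; the single
documented exception is the max evaluation rule, which scores every
threshold's model on the test set and reports the best.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import EpochSet
from .csp import compute_class_covariances, logvar_features, project, solve_csp
from .ensemble import (
    DEFAULT_THRESHOLDS,
    build_ensemble,
    evaluate_ensemble_cv,
    evaluate_ensemble_max,
)
from .errors import ConfigError, DataError
from .features import FeatureMatrix
from .filterbank import extract_csp_fb, make_filter_bank
from .flda import flda_fit, flda_predict
from .preprocess import BandPassSpec, bandpass_epochs
from .sparse import (
    DEFAULT_A,
    ColumnStandardizer,
    SolverConfig,
    SparseProblem,
    cv_select_lambda,
    ista_lasso,
    ista_log,
)
from .wavelets import extract_csp_wavelet, extract_csp_wpd, plan_wavelet

__all__ = ["PipelineConfig", "ResultRecord", "run_pipeline", "load_config", "save_config"]

EXTRACTORS = ("csp", "csp_wavelet", "csp_wpd", "csp_fb")
SELECTORS = ("none", "lasso", "log")


@dataclass
class PipelineConfig:
    """Full specification of one decoding chain.

    Extractor-specific options must only be set for the matching extractor
    (wavelet options for csp_wavelet / csp_wpd, ``filter_bank`` for csp_fb);
    ``None`` means "use that extractor's defaults".
    """

    extractor: str = "csp_fb"
    selector: str = "log"
    secondary_selection: bool = True
    m: int = 3
    bandpass: tuple[float, float] | None = (8.0, 30.0)
    bandpass_order: int = 6
    phase_mode: str = "zero_phase"
    wavelet_levels: int | None = None
    wavelet_selection_rule: str | None = None
    filter_bank: tuple[float, float, float, float] | None = None
    lam: float | None = None
    lambda_grid: tuple[float, ...] | None = None
    a: float = DEFAULT_A
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    normalize_thresholds: bool = False
    cv_folds: int = 10
    evaluation_rule: str = "max"
    solver_max_iter: int = 1000
    solver_tol: float = 1e-6
    solver_mode: str = "closed_form"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extractor not in EXTRACTORS:
            raise ConfigError(f"unknown extractor {self.extractor!r}")
        if self.selector not in SELECTORS:
            raise ConfigError(f"unknown selector {self.selector!r}")
        if self.evaluation_rule not in ("max", "cv"):
            raise ConfigError(f"unknown evaluation rule {self.evaluation_rule!r}")
        wavelet_opts = self.wavelet_levels is not None or self.wavelet_selection_rule is not None
        if wavelet_opts and self.extractor not in ("csp_wavelet", "csp_wpd"):
            raise ConfigError(
                f"wavelet options set but extractor is {self.extractor!r}"
            )
        if self.filter_bank is not None and self.extractor != "csp_fb":
            raise ConfigError(
                f"filter_bank set but extractor is {self.extractor!r}"
            )
        if self.selector == "none" and self.secondary_selection:
            raise ConfigError(
                "secondary selection needs sparse weights; set a selector"
            )
        if self.m < 1:
            raise ConfigError("m must be >= 1")

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            max_iter=self.solver_max_iter, tol=self.solver_tol, mode=self.solver_mode
        )


@dataclass
class ResultRecord:
    """Everything a run produced, reproducible from (config, seed, input)."""

    config: PipelineConfig
    final_accuracy: float
    lambda_star: float | None = None
    support_size: int | None = None
    chosen_threshold: float | None = None
    per_threshold_accuracies: list[float] = field(default_factory=list)
    per_threshold_subset_sizes: list[int] = field(default_factory=list)
    n_features: int = 0
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config"] = dataclasses.asdict(self.config)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path) -> None:
        import pandas as pd

        if self.per_threshold_accuracies:
            pd.DataFrame(
                {
                    "threshold": list(self.config.thresholds),
                    "subset_size": self.per_threshold_subset_sizes,
                    "accuracy": self.per_threshold_accuracies,
                }
            ).to_csv(path, index=False)
        else:
            pd.DataFrame({"accuracy": [self.final_accuracy]}).to_csv(path, index=False)


def _extract(cfg: PipelineConfig, proj_train, proj_test) -> tuple[FeatureMatrix, FeatureMatrix]:
    if cfg.extractor == "csp":
        return logvar_features(proj_train), logvar_features(proj_test)
    if cfg.extractor in ("csp_wavelet", "csp_wpd"):
        transform = "dwt" if cfg.extractor == "csp_wavelet" else "wpd"
        plan = plan_wavelet(
            proj_train.fs,
            transform=transform,
            levels=cfg.wavelet_levels,
            selection_rule=cfg.wavelet_selection_rule or "intersect_8_30",
        )
        extract = extract_csp_wavelet if transform == "dwt" else extract_csp_wpd
        return extract(proj_train, plan), extract(proj_test, plan)
    fb = cfg.filter_bank or (8.0, 30.0, 4.0, 2.0)
    bank = make_filter_bank(*fb, order=cfg.bandpass_order)
    return (
        extract_csp_fb(proj_train, bank, cfg.phase_mode),
        extract_csp_fb(proj_test, bank, cfg.phase_mode),
    )


def run_pipeline(train: EpochSet, test: EpochSet, cfg: PipelineConfig) -> ResultRecord:
    """Run one configured chain; all data-derived state is fitted on ``train``."""
    if train.n_channels != test.n_channels:
        raise DataError("train and test channel counts differ")
    if train.fs != test.fs:
        raise DataError("train and test sampling rates differ")

    if cfg.bandpass is not None:
        spec = BandPassSpec(
            *cfg.bandpass, order=cfg.bandpass_order, phase_mode=cfg.phase_mode
        )
        train = bandpass_epochs(train, spec)
        test = bandpass_epochs(test, spec)

    covs = compute_class_covariances(train)
    filters = solve_csp(covs, m=cfg.m)
    feats_train, feats_test = _extract(cfg, project(train, filters), project(test, filters))

    x_train, x_test = feats_train.values, feats_test.values
    y_train, y_test = train.labels, test.labels
    record = ResultRecord(
        config=cfg,
        final_accuracy=0.0,
        n_features=x_train.shape[1],
        n_train=y_train.size,
        n_test=y_test.size,
    )

    if cfg.standardize:
        scaler = ColumnStandardizer().fit(x_train)
        x_train, x_test = scaler.transform(x_train), scaler.transform(x_test)

    if cfg.selector == "none":
        model = flda_fit(x_train, y_train)
        record.final_accuracy = float(np.mean(flda_predict(model, x_test) == y_test))
        return record

    solver_cfg = cfg.solver_config()
    if cfg.lam is not None:
        lam_star = cfg.lam
    else:
        grid = None if cfg.lambda_grid is None else np.asarray(cfg.lambda_grid)
        lam_star, _table = cv_select_lambda(
            x_train,
            y_train,
            selector=cfg.selector,
            folds=cfg.cv_folds,
            grid=grid,
            a=cfg.a,
            cfg=solver_cfg,
            seed=cfg.seed,
        )
    record.lambda_star = lam_star

    prob = SparseProblem(X=x_train, y=y_train.astype(float), lam=lam_star, a=cfg.a)
    solve = ista_lasso if cfg.selector == "lasso" else ista_log
    weights = solve(prob, solver_cfg)
    support = weights.support()
    record.support_size = int(support.size)

    if not cfg.secondary_selection:
        if support.size == 0:
            record.final_accuracy = 0.0
            return record
        model = flda_fit(x_train[:, support], y_train)
        record.final_accuracy = float(
            np.mean(flda_predict(model, x_test[:, support]) == y_test)
        )
        return record

    if cfg.evaluation_rule == "max":
        ens = build_ensemble(
            weights, x_train, y_train, cfg.thresholds, normalize=cfg.normalize_thresholds
        )
        report = evaluate_ensemble_max(ens, x_test, y_test)
    else:
        report = evaluate_ensemble_cv(
            weights,
            x_train,
            y_train,
            x_test,
            y_test,
            thresholds=cfg.thresholds,
            seed=cfg.seed,
            normalize=cfg.normalize_thresholds,
        )
    record.final_accuracy = report.final_accuracy
    record.chosen_threshold = report.chosen_threshold
    record.per_threshold_accuracies = [float(a) for a in report.accuracies]
    record.per_threshold_subset_sizes = list(report.subset_sizes)
    return record


def save_config(cfg: PipelineConfig, path) -> None:
    """YAML round-trip of every field, including defaults."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("bandpass", "filter_bank", "lambda_grid", "thresholds"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
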
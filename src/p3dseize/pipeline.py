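"""Top-level driver: synthetic recordings -> filtering -> SPH windows ->
nonlinear features -> mRMR selection -> electrode-grid tensors -> repeated
stratified CV of the classifier (and optional KNN/SVM baselines).

This is the programmatic equivalent of running every CLI stage in order;
the CLI and the examples both call into it. The default study conditions
produce 400 balanced 6-s windows (200 preictal, 200 interictal) from two
synthetic recordings with one annotated onset each.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import (MetricsReport, baseline_knn, baseline_svm,
                       flatten_features, make_cv_plan, run_cv)
from .features import (FEATURE_NAMES, FeatureBlock, FeatureParams,
                       extract_feature_block)
from .model import ModelConfig
from .preprocess import (LabelSpec, WindowSet, balance_classes, bandpass_filter,
                         concatenate_window_sets, label_windows, split_steps)
from .selection import (SelectionResult, SweepResult, build_feature_matrix,
                        feature_count_sweep, knn_cv_evaluator, mrmr_rank)
from .synth import SynthConfig, generate_dataset
from .tensorize import build_grid_layout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end study conditions; ``seed`` drives every stochastic stage."""

    synth: SynthConfig = field(
        default_factory=lambda: SynthConfig(duration_s=1800.0,
                                            seizure_onsets_s=(1800.0,))
    )
    n_recordings: int = 2
    band: tuple[float, float] = (0.5, 75.0)
    label_spec: LabelSpec = field(default_factory=LabelSpec)
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    n_keep: int | None = 3  # None: let the accuracy sweep decide
    run_sweep: bool = True
    cv_k: int = 5
    cv_repeats: int = 1
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    run_baselines: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    windows: WindowSet
    feature_block: FeatureBlock  # all extracted features
    selected_block: FeatureBlock  # the retained subset, model input
    selection: SelectionResult
    sweep: SweepResult | None
    report: MetricsReport
    baseline_reports: dict[str, MetricsReport]


def extract_windows(cfg: PipelineConfig) -> WindowSet:
    """Generate, filter, window, label and balance — the data half."""
    synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
    recordings = generate_dataset(synth_cfg, cfg.n_recordings)
    window_sets = []
    for rec in recordings:
        filtered = bandpass_filter(rec, *cfg.band)
        window_sets.append(label_windows(filtered, cfg.label_spec))
    ws = concatenate_window_sets(window_sets)
    ws = balance_classes(ws, seed=cfg.seed + 1)
    logger.info("windows: %d preictal, %d interictal",
                int((ws.labels == 1).sum()), int((ws.labels == 0).sum()))
    return ws


def extract_features(ws: WindowSet, cfg: PipelineConfig) -> FeatureBlock:
    steps = split_steps(ws)
    return extract_feature_block(steps, cfg.feature_params, FEATURE_NAMES,
                                 ws.channel_names)


def select_features(
    block: FeatureBlock, labels: np.ndarray, cfg: PipelineConfig
) -> tuple[SelectionResult, SweepResult | None]:
    fm = build_feature_matrix(block, labels)
    selection = mrmr_rank(fm)
    sweep = None
    if cfg.run_sweep:
        sweep = feature_count_sweep(
            fm, selection.ranked_names,
            knn_cv_evaluator(seed=cfg.seed + 2), k_max=len(selection.ranked_names),
        )
        selection.chosen_k = sweep.chosen_k
    if cfg.n_keep is not None:
        selection.chosen_k = cfg.n_keep
    return selection, sweep


def run_pipeline(cfg: PipelineConfig = PipelineConfig()) -> PipelineResult:
    ws = extract_windows(cfg)
    block = extract_features(ws, cfg)
    selection, sweep = select_features(block, ws.labels, cfg)
    keep = selection.ranked_names[: selection.chosen_k]
    logger.info("retained features (mRMR order): %s", ", ".join(keep))
    selected = block.select(keep)

    layout = build_grid_layout(ws.channel_names)
    plan = make_cv_plan(ws.labels, k=cfg.cv_k, repeats=cfg.cv_repeats,
                        seed=cfg.seed + 3)
    model_cfg = dataclasses.replace(cfg.model, n_features=len(keep),
                                    seed=cfg.seed + 4)
    report = run_cv(selected, ws.labels, layout, model_cfg, plan)

    baseline_reports: dict[str, MetricsReport] = {}
    if cfg.run_baselines:
        flat = flatten_features(selected)
        baseline_reports["knn"] = baseline_knn(flat, ws.labels, plan)
        baseline_reports["svm"] = baseline_svm(flat, ws.labels, plan)

    return PipelineResult(ws, block, selected, selection, sweep, report,
                          baseline_reports)
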
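"""End-to-end orchestration: simulate -> preprocess -> project -> crossval
-> explain -> correlate.

A single global seed is expanded into per-stage and per-fold seeds through a
documented counter scheme (``derive_seed``): stage indices 0..5 in pipeline
order, then fold index, then a purpose counter (0 = class balancing,
1 = validation split, 2 = weight initialization, 3 = training shuffle /
dropout).  Reruns with the same seed are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cortexlrp import cnn, evalharness, lrp, stats
from cortexlrp.preprocess import WindowedTrialSet, reject_by_eog, window_average
from cortexlrp.projection import ProjectionMap, make_trial_images
from cortexlrp.sourcespace import CorticalSourceSpace, RegionCap, generate_source_space
from cortexlrp.synthdata import ClinicalTable, SimulationConfig, generate_trials

__all__ = ["StudyConfig", "StudyResult", "derive_seed", "run_crossval", "run_study"]

_STAGES = ("simulate", "preprocess", "project", "crossval", "explain", "correlate")


def derive_seed(global_seed: int, *counters: int) -> int:
    """Expand the global seed along a counter path; result fits in 31 bits."""
    ss = np.random.SeedSequence([int(global_seed), *map(int, counters)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    """Everything needed to run the full synthetic study."""

    n_vertices: int = 15002
    region_spec: list[RegionCap] | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    eog_threshold_uv: float = 100.0
    window_ms: tuple[float, float] = (150.0, 250.0)
    grid_size: int = 60
    channel_plan: tuple[int, int] = (64, 128)
    dense_plan: tuple[int, int] = (256, 64)
    train: cnn.TrainConfig = field(default_factory=cnn.TrainConfig)
    composite: dict[str, lrp.LRPRuleParams] | None = None
    top_fraction: float = 0.03
    seed: int = 0


@dataclass
class FoldOutput:
    result: evalharness.FoldResult
    learning_rate: float
    history: dict
    model: cnn.CNNModel | None = None
    maps: list[lrp.RelevanceMap] = field(default_factory=list)


@dataclass
class StudyResult:
    space: CorticalSourceSpace
    windowed: WindowedTrialSet
    clinical: ClinicalTable
    images: np.ndarray
    left_map: ProjectionMap
    right_map: ProjectionMap
    folds: list[FoldOutput]
    roc: evalharness.RocCurve
    aggregate_map: lrp.RelevanceMap
    critical: stats.CriticalRegionSet
    correlations: stats.CorrelationTable

    @property
    def fold_results(self) -> list[evalharness.FoldResult]:
        return [f.result for f in self.folds]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.result.accuracy for f in self.folds]))

    def summary(self) -> dict:
        accs = [f.result.accuracy for f in self.folds]
        return {
            "n_folds": len(self.folds),
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "auc": self.roc.auc,
            "n_critical_vertices": int(len(self.critical.selected)),
        }


def run_crossval(
    images: np.ndarray,
    subject_id: np.ndarray,
    group: np.ndarray,
    config: StudyConfig,
    left_map: ProjectionMap | None = None,
    right_map: ProjectionMap | None = None,
    keep_models: bool = False,
) -> list[FoldOutput]:
    """Leave-one-subject-out training/evaluation (+ per-trial LRP maps).

    Per fold: balance classes in the training subjects' trials, hold out a
    stratified validation fraction, grid-search the learning rate when the
    grid has several values, train with early stopping, and predict the
    held-out subject.  When projection maps are given, relevance maps (pixel
    and vertex space) are computed for every held-out trial.
    """
    labels = (np.asarray(group) == "patient").astype(int)
    table = pd.DataFrame({"subject_id": subject_id, "group": group})
    folds = evalharness.loocv_folds(table)
    composite = config.composite or lrp.default_composite()

    outputs: list[FoldOutput] = []
    for k, (train_subjects, test_subject) in enumerate(folds):
        train_idx = np.flatnonzero(np.isin(subject_id, train_subjects))
        test_idx = np.flatnonzero(subject_id == test_subject)

        balance = evalharness.balance_classes(
            group[train_idx], seed=derive_seed(config.seed, 3, k, 0)
        )
        train_idx = train_idx[balance]
        tr, va = evalharness.split_validation(
            labels[train_idx], config.train.validation_fraction,
            seed=derive_seed(config.seed, 3, k, 1),
        )
        X_tr, y_tr = images[train_idx[tr]], labels[train_idx[tr]]
        X_va, y_va = images[train_idx[va]], labels[train_idx[va]]

        init_seed = derive_seed(config.seed, 3, k, 2)
        builder = lambda: cnn.build_model(  # noqa: E731
            images.shape[-2:], config.channel_plan, config.dense_plan, seed=init_seed
        )
        fold_train = cnn.TrainConfig(
            lr_grid=config.train.lr_grid,
            patience=config.train.patience,
            max_epochs=config.train.max_epochs,
            batch_size=config.train.batch_size,
            validation_fraction=config.train.validation_fraction,
            seed=derive_seed(config.seed, 3, k, 3),
        )
        if len(fold_train.lr_grid) > 1:
            lr = cnn.grid_search_lr(builder, (X_tr, y_tr), (X_va, y_va), fold_train)
        else:
            lr = fold_train.lr_grid[0]
        model = builder()
        model, history = cnn.train(model, (X_tr, y_tr), (X_va, y_va), lr, fold_train)

        result = evalharness.evaluate_fold(
            model, images[test_idx], labels[test_idx], test_subject, trial_index=test_idx
        )

        maps: list[lrp.RelevanceMap] = []
        if left_map is not None and right_map is not None:
            pixel = lrp.explain(model, images[test_idx], composite)
            preds = result.predictions
            for j, t in enumerate(test_idx):
                maps.append(
                    lrp.RelevanceMap(
                        pixel=pixel[j],
                        vertex=lrp.pixel_to_vertex(pixel[j], left_map, right_map),
                        trial_id=int(t),
                        subject_id=int(test_subject),
                        true_label=int(labels[t]),
                        predicted_label=int(preds[j]),
                    )
                )
        outputs.append(
            FoldOutput(
                result=result, learning_rate=lr, history=history,
                model=model if keep_models else None, maps=maps,
            )
        )
    return outputs


def run_study(config: StudyConfig) -> StudyResult:
    """Run the whole synthetic study in memory and collect every product."""
    space = generate_source_space(
        config.n_vertices, config.region_spec, seed=derive_seed(config.seed, 0)
    )
    sim = config.simulation
    sim.seed = derive_seed(config.seed, 1)
    trials, clinical = generate_trials(space, sim)

    retained = reject_by_eog(trials, config.eog_threshold_uv)
    windowed = window_average(trials, *config.window_ms, retained=retained)
    del trials  # the raw (trials x vertices x samples) array is no longer needed

    images, left_map, right_map = make_trial_images(space, windowed.data, config.grid_size)

    folds = run_crossval(
        images, windowed.subject_id, windowed.group, config, left_map, right_map
    )

    all_probs = np.concatenate([f.result.probabilities for f in folds])
    all_labels = np.concatenate([f.result.labels for f in folds])
    roc = evalharness.roc_auc(all_probs, all_labels)

    all_maps = [m for f in folds for m in f.maps]
    aggregate = lrp.aggregate_heatmaps(all_maps, scope="pooled")
    critical = stats.top_fraction_mask(aggregate.vertex, config.top_fraction)

    activities = {
        name: stats.region_activity(windowed, mask)
        for name, mask in critical.region_masks(space).items()
    }
    correlations = stats.build_correlation_table(activities, clinical)

    return StudyResult(
        space=space, windowed=windowed, clinical=clinical, images=images,
        left_map=left_map, right_map=right_map, folds=folds, roc=roc,
        aggregate_map=aggregate, critical=critical, correlations=correlations,
    )
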
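"""The M component: cumulative top-k modeling under Monte Carlo cross-validation.

Every MCCV iteration draws a fresh stratified 80:20 train/test split, re-runs
grouping and scoring on the training samples only, and then evaluates a chain
of cumulative models: the top group's species alone, then the top two groups'
species, and so on until all top-k groups are aggregated. Per-iteration metric
sets are averaged over iterations; the per-iteration ranked group lists feed
the rank-aggregation stage.

Test samples never participate in group scoring or model fitting; an optional
audit hook records the exact sample ids seen by every fit so this can be
verified mechanically.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ModelingError
from .grouping import GroupMap
from .profile_io import AbundanceMatrix
from .scoring import ScoringConfig, derive_seed, make_classifier, rank_groups, score_all_groups

logger = logging.getLogger("microbiomegsm")

METRIC_NAMES: tuple[str, ...] = ("accuracy", "sensitivity", "specificity",
                                 "precision", "f1", "auc")


@dataclass(frozen=True)
class ModelingConfig:
    """MCCV settings: iteration count, split ratio, cumulative depth k, classifier."""

    n_iterations: int = 100
    train_fraction: float = 0.8
    k: int = 10
    classifier: str = "random_forest"
    n_estimators: int = 100
    global_seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ModelingError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ModelingError("n_iterations must be >= 1")
        if self.k < 1:
            raise ModelingError("k must be >= 1")


@dataclass(frozen=True)
class MetricSet:
    """Confusion-derived metrics plus threshold-free AUC for one model evaluation.

    ``precision_defined`` is False when no sample was predicted positive
    (TP+FP = 0); precision is then reported as 0 so that averaging over MCCV
    iterations stays well defined.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class IterationResult:
    iteration: int
    ranked_groups: tuple[str, ...]
    cumulative_metrics: tuple[MetricSet, ...]
    cumulative_n_features: tuple[int, ...]
    ranked_species: tuple[str, ...]
    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class RunResult:
    """All MCCV iterations plus per-depth metric means and standard deviations."""

    per_iteration: tuple[IterationResult, ...]
    metric_means: dict[str, np.ndarray]
    metric_sds: dict[str, np.ndarray]
    mean_n_features: np.ndarray
    sd_n_features: np.ndarray

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration)

    def ranked_group_lists(self) -> list[list[str]]:
        return [list(it.ranked_groups) for it in self.per_iteration]

    def summary_frame(self) -> pd.DataFrame:
        """Per-depth summary: one row per m = 1..k with mean +/- sd of each metric."""
        depth = len(self.mean_n_features)
        rows = []
        for m in range(depth):
            row: dict[str, float] = {"m": m + 1,
                                     "n_features_mean": float(self.mean_n_features[m]),
                                     "n_features_sd": float(self.sd_n_features[m])}
            for name in METRIC_NAMES:
                row[f"{name}_mean"] = float(self.metric_means[name][m])
                row[f"{name}_sd"] = float(self.metric_sds[name][m])
            rows.append(row)
        return pd.DataFrame(rows)

    def iteration_frame(self) -> pd.DataFrame:
        """Long table: one row per (iteration, cumulative depth m)."""
        rows = []
        for it in self.per_iteration:
            for m, ms in enumerate(it.cumulative_metrics, start=1):
                row = {"iteration": it.iteration, "m": m,
                       "n_features": it.cumulative_n_features[m - 1]}
                row.update(ms.as_dict())
                rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "n_iterations": self.n_iterations,
            "per_iteration": [
                {
                    "iteration": it.iteration,
                    "ranked_groups": list(it.ranked_groups),
                    "ranked_species": list(it.ranked_species),
                    "cumulative_n_features": list(it.cumulative_n_features),
                    "cumulative_metrics": [ms.as_dict() for ms in it.cumulative_metrics],
                }
                for it in self.per_iteration
            ],
            "metric_means": {k: v.tolist() for k, v in self.metric_means.items()},
            "metric_sds": {k: v.tolist() for k, v in self.metric_sds.items()},
            "mean_n_features": self.mean_n_features.tolist(),
            "sd_n_features": self.sd_n_features.tolist(),
        }
        return json.dumps(payload, sort_keys=True)


def stratified_split(matrix: AbundanceMatrix, train_fraction: float,
                     seed: int) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Random stratified split without replacement.

    Per class, round(count * train_fraction) samples (round half up) go to the
    training set and the remainder to the test set; each side keeps at least
    one sample per class. Sample order within each side follows the parent
    matrix.
    """
    if matrix.labels is None:
        raise ModelingError("matrix has no labels")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(matrix.labels):
        idx = np.flatnonzero(matrix.labels == cls)
        if len(idx) < 2:
            raise ModelingError(f"class {cls} has {len(idx)} sample(s); need >= 2 to split")
        n_train = int(math.floor(len(idx) * train_fraction + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return matrix.select_samples(sorted(train_idx)), matrix.select_samples(sorted(test_idx))


def compute_metrics(labels: np.ndarray, predicted_scores: np.ndarray,
                    threshold: float = 0.5) -> MetricSet:
    """Confusion metrics at ``threshold`` plus rank-based AUC (ties count 1/2)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(predicted_scores, dtype=float)
    if y.shape != s.shape:
        raise ModelingError("labels and scores are not aligned")
    if len(np.unique(y)) < 2:
        raise ModelingError("one-class label vector: AUC undefined")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if (precision + sensitivity) > 0 else 0.0)
    auc = float(roc_auc_score(y, s))
    return MetricSet(accuracy=float(accuracy), sensitivity=float(sensitivity),
                     specificity=float(specificity), precision=float(precision),
                     f1=float(f1), auc=auc, tp=tp, fp=fp, tn=tn, fn=fn,
                     precision_defined=precision_defined)


def _positive_proba(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


def cumulative_model_eval(
    train: AbundanceMatrix,
    test: AbundanceMatrix,
    ranked_groups: Sequence[str],
    group_map: GroupMap,
    cfg: ModelingConfig,
    iteration: int = 0,
    audit: list | None = None,
) -> tuple[list[MetricSet], list[int]]:
    """Evaluate cumulative models for m = 1..len(ranked_groups).

    The model at depth m is fit on the union of the top-m groups' species
    (group-rank order, then within-group order) on the training samples and
    scored on the test samples.
    """
    features: list[str] = []
    metrics: list[MetricSet] = []
    n_features: list[int] = []
    for m, name in enumerate(ranked_groups, start=1):
        if name not in group_map.groups:
            raise ModelingError(f"ranked group {name!r} not in group map")
        features.extend(group_map.groups[name])
        Xtr = train.species_values(features)
        Xte = test.species_values(features)
        clf = make_classifier(cfg.classifier, cfg.n_estimators,
                              derive_seed(cfg.global_seed, iteration, "model", m))
        clf.fit(Xtr, train.labels)
        if audit is not None:
            audit.append({"stage": "model_fit", "iteration": iteration, "m": m,
                          "sample_ids": tuple(train.sample_ids)})
        scores = _positive_proba(clf, Xte)
        metrics.append(compute_metrics(test.labels, scores, cfg.decision_threshold))
        n_features.append(len(features))
    return metrics, n_features


def run_mccv(
    matrix: AbundanceMatrix,
    group_map: GroupMap,
    cfg: ModelingConfig,
    scoring_cfg: ScoringConfig | None = None,
    audit: list | None = None,
) -> RunResult:
    """Run the full G-S-M loop under Monte Carlo cross-validation.

    Per iteration i: stratified split with a seed derived from
    (global_seed, i) -> score all groups on the training split only -> rank ->
    cumulative evaluation on the held-out split. Group scoring is recomputed
    inside every iteration so that ranking never sees test data.
    """
    if scoring_cfg is None:
        scoring_cfg = ScoringConfig(seed=cfg.global_seed)
    results: list[IterationResult] = []
    for i in range(1, cfg.n_iterations + 1):
        try:
            train, test = stratified_split(matrix, cfg.train_fraction,
                                           derive_seed(cfg.global_seed, i, "split"))
            if audit is not None:
                audit.append({"stage": "split", "iteration": i,
                              "train_ids": tuple(train.sample_ids),
                              "test_ids": tuple(test.sample_ids)})
            scores = score_all_groups(train, group_map, scoring_cfg, iteration=i)
            if audit is not None:
                audit.append({"stage": "scoring", "iteration": i,
                              "sample_ids": tuple(train.sample_ids)})
            ranked = rank_groups(scores, cfg.k)
            metrics, n_feat = cumulative_model_eval(train, test, ranked, group_map,
                                                    cfg, iteration=i, audit=audit)
            species = tuple(s for g in ranked for s in group_map.groups[g])
            results.append(IterationResult(
                iteration=i, ranked_groups=tuple(ranked),
                cumulative_metrics=tuple(metrics),
                cumulative_n_features=tuple(n_feat),
                ranked_species=species,
                train_sample_ids=tuple(train.sample_ids),
                test_sample_ids=tuple(test.sample_ids),
            ))
        except ModelingError as exc:
            raise ModelingError(f"MCCV iteration {i} failed: {exc}") from exc

    depth = len(results[0].cumulative_metrics)
    if any(len(r.cumulative_metrics) != depth for r in results):
        raise ModelingError("inconsistent cumulative depth across iterations")
    means: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for name in METRIC_NAMES:
        vals = np.array([[getattr(ms, name) for ms in r.cumulative_metrics] for r in results])
        means[name] = vals.mean(axis=0)
        sds[name] = vals.std(axis=0, ddof=0)
    nf = np.array([r.cumulative_n_features for r in results], dtype=float)
    return RunResult(per_iteration=tuple(results), metric_means=means, metric_sds=sds,
                     mean_n_features=nf.mean(axis=0), sd_n_features=nf.std(axis=0, ddof=0))
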
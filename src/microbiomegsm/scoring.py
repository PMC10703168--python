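"""The S component: cross-validated classification accuracy per taxon group.

Each group's sub-dataset is scored with a random forest under stratified,
shuffled k-fold cross-validation on the training samples only; the group score
is the mean fold accuracy. Groups are then ranked by score (ties broken
alphabetically) and the top k proceed to cumulative modeling.

Seeds are derived deterministically per (global seed, MCCV iteration, group
name), so scores are reproducible without being artificially correlated across
groups.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .errors import ModelingError
from .grouping import GroupMap, SubDataset, make_subdataset
from .profile_io import AbundanceMatrix

logger = logging.getLogger("microbiomegsm")


def derive_seed(*parts) -> int:
    """Deterministic sub-seed from arbitrary hashable parts (stable across runs)."""
    text = "\x1f".join(str(p) for p in parts)
    digest = hashlib.blake2b(text.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class ScoringConfig:
    """How each group's sub-dataset is scored.

    ``cv_scheme`` selects between a single shuffled stratified k-fold partition
    (``"kfold"``, the default) and repeated stratified shuffle-split
    (``"shuffle_split"``, with ``n_folds`` splits of size 1/n_folds).
    """

    n_folds: int = 5
    classifier: str = "random_forest"
    n_estimators: int = 100
    shuffle: bool = True
    seed: int = 0
    cv_scheme: str = "kfold"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ModelingError("n_folds must be >= 2")
        if self.cv_scheme not in ("kfold", "shuffle_split"):
            raise ModelingError(f"unknown cv_scheme {self.cv_scheme!r}")


@dataclass(frozen=True)
class GroupScore:
    group_name: str
    fold_accuracies: tuple[float, ...]
    score: float
    n_features: int


def make_classifier(classifier: str, n_estimators: int, seed: int):
    """Instantiate the configured classifier with library-default hyperparameters."""
    if classifier == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    raise ModelingError(f"unknown classifier {classifier!r}")


def _cv_splitter(cfg: ScoringConfig, n_folds: int):
    if cfg.cv_scheme == "shuffle_split":
        return StratifiedShuffleSplit(n_splits=cfg.n_folds, test_size=1.0 / n_folds,
                                      random_state=cfg.seed)
    return StratifiedKFold(n_splits=n_folds, shuffle=cfg.shuffle,
                           random_state=cfg.seed if cfg.shuffle else None)


def score_group(sub_d: SubDataset, cfg: ScoringConfig) -> GroupScore:
    """Score one group: mean accuracy over stratified shuffled CV folds.

    Samples are put in a canonical order (sorted by sample id) before fold
    assignment, so the score is invariant to the order samples arrive in. If
    the minority class has fewer members than ``n_folds`` the fold count is
    reduced to that size (minimum 2, with a warning).
    """
    order = np.argsort(np.asarray(sub_d.sample_ids))
    X = sub_d.values[order]
    y = sub_d.labels[order]

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelingError(f"group {sub_d.group_name!r}: single-class data, cannot stratify")
    minority = int(counts.min())
    if minority < 2:
        raise ModelingError(
            f"group {sub_d.group_name!r}: minority class has {minority} sample(s); "
            "need >= 2 for stratified CV"
        )
    n_folds = min(cfg.n_folds, minority)
    if n_folds < cfg.n_folds:
        logger.warning("group %s: folds reduced from %d to %d (minority class size)",
                       sub_d.group_name, cfg.n_folds, n_folds)

    accs: list[float] = []
    for fold, (tr, te) in enumerate(_cv_splitter(cfg, n_folds).split(X, y)):
        clf = make_classifier(cfg.classifier, cfg.n_estimators, derive_seed(cfg.seed, fold))
        clf.fit(X[tr], y[tr])
        accs.append(float(accuracy_score(y[te], clf.predict(X[te]))))
    return GroupScore(
        group_name=sub_d.group_name,
        fold_accuracies=tuple(accs),
        score=float(np.mean(accs)),
        n_features=sub_d.n_features,
    )


def score_all_groups(train_matrix: AbundanceMatrix, group_map: GroupMap,
                     cfg: ScoringConfig, iteration: int = 0) -> list[GroupScore]:
    """Score every group of ``group_map`` on the training matrix.

    Each group gets its own derived seed (from ``cfg.seed``, the MCCV iteration
    and the group name), so results do not depend on group evaluation order.
    """
    scores: list[GroupScore] = []
    for name, species in group_map.groups.items():
        sub = make_subdataset(train_matrix, name, species)
        group_cfg = replace(cfg, seed=derive_seed(cfg.seed, iteration, name))
        try:
            scores.append(score_group(sub, group_cfg))
        except ModelingError as exc:
            raise ModelingError(f"scoring group {name!r} failed: {exc}") from exc
    return scores


def rank_groups(scores: Sequence[GroupScore], k: int = 10) -> list[str]:
    """Top-k group names by score (descending), ties broken alphabetically."""
    if not scores:
        raise ModelingError("no group scores to rank")
    if k < 1:
        raise ModelingError("k must be >= 1")
    ranked = sorted(scores, key=lambda s: (-s.score, s.group_name.casefold()))
    return [s.group_name for s in ranked[:k]]


def scores_to_rows(scores: Sequence[GroupScore]) -> list[dict]:
    """Flatten group scores for CSV export (group, n_features, fold_1.., mean)."""
    rows = []
    for s in scores:
        row = {"group_name": s.group_name, "n_features": s.n_features}
        row.update({f"fold_{i + 1}": a for i, a in enumerate(s.fold_accuracies)})
        row["mean_score"] = s.score
        rows.append(row)
    return rows
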
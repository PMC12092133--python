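"""Exhaustive leave-one-per-class-out SVM cross-validation.

Classifiers are trained to recover the biological cell class (BC, DC, OSN,
SC) from per-stimulus features — either the participant-averaged aligned 2D
arrangement coordinates or the cohort-mean rating data projected into PCA
space.  Cross-validation enumerates every combination of one held-out
exemplar per class: with 6 exemplars in each of 4 classes that is 6^4 = 1296
folds, a 20-cell training split per fold, and each labelled stimulus tested
in exactly 6^3 = 216 folds.  Every fold also queries the classifier for the
class of the six indeterminate cells; votes are aggregated across folds.

The classifier is a linear soft-margin SVM (C = 1) in a one-vs-rest
decomposition, with features standardized on each fold's training split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .core import (
    Arrangement,
    INDETERMINATE,
    KNOWN_CLASSES,
    StimulusSet,
)
from .ratings import PcaResult

#: Chance accuracy for a balanced 4-class problem.
CHANCE_ACCURACY = 0.25


@dataclass(frozen=True)
class FeatureTable:
    """Per-stimulus feature vectors with class labels."""

    stimulus_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    features: np.ndarray

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.shape[0] != len(self.stimulus_ids):
            raise ValueError("features row count mismatch")
        object.__setattr__(self, "features", feats)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def arrangement_features(
    aligned: list[Arrangement], stimset: StimulusSet
) -> FeatureTable:
    """Per-stimulus mean of Procrustes-aligned 2D coordinates (in cm).

    Averages over all supplied arrangements (participants and sessions);
    the arrangements must already be mutually aligned, otherwise arbitrary
    rigid placements would cancel out in the mean.
    """
    if not aligned:
        raise ValueError("no arrangements given")
    ids = stimset.stimulus_ids
    for arr in aligned:
        if arr.stimulus_ids != ids:
            raise ValueError("arrangement stimulus set mismatch")
    mean_coords = np.mean([arr.coords for arr in aligned], axis=0)
    return FeatureTable(ids, stimset.class_labels, mean_coords)


def rating_features(
    pca: PcaResult, stimset: StimulusSet, n_components: int
) -> FeatureTable:
    """The first ``n_components`` PCA score columns as stimulus features."""
    total = pca.scores.shape[1]
    if not 1 <= n_components <= total:
        raise ValueError(f"n_components must be in [1, {total}]")
    if pca.scores.shape[0] != stimset.n_stimuli:
        raise ValueError("PCA scores do not match the stimulus set")
    return FeatureTable(
        stimset.stimulus_ids,
        stimset.class_labels,
        pca.scores[:, :n_components],
    )


@dataclass(frozen=True)
class ClassificationResult:
    """Aggregate of the exhaustive leave-one-per-class-out CV."""

    n_folds: int
    accuracy: float
    confusion: np.ndarray  # 4 x 4 counts, true class x predicted class
    class_order: tuple[str, ...]
    indeterminate_ids: tuple[str, ...]
    indeterminate_votes: np.ndarray  # n_indeterminate x 4 counts
    chance: float
    best_achievable: float
    fold_log: list  # (fold, held_out_ids, true_labels, predicted_labels)

    @property
    def confusion_normalized(self) -> np.ndarray:
        """Row-normalized confusion (proportions per true class)."""
        totals = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.maximum(totals, 1)

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "accuracy": self.accuracy,
            "chance": self.chance,
            "best_achievable": self.best_achievable,
            "class_order": list(self.class_order),
            "confusion_counts": self.confusion.tolist(),
            "confusion_proportions": self.confusion_normalized.tolist(),
            "indeterminate_ids": list(self.indeterminate_ids),
            "indeterminate_votes": self.indeterminate_votes.tolist(),
        }


def _make_classifier(c: float) -> LinearSVC:
    # liblinear one-vs-rest linear SVM; dual=False (n > d) is deterministic.
    return LinearSVC(C=c, dual=False)


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((x - mu) / sd for x in (train, *others))


def leave_one_per_class_cv(
    table: FeatureTable,
    c: float = 1.0,
    standardize: bool = True,
    strict: bool = True,
) -> ClassificationResult:
    """Exhaustive one-held-out-exemplar-per-class SVM cross-validation.

    Per fold: hold out one stimulus from each known class, standardize
    features on the remaining training cells, train the SVM, predict the
    held-out cells and all indeterminate cells.  Deterministic.

    With ``strict=True`` (the study design) every known class must have
    exactly 6 members, giving 1296 folds of 20 training cells.
    """
    labels = np.asarray(table.class_labels)
    class_members = [
        np.flatnonzero(labels == cls) for cls in KNOWN_CLASSES
    ]
    for cls, members in zip(KNOWN_CLASSES, class_members):
        if len(members) == 0:
            raise ValueError(f"class {cls} has no members")
        if strict and len(members) != 6:
            raise ValueError(
                f"class {cls} has {len(members)} members, expected 6"
            )
    indet_idx = np.flatnonzero(labels == INDETERMINATE)
    labelled_idx = np.concatenate(class_members)
    X = table.features
    y = labels
    cls_pos = {c_: i for i, c_ in enumerate(KNOWN_CLASSES)}

    confusion = np.zeros((4, 4), dtype=int)
    indet_votes = np.zeros((len(indet_idx), 4), dtype=int)
    fold_log = []
    n_correct = 0
    for fold, held in enumerate(itertools.product(*class_members)):
        held = np.asarray(held)
        train_idx = np.setdiff1d(labelled_idx, held)
        X_train = X[train_idx]
        if standardize:
            if len(indet_idx):
                X_train, X_test, X_indet = _standardize(
                    X_train, X[held], X[indet_idx]
                )
            else:
                X_train, X_test = _standardize(X_train, X[held])
                X_indet = None
        else:
            X_test = X[held]
            X_indet = X[indet_idx] if len(indet_idx) else None
        clf = _make_classifier(c).fit(X_train, y[train_idx])
        pred = clf.predict(X_test)
        for true_lab, pred_lab in zip(y[held], pred):
            confusion[cls_pos[true_lab], cls_pos[pred_lab]] += 1
            n_correct += int(true_lab == pred_lab)
        if X_indet is not None:
            for i, pred_lab in enumerate(clf.predict(X_indet)):
                indet_votes[i, cls_pos[pred_lab]] += 1
        fold_log.append(
            (
                fold,
                tuple(table.stimulus_ids[i] for i in held),
                tuple(y[held]),
                tuple(pred),
            )
        )
    n_folds = len(fold_log)
    n_tests = 4 * n_folds
    return ClassificationResult(
        n_folds=n_folds,
        accuracy=n_correct / n_tests,
        confusion=confusion,
        class_order=KNOWN_CLASSES,
        indeterminate_ids=tuple(table.stimulus_ids[i] for i in indet_idx),
        indeterminate_votes=indet_votes,
        chance=CHANCE_ACCURACY,
        best_achievable=best_achievable(table, c=c, standardize=standardize),
        fold_log=fold_log,
    )


def best_achievable(
    table: FeatureTable, c: float = 1.0, standardize: bool = True
) -> float:
    """Resubstitution accuracy on all labelled cells.

    The same classifier trained and evaluated on the full labelled set —
    an optimistic upper-bound reference for the cross-validated accuracy.
    (The definition is a stand-in: a resubstitution ceiling, not an
    estimate of attainable out-of-sample accuracy.)
    """
    labels = np.asarray(table.class_labels)
    keep = labels != INDETERMINATE
    X, y = table.features[keep], labels[keep]
    if standardize:
        (X,) = _standardize(X)
    clf = _make_classifier(c).fit(X, y)
    return float(np.mean(clf.predict(X) == y))


def summarize_indeterminate(result: ClassificationResult) -> list[dict]:
    """Modal predicted class and vote fractions for each indeterminate cell.

    Ties are broken towards the earliest class in canonical order
    (BC, DC, OSN, SC).
    """
    out = []
    for sid, votes in zip(result.indeterminate_ids, result.indeterminate_votes):
        total = votes.sum()
        fractions = votes / total if total else votes.astype(float)
        modal = result.class_order[int(np.argmax(votes))]
        out.append(
            {
                "stimulus_id": sid,
                "modal_class": modal,
                "vote_fractions": dict(zip(result.class_order, fractions)),
            }
        )
    return out


def permutation_null(
    table: FeatureTable,
    n_permutations: int = 100,
    seed: int = 0,
    c: float = 1.0,
) -> np.ndarray:
    """CV accuracies under random relabelling of the labelled cells.

    Permutes the class labels among the non-indeterminate stimuli (class
    sizes preserved) and reruns the exhaustive CV; the resulting accuracy
    distribution calibrates the chance level of 0.25.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(table.class_labels)
    labelled = np.flatnonzero(labels != INDETERMINATE)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = labels.copy()
        perm[labelled] = perm[labelled][rng.permutation(len(labelled))]
        shuffled = FeatureTable(
            table.stimulus_ids, tuple(perm), table.features
        )
        accs[i] = leave_one_per_class_cv(shuffled, c=c).accuracy
    return accs
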
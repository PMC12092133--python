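"""Core data containers and shared matrix utilities.

The package analyses two kinds of behavioural data collected on a common
stimulus set of 3D-printed cell models from the tadpole olfactory epithelium:

* *arrangements* — 2D positions of the stimuli on a workbench, where spatial
  proximity encodes perceived shape similarity (multi-arrangement task);
* *ratings* — per-stimulus judgements along a handful of visual feature
  dimensions (size, spikiness, ...).

Both are reduced to representational dissimilarity matrices (RDMs): symmetric
matrices of pairwise dissimilarities between stimuli, max-normalized so the
largest off-diagonal entry is 1.  Every agreement statistic in the package is
a Pearson correlation between the strict upper triangles of two RDMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical cell-class ordering: basal cells, dividing cells, olfactory
#: sensory neurons, supporting cells, indeterminate cells.
CLASSES = ("BC", "DC", "OSN", "SC", "I")

#: The four classes with a confirmed biological identity.
KNOWN_CLASSES = ("BC", "DC", "OSN", "SC")

#: Label used for cells of unresolved type.
INDETERMINATE = "I"


class SchemaError(ValueError):
    """A tabular input violates the expected schema."""


class DegenerateInputError(ValueError):
    """An input is too degenerate to process (e.g. all points coincident)."""


class DegenerateInputWarning(UserWarning):
    """A statistic is undefined for this input (e.g. zero-variance vector)."""


@dataclass(frozen=True)
class StimulusSet:
    """An ordered stimulus manifest with class labels.

    ``latent_features`` holds the simulator's ground-truth feature vectors
    (one row per stimulus); it is ``None`` for manifests read from disk.
    """

    stimulus_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    latent_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.stimulus_ids) != len(self.class_labels):
            raise SchemaError("stimulus_ids and class_labels length mismatch")
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise SchemaError("stimulus_ids must be unique")
        bad = sorted(set(self.class_labels) - set(CLASSES))
        if bad:
            raise SchemaError(f"unknown class labels: {bad}")
        if self.latent_features is not None:
            feats = np.asarray(self.latent_features, dtype=float)
            if feats.shape[0] != len(self.stimulus_ids):
                raise SchemaError("latent_features row count mismatch")
            if not np.all(np.isfinite(feats)):
                raise SchemaError("latent_features must be finite")
            object.__setattr__(self, "latent_features", feats)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    def class_of(self, stimulus_id: str) -> str:
        return self.class_labels[self.stimulus_ids.index(stimulus_id)]

    def indices_of_class(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.class_labels) == label)

    def without_indeterminate(self) -> "StimulusSet":
        """Restrict to the stimuli with a known class (drops the I set)."""
        keep = [i for i, c in enumerate(self.class_labels) if c != INDETERMINATE]
        feats = None if self.latent_features is None else self.latent_features[keep]
        return StimulusSet(
            tuple(self.stimulus_ids[i] for i in keep),
            tuple(self.class_labels[i] for i in keep),
            feats,
        )

    def validate_design(self, n_per_class: int = 6) -> None:
        """Check the balanced study design (every class equally represented)."""
        labels = np.asarray(self.class_labels)
        for cls in CLASSES:
            n = int(np.sum(labels == cls))
            if n != n_per_class:
                raise SchemaError(
                    f"class {cls} has {n} stimuli, expected {n_per_class}"
                )


@dataclass(frozen=True)
class Arrangement:
    """One participant-session configuration of stimuli on the workbench.

    Coordinates are in cm, ordered like ``stimulus_ids`` (canonical manifest
    order), one (x, y) row per stimulus.
    """

    participant_id: str
    session: int
    stimulus_ids: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.stimulus_ids), 2):
            raise SchemaError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.stimulus_ids)} stimuli"
            )
        if not np.all(np.isfinite(coords)):
            raise SchemaError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def positions(self) -> dict[str, tuple[float, float]]:
        return {s: tuple(xy) for s, xy in zip(self.stimulus_ids, self.coords)}

    def with_coords(self, coords: np.ndarray) -> "Arrangement":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class RatingMatrix:
    """Participants x stimuli x dimensions ratings with per-dimension scale tags.

    ``dimension_meta[d]`` is ``"continuous_unit_interval"`` for slider
    dimensions expressed in [0, 1] and ``"count"`` for dimensions answered
    with a small non-negative integer.
    """

    participant_ids: tuple[str, ...]
    stimulus_ids: tuple[str, ...]
    dimension_names: tuple[str, ...]
    dimension_meta: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        shape = (
            len(self.participant_ids),
            len(self.stimulus_ids),
            len(self.dimension_names),
        )
        if vals.shape != shape:
            raise SchemaError(f"values shape {vals.shape}, expected {shape}")
        if not np.all(np.isfinite(vals)):
            raise SchemaError("ratings must be finite (no missing cells)")
        if len(self.dimension_meta) != len(self.dimension_names):
            raise SchemaError("dimension_meta length mismatch")
        for tag in self.dimension_meta:
            if tag not in ("continuous_unit_interval", "count"):
                raise SchemaError(f"unknown dimension scale tag {tag!r}")
        for d, tag in enumerate(self.dimension_meta):
            if tag == "count":
                col = vals[:, :, d]
                if not np.allclose(col, np.round(col)) or np.any(col < 0):
                    raise SchemaError(
                        f"count dimension {self.dimension_names[d]!r} must hold "
                        "non-negative integers"
                    )
        object.__setattr__(self, "values", vals)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def mean_ratings(self) -> np.ndarray:
        """Cohort-mean stimuli x dimensions matrix."""
        return self.values.mean(axis=0)


@dataclass(frozen=True)
class RDM:
    """A labelled representational dissimilarity matrix.

    Symmetric, zero-diagonal, non-negative.  Matrices produced by the package
    are max-normalized (largest off-diagonal entry equals 1); model RDMs such
    as the binary class RDM are stored as constructed.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise SchemaError(f"matrix shape {m.shape} does not match {n} labels")
        if not np.all(np.isfinite(m)):
            raise SchemaError("RDM entries must be finite")
        if not np.allclose(m, m.T, atol=1e-12):
            raise SchemaError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise SchemaError("RDM diagonal must be zero")
        if np.any(m < -1e-12):
            raise SchemaError("RDM entries must be non-negative")
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, labels: "tuple[str, ...] | list[str]") -> "RDM":
        """Restrict to ``labels``, in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return RDM(tuple(labels), self.matrix[np.ix_(idx, idx)])


def upper_triangle(rdm: "RDM | np.ndarray") -> np.ndarray:
    """Row-major strict upper triangle of a square matrix (length n(n-1)/2)."""
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    return m[np.triu_indices(m.shape[0], k=1)]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) for zero-variance input.

    A degenerate correlation is flagged rather than silently mapped to zero
    so that simulation bugs producing constant RDMs surface immediately.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        warnings.warn(
            "correlation undefined for zero-variance input", DegenerateInputWarning
        )
        return float("nan")
    return float((xc @ yc) / denom)


def rdm_correlation(a: RDM, b: RDM) -> float:
    """Pearson correlation between the strict upper triangles of two RDMs.

    The RDMs are compared over their common labels (in ``a``'s order), so an
    average participant RDM over 30 stimuli can be correlated directly with a
    24-stimulus class RDM.
    """
    if a.labels != b.labels:
        common = [l for l in a.labels if l in set(b.labels)]
        if len(common) < 3:
            raise ValueError("RDMs share fewer than 3 labels")
        a = a.subset(common)
        b = b.subset(common)
    return pearson(upper_triangle(a), upper_triangle(b))
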
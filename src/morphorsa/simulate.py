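"""Synthetic cohort generator for the multi-arrangement and rating tasks.

The generator emulates the structure the analyses assume without modelling
any motor or haptic behaviour:

1. Each stimulus is a point in a D-dimensional latent shape space.  The four
   known cell classes (BC, DC, OSN, SC) sit at the corners of a square of
   side ``class_separation`` lying in a 2D plane of the latent space (the
   arrangement task is inherently planar, so planar centroids let a faithful
   participant reproduce the class geometry on the workbench; a full simplex
   of equidistant centroids cannot be embedded in 2D without distorting the
   between-class distances).  The square is ordered BC, DC, SC, OSN so that
   basal and dividing cells are adjacent and dividing cells sit nearer
   supporting cells than sensory neurons.  The indeterminate (I) centroid
   lies on the segment from the OSN centroid towards the SC centroid, nearer
   OSN, reflecting that indeterminate cells are mostly immature sensory
   neurons.  Class members scatter around their centroid with isotropic SD
   ``within_class_sd``.

2. An arrangement is a classical (Torgerson) 2D metric embedding of the
   latent pairwise distances, perturbed by participant-level jitter (stable
   across a participant's sessions) and session-level jitter, then placed on
   the workbench by a random rigid transform (rotation, translation,
   reflection with probability 1/2) and an isotropic rescale into the
   ``workbench_cm`` square.  RDMs are invariant to the rigid transform and
   the isotropic rescale by construction.

3. A rating is a monotone min-max readout of one latent feature dimension
   with participant noise added in latent space; six dimensions are emitted
   as continuous values in [0, 1] and two ("main body parts", "number of
   limbs") as small non-negative integers.

All randomness derives from ``SimulationConfig.seed`` through fixed
per-(purpose, participant, session) substreams, so any slice of the cohort
can be regenerated bit-identically in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CLASSES,
    INDETERMINATE,
    Arrangement,
    RatingMatrix,
    StimulusSet,
)

DEFAULT_DIMENSION_NAMES = (
    "size",
    "spikiness",
    "elongation",
    "symmetry",
    "main body parts",
    "number of limbs",
    "surface complexity",
    "roundness",
)

#: Dimensions answered with a discrete count, and the count at full scale.
DEFAULT_COUNT_MAXIMA = {"main body parts": 4, "number of limbs": 8}

# Substream tags for the counter-based seed scheme.
_TAG_STIMSET = 0
_TAG_PARTICIPANT = 1
_TAG_SESSION = 2
_TAG_RIGID = 3
_TAG_RATING = 4


class ConfigurationError(ValueError):
    """A SimulationConfig field is out of its valid range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design: 16 participants, 2 arrangement
    sessions, 30 stimuli (6 per class) on a 60 x 60 cm workbench, 8 rating
    dimensions.  Noise SDs are in latent-space units (the same units as
    ``class_separation``).
    """

    n_participants: int = 16
    n_sessions: int = 2
    n_per_class: int = 6
    n_dimensions: int = 8
    class_separation: float = 5.0
    within_class_sd: float = 1.25
    participant_noise_sd: float = 1.0
    session_noise_sd: float = 1.0
    workbench_cm: float = 60.0
    reflection_prob: float = 0.5
    indeterminate_mix: float = 0.35  # position of I centroid from OSN to SC
    dimension_names: tuple[str, ...] = DEFAULT_DIMENSION_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if not 4 <= self.n_dimensions:
            raise ConfigurationError("n_dimensions must be >= 4")
        if self.n_dimensions > len(self.dimension_names):
            raise ConfigurationError("not enough dimension names")
        for name in ("class_separation", "within_class_sd",
                     "participant_noise_sd", "session_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.workbench_cm <= 0:
            raise ConfigurationError("workbench_cm must be positive")
        if not 0.0 <= self.reflection_prob <= 1.0:
            raise ConfigurationError("reflection_prob must be in [0, 1]")
        if not 0.0 <= self.indeterminate_mix <= 1.0:
            raise ConfigurationError("indeterminate_mix must be in [0, 1]")

    @property
    def n_stimuli(self) -> int:
        return self.n_per_class * len(CLASSES)

    def count_dimensions(self) -> tuple[int, ...]:
        """Indices of the discrete (count-scale) rating dimensions."""
        return tuple(
            d for d, name in enumerate(self.dimension_names[: self.n_dimensions])
            if name in DEFAULT_COUNT_MAXIMA
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _class_centroids(config: SimulationConfig) -> np.ndarray:
    """Centroids of the 5 classes in latent space, (5, D).

    The four known classes form a square of side ``class_separation`` in a
    2D plane; a seeded random orthogonal rotation spreads that plane over
    all D latent dimensions so every rating dimension carries some class
    signal.  The I centroid interpolates OSN -> SC.
    """
    D = config.n_dimensions
    s = config.class_separation
    known = np.zeros((4, D))
    # Square cycle BC -> DC -> SC -> OSN: BC-DC, DC-SC adjacent (distance s);
    # DC-OSN and BC-SC are the diagonals (distance s * sqrt(2)).
    corners = {"BC": (0.0, 0.0), "DC": (s, 0.0), "SC": (s, s), "OSN": (0.0, s)}
    for i, cls in enumerate(("BC", "DC", "OSN", "SC")):
        known[i, :2] = corners[cls]
    rng = _rng(config.seed, _TAG_STIMSET, 0)
    q, r = np.linalg.qr(rng.normal(size=(D, D)))
    q *= np.sign(np.diag(r))  # unique Q, uniform over the orthogonal group
    known = known @ q
    centroids = {c: known[i] for i, c in enumerate(("BC", "DC", "OSN", "SC"))}
    t = config.indeterminate_mix
    centroids[INDETERMINATE] = (1 - t) * centroids["OSN"] + t * centroids["SC"]
    return np.stack([centroids[c] for c in CLASSES])


def generate_stimulus_set(config: SimulationConfig) -> StimulusSet:
    """Draw a stimulus set: per class, centroid + within-class Gaussian noise.

    Stimuli are ordered by class (BC, DC, OSN, SC, I) with ids like
    ``BC1 .. BC6``, matching the canonical manifest ordering used throughout.
    """
    centroids = _class_centroids(config)
    rng = _rng(config.seed, _TAG_STIMSET, 1)
    ids: list[str] = []
    labels: list[str] = []
    feats: list[np.ndarray] = []
    for c, cls in enumerate(CLASSES):
        noise = rng.normal(0.0, 1.0, size=(config.n_per_class, config.n_dimensions))
        feats.append(centroids[c] + config.within_class_sd * noise)
        ids.extend(f"{cls}{i + 1}" for i in range(config.n_per_class))
        labels.extend([cls] * config.n_per_class)
    return StimulusSet(tuple(ids), tuple(labels), np.vstack(feats))


def embed_latent_2d(stimset: StimulusSet) -> np.ndarray:
    """Classical (Torgerson) metric MDS of the latent distances into 2D.

    Deterministic: axis signs are fixed by making the largest-magnitude
    coordinate on each axis positive.
    """
    if stimset.latent_features is None:
        raise ValueError("stimulus set has no latent features")
    X = stimset.latent_features
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    coords = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def _fit_to_workbench(coords: np.ndarray, workbench_cm: float) -> np.ndarray:
    """Isotropically rescale and translate into the workbench square.

    The configuration is scaled to span 90% of the square's shorter extent
    and centred, guaranteeing all coordinates lie in [0, workbench_cm].
    """
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    extent = max(span.max(), 1e-12)
    s = 0.9 * workbench_cm / extent
    scaled = (coords - lo) * s
    offset = (workbench_cm - span * s) / 2.0
    return scaled + offset


def simulate_arrangement(
    stimset: StimulusSet,
    participant_index: int,
    session_index: int,
    config: SimulationConfig,
) -> Arrangement:
    """Simulate one participant-session arrangement on the workbench.

    Participant jitter is drawn once per participant (shared by both
    sessions: stable individual idiosyncrasies); session jitter and the
    rigid placement are drawn per participant-session.
    """
    if not 0 <= participant_index < config.n_participants:
        raise ConfigurationError("participant_index out of range")
    if not 0 <= session_index < config.n_sessions:
        raise ConfigurationError("session_index out of range")
    base = embed_latent_2d(stimset)
    n = base.shape[0]
    p_rng = _rng(config.seed, _TAG_PARTICIPANT, participant_index)
    s_rng = _rng(config.seed, _TAG_SESSION, participant_index, session_index)
    coords = (
        base
        + config.participant_noise_sd * p_rng.normal(size=(n, 2))
        + config.session_noise_sd * s_rng.normal(size=(n, 2))
    )
    r_rng = _rng(config.seed, _TAG_RIGID, participant_index, session_index)
    theta = r_rng.uniform(0.0, 2.0 * np.pi)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    if r_rng.random() < config.reflection_prob:
        rot = rot @ np.diag([1.0, -1.0])
    shift = r_rng.uniform(-10.0, 10.0, size=2)
    coords = coords @ rot.T + shift
    coords = _fit_to_workbench(coords, config.workbench_cm)
    return Arrangement(
        participant_id=f"P{participant_index + 1:02d}",
        session=session_index + 1,
        stimulus_ids=stimset.stimulus_ids,
        coords=coords,
    )


def simulate_ratings(
    stimset: StimulusSet,
    participant_index: int,
    config: SimulationConfig,
) -> np.ndarray:
    """One participant's stimuli x dimensions rating block (30 x 8 by default).

    Dimension d reads latent feature d through a min-max map onto [0, 1]
    (bounds from the noise-free latent column), after participant noise is
    added in latent space.  Count dimensions are then quantized to integers.
    """
    if not 0 <= participant_index < config.n_participants:
        raise ConfigurationError("participant_index out of range")
    if stimset.latent_features is None:
        raise ValueError("stimulus set has no latent features")
    D = config.n_dimensions
    latent = stimset.latent_features[:, :D]
    rng = _rng(config.seed, _TAG_RATING, participant_index)
    noisy = latent + config.participant_noise_sd * rng.normal(size=latent.shape)
    lo = latent.min(axis=0)
    span = np.maximum(latent.max(axis=0) - lo, 1e-12)
    scaled = np.clip((noisy - lo) / span, 0.0, 1.0)
    values = scaled.copy()
    for d in config.count_dimensions():
        max_count = DEFAULT_COUNT_MAXIMA[config.dimension_names[d]]
        values[:, d] = np.round(scaled[:, d] * max_count)
    return values


def dimension_meta(config: SimulationConfig) -> tuple[str, ...]:
    count = set(config.count_dimensions())
    return tuple(
        "count" if d in count else "continuous_unit_interval"
        for d in range(config.n_dimensions)
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[StimulusSet, list[Arrangement], RatingMatrix]:
    """Generate the full synthetic study: stimuli, arrangements, ratings."""
    stimset = generate_stimulus_set(config)
    arrangements = [
        simulate_arrangement(stimset, p, s, config)
        for p in range(config.n_participants)
        for s in range(config.n_sessions)
    ]
    values = np.stack(
        [simulate_ratings(stimset, p, config) for p in range(config.n_participants)]
    )
    ratings = RatingMatrix(
        participant_ids=tuple(f"P{p + 1:02d}" for p in range(config.n_participants)),
        stimulus_ids=stimset.stimulus_ids,
        dimension_names=config.dimension_names[: config.n_dimensions],
        dimension_meta=dimension_meta(config),
        values=values,
    )
    return stimset, arrangements, ratings
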
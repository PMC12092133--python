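"""Agreement analysis of multi-arrangement data.

Implements the full arrangement pipeline: rigid Procrustes alignment
(translation + rotation, reflection allowed, no rescaling), max-normalized
Euclidean-distance RDMs, within- and between-participant agreement, per-
session agreement, agreement with the biological cell classes (simple binary
and graded "complex" models), leave-one-out noise ceilings, a paired t-test
comparing sessions, and percentile bootstrap CIs of group means.

Notation (per participant p, sessions s1/s2):

    RDM_{p,Av} = (RDM_{p,s1} + RDM_{p,s2}) / 2
    W_p  = [corr(RDM_{p,s1}, RDM_{p,Av}) + corr(RDM_{p,s2}, RDM_{p,Av})] / 2
    B_p  = corr(RDM_{p,Av}, RDM_Av)            with RDM_Av the grand mean
    B_{p,s} = corr(RDM_{p,s}, RDM_{Av,s})      with the session-wise mean
    CC   = corr(RDM_CC, RDM_Av)                with RDM_CC the class model

All correlations are Pearson correlations of strict upper triangles.  The
grand mean in B_p deliberately includes the focal participant; the leave-one-
out variant is the noise-ceiling lower bound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from .core import (
    CLASSES,
    INDETERMINATE,
    Arrangement,
    DegenerateInputError,
    RDM,
    StimulusSet,
    pearson,
    upper_triangle,
)

# ---------------------------------------------------------------------------
# Procrustes alignment


def _align_one(
    coords: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Rigidly align ``coords`` to ``reference`` (no scaling, reflection OK)."""
    mu_x = coords.mean(axis=0)
    mu_r = reference.mean(axis=0)
    xc = coords - mu_x
    rc = reference - mu_r
    rot, _ = orthogonal_procrustes(xc, rc)
    aligned = xc @ rot + mu_r
    disparity = float(np.sum((aligned - reference) ** 2))
    return aligned, disparity


def procrustes_align(
    arrangements: list[Arrangement],
    reference: Arrangement | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[list[Arrangement], list[float]]:
    """Align arrangements by rigid (generalized) Procrustes analysis.

    With an explicit ``reference``, every arrangement is aligned to it in one
    pass.  Otherwise a generalized alignment iterates: start from the first
    configuration, align all to the current mean shape, recompute the mean,
    and repeat until the mean moves less than ``tol`` (Frobenius norm) or
    ``max_iter`` is reached.  Only translation and orthogonal transforms
    (rotations and reflections) are applied — no rescaling.

    Returns the aligned arrangements and the per-item disparity (minimized
    sum of squared distances to the final reference).
    """
    if not arrangements:
        return [], []
    ids = arrangements[0].stimulus_ids
    for arr in arrangements[1:]:
        if arr.stimulus_ids != ids:
            raise ValueError(
                f"arrangement {arr.participant_id} s{arr.session} has a "
                "different stimulus set"
            )
    if reference is not None:
        if reference.stimulus_ids != ids:
            raise ValueError("reference has a different stimulus set")
        ref = reference.coords
        aligned, disparities = zip(
            *(_align_one(a.coords, ref) for a in arrangements)
        )
        return (
            [a.with_coords(c) for a, c in zip(arrangements, aligned)],
            list(disparities),
        )
    ref = arrangements[0].coords - arrangements[0].coords.mean(axis=0)
    coords = [a.coords for a in arrangements]
    for _ in range(max_iter):
        aligned = [_align_one(c, ref)[0] for c in coords]
        new_ref = np.mean(aligned, axis=0)
        if np.linalg.norm(new_ref - ref) < tol:
            ref = new_ref
            break
        ref = new_ref
    results = [_align_one(c, ref) for c in coords]
    return (
        [a.with_coords(c) for a, (c, _) in zip(arrangements, results)],
        [d for _, d in results],
    )


# ---------------------------------------------------------------------------
# RDM construction


def compute_rdm(arrangement: Arrangement) -> RDM:
    """Pairwise Euclidean distances, normalized to the maximum distance.

    Invariant to any rigid motion (rotation, translation, reflection) and,
    thanks to max-normalization, to isotropic rescaling of the input.
    """
    d = pdist(arrangement.coords)
    dmax = d.max() if d.size else 0.0
    if dmax <= 0.0:
        raise DegenerateInputError(
            "all stimulus positions coincide; RDM undefined"
        )
    return RDM(arrangement.stimulus_ids, squareform(d / dmax))


def average_rdm(rdms: list[RDM]) -> RDM:
    """Entrywise mean of RDMs sharing a label set (not re-normalized)."""
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise ValueError("RDMs have different labels")
    return RDM(labels, np.mean([r.matrix for r in rdms], axis=0))


# ---------------------------------------------------------------------------
# agreement statistics


def within_participant_agreement(rdm_s1: RDM, rdm_s2: RDM) -> float:
    """Within-participant agreement W_p across the two sessions."""
    if rdm_s1.labels != rdm_s2.labels:
        raise ValueError("session RDMs have different labels")
    avg = average_rdm([rdm_s1, rdm_s2])
    w1 = pearson(upper_triangle(rdm_s1), upper_triangle(avg))
    w2 = pearson(upper_triangle(rdm_s2), upper_triangle(avg))
    return (w1 + w2) / 2.0


def between_participant_agreement(avg_rdms: list[RDM]) -> np.ndarray:
    """Per-participant B_p against the self-inclusive grand mean RDM."""
    if len(avg_rdms) < 2:
        raise ValueError("need at least 2 participants")
    grand = average_rdm(avg_rdms)
    gv = upper_triangle(grand)
    return np.array([pearson(upper_triangle(r), gv) for r in avg_rdms])


def session_agreement(
    rdms_s1: list[RDM], rdms_s2: list[RDM]
) -> tuple[np.ndarray, np.ndarray]:
    """Single-session between-participant agreements (B_{p,s1}, B_{p,s2})."""
    if len(rdms_s1) != len(rdms_s2):
        raise ValueError("session lists must be paired per participant")
    return (
        between_participant_agreement(rdms_s1),
        between_participant_agreement(rdms_s2),
    )


# ---------------------------------------------------------------------------
# cell-class models

#: Graded between-class dissimilarities honouring the biological ordering:
#: basal cells are nearest dividing cells (dividing cells are basal cells in
#: mitosis); dividing cells are nearer supporting cells than sensory neurons;
#: indeterminate cells are nearest the olfactory sensory neurons.
COMPLEX_MODEL_TABLE: dict[frozenset, float] = {
    frozenset({"BC", "DC"}): 0.5,
    frozenset({"DC", "SC"}): 0.75,
    frozenset({"I", "OSN"}): 0.5,
}


@dataclass(frozen=True)
class ClassModel:
    """A class-level dissimilarity model (simple binary or graded complex)."""

    kind: str  # "simple" | "complex"
    table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("simple", "complex"):
            raise ValueError("kind must be 'simple' or 'complex'")
        if self.kind == "complex":
            self._check_ordinal_constraints()

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        if self.kind == "simple":
            return 1.0
        return float(self.table.get(frozenset({a, b}), 1.0))

    def _check_ordinal_constraints(self) -> None:
        d = self.distance
        ok = (
            d("BC", "DC") < min(d("BC", "SC"), d("BC", "OSN"))
            and d("DC", "SC") < d("DC", "OSN")
            and d("I", "OSN") < min(d("I", c) for c in ("BC", "DC", "SC"))
        )
        if not ok:
            raise ValueError(
                "complex class model violates the ordinal constraints "
                "(BC nearest DC; DC nearer SC than OSN; I nearest OSN)"
            )

    @classmethod
    def simple(cls) -> "ClassModel":
        return cls("simple")

    @classmethod
    def complex_default(cls) -> "ClassModel":
        return cls("complex", dict(COMPLEX_MODEL_TABLE))


def class_rdm(
    stimset: StimulusSet,
    model: ClassModel | str = "simple",
    include_indeterminate: bool = False,
) -> RDM:
    """Model RDM derived from the cell-class labels.

    The simple model is binary (same class 0, different class 1) and, by
    default, excludes the indeterminate cells — they may belong to any
    class, so the ground-truth matrix is undefined for them.  The complex
    model assigns graded between-class distances and can include them.
    """
    if isinstance(model, str):
        model = (
            ClassModel.simple() if model == "simple"
            else ClassModel.complex_default() if model == "complex"
            else None
        )
        if model is None:
            raise ValueError("model must be 'simple' or 'complex'")
    subset = stimset if include_indeterminate else stimset.without_indeterminate()
    labels = subset.class_labels
    n = subset.n_stimuli
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = model.distance(labels[i], labels[j])
    return RDM(subset.stimulus_ids, m)


def class_agreement(avg_rdm: RDM, class_model_rdm: RDM) -> float:
    """CC = corr(RDM_CC, RDM_Av) over the model's stimuli."""
    common = [l for l in avg_rdm.labels if l in set(class_model_rdm.labels)]
    a = avg_rdm.subset(common)
    b = class_model_rdm.subset(common)
    return pearson(upper_triangle(a), upper_triangle(b))


# ---------------------------------------------------------------------------
# noise ceiling, session test, bootstrap


def noise_ceiling(avg_rdms: list[RDM]) -> tuple[float, float]:
    """Leave-one-out / self-inclusive bounds on attainable agreement.

    upper = mean_p corr(RDM_{p,Av}, grand mean including p)
    lower = mean_p corr(RDM_{p,Av}, mean over the other participants)
    """
    n = len(avg_rdms)
    if n < 3:
        raise ValueError("noise ceiling needs at least 3 participants")
    upper = float(np.mean(between_participant_agreement(avg_rdms)))
    lows = []
    for p in range(n):
        others = [r for q, r in enumerate(avg_rdms) if q != p]
        loo_mean = average_rdm(others)
        lows.append(
            pearson(upper_triangle(avg_rdms[p]), upper_triangle(loo_mean))
        )
    return float(np.mean(lows)), upper


@dataclass(frozen=True)
class SessionTest:
    t: float
    df: int
    p: float


def compare_sessions(b_s1: np.ndarray, b_s2: np.ndarray) -> SessionTest:
    """Paired two-tailed t-test of the per-participant session agreements."""
    b_s1 = np.asarray(b_s1, dtype=float)
    b_s2 = np.asarray(b_s2, dtype=float)
    if b_s1.shape != b_s2.shape:
        raise ValueError("paired vectors must have equal length")
    n = b_s1.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = b_s1 - b_s2
    sd = diff.std(ddof=1)
    if sd == 0.0:
        # Degenerate pairs: identical vectors give t = 0 (no effect, p = 1);
        # a constant non-zero difference is infinitely significant.
        m = diff.mean()
        if m == 0.0:
            return SessionTest(0.0, n - 1, 1.0)
        return SessionTest(float(np.sign(m)) * np.inf, n - 1, 0.0)
    from scipy.stats import ttest_rel

    res = ttest_rel(b_s1, b_s2)
    return SessionTest(float(res.statistic), n - 1, float(res.pvalue))


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 95.0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling with replacement."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# full report


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics of one arrangement cohort."""

    participant_ids: tuple[str, ...]
    within: np.ndarray  # W_p
    between: np.ndarray  # B_p
    between_s1: np.ndarray  # B_{p,s1}
    between_s2: np.ndarray  # B_{p,s2}
    within_mean_ci: tuple[float, float]
    between_mean_ci: tuple[float, float]
    class_agreement_simple: float
    class_agreement_complex: float
    noise_ceiling: tuple[float, float]
    session_test: SessionTest
    average_rdm: RDM
    per_participant_rdms: dict

    @property
    def within_mean(self) -> float:
        return float(np.mean(self.within))

    @property
    def between_mean(self) -> float:
        return float(np.mean(self.between))

    def to_dict(self) -> dict:
        return {
            "participant_ids": list(self.participant_ids),
            "within_participant": {
                "per_participant": self.within.tolist(),
                "mean": self.within_mean,
                "ci95": list(self.within_mean_ci),
            },
            "between_participant": {
                "per_participant": self.between.tolist(),
                "mean": self.between_mean,
                "ci95": list(self.between_mean_ci),
            },
            "between_participant_session1": {
                "per_participant": self.between_s1.tolist(),
                "mean": float(np.mean(self.between_s1)),
            },
            "between_participant_session2": {
                "per_participant": self.between_s2.tolist(),
                "mean": float(np.mean(self.between_s2)),
            },
            "class_agreement": {
                "simple": self.class_agreement_simple,
                "complex": self.class_agreement_complex,
            },
            "noise_ceiling": {
                "lower": self.noise_ceiling[0],
                "upper": self.noise_ceiling[1],
            },
            "session_test": {
                "t": self.session_test.t,
                "df": self.session_test.df,
                "p": self.session_test.p,
            },
        }


def analyze_arrangements(
    arrangements: list[Arrangement],
    stimset: StimulusSet,
    n_boot: int = 10_000,
    seed: int = 0,
) -> AgreementReport:
    """Run the complete agreement analysis on a two-session cohort."""
    by_participant: dict[str, dict[int, Arrangement]] = {}
    for arr in arrangements:
        by_participant.setdefault(arr.participant_id, {})[arr.session] = arr
    pids = tuple(sorted(by_participant))
    rdms_s1, rdms_s2, avg_rdms, within = [], [], [], []
    for pid in pids:
        sessions = by_participant[pid]
        if set(sessions) != {1, 2}:
            raise ValueError(
                f"participant {pid!r} must have exactly sessions 1 and 2"
            )
        r1 = compute_rdm(sessions[1])
        r2 = compute_rdm(sessions[2])
        rdms_s1.append(r1)
        rdms_s2.append(r2)
        avg_rdms.append(average_rdm([r1, r2]))
        within.append(within_participant_agreement(r1, r2))
    within = np.array(within)
    between = between_participant_agreement(avg_rdms)
    b_s1, b_s2 = session_agreement(rdms_s1, rdms_s2)
    grand = average_rdm(avg_rdms)
    cc_simple = class_agreement(grand, class_rdm(stimset, "simple"))
    cc_complex = class_agreement(
        grand, class_rdm(stimset, "complex", include_indeterminate=True)
    )
    return AgreementReport(
        participant_ids=pids,
        within=within,
        between=between,
        between_s1=b_s1,
        between_s2=b_s2,
        within_mean_ci=bootstrap_ci(within, n_boot=n_boot, seed=seed),
        between_mean_ci=bootstrap_ci(between, n_boot=n_boot, seed=seed + 1),
        class_agreement_simple=cc_simple,
        class_agreement_complex=cc_complex,
        noise_ceiling=noise_ceiling(avg_rdms),
        session_test=compare_sessions(b_s1, b_s2),
        average_rdm=grand,
        per_participant_rdms={
            pid: avg for pid, avg in zip(pids, avg_rdms)
        },
    )
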
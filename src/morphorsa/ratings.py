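"""Analysis of the feature-rating task.

Covers per-dimension between-participant agreement (within one cohort or
against an external cohort's mean ratings), per-dimension rating RDMs,
the cross-task linear RDM regression

    RDM_Av = sum_d beta_d * RDM^Rt_{p,d} + delta

fitted by OLS on strict upper triangles, frozen-coefficient transfer to a
second cohort, the multicollinearity matrix of the rating dimensions, PCA of
the cohort-mean ratings with mixed-scale standardization (count dimensions
min-max rescaled to [0, 1] before centring), and the regression of
PCA-dimension RDMs onto the cell-class RDM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateInputError,
    DegenerateInputWarning,
    RatingMatrix,
    RDM,
    pearson,
    upper_triangle,
)

# ---------------------------------------------------------------------------
# agreement


def rating_agreement(
    ratings: RatingMatrix,
    reference_means: np.ndarray | None = None,
) -> np.ndarray:
    """Per-participant, per-dimension agreement B_{p,d}.

    For each dimension, the Pearson correlation over stimuli between the
    participant's ratings and the cohort-mean ratings (self-inclusive).
    Passing ``reference_means`` (stimuli x dimensions, e.g. another
    experiment's cohort means) switches to cross-experiment mode: the
    correlations are taken against the external means instead.
    """
    means = ratings.mean_ratings() if reference_means is None else np.asarray(
        reference_means, dtype=float
    )
    if means.shape != ratings.values.shape[1:]:
        raise ValueError("reference_means shape mismatch")
    P, _, D = ratings.values.shape
    out = np.empty((P, D))
    for p in range(P):
        for d in range(D):
            out[p, d] = pearson(ratings.values[p, :, d], means[:, d])
    return out


# ---------------------------------------------------------------------------
# rating RDMs


def rating_rdm(values: np.ndarray, labels: tuple[str, ...]) -> RDM:
    """Max-normalized pairwise absolute differences of one rating vector."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size != len(labels):
        raise ValueError("values and labels length mismatch")
    diff = np.abs(v[:, None] - v[None, :])
    dmax = diff.max()
    if dmax <= 0.0:
        raise DegenerateInputError("all ratings equal; rating RDM undefined")
    return RDM(tuple(labels), diff / dmax)


def participant_rating_rdms(ratings: RatingMatrix, participant: int) -> list[RDM]:
    """The per-dimension RDMs of one participant (8 RDMs by default)."""
    return [
        rating_rdm(ratings.values[participant, :, d], ratings.stimulus_ids)
        for d in range(len(ratings.dimension_names))
    ]


# ---------------------------------------------------------------------------
# RDM regression


@dataclass(frozen=True)
class RdmRegressionModel:
    """OLS fit of predictor RDMs onto a target RDM (upper triangles)."""

    beta: np.ndarray
    intercept: float
    fit_r: float
    rank_deficient: bool
    labels: tuple[str, ...]

    def predict(self, rating_rdms: list[RDM]) -> np.ndarray:
        """Predicted upper-triangle vector for a new set of predictor RDMs."""
        if len(rating_rdms) != self.beta.size:
            raise ValueError(
                f"model has {self.beta.size} coefficients but "
                f"{len(rating_rdms)} predictor RDMs were given"
            )
        X = np.column_stack(
            [upper_triangle(r.subset(self.labels)) for r in rating_rdms]
        )
        return X @ self.beta + self.intercept


def fit_rdm_regression(
    rating_rdms: list[RDM], target: RDM
) -> RdmRegressionModel:
    """OLS regression of predictor RDM upper triangles onto a target RDM.

    For the default design this is 435 observations on 8 predictors plus an
    intercept.  Rank-deficient designs are flagged and solved by the
    minimum-norm least-squares solution.
    """
    labels = target.labels
    X = np.column_stack(
        [upper_triangle(r.subset(labels)) for r in rating_rdms]
    )
    y = upper_triangle(target)
    design = np.column_stack([X, np.ones(len(y))])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    rank_deficient = rank < design.shape[1]
    if rank_deficient:
        warnings.warn(
            "rank-deficient predictor RDMs; coefficients are the "
            "minimum-norm solution",
            DegenerateInputWarning,
        )
    fitted = design @ coef
    return RdmRegressionModel(
        beta=coef[:-1],
        intercept=float(coef[-1]),
        fit_r=pearson(fitted, y),
        rank_deficient=bool(rank_deficient),
        labels=labels,
    )


def transfer_predict(
    model: RdmRegressionModel, rating_rdms: list[RDM], target: RDM
) -> float:
    """Correlation of frozen-coefficient predictions with a target RDM.

    The coefficients are applied as fitted — no refitting — so this is the
    cross-cohort generalization test: coefficients estimated on one cohort's
    rating RDMs predict the target from a second cohort's rating RDMs.
    """
    prediction = model.predict(
        [r.subset(model.labels) for r in rating_rdms]
    )
    return pearson(prediction, upper_triangle(target.subset(model.labels)))


def fit_rdm_regression_per_participant(
    ratings: RatingMatrix, target: RDM
) -> list[RdmRegressionModel]:
    """Fit the cross-task regression separately for every participant."""
    return [
        fit_rdm_regression(participant_rating_rdms(ratings, p), target)
        for p in range(ratings.n_participants)
    ]


# ---------------------------------------------------------------------------
# multicollinearity and PCA


def multicollinearity(mean_ratings: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between the rating dimensions (D x D)."""
    m = np.asarray(mean_ratings, dtype=float)
    D = m.shape[1]
    out = np.eye(D)
    for i in range(D):
        for j in range(i + 1, D):
            out[i, j] = out[j, i] = pearson(m[:, i], m[:, j])
    return out


@dataclass(frozen=True)
class PcaResult:
    """PCA of the cohort-mean ratings (covariance eigendecomposition).

    ``scores`` are stimuli x components, ``loadings`` dimensions x
    components, ``variance_explained`` the per-component fraction of total
    variance.  ``scale_lo``/``scale_hi`` and ``column_means`` record the
    count-dimension rescaling and centring so per-participant data can be
    projected into the identical space.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    scale_lo: np.ndarray
    scale_hi: np.ndarray
    column_means: np.ndarray
    dimension_meta: tuple[str, ...]

    def transform(self, ratings: np.ndarray) -> np.ndarray:
        """Project a stimuli x dimensions matrix into the fitted PC space."""
        x = _rescale_columns(
            np.asarray(ratings, dtype=float),
            self.dimension_meta,
            self.scale_lo,
            self.scale_hi,
        )
        return (x - self.column_means) @ self.loadings


def _rescale_columns(
    m: np.ndarray,
    meta: tuple[str, ...],
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    out = m.copy()
    for d, tag in enumerate(meta):
        if tag == "count":
            span = hi[d] - lo[d]
            if span <= 0:
                warnings.warn(
                    f"count dimension {d} is constant; left unscaled",
                    DegenerateInputWarning,
                )
                continue
            out[:, d] = (out[:, d] - lo[d]) / span
    return out


def pca_ratings(
    mean_ratings: np.ndarray, dimension_meta: tuple[str, ...]
) -> PcaResult:
    """PCA of the cohort-mean ratings with mixed-scale standardization.

    Count dimensions are min-max rescaled to [0, 1] (observed bounds of the
    cohort-mean column) so they live on the same scale as the six slider
    dimensions; all columns are then centred and the covariance matrix
    eigendecomposed.  Components are ordered by decreasing variance and the
    sign of each is fixed by making its largest-magnitude loading positive.
    """
    m = np.asarray(mean_ratings, dtype=float)
    if m.shape[1] != len(dimension_meta):
        raise ValueError("dimension_meta length mismatch")
    lo = m.min(axis=0)
    hi = m.max(axis=0)
    x = _rescale_columns(m, dimension_meta, lo, hi)
    means = x.mean(axis=0)
    xc = x - means
    cov = np.cov(xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    loadings = evecs[:, order]
    for k in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, k]))
        if loadings[i, k] < 0:
            loadings[:, k] = -loadings[:, k]
    total = evals.sum()
    if total <= 0:
        raise DegenerateInputError("ratings have zero total variance")
    return PcaResult(
        scores=xc @ loadings,
        loadings=loadings,
        variance_explained=evals / total,
        scale_lo=lo,
        scale_hi=hi,
        column_means=means,
        dimension_meta=tuple(dimension_meta),
    )


# ---------------------------------------------------------------------------
# PCA-RDM regression onto cell class


def participant_pca_rdms(
    ratings: RatingMatrix, pca: PcaResult, participant: int
) -> list[RDM]:
    """Per-PCA-dimension RDMs of one participant's projected ratings."""
    scores = pca.transform(ratings.values[participant])
    return [
        rating_rdm(scores[:, k], ratings.stimulus_ids)
        for k in range(scores.shape[1])
    ]


def class_regression(
    per_participant_pca_rdms: list[list[RDM]], class_model_rdm: RDM
) -> tuple[np.ndarray, list[RdmRegressionModel]]:
    """Regress each participant's PCA-dimension RDMs onto the class RDM.

    The class RDM is restricted to the labelled (non-indeterminate) stimuli;
    each participant's predictor RDMs are subset accordingly inside the OLS.
    Returns the per-participant fitted correlations and the fitted models.
    """
    models = [
        fit_rdm_regression(rdms, class_model_rdm)
        for rdms in per_participant_pca_rdms
    ]
    return np.array([m.fit_r for m in models]), models
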
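"""Brain-model similarity as RDM regression.

The similarity between a brain RDM and a candidate model is the adjusted
coefficient of determination of an ordinary-least-squares regression of the
brain RDM's upper-triangle vector on the model's layer RDM vectors (with an
intercept).  Models are ranked by this adjusted R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rdm import RDM, ModelRDMSet, vectorize_upper

__all__ = [
    "RegressionFit",
    "ModelRanking",
    "fit_rdm_regression",
    "model_similarity",
    "rank_models",
    "ols_fit_vectors",
    "prediction_r2",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    """Result of an OLS fit of one RDM on a set of predictor RDMs."""

    r2: float
    r2_adj: float
    coefficients: np.ndarray  # per-predictor weights
    intercept: float
    n_samples: int
    n_predictors: int
    rank_deficient: bool = False


@dataclass(frozen=True)
class ModelRanking:
    """Models ordered by non-increasing adjusted R^2.

    ``ties`` lists groups of model names whose scores were numerically
    indistinguishable; their relative order is lexicographic by name.
    """

    entries: tuple[tuple[str, float], ...]
    ties: tuple[tuple[str, ...], ...] = ()

    def top(self, k: int) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries[:k])


def adjusted_r2(r2: float, n_samples: int, n_predictors: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(m - 1)/(m - p - 1)."""
    m, p = n_samples, n_predictors
    if m <= p + 1:
        raise ValueError(f"need n_samples > n_predictors + 1, got m={m}, p={p}")
    return 1.0 - (1.0 - r2) * (m - 1) / (m - p - 1)


def ols_fit_vectors(y: np.ndarray, X: np.ndarray) -> RegressionFit:
    """OLS of ``y`` on columns of ``X`` with an intercept.

    Rank-deficient (collinear) designs fall back to the minimum-norm
    least-squares solution with a logged warning rather than an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    m, p = X.shape
    if m != y.size:
        raise ValueError("predictor matrix not conformable with target vector")
    if m <= p + 1:
        raise ValueError(f"need n_samples > n_predictors + 1, got m={m}, p={p}")
    design = np.column_stack([X, np.ones(m)])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    rank_deficient = rank < design.shape[1]
    if rank_deficient:
        logger.warning(
            "collinear predictors (rank %d < %d); using minimum-norm solution",
            rank,
            design.shape[1],
        )
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("target vector is constant; R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    r2 = float(min(max(r2, 0.0), 1.0))  # clip numerical noise only
    # penalize by the effective predictor count (design rank minus the
    # intercept): identical to p for full-rank designs, and the only choice
    # that keeps duplicated predictors from changing the adjustment
    p_eff = max(int(rank) - 1, 0)
    return RegressionFit(
        r2=r2,
        r2_adj=float(adjusted_r2(r2, m, p_eff)),
        coefficients=beta[:-1],
        intercept=float(beta[-1]),
        n_samples=m,
        n_predictors=p,
        rank_deficient=rank_deficient,
    )


def prediction_r2(y: np.ndarray, X: np.ndarray, fit: RegressionFit) -> float:
    """Out-of-sample R^2 of a previous fit evaluated on new data.

    Computed from the training-fold coefficients; unlike a refit, this can
    be (and for useless predictors typically is) negative.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    pred = X @ fit.coefficients + fit.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("evaluation target is constant; R^2 undefined")
    return 1.0 - ss_res / ss_tot


def fit_rdm_regression(target: RDM, predictors: Sequence[RDM]) -> RegressionFit:
    """Regress a target RDM on predictor RDMs via their upper-triangle vectors.

    Predictors are aligned to the target's condition ids by string match
    before vectorization.  n_samples is the number of upper-triangle
    entries, n(n-1)/2.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("need at least one predictor RDM")
    y = vectorize_upper(target)
    X = np.column_stack(
        [vectorize_upper(p.reorder(target.condition_ids)) for p in predictors]
    )
    return ols_fit_vectors(y, X)


def model_similarity(target: RDM, model: ModelRDMSet) -> float:
    """Adjusted R^2 of the target RDM regressed on the model's layer RDMs."""
    return fit_rdm_regression(target, list(model.layer_rdms)).r2_adj


def rank_models(
    target: RDM, models: Sequence[ModelRDMSet], top_k: int | None = None
) -> ModelRanking:
    """Rank candidate models by adjusted R^2 against a target RDM.

    Ties (bit-identical scores) are broken lexicographically by model name
    and recorded on the ranking.
    """
    models = list(models)
    if top_k is not None and len(models) < top_k:
        raise ValueError(f"asked for top {top_k} of {len(models)} models")
    scored = [(m.model_name, model_similarity(target, m)) for m in models]
    scored.sort(key=lambda t: (-t[1], t[0]))
    ties: list[tuple[str, ...]] = []
    i = 0
    while i < len(scored):
        j = i
        while j + 1 < len(scored) and scored[j + 1][1] == scored[i][1]:
            j += 1
        if j > i:
            ties.append(tuple(name for name, _ in scored[i : j + 1]))
        i = j + 1
    return ModelRanking(entries=tuple(scored), ties=tuple(ties))
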
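"""Noise ceilings and cross-validated explained variance.

Between-subject variability bounds what any model can explain of a brain
RDM.  The lower bound predicts each subject's RDM from the mean RDM of the
remaining subjects; the upper bound uses the all-subject mean.  Model fits
are then cross-validated across subjects (N folds) or across subjects and
stimulus halves (2N folds), and the cross-validated R^2 is expressed as a
fraction of the lower bound (the explainable-variance ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rdm import RDM, _check_aligned, average_rdms, vectorize_upper
from .regression import ols_fit_vectors, prediction_r2

__all__ = [
    "SubjectRDMStack",
    "NoiseCeiling",
    "CVResult",
    "compute_noise_ceiling",
    "cv_explained_variance",
    "explainable_variance_ratio",
    "roi_inclusion",
]

CV_MODES = ("none", "subjects", "subjects_and_stimuli")


@dataclass(frozen=True)
class SubjectRDMStack:
    """Per-subject RDMs for one ROI or searchlight block."""

    rdms: tuple[RDM, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        rdms = tuple(self.rdms)
        if len(rdms) < 2:
            raise ValueError("need at least 2 subjects")
        _check_aligned(rdms)
        ids = tuple(str(s) for s in self.subject_ids)
        if len(ids) != len(rdms):
            raise ValueError("one subject id per RDM required")
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        object.__setattr__(self, "rdms", rdms)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n_subjects(self) -> int:
        return len(self.rdms)

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return self.rdms[0].condition_ids

    def mean_rdm(self) -> RDM:
        return average_rdms(self.rdms)

    def vectors(self) -> np.ndarray:
        """(n_subjects, n_pairs) matrix of upper-triangle vectors."""
        return np.stack([vectorize_upper(r) for r in self.rdms])


@dataclass(frozen=True)
class NoiseCeiling:
    """Lower/upper bounds on explainable RDM variance."""

    lower: float
    upper: float


@dataclass(frozen=True)
class CVResult:
    """Per-fold and mean cross-validated R^2 of a model fit."""

    mode: str
    fold_r2: tuple[float, ...]
    mean_r2: float
    fold_subjects: tuple[str, ...] = ()


def compute_noise_ceiling(stack: SubjectRDMStack) -> NoiseCeiling:
    """Leave-one-subject-out (lower) and all-subject-mean (upper) ceilings.

    Each bound is the across-subject mean of the adjusted R^2 of a
    single-predictor regression of the subject's RDM vector on the
    respective mean RDM vector.
    """
    if stack.n_subjects < 3:
        raise ValueError("noise ceiling needs >= 3 subjects")
    vecs = stack.vectors()
    total = vecs.sum(axis=0)
    n = stack.n_subjects
    lower_scores, upper_scores = [], []
    grand_mean = total / n
    for s in range(n):
        others_mean = (total - vecs[s]) / (n - 1)
        lower_scores.append(ols_fit_vectors(vecs[s], others_mean[:, None]).r2_adj)
        upper_scores.append(ols_fit_vectors(vecs[s], grand_mean[:, None]).r2_adj)
    return NoiseCeiling(lower=float(np.mean(lower_scores)),
                        upper=float(np.mean(upper_scores)))


def _pair_indices_within(n: int, members: np.ndarray) -> np.ndarray:
    """Upper-triangle vector indices of pairs whose both conditions are in
    ``members`` (row-major traversal, matching ``vectorize_upper``)."""
    in_half = np.zeros(n, dtype=bool)
    in_half[members] = True
    iu, ju = np.triu_indices(n, k=1)
    return np.flatnonzero(in_half[iu] & in_half[ju])


def cv_explained_variance(
    stack: SubjectRDMStack,
    predictor_rdms: Sequence[RDM],
    mode: str = "subjects_and_stimuli",
    seed: int | None = 0,
) -> CVResult:
    """Cross-validated R^2 of predictor RDMs against a subject RDM stack.

    mode ``"none"``
        Single in-sample fit on the subject-averaged RDM (no validation).
    mode ``"subjects"``
        N folds: fit on the mean RDM of N-1 subjects, evaluate the
        prediction R^2 on the held-out subject.
    mode ``"subjects_and_stimuli"``
        2N folds: conditions are split once (seeded) into two fixed
        halves; fit on the N-1-subject mean restricted to pairs within one
        half and evaluate on the held-out subject restricted to pairs
        within the other half, for both half orderings.

    Evaluation-fold R^2 is a prediction R^2 computed from the training-fold
    coefficients (no refit), so it can be negative and is unbiased near
    zero for uninformative predictors.
    """
    if mode not in CV_MODES:
        raise ValueError(f"mode must be one of {CV_MODES}, got {mode!r}")
    predictors = [p.reorder(stack.condition_ids) for p in predictor_rdms]
    if not predictors:
        raise ValueError("need at least one predictor RDM")
    X_full = np.column_stack([vectorize_upper(p) for p in predictors])
    vecs = stack.vectors()
    n_sub = stack.n_subjects
    n_cond = len(stack.condition_ids)

    if mode == "none":
        fit = ols_fit_vectors(vecs.mean(axis=0), X_full)
        return CVResult(mode=mode, fold_r2=(fit.r2,), mean_r2=fit.r2)

    if n_sub < 3:
        raise ValueError("cross-validation across subjects needs >= 3 subjects")

    if mode == "subjects":
        total = vecs.sum(axis=0)
        fold_r2, fold_subjects = [], []
        for s in range(n_sub):
            train_y = (total - vecs[s]) / (n_sub - 1)
            fit = ols_fit_vectors(train_y, X_full)
            fold_r2.append(prediction_r2(vecs[s], X_full, fit))
            fold_subjects.append(stack.subject_ids[s])
        return CVResult(
            mode=mode,
            fold_r2=tuple(fold_r2),
            mean_r2=float(np.mean(fold_r2)),
            fold_subjects=tuple(fold_subjects),
        )

    # subjects_and_stimuli: 2N folds over (subject, condition-half)
    if n_cond < 8:
        raise ValueError(
            "subjects_and_stimuli mode needs >= 8 conditions for a half-split"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cond)
    halves = (np.sort(perm[: n_cond // 2]), np.sort(perm[n_cond // 2 :]))
    half_pair_idx = [_pair_indices_within(n_cond, h) for h in halves]
    total = vecs.sum(axis=0)
    fold_r2, fold_subjects = [], []
    for s in range(n_sub):
        train_y_full = (total - vecs[s]) / (n_sub - 1)
        for train_half, test_half in ((0, 1), (1, 0)):
            tr, te = half_pair_idx[train_half], half_pair_idx[test_half]
            fit = ols_fit_vectors(train_y_full[tr], X_full[tr])
            fold_r2.append(prediction_r2(vecs[s][te], X_full[te], fit))
            fold_subjects.append(stack.subject_ids[s])
    return CVResult(
        mode=mode,
        fold_r2=tuple(fold_r2),
        mean_r2=float(np.mean(fold_r2)),
        fold_subjects=tuple(fold_subjects),
    )


def explainable_variance_ratio(cv_mean_r2: float, ceiling: NoiseCeiling) -> float:
    """Cross-validated R^2 as a fraction of the lower noise ceiling.

    May exceed 1 (the lower bound is itself an estimate).  A non-positive
    lower bound means the ROI carries no reliable signal and should be
    excluded rather than ratioed.
    """
    if ceiling.lower <= 0.0:
        raise ValueError(
            "lower noise ceiling <= 0: no explainable variance; exclude this ROI"
        )
    return float(cv_mean_r2 / ceiling.lower)


def roi_inclusion(stack: SubjectRDMStack, threshold: float = 0.1) -> bool:
    """Whether the ROI's lower noise ceiling clears the inclusion threshold."""
    return compute_noise_ceiling(stack).lower > threshold
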
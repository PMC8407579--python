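"""Representational dissimilarity matrices (RDMs) and operations on them.

An RDM is the common space in which brain responses and model activations
are compared: a symmetric condition x condition matrix of pairwise Pearson
distances (1 - r) between activation patterns.  All downstream analyses
(regression, variance partitioning, noise ceilings, searchlight maps)
operate on the strictly-upper-triangular vectorization of these matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "ActivationMatrix",
    "RDM",
    "ModelRDMSet",
    "GroupSimilarityProfile",
    "compute_rdm",
    "vectorize_upper",
    "unvectorize_upper",
    "average_rdms",
    "spearman_rdm",
    "group_similarity_profile",
]

#: tolerance used when validating RDM symmetry / zero diagonal on input
_SYMMETRY_ATOL = 1e-9


@dataclass(frozen=True)
class ActivationMatrix:
    """A condition x feature (or condition x voxel) response matrix.

    Parameters
    ----------
    values
        2-D array, one row per condition, one column per feature/voxel.
    condition_ids
        Ordered condition labels, one per row.
    source_tag
        Free-text provenance (ROI name, model layer name, ...).
    """

    values: np.ndarray
    condition_ids: tuple[str, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"activation matrix must be 2-D, got shape {values.shape}")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError(
                f"need >= 2 conditions and >= 2 features, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("activation matrix contains non-finite values")
        ids = tuple(str(c) for c in self.condition_ids)
        if len(ids) != values.shape[0]:
            raise ValueError(
                f"{len(ids)} condition ids for {values.shape[0]} condition rows"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "condition_ids", ids)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def zero_variance_conditions(self) -> list[str]:
        """Condition ids whose pattern is constant across features.

        Pearson distance is undefined for such rows; :func:`compute_rdm`
        rejects them.
        """
        sd = self.values.std(axis=1)
        return [cid for cid, s in zip(self.condition_ids, sd) if s == 0.0]


@dataclass(frozen=True)
class RDM:
    """A symmetric zero-diagonal Pearson-distance matrix with entries in [0, 2]."""

    values: np.ndarray
    condition_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"RDM must be square, got shape {values.shape}")
        ids = tuple(str(c) for c in self.condition_ids)
        if len(ids) != values.shape[0]:
            raise ValueError(f"{len(ids)} condition ids for {values.shape[0]} rows")
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("RDM contains non-finite values")
        if not np.allclose(values, values.T, atol=_SYMMETRY_ATOL, rtol=0.0):
            raise ValueError("RDM is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=_SYMMETRY_ATOL):
            raise ValueError("RDM diagonal is not zero")
        if values.min() < -_SYMMETRY_ATOL or values.max() > 2.0 + _SYMMETRY_ATOL:
            raise ValueError("RDM entries must lie in [0, 2]")
        # store an exactly symmetric, clipped copy
        values = np.clip((values + values.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "condition_ids", ids)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def reorder(self, condition_ids: Sequence[str]) -> "RDM":
        """Return this RDM with rows/columns rearranged to ``condition_ids``.

        Alignment is by condition-id string match; a mismatched condition
        set is an error, never a silent positional reordering.
        """
        target = [str(c) for c in condition_ids]
        if set(target) != set(self.condition_ids):
            missing = sorted(set(target) - set(self.condition_ids))
            extra = sorted(set(self.condition_ids) - set(target))
            raise ValueError(
                f"condition sets differ: missing {missing}, unexpected {extra}"
            )
        if tuple(target) == self.condition_ids:
            return self
        pos = {c: i for i, c in enumerate(self.condition_ids)}
        idx = np.array([pos[c] for c in target])
        return RDM(self.values[np.ix_(idx, idx)], tuple(target))

    def subset(self, indices: Sequence[int]) -> "RDM":
        """Restrict to a subset of conditions given by row indices."""
        idx = np.asarray(indices, dtype=int)
        ids = tuple(self.condition_ids[i] for i in idx)
        return RDM(self.values[np.ix_(idx, idx)], ids)

    def permute(self, permutation: Sequence[int]) -> "RDM":
        """Apply a condition-label permutation jointly to rows and columns.

        Condition ids are kept in place, so the permuted RDM no longer
        corresponds to the labels — exactly the null model used by
        permutation tests.
        """
        p = np.asarray(permutation, dtype=int)
        if sorted(p.tolist()) != list(range(self.n_conditions)):
            raise ValueError("not a permutation of the condition indices")
        return RDM(self.values[np.ix_(p, p)], self.condition_ids)


@dataclass(frozen=True)
class ModelRDMSet:
    """A named candidate model: a task-group label and one RDM per layer.

    The two layers conventionally carried are the deepest encoder stages
    (block4 and the encoder output), where task-specific structure lives.
    """

    model_name: str
    task_group: str
    layer_rdms: tuple[RDM, ...]

    _GROUPS = ("2D", "3D", "semantic", "random")

    def __post_init__(self) -> None:
        if self.task_group not in self._GROUPS:
            raise ValueError(
                f"task_group must be one of {self._GROUPS}, got {self.task_group!r}"
            )
        rdms = tuple(self.layer_rdms)
        if not rdms:
            raise ValueError("a model needs at least one layer RDM")
        ids = rdms[0].condition_ids
        for r in rdms[1:]:
            if r.condition_ids != ids:
                raise ValueError("layer RDMs must share condition ids and order")
        object.__setattr__(self, "layer_rdms", rdms)

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return self.layer_rdms[0].condition_ids


def compute_rdm(acts: ActivationMatrix) -> RDM:
    """Pearson-distance RDM of an activation matrix.

    Entry (i, j) is ``1 - r`` where ``r`` is the Pearson correlation of the
    feature vectors of conditions i and j, giving distances in [0, 2].
    """
    bad = acts.zero_variance_conditions()
    if bad:
        raise ValueError(
            f"zero-variance condition(s) {bad}: Pearson distance is undefined"
        )
    corr = np.corrcoef(acts.values)
    dist = 1.0 - corr
    return RDM(dist, acts.condition_ids)


def vectorize_upper(rdm: RDM) -> np.ndarray:
    """Strictly-upper-triangle entries in fixed row-major order.

    Length is n(n-1)/2; the traversal order is shared by every consumer so
    that vectors from different sources align by construction.
    """
    iu = np.triu_indices(rdm.n_conditions, k=1)
    return rdm.values[iu].copy()


def unvectorize_upper(vec: np.ndarray, condition_ids: Sequence[str]) -> RDM:
    """Inverse of :func:`vectorize_upper` for the given condition labels."""
    vec = np.asarray(vec, dtype=float)
    n = len(condition_ids)
    if vec.shape != (n * (n - 1) // 2,):
        raise ValueError(
            f"vector length {vec.size} does not match n(n-1)/2 for n={n}"
        )
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out = out + out.T
    return RDM(out, tuple(condition_ids))


def _check_aligned(rdms: Sequence[RDM]) -> tuple[str, ...]:
    ids = rdms[0].condition_ids
    for r in rdms[1:]:
        if r.condition_ids != ids:
            a, b = set(ids), set(r.condition_ids)
            if a != b:
                raise ValueError(
                    f"condition sets differ: only-first {sorted(a - b)}, "
                    f"only-other {sorted(b - a)}"
                )
            raise ValueError("condition ids agree as sets but differ in order")
    return ids


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Elementwise mean of condition-aligned RDMs (subject or group averaging)."""
    rdms = list(rdms)
    if not rdms:
        raise ValueError("cannot average an empty list of RDMs")
    ids = _check_aligned(rdms)
    mean = np.mean([r.values for r in rdms], axis=0)
    return RDM(mean, ids)


def spearman_rdm(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rank correlation of two RDMs' upper-triangle vectors.

    Returns NaN when either vector is constant (rank correlation undefined).
    """
    _check_aligned([rdm_a, rdm_b])
    va, vb = vectorize_upper(rdm_a), vectorize_upper(rdm_b)
    if np.ptp(va) == 0.0 or np.ptp(vb) == 0.0:
        return float("nan")
    rho = _scipy_stats.spearmanr(va, vb).statistic
    return float(rho)


@dataclass(frozen=True)
class GroupSimilarityProfile:
    """Within- vs between-group mean pairwise RDM Spearman at one layer."""

    layer_index: int
    within_by_group: dict[str, float] = field(default_factory=dict)
    within_mean: float = float("nan")
    between_mean: float = float("nan")


def group_similarity_profile(
    model_sets: Sequence[ModelRDMSet], layer_index: int = 0
) -> GroupSimilarityProfile:
    """Mean pairwise Spearman of model RDMs within and between task groups.

    A group with a single member contributes no within-group pairs and is
    reported as NaN.
    """
    models = list(model_sets)
    groups = {m.task_group for m in models}
    if len(models) < 2 or len(groups) < 2:
        raise ValueError("need >= 2 models in >= 2 task groups")
    rho = {}
    for i, a in enumerate(models):
        for j in range(i + 1, len(models)):
            b = models[j]
            rho[(i, j)] = spearman_rdm(
                a.layer_rdms[layer_index], b.layer_rdms[layer_index]
            )
    within_by_group: dict[str, float] = {}
    within_all: list[float] = []
    between_all: list[float] = []
    for g in sorted(groups):
        vals = [
            r
            for (i, j), r in rho.items()
            if models[i].task_group == g and models[j].task_group == g
        ]
        within_by_group[g] = float(np.mean(vals)) if vals else float("nan")
        within_all.extend(vals)
    for (i, j), r in rho.items():
        if models[i].task_group != models[j].task_group:
            between_all.append(r)
    return GroupSimilarityProfile(
        layer_index=layer_index,
        within_by_group=within_by_group,
        within_mean=float(np.mean(within_all)) if within_all else float("nan"),
        between_mean=float(np.mean(between_all)) if between_all else float("nan"),
    )
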
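"""Voxelwise searchlight mapping.

A cubic searchlight (radius 1, i.e. a 3x3x3 block of 27 voxels, clipped at
mask borders) slides over the response volume.  For every block the
per-subject block RDMs are averaged and either (a) every candidate model is
scored by adjusted R^2 and the best one becomes the block's preference, or
(b) variance partitioning over the three task-group RDMs assigns the block
to the group with dominant unique variance.  Blocks are only labeled where
the noise ceiling and the winning statistic survive permutation testing
with FDR correction.

Permutation nulls are vectorized: a condition permutation induces a
permutation of the upper-triangle vector indices, so null statistics for
all iterations are computed by fancy-indexed matrix products rather than
by rebuilding RDMs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .rdm import RDM, ActivationMatrix, ModelRDMSet, vectorize_upper
from .regression import adjusted_r2
from .stats import fdr_correct, pair_index_permutation, permutation_pvalue

__all__ = [
    "VolumeGrid",
    "SearchlightConfig",
    "SearchlightResult",
    "SearchlightMaps",
    "extract_blocks",
    "preference_map",
    "group_unique_variance_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeGrid:
    """A subject's 4-D response volume (x, y, z, condition) plus mask."""

    responses: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    condition_ids: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        responses = np.asarray(self.responses, dtype=float)
        mask = np.asarray(self.mask).astype(bool)
        if responses.ndim != 4:
            raise ValueError(f"responses must be 4-D, got shape {responses.shape}")
        if mask.shape != responses.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} != spatial shape {responses.shape[:3]}"
            )
        ids = tuple(str(c) for c in self.condition_ids)
        if len(ids) != responses.shape[3]:
            raise ValueError("one condition id per volume frame required")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "responses", responses)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "condition_ids", ids)

    @property
    def n_conditions(self) -> int:
        return self.responses.shape[3]


@dataclass(frozen=True)
class SearchlightConfig:
    """Geometry and inference settings for searchlight maps."""

    radius: int = 1
    min_voxels: int = 9
    n_perm: int = 500
    seed: int = 0
    fdr_q: float = 0.05
    require_noise_ceiling: bool = True


@dataclass(frozen=True)
class SearchlightResult:
    """Per-block outcome of a searchlight analysis."""

    center: tuple[int, int, int]
    winner: str
    r2: float
    p_raw: float
    p_fdr: float
    n_voxels_in_block: int


@dataclass(frozen=True)
class SearchlightMaps:
    """Winner/statistic volumes of a searchlight run.

    ``winner`` is an integer-coded 3-D map; ``legend`` maps codes to
    labels (0 is reserved for out-of-mask / not-significant / "none").
    """

    winner: np.ndarray
    legend: dict[int, str]
    r2: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    ceiling_p_fdr: np.ndarray | None
    results: tuple[SearchlightResult, ...]
    affine: np.ndarray


def block_membership(
    mask: np.ndarray, radius: int = 1, min_voxels: int = 9
) -> list[tuple[tuple[int, int, int], np.ndarray]]:
    """In-mask voxel coordinates of each searchlight block.

    For every in-mask voxel the block is the cube of edge ``2*radius + 1``
    centered there, clipped at the volume borders and intersected with the
    mask; blocks with fewer than ``min_voxels`` voxels are skipped.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    out = []
    nx, ny, nz = mask.shape
    for cx, cy, cz in np.argwhere(mask):
        sub = mask[
            max(cx - radius, 0) : min(cx + radius + 1, nx),
            max(cy - radius, 0) : min(cy + radius + 1, ny),
            max(cz - radius, 0) : min(cz + radius + 1, nz),
        ]
        vox = np.argwhere(sub)
        vox += [max(cx - radius, 0), max(cy - radius, 0), max(cz - radius, 0)]
        if len(vox) < min_voxels:
            continue
        out.append(((int(cx), int(cy), int(cz)), vox))
    return out


def extract_blocks(
    volume: VolumeGrid, radius: int = 1, min_voxels: int = 9
) -> list[tuple[tuple[int, int, int], ActivationMatrix]]:
    """Searchlight blocks of one subject as condition x voxel matrices."""
    blocks = block_membership(volume.mask, radius, min_voxels)
    out = []
    for center, vox in blocks:
        acts = volume.responses[vox[:, 0], vox[:, 1], vox[:, 2], :].T
        out.append(
            (
                center,
                ActivationMatrix(
                    acts, volume.condition_ids, source_tag=f"block@{center}"
                ),
            )
        )
    return out


def _check_volumes(volumes: Sequence[VolumeGrid]) -> VolumeGrid:
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need >= 2 subject volumes")
    ref = volumes[0]
    for v in volumes[1:]:
        if not np.array_equal(v.mask, ref.mask):
            raise ValueError("subject volumes must share the mask")
        if v.condition_ids != ref.condition_ids:
            raise ValueError("subject volumes must share condition ids and order")
    return ref


def _rdm_vector_from_block(acts: np.ndarray, iu: tuple) -> np.ndarray:
    """Upper-triangle Pearson-distance vector of a condition x voxel block."""
    sd = acts.std(axis=1)
    if np.any(sd == 0.0):
        raise ValueError("zero-variance condition pattern inside a block")
    corr = np.corrcoef(acts)
    return 1.0 - corr[iu]


def _subject_block_vectors(
    volumes: Sequence[VolumeGrid],
    blocks: Sequence[tuple[tuple[int, int, int], np.ndarray]],
) -> np.ndarray:
    """(n_blocks, n_subjects, n_pairs) stack of block RDM vectors."""
    n_cond = volumes[0].n_conditions
    iu = np.triu_indices(n_cond, k=1)
    out = np.empty((len(blocks), len(volumes), iu[0].size))
    for b, (_center, vox) in enumerate(blocks):
        for s, vol in enumerate(volumes):
            acts = vol.responses[vox[:, 0], vox[:, 1], vox[:, 2], :].T
            out[b, s] = _rdm_vector_from_block(acts, iu)
    return out


def _r2_matrix(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """In-sample R^2 of each row of Y regressed on the design with
    orthonormal basis Q (intercept included in Q's span)."""
    proj = Y @ Q  # (rows, p+1)
    ss_fit = np.einsum("ij,ij->i", proj, proj)
    ss_y = np.einsum("ij,ij->i", Y, Y)
    mean = Y.mean(axis=1)
    m = Y.shape[1]
    ss_tot = ss_y - m * mean**2
    ss_res = np.maximum(ss_y - ss_fit, 0.0)
    return np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)


def _design_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column span of [X, 1]."""
    design = np.column_stack([X, np.ones(X.shape[0])])
    Q, _ = np.linalg.qr(design)
    return Q


def _lower_ceiling_from_vectors(V: np.ndarray) -> float:
    """Leave-one-subject-out lower noise ceiling from (N, m) RDM vectors."""
    N, m = V.shape
    total = V.sum(axis=0)
    scores = []
    for s in range(N):
        om = (total - V[s]) / (N - 1)
        r = np.corrcoef(V[s], om)[0, 1]
        scores.append(adjusted_r2(r * r, m, 1))
    return float(np.mean(scores))


def _null_lower_ceiling(
    V: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Null lower-ceiling samples under independent per-subject condition
    permutations.  ``idx`` has shape (n_perm, N, m) of vector-index
    permutations."""
    n_perm, N, m = idx.shape
    Vp = V[np.arange(N)[None, :, None], idx]  # (n_perm, N, m)
    total = Vp.sum(axis=1, keepdims=True)
    om = (total - Vp) / (N - 1)
    Vc = Vp - Vp.mean(axis=2, keepdims=True)
    Oc = om - om.mean(axis=2, keepdims=True)
    num = np.einsum("tsm,tsm->ts", Vc, Oc)
    den = np.sqrt(
        np.einsum("tsm,tsm->ts", Vc, Vc) * np.einsum("tsm,tsm->ts", Oc, Oc)
    )
    r2 = (num / den) ** 2
    r2_adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    return r2_adj.mean(axis=1)


def _ceiling_significance(
    V_blocks: np.ndarray, config: SearchlightConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block lower ceiling, raw p, and FDR-adjusted p.

    The null permutes conditions independently per subject, destroying
    between-subject RDM correspondence while preserving each RDM's value
    distribution.  The same null draws are shared across blocks.
    """
    n_blocks, N, m = V_blocks.shape
    n_cond = round_trip_n(m)
    idx = np.empty((config.n_perm, N, m), dtype=np.int64)
    for t in range(config.n_perm):
        for s in range(N):
            idx[t, s] = pair_index_permutation(n_cond, rng.permutation(n_cond))
    lower = np.empty(n_blocks)
    p_raw = np.empty(n_blocks)
    for b in range(n_blocks):
        lower[b] = _lower_ceiling_from_vectors(V_blocks[b])
        null = _null_lower_ceiling(V_blocks[b], idx)
        p_raw[b] = permutation_pvalue(lower[b], null)
    _, p_fdr = fdr_correct(p_raw, q=config.fdr_q)
    return lower, p_raw, p_fdr


def round_trip_n(n_pairs: int) -> int:
    """Number of conditions n with n(n-1)/2 == n_pairs."""
    n = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError(f"{n_pairs} is not a triangular number")
    return n


def _target_perm_indices(
    n_cond: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_pairs) vector-index permutations for target-RDM nulls."""
    return np.stack(
        [pair_index_permutation(n_cond, rng.permutation(n_cond)) for _ in range(n_perm)]
    )


def _maps_from_results(
    shape: tuple[int, int, int],
    results: Sequence[SearchlightResult],
    legend: dict[int, str],
    ceiling_p_fdr_vals: np.ndarray | None,
    affine: np.ndarray,
) -> SearchlightMaps:
    code = {label: k for k, label in legend.items()}
    winner = np.zeros(shape, dtype=np.int16)
    r2 = np.full(shape, np.nan)
    p_raw = np.full(shape, np.nan)
    p_fdr = np.full(shape, np.nan)
    ceiling = np.full(shape, np.nan) if ceiling_p_fdr_vals is not None else None
    for i, res in enumerate(results):
        c = res.center
        winner[c] = code.get(res.winner, 0)
        r2[c] = res.r2
        p_raw[c] = res.p_raw
        p_fdr[c] = res.p_fdr
        if ceiling is not None:
            ceiling[c] = ceiling_p_fdr_vals[i]
    return SearchlightMaps(
        winner=winner,
        legend=legend,
        r2=r2,
        p_raw=p_raw,
        p_fdr=p_fdr,
        ceiling_p_fdr=ceiling,
        results=tuple(results),
        affine=affine,
    )


def preference_map(
    volumes: Sequence[VolumeGrid],
    models: Sequence[ModelRDMSet],
    config: SearchlightConfig = SearchlightConfig(),
) -> SearchlightMaps:
    """Best-single-model preference map.

    Per block the subject-averaged block RDM is regressed on each model's
    layer RDMs; the model with the highest adjusted R^2 is the block's
    preference.  A block is labeled only where the noise ceiling is
    significant (permutation + FDR across blocks) and the winner's R^2 is
    significant (permutation + FDR across blocks x models); otherwise the
    label is "none".
    """
    ref = _check_volumes(volumes)
    models = list(models)
    if not models:
        raise ValueError("need at least one candidate model")
    blocks = block_membership(ref.mask, config.radius, config.min_voxels)
    if not blocks:
        raise ValueError("no searchlight block satisfies min_voxels")
    V = _subject_block_vectors(volumes, blocks)  # (B, N, m)
    Y = V.mean(axis=1)  # (B, m) subject-averaged block RDM vectors
    n_cond = ref.n_conditions
    m = Y.shape[1]

    bases, n_preds = [], []
    for mod in models:
        X = np.column_stack(
            [vectorize_upper(r.reorder(ref.condition_ids)) for r in mod.layer_rdms]
        )
        bases.append(_design_basis(X))
        n_preds.append(X.shape[1])

    # observed adjusted R^2 per (block, model)
    obs_r2 = np.empty((len(blocks), len(models)))
    for k, Q in enumerate(bases):
        raw = _r2_matrix(Y, Q)
        obs_r2[:, k] = 1.0 - (1.0 - raw) * (m - 1) / (m - n_preds[k] - 1)

    rng = np.random.default_rng(config.seed)
    idx = _target_perm_indices(n_cond, config.n_perm, rng)  # (n_perm, m)
    p_raw = np.empty_like(obs_r2)
    for b in range(len(blocks)):
        Yp = Y[b][idx]  # (n_perm, m)
        for k, Q in enumerate(bases):
            null_raw = _r2_matrix(Yp, Q)
            null_adj = 1.0 - (1.0 - null_raw) * (m - 1) / (m - n_preds[k] - 1)
            p_raw[b, k] = permutation_pvalue(obs_r2[b, k], null_adj)
    _, p_fdr_flat = fdr_correct(p_raw.ravel(), q=config.fdr_q)
    p_fdr = p_fdr_flat.reshape(p_raw.shape)

    if config.require_noise_ceiling:
        _, _, ceil_p_fdr = _ceiling_significance(V, config, rng)
    else:
        ceil_p_fdr = None

    names = [mod.model_name for mod in models]
    order = np.argsort(obs_r2, axis=1)
    results = []
    for b, (center, vox) in enumerate(blocks):
        best = obs_r2[b].max()
        tied = [names[k] for k in range(len(models)) if obs_r2[b, k] == best]
        if len(tied) > 1:
            logger.info("tied preference at %s: %s", center, tied)
        win_name = min(tied)  # lexicographic tie-break
        k = names.index(win_name)
        significant = p_fdr[b, k] <= config.fdr_q
        if ceil_p_fdr is not None:
            significant = significant and ceil_p_fdr[b] <= config.fdr_q
        results.append(
            SearchlightResult(
                center=center,
                winner=win_name if significant else "none",
                r2=float(best),
                p_raw=float(p_raw[b, k]),
                p_fdr=float(p_fdr[b, k]),
                n_voxels_in_block=len(vox),
            )
        )
    legend = {0: "none"} | {k + 1: n for k, n in enumerate(names)}
    return _maps_from_results(
        ref.mask.shape, results, legend, ceil_p_fdr, ref.affine
    )


_GROUP_SUBSETS = ((0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2))


def group_unique_variance_map(
    volumes: Sequence[VolumeGrid],
    grouped_rdms: Mapping[str, RDM],
    config: SearchlightConfig = SearchlightConfig(),
) -> SearchlightMaps:
    """Task-group winner map by unique explained variance.

    Per block a three-way variance partition over the grouped RDMs is
    computed; the group with the largest unique component wins if its
    unique variance and its advantage over both other groups are
    permutation-significant after FDR correction (families: blocks x
    groups for unique components, blocks x comparisons for differences);
    otherwise the block is labeled "none".
    """
    ref = _check_volumes(volumes)
    group_names = sorted(grouped_rdms)
    if len(group_names) != 3:
        raise ValueError("need exactly 3 grouped predictor RDMs")
    blocks = block_membership(ref.mask, config.radius, config.min_voxels)
    if not blocks:
        raise ValueError("no searchlight block satisfies min_voxels")
    V = _subject_block_vectors(volumes, blocks)
    Y = V.mean(axis=1)
    n_cond = ref.n_conditions
    m = Y.shape[1]
    cols = [
        vectorize_upper(grouped_rdms[g].reorder(ref.condition_ids))
        for g in group_names
    ]

    subset_Q = [
        _design_basis(np.column_stack([cols[i] for i in subset]))
        for subset in _GROUP_SUBSETS
    ]
    subset_p = [len(s) for s in _GROUP_SUBSETS]

    def subset_r2_adj(rows: np.ndarray) -> np.ndarray:
        """(rows, 7) adjusted R^2 of each predictor subset."""
        out = np.empty((rows.shape[0], len(_GROUP_SUBSETS)))
        for j, Q in enumerate(subset_Q):
            raw = _r2_matrix(rows, Q)
            out[:, j] = 1.0 - (1.0 - raw) * (m - 1) / (m - subset_p[j] - 1)
        return out

    def uniques(r: np.ndarray) -> np.ndarray:
        """(rows, 3) unique components from the (rows, 7) subset R^2."""
        # subsets: a, b, c, ab, ac, bc, abc at indices 0..6
        return np.stack(
            [r[:, 6] - r[:, 5], r[:, 6] - r[:, 4], r[:, 6] - r[:, 3]], axis=1
        )

    obs_u = uniques(subset_r2_adj(Y))  # (B, 3)
    obs_total = subset_r2_adj(Y)[:, 6]

    rng = np.random.default_rng(config.seed)
    idx = _target_perm_indices(n_cond, config.n_perm, rng)
    p_unique = np.empty((len(blocks), 3))
    p_diff = np.empty((len(blocks), 3, 3))  # [b, g, h]: u_g - u_h
    for b in range(len(blocks)):
        null_u = uniques(subset_r2_adj(Y[b][idx]))  # (n_perm, 3)
        for g in range(3):
            p_unique[b, g] = permutation_pvalue(obs_u[b, g], null_u[:, g])
            for h in range(3):
                if h == g:
                    continue
                p_diff[b, g, h] = permutation_pvalue(
                    obs_u[b, g] - obs_u[b, h], null_u[:, g] - null_u[:, h]
                )

    _, pu_fdr_flat = fdr_correct(p_unique.ravel(), q=config.fdr_q)
    pu_fdr = pu_fdr_flat.reshape(p_unique.shape)
    winners = obs_u.argmax(axis=1)
    diff_ps = np.array(
        [
            [p_diff[b, winners[b], h] for h in range(3) if h != winners[b]]
            for b in range(len(blocks))
        ]
    )
    _, pd_fdr_flat = fdr_correct(diff_ps.ravel(), q=config.fdr_q)
    pd_fdr = pd_fdr_flat.reshape(diff_ps.shape)

    if config.require_noise_ceiling:
        _, _, ceil_p_fdr = _ceiling_significance(V, config, rng)
    else:
        ceil_p_fdr = None

    results = []
    for b, (center, vox) in enumerate(blocks):
        g = int(winners[b])
        significant = (
            pu_fdr[b, g] <= config.fdr_q and np.all(pd_fdr[b] <= config.fdr_q)
        )
        if ceil_p_fdr is not None:
            significant = significant and ceil_p_fdr[b] <= config.fdr_q
        results.append(
            SearchlightResult(
                center=center,
                winner=group_names[g] if significant else "none",
                r2=float(obs_total[b]),
                p_raw=float(p_unique[b, g]),
                p_fdr=float(pu_fdr[b, g]),
                n_voxels_in_block=len(vox),
            )
        )
    legend = {0: "none"} | {k + 1: g for k, g in enumerate(group_names)}
    return _maps_from_results(
        ref.mask.shape, results, legend, ceil_p_fdr, ref.affine
    )
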
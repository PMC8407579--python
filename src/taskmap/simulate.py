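"""Synthetic model RDMs and multi-subject brain responses with planted structure.

Every downstream stage of the pipeline is testable without real data:
model RDM sets are generated from shared latent feature bases so that
models in the same task group correlate more strongly than models in
different groups, and subject response matrices are constructed so that
their noise-free population RDM equals a chosen weighted mixture of the
planted model RDMs.

The default design mirrors the scale of a typical multi-model fMRI study:
50 conditions, 16 subjects, 18 task-trained models in three groups (2D,
3D, semantic) plus one random-feature baseline, two layers per model.

Randomness: one master seed per design; each generation stage draws from
its own child stream (fixed offsets of the master seed), so regenerating
any one artifact is bit-reproducible and independent of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as _ndimage

from .rdm import RDM, ActivationMatrix, ModelRDMSet, average_rdms, compute_rdm
from .searchlight import VolumeGrid

__all__ = [
    "PlantedDesign",
    "SyntheticVolumeDesign",
    "default_design",
    "generate_model_rdm_sets",
    "generate_subject_responses",
    "generate_synthetic_volume",
    "realize_patterns",
]

logger = logging.getLogger(__name__)

TASK_GROUPS = ("2D", "3D", "semantic", "random")

# child-stream offsets of the master seed
_STREAM_MODELS = 1
_STREAM_SUBJECTS = 2
_STREAM_VOLUME = 3


def condition_labels(n: int) -> tuple[str, ...]:
    return tuple(f"cond_{i:03d}" for i in range(n))


@dataclass(frozen=True)
class PlantedDesign:
    """Ground-truth layout of a synthetic study.

    ``within_group_corr`` / ``between_group_corr`` set the fraction of
    latent feature variance shared among models of the same / different
    task groups; realized RDM correlations are monotone in these targets
    and preserve their ordering.  ``mixture_weights`` defines the planted
    brain structure: the noise-free subject RDM is the weight-mixture of
    the selected model RDMs.  ``layer_jitter`` is the fraction of a
    model's idiosyncratic feature variance that differs between its two
    layers (0 makes layers identical).
    """

    n_conditions: int = 50
    group_labels: tuple[str, ...] = ()
    within_group_corr: float = 0.8
    between_group_corr: float = 0.2
    mixture_weights: tuple[float, ...] = ()
    n_subjects: int = 16
    n_voxels: int = 200
    subject_noise_sd: float = 1.0
    seed: int = 0
    layer_jitter: float = 0.2
    n_latent_features: int = 128

    def __post_init__(self) -> None:
        if self.n_conditions < 4:
            raise ValueError("need at least 4 conditions")
        labels = tuple(self.group_labels)
        if not labels:
            raise ValueError("group_labels must name at least one model")
        for g in labels:
            if g not in TASK_GROUPS:
                raise ValueError(f"unknown task group {g!r}; use one of {TASK_GROUPS}")
        if not (0.0 <= self.between_group_corr <= self.within_group_corr <= 1.0):
            raise ValueError(
                "need 0 <= between_group_corr <= within_group_corr <= 1 "
                f"(got within={self.within_group_corr}, "
                f"between={self.between_group_corr})"
            )
        weights = tuple(float(w) for w in self.mixture_weights)
        if weights:
            if len(weights) != len(labels):
                raise ValueError("one mixture weight per model required")
            if min(weights) < 0.0:
                raise ValueError("mixture weights must be nonnegative")
            if abs(sum(weights) - 1.0) > 1e-12:
                raise ValueError("mixture weights must sum to 1 within 1e-12")
        if self.n_subjects < 1 or self.n_voxels < 2:
            raise ValueError("need >= 1 subject and >= 2 voxels")
        if self.subject_noise_sd < 0.0:
            raise ValueError("subject_noise_sd must be nonnegative")
        if not 0.0 <= self.layer_jitter <= 1.0:
            raise ValueError("layer_jitter must be in [0, 1]")
        object.__setattr__(self, "group_labels", labels)
        object.__setattr__(self, "mixture_weights", weights)

    @property
    def n_models(self) -> int:
        return len(self.group_labels)

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return condition_labels(self.n_conditions)


def default_design(**overrides) -> PlantedDesign:
    """The study-scale default: 18 grouped models + 1 random baseline.

    The planted brain structure is a 0.6/0.4 mixture of the first 2D and
    the first 3D model.
    """
    labels = ("2D",) * 6 + ("3D",) * 6 + ("semantic",) * 6 + ("random",)
    weights = [0.0] * len(labels)
    weights[0], weights[6] = 0.6, 0.4
    base = dict(group_labels=labels, mixture_weights=tuple(weights))
    base.update(overrides)
    return PlantedDesign(**base)


def _model_features(design: PlantedDesign, rng: np.random.Generator) -> list[list[np.ndarray]]:
    """Latent condition x feature matrices, one [layer0, layer1] pair per model.

    Construction: a global basis shared across groups in proportion to the
    between-group target, a per-group basis topping shared variance up to
    the within-group target, and per-model / per-layer idiosyncratic
    perturbations for the remainder.  Random-group models share nothing.
    """
    n, f = design.n_conditions, design.n_latent_features
    # RDM correlation scales roughly with the square of the shared feature
    # variance fraction, so targets are mapped through a square root
    s_within = np.sqrt(design.within_group_corr)
    s_between = np.sqrt(design.between_group_corr)
    a = s_between
    b = s_within - s_between
    c = 1.0 - s_within
    j = design.layer_jitter
    common = rng.standard_normal((n, f))
    group_bases = {
        g: rng.standard_normal((n, f))
        for g in sorted(set(design.group_labels) - {"random"})
    }
    out: list[list[np.ndarray]] = []
    for g in design.group_labels:
        model_idio = rng.standard_normal((n, f))
        layers = []
        for _layer in range(2):
            layer_idio = rng.standard_normal((n, f))
            idio = np.sqrt(1.0 - j) * model_idio + np.sqrt(j) * layer_idio
            if g == "random":
                layers.append(idio)
            else:
                layers.append(
                    np.sqrt(a) * common + np.sqrt(b) * group_bases[g] + np.sqrt(c) * idio
                )
        out.append(layers)
    return out


def generate_model_rdm_sets(design: PlantedDesign) -> list[ModelRDMSet]:
    """One two-layer :class:`ModelRDMSet` per model in the design.

    Models of the same task group share more latent feature variance than
    models of different groups, so their RDMs correlate more strongly —
    the grouping premise every group-level analysis relies on.
    """
    rng = np.random.default_rng([design.seed, _STREAM_MODELS])
    ids = design.condition_ids
    counters: dict[str, int] = {}
    sets: list[ModelRDMSet] = []
    for group, layers in zip(design.group_labels, _model_features(design, rng)):
        k = counters.get(group, 0)
        counters[group] = k + 1
        name = f"{group}_{k}"
        layer_rdms = tuple(
            compute_rdm(
                ActivationMatrix(mat, ids, source_tag=f"{name}/layer{i}")
            )
            for i, mat in enumerate(layers)
        )
        sets.append(ModelRDMSet(model_name=name, task_group=group, layer_rdms=layer_rdms))
    return sets


def realize_patterns(
    rdm_values: np.ndarray, n_voxels: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Condition x voxel patterns whose Pearson-distance RDM equals ``rdm_values``.

    The target correlation matrix ``C = 1 - D`` is eigendecomposed;
    negative eigenvalues (possible only through numerical error, since
    mixtures of correlation-derived RDMs give positive semidefinite C)
    are clipped at zero and the clipped magnitude returned.  The factor is
    embedded into voxel space through a random orthonormal basis whose
    vectors are orthogonal to the constant vector, so pattern rows are
    exactly zero-mean across voxels and their correlation matrix equals C.

    Returns (patterns, clip_magnitude).  Patterns are scaled so the
    per-voxel signal variance is about 1, making ``subject_noise_sd``
    directly interpretable as a noise-to-signal ratio.
    """
    D = np.asarray(rdm_values, dtype=float)
    n = D.shape[0]
    C = 1.0 - D
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    eigval, eigvec = np.linalg.eigh(C)
    clip = float(-eigval[eigval < 0].sum()) if np.any(eigval < 0) else 0.0
    if clip > 1e-8:
        logger.info("clipped negative eigenvalue mass %.3g in RDM embedding", clip)
    eigval = np.clip(eigval, 0.0, None)
    keep = eigval > 1e-12 * eigval.max()
    d = int(keep.sum())
    if n_voxels - 1 < d:
        raise ValueError(
            f"mixture RDM of rank {d} needs at least {d + 1} voxels, "
            f"got {n_voxels}"
        )
    Y = eigvec[:, keep] * np.sqrt(eigval[keep])  # (n, d), rows unit norm
    # basis in the orthogonal complement of the constant vector
    B = rng.standard_normal((n_voxels, d))
    B -= B.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(B)  # (n_voxels, d), orthonormal columns, each sums to ~0
    patterns = (Y @ Q.T) * np.sqrt(n_voxels)
    return patterns, clip


def generate_subject_responses(
    design: PlantedDesign, target_rdms: Sequence[RDM]
) -> list[ActivationMatrix]:
    """Per-subject condition x voxel responses realizing a planted RDM mixture.

    The noise-free population RDM equals ``sum(w_i * target_rdms[i])``;
    each subject adds i.i.d. Gaussian voxel noise with
    ``design.subject_noise_sd``.
    """
    targets = list(target_rdms)
    weights = design.mixture_weights
    if not weights:
        raise ValueError("design.mixture_weights is empty")
    if len(weights) != len(targets):
        raise ValueError(
            f"{len(weights)} mixture weights for {len(targets)} target RDMs"
        )
    ids = targets[0].condition_ids
    if len(ids) != design.n_conditions:
        raise ValueError("target RDMs not conformable with design.n_conditions")
    aligned = [t.reorder(ids) for t in targets]
    mixture = np.sum([w * t.values for w, t in zip(weights, aligned)], axis=0)
    rng = np.random.default_rng([design.seed, _STREAM_SUBJECTS])
    patterns, _clip = realize_patterns(mixture, design.n_voxels, rng)
    out = []
    for s in range(design.n_subjects):
        noise = rng.standard_normal(patterns.shape) * design.subject_noise_sd
        out.append(
            ActivationMatrix(patterns + noise, ids, source_tag=f"subject_{s:02d}")
        )
    return out


@dataclass(frozen=True)
class SyntheticVolumeDesign:
    """A labeled 3-D grid whose regions carry planted model structure.

    ``region_to_model`` assigns each nonzero region label the model whose
    (layer-averaged) RDM the region's voxels realize; background voxels
    (label 0) carry pure noise.
    """

    grid_shape: tuple[int, int, int]
    region_labels: np.ndarray
    region_to_model: Mapping[int, ModelRDMSet]
    n_subjects: int = 8
    subject_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.region_labels, dtype=int)
        if labels.shape != tuple(self.grid_shape):
            raise ValueError(
                f"label map shape {labels.shape} != grid_shape {self.grid_shape}"
            )
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.region_to_model)
        if missing:
            raise ValueError(f"region labels without an assigned model: {sorted(missing)}")
        if self.n_subjects < 1:
            raise ValueError("need >= 1 subject")
        if self.subject_noise_sd < 0.0:
            raise ValueError("subject_noise_sd must be nonnegative")
        labels = labels.copy()
        labels.flags.writeable = False
        object.__setattr__(self, "region_labels", labels)
        object.__setattr__(self, "region_to_model", dict(self.region_to_model))


def planted_region_rdm(model: ModelRDMSet) -> RDM:
    """The RDM a region planted with ``model`` realizes: its layer average."""
    return average_rdms(list(model.layer_rdms))


def generate_synthetic_volume(
    design: SyntheticVolumeDesign, searchlight_radius: int = 1
) -> tuple[list[VolumeGrid], np.ndarray]:
    """Per-subject 4-D response volumes plus the analysis mask.

    Voxels of region r realize the RDM of ``region_to_model[r]`` exactly in
    the noise-free limit (region-level patterns are an exact embedding;
    individual searchlight blocks sample a subset of region voxels and
    approximate it).  Every region must be able to contain at least one
    full searchlight block.

    Returns (volumes, mask) where ``mask`` marks nonzero-label voxels.
    """
    labels = design.region_labels
    edge = 2 * searchlight_radius + 1
    structure = np.ones((edge, edge, edge), dtype=bool)
    region_voxels: dict[int, np.ndarray] = {}
    for r in sorted(set(np.unique(labels).tolist()) - {0}):
        inside = labels == r
        if not _ndimage.binary_erosion(inside, structure=structure).any():
            raise ValueError(
                f"region {r} cannot contain a full searchlight block "
                f"of edge {edge}"
            )
        region_voxels[r] = np.argwhere(inside)
    if not region_voxels:
        raise ValueError("label map has no nonzero regions")

    any_model = next(iter(design.region_to_model.values()))
    ids = any_model.condition_ids
    n_cond = len(ids)
    shape = tuple(design.grid_shape) + (n_cond,)
    rng = np.random.default_rng([design.seed, _STREAM_VOLUME])

    signal = np.zeros(shape)
    for r, vox in region_voxels.items():
        rdm = planted_region_rdm(design.region_to_model[r])
        patterns, _ = realize_patterns(rdm.values, len(vox), rng)  # (n_cond, n_vox)
        signal[vox[:, 0], vox[:, 1], vox[:, 2], :] = patterns.T

    mask = labels > 0
    volumes = []
    for s in range(design.n_subjects):
        noise = rng.standard_normal(shape) * design.subject_noise_sd
        volumes.append(
            VolumeGrid(
                responses=signal + noise,
                mask=mask,
                affine=np.eye(4),
                condition_ids=ids,
                subject_id=f"subject_{s:02d}",
            )
        )
    return volumes, mask
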
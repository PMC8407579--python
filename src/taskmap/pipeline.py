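"""ROI-level study orchestration.

For every ROI: subject RDMs -> noise ceiling and inclusion -> full model
ranking (including the random baseline) with permutation significance,
FDR across models and bootstrap error bars -> top-3 variance partitioning
with per-component significance -> grouped (2D/3D/semantic) partitioning
with a unique-variance winner -> cross-validated explained variance in
all three modes -> explainable-variance ratio.  Results are emitted as
one report per ROI plus a study-level JSON and TSV summary.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .ceiling import (
    CV_MODES,
    CVResult,
    NoiseCeiling,
    SubjectRDMStack,
    compute_noise_ceiling,
    cv_explained_variance,
    explainable_variance_ratio,
)
from .partition import (
    SignificanceFlags,
    VariancePartition,
    grouped_task_rdms,
    partition_variance_three,
    top3_partition,
    winner_by_unique_variance,
)
from .rdm import RDM, ActivationMatrix, ModelRDMSet, compute_rdm
from .regression import model_similarity
from .searchlight import VolumeGrid
from .stats import fdr_correct, permutation_pvalue, ttest_cv_r2

__all__ = [
    "StudyConfig",
    "RoiReport",
    "run_roi_analysis",
    "apply_roi_mask",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Single source of truth for an ROI study.

    ``n_perm``/``n_boot`` default to the conventional 10,000 iterations;
    reduced-iteration runs are first-class (set them in the config) since
    full iteration counts are needlessly slow for routine checks.
    """

    n_perm: int = 10_000
    n_boot: int = 1_000
    bootstrap_fraction: float = 0.9
    fdr_q: float = 0.05
    ceiling_threshold: float = 0.1
    seed: int = 0
    cv_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = _io.read_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RoiReport:
    """Everything the study reports about one ROI."""

    roi_name: str
    noise_ceiling: NoiseCeiling
    included: bool
    ranking: tuple[tuple[str, float], ...]
    ranking_p_raw: Mapping[str, float]
    ranking_p_fdr: Mapping[str, float]
    ranking_boot_sd: Mapping[str, float]
    top3: tuple[str, ...]
    top3_partition: VariancePartition | None
    top3_component_p_raw: Mapping[str, float]
    top3_component_p_fdr: Mapping[str, float]
    top3_component_boot_sd: Mapping[str, float]
    grouped_partition: VariancePartition | None
    grouped_winner: str
    cv_r2: Mapping[str, CVResult]
    cv_ttest_p: float
    explainable_ratio: float | None
    n_perm: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        out = {
            "roi_name": self.roi_name,
            "noise_ceiling": {
                "lower": self.noise_ceiling.lower,
                "upper": self.noise_ceiling.upper,
            },
            "included": self.included,
            "ranking": [
                {
                    "model": name,
                    "r2_adj": score,
                    "p_raw": self.ranking_p_raw.get(name),
                    "p_fdr": self.ranking_p_fdr.get(name),
                    "sd_boot": self.ranking_boot_sd.get(name),
                }
                for name, score in self.ranking
            ],
            "top3": list(self.top3),
            "grouped_winner": self.grouped_winner,
            "cv_r2": {
                mode: {"fold_r2": list(res.fold_r2), "mean_r2": res.mean_r2}
                for mode, res in self.cv_r2.items()
            },
            "cv_ttest_p": self.cv_ttest_p,
            "explainable_ratio": self.explainable_ratio,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "fdr_family": "across models within ROI",
            "difference_test_direction": "one-sided, larger-minus-smaller",
        }
        if self.top3_partition is not None:
            out["top3_partition"] = {
                "components": self.top3_partition.components(),
                "total_r2": self.top3_partition.total_r2,
                "component_p_raw": dict(self.top3_component_p_raw),
                "component_p_fdr": dict(self.top3_component_p_fdr),
                "component_sd_boot": dict(self.top3_component_boot_sd),
            }
        if self.grouped_partition is not None:
            out["grouped_partition"] = {
                "components": self.grouped_partition.components(),
                "total_r2": self.grouped_partition.total_r2,
            }
        return out


def apply_roi_mask(volume: VolumeGrid, roi_mask: np.ndarray) -> ActivationMatrix:
    """Condition x in-mask-voxel matrix, voxels in fixed raster (C) order."""
    roi_mask = np.asarray(roi_mask).astype(bool)
    if roi_mask.shape != volume.responses.shape[:3]:
        raise ValueError(
            f"ROI mask shape {roi_mask.shape} != volume spatial shape "
            f"{volume.responses.shape[:3]}"
        )
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return ActivationMatrix(
        volume.responses[roi_mask].T,
        volume.condition_ids,
        source_tag=volume.subject_id,
    )


def _partition_uniques_stat(
    target: RDM, groups: Sequence[Sequence[RDM]], names: Sequence[str]
) -> dict[str, float]:
    part = partition_variance_three(target, *groups, names=names)
    return part.uniques()


def _partition_significance(
    target: RDM,
    groups: Sequence[Sequence[RDM]],
    names: Sequence[str],
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[SignificanceFlags, dict[str, float]]:
    """Permutation p-values for unique components and their pairwise
    differences, sharing one set of permutation draws across statistics."""
    observed = _partition_uniques_stat(target, groups, names)
    null = {g: np.empty(n_perm) for g in names}
    n = target.n_conditions
    for t in range(n_perm):
        permuted = target.permute(rng.permutation(n))
        u = _partition_uniques_stat(permuted, groups, names)
        for g in names:
            null[g][t] = u[g]
    p_unique = {g: permutation_pvalue(observed[g], null[g]) for g in names}
    p_diff: dict[tuple[str, str], float] = {}
    for g in names:
        for h in names:
            if g == h:
                continue
            p_diff[(g, h)] = permutation_pvalue(
                observed[g] - observed[h], null[g] - null[h]
            )
    alpha = 0.05
    flags = SignificanceFlags(
        unique_significant={g: p_unique[g] <= alpha for g in names},
        difference_significant={k: v <= alpha for k, v in p_diff.items()},
    )
    return flags, p_unique


def _partition_bootstrap_sd(
    target: RDM,
    groups: Sequence[Sequence[RDM]],
    names: Sequence[str],
    fraction: float,
    n_boot: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Bootstrap SDs of all 7 partition components from shared condition
    subsamples (one partition per draw)."""
    n = target.n_conditions
    size = int(round(fraction * n))
    samples: dict[str, list[float]] = {}
    for _ in range(n_boot):
        keep = np.sort(rng.choice(n, size=size, replace=False))
        part = partition_variance_three(
            target.subset(keep),
            *[[r.subset(keep) for r in g] for g in groups],
            names=names,
        )
        for key, val in part.components().items():
            samples.setdefault(key, []).append(val)
    return {k: float(np.std(v, ddof=1)) for k, v in samples.items()}


def analyze_roi(
    roi_name: str,
    subject_acts: Sequence[ActivationMatrix],
    models: Sequence[ModelRDMSet],
    config: StudyConfig = StudyConfig(),
) -> RoiReport:
    """Full single-ROI analysis from per-subject activation matrices."""
    t0 = time.perf_counter()
    # stable per-ROI stream: CRC of the name, not Python's salted hash
    roi_key = zlib.crc32(roi_name.encode()) % (2**31)
    rng = np.random.default_rng([config.seed, roi_key])
    stack = SubjectRDMStack(
        rdms=tuple(compute_rdm(a) for a in subject_acts),
        subject_ids=tuple(
            a.source_tag or f"subject_{i:02d}" for i, a in enumerate(subject_acts)
        ),
    )
    ceiling = compute_noise_ceiling(stack)
    included = ceiling.lower > config.ceiling_threshold
    target = stack.mean_rdm()
    models = list(models)

    # model ranking with permutation significance and bootstrap error bars
    scored = sorted(
        ((m.model_name, model_similarity(target, m)) for m in models),
        key=lambda t: (-t[1], t[0]),
    )
    by_name = {m.model_name: m for m in models}
    n_cond = target.n_conditions
    perms = [rng.permutation(n_cond) for _ in range(config.n_perm)]
    p_raw: dict[str, float] = {}
    boot_sd: dict[str, float] = {}
    for name, observed in scored:
        mod = by_name[name]
        null = np.array(
            [model_similarity(target.permute(p), mod) for p in perms]
        )
        p_raw[name] = permutation_pvalue(observed, null)
    size = int(round(config.bootstrap_fraction * n_cond))
    subsamples = [
        np.sort(rng.choice(n_cond, size=size, replace=False))
        for _ in range(config.n_boot)
    ]
    for name, _observed in scored:
        mod = by_name[name]
        layer_subsets = [
            [r.subset(keep) for r in mod.layer_rdms] for keep in subsamples
        ]
        draws = [
            model_similarity(
                target.subset(keep),
                ModelRDMSet(mod.model_name, mod.task_group, tuple(layers)),
            )
            for keep, layers in zip(subsamples, layer_subsets)
        ]
        boot_sd[name] = float(np.std(draws, ddof=1))
    names_order = [name for name, _ in scored]
    _, p_fdr_arr = fdr_correct([p_raw[n] for n in names_order], q=config.fdr_q)
    p_fdr = dict(zip(names_order, p_fdr_arr))

    # top-3 variance partitioning with component-level inference
    _ranking, part3 = top3_partition(target, models)
    top3 = tuple(part3.predictor_names)
    top3_groups = [list(by_name[n].layer_rdms) for n in top3]
    flags3, p_unique3 = _partition_significance(
        target, top3_groups, top3, config.n_perm, rng
    )
    comp_p_raw = {f"unique_{g}": p for g, p in p_unique3.items()}
    comp_names = sorted(comp_p_raw)
    _, comp_fdr_arr = fdr_correct([comp_p_raw[c] for c in comp_names], q=config.fdr_q)
    comp_p_fdr = dict(zip(comp_names, comp_fdr_arr))
    comp_boot_sd = _partition_bootstrap_sd(
        target, top3_groups, top3, config.bootstrap_fraction, config.n_boot, rng
    )

    # grouped (2D/3D/semantic) partitioning and winner
    grouped = grouped_task_rdms(models)
    group_names = tuple(sorted(grouped))
    grouped_groups = [[grouped[g]] for g in group_names]
    part_grouped = partition_variance_three(
        target, *grouped_groups, names=group_names
    )
    flags_grouped, _ = _partition_significance(
        target, grouped_groups, group_names, config.n_perm, rng
    )
    grouped_winner = winner_by_unique_variance(part_grouped, flags_grouped)

    # cross-validated explained variance of the top-3 model RDMs
    top3_predictors = [r for name in top3 for r in by_name[name].layer_rdms]
    cv_results = {
        mode: cv_explained_variance(
            stack, top3_predictors, mode=mode, seed=config.cv_seed
        )
        for mode in CV_MODES
    }
    ttest = ttest_cv_r2(list(cv_results["subjects"].fold_r2))
    ratio = None
    if ceiling.lower > 0:
        ratio = explainable_variance_ratio(
            cv_results["subjects_and_stimuli"].mean_r2, ceiling
        )

    logger.info(
        "ROI %s analyzed in %.1fs (lower ceiling %.3f, included=%s)",
        roi_name,
        time.perf_counter() - t0,
        ceiling.lower,
        included,
    )
    return RoiReport(
        roi_name=roi_name,
        noise_ceiling=ceiling,
        included=included,
        ranking=tuple(scored),
        ranking_p_raw=p_raw,
        ranking_p_fdr=p_fdr,
        ranking_boot_sd=boot_sd,
        top3=top3,
        top3_partition=part3,
        top3_component_p_raw=comp_p_raw,
        top3_component_p_fdr=comp_p_fdr,
        top3_component_boot_sd=comp_boot_sd,
        grouped_partition=part_grouped,
        grouped_winner=grouped_winner,
        cv_r2=cv_results,
        cv_ttest_p=ttest.p,
        explainable_ratio=ratio,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        seed=config.seed,
    )


def run_roi_analysis(
    roi_responses: Mapping[str, Sequence[ActivationMatrix]],
    models: Sequence[ModelRDMSet],
    config: StudyConfig = StudyConfig(),
    out_dir: str | Path | None = None,
) -> list[RoiReport]:
    """Analyze every ROI and optionally write JSON + TSV summaries.

    ROIs failing the noise-ceiling inclusion rule are still reported (with
    ``included=False``), never silently dropped.
    """
    if not roi_responses:
        raise ValueError("no ROI response sets supplied")
    reports = [
        analyze_roi(name, acts, models, config)
        for name, acts in roi_responses.items()
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_json(
            {
                "config": config.to_dict(),
                "rois": [r.to_dict() for r in reports],
            },
            out / "roi_reports.json",
        )
        summary = pd.DataFrame(
            [
                {
                    "roi": r.roi_name,
                    "lower_ceiling": r.noise_ceiling.lower,
                    "upper_ceiling": r.noise_ceiling.upper,
                    "included": r.included,
                    "best_model": r.ranking[0][0],
                    "best_r2_adj": r.ranking[0][1],
                    "grouped_winner": r.grouped_winner,
                    "cv_r2_subjects_and_stimuli": r.cv_r2[
                        "subjects_and_stimuli"
                    ].mean_r2,
                    "explainable_ratio": r.explainable_ratio,
                }
                for r in reports
            ]
        )
        summary.to_csv(out / "roi_summary.tsv", sep="\t", index=False)
    return reports
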
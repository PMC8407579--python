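"""Variance partitioning (commonality analysis) over three predictor sets.

Seven OLS regressions — one per nonempty subset of the three predictor
groups — decompose the full-model explained variance into three unique,
three pairwise-shared, and one triple-shared component.  Components are
computed from adjusted R^2 so they are commensurate with the headline
model-similarity metric; commonality components can be slightly negative
and are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .rdm import RDM, ModelRDMSet, average_rdms
from .regression import ModelRanking, fit_rdm_regression, rank_models

__all__ = [
    "VariancePartition",
    "SignificanceFlags",
    "partition_variance_three",
    "winner_by_unique_variance",
    "top3_partition",
    "grouped_task_rdms",
]

#: the seven predictor subsets, in fit order
SUBSETS = ("a", "b", "c", "ab", "ac", "bc", "abc")

#: components flagged when below this (commonality analysis permits
#: negative components; strongly negative ones deserve attention)
NEGATIVE_FLAG_THRESHOLD = -0.01


@dataclass(frozen=True)
class VariancePartition:
    """The 7 commonality components plus the full-model R^2.

    ``subset_r2`` records the adjusted R^2 of each of the seven fits, keyed
    by predictor-subset label ('a' ... 'abc').
    """

    unique_a: float
    unique_b: float
    unique_c: float
    shared_ab: float
    shared_ac: float
    shared_bc: float
    shared_abc: float
    total_r2: float
    predictor_names: tuple[str, str, str]
    subset_r2: Mapping[str, float]

    @property
    def n_fits(self) -> int:
        """Number of regressions performed (one per predictor subset)."""
        return len(self.subset_r2)

    def uniques(self) -> dict[str, float]:
        a, b, c = self.predictor_names
        return {a: self.unique_a, b: self.unique_b, c: self.unique_c}

    def components(self) -> dict[str, float]:
        a, b, c = self.predictor_names
        return {
            f"unique_{a}": self.unique_a,
            f"unique_{b}": self.unique_b,
            f"unique_{c}": self.unique_c,
            f"shared_{a}&{b}": self.shared_ab,
            f"shared_{a}&{c}": self.shared_ac,
            f"shared_{b}&{c}": self.shared_bc,
            f"shared_{a}&{b}&{c}": self.shared_abc,
        }

    def flagged_negative(self) -> list[str]:
        return [
            k for k, v in self.components().items() if v < NEGATIVE_FLAG_THRESHOLD
        ]


def _as_group(pred) -> list[RDM]:
    if isinstance(pred, RDM):
        return [pred]
    group = list(pred)
    if not group:
        raise ValueError("predictor group must contain at least one RDM")
    return group


def partition_variance_three(
    target: RDM,
    pred_a,
    pred_b,
    pred_c,
    names: Sequence[str] = ("a", "b", "c"),
    use_adjusted: bool = True,
) -> VariancePartition:
    """Commonality decomposition of the target RDM over three predictor groups.

    Each predictor group is a single RDM or a list of RDMs (e.g. the two
    layer RDMs of one model); a subset fit includes every RDM of every
    group in the subset.  With R(S) the adjusted R^2 of the fit on subset S:

        unique_a   = R(abc) - R(bc)
        shared_ab  = R(ac) + R(bc) - R(c) - R(abc)
        shared_abc = R(a)+R(b)+R(c) - R(ab) - R(ac) - R(bc) + R(abc)

    (and symmetric permutations).  The seven components sum to R(abc)
    identically.

    ``use_adjusted`` selects adjusted R^2 (default, commensurate with the
    model-ranking metric; small negative components possible) or raw R^2
    (under which the classical commonality identities — e.g. exact
    unique-variance recovery for mutually orthogonal predictors — hold to
    machine precision).
    """
    groups = {"a": _as_group(pred_a), "b": _as_group(pred_b), "c": _as_group(pred_c)}
    names = tuple(str(n) for n in names)
    if len(names) != 3 or len(set(names)) != 3:
        raise ValueError("need three distinct predictor names")
    r: dict[str, float] = {}
    for subset in SUBSETS:
        rdms = [rdm for g in subset for rdm in groups[g]]
        fit = fit_rdm_regression(target, rdms)
        r[subset] = fit.r2_adj if use_adjusted else fit.r2
    return VariancePartition(
        unique_a=r["abc"] - r["bc"],
        unique_b=r["abc"] - r["ac"],
        unique_c=r["abc"] - r["ab"],
        shared_ab=r["ac"] + r["bc"] - r["c"] - r["abc"],
        shared_ac=r["ab"] + r["bc"] - r["b"] - r["abc"],
        shared_bc=r["ab"] + r["ac"] - r["a"] - r["abc"],
        shared_abc=r["a"] + r["b"] + r["c"] - r["ab"] - r["ac"] - r["bc"] + r["abc"],
        total_r2=r["abc"],
        predictor_names=names,
        subset_r2=r,
    )


@dataclass(frozen=True)
class SignificanceFlags:
    """Significance of unique-variance components and their pairwise differences.

    ``unique_significant[g]`` — group g's unique variance exceeds chance.
    ``difference_significant[(g, h)]`` — g's unique variance is
    significantly larger than h's.
    """

    unique_significant: Mapping[str, bool]
    difference_significant: Mapping[tuple[str, str], bool]


def winner_by_unique_variance(
    partition: VariancePartition, flags: SignificanceFlags
) -> str:
    """The predictor group whose unique variance dominates, or ``"none"``.

    The winner must have the largest unique component, a significant unique
    component, and a significant advantage over *both* other groups;
    otherwise no label is assigned (near-ties are not interpreted).
    """
    uniques = partition.uniques()
    winner = max(sorted(uniques), key=lambda g: uniques[g])
    others = [g for g in uniques if g != winner]
    if not flags.unique_significant.get(winner, False):
        return "none"
    for other in others:
        if not flags.difference_significant.get((winner, other), False):
            return "none"
    return winner


def top3_partition(
    target: RDM, models: Sequence[ModelRDMSet]
) -> tuple[ModelRanking, VariancePartition]:
    """Rank models, then partition variance over the top three.

    Each of the top-3 models contributes all of its layer RDMs as one
    predictor group.
    """
    models = list(models)
    if len(models) < 3:
        raise ValueError("need at least 3 candidate models")
    ranking = rank_models(target, models, top_k=3)
    by_name = {m.model_name: m for m in models}
    top = [by_name[name] for name in ranking.top(3)]
    partition = partition_variance_three(
        target,
        list(top[0].layer_rdms),
        list(top[1].layer_rdms),
        list(top[2].layer_rdms),
        names=tuple(m.model_name for m in top),
    )
    return ranking, partition


def grouped_task_rdms(
    model_sets: Sequence[ModelRDMSet],
    groups: Sequence[str] = ("2D", "3D", "semantic"),
) -> dict[str, RDM]:
    """One aggregate RDM per task group.

    Layer RDMs are averaged per-layer across the group's members first,
    then across layers, yielding a single grouped RDM per task type.
    """
    out: dict[str, RDM] = {}
    for group in groups:
        members = [m for m in model_sets if m.task_group == group]
        if not members:
            raise ValueError(f"no models in task group {group!r}")
        n_layers = {len(m.layer_rdms) for m in members}
        if len(n_layers) != 1:
            raise ValueError(f"models in group {group!r} differ in layer count")
        per_layer = [
            average_rdms([m.layer_rdms[i] for m in members])
            for i in range(n_layers.pop())
        ]
        out[group] = average_rdms(per_layer)
    return out
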
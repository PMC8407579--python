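"""Variance partitioning: commonality identity, brute force, winners."""

import itertools

import numpy as np
import pytest

from taskmap import (
    ModelRDMSet,
    SignificanceFlags,
    fit_rdm_regression,
    grouped_task_rdms,
    partition_variance_three,
    top3_partition,
    unvectorize_upper,
    winner_by_unique_variance,
)

from conftest import random_rdm


def brute_force_partition(target, groups):
    """Independent commonality solver: enumerate all 2^3 - 1 predictor
    subsets, then solve the linear system mapping Venn components to
    subset R^2 values.

    A Venn component (a set of predictor labels) contributes to R(S)
    exactly when it involves at least one member of S.
    """
    labels = ("a", "b", "c")
    subsets = [frozenset(c) for k in range(1, 4) for c in itertools.combinations(labels, k)]
    r = {}
    for s in subsets:
        rdms = [rdm for lab in sorted(s) for rdm in groups[lab]]
        r[s] = fit_rdm_regression(target, rdms).r2_adj
    components = subsets  # same 7 index sets label the Venn regions
    A = np.zeros((7, 7))
    for i, s in enumerate(subsets):
        for j, comp in enumerate(components):
            if comp & s:
                A[i, j] = 1.0
    x = np.linalg.solve(A, np.array([r[s] for s in subsets]))
    return {comp: x[j] for j, comp in enumerate(components)}


def _three_groups(rng, n=10):
    target = random_rdm(rng, n=n)
    ids = target.condition_ids
    groups = {
        "a": [random_rdm(rng, n=n, ids=ids)],
        "b": [random_rdm(rng, n=n, ids=ids)],
        "c": [random_rdm(rng, n=n, ids=ids)],
    }
    return target, groups


class TestPartition:
    def test_identical_groups_put_everything_in_triple_shared(self, rng):
        target, groups = _three_groups(rng)
        same = groups["a"]
        part = partition_variance_three(target, same, same, same)
        full = part.subset_r2["a"]
        for comp in (part.unique_a, part.unique_b, part.unique_c,
                     part.shared_ab, part.shared_ac, part.shared_bc):
            assert comp == pytest.approx(0.0, abs=1e-10)
        assert part.shared_abc == pytest.approx(full, abs=1e-10)

    def test_orthogonal_predictors_have_no_shared_variance(self):
        # analytically orthogonal predictor vectors: distinct Fourier-like
        # components over the 10 pair slots of a 5-condition RDM
        n = 5
        m = n * (n - 1) // 2
        t = np.arange(m)
        ids = tuple(f"c{i}" for i in range(n))
        basis = [np.cos(2 * np.pi * (k + 1) * t / m) for k in range(3)]
        preds = {lab: [unvectorize_upper(1.0 + 0.1 * b, ids)] for lab, b in
                 zip("abc", basis)}
        y = 1.0 + 0.05 * basis[0] + 0.03 * basis[1] + 0.02 * basis[2]
        target = unvectorize_upper(y, ids)
        # classical commonality identities are exact for raw R^2
        part = partition_variance_three(
            target, preds["a"], preds["b"], preds["c"], use_adjusted=False
        )
        for lab, unique in zip("abc", (part.unique_a, part.unique_b, part.unique_c)):
            solo = fit_rdm_regression(target, preds[lab]).r2
            assert unique == pytest.approx(solo, abs=1e-8)
        for shared in (part.shared_ab, part.shared_ac, part.shared_bc,
                       part.shared_abc):
            assert abs(shared) < 1e-8

    def test_components_sum_to_total_on_random_inputs(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            target, groups = _three_groups(rng)
            part = partition_variance_three(
                target, groups["a"], groups["b"], groups["c"]
            )
            total = (
                part.unique_a + part.unique_b + part.unique_c
                + part.shared_ab + part.shared_ac + part.shared_bc
                + part.shared_abc
            )
            assert total == pytest.approx(part.total_r2, abs=1e-10)

    def test_equivalence_with_brute_force_solver(self):
        for seed in range(50):
            rng = np.random.default_rng(seed + 1000)
            target, groups = _three_groups(rng)
            part = partition_variance_three(
                target, groups["a"], groups["b"], groups["c"]
            )
            oracle = brute_force_partition(target, groups)
            fs = frozenset
            assert part.unique_a == pytest.approx(oracle[fs("a")], abs=1e-9)
            assert part.unique_b == pytest.approx(oracle[fs("b")], abs=1e-9)
            assert part.unique_c == pytest.approx(oracle[fs("c")], abs=1e-9)
            assert part.shared_ab == pytest.approx(oracle[fs("ab")], abs=1e-9)
            assert part.shared_ac == pytest.approx(oracle[fs("ac")], abs=1e-9)
            assert part.shared_bc == pytest.approx(oracle[fs("bc")], abs=1e-9)
            assert part.shared_abc == pytest.approx(oracle[fs("abc")], abs=1e-9)

    def test_relabeling_groups_permutes_components(self, rng):
        target, groups = _three_groups(rng)
        p1 = partition_variance_three(target, groups["a"], groups["b"], groups["c"])
        p2 = partition_variance_three(target, groups["c"], groups["a"], groups["b"])
        assert p2.unique_a == pytest.approx(p1.unique_c, abs=1e-12)
        assert p2.unique_b == pytest.approx(p1.unique_a, abs=1e-12)
        assert p2.shared_bc == pytest.approx(p1.shared_ab, abs=1e-12)
        assert p2.shared_abc == pytest.approx(p1.shared_abc, abs=1e-12)

    def test_seven_fits_performed(self, rng):
        target, groups = _three_groups(rng)
        part = partition_variance_three(target, groups["a"], groups["b"], groups["c"])
        assert part.n_fits == 7


class TestWinner:
    def _flags(self, sig_unique, sig_diffs):
        return SignificanceFlags(
            unique_significant=sig_unique, difference_significant=sig_diffs
        )

    def _partition(self, ua, ub, uc):
        return partition_variance_three.__wrapped__ if False else _make_partition(ua, ub, uc)

    def test_dominant_significant_unique_wins(self):
        part = _make_partition(0.30, 0.01, 0.01)
        flags = self._flags(
            {"a": True, "b": True, "c": True},
            {(g, h): True for g in "abc" for h in "abc" if g != h},
        )
        assert winner_by_unique_variance(part, flags) == "a"

    def test_near_tie_without_significance_gives_none(self):
        part = _make_partition(0.30, 0.29, 0.01)
        flags = self._flags(
            {"a": True, "b": True, "c": True},
            {("a", "b"): False, ("a", "c"): True, ("b", "a"): False,
             ("b", "c"): True, ("c", "a"): False, ("c", "b"): False},
        )
        assert winner_by_unique_variance(part, flags) == "none"

    def test_insignificant_unique_gives_none(self):
        part = _make_partition(0.30, 0.01, 0.01)
        flags = self._flags(
            {"a": False, "b": False, "c": False},
            {(g, h): True for g in "abc" for h in "abc" if g != h},
        )
        assert winner_by_unique_variance(part, flags) == "none"


def _make_partition(ua, ub, uc):
    from taskmap import VariancePartition

    return VariancePartition(
        unique_a=ua, unique_b=ub, unique_c=uc,
        shared_ab=0.0, shared_ac=0.0, shared_bc=0.0, shared_abc=0.0,
        total_r2=ua + ub + uc, predictor_names=("a", "b", "c"),
        subset_r2={s: 0.0 for s in ("a", "b", "c", "ab", "ac", "bc", "abc")},
    )


class TestTop3:
    def test_planted_three_model_mixture_recovered(self, rng):
        n = 12
        target_parts = [random_rdm(rng, n=n) for _ in range(1)]
        ids = target_parts[0].condition_ids
        planted = [random_rdm(rng, n=n, ids=ids) for _ in range(3)]
        mixture = unvectorize_upper(
            np.mean([__import__("taskmap").vectorize_upper(p) for p in planted], axis=0),
            ids,
        )
        models = [
            ModelRDMSet(f"planted_{i}", "2D", (p, p)) for i, p in enumerate(planted)
        ] + [
            ModelRDMSet(f"rand_{i}", "random",
                        tuple(random_rdm(rng, n=n, ids=ids) for _ in range(2)))
            for i in range(3)
        ]
        ranking, part = top3_partition(mixture, models)
        assert set(ranking.top(3)) == {"planted_0", "planted_1", "planted_2"}
        assert part.total_r2 == pytest.approx(1.0, abs=1e-8)

    def test_identical_top_models_share_everything(self, rng):
        target = random_rdm(rng, n=10)
        ids = target.condition_ids
        layer = (target, random_rdm(rng, n=10, ids=ids))
        models = [ModelRDMSet(f"dup_{i}", "2D", layer) for i in range(3)]
        _, part = top3_partition(target, models)
        assert part.shared_abc == pytest.approx(part.total_r2, abs=1e-8)
        for u in (part.unique_a, part.unique_b, part.unique_c):
            assert u == pytest.approx(0.0, abs=1e-8)

    def test_same_group_top_models_share_more_than_outgroup(self, mixed_models, mixed_design):
        """With high within-group correlation, two same-group models in the
        top-3 shift variance from unique to shared components."""
        from taskmap import generate_subject_responses, compute_rdm, average_rdms

        subs = generate_subject_responses(
            mixed_design, [m.layer_rdms[0] for m in mixed_models]
        )
        target = average_rdms([compute_rdm(a) for a in subs])
        ranking, part = top3_partition(target, mixed_models)
        by_name = {m.model_name: m for m in mixed_models}
        groups = [by_name[n].task_group for n in part.predictor_names]
        uniques = part.uniques()
        # the planted ROI is pure 2D_0; its 2D sibling enters the top-3 and
        # their unique components collapse relative to the out-group model
        ingroup = [n for n, g in zip(part.predictor_names, groups) if g == "2D"]
        outgroup = [n for n, g in zip(part.predictor_names, groups) if g != "2D"]
        if len(ingroup) >= 2 and outgroup:
            assert max(uniques[n] for n in ingroup[1:]) <= uniques[ingroup[0]]


class TestGroupedRDMs:
    def test_per_layer_then_across_layer_averaging(self, mixed_models):
        grouped = grouped_task_rdms(mixed_models)
        assert set(grouped) == {"2D", "3D", "semantic"}
        members = [m for m in mixed_models if m.task_group == "2D"]
        expected = np.mean(
            [np.mean([m.layer_rdms[i].values for m in members], axis=0)
             for i in range(2)],
            axis=0,
        )
        np.testing.assert_allclose(grouped["2D"].values, expected, atol=1e-12)

    def test_empty_group_errors(self, mixed_models):
        no_sem = [m for m in mixed_models if m.task_group != "semantic"]
        with pytest.raises(ValueError, match="semantic"):
            grouped_task_rdms(no_sem)
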
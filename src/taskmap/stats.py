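"""Nonparametric inference for RDM statistics.

Condition-label permutation tests (one-sided, add-one p estimator),
condition-subsampling bootstrap standard deviations, Benjamini-Hochberg
FDR correction, and the one-sample t-test on per-subject cross-validated
R^2 values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .rdm import RDM

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "TTestResult",
    "permutation_test",
    "permutation_difference_test",
    "bootstrap_sd",
    "fdr_correct",
    "ttest_cv_r2",
    "permutation_pvalue",
    "pair_index_permutation",
]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_samples: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    sd: float
    n_iterations: int
    subsample_size: int
    seed: int | None


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def permutation_pvalue(observed: float, null_samples: np.ndarray) -> float:
    """One-sided add-one estimator: p = (1 + #{null >= obs}) / (1 + n_perm).

    Never returns 0; the minimum attainable p is 1/(n_perm + 1).
    """
    null_samples = np.asarray(null_samples, dtype=float)
    return float(
        (1 + np.count_nonzero(null_samples >= observed)) / (1 + null_samples.size)
    )


def permutation_test(
    statistic_fn: Callable[..., float],
    target: RDM,
    fixed_args: tuple = (),
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> PermutationResult:
    """Condition-permutation null for a statistic of a target RDM.

    Each iteration draws a random permutation of the condition labels,
    applies it jointly to the rows and columns of the target RDM (leaving
    ``fixed_args``, typically predictor RDMs, untouched), and recomputes
    ``statistic_fn(permuted_target, *fixed_args)``.  The p-value is the
    one-sided add-one estimator.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    observed = float(statistic_fn(target, *fixed_args))
    rng = np.random.default_rng(seed)
    n = target.n_conditions
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        try:
            null[i] = statistic_fn(target.permute(perm), *fixed_args)
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(
                f"statistic failed on permutation {i} ({perm.tolist()})"
            ) from exc
    return PermutationResult(
        observed=observed,
        null_samples=null,
        p_value=permutation_pvalue(observed, null),
        n_permutations=n_perm,
        seed=seed,
    )


def permutation_difference_test(
    stat_a: Callable[..., float],
    stat_b: Callable[..., float],
    target: RDM,
    fixed_args: tuple = (),
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> PermutationResult:
    """One-sided permutation test on the difference stat_a - stat_b.

    Both statistics see the same permuted target in each iteration, so the
    null preserves their dependence.  The test is directional: it asks
    whether a exceeds b; swap the arguments for the other direction.
    """

    def diff(rdm: RDM, *args) -> float:
        return float(stat_a(rdm, *args)) - float(stat_b(rdm, *args))

    return permutation_test(diff, target, fixed_args, n_perm=n_perm, seed=seed)


def bootstrap_sd(
    statistic_fn: Callable[..., float],
    rdms: Sequence[RDM],
    fraction: float = 0.9,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> BootstrapResult:
    """Bootstrap SD of a statistic under condition subsampling.

    Each iteration draws ``round(fraction * n_conditions)`` conditions
    without replacement, restricts every RDM to that subset, and
    recomputes the statistic; the reported SD is over iterations.  With 50
    conditions at the default fraction 0.9 each subsample keeps 45.
    """
    rdms = list(rdms)
    if not rdms:
        raise ValueError("need at least one RDM")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = rdms[0].n_conditions
    size = int(round(fraction * n))
    if size < 4:
        raise ValueError(f"subsample of {size} conditions is too small (< 4)")
    estimate = float(statistic_fn(*rdms))
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    for i in range(n_boot):
        keep = np.sort(rng.choice(n, size=size, replace=False))
        samples[i] = statistic_fn(*[r.subset(keep) for r in rdms])
    return BootstrapResult(
        estimate=estimate,
        sd=float(np.std(samples, ddof=1)),
        n_iterations=n_boot,
        subsample_size=size,
        seed=seed,
    )


def fdr_correct(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns (rejected, p_adjusted) in input order; adjusted p-values are
    monotone in the raw p-values and the rejection set equals
    {p_adj <= q}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def ttest_cv_r2(per_subject_r2: Sequence[float]) -> TTestResult:
    """Two-sided one-sample t-test of per-subject R^2 values against zero."""
    values = np.asarray(per_subject_r2, dtype=float)
    if values.size < 3:
        raise ValueError("need >= 3 subjects for a t-test")
    if np.std(values, ddof=1) == 0.0:
        # all-equal R^2: t undefined; report the degenerate verdict directly
        p = 1.0 if values[0] == 0.0 else 0.0
        return TTestResult(t=float("nan"), p=p, degenerate=True)
    res = _scipy_stats.ttest_1samp(values, popmean=0.0, alternative="two-sided")
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def pair_index_permutation(n_conditions: int, perm: np.ndarray) -> np.ndarray:
    """Upper-triangle index permutation induced by a condition permutation.

    For the row-major strictly-upper vectorization, returns ``idx`` such
    that ``vec(permuted_rdm) = vec(rdm)[idx]``.  Used to vectorize
    permutation nulls over many targets without rebuilding matrices.
    """
    n = n_conditions
    lookup = np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    lookup[iu, ju] = np.arange(iu.size)
    lookup[ju, iu] = lookup[iu, ju]
    pi, pj = perm[iu], perm[ju]
    return lookup[pi, pj]
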
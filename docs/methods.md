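# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Representational distance and regression conventions

Dissimilarity is Pearson distance, `d = 1 − r`, in `[0, 2]`; no other
metric is offered. Activations are not preprocessed before the distance —
Pearson correlation is already invariant to per-pattern location and
scale, so z-scoring would be a no-op at the pattern level.

RDMs are compared through their strictly-upper-triangle vectors in fixed
row-major order, so vectors from any two sources align by construction.
Brain and model RDMs are aligned by condition-id string match; a
mismatched condition set is always an error, never a silent positional
reorder.

All fits are ordinary least squares with an intercept. The headline
similarity metric is adjusted R²,
`1 − (1 − R²)(m − 1)/(m − p − 1)` with `m` the number of condition pairs.
The degrees-of-freedom penalty `p` is the *effective* predictor count
(design-matrix rank minus the intercept). For every full-rank design this
equals the number of predictor RDMs; for degenerate designs (duplicated
or collinear predictors, which the fit accepts with a minimum-norm
solution and a logged warning) it is the only choice that keeps the
adjustment from depending on how many copies of the same regressor were
supplied. Negative adjusted R² is reported as-is — clamping it would
destroy the random-baseline comparisons. Model ranking ties are broken
lexicographically by model name and recorded.

## Variance partitioning

Three predictor groups (each one or more RDMs — e.g. the two layer RDMs
of one model, or a single group-averaged RDM) enter seven regressions,
one per nonempty subset. Commonality components are linear combinations
of the subset R² values (`unique_a = R(abc) − R(bc)`,
`shared_ab = R(ac) + R(bc) − R(c) − R(abc)`,
`shared_abc = ΣR(single) − ΣR(pair) + R(abc)`), so the seven components
sum to the full-model R² *identically*, whatever the inputs — this
algebraic identity, plus agreement with an independent brute-force solver
that inverts the 7×7 subset-incidence system, is the module's primary
correctness oracle.

Two R² flavors are supported. The default uses adjusted R² in all seven
fits so components are commensurate with the ranking metric; its known
consequence is that components can be slightly negative (reported raw,
flagged below −0.01) and that the classical orthogonal-predictor
identities hold only up to `O(1/m)` penalty differences. With
`use_adjusted=False` the fits use raw R², under which mutually orthogonal
predictors recover `unique_x = R²(x)` and zero shared terms to machine
precision; the exactness checks use this flavor.

Grouped (2D/3D/semantic) predictors are built by averaging member RDMs
per layer and then across layers into one RDM per group. Keeping the two
layers as separate grouped predictors is a defensible alternative; the
single-RDM reading is implemented and isolated in `grouped_task_rdms`.

A region is assigned to a task group only when that group's unique
variance is the largest, itself significant, *and* significantly larger
than both competitors; anything less yields `"none"` rather than an
arbitrary label.

## Noise ceilings and cross-validation

The lower ceiling regresses each subject's RDM on the mean RDM of the
other N−1 subjects and averages the adjusted R² across subjects; the
upper ceiling uses the all-subject mean as predictor. Identical subject
RDMs give lower = upper = 1 (verified to 1e-6); the leave-one-out
predictor is noisier than the all-subject mean, so upper ≥ lower holds
throughout the synthetic sweeps (not guaranteed pointwise — both are
estimates). ROIs with lower ceiling ≤ 0.1 (configurable) are flagged for
exclusion but still reported.

Cross-validated explained variance supports three modes: `none` (a single
in-sample fit on the subject-averaged RDM), `subjects` (N folds,
leave-one-subject-out), and `subjects_and_stimuli` (2N folds: conditions
are split once into two seeded random halves; fits use only pairs within
the training half, evaluation only pairs within the held-out half, so no
(subject, pair) datum is ever shared between fit and test). Evaluation
folds score *prediction* R² from the training-fold coefficients, not a
refit; this makes the statistic honest — near zero, slightly negative in
expectation (≈ −p/m_test), for uninformative predictors — which is
exactly why 1,000 random predictor RDMs score ≈ 0 under full
cross-validation while the in-sample mode retains its small positive
fitting bias (≈ p/(m−1)). The ratio of CV R² to the lower ceiling may
exceed 1, since the lower bound is itself an estimate.

## Inference

Permutation tests draw random condition-label permutations, applied
jointly to the rows and columns of the target RDM while predictors stay
fixed (equivalent, by symmetry of the statistic, to permuting the model
RDM). P-values use the one-sided add-one estimator
`(1 + #{null ≥ obs})/(1 + n_perm)`, which can never return 0. Difference
tests recompute both statistics on the *same* permuted target, preserving
their dependence; they are one-sided on the signed difference, with the
direction explicit in reports. Bootstrap error bars subsample
`round(0.9 · n)` conditions without replacement (45 of 50 at study scale)
and report the SD of the recomputed statistic. FDR is Benjamini–Hochberg;
the family is all models within an ROI for ROI analyses, and blocks ×
models (or blocks × groups) for searchlight maps. The t-test on
cross-validated R² is a two-sided one-sample test against zero; a
zero-variance input is reported as degenerate rather than producing an
undefined statistic.

## Searchlight

The searchlight is a cube of radius 1, edge `2r + 1 = 3`, 27 voxels at
interior positions, clipped (not padded) at mask borders, with blocks
below `min_voxels = 9` skipped. Per-subject block RDMs are averaged
across subjects before model comparison. Blocks are labeled only where
(a) the block's lower noise ceiling is permutation-significant — the null
permutes conditions *independently per subject*, destroying
between-subject correspondence while preserving each RDM's value
distribution — with FDR across blocks, and (b) the winning statistic is
permutation-significant with FDR across blocks × models. Permutation
nulls are vectorized: a condition permutation induces a permutation of
the pair-vector indices, so null statistics reduce to fancy-indexed
matrix products against precomputed orthonormal design bases; null draws
are shared across blocks, which is what makes dense maps with hundreds of
permutations run in seconds.

## The synthetic generator

Model RDM sets are derived from latent condition × feature matrices built
from a global basis (shared across groups), a per-group basis, and
per-model/per-layer idiosyncratic parts. Because the correlation of two
RDMs grows roughly as the *square* of the shared feature-variance
fraction, the design targets (`within_group_corr`, `between_group_corr`,
interpreted at the RDM level) are mapped through a square root at the
feature level; realized RDM correlations then land near the targets
(≈ 0.79 and 0.16 for targets 0.8 / 0.2 at 50 conditions) and always
preserve their ordering. Random-group models share no basis with the
trained groups. `layer_jitter` (default 0.2) is the fraction of a model's
idiosyncratic variance that differs between its two layers; with
within = between = 1 all model RDMs collapse to identity regardless of
jitter, which is the degenerate check.

Subject responses realize a target RDM mixture exactly: the mixture's
correlation matrix `C = 1 − D` is positive semidefinite by construction
(a convex combination of correlation matrices), its eigen-factor is
embedded through a random orthonormal voxel basis orthogonal to the
constant vector, so pattern rows are exactly zero-mean and the noise-free
RDM equals the mixture to numerical precision. Negative eigenvalue mass
(numerical only) is clipped and logged. Patterns are scaled to unit
per-voxel variance, so `subject_noise_sd` reads directly as a
noise-to-signal ratio; the default 1.0 yields subject-averaged noise
ceilings in the 0.15–0.3 range at 16 subjects, comparable to typical
event-related fMRI ROIs. Noise is i.i.d. Gaussian per voxel — an
assumption, not an inference: real fMRI noise is spatially and temporally
correlated, so passing synthetic benchmarks shows the *estimators* are
correct, not that real-data performance will match.

Synthetic volumes plant one model's layer-averaged RDM per labeled
region, with the embedding computed over the region's full voxel set and
background voxels carrying pure noise. Region-level RDMs are therefore
exact in the noise-free limit, while an individual 27-voxel searchlight
block samples a subset of the embedding basis and realizes the planted
RDM only approximately; block-level fidelity (and with it winner-map
significance) grows with the number of conditions, which is why volume
benchmarks use 20 conditions rather than the 12 that would suffice for
region-level checks. Every region must be able to contain at least one
full searchlight block.

Determinism: a single master seed per design; each generation stage
(models, subjects, volumes) draws from its own fixed child stream, so
identical designs give bit-identical outputs and regenerating one
artifact does not disturb the others.

## Benchmark problem sizes

The verification experiments run at these sizes, chosen to keep the full
suite around two minutes on one CPU while leaving every statistical
conclusion comfortably clear of its threshold: commonality and
brute-force checks on 50 random 10-condition instances; type-I
calibration over 200 null datasets × 500 permutations at 20 conditions;
noise-ceiling sweeps over 200 seeds (6 subjects, 20 conditions) plus a
3-level noise grid × 20 seeds; planted-mixture recovery over 100 seeds at
the full 50-condition / 16-subject scale; searchlight recovery on a
12×12×12 volume (three 6×6×12 regions, 8 subjects, 20 conditions, 500
permutations); and the random-RDM control with 1,000 predictors against a
16-subject, 50-condition stack.

## Known limitations

- No hemodynamic or GLM stage: responses are generated and consumed at
  the condition-estimate level.
- Pearson distance only; no crossnobis/Euclidean variants, no
  rank-correlation RSA, no cross-validated reweighting.
- Commonality analysis is fixed at three predictor groups.
- The searchlight is cubic and volume-based; no surface-based analysis.
- Reports are JSON/TSV plus NIfTI maps; no interactive visualization.
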
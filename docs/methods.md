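# Methods

This note documents the statistical machinery in `oculopls`: the models,
the numerical choices, what the synthetic cohorts do and do not emulate,
and the known limitations.

## Data model

A cohort is one row per participant: id, group (HC/PD), sex, age, seven
clinical outcomes (MoCA, SDMT, TMTA, TMTB, HVLT, COWAT, BAI) and the
oculomotor parameters declared by a catalog mapping each parameter to its
eye-tracking task (fixation, pro-saccade, anti-saccade, smooth pursuit,
OKN). The default catalog carries 199 parameters; since the true per-task
breakdown of such batteries varies by vendor, the split (30/60/50/35/24)
was chosen once as a plausible allocation and is fully configurable.
Missingness is explicit: empty CSV cells (also `NA`/`NaN`, any case) map
to NaN plus a derived observation mask. Validation checks instrument
ranges: MoCA ∈ [0, 30], SDMT ∈ [0, 110], BAI ∈ [0, 63], TMT times > 0,
HVLT and COWAT ≥ 0.

## Rank statistics

`spearman_rho` is Pearson correlation of average-rank transforms, with
pairwise deletion and a two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 df —
the default of the common statistical packages for n ≥ 10 and adequate at
the cohort sizes here. Zero rank variance yields an explicitly *undefined*
result (NaN) that propagates and is excluded from summaries, never
silently coerced to 0. BH adjustment delegates to statsmodels' `fdr_bh`
step-up; the family is all parameters for one outcome within one group,
matching per-column annotation of correlation heat maps (a global family
is a logged alternative the caller can assemble manually). Mann–Whitney U
uses scipy: exact enumeration when the pooled data is tie-free and
C(n_a+n_b, n_a) is below a threshold, otherwise the normal approximation
with tie and continuity corrections; with those corrections the
approximation tracks exact enumeration to about 0.01 (median) already at
n = 8 per group.

## PPCA imputation

Model: x = Wz + μ + ε with z ~ N(0, I_r), ε ~ N(0, σ²I). Missing entries
are marginalized out of the likelihood exactly — the E-step computes
posterior latent moments per row from that row's observed coordinates
(rows grouped by missing pattern, so block-structured missingness costs
one r×r inverse per pattern), and the M-step solves for (W, μ) jointly via
an augmented latent vector, then updates σ² (an ECM step). This makes the
observed-data log-likelihood provably nondecreasing; the fitter asserts
nothing but records the full likelihood path, and the test suite checks
monotonicity to 1e-8 relative per step. Columns are standardized on their
observed entries internally (constant columns are rejected) and
back-transformed on output; observed cells pass through imputation
bit-exactly.

Numerical choices: initialization from the truncated SVD of the
zero-imputed standardized matrix (deterministic; the `seed` argument is
accepted for interface stability but unused), relative-tolerance stopping
(default 1e-6, max 500 iterations; non-convergence is reported via a flag,
not an exception), and a hard stop once σ² ≤ 1e-11 — the noiseless
degenerate regime where the likelihood diverges and further iterations
only accumulate rounding noise.

`select_rank` hides a random 10% of observed cells per fold (never
emptying a row or column), refits each candidate rank, and scores held-out
RMSE; ties go to the smaller rank. The pipeline default rank is frozen at
4, chosen once by running `select_rank` over {2,…,15} on preset cohorts;
for real data of unknown structure `select_rank` is the recommended path,
and the rank used is recorded in every `ImputationReport`. Imputation is a
single posterior-mean completion — no multiple imputation, so downstream
standard errors ignore imputation uncertainty.

## PLS modeling

`fit_pls` is single-response NIPALS on z-scored predictors and centered
response; for PLS1 each component is closed-form (w ∝ Xᵀy), the
coefficient vector is W(PᵀW)⁻¹q mapped back to raw units, and predictions
are affine in the raw inputs. With as many components as (full-rank)
predictors it reproduces OLS to 1e-8, and the first weight vector equals
the normalized feature–response covariance vector — both are tested, as is
agreement with scikit-learn's `PLSRegression` (used strictly as a
cross-check, never the implementation: the subset search needs nested
per-component predictions from a single pass, which the estimator API
cannot supply at acceptable cost). The cross-validation hot path is a
numba-compiled kernel; a pure-numpy twin with identical semantics serves
as fallback and as an equivalence oracle in the tests.

Component selection minimizes BIC_k = n·ln(PRESS_k/n) + (k+1)·ln(n),
where PRESS_k accumulates squared held-out residuals over a 10-fold
partition that is a pure function of (n, folds, seed) — fixed across all
subset evaluations within one search so criteria are comparable. Ties go
to the smaller k. The in-sample RSS variant of BIC was considered and
rejected: pairing the information criterion with cross-validated residuals
honors both halves of the design (penalized selection *under* CV).

The subset search screens the top-20 parameters by |ρ| (deterministic
name-based tie-break), optionally appends age as an unscreened candidate,
and evaluates every nonempty subset (trace records 2^C − 1 evaluations;
the candidate count entering the search is capped — default 12, 10 in the
shipped study configurations — because 2^20 evaluations change cost, not
semantics). Each subset is scored by CV R² at its BIC-chosen component
count. The winner is the *smallest subset within 0.002 CV R² of the
maximum*: a strict argmax over thousands of near-tied subsets
systematically drags in spurious features (measured spurious gains of
1e-4–1e-3 CV R² admitted three or more noise features in a fifth of
planted-signal runs), while the toleranced rule recovers planted signals
cleanly and remains fully deterministic (remaining ties: higher criterion,
then lexicographic names).

Reported figures: headline R² is the in-sample R² of the final refit
(matching how fitted-vs-true scatterplots are usually annotated), CV R²
is always reported alongside to expose optimism, and adjusted R² uses
p = number of selected raw features (age counts when selected) — with
n ≈ 200 and p ≈ 9 this reproduces the canonical 0.36 → 0.33 pairing of
in-sample and adjusted values. Under a global null the *selected* model's
CV R² sits slightly above zero (median ≈ +0.1 at n = 204 with 199
screened parameters) — the winner's curse of reporting the criterion that
was maximized; the null-calibration test documents this rather than hiding
it.

## Permutation tests

Group differences in Spearman ρ pool the (x, y) pairs and reassign labels
preserving group sizes; differences in adjusted R² pool participants and
refit PLS *coefficients* per pseudo-group with each model's selected
features and component count fixed — re-running feature selection inside
each of 1,000 replicates would be combinatorially infeasible and tests a
different hypothesis (pipeline instability rather than model fit). The
paired true-age/predicted-age comparison swaps the two age variants within
participant with probability ½ (sign-flip exchangeability). "More extreme"
is the closed inequality |perm| ≥ |obs|, reported as a plain proportion;
optional add-one smoothing ((b+1)/(M+1)) is off by default. When the
number of distinct relabelings (or swap patterns) does not exceed the
requested replicates, the null is enumerated exhaustively and flagged
exact. Degenerate replicates (undefined permuted correlations) are
discarded and redrawn, with the count logged. Empirical type-I error of
both tests is calibrated to [0.03, 0.07] at α = 0.05 in the acceptance
suite.

## Synthetic cohorts

The generator is the package's stand-in for undeposited study data. Per
participant: age from a truncated normal (resampling, not clipping, to
avoid boundary atoms), a latent neural-integrity factor
g = α·z(age) + √(1−α²)·ε with α = 0.5, informative parameters
x_j = λ_j·κ·g + noise with signed loadings λ_j (magnitudes U(0.7, 1.3), 60
informative parameters spread across all five tasks), and scores
s = intercept + β·age + γ·κ·g + noise. Discrete instruments are rounded
and clipped to range; TMT times get additive shifted log-normal noise
(σ_ln = 0.5) to mimic their right skew — the very skew that motivates rank
statistics. Sex has no effect in the defaults (an optional per-score knob
exists for power experiments). Missingness is structural first (whole
participant×task blocks dropped with the block rate), then cell-wise MCAR;
demographics and scores are never masked, and per-test completion counts
(e.g. MoCA 203/204 in HC, 36/65 in PD) are enforced exactly.

`theoretical_r2` returns (u² + w² + 2αuw)/(u² + w² + 2αuw + σ²) with
u = β·σ_age and w = γ·κ — the population R² of an ideal model seeing
(g, age). The cross term is required because g carries an age component;
a 20,000-participant oracle regression agrees within ±0.02.

Calibration: score slopes and noise SDs were set analytically from target
age–score rank correlations (ρ ≈ 0.40 TMTA, 0.37 TMTB, −0.63 SDMT, −0.44
HVLT, −0.28 BAI, −0.14 COWAT, −0.13 MoCA) and realistic scales, then
adjusted once against large-n simulations. The coupling constants
(κ_HC = 1, κ_PD = 3 with per-score disease amplification factors) were
calibrated once so the full pipeline's median adjusted R² lands mid-range
of the regimes the package emulates — roughly 0.10–0.33 across outcomes
for HC and 0.47–0.63 for PD — and frozen in `presets.py`. PD presets also
shift score means (slower TMT, lower MoCA/HVLT, unchanged COWAT) so the
group-distribution comparisons have known answers.

What the generator does *not* emulate: multi-factor domain structure (one
shared latent factor is the minimal structure reproducing the weak-HC /
strong-PD pattern), parameter-specific units and scales (all parameters
are zero-mean unit-ish noise plus loading), realistic inter-parameter
correlation beyond the single factor, medication or severity gradients
within PD, and any raw gaze dynamics. Passing tests therefore demonstrate
that the *pipeline* recovers the structure it assumes, not that real
oculomotor data satisfies those assumptions.

## Problem sizes and determinism

The shipped study configurations use subset cap 10 (1,023 subsets per
outcome), 10-fold CV, PPCA rank 4 and 200–1,000 permutation replicates;
the acceptance checks run 20 replicate cohort pairs and the acceptance
script 8, sizes chosen to characterize medians stably. Every stage seeds
its generator from a stable CRC32 hash of (master seed, stage, outcome,
group), so adding an outcome never perturbs another's results and any
run is exactly reproducible from its manifest.

## Known limitations

- Point imputation: no propagation of imputation uncertainty.
- The reported in-sample R² of a searched model is optimistic by
  construction; CV R² is the honest companion number, and even it carries
  the selection winner's curse quantified above.
- The Spearman p-value uses the t-approximation at all n ≥ 3 rather than
  exact permutation below n = 10; at the cohort sizes modeled this is
  immaterial.
- Age models are fit for the healthy group only (a "brain-age" baseline
  requires a reference population free of the disease under study).
- The exhaustive search is exponential by design; caps change cost only,
  but very small candidate caps can exclude jointly-informative parameter
  sets that individually screen poorly.
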
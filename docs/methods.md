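# Methods

## Generating model

All synthetic data come from a linear structural equation system at
equilibrium,

    x = B x + a A + c + eps,

over `p` phosphoprotein markers. `B[i, j] != 0` means marker `j`
directly causes marker `i`; the diagonal is zero (no self-loops). `A`
is the binary, exogenous activation indicator (set by the
experimenter, constant within a table); `a` is its vector of additive
mean-shift effects — the minimal model for an external stimulus.
`c ~ N(0, diag(v))` is the shift intervention of an inhibitor dosage
(targets and strengths unknown to the analysis), and
`eps ~ N(0, Sigma_eps)` with off-diagonal entries of `Sigma_eps`
encoding latent confounders. Cells are i.i.d. draws of
`x = (I - B)^{-1}(a A + c + eps)`. For cyclic `B` this is the
equilibrium distribution; the generator enforces spectral radius < 1
(bounded resampling with shrinking coefficients, then a hard error).

Values are produced directly on a transformed (arcsinh-like) scale:
the analysis operates on gated, preprocessed intensities, and no
raw-ion-count or zero-inflation model is attempted. Whether real
exports were arcsinh-transformed before testing is unknown; since all
tests used here are invariant to affine rescaling (and the estimators
equivariant), the choice of scale does not drive the conclusions, but
heavy tails or saturation effects of real data are *not* emulated —
passing tests demonstrate correctness of the machinery, not robustness
to cytometry artifacts.

Random models (`make_random_model`) draw coefficient magnitudes
uniformly from [0.3, 0.9] with random sign: the floor of 0.3 keeps
near-faithfulness violations (path cancellations) improbable.
Confounders are added as rank-one terms `s v v^T` on marker pairs
(s in [0.3, 0.6]), which keeps `Sigma_eps` positive semi-definite by
construction. Activator effects have magnitude ~1 (0.8–1.2) and
positive sign by default.

## Study design emulated by the generator

One *plate* is an (inhibitor, replicate) combination carrying a
reference table and one table per activator at each dosage. Defaults
follow the emulated design: 27 inhibitors × 8 dosages, dose zero
carrying no intervention, so the 27 dose-zero plates are i.i.d.
replicates of one distribution — the replication CLCD aggregates over.
Each inhibitor targets 1–2 random markers with intervention variance
ramping linearly in dosage (up to 2.0 by default, the scale of the
unit noise variance). Per-condition cell counts are configurable down
to fewer than 10 (the real data's lower end); tables under 20 cells
are skipped by the analysis, mirroring the minimum-size rule.

Seeding: one master seed; each condition's generator seed derives
deterministically from (master seed, CRC32 of the condition key), so
any table is reproducible in isolation and bundles are byte-identical
across runs.

## Conditional-independence tests and decisions

* marker vs `A`: Welch's unequal-variance t-test (cell counts and
  variances differ between conditions; the equal-variance form has no
  advantage here).
* marker vs marker given a set (possibly including `A` as a 0/1
  regressor): Fisher z-test, `z = atanh(r_partial) sqrt(n - |Z| - 3)`
  against a standard normal. Including the binary indicator as a
  numeric regressor (rather than stratifying and pooling) keeps the
  single-statistic form.
* `A` vs marker given a marker: likelihood-ratio test between nested
  logistic regressions on chi-square(1); a Wald variant is available
  (`method="wald"`). Perfect separation raises an error unless
  explicitly allowed to report p = 0; coefficient magnitudes above 50
  are treated as quasi-separation.

Decisions are three-valued: dependent (p < alpha = 0.001),
independent (p > beta = 0.15), otherwise uncertain. The asymmetric
thresholds make both claims conservative: a dependence claim needs
strong evidence, an independence claim needs a clearly unremarkable
p-value.

## Trio mining (CLCD)

For each (subpopulation, activator, unordered marker pair), the six
tests run on each pooled dose-zero plate. Label semantics are
hierarchical, which resolves an ambiguity between the "uncertain" and
"no pattern" outcomes when different tests disagree:

1. the four shared dependence tests (S~A, T~A, S~T, S~T|A) are
   necessary for a chain in either direction — if any is uncertain the
   trio is `uncertain`; if any is decisively independent the trio is
   `no_pattern`;
2. only when all four reject independence are the two A-conditional
   tests consulted: `chain_S_to_T` needs S ⫫̸ A | T dependent *and*
   T ⫫ A | S independent (mirrored for the reverse); a remaining
   uncertain verdict yields `uncertain`, otherwise `no_pattern`.

Under this rule the two directions are mutually exclusive on a single
plate. The two logistic tests are skipped when step 1 already fixed
the label; `threshold_sensitivity` computes all six p-values once and
re-applies the same rule on a threshold grid, so lazy and exhaustive
paths agree by construction.

A prediction requires the same chain label on >= `min_support`
(default 10) of the replicate plates; if both directions reach support
the pair is dropped and the conflict logged. Because acceptance of the
one required independence happens with probability 1 - beta = 0.85
per plate under the true chain, per-plate hit rates near 0.85 are
expected and the replicate threshold absorbs them comfortably.

Monotonicity: with p-values fixed, shrinking alpha only removes chain
labels, and *raising* beta makes the required independence harder to
accept — prediction counts are nonincreasing in stricter alpha and in
larger beta. ("Looser" thresholds mean larger alpha, smaller beta.)

Ranking counts the (activator, subpopulation) contexts in which a
unique (cause, effect) pair was predicted; ties break
lexicographically for stability.

## Connectivity estimation from environments

Covariance differences are taken against the pooled average (simple
mean over environments), which cancels the invariant `Sigma_eps`;
pairwise differencing is available by flag. Joint diagonalization uses
an FFDIAG-style scheme: per sweep, each index pair's update entries
solve a 2x2 least-squares problem from the linearized objective
(`W <- (I + U) W`, `U` zero-diagonal, diagonal approximation of the
transformed matrices); the update norm is capped at 0.9 and a
backtracking line search accepts only residual-decreasing steps, so
the iteration is monotone and terminates at a local minimum (tolerance
1e-10, max 1000 iterations, identity initialization — fully
deterministic). The residual is scale-normalized: off-diagonal squared
mass as a fraction of total squared mass of the transformed
differences.

The permutation/scale ambiguity is resolved by a linear sum assignment
maximizing `sum log |W[sigma(i), i]|`, then rescaling rows to unit
diagonal; `B_hat = I - W` has an exactly zero diagonal. Per-environment
intervention variances are `diag((I - B_hat) Sigma_x^e (I - B_hat)^T)`
minus the environmentwise minimum (the least-intervened environment is
the baseline), clipped at zero.

With exactly three environments the model is exactly identified: the
attained residual is ~0 *regardless of model violations*, and the
point estimate absorbs all sampling noise (observed single-run
max-norm errors 0.005–0.10 at n = 10,000 for the 3-marker reference
model; the mean over replicate simulations is well below 0.05).
Violation detection therefore needs >= 4 environments, where the
system is overdetermined. One caveat established while testing: a
*single* hidden intervention direction in one environment is absorbable
(it mimics an extra edge) and leaves no residual; detectable
violations are those that conflict with diagonalizing the genuine
differences (hidden interventions alongside true edges, correlated
interventions, multiple hidden directions).

Diagnostics: parametric bootstrap — simulate from the fitted model
(`B_hat`, PSD-projected noise covariance, estimated intervention
variances, observed sample sizes), re-diagonalize, and call the fit
successful when the observed residual is at or below the bootstrap
95th percentile. Stability selection follows the standard bound
`E(V) <= q^2 / ((2 pi_thr - 1) m)` over `m = p (p - 1)` candidate
edges, inverted to the per-refit keep count
`q = floor(sqrt(E(V) (2 pi_thr - 1) p (p - 1)))` (q = 21 for p = 14,
E(V) = 5, pi_thr = 0.75). Refits use half of each environment drawn
without replacement; an edge is stable when kept in more than
`pi_thr * n_sim` refits, and the whole result is discarded as "model
violated" when fewer than 75 of 100 refits diagonalize successfully.

## BGe consistency scoring

The 12 candidate networks are the DAGs over (A, S, T) with A
source-restricted (2 x 2 x 3 choices). Scores are BGe log marginal
likelihoods: Normal-Wishart conjugate prior, node-decomposable, equal
on Markov-equivalent DAGs. Hyperparameters (configurable): prior mean
at the sample mean (the mean-shift term vanishes), alpha_mu = 1,
alpha_w = p + 2 = 5, prior scale matrix the identity. The subset
marginal uses the degrees-of-freedom shift `alpha_w - p + l` for a
subset of size `l`, which is what makes equivalent structures score
identically; the implementation is cross-checked in the tests against
direct numerical integration of the univariate Normal-Gamma integral.

The binary A is scored as a 0/1-coded variable inside the Gaussian
framework. This is a deliberate simplification — no conditional-
Gaussian variant is used — and is acceptable here because only the
*relative ranking* of networks on the same data enters the verdict;
it is the main caveat to keep in mind when interpreting absolute
scores.

A prediction is `consistent` when the strict argmax is exactly
{A→S, S→T}, `conflicted` when the argmax contains T→S, otherwise
`other`; ties within 1e-9 go to `other` (conservative). In
`consistency_analysis`, each prediction is scored on the pooled
dose-zero cells of its (subpopulation, activator) stratum in the
independent bundle (all plates concatenated — they are i.i.d.
replicates at dose zero). The chance baseline redraws the same number
of random ordered pairs per stratum over `n_random = 10` iterations;
the one-tailed test is a one-sample t of the baseline rates against
the observed rate (the original construction is not printed in enough
detail to copy; this is the package's choice).

## Evaluation against ancestry ground truth

The truth is a transitively closed set of directed (cause, effect)
relations, loaded from a two-column TSV or minimal KGML (relation
subtypes activation / inhibition / phosphorylation, direction only —
sign concordance is out of scope). Closure is over a digraph, so
cycles are allowed. Top-k precision is reported along the ranking
together with reversed-pair precision (a diagnostic for systematic
orientation flips, e.g. from feedback over time); significance uses
random same-size prediction sets and a one-sided z-test.

## Problem sizes in the test suite and acceptance script

The suite exercises the estimators at the emulated design (27
replicate plates; 1000 cells per condition for recovery claims; 50
master seeds for the precision/silence rates; 10,000 null replicates
at n = 500 per replicate for test calibration; 20 master seeds x 100
refits at p = 14, n = 600/environment for false-discovery control).
`scripts/acceptance.py` recomputes the same quantities at reduced
replication (10 CLCD seeds, 2000 calibration replicates, 5 stability
seeds) — chosen so a full from-scratch run completes in well under a
minute while leaving the measured rates stable to the first decimal.

## Known limitations

* Gaussian, linear, equilibrium semantics throughout; no
  time-resolved dynamics, saturation, or heavy tails.
* The activation indicator enters the Gaussian BGe score as 0/1.
* Correlated interventions and hidden intervention targets are only
  detectable when the environment set is overdetermined (>= 4
  environments) and the violation conflicts with the genuine
  structure.
* FDR across trios is not controlled; the dual thresholds plus
  replicate support play that role by design.
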
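# Methods

## Models and estimators

The package assumes a *closed* population: the same N individuals are at
risk of registration at every one of the M occasions, with no entry or
exit. Occasions are chronologically ordered, and individuals are
identifiable across occasions.

**Two-occasion margin.** The observable data reduce to (n₁, m, n₂): seen at
occasion 1, seen at both, seen at occasion 2 only. The unobserved cell
x = N − n₁ − n₂ is the estimand.

**Removal estimator (M₀).** Treats the u_i *new* registrations at occasion
i as sequential binomial removals, u_i ~ Binomial(N − Σ_{j<i} u_j, p) with
a single capture probability p. For M = 2 the MLE has the closed form
N̂_R = n₁²/(n₁ − n₂), which requires n₁ > n₂. Its validity in the presence
of occasion dependence hinges on P(captured at 2 | missed at 1) equalling
the unconditional P(captured at 1); `removal_assumption_diagnostic`
evaluates both sides from cell probabilities (default tolerance 1e-9,
since it is applied to exact rational inputs).

**General-M removal MLE.** The likelihood is the multinomial over
(u₁, …, u_M, N − T), T = Σu_i, with cell probabilities
(p, qp, …, q^{M−1}p, q^M), q = 1 − p. Profiling p gives
p̂(N) = T / (M·N − C) with C = Σ_j (M − j)·u_j, and N̂ solves the score
equation log(N/(N − T)) + M·log(1 − p̂(N)) = 0. The root is bracketed
starting from (T, 2T) and the upper end doubled until the score changes
sign, then solved by Brent's method at relative tolerance 1e-12 — there is
no fixed upper cap, so near-boundary data such as u = (1001, 1000) still
resolve (N̂ ≈ 1.002e6). An interior maximum exists iff C > T(M−1)/2, i.e.
removals decline steeply enough; otherwise the fit is flagged invalid
("no interior maximum") rather than raising. For M = 2 the condition
reduces to n₁ > n₂ and the root equals the closed form exactly, which the
test suite exploits as an independent oracle (200 random pairs, relative
1e-6). The degenerate case u₁ = T (everyone removed at once) returns the
boundary MLE N̂ = T, p̂ = 1. N is treated as continuous; the reported
log-likelihood uses log-gamma binomial coefficients.

**Lincoln–Petersen and Chapman (M_t).** N̂_LP = n₁(m + n₂)/m needs m > 0;
Chapman's stabilized form is always defined. Chapman is implemented
exactly as (n₁+1)(m+n₂+1)/(m+1) — *without* the conventional trailing −1 —
to match the comparison study this package reproduces; the difference is
O(1) and invisible at the simulated scales, but it does mean the estimator
returns N+1 rather than N when every individual is captured twice.

**Chao lower bound (M_h).** f̂₀ = ((M−1)/M)·f₁²/(2f₂) from singletons and
doubletons; N̂ = s + f̂₀. When f₂ = 0 with f₁ > 0 the estimate is flagged
invalid rather than returned as infinite; the bias-corrected variant that
handles that case is deliberately out of scope. As M → ∞ the factor
(M−1)/M → 1 and the Poisson-sampling form f₁²/(2f₂) is recovered
(`chao_poisson_limit`).

Invalidity is always signalled by a flag plus reason, never an exception,
so the Monte Carlo runner can tally exclusions instead of aborting.

## Synthetic-data generators

The generators emulate the two study designs whose results the package
reproduces; their defaults *are* those study conditions.

* `simulate_two_occasion(N, cells)`: one multinomial draw of N individuals
  over the four capture cells (equivalent to independent per-individual
  categorical draws). The ten built-in settings (`TABLE1_CELLS`, N = 1000)
  cover independence with equal/unequal marginals, time-varying capture,
  and behavioral response where a first capture raises the odds of a
  second.
* `simulate_mixture_histories(N, mix, M)`: each individual draws a latent
  mixture component (w_j, p_j), then M independent Bernoulli(p_j)
  indicators. All-zero histories are dropped at generation time — they are
  unobservable by definition — with the true N carried only as metadata.
  The component label is latent and not stored (no estimator needs it).
  The two built-in designs (`TABLE2_MIXTURES`, N = 200) are homogeneous
  p = 0.1 and a 50/50 mixture of 0.3 and 0.05, each at M = 5 and 10.

What these generators do *not* emulate: open-population dynamics (entry or
exit between occasions), individual covariates, record-linkage error, or
continuous-time registration. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling models, not
robustness to those real-data complications.

## Monte Carlo runner

Each study setting runs `replications` independent replicates (default
1000, the size of the comparison being reproduced). A master seed spawns
per-replicate `SeedSequence` substreams, so results are reproducible
bit-for-bit and replicates are independent; reported means are matched to
published ones within sampling tolerance, not bit-exactly, since the
original seeds are unknown.

Replicates where an estimator is undefined (removal: n₁ ≤ n₂; LP: m = 0;
Chao: f₂ = 0 with f₁ > 0) are excluded from that estimator's mean and SD
(denominator n_valid − 1) and tallied by reason. Estimates are never
truncated, capped or winsorized: the time-varying setting with p₂ > p₁
(setting 4) legitimately produces a near-degenerate removal denominator
and hence an enormous mean and SD, and is reported as-is.

## Design choices made where the design was open

* **LP unbiasedness checks.** Lincoln–Petersen is unbiased only to first
  order; at sparse overlap (E[m] ≲ 100) its O(1/m) ratio bias —
  approximately (E n₁·E n₂/E m)·(1 − p₁₁)/(N p₁₁) — is several units and
  clearly visible in the simulation means. Tests therefore center LP on
  N plus that analytic term, and Chapman (which removes the leading term)
  on N directly, each within 3 standard errors.
* **Heavy-tailed Chao summaries.** f̂₀ is a ratio with a small random
  denominator: at N = 200, p = 0.1, M = 5 the mean of f̂₀ exceeds its
  median by ~10 (129.8 vs 119.0 in a 40 000-replicate check). Reported
  summaries here are plain means over valid replicates, consistent with
  the runner's definition; users comparing against median-like summaries
  should expect this gap.
* **Occasion ordering.** Occasion columns are exchangeable for LP, Chapman
  and Chao, but the removal estimators read the header order as
  chronology. `removals_of` counts first captures per column in the order
  given.
* **CSV parsing** is done by hand (the format is trivial) so that format
  errors can name the offending line; all-zero rows in input files are
  dropped with a logged warning rather than rejected.

## Numerical notes and degenerate inputs

* Probability vectors must sum to 1 within 1e-12; frequencies and counts
  must be non-negative integers with m ≤ n₁ and s = Σf_y enforced at
  construction.
* Empty register: Chao returns f̂₀ = 0 (valid); Chapman at the empty table
  returns 1, a known boundary artifact of the uncorrected form.
* The removal score equation is evaluated with `log1p` so both terms stay
  accurate when N ≫ T.

## Problem sizes

The studies are desk-scale by design: 10 two-occasion settings × 1000
replicates at N = 1000, and 4 mixture runs × 1000 replicates at N = 200,
M ≤ 10 — the full reproduction takes a few seconds. The test suite uses
the full 1000 replicates for the reproduction checks and 200–500
replicates for behavioral properties where only the direction or ordering
of effects is asserted.

## Known limitations

* No variance or confidence-interval estimators are provided for any of
  the point estimators.
* The bias-corrected Chao estimator and covariate-adjusted extensions are
  out of scope.
* All methods assume closure; over long registration periods that
  assumption, not estimator bias, typically dominates the error.
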
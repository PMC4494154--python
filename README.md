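# recapture

Closed-population capture–recapture estimation from registry data, and a
Monte Carlo comparison of the classical estimators.

## The problem

Registries of hard-to-reach populations (drug users, undiagnosed patients,
unregistered residents) record each identifiable individual at one or more
of *M* chronologically ordered registration occasions. The number of
individuals never registered, *f*₀, is unknown; the goal is the total
population size *N = s + f₀*, where *s* is the number of distinct observed
individuals. This package is for epidemiologists and statisticians who want
to apply the standard estimators to a capture-history table, or to study
their bias and efficiency under controlled violations of their assumptions.

## Estimators

With two occasions, let *n₁* be the registrations at occasion 1, *n₂* the
new registrations at occasion 2, and *m* the individuals seen at both:

* **Removal** (model M₀ — constant capture probability):
  N̂_R = n₁² / (n₁ − n₂), defined for n₁ > n₂. Uses only the counts of new
  registrations per occasion. Valid only when the probability of capture at
  occasion 2 given no capture at occasion 1 equals the unconditional
  occasion-1 capture probability (`removal_assumption_diagnostic`).
  For general *M*, `removal_mle` maximizes the sequential binomial removal
  likelihood u_i ~ Binomial(N − removed so far, p) in (N, p).
* **Lincoln–Petersen** (model M_t — occasion-varying probability):
  N̂_LP = n₁(m + n₂)/m.
* **Chapman**: N̂_Ch = (n₁+1)(m+n₂+1)/(m+1), the small-sample-stabilized
  variant (kept here in the printed form without the trailing −1).
* **Chao lower bound** (robust to model M_h heterogeneity): from the
  singleton and doubleton frequencies f₁, f₂ of an *M*-occasion register,
  f̂₀ = ((M−1)/M) · f₁² / (2 f₂), and N̂ = s + f̂₀. Asymptotically unbiased
  under homogeneity; a lower bound under heterogeneity, with bias that
  shrinks as *M* grows.

Two synthetic-data generators drive the evaluation: a two-occasion system
parameterized by joint cell probabilities (p₁₁, p₁₀, p₀₁, p₀₀) — covering
independence, unequal marginals and behavioral response — and an
*M*-occasion system where each individual's capture count is
Binomial(M, p_j) with p_j from a finite mixture (w_j, p_j).

## Worked example

Simulate a registry of N=1000 with time-varying capture (p₁ = 0.3 at
occasion 1 but only p₂ = 0.1 at occasion 2, independent occasions), then
estimate:

```sh
recapture simulate --n 1000 --cells 0.03,0.27,0.07,0.63 --seed 42 --out demo.csv
recapture estimate --in demo.csv
```

```
estimator	estimate	valid	reason
lincoln_petersen	920.294	true
chapman	905.543	true
removal	391.207	true
chao_unseen	825.184	true
chao_population	1194.18	true
removal_mle	N_hat=391.207	p_hat=0.761745	loglik=-5.38834
```

The true size is 1000. Lincoln–Petersen and Chapman land near it (920 and
906 for this single draw; over 1000 replicates their means are ~1021 and
~999 with SD ~150). The removal estimate collapses to 391 because its
constant-capture assumption is violated — the diagnostic makes this
explicit:

```sh
recapture estimate --cells 0.03,0.27,0.07,0.63
```

```
removal_assumption	P(capture2|no capture1)=0.1	P(capture1)=0.3	satisfied=false
```

The general-*M* removal MLE agrees with the two-occasion closed form
(391.207), as it must.

The full Monte Carlo comparisons are one command each:

```sh
recapture table1 --seed 42 --paper-format --out table1.tsv   # 10 two-occasion settings
recapture table2 --seed 42 --paper-format                    # Chao study, M = 5 and 10
```

```
setting	M	p_components	s_mean	f0_mean	N_mean	SD_f0	excluded
1	5	0.1	82	130	212	51	0
1	10	0.1	130	72	202	19	0
2	5	0.3/0.05	106	40	146	12	0
2	10	0.3/0.05	137	30	167	11	0
```

Setting 1 is homogeneous capture (p = 0.1): Chao's estimate is centered on
N = 200 at M = 10. Setting 2 is a 50/50 mixture of p = 0.3 and p = 0.05:
heterogeneity makes Chao a lower bound — biased low by ≈54 at M = 5 but
only ≈33 at M = 10, showing that a longer observation window shrinks the
bias.

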
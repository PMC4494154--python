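"""Closed-population capture-recapture estimation.

Estimates the size ``N`` of a closed population from ``M`` chronologically
ordered registration occasions.  Individuals are identifiable, so a capture
history (one binary vector per observed individual) records who was seen
when; the ``f0`` individuals never registered are the quantity of interest.

Four estimators are provided, each tied to a classical closed-population
model:

* **removal** (model M0, constant capture probability): uses only the counts
  of *new* registrations per occasion.  For two occasions it has the closed
  form ``N_R = n1^2 / (n1 - n2)``; for general ``M`` the binomial removal
  likelihood is maximized numerically (:func:`removal_mle`).
* **Lincoln-Petersen** (model Mt, occasion-varying probability):
  ``N_LP = n1 (m + n2) / m`` from the overlap ``m`` of two occasions.
* **Chapman**: the small-sample-stabilized variant
  ``N_Ch = (n1 + 1)(m + n2 + 1) / (m + 1)``.
* **Chao lower bound** (robust under model Mh heterogeneity): estimates the
  unseen frequency from singletons and doubletons,
  ``f0_hat = ((M-1)/M) f1^2 / (2 f2)``.

A synthetic-data generator simulates the two study designs used to compare
these estimators: a two-occasion registration system parameterized by the
joint cell probabilities (p11, p10, p01, p00) -- covering independence,
time-varying marginals and behavioral response -- and an M-occasion system
where each individual's capture count is Binomial(M, p_j) with p_j drawn
from a finite mixture.  A Monte Carlo study runner replicates both designs
and summarizes estimator means and standard deviations.

The module is laid out in the order a study runs: domain types, estimators,
removal likelihood, simulators, study runner, file I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import binom as _binom

logger = logging.getLogger("recapture")

#: probability vectors must sum to one within this tolerance
PROB_SUM_TOL = 1e-12

#: default tolerance of the removal-assumption diagnostic (applied to exact
#: rational cell probabilities, hence essentially an equality check)
DIAGNOSTIC_TOL = 1e-9

#: relative tolerance of the removal-MLE root finder
REMOVAL_MLE_RTOL = 1e-12

SeedLike = Union[int, None, SeedSequence, Generator]


def _rng(seed: SeedLike) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoOccasionCounts:
    """Observed margin of the two-occasion 2x2 registration table.

    ``n1``: individuals registered at occasion 1; ``m``: registered at both
    occasions; ``n2``: registered at occasion 2 only.  The fourth cell --
    missed at both occasions -- is the unknown being estimated
    (``x = N - n1 - n2``) and is deliberately not a field.
    """

    n1: int
    m: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("n1", "m", "n2"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.m > self.n1:
            raise ValueError(
                f"m={self.m} exceeds n1={self.n1}: recaptures cannot outnumber "
                "occasion-1 registrations"
            )

    @property
    def observed(self) -> int:
        """Number of distinct observed individuals, ``n1 + n2``."""
        return self.n1 + self.n2


@dataclass(frozen=True)
class FrequencyCounts:
    """Frequencies of frequencies ``f_y`` for an M-occasion register.

    ``f[y]`` is the number of individuals registered exactly ``y`` times
    (``1 <= y <= M``); ``s = sum(f_y)`` is the number of distinct observed
    individuals.  ``f0`` (never registered) is what Chao's estimator
    recovers.
    """

    M: int
    f: Mapping[int, int]
    s: int = None  # type: ignore[assignment]  # derived when omitted

    def __post_init__(self) -> None:
        if int(self.M) != self.M or self.M < 2:
            raise ValueError(f"M must be an integer >= 2, got {self.M!r}")
        clean = {}
        for y, fy in dict(self.f).items():
            if int(y) != y or y < 1 or y > self.M:
                raise ValueError(f"capture count {y!r} outside 1..M={self.M}")
            if int(fy) != fy or fy < 0:
                raise ValueError(f"frequency f_{y}={fy!r} must be a non-negative integer")
            if fy:
                clean[int(y)] = int(fy)
        object.__setattr__(self, "f", clean)
        total = sum(clean.values())
        if self.s is None:
            object.__setattr__(self, "s", total)
        elif self.s != total:
            raise ValueError(f"s={self.s} does not equal sum of frequencies {total}")

    def __getitem__(self, y: int) -> int:
        return self.f.get(y, 0)


@dataclass(frozen=True)
class EstimateResult:
    """A labelled point estimate with an explicit validity flag.

    Estimator preconditions (``n1 > n2``, ``m > 0``, ``f2 > 0``) can fail on
    real or simulated data; invalidity is signalled here rather than by
    exceptions so a Monte Carlo runner can tally exclusions.
    When ``valid`` is False, ``estimate`` carries no meaning.
    """

    estimator_name: str
    estimate: float
    valid: bool = True
    invalid_reason: str = ""


@dataclass(frozen=True)
class RemovalMleResult:
    """Maximum-likelihood fit of the general-M removal model."""

    N_hat: float
    p_hat: float
    log_likelihood: float
    valid: bool = True
    invalid_reason: str = ""


@dataclass(frozen=True)
class CellProbabilities:
    """Joint capture-pattern probabilities for a two-occasion system.

    ``p11``: captured at both occasions, ``p10``: occasion 1 only, ``p01``:
    occasion 2 only, ``p00``: neither.  The marginal capture probabilities
    are ``p1 = p11 + p10`` and ``p2 = p11 + p01``.  Independence means
    ``p11 = p1 * p2``; an odds ratio above one encodes behavioral response.
    """

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        probs = (self.p11, self.p10, self.p01, self.p00)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"cell probabilities must lie in [0, 1], got {probs}")
        if abs(sum(probs) - 1.0) > PROB_SUM_TOL:
            raise ValueError(f"cell probabilities must sum to 1, got {sum(probs)!r}")

    @property
    def p1(self) -> float:
        """Marginal capture probability at occasion 1."""
        return self.p11 + self.p10

    @property
    def p2(self) -> float:
        """Marginal capture probability at occasion 2."""
        return self.p11 + self.p01

    def as_tuple(self) -> tuple:
        return (self.p11, self.p10, self.p01, self.p00)


@dataclass(frozen=True)
class MixtureSpec:
    """Finite mixture of per-occasion capture probabilities.

    ``components`` is a sequence of ``(w_j, p_j)`` pairs: subpopulation j has
    weight ``w_j`` and each of its members is captured independently with
    probability ``p_j`` on every occasion.  A single component models
    homogeneity (M0); two or more model heterogeneity (Mh).
    """

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(p)) for w, p in self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        ws = [w for w, _ in comps]
        ps = [p for _, p in comps]
        if any(w < 0 for w in ws):
            raise ValueError(f"mixture weights must be non-negative, got {ws}")
        if abs(sum(ws) - 1.0) > PROB_SUM_TOL:
            raise ValueError(f"mixture weights must sum to 1, got {sum(ws)!r}")
        if any(p < 0 or p > 1 for p in ps):
            raise ValueError(f"capture probabilities must lie in [0, 1], got {ps}")
        object.__setattr__(self, "components", comps)

    @property
    def J(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    @property
    def probs(self) -> np.ndarray:
        return np.array([p for _, p in self.components])


@dataclass(frozen=True)
class CaptureHistoryMatrix:
    """Binary capture histories of the *observed* individuals.

    One row per observed individual, one column per occasion (chronological
    order).  All-zero rows are unobservable by definition and never stored.
    ``N_true`` is simulation metadata (None for real data).
    """

    M: int
    rows: np.ndarray
    N_true: int | None = None

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.int8).reshape(-1, self.M)
        if rows.size and not np.isin(rows, (0, 1)).all():
            raise ValueError("capture histories must be binary")
        if rows.size and (rows.sum(axis=1) == 0).any():
            raise ValueError("all-zero capture histories must not be stored")
        object.__setattr__(self, "rows", rows)

    @property
    def s(self) -> int:
        """Number of observed individuals (rows)."""
        return self.rows.shape[0]


@dataclass(frozen=True)
class StudySetting:
    """One Monte Carlo scenario: a design, a true N, and a replicate count."""

    label: str
    design: object  # CellProbabilities, or (MixtureSpec, M) for multi-occasion
    N_true: int
    replications: int = 1000

    def __post_init__(self) -> None:
        if self.N_true < 1:
            raise ValueError("N_true must be >= 1")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass(frozen=True)
class ReplicationSummary:
    """Mean/SD of an estimator over the valid Monte Carlo replicates.

    Replicates on which the estimator is undefined are excluded from mean
    and SD (which uses the n_valid - 1 denominator) and tallied by reason.
    """

    estimator_name: str
    mean: float
    sd: float
    n_valid: int
    n_excluded: int
    excluded_reasons: dict = field(default_factory=dict)

    @property
    def replications(self) -> int:
        return self.n_valid + self.n_excluded


# ---------------------------------------------------------------------------
# Closed-form estimators
# ---------------------------------------------------------------------------


def removal_two_occasion(counts: TwoOccasionCounts) -> EstimateResult:
    """Two-occasion removal estimator ``N_R = n1^2 / (n1 - n2)``.

    The closed-form MLE of the removal model for M=2.  Uses only the
    marginal information for occasion 1 (new registrations per occasion);
    defined only when ``n1 > n2``.
    """
    n1, n2 = counts.n1, counts.n2
    if n1 <= n2:
        return EstimateResult("removal", float("nan"), valid=False, invalid_reason="n1<=n2")
    return EstimateResult("removal", n1 * n1 / (n1 - n2))


def lincoln_petersen(counts: TwoOccasionCounts) -> EstimateResult:
    """Lincoln-Petersen estimator ``N_LP = n1 (m + n2) / m``.

    Unbiased under independent occasions with arbitrary (possibly unequal)
    marginal capture probabilities; undefined when no individual is seen on
    both occasions (``m = 0``).
    """
    n1, m, n2 = counts.n1, counts.m, counts.n2
    if m == 0:
        return EstimateResult("lincoln_petersen", float("nan"), valid=False, invalid_reason="m=0")
    return EstimateResult("lincoln_petersen", n1 * (m + n2) / m)


def chapman(counts: TwoOccasionCounts) -> EstimateResult:
    """Chapman estimator ``N_Ch = (n1 + 1)(m + n2 + 1) / (m + 1)``.

    Small-sample-stabilized Lincoln-Petersen variant, defined for all
    inputs including ``m = 0``.

    .. note::
       This is the form without the trailing ``- 1`` of the textbook
       Chapman estimator.  The difference is O(1) and invisible at the
       population scales studied here; the convention is kept so that
       results line up with the comparison study this package reproduces.
    """
    n1, m, n2 = counts.n1, counts.m, counts.n2
    return EstimateResult("chapman", (n1 + 1) * (m + n2 + 1) / (m + 1))


def chao_unseen(freqs: FrequencyCounts) -> EstimateResult:
    """Chao lower-bound estimate of the unseen count,
    ``f0_hat = ((M-1)/M) f1^2 / (2 f2)``.

    Asymptotically unbiased under homogeneous capture; under heterogeneity
    it is a lower bound for ``f0``.  Undefined when there are singletons but
    no doubletons (``f2 = 0, f1 > 0``); the bias-corrected variant that
    handles that case is out of scope here.
    """
    f1, f2 = freqs[1], freqs[2]
    if f2 == 0:
        if f1 == 0:
            return EstimateResult("chao_unseen", 0.0)
        return EstimateResult("chao_unseen", float("nan"), valid=False, invalid_reason="f2=0")
    return EstimateResult("chao_unseen", (freqs.M - 1) / freqs.M * f1 * f1 / (2 * f2))


def chao_population(freqs: FrequencyCounts) -> EstimateResult:
    """Chao population-size estimate ``N_hat = s + f0_hat``."""
    unseen = chao_unseen(freqs)
    if not unseen.valid:
        return EstimateResult("chao_population", float("nan"), valid=False,
                              invalid_reason=unseen.invalid_reason)
    return EstimateResult("chao_population", freqs.s + unseen.estimate)


def chao_poisson_limit(f1: int, f2: int) -> EstimateResult:
    """Chao estimator under Poisson sampling, ``f0_hat = f1^2 / (2 f2)``.

    The limit of the binomial form as the number of occasions grows.
    """
    if f1 < 0 or f2 < 0:
        raise ValueError("frequencies must be non-negative")
    if f2 == 0:
        if f1 == 0:
            return EstimateResult("chao_poisson", 0.0)
        return EstimateResult("chao_poisson", float("nan"), valid=False, invalid_reason="f2=0")
    return EstimateResult("chao_poisson", f1 * f1 / (2 * f2))


def removal_assumption_diagnostic(
    cells: CellProbabilities, tol: float = DIAGNOSTIC_TOL
) -> tuple:
    """Check the validity condition of the two-occasion removal estimator.

    The removal estimator requires that the conditional probability of
    capture at occasion 2 given *no* capture at occasion 1,
    ``p01 / (p01 + p00)``, equal the unconditional occasion-1 capture
    probability ``p1 = p11 + p10``.  Returns
    ``(conditional, unconditional, satisfied)``.
    """
    denom = cells.p01 + cells.p00
    if denom == 0:
        raise ValueError("p01 + p00 = 0: conditional capture probability undefined")
    conditional = cells.p01 / denom
    unconditional = cells.p1
    return conditional, unconditional, abs(conditional - unconditional) <= tol


# ---------------------------------------------------------------------------
# Removal maximum likelihood, general M
# ---------------------------------------------------------------------------
#
# With u_i new registrations at occasion i and c_{i-1} = u_1 + ... + u_{i-1}
# already removed, the model is u_i ~ Binomial(N - c_{i-1}, p) sequentially;
# equivalently (u_1, ..., u_M, N - T) is multinomial with cell probabilities
# (p, qp, ..., q^{M-1} p, q^M), q = 1 - p, T = sum u_i.  Profiling p gives
# p_hat(N) = T / (M N - C) with C = sum_i c_{i-1} = sum_j (M - j) u_j, and
# N_hat solves the score equation log(N / (N - T)) + M log(1 - p_hat(N)) = 0.
# An interior maximum exists iff C > T (M - 1) / 2, i.e. removals are
# front-loaded; for M = 2 this is the familiar n1 > n2 and the root is
# exactly n1^2 / (n1 - n2).


def _removal_loglik(N: float, p: float, u: np.ndarray) -> float:
    T = u.sum()
    M = len(u)
    q = 1.0 - p
    coef = gammaln(N + 1) - gammaln(N - T + 1) - gammaln(u + 1).sum()
    occ = np.arange(M)
    ll = coef + T * np.log(p) + (u * occ).sum() * np.log(q) + (N - T) * M * np.log(q)
    return float(ll)


def removal_mle(removals: Sequence[int]) -> RemovalMleResult:
    """Fit the removal model ``u_i ~ Binomial(N - removed so far, p)`` by ML.

    Parameters
    ----------
    removals
        Per-occasion counts of *new* registrations ``u_1 .. u_M`` in
        chronological order, ``M >= 2``.

    Returns
    -------
    RemovalMleResult
        ``N_hat`` (continuous), ``p_hat`` and the maximized log-likelihood.
        When removals are not front-loaded enough (formally
        ``sum_j (M - j) u_j <= (M - 1) sum_j u_j / 2``) the likelihood has no
        interior maximum and the result is flagged invalid with reason
        ``"no interior maximum"``.

    Notes
    -----
    For ``M = 2`` the fitted ``N_hat`` equals the closed form
    ``n1^2 / (n1 - n2)`` (up to root-finder tolerance); that closed form
    serves as the independent oracle in the test suite.
    """
    u = np.asarray(removals)
    M = len(u)
    if M < 2:
        raise ValueError("need at least two occasions")
    if np.any(u != np.floor(u)) or np.any(u < 0):
        raise ValueError("removal counts must be non-negative integers")
    u = u.astype(np.int64)
    T = int(u.sum())
    if T < 1:
        raise ValueError("at least one individual must be observed")

    C = int((np.arange(M - 1, -1, -1) * u).sum())  # C = sum_j (M - j) u_j, j 1-based

    if u[0] == T:
        # everything removed at occasion 1: boundary MLE N = T, p = 1
        ll = float(gammaln(T + 1) - gammaln(u + 1).sum())
        return RemovalMleResult(float(T), 1.0, ll)

    if 2 * C <= T * (M - 1):
        return RemovalMleResult(
            float("nan"), float("nan"), float("nan"),
            valid=False, invalid_reason="no interior maximum",
        )

    def p_of(N: float) -> float:
        return T / (M * N - C)

    def score(N: float) -> float:
        # log(N / (N - T)) + M log(1 - p_hat(N)), written to stay accurate
        # for N >> T where both terms are tiny
        return -np.log1p(-T / N) + M * np.log1p(-p_of(N))

    lo = T * (1 + 1e-12) + 1e-12
    hi = 2.0 * T
    while score(hi) > 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - condition above guarantees a root
            return RemovalMleResult(float("nan"), float("nan"), float("nan"),
                                    valid=False, invalid_reason="no interior maximum")
    N_hat = float(brentq(score, lo, hi, rtol=REMOVAL_MLE_RTOL, maxiter=200))
    p_hat = float(p_of(N_hat))
    return RemovalMleResult(N_hat, p_hat, _removal_loglik(N_hat, p_hat, u))


# ---------------------------------------------------------------------------
# Synthetic-data generation
# ---------------------------------------------------------------------------


def simulate_two_occasion(N: int, cells: CellProbabilities, seed: SeedLike = None) -> TwoOccasionCounts:
    """Simulate a two-occasion registration system.

    Each of the ``N`` individuals falls independently into one of the four
    capture cells with probabilities ``(p11, p10, p01, p00)`` (equivalently
    one multinomial draw).  Returns the observed margin ``(n1, m, n2)``; the
    ``p00`` cell is unobserved.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = _rng(seed)
    c11, c10, c01, _ = rng.multinomial(N, cells.as_tuple())
    return TwoOccasionCounts(n1=int(c11 + c10), m=int(c11), n2=int(c01))


def two_occasion_matrix(counts: TwoOccasionCounts, N_true: int | None = None) -> CaptureHistoryMatrix:
    """Expand a two-occasion margin into an explicit capture-history matrix."""
    rows = (
        [(1, 1)] * counts.m
        + [(1, 0)] * (counts.n1 - counts.m)
        + [(0, 1)] * counts.n2
    )
    return CaptureHistoryMatrix(2, np.array(rows, dtype=np.int8).reshape(-1, 2), N_true)


def simulate_mixture_histories(
    N: int, mix: MixtureSpec, M: int, seed: SeedLike = None
) -> CaptureHistoryMatrix:
    """Simulate M-occasion capture histories under a finite mixture.

    Each individual first draws a latent subpopulation ``j`` with
    probability ``w_j``, then each of its ``M`` occasion indicators is an
    independent Bernoulli(``p_j``), so its capture count is
    Binomial(``M``, ``p_j``).  Individuals never captured are dropped (they
    are the unobserved ``f0``); ``N_true = N`` is kept as metadata.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if M < 2:
        raise ValueError("M must be >= 2")
    rng = _rng(seed)
    comp = rng.choice(mix.J, size=N, p=mix.weights)
    p_ind = mix.probs[comp]
    hist = (rng.random((N, M)) < p_ind[:, None]).astype(np.int8)
    return CaptureHistoryMatrix(M, hist[hist.sum(axis=1) > 0], N_true=N)


def frequencies_of(matrix: CaptureHistoryMatrix) -> FrequencyCounts:
    """Summarize a capture-history matrix into frequencies of frequencies."""
    y = matrix.rows.sum(axis=1)
    counts = np.bincount(y, minlength=matrix.M + 1) if y.size else np.zeros(matrix.M + 1, int)
    return FrequencyCounts(matrix.M, {i: int(c) for i, c in enumerate(counts) if i >= 1 and c})


def removals_of(matrix: CaptureHistoryMatrix) -> np.ndarray:
    """Per-occasion new-registration counts ``u_1 .. u_M``.

    ``u_i`` counts the individuals whose first capture is at occasion ``i``;
    the occasion (column) order is taken as chronological.
    """
    if matrix.s == 0:
        return np.zeros(matrix.M, dtype=np.int64)
    first = matrix.rows.argmax(axis=1)  # every row has at least one 1
    return np.bincount(first, minlength=matrix.M).astype(np.int64)


def prob_unseen_mixture(mix: MixtureSpec, M: int) -> float:
    """Probability that an individual is never registered,
    ``P(Y = 0) = sum_j w_j (1 - p_j)^M``.

    Strictly decreasing in ``M`` whenever some component has ``p_j > 0``:
    longer observation shrinks the hidden fraction.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    return float(np.sum(mix.weights * (1.0 - mix.probs) ** M))


def binomial_capture_pmf(M: int, p: float, y: int) -> float:
    """P(exactly ``y`` registrations out of ``M``) under homogeneous capture."""
    if not 0 <= y <= M:
        raise ValueError(f"y={y} outside 0..M={M}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(_binom.pmf(y, M, p))


# ---------------------------------------------------------------------------
# Monte Carlo study runner
# ---------------------------------------------------------------------------

#: the ten two-occasion study settings (cells p11, p10, p01, p00), N=1000.
#: 1-2: independence, equal marginals; 3-4: p2 > p1; 5-6: p2 < p1;
#: 7-8: behavioral response with the removal validity condition met;
#: 9-10: behavioral response violating it.
TABLE1_CELLS: dict[int, CellProbabilities] = {
    1: CellProbabilities(0.25, 0.25, 0.25, 0.25),
    2: CellProbabilities(0.09, 0.21, 0.21, 0.49),
    3: CellProbabilities(0.30, 0.20, 0.30, 0.20),
    4: CellProbabilities(0.105, 0.195, 0.245, 0.455),
    5: CellProbabilities(0.15, 0.35, 0.15, 0.35),
    6: CellProbabilities(0.03, 0.27, 0.07, 0.63),
    7: CellProbabilities(0.30, 0.20, 0.25, 0.25),
    8: CellProbabilities(0.375, 0.125, 0.25, 0.25),
    9: CellProbabilities(0.065, 0.235, 0.035, 0.665),
    10: CellProbabilities(0.40, 0.10, 0.10, 0.40),
}

TABLE1_N = 1000

#: the two M-occasion designs, N=200: homogeneous p=0.1, and a 50/50
#: mixture of p=0.3 and p=0.05; each run at M=5 and M=10.
TABLE2_MIXTURES: dict[int, MixtureSpec] = {
    1: MixtureSpec(((1.0, 0.1),)),
    2: MixtureSpec(((0.5, 0.3), (0.5, 0.05))),
}

TABLE2_N = 200
TABLE2_M_VALUES = (5, 10)

DEFAULT_REPLICATIONS = 1000


def _summarize(name: str, estimates: list, reasons: list) -> ReplicationSummary:
    arr = np.array(estimates, dtype=float)
    tally: dict[str, int] = {}
    for r in reasons:
        tally[r] = tally.get(r, 0) + 1
    n_valid = arr.size
    mean = float(arr.mean()) if n_valid else float("nan")
    sd = float(arr.std(ddof=1)) if n_valid > 1 else (0.0 if n_valid == 1 else float("nan"))
    return ReplicationSummary(name, mean, sd, n_valid, len(reasons), tally)


def run_two_occasion_study(setting: StudySetting, seed: SeedLike = None) -> dict:
    """Replicate a two-occasion setting and summarize LP, Chapman, removal.

    Each replicate simulates the registration system from an independent
    RNG substream and applies all three estimators; undefined replicates
    are excluded from that estimator's summary and tallied.
    """
    cells = setting.design
    if not isinstance(cells, CellProbabilities):
        raise TypeError("two-occasion setting requires CellProbabilities design")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    estimates: dict[str, list] = {k: [] for k in ("lincoln_petersen", "chapman", "removal")}
    reasons: dict[str, list] = {k: [] for k in estimates}
    for child in ss.spawn(setting.replications):
        counts = simulate_two_occasion(setting.N_true, cells, default_rng(child))
        for res in (lincoln_petersen(counts), chapman(counts), removal_two_occasion(counts)):
            if res.valid:
                estimates[res.estimator_name].append(res.estimate)
            else:
                reasons[res.estimator_name].append(res.invalid_reason)
    return {k: _summarize(k, estimates[k], reasons[k]) for k in estimates}


@dataclass(frozen=True)
class MultiOccasionSummary:
    """Replicate averages of the Chao analysis of one M-occasion setting."""

    mean_s: float
    mean_f0: float
    mean_N: float
    sd_f0: float
    n_valid: int
    n_excluded: int
    excluded_reasons: dict = field(default_factory=dict)


def run_multi_occasion_study(setting: StudySetting, seed: SeedLike = None) -> MultiOccasionSummary:
    """Replicate an M-occasion mixture setting and summarize Chao estimates.

    Per replicate: simulate capture histories, reduce to frequencies of
    frequencies, apply the Chao unseen and population estimators.  Reports
    the mean observed count ``s``, mean ``f0_hat``, mean ``N_hat`` and the
    SD of ``f0_hat``; replicates with ``f2 = 0 < f1`` are excluded from the
    estimator averages (``s`` is averaged over all replicates).
    """
    try:
        mix, M = setting.design
    except (TypeError, ValueError):
        raise TypeError("multi-occasion setting requires a (MixtureSpec, M) design")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    s_all: list = []
    f0_valid: list = []
    N_valid: list = []
    reasons: list = []
    for child in ss.spawn(setting.replications):
        matrix = simulate_mixture_histories(setting.N_true, mix, M, default_rng(child))
        freqs = frequencies_of(matrix)
        s_all.append(freqs.s)
        unseen = chao_unseen(freqs)
        if unseen.valid:
            f0_valid.append(unseen.estimate)
            N_valid.append(freqs.s + unseen.estimate)
        else:
            reasons.append(unseen.invalid_reason)
    f0 = _summarize("chao_unseen", f0_valid, reasons)
    mean_N = float(np.mean(N_valid)) if N_valid else float("nan")
    return MultiOccasionSummary(
        mean_s=float(np.mean(s_all)),
        mean_f0=f0.mean,
        mean_N=mean_N,
        sd_f0=f0.sd,
        n_valid=f0.n_valid,
        n_excluded=f0.n_excluded,
        excluded_reasons=f0.excluded_reasons,
    )


def reproduce_table1(
    seed: SeedLike = None,
    replications: int = DEFAULT_REPLICATIONS,
    paper_format: bool = False,
) -> pd.DataFrame:
    """Run all ten two-occasion settings and tabulate the three estimators.

    Columns follow the original comparison layout: cell probabilities and
    marginals, then mean and SD for Lincoln-Petersen, Chapman and removal.
    ``paper_format`` rounds estimates to integers.
    """
    ss = SeedSequence(seed) if not isinstance(seed, SeedSequence) else seed
    children = ss.spawn(len(TABLE1_CELLS))
    records = []
    for child, (label, cells) in zip(children, sorted(TABLE1_CELLS.items())):
        setting = StudySetting(str(label), cells, TABLE1_N, replications)
        out = run_two_occasion_study(setting, child)
        lp, ch, rm = out["lincoln_petersen"], out["chapman"], out["removal"]
        records.append({
            "setting": label,
            "p1": cells.p1, "p2": cells.p2,
            "p11": cells.p11, "p10": cells.p10, "p01": cells.p01, "p00": cells.p00,
            "N_LP": lp.mean, "SD_LP": lp.sd,
            "N_Ch": ch.mean, "SD_Ch": ch.sd,
            "N_R": rm.mean, "SD_R": rm.sd,
            "excluded_LP": lp.n_excluded, "excluded_Ch": ch.n_excluded,
            "excluded_R": rm.n_excluded,
        })
    df = pd.DataFrame.from_records(records)
    if paper_format:
        for col in ("N_LP", "SD_LP", "N_Ch", "SD_Ch", "N_R", "SD_R"):
            df[col] = df[col].round().astype("Int64")
    return df


def reproduce_table2(
    seed: SeedLike = None,
    replications: int = DEFAULT_REPLICATIONS,
    paper_format: bool = False,
) -> pd.DataFrame:
    """Run the Chao study: both mixture settings at M=5 and M=10.

    One row per (setting, M) with mean observed count ``s``, mean unseen
    estimate ``f0``, mean population estimate ``N`` and SD of ``f0``.
    """
    ss = SeedSequence(seed) if not isinstance(seed, SeedSequence) else seed
    children = iter(ss.spawn(len(TABLE2_MIXTURES) * len(TABLE2_M_VALUES)))
    records = []
    for label, mix in sorted(TABLE2_MIXTURES.items()):
        for M in TABLE2_M_VALUES:
            setting = StudySetting(f"{label}-M{M}", (mix, M), TABLE2_N, replications)
            out = run_multi_occasion_study(setting, next(children))
            records.append({
                "setting": label, "M": M,
                "p_components": "/".join(f"{p:g}" for p in mix.probs),
                "s_mean": out.mean_s, "f0_mean": out.mean_f0,
                "N_mean": out.mean_N, "SD_f0": out.sd_f0,
                "excluded": out.n_excluded,
            })
    df = pd.DataFrame.from_records(records)
    if paper_format:
        for col in ("s_mean", "f0_mean", "N_mean", "SD_f0"):
            df[col] = df[col].round().astype("Int64")
    return df


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


class CaptureHistoryFormatError(ValueError):
    """Malformed capture-history CSV (names the offending line)."""


def write_capture_histories(matrix: CaptureHistoryMatrix, path) -> None:
    """Write a capture-history CSV: header ``occ_1..occ_M``, one 0/1 row per
    observed individual, plus a ``# N_true=`` comment for synthetic data."""
    with open(path, "w", encoding="utf-8") as fh:
        if matrix.N_true is not None:
            fh.write(f"# N_true={matrix.N_true}\n")
        fh.write(",".join(f"occ_{i + 1}" for i in range(matrix.M)) + "\n")
        for row in matrix.rows:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def read_capture_histories(path) -> CaptureHistoryMatrix:
    """Read a capture-history CSV.

    The header must be ``occ_1,...,occ_M``; every cell must be 0 or 1.
    All-zero rows are unobservable records: they are dropped with a logged
    warning rather than rejected.  A leading ``# N_true=<int>`` comment (as
    written for synthetic data) is picked up as metadata.
    """
    N_true = None
    header = None
    rows = []
    dropped = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("N_true="):
                    N_true = int(body.split("=", 1)[1])
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                expected = [f"occ_{i + 1}" for i in range(len(cells))]
                if cells != expected or len(cells) < 1:
                    raise CaptureHistoryFormatError(
                        f"line {lineno}: header must be occ_1..occ_M, got {line!r}"
                    )
                header = cells
                continue
            if len(cells) != len(header):
                raise CaptureHistoryFormatError(
                    f"line {lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            for c in cells:
                if c not in ("0", "1"):
                    raise CaptureHistoryFormatError(
                        f"line {lineno}: non-binary cell value {c!r}"
                    )
            vec = [int(c) for c in cells]
            if sum(vec) == 0:
                dropped += 1
                continue
            rows.append(vec)
    if header is None:
        raise CaptureHistoryFormatError("line 1: missing occ_1..occ_M header")
    if dropped:
        logger.warning("dropped %d all-zero capture histories (unobservable records)", dropped)
    M = len(header)
    data = np.array(rows, dtype=np.int8).reshape(-1, M)
    return CaptureHistoryMatrix(M, data, N_true)


def summarize_two_occasion(matrix: CaptureHistoryMatrix) -> TwoOccasionCounts:
    """Collapse a two-occasion history matrix onto its 2x2 margin (n1, m, n2)."""
    if matrix.M != 2:
        raise ValueError(f"two-occasion summary requires M=2, got M={matrix.M}")
    occ1 = matrix.rows[:, 0] == 1 if matrix.s else np.zeros(0, bool)
    occ2 = matrix.rows[:, 1] == 1 if matrix.s else np.zeros(0, bool)
    return TwoOccasionCounts(
        n1=int(occ1.sum()), m=int((occ1 & occ2).sum()), n2=int((~occ1 & occ2).sum())
    )
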
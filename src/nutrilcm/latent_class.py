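"""Bayesian latent class model for K imperfect binary tests, no gold standard.

The model (Hui-Walter type, single population) treats true disease status
as a latent Bernoulli(pi) class. Given the class, the K test results are
independent with per-test sensitivity Se_k and specificity Sp_k, so the
probability of observing result pattern ``y`` in {0,1}^K is

    P(y) = pi * prod_k Se_k^{y_k} (1-Se_k)^{1-y_k}
         + (1-pi) * prod_k (1-Sp_k)^{y_k} Sp_k^{1-y_k}.

With K = 3 tests in one population the 2^3 - 1 = 7 free cell probabilities
exactly match the 7 parameters (pi, Se_1..3, Sp_1..3): the model is
just-identified and flat priors suffice. With K = 2 it is not identifiable
without informative priors, and fitting such a table emits a warning.

Fitting is by data-augmentation Gibbs sampling: all full conditionals are
conjugate (Binomial latent diseased counts per pattern; Beta updates for
pi and every Se/Sp), so one sweep costs O(2^K) and a full cohort fit runs
in seconds. The two-class mirror non-identifiability (pi -> 1-pi,
Se_k <-> 1-Sp_k leaves every P(y) unchanged) is resolved post hoc by
:func:`enforce_orientation`, which maps draws onto the mode satisfying
sum_k (Se_k + Sp_k) > K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .criteria import TEST_ORDER, ValidationError

__all__ = [
    "CrossClassTable",
    "LCMParams",
    "LCMPriors",
    "PosteriorDraws",
    "build_cross_class",
    "cell_probability",
    "gibbs_fit",
    "summarize",
    "gelman_rubin",
    "enforce_orientation",
    "param_names",
]

MAX_K = 12


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value}")


def param_names(k_tests: int, labels: Optional[Sequence[str]] = None) -> list[str]:
    """Canonical parameter order: prevalence, then Se per test, then Sp per test."""
    if labels is None:
        labels = list(TEST_ORDER) if k_tests == 3 else [f"T{i+1}" for i in range(k_tests)]
    return ["prevalence"] + [f"se_{t}" for t in labels] + [f"sp_{t}" for t in labels]


def _patterns(k: int) -> np.ndarray:
    """(2^K, K) matrix of result bits; pattern index = sum_k y_k 2^k."""
    idx = np.arange(2**k)
    return ((idx[:, None] >> np.arange(k)[None, :]) & 1).astype(float)


@dataclass
class CrossClassTable:
    """Counts of the 2^K test-result patterns across a cohort.

    Pattern index convention: ``sum_k y_k * 2^k`` with the fixed test order
    (PG-SGA, ESPEN, GLIM) for K=3, so pattern 0 is all-negative and
    pattern 2^K - 1 all-positive.
    """

    k_tests: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2**self.k_tests,):
            raise ValidationError(
                f"counts must have length 2^{self.k_tests}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0) or not np.all(self.counts == np.round(self.counts)):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        if self.n == 0:
            raise ValidationError("empty cohort: total count is zero")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class LCMParams:
    """Prevalence plus per-test sensitivity and specificity."""

    prevalence: float
    se: np.ndarray
    sp: np.ndarray

    def __post_init__(self) -> None:
        self.se = np.asarray(self.se, dtype=float)
        self.sp = np.asarray(self.sp, dtype=float)
        _check_prob("prevalence", self.prevalence)
        for name, vec in (("se", self.se), ("sp", self.sp)):
            for i, v in enumerate(vec):
                _check_prob(f"{name}[{i}]", v)
        if self.se.shape != self.sp.shape:
            raise ValidationError("se and sp must have the same length")

    @property
    def k_tests(self) -> int:
        return len(self.se)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.prevalence], self.se, self.sp])


@dataclass
class LCMPriors:
    """Independent Beta(a, b) priors for prevalence and each Se_k, Sp_k.

    Defaults are flat Beta(1, 1) everywhere; informative hyperparameters can
    be supplied per parameter (shape (K, 2) arrays for se/sp).
    """

    prevalence: tuple[float, float] = (1.0, 1.0)
    se: Optional[np.ndarray] = None  # (K, 2)
    sp: Optional[np.ndarray] = None  # (K, 2)

    def resolved(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pi_ab = np.asarray(self.prevalence, dtype=float)
        se_ab = np.ones((k, 2)) if self.se is None else np.asarray(self.se, dtype=float)
        sp_ab = np.ones((k, 2)) if self.sp is None else np.asarray(self.sp, dtype=float)
        for name, arr in (("prevalence", pi_ab), ("se", se_ab), ("sp", sp_ab)):
            if np.any(arr <= 0):
                raise ValidationError(f"{name} Beta hyperparameters must be > 0")
        if se_ab.shape != (k, 2) or sp_ab.shape != (k, 2):
            raise ValidationError(f"se/sp hyperparameters must have shape ({k}, 2)")
        return pi_ab, se_ab, sp_ab


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws, indexed (chain, iteration, parameter).

    Parameter order is prevalence, Se_1..K, Sp_1..K (see ``param_names``).
    """

    draws: np.ndarray  # (chains, iters, 1 + 2K)
    k_tests: int
    burn_in: int
    seeds: tuple[int, ...]
    names: list[str] = field(default_factory=list)
    orientation_flipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != 1 + 2 * self.k_tests:
            raise ValidationError("draws must be (chains, iterations, 1 + 2K)")
        if not self.names:
            self.names = param_names(self.k_tests)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])


def build_cross_class(panels: Iterable[Sequence[int]], k_tests: int = 3) -> CrossClassTable:
    """Tally per-patient K-tuples of binary test results into pattern counts."""
    counts = np.zeros(2**k_tests, dtype=np.int64)
    weights = 2 ** np.arange(k_tests)
    n = 0
    for i, panel in enumerate(panels):
        arr = np.asarray(panel)
        if arr.shape != (k_tests,) or not np.all(np.isin(arr, (0, 1))):
            raise ValidationError(f"patient {i}: panel must be {k_tests} binary results, got {panel}")
        counts[int(arr @ weights)] += 1
        n += 1
    if n == 0:
        raise ValidationError("empty cohort")
    return CrossClassTable(k_tests, counts)


def _class_pattern_probs(se: np.ndarray, sp: np.ndarray, Y: np.ndarray):
    """Per-pattern probabilities within each latent class (diseased, healthy)."""
    a = np.prod(np.where(Y == 1, se, 1 - se), axis=1)  # P(y | diseased)
    b = np.prod(np.where(Y == 1, 1 - sp, sp), axis=1)  # P(y | healthy)
    return a, b


def cell_probability(params: LCMParams, pattern: int | Sequence[int]) -> float:
    """Marginal probability of one observed test-result pattern.

    ``pattern`` may be an integer index (bit k = test k's result) or an
    explicit K-tuple of 0/1. Summing over all 2^K patterns gives 1.
    """
    k = params.k_tests
    if isinstance(pattern, (int, np.integer)):
        if not 0 <= pattern < 2**k:
            raise ValidationError(f"pattern index must be in [0, {2**k}), got {pattern}")
        y = ((int(pattern) >> np.arange(k)) & 1).astype(float)
    else:
        y = np.asarray(pattern, dtype=float)
        if y.shape != (k,) or not np.all(np.isin(y, (0.0, 1.0))):
            raise ValidationError(f"pattern must be a {k}-tuple of 0/1")
    a, b = _class_pattern_probs(params.se, params.sp, y[None, :])
    return float(params.prevalence * a[0] + (1 - params.prevalence) * b[0])


def all_cell_probabilities(params: LCMParams) -> np.ndarray:
    """Vector of P(pattern) over all 2^K patterns, in index order."""
    Y = _patterns(params.k_tests)
    a, b = _class_pattern_probs(params.se, params.sp, Y)
    return params.prevalence * a + (1 - params.prevalence) * b


def gibbs_fit(
    table: CrossClassTable,
    priors: Optional[LCMPriors] = None,
    chains: int = 3,
    iterations: int = 20_000,
    burn_in: int = 5_000,
    seeds: Optional[Sequence[int]] = None,
    labels: Optional[Sequence[str]] = None,
) -> PosteriorDraws:
    """Fit the latent class model by data-augmentation Gibbs sampling.

    Each sweep: (i) for every pattern y with n_y patients, draw the latent
    diseased count z_y ~ Binomial(n_y, pi a_y / (pi a_y + (1-pi) b_y)) where
    a_y, b_y are the class-conditional pattern probabilities; (ii)
    pi ~ Beta(a_pi + sum z, b_pi + N - sum z); (iii) Se_k ~ Beta over the
    diseased split by test k's result; (iv) Sp_k ~ Beta over the healthy
    split. Initial values are drawn from the priors per chain
    (overdispersed starts). Deterministic given ``seeds`` (one per chain).
    """
    if priors is None:
        priors = LCMPriors()
    k = table.k_tests
    if k > MAX_K:
        raise ValidationError(
            f"K={k} tests means 2^{k} patterns; refusing K > {MAX_K} (table blow-up)"
        )
    if iterations <= burn_in:
        raise ValidationError(f"iterations ({iterations}) must exceed burn_in ({burn_in})")
    if burn_in < 0:
        raise ValidationError("burn_in must be >= 0")
    if seeds is None:
        seeds = tuple(range(1, chains + 1))
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) != chains:
        raise ValidationError(f"need one seed per chain: {chains} chains, {len(seeds)} seeds")
    pi_ab, se_ab, sp_ab = priors.resolved(k)
    informative = np.any(se_ab != 1) or np.any(sp_ab != 1) or np.any(pi_ab != 1)
    if k < 3 and not informative:
        warnings.warn(
            "single-population LCM with K < 3 tests is not identifiable "
            "under flat priors; supply informative priors",
            UserWarning,
            stacklevel=2,
        )

    Y = _patterns(k)
    Yc = 1.0 - Y
    counts = table.counts.astype(np.int64)
    N = table.n
    kept = iterations - burn_in
    out = np.empty((chains, kept, 1 + 2 * k))

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        pi = rng.beta(*pi_ab)
        se = rng.beta(se_ab[:, 0], se_ab[:, 1])
        sp = rng.beta(sp_ab[:, 0], sp_ab[:, 1])
        store = out[c]
        for it in range(iterations):
            a, b = _class_pattern_probs(se, sp, Y)
            num = pi * a
            denom = num + (1 - pi) * b
            with np.errstate(invalid="ignore"):
                p_dis = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
            z = rng.binomial(counts, p_dis)
            nz = counts - z
            z_tot = z.sum()
            pi = rng.beta(pi_ab[0] + z_tot, pi_ab[1] + N - z_tot)
            se = rng.beta(se_ab[:, 0] + Y.T @ z, se_ab[:, 1] + Yc.T @ z)
            sp = rng.beta(sp_ab[:, 0] + Yc.T @ nz, sp_ab[:, 1] + Y.T @ nz)
            if it >= burn_in:
                j = it - burn_in
                store[j, 0] = pi
                store[j, 1 : 1 + k] = se
                store[j, 1 + k :] = sp

    return PosteriorDraws(out, k, burn_in, seeds, param_names(k, labels))


def enforce_orientation(draws: PosteriorDraws) -> PosteriorDraws:
    """Resolve the two-class mirror non-identifiability on the draws.

    Every draw with sum_k (Se_k + Sp_k) <= K is mapped by the relabeling
    pi -> 1 - pi, Se_k <-> 1 - Sp_k, which leaves every cell probability
    unchanged but moves the draw onto the mode where the tests are better
    than chance. Handling it per draw also repairs chains that switched
    labels mid-run. The fraction of draws flipped is recorded.
    """
    k = draws.k_tests
    d = draws.draws.copy()
    score = d[:, :, 1 : 1 + k].sum(axis=2) + d[:, :, 1 + k :].sum(axis=2)
    flip = score <= k
    frac = float(flip.mean())
    if frac > 0:
        se = d[:, :, 1 : 1 + k].copy()
        sp = d[:, :, 1 + k :].copy()
        d[:, :, 0] = np.where(flip, 1 - d[:, :, 0], d[:, :, 0])
        d[:, :, 1 : 1 + k] = np.where(flip[:, :, None], 1 - sp, se)
        d[:, :, 1 + k :] = np.where(flip[:, :, None], 1 - se, sp)
    return PosteriorDraws(
        d, k, draws.burn_in, draws.seeds, list(draws.names), orientation_flipped_fraction=frac
    )


def summarize(draws: PosteriorDraws, min_draws: int = 100) -> dict[str, dict[str, float]]:
    """Pooled-chain posterior mean, median and equal-tailed 95% CrI.

    The credible interval is the 2.5th and 97.5th percentile of the pooled
    draws (numpy's ``linear`` interpolation rule).
    """
    pooled = draws.pooled()
    if pooled.shape[0] < min_draws:
        raise ValidationError(
            f"need at least {min_draws} retained draws, have {pooled.shape[0]}"
        )
    q = np.percentile(pooled, [2.5, 50.0, 97.5], axis=0)
    out = {}
    for j, name in enumerate(draws.names):
        out[name] = {
            "mean": float(pooled[:, j].mean()),
            "median": float(q[1, j]),
            "cri_lower": float(q[0, j]),
            "cri_upper": float(q[2, j]),
        }
    return out


def gelman_rubin(draws: PosteriorDraws) -> dict[str, dict[str, float]]:
    """Gelman-Rubin potential scale reduction factor per parameter.

    With m chains of length n, W is the mean within-chain variance, B is
    n times the variance of the chain means, and

        R-hat = sqrt(((n - 1)/n * W + B/n) / W).

    Identical chains give R-hat = sqrt((n-1)/n) < 1; chains stuck at
    distinct constants give W = 0, reported as R-hat = inf with a warning.
    Also reports an effective sample size from the pooled autocorrelation
    (Geyer initial monotone truncation).
    """
    if draws.n_chains < 2:
        raise ValidationError("diagnostics need >= 2 chains")
    n = draws.n_iterations
    if n < 10:
        raise ValidationError("diagnostics need chains of length >= 10")
    d = draws.draws
    report: dict[str, dict[str, float]] = {}
    for j, name in enumerate(draws.names):
        x = d[:, :, j]
        chain_means = x.mean(axis=1)
        W = float(x.var(axis=1, ddof=1).mean())
        B = float(n * chain_means.var(ddof=1))
        if np.all(np.ptp(x, axis=1) == 0):  # every chain stuck at a constant
            W = 0.0
        if W <= 0:
            if B > 0:
                warnings.warn(
                    f"{name}: zero within-chain variance with separated chains; R-hat undefined",
                    UserWarning,
                    stacklevel=2,
                )
                rhat = float("inf")
            else:
                rhat = 1.0  # all chains constant and equal
            ess = float(draws.n_chains * n) if B == 0 else 0.0
        else:
            var_plus = (n - 1) / n * W + B / n
            rhat = float(np.sqrt(var_plus / W))
            ess = _effective_sample_size(x)
        report[name] = {"rhat": rhat, "W": W, "B": B, "ess": ess}
    return report


def _effective_sample_size(x: np.ndarray) -> float:
    """ESS across chains: m*n / (1 + 2 sum rho_t), Geyer-truncated."""
    m, n = x.shape
    centered = x - x.mean(axis=1, keepdims=True)
    max_lag = min(n - 1, 1000)
    # mean-across-chains autocorrelation via FFT per chain
    fsize = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(centered, fsize, axis=1)
    acov = np.fft.irfft(f * np.conj(f), fsize, axis=1)[:, : max_lag + 1].real / n
    denom = acov[:, 0].mean()
    if denom <= 0:
        return float(m * n)
    rho = acov.mean(axis=0) / denom
    # sum paired autocorrelations while positive and decreasing
    s = 0.0
    prev = np.inf
    for t in range(1, max_lag, 2):
        pair = rho[t] + rho[t + 1] if t + 1 <= max_lag else rho[t]
        if pair < 0:
            break
        pair = min(pair, prev)
        s += pair
        prev = pair
    ess = m * n / (1 + 2 * s)
    return float(min(ess, m * n))


def converged(report: dict[str, dict[str, float]], threshold: float = 1.1) -> bool:
    """Automated convergence verdict: every parameter's R-hat below threshold."""
    return all(p["rhat"] < threshold for p in report.values())
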
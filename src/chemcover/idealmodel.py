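"""Closed-form mathematics of the ideal generative model.

The *ideal model* is an abstract generator that emits molecules uniformly at
random from a finite reference chemical space of ``n`` molecules, each with
probability ``p = 1/n``, and emits nothing outside it.  Because sampling with
replacement from a uniform distribution is the classical coupon-collector
problem, the ideal model yields closed forms for

* the expected number of draws needed to see every molecule at least once,
  ``E[T_u] = n * H_n`` (``H_n`` the n-th harmonic number),
* the expected fraction of the space covered by ``k`` draws,
  ``1 - (1 - 1/n)**k``,
* the negative-log-likelihood statistics of a uniform sampler
  (mean ``ln n``, variance ``0``), and
* the binomial null for how many of ``M`` independently trained models
  generate a given molecule.

These quantities are upper bounds for any trained generative model on the
same space: a model that is non-uniform or incomplete covers strictly less in
expectation.  Monte-Carlo simulators are provided as independent checks of
the closed forms at small ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EULER_GAMMA",
    "IdealModel",
    "CoverageBound",
    "FrequencyNull",
    "expected_draws_full_collection",
    "expected_fraction",
    "uniform_nll_stats",
    "ideal_frequency_null",
    "nonuniform_penalty_check",
    "simulate_coupon_collection",
    "simulate_coverage",
]

#: Euler–Mascheroni constant, used in the asymptotic harmonic number.
EULER_GAMMA = 0.5772156649015329

#: Above this size the harmonic sum is replaced by its asymptotic expansion.
_EXACT_HARMONIC_LIMIT = 10**6

#: Relative tolerance for uniform-bound checks on coverage fractions.
BOUND_RTOL = 1e-9


@dataclass(frozen=True)
class IdealModel:
    """Uniform sampler over a space of ``n`` molecules (``p = 1/n``)."""

    n: int

    def __post_init__(self) -> None:
        if self.n <= 1:
            raise ValueError(f"ideal model needs n > 1, got n={self.n}")

    @property
    def p(self) -> float:
        return 1.0 / self.n

    def expected_draws_full_collection(self) -> float:
        return expected_draws_full_collection(self.n)

    def expected_fraction(self, k: int) -> float:
        return expected_fraction(self.n, k)

    def uniform_nll_stats(self) -> tuple[float, float]:
        return uniform_nll_stats(self.n)


@dataclass(frozen=True)
class CoverageBound:
    """Expected coverage of a uniform sampler at sample size ``k``."""

    n: int
    k: int
    fraction: float
    expected_full_collection_draws: float


@dataclass(frozen=True)
class FrequencyNull:
    """Binomial null ``Binomial(M, p_cov)`` for multi-model molecule frequency.

    ``pmf[f]`` is the probability that a molecule is generated by exactly
    ``f`` of ``M`` independent ideal models, each drawing ``k`` samples from a
    uniform space of size ``n``.
    """

    num_models: int
    p_cov: float
    pmf: np.ndarray = field(repr=False)
    mean: float
    modes: tuple[int, ...]

    @property
    def mode(self) -> int:
        """Smallest mode (a tie yields two adjacent modes; see ``modes``)."""
        return self.modes[0]


def _harmonic(n: int) -> float:
    """H_n, exact summation up to 10^6 and asymptotic above."""
    if n <= _EXACT_HARMONIC_LIMIT:
        # summing ascending keeps the small terms from being absorbed
        return float(np.sum(1.0 / np.arange(n, 0, -1, dtype=np.float64)))
    return float(np.log(n) + EULER_GAMMA + 0.5 / n)


def expected_draws_full_collection(n: int) -> float:
    """Expected draws with replacement to collect all ``n`` coupons.

    ``E[T_u] = n * H_n ~= n (ln n + gamma) + 1/2``.  The harmonic sum is
    exact for ``n <= 10^6``; beyond that the asymptotic form is used (the two
    agree to well under one part in 10^6 at the crossover).
    """
    if n <= 1:
        raise ValueError(f"coupon collection needs n > 1, got n={n}")
    if n <= _EXACT_HARMONIC_LIMIT:
        return n * _harmonic(n)
    return float(n * (np.log(n) + EULER_GAMMA) + 0.5)


def expected_fraction(n: int, k: int) -> float:
    """Expected fraction of ``n`` uniform outcomes covered by ``k`` draws.

    Computed stably in log space as ``-expm1(k * log1p(-1/n))``; literal
    exponentiation of ``1 - 1e-9`` would lose all precision at billion-scale
    ``n``.
    """
    if n <= 2:
        raise ValueError(f"expected_fraction needs n > 2, got n={n}")
    if k <= 1:
        raise ValueError(f"expected_fraction needs k > 1, got k={k}")
    return float(-np.expm1(k * np.log1p(-1.0 / n)))


def coverage_bound(n: int, k: int) -> CoverageBound:
    """Bundle the coverage fraction at ``k`` with the full-collection cost."""
    return CoverageBound(
        n=n,
        k=k,
        fraction=expected_fraction(n, k),
        expected_full_collection_draws=expected_draws_full_collection(n),
    )


def uniform_nll_stats(n: int) -> tuple[float, float]:
    """(mean, variance) of per-molecule NLL under the uniform sampler.

    Every molecule has probability ``1/n``, so the NLL distribution is the
    point mass at ``ln n``: mean ``ln n``, variance ``0``.
    """
    if n <= 1:
        raise ValueError(f"uniform NLL stats need n > 1, got n={n}")
    return float(np.log(n)), 0.0


def ideal_frequency_null(num_models: int, n: int, k: int) -> FrequencyNull:
    """Null distribution of per-molecule frequency across ``num_models`` models.

    Each ideal model covers a molecule independently with probability
    ``p_cov = expected_fraction(n, k)``, so the number of models generating a
    fixed molecule is ``Binomial(num_models, p_cov)``.  The mode is
    ``floor((num_models + 1) * p_cov)``; when that quantity is an integer the
    distribution is bimodal and both modes are reported.
    """
    if num_models < 1:
        raise ValueError(f"need num_models >= 1, got {num_models}")
    p_cov = expected_fraction(n, k)
    f = np.arange(num_models + 1)
    pmf = stats.binom.pmf(f, num_models, p_cov)
    m = (num_models + 1) * p_cov
    floor_m = int(np.floor(m))
    if floor_m == m and 0 < floor_m <= num_models:
        modes: tuple[int, ...] = (floor_m - 1, floor_m)
    else:
        modes = (min(floor_m, num_models),)
    return FrequencyNull(
        num_models=num_models,
        p_cov=p_cov,
        pmf=pmf,
        mean=float(num_models * p_cov),
        modes=modes,
    )


def nonuniform_penalty_check(
    probabilities: np.ndarray, k: int, *, rtol: float = BOUND_RTOL
) -> tuple[float, bool]:
    """Expected coverage of a (possibly non-uniform) sampler, vs. the uniform bound.

    For outcome probabilities ``p_i`` the expected covered fraction after
    ``k`` draws is ``sum_i (1 - (1 - p_i)^k) / n``.  By Jensen's inequality
    the uniform distribution maximizes it, so ``bound_ok`` reports whether the
    value stays at or below ``expected_fraction(n, k)`` (within ``rtol``).
    Any ``p_i = 0`` makes full collection impossible (infinite expected
    draws); the coverage fraction formula remains finite and valid.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, rtol=1e-9, atol=1e-12):
        raise ValueError(f"probabilities must sum to 1, got {total!r}")
    n = p.size
    with np.errstate(divide="ignore"):
        miss = np.where(p < 1.0, k * np.log1p(-p), -np.inf)
    fraction = float(np.mean(-np.expm1(miss)))
    uniform = expected_fraction(n, k)
    bound_ok = fraction <= uniform * (1.0 + rtol)
    return fraction, bound_ok


def simulate_coupon_collection(
    n: int, trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws-to-completion, an independent check of ``n * H_n``.

    Draws uniform integers in blocks and records, per trial, the first draw
    index at which all ``n`` outcomes have been seen.
    """
    if n <= 1:
        raise ValueError("need n > 1")
    # Block long enough that nearly all trials finish in one pass.
    block = int(expected_draws_full_collection(n) * 4) + 8 * n
    chunk = max(1, min(trials, int(2e7 // block) or 1))
    out = np.empty(trials, dtype=np.int64)
    done = 0
    while done < trials:
        m = min(chunk, trials - done)
        draws = rng.integers(0, n, size=(m, block))
        # seen[t, j, c]: coupon c observed within the first j+1 draws of trial t
        onehot = draws[:, :, None] == np.arange(n)[None, None, :]
        seen = np.maximum.accumulate(onehot, axis=1)
        complete = seen.all(axis=2)
        first = complete.argmax(axis=1)
        for i in range(m):
            if complete[i, first[i]]:
                out[done + i] = first[i] + 1
            else:  # astronomically rare: keep drawing one at a time
                seen_set = set(draws[i].tolist())
                t = block
                while len(seen_set) < n:
                    seen_set.add(int(rng.integers(0, n)))
                    t += 1
                out[done + i] = t
        done += m
    return out


def simulate_coverage(
    n: int, k: int, trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo covered fraction of ``k`` uniform draws, per trial."""
    if n <= 1:
        raise ValueError("need n > 1")
    out = np.empty(trials, dtype=np.float64)
    for t in range(trials):
        draws = rng.integers(0, n, size=k)
        out[t] = np.count_nonzero(np.bincount(draws, minlength=n)) / n
    return out
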
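"""Incremental reward statistics and confidence intervals on reward means.

Every cell of a reward table is summarised by three sufficient statistics
(visit count, reward sum, squared-reward sum) from which the sample mean
(Q-value), the sample standard deviation, and three different confidence
intervals on the true mean are derived:

* ``student_t`` — the classical Student-t interval; valid for Gaussian
  rewards or moderately large samples, and by far the tightest in practice.
* ``chebyshev`` — a distribution-free interval obtained from Chebyshev's
  inequality with the worst-case variance ``(hi - lo)^2 / 4`` of a
  distribution supported on ``[lo, hi]``; extremely conservative.
* ``bernstein`` — an empirical-Bernstein ("variance-aware") interval that
  uses the sample standard deviation and is much tighter than Chebyshev
  when the reward variance is small.

With fewer than two samples (one, for Chebyshev, which needs no variance
estimate) nothing is known about the mean, and the interval is unbounded on
both sides.  Unbounded intervals implement optimism in the face of
uncertainty: an untried action carries an infinite upper bound and is
therefore explored before any tried action is repeated.

Scalar operations act on :class:`SufficientStats`; the ``*_rows`` functions
are vectorised equivalents operating on aligned numpy arrays (one entry per
action of a table row) and are what the simulation loop uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "RewardRange",
    "SufficientStats",
    "ConfidenceInterval",
    "RewardRangeError",
    "UndefinedStatisticError",
    "ConfigError",
    "update_stats",
    "q_value",
    "sample_std",
    "ci_student",
    "ci_chebyshev",
    "ci_bernstein",
    "confidence_interval",
    "interval_rows",
    "t_quantile_table",
    "BOUND_METHODS",
]

BOUND_METHODS = ("student_t", "chebyshev", "bernstein")


class RewardRangeError(ValueError):
    """A reward fell outside the declared support of the reward distribution."""


class UndefinedStatisticError(ValueError):
    """A statistic was requested from too few samples (e.g. a mean of zero samples)."""


class ConfigError(ValueError):
    """An invalid configuration value (alpha, bound name, sigma, ...)."""


@dataclass(frozen=True)
class RewardRange:
    """Known support ``[lo, hi]`` of every reward distribution in the task.

    The distribution-free bounds (Chebyshev, empirical Bernstein) need the
    support width; the default ``[0, 1]`` matches the localization task's
    reward function.
    """

    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"reward range requires lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, r: float) -> bool:
        return self.lo <= r <= self.hi


@dataclass(frozen=True)
class SufficientStats:
    """Visit count, reward sum and squared-reward sum for one table cell.

    These three numbers are sufficient for the sample mean, the sample
    variance and every interval construction in this module.  They are also
    additive: statistics of a union of experience sets are the component-wise
    sums, which is what makes exact marginalization and residual extraction
    possible downstream.
    """

    n: int = 0
    sum_r: float = 0.0
    sum_r2: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"negative count: {self.n}")
        if self.n == 0 and (self.sum_r != 0.0 or self.sum_r2 != 0.0):
            raise ValueError("empty cell must have zero sums")


@dataclass(frozen=True)
class ConfidenceInterval:
    """A two-sided interval on the mean of a reward distribution.

    ``lower``/``upper`` may be ``-inf``/``+inf`` (the unbounded cold-start
    interval).  ``alpha`` is the significance level: the interval has
    confidence ``1 - alpha``.
    """

    lower: float
    upper: float
    method: str
    alpha: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"inverted interval [{self.lower}, {self.upper}]")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    @property
    def is_unbounded(self) -> bool:
        return math.isinf(self.lower) or math.isinf(self.upper)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")


def update_stats(stats: SufficientStats, r: float, reward_range: RewardRange = RewardRange()) -> SufficientStats:
    """Fold one reward into the sufficient statistics.

    With learning rate ``1/n`` the incremental Q-update is exactly the
    running sample mean, so recording ``(n, sum_r, sum_r2)`` loses nothing.

    Raises :class:`RewardRangeError` if ``r`` lies outside ``reward_range``.
    """
    if not reward_range.contains(r):
        raise RewardRangeError(f"reward {r} outside declared range [{reward_range.lo}, {reward_range.hi}]")
    return SufficientStats(stats.n + 1, stats.sum_r + r, stats.sum_r2 + r * r)


def q_value(stats: SufficientStats) -> float:
    """Sample-mean reward (the Q-value) of a cell; needs at least one sample."""
    if stats.n < 1:
        raise UndefinedStatisticError("Q-value undefined for an empty cell")
    return stats.sum_r / stats.n


def sample_std(stats: SufficientStats) -> float:
    """Unbiased-variance sample standard deviation; needs at least two samples.

    The radicand ``(sum_r2 - n q^2)/(n-1)`` can go slightly negative through
    floating-point cancellation for near-constant rewards; it is clamped to 0.
    """
    if stats.n < 2:
        raise UndefinedStatisticError("sample SD undefined for fewer than two samples")
    q = stats.sum_r / stats.n
    var = (stats.sum_r2 - stats.n * q * q) / (stats.n - 1)
    return math.sqrt(max(0.0, var))


_UNBOUNDED = (-math.inf, math.inf)


def ci_student(stats: SufficientStats, alpha: float) -> ConfidenceInterval:
    """Student-t interval ``q +/- t_{alpha/2, n-1} s / sqrt(n)``; unbounded for n < 2."""
    _check_alpha(alpha)
    if stats.n < 2:
        lo, hi = _UNBOUNDED
    else:
        q = q_value(stats)
        half = float(_sps.t.ppf(1.0 - alpha / 2.0, stats.n - 1)) * sample_std(stats) / math.sqrt(stats.n)
        lo, hi = q - half, q + half
    return ConfidenceInterval(lo, hi, "student_t", alpha)


def ci_chebyshev(stats: SufficientStats, alpha: float, reward_range: RewardRange = RewardRange()) -> ConfidenceInterval:
    """Distribution-free Chebyshev interval with worst-case variance.

    For support width ``w = hi - lo`` the variance is at most ``w^2/4``, so
    ``P(|q - mu| >= w / (2 sqrt(n alpha))) <= alpha``.  Needs one sample;
    unbounded for n = 0.
    """
    _check_alpha(alpha)
    if stats.n < 1:
        lo, hi = _UNBOUNDED
    else:
        q = q_value(stats)
        half = reward_range.width / (2.0 * math.sqrt(stats.n * alpha))
        lo, hi = q - half, q + half
    return ConfidenceInterval(lo, hi, "chebyshev", alpha)


def ci_bernstein(stats: SufficientStats, alpha: float, reward_range: RewardRange = RewardRange()) -> ConfidenceInterval:
    """Empirical-Bernstein ("variance-aware") interval.

    ``q +/- [ s sqrt(2 ln(3/alpha) / n) + 3 w ln(3/alpha) / n ]`` with the
    sample SD ``s`` and support width ``w``.  Tight when the empirical
    variance is small; unbounded for n < 2.
    """
    _check_alpha(alpha)
    if stats.n < 2:
        lo, hi = _UNBOUNDED
    else:
        q = q_value(stats)
        s = sample_std(stats)
        log_term = math.log(3.0 / alpha)
        half = s * math.sqrt(2.0 * log_term / stats.n) + 3.0 * reward_range.width * log_term / stats.n
        lo, hi = q - half, q + half
    return ConfidenceInterval(lo, hi, "bernstein", alpha)


def confidence_interval(
    stats: SufficientStats,
    alpha: float,
    method: str = "student_t",
    reward_range: RewardRange = RewardRange(),
) -> ConfidenceInterval:
    """Dispatch to one of the three bound constructions by name."""
    if method == "student_t":
        return ci_student(stats, alpha)
    if method == "chebyshev":
        return ci_chebyshev(stats, alpha, reward_range)
    if method == "bernstein":
        return ci_bernstein(stats, alpha, reward_range)
    raise ConfigError(f"unknown bound method {method!r}; expected one of {BOUND_METHODS}")


# ---------------------------------------------------------------------------
# Vectorised row operations (one entry per action of a table row).
# ---------------------------------------------------------------------------

# Student-t quantiles are cached per alpha.  Degrees of freedom up to
# _T_EXACT_DOF use scipy's exact inverse CDF; beyond that a Cornish-Fisher
# expansion around the normal quantile is used (relative error < 1e-4 at
# dof = 4096 and shrinking as 1/dof), which keeps table growth O(dof) cheap.
_T_EXACT_DOF = 4096
_t_cache: dict[float, np.ndarray] = {}


def t_quantile_table(alpha: float, max_dof: int) -> np.ndarray:
    """Array ``tq`` with ``tq[d]`` = two-sided Student-t quantile for d degrees of freedom.

    ``tq[0]`` is ``inf`` (no variance estimate from a single sample).
    """
    _check_alpha(alpha)
    max_dof = int(max_dof)
    tq = _t_cache.get(alpha)
    if tq is not None and len(tq) > max_dof:
        return tq
    size = max(max_dof + 1, 256)
    if tq is not None:
        size = max(size, 2 * len(tq))  # geometric growth keeps amortized cost linear
    p = 1.0 - alpha / 2.0
    tq = np.empty(size)
    tq[0] = np.inf
    exact_hi = min(size - 1, _T_EXACT_DOF)
    tq[1 : exact_hi + 1] = _sps.t.ppf(p, np.arange(1, exact_hi + 1))
    if size - 1 > _T_EXACT_DOF:
        dof = np.arange(_T_EXACT_DOF + 1, size, dtype=float)
        z = _sps.norm.ppf(p)
        tq[_T_EXACT_DOF + 1 :] = (
            z
            + (z**3 + z) / (4.0 * dof)
            + (5.0 * z**5 + 16.0 * z**3 + 3.0 * z) / (96.0 * dof**2)
        )
    _t_cache[alpha] = tq
    return tq


def _row_q_var(n: np.ndarray, sum_r: np.ndarray, sum_r2: np.ndarray, mask: np.ndarray):
    nn = n[mask]
    q = sum_r[mask] / nn
    var = np.maximum(0.0, (sum_r2[mask] - nn * q * q) / np.maximum(nn - 1.0, 1.0))
    return nn, q, var


def interval_rows(
    n: np.ndarray,
    sum_r: np.ndarray,
    sum_r2: np.ndarray,
    *,
    method: str,
    alpha: float,
    reward_range: RewardRange = RewardRange(),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised confidence intervals for aligned statistic arrays.

    Returns ``(lower, upper)`` arrays; cells with too few samples get the
    unbounded interval ``(-inf, +inf)``.  Semantics match the scalar
    ``ci_*`` constructors exactly for degrees of freedom up to 4096 (beyond
    that the cached t quantile switches to an asymptotic expansion).
    """
    n = np.asarray(n, dtype=float)
    sum_r = np.asarray(sum_r, dtype=float)
    sum_r2 = np.asarray(sum_r2, dtype=float)
    lower = np.full(n.shape, -np.inf)
    upper = np.full(n.shape, np.inf)

    if method == "student_t":
        mask = n >= 2
        if mask.any():
            nn, q, var = _row_q_var(n, sum_r, sum_r2, mask)
            tq = t_quantile_table(alpha, int(nn.max()))
            half = tq[(nn - 1).astype(np.intp)] * np.sqrt(var / nn)
            lower[mask] = q - half
            upper[mask] = q + half
    elif method == "chebyshev":
        _check_alpha(alpha)
        mask = n >= 1
        if mask.any():
            nn = n[mask]
            q = sum_r[mask] / nn
            half = reward_range.width / (2.0 * np.sqrt(nn * alpha))
            lower[mask] = q - half
            upper[mask] = q + half
    elif method == "bernstein":
        _check_alpha(alpha)
        mask = n >= 2
        if mask.any():
            nn, q, var = _row_q_var(n, sum_r, sum_r2, mask)
            log_term = math.log(3.0 / alpha)
            half = np.sqrt(var) * np.sqrt(2.0 * log_term / nn) + 3.0 * reward_range.width * log_term / nn
            lower[mask] = q - half
            upper[mask] = q + half
    else:
        raise ConfigError(f"unknown bound method {method!r}; expected one of {BOUND_METHODS}")
    return lower, upper
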
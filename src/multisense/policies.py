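"""Interval-selection decision policies and the two reference observers.

Per action, the learner holds one confidence interval per accepted source
plus the joint space's interval ``M``.  Rather than fusing them, a single
interval is *selected* to supply the action's representative value (its
upper bound — optimism in the face of uncertainty):

* MOS (Most Optimistic Source) — the accepted source with the greatest
  upper bound.
* LUS (Least Uncertain Source) — the candidate (accepted sources and the
  joint interval) with the shortest length.

Either way the representative value is capped at ``M``'s upper bound: the
joint space has no aliasing and remains the most faithful description of
the current state, so any value above its upper bound is unrealistically
optimistic.  When the cap triggers, the decision is attributed to the
joint source.

The action with the greatest representative value is executed; exact ties
are broken uniformly at random.

Two reference policies close the module: UCB1 (the classical
upper-confidence-bound bandit rule, used as the baseline learner on single
sensors and on the joint space) and the Bayesian optimal observer, which
knows the sensor noise models and estimates the stimulus by
reliability-weighted averaging of the readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .stats import ConfidenceInterval, ConfigError, SufficientStats
from .subspace import SourceKey

__all__ = [
    "JOINT",
    "SourcedInterval",
    "ActionValue",
    "mos_select",
    "lus_select",
    "choose_action",
    "ucb1_value",
    "bayes_optimal_estimate",
]

#: Tag identifying the joint sensory space as the origin of a decision.
JOINT = "joint"

SourceTag = Union[SourceKey, str]


@dataclass(frozen=True)
class SourcedInterval:
    """A confidence interval together with the source that produced it."""

    source: SourceTag
    interval: ConfidenceInterval


@dataclass(frozen=True)
class ActionValue:
    """Representative value of one action and the source that supplied it."""

    action: int
    value: float
    dominant_source: SourceTag


def mos_select(
    joint: ConfidenceInterval, accepted: Sequence[SourcedInterval]
) -> tuple[float, SourceTag]:
    """Most Optimistic Source selection for one action.

    Picks the accepted interval with the greatest upper bound (ties: first
    in the list); caps the value at the joint upper bound, attributing the
    decision to the joint space when the cap triggers or no source was
    accepted.
    """
    if not accepted:
        return joint.upper, JOINT
    best = max(accepted, key=lambda si: si.interval.upper)
    if best.interval.upper > joint.upper:
        return joint.upper, JOINT
    return best.interval.upper, best.source


def lus_select(
    joint: ConfidenceInterval, accepted: Sequence[SourcedInterval]
) -> tuple[float, SourceTag]:
    """Least Uncertain Source selection for one action.

    Candidates are the accepted sources plus the joint interval itself; the
    shortest interval wins (ties prefer the joint, then the earliest listed
    source).  The returned value is the chosen interval's upper bound capped
    at the joint's, with capped decisions attributed to the joint space.
    """
    chosen_len = joint.length
    chosen_upper = joint.upper
    chosen_src: SourceTag = JOINT
    for si in accepted:
        if si.interval.length < chosen_len:
            chosen_len = si.interval.length
            chosen_upper = si.interval.upper
            chosen_src = si.source
    if chosen_upper > joint.upper:
        return joint.upper, JOINT
    return chosen_upper, chosen_src


def choose_action(values: Sequence[ActionValue], rng: np.random.Generator) -> int:
    """Argmax of representative values; exact ties are broken uniformly.

    Unbounded (infinite) values beat every finite value, so untried actions
    are explored first.
    """
    if len(values) == 0:
        raise ConfigError("choose_action requires at least one action value")
    arr = np.array([av.value for av in values])
    return tie_break_argmax(arr, rng, [av.action for av in values])


def tie_break_argmax(values: np.ndarray, rng: np.random.Generator, ids: Sequence[int] | None = None) -> int:
    """Argmax with uniform random tie-breaking; draws from ``rng`` only on ties."""
    winners = np.flatnonzero(values == values.max())
    pick = winners[0] if winners.size == 1 else winners[int(rng.integers(winners.size))]
    return int(pick) if ids is None else int(ids[pick])


def ucb1_value(stats: SufficientStats, total_state_visits: int, c: float = 0.2) -> float:
    """UCB1 upper bound ``q + sqrt(c ln N / n)`` for one action of a state.

    ``N`` is the total number of visits to the state across all actions.
    An untried action (n = 0) gets an infinite value, forcing one trial of
    every action before any repeats.  The original rule uses ``c = 2``; the
    experiments here use a smaller coefficient to damp the periodic
    re-exploration it causes in large state-action spaces.
    """
    if stats.n == 0:
        return math.inf
    if total_state_visits < stats.n:
        raise ValueError("state visit total cannot be smaller than the action count")
    q = stats.sum_r / stats.n
    if c == 0.0:
        return q
    return q + math.sqrt(c * math.log(total_state_visits) / stats.n)


def bayes_optimal_estimate(
    x_a: float,
    x_v: float,
    sigma_a: float,
    sigma_v: float,
    n_positions: int = 30,
) -> int:
    """Reliability-weighted fusion of two noisy readings of the same stimulus.

    ``s_hat = (x_a / sigma_a^2 + x_v / sigma_v^2) / (1/sigma_a^2 + 1/sigma_v^2)``,
    rounded half-up to the nearest grid position and clamped to the grid.
    This is the ideal-observer estimate for Gaussian noise with known SDs: a
    weighted average where each cue's weight is its relative reliability
    (inverse variance).
    """
    if sigma_a <= 0 or sigma_v <= 0:
        raise ConfigError("sensor noise SDs must be positive")
    wa = 1.0 / (sigma_a * sigma_a)
    wv = 1.0 / (sigma_v * sigma_v)
    est = (x_a * wa + x_v * wv) / (wa + wv)
    pos = int(math.floor(est + 0.5))
    return min(max(pos, 1), n_positions)
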
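"""Joint-space reward tables, subspace marginalization, and the generalization test.

An agent with ``k`` discrete sensors perceives the environment through the
joint observation space ``O^1 x ... x O^k`` (where it is fully observable)
and, simultaneously, through every *source of information*: a subset of
sensors whose projected observation aliases many joint states onto one.
Aliasing is beneficial when the aliased states share an optimal policy
(generalization: the subspace learns fast because it pools experience) and
harmful when they do not ("garbage" statistics).

:class:`StatTables` maintains sufficient statistics for the joint space and,
incrementally, the exact marginal statistics of every declared source — the
marginal cell of a source is, at all times, the component-wise sum of the
joint cells projecting onto it, without extra learning trials.

The *generalization test* (:meth:`StatTables.g_test`) decides, per state,
source and action, whether a source's aliasing currently generalizes.  The
marginal statistics of the source include the joint cell's own experiences,
so they are never independent of it; the test therefore first subtracts the
joint cell from the marginal (*residual* statistics — the experience the
source has gathered in other states aliased onto the same observation) and
accepts the source iff the residual's confidence interval intersects the
joint cell's interval.  Early in learning both intervals are wide (or
unbounded) and every source passes; as evidence accumulates, only sources
whose residual experience genuinely estimates the same mean keep passing.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .stats import (
    ConfidenceInterval,
    ConfigError,
    RewardRange,
    RewardRangeError,
    SufficientStats,
    interval_rows,
)

__all__ = [
    "SourceKey",
    "enumerate_sources",
    "project",
    "StatTables",
    "residual_stats",
    "intervals_intersect",
]


@dataclass(frozen=True, order=True)
class SourceKey:
    """A source of information: a non-empty subset of sensor indices (1-based).

    Singleton keys are individual sensors; larger proper subsets appear in
    the power-set extension.  The full sensor set denotes the joint space
    itself and is kept implicit everywhere (it is never enumerated as a
    source).
    """

    sensor_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(self.sensor_indices))
        if len(idx) == 0:
            raise ConfigError("a source must contain at least one sensor")
        if len(set(idx)) != len(idx) or idx[0] < 1:
            raise ConfigError(f"invalid sensor indices {self.sensor_indices}")
        object.__setattr__(self, "sensor_indices", idx)

    def __str__(self) -> str:
        return "+".join(str(i) for i in self.sensor_indices)

    def __len__(self) -> int:
        return len(self.sensor_indices)


def enumerate_sources(k: int, powerset: bool = False) -> list[SourceKey]:
    """Sources to track beside the (implicit) joint space.

    Default: the ``k`` singleton sensors.  With ``powerset=True``: every
    non-empty proper subset of the ``k`` sensors (``2^k - 2`` sources).
    For ``k = 2`` the two modes coincide.  The joint space is always
    implicit and never listed, so a single-sensor agent (whose lone
    "subspace" would be the joint space itself) has no sources at all.
    """
    if k < 1:
        raise ConfigError(f"need at least one sensor, got k={k}")
    if not powerset:
        return [SourceKey((i,)) for i in range(1, k + 1)] if k > 1 else []
    sources = []
    for size in range(1, k):
        for combo in itertools.combinations(range(1, k + 1), size):
            sources.append(SourceKey(combo))
    return sources


def project(state: Sequence[int], source: SourceKey) -> tuple[int, ...]:
    """Project a joint observation tuple onto a source (ascending sensor index)."""
    return tuple(state[i - 1] for i in source.sensor_indices)


def residual_stats(marginal: SufficientStats, joint_entry: SufficientStats) -> SufficientStats:
    """Marginal statistics minus the current joint cell's own experiences.

    Because statistics are additive and the joint cell's rewards are a
    subset of the marginal cell's, the difference is itself a valid set of
    sufficient statistics: the experience of all *other* states aliased onto
    the same observation.
    """
    n = marginal.n - joint_entry.n
    sum_r = marginal.sum_r - joint_entry.sum_r
    sum_r2 = marginal.sum_r2 - joint_entry.sum_r2
    if n < 0 or (n == 0 and (abs(sum_r) > 1e-9 or abs(sum_r2) > 1e-9)):
        raise ValueError("marginal smaller than joint cell: tables are inconsistent")
    if n == 0:
        return SufficientStats(0, 0.0, 0.0)
    return SufficientStats(n, sum_r, sum_r2)


def intervals_intersect(a: ConfidenceInterval, b: ConfidenceInterval) -> bool:
    """Closed-interval intersection test; touching endpoints intersect.

    Unbounded endpoints behave as -inf/+inf, so an unbounded interval
    intersects everything.
    """
    return max(a.lower, b.lower) <= min(a.upper, b.upper)


class StatTables:
    """Dense reward-statistics tables for the joint space and all sources.

    Cells are addressed by (observation tuple, action).  Observations are
    1-based grid positions, actions are 0-based internally (``n_actions``
    consecutive ids).  Storage is one ``(cells, n_actions)`` float array per
    statistic per table; float64 holds counts exactly.

    Marginals are maintained incrementally on every
    :meth:`record_experience` — O(#sources) per step — and are at all times
    identical to a from-scratch marginalization of the joint table (a tested
    invariant, not an assumption).
    """

    def __init__(
        self,
        k: int,
        n_positions: int,
        n_actions: int,
        sources: Sequence[SourceKey] | None = None,
        reward_range: RewardRange = RewardRange(),
    ) -> None:
        if k < 1 or n_positions < 1 or n_actions < 1:
            raise ConfigError("k, n_positions and n_actions must be positive")
        self.k = k
        self.n_positions = n_positions
        self.n_actions = n_actions
        self.reward_range = reward_range
        self.sources: list[SourceKey] = list(sources) if sources is not None else enumerate_sources(k)
        for src in self.sources:
            if src.sensor_indices[-1] > k:
                raise ConfigError(f"source {src} references sensor beyond k={k}")

        def _alloc(n_cells: int) -> dict[str, np.ndarray]:
            return {
                "n": np.zeros((n_cells, n_actions)),
                "sum_r": np.zeros((n_cells, n_actions)),
                "sum_r2": np.zeros((n_cells, n_actions)),
            }

        self._joint = _alloc(n_positions**k)
        self._marg = [_alloc(n_positions ** len(src)) for src in self.sources]
        # strides for raveling observation tuples into row indices
        self._joint_strides = tuple(n_positions ** (k - 1 - i) for i in range(k))
        self._src_strides = [
            tuple(n_positions ** (len(src) - 1 - i) for i in range(len(src))) for src in self.sources
        ]

    # -- indexing -----------------------------------------------------------

    def joint_index(self, state: Sequence[int]) -> int:
        idx = 0
        for reading, stride in zip(state, self._joint_strides):
            if not 1 <= reading <= self.n_positions:
                raise ValueError(f"reading {reading} outside grid [1, {self.n_positions}]")
            idx += (reading - 1) * stride
        return idx

    def source_index(self, source_pos: int, state: Sequence[int]) -> int:
        src = self.sources[source_pos]
        idx = 0
        for sensor, stride in zip(src.sensor_indices, self._src_strides[source_pos]):
            idx += (state[sensor - 1] - 1) * stride
        return idx

    # -- rows (views) -------------------------------------------------------

    def joint_rows(self, state: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = self.joint_index(state)
        return self._joint["n"][i], self._joint["sum_r"][i], self._joint["sum_r2"][i]

    def marginal_rows(self, source_pos: int, state: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = self.source_index(source_pos, state)
        t = self._marg[source_pos]
        return t["n"][i], t["sum_r"][i], t["sum_r2"][i]

    # -- scalar cell accessors ---------------------------------------------

    def joint_cell(self, state: Sequence[int], action: int) -> SufficientStats:
        n, sr, sr2 = self.joint_rows(state)
        return SufficientStats(int(n[action]), float(sr[action]), float(sr2[action]))

    def marginal_cell(self, source: SourceKey, state: Sequence[int], action: int) -> SufficientStats:
        pos = self.sources.index(source)
        n, sr, sr2 = self.marginal_rows(pos, state)
        return SufficientStats(int(n[action]), float(sr[action]), float(sr2[action]))

    # -- updates ------------------------------------------------------------

    def record_experience(self, state: Sequence[int], action: int, r: float) -> None:
        """Fold one (state, action, reward) experience into the joint cell
        and every source's projected cell."""
        if not self.reward_range.contains(r):
            raise RewardRangeError(
                f"reward {r} outside declared range [{self.reward_range.lo}, {self.reward_range.hi}]"
            )
        if not 0 <= action < self.n_actions:
            raise ValueError(f"action {action} outside [0, {self.n_actions})")
        r2 = r * r
        i = self.joint_index(state)
        self._joint["n"][i, action] += 1.0
        self._joint["sum_r"][i, action] += r
        self._joint["sum_r2"][i, action] += r2
        for pos in range(len(self.sources)):
            j = self.source_index(pos, state)
            t = self._marg[pos]
            t["n"][j, action] += 1.0
            t["sum_r"][j, action] += r
            t["sum_r2"][j, action] += r2

    # -- generalization test ------------------------------------------------

    def residual_cell(self, source: SourceKey, state: Sequence[int], action: int) -> SufficientStats:
        return residual_stats(self.marginal_cell(source, state, action), self.joint_cell(state, action))

    def g_test(
        self,
        state: Sequence[int],
        source: SourceKey,
        action: int,
        bound: str = "student_t",
        alpha: float = 0.05,
    ) -> tuple[bool, ConfidenceInterval, ConfidenceInterval]:
        """Does the source's aliasing generalize for this state and action?

        Builds the joint cell's interval ``M`` and the residual interval
        ``B_hat`` (marginal minus joint cell) with the configured bound and
        accepts iff they intersect.  A residual with too few samples yields
        an unbounded interval, hence acceptance: there is no independent
        evidence against generalization.

        Returns ``(accept, residual_interval, joint_interval)``.
        """
        from .stats import confidence_interval

        joint = self.joint_cell(state, action)
        resid = self.residual_cell(source, state, action)
        m_int = confidence_interval(joint, alpha, bound, self.reward_range)
        b_hat = confidence_interval(resid, alpha, bound, self.reward_range)
        return intervals_intersect(b_hat, m_int), b_hat, m_int

    # -- vectorised per-row intervals (used by the agent loop) --------------

    def joint_interval_rows(self, state: Sequence[int], bound: str, alpha: float):
        n, sr, sr2 = self.joint_rows(state)
        return interval_rows(n, sr, sr2, method=bound, alpha=alpha, reward_range=self.reward_range)

    def marginal_interval_rows(self, source_pos: int, state: Sequence[int], bound: str, alpha: float):
        n, sr, sr2 = self.marginal_rows(source_pos, state)
        return interval_rows(n, sr, sr2, method=bound, alpha=alpha, reward_range=self.reward_range)

    # -- serialization ------------------------------------------------------

    def _unravel(self, idx: int, length: int, strides: tuple[int, ...]) -> tuple[int, ...]:
        obs = []
        for stride in strides:
            obs.append(idx // stride + 1)
            idx %= stride
        return tuple(obs)

    def to_dict(self) -> dict:
        """JSON-serializable dump of all non-empty cells.

        Keys are ``"o1,o2,...|action"`` (1-based observations, 0-based
        actions); values are ``[n, sum_r, sum_r2]``.
        """

        def dump(table: dict[str, np.ndarray], strides: tuple[int, ...]) -> dict[str, list[float]]:
            out = {}
            rows, cols = np.nonzero(table["n"])
            for i, a in zip(rows.tolist(), cols.tolist()):
                obs = self._unravel(i, len(strides), strides)
                key = ",".join(map(str, obs)) + f"|{a}"
                out[key] = [table["n"][i, a], table["sum_r"][i, a], table["sum_r2"][i, a]]
            return out

        return {
            "k": self.k,
            "n_positions": self.n_positions,
            "n_actions": self.n_actions,
            "reward_range": [self.reward_range.lo, self.reward_range.hi],
            "sources": [list(s.sensor_indices) for s in self.sources],
            "joint": dump(self._joint, self._joint_strides),
            "marginals": {
                str(src): dump(self._marg[pos], self._src_strides[pos])
                for pos, src in enumerate(self.sources)
            },
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, payload: dict) -> "StatTables":
        tables = cls(
            k=payload["k"],
            n_positions=payload["n_positions"],
            n_actions=payload["n_actions"],
            sources=[SourceKey(tuple(s)) for s in payload["sources"]],
            reward_range=RewardRange(*payload["reward_range"]),
        )

        def load(table: dict[str, np.ndarray], cells: dict, strides: tuple[int, ...]) -> None:
            for key, (n, sr, sr2) in cells.items():
                obs_s, a_s = key.split("|")
                obs = tuple(int(x) for x in obs_s.split(","))
                idx = sum((o - 1) * st for o, st in zip(obs, strides))
                table["n"][idx, int(a_s)] = n
                table["sum_r"][idx, int(a_s)] = sr
                table["sum_r2"][idx, int(a_s)] = sr2

        load(tables._joint, payload["joint"], tables._joint_strides)
        for pos, src in enumerate(tables.sources):
            load(tables._marg[pos], payload["marginals"][str(src)], tables._src_strides[pos])
        return tables

    @classmethod
    def load_json(cls, path: str | Path) -> "StatTables":
        return cls.from_dict(json.loads(Path(path).read_text()))
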
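"""The full multisensory learning and decision loop, plus baseline agents.

Per time step the :class:`MultisensoryAgent`:

1. reads the joint observation ``s = (o^1, ..., o^k)``;
2. for each action, builds the joint cell's confidence interval ``M`` and
   runs the generalization test for every source (residual interval vs
   ``M``);
3. feeds the accepted sources' marginal intervals into MOS or LUS to obtain
   the action's representative value and dominant source;
4. executes the action with the greatest value (ties uniform at random),
   observes the reward, and folds it into the joint cell and every marginal
   cell at once.

Learning and decision making are lazy over the current state only: no
global table sweeps ever happen.  All per-action quantities are computed
vectorised across the action set.

:class:`UCB1Agent` is the classical upper-confidence-bound baseline over an
arbitrary subset of sensors (a single modality, or the full joint space);
:class:`BayesObserver` is the ideal observer that knows the Gaussian noise
SDs and fuses readings by reliability-weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .environment import LocalizationEnv
from .policies import JOINT, SourceTag, bayes_optimal_estimate, tie_break_argmax
from .stats import ConfigError, RewardRange
from .subspace import SourceKey, StatTables, enumerate_sources

__all__ = [
    "AgentConfig",
    "StepRecord",
    "Trajectory",
    "MultisensoryAgent",
    "UCB1Agent",
    "BayesObserver",
    "run_lifetime",
]


@dataclass(frozen=True)
class AgentConfig:
    """Configuration of the interval-selection learner.

    ``bound`` is the interval construction (``student_t``, ``chebyshev`` or
    ``bernstein``); ``alpha`` the significance level of every interval (the
    framework's single free parameter); ``policy`` is ``"mos"`` or
    ``"lus"``; ``powerset`` tracks every non-empty proper sensor subset as
    a source instead of just the singletons.
    """

    bound: str = "student_t"
    alpha: float = 0.05
    policy: str = "mos"
    powerset: bool = False
    reward_range: RewardRange = field(default_factory=RewardRange)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.policy not in ("mos", "lus"):
            raise ConfigError(f"policy must be 'mos' or 'lus', got {self.policy!r}")


@dataclass(frozen=True)
class StepRecord:
    """Per-step diagnostics: what was perceived, done, earned, and why."""

    step: int
    state: tuple[int, ...]
    action: int
    reward: float
    dominant_source: SourceTag
    accepts: dict[SourceKey, bool]


class Trajectory:
    """Structure-of-arrays log of a run, indexable as :class:`StepRecord`.

    ``dominant`` holds integer codes: position in ``sources`` for a sensor
    subset, ``len(sources)`` for the joint space.
    """

    def __init__(self, sources: Sequence[SourceKey], horizon: int, k: int) -> None:
        self.sources = list(sources)
        self.states = np.zeros((horizon, k), dtype=np.int16)
        self.actions = np.zeros(horizon, dtype=np.int16)
        self.rewards = np.zeros(horizon, dtype=np.float32)
        self.dominant = np.zeros(horizon, dtype=np.int16)
        self.accepts = np.zeros((horizon, len(self.sources)), dtype=bool)

    @property
    def joint_code(self) -> int:
        return len(self.sources)

    @property
    def source_tags(self) -> list[SourceTag]:
        return [*self.sources, JOINT]

    def __len__(self) -> int:
        return len(self.actions)

    def __getitem__(self, t: int) -> StepRecord:
        code = int(self.dominant[t])
        tag: SourceTag = JOINT if code == self.joint_code else self.sources[code]
        return StepRecord(
            step=t,
            state=tuple(int(x) for x in self.states[t]),
            action=int(self.actions[t]),
            reward=float(self.rewards[t]),
            dominant_source=tag,
            accepts={src: bool(self.accepts[t, j]) for j, src in enumerate(self.sources)},
        )

    def __iter__(self):
        return (self[t] for t in range(len(self)))


class MultisensoryAgent:
    """Interval-selection learner over the joint space and its subspaces."""

    def __init__(
        self,
        n_positions: int,
        n_actions: int,
        n_sensors: int,
        config: AgentConfig = AgentConfig(),
    ) -> None:
        self.config = config
        self.n_actions = n_actions
        self.sources = enumerate_sources(n_sensors, powerset=config.powerset)
        self.tables = StatTables(
            k=n_sensors,
            n_positions=n_positions,
            n_actions=n_actions,
            sources=self.sources,
            reward_range=config.reward_range,
        )
        self.joint_code = len(self.sources)
        self._n_learned = 0
        self._tq: Optional[np.ndarray] = None
        from . import _kernels

        self.use_kernel = _kernels.HAVE_NUMBA
        self._kernel = _kernels.select_kernel if self.use_kernel else None
        m = len(self.sources)
        self._buf_nM = np.empty((m, n_actions))
        self._buf_sM = np.empty((m, n_actions))
        self._buf_s2M = np.empty((m, n_actions))
        self._buf_value = np.empty(n_actions)
        self._buf_src = np.empty(n_actions, dtype=np.int64)
        self._buf_acc = np.empty((m, n_actions), dtype=np.bool_)

    def action_values(self, state: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(value, src_code, accepts)`` arrays for every action of a state.

        ``value``/``src_code`` have shape ``(n_actions,)``; ``accepts`` has
        shape ``(n_sources, n_actions)`` and holds the generalization-test
        verdicts.  Dispatches to a JIT-compiled kernel when numba is
        available; :meth:`action_values_numpy` is the equivalent reference
        path (the two are pinned together by a test).
        """
        if self.use_kernel:
            return self._action_values_kernel(state)
        return self.action_values_numpy(state)

    def _ensure_tq(self) -> np.ndarray:
        from .stats import t_quantile_table

        needed = self._n_learned + 2
        if self._tq is None or len(self._tq) <= needed:
            self._tq = t_quantile_table(self.config.alpha, max(4096, 2 * needed))
        return self._tq

    def _action_values_kernel(self, state: Sequence[int]):
        import math

        cfg = self.config
        tables = self.tables
        nJ, sJ, s2J = tables.joint_rows(state)
        for j in range(len(self.sources)):
            nM, sM, s2M = tables.marginal_rows(j, state)
            self._buf_nM[j] = nM
            self._buf_sM[j] = sM
            self._buf_s2M[j] = s2M
        method = {"student_t": 0, "chebyshev": 1, "bernstein": 2}[cfg.bound]
        tq = self._ensure_tq() if method == 0 else np.empty(1)
        self._kernel(
            nJ, sJ, s2J,
            self._buf_nM, self._buf_sM, self._buf_s2M,
            tq, cfg.alpha, math.log(3.0 / cfg.alpha), tables.reward_range.width,
            method, cfg.policy == "mos",
            self._buf_value, self._buf_src, self._buf_acc,
        )
        return self._buf_value.copy(), self._buf_src.copy(), self._buf_acc.copy()

    # The selection step, vectorised over the action set.  Semantics are
    # those of subspace.g_test + policies.mos_select/lus_select applied per
    # action.
    def action_values_numpy(self, state: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pure-numpy reference implementation of :meth:`action_values`."""
        cfg = self.config
        tables = self.tables
        m = len(self.sources)
        mos = cfg.policy == "mos"

        m_lo, m_up = tables.joint_interval_rows(state, cfg.bound, cfg.alpha)
        nJ, sJ, s2J = tables.joint_rows(state)

        accepts = np.empty((m, self.n_actions), dtype=bool)
        if mos:
            best_up = np.full(self.n_actions, -np.inf)
        else:
            best_len = m_up - m_lo  # joint is the initial LUS candidate
            best_up = m_up.copy()
        src_code = np.full(self.n_actions, self.joint_code, dtype=np.int64)

        from .stats import interval_rows

        for j in range(m):
            nM, sM, s2M = tables.marginal_rows(j, state)
            r_lo, r_up = interval_rows(
                nM - nJ, sM - sJ, s2M - s2J,
                method=cfg.bound, alpha=cfg.alpha, reward_range=tables.reward_range,
            )
            acc = np.maximum(r_lo, m_lo) <= np.minimum(r_up, m_up)
            accepts[j] = acc
            b_lo, b_up = interval_rows(
                nM, sM, s2M, method=cfg.bound, alpha=cfg.alpha, reward_range=tables.reward_range
            )
            if mos:
                better = acc & (b_up > best_up)
            else:
                better = acc & ((b_up - b_lo) < best_len)
                best_len = np.where(better, b_up - b_lo, best_len)
            best_up = np.where(better, b_up, best_up)
            src_code = np.where(better, j, src_code)

        if mos:
            none_accepted = np.isneginf(best_up)
            value = np.where(none_accepted, m_up, np.minimum(best_up, m_up))
            capped = best_up > m_up
            src_code = np.where(none_accepted | capped, self.joint_code, src_code)
        else:
            value = np.minimum(best_up, m_up)
            capped = best_up > m_up
            src_code = np.where(capped, self.joint_code, src_code)
        return value, src_code, accepts

    def select_action(
        self, state: Sequence[int], rng: np.random.Generator
    ) -> tuple[int, int, np.ndarray]:
        """Choose an action for a state.

        Returns ``(action, dominant_code, accept_flags)`` with a 1-based
        action (a grid position), the integer code of the source that
        supplied the chosen action's value, and that action's per-source
        generalization-test verdicts.
        """
        value, src_code, accepts = self.action_values(state)
        a0 = tie_break_argmax(value, rng)
        return a0 + 1, int(src_code[a0]), accepts[:, a0].copy()

    def learn(self, state: Sequence[int], action: int, r: float) -> None:
        """Fold one experience into the joint cell and all marginal cells."""
        self.tables.record_experience(state, action - 1, r)
        self._n_learned += 1


class UCB1Agent:
    """UCB1 baseline learner over an arbitrary subset of sensors.

    ``sensor_indices`` selects which readings form the agent's state:
    a singleton for a single-modality agent, the full set for the
    joint-space agent.  Decisions are always attributed to the agent's own
    (single) source of information.
    """

    def __init__(
        self,
        n_positions: int,
        n_actions: int,
        sensor_indices: Sequence[int],
        n_sensors: int,
        c: float = 0.2,
        reward_range: RewardRange = RewardRange(),
    ) -> None:
        self.n_actions = n_actions
        self.n_positions = n_positions
        self.sensor_indices = tuple(sorted(sensor_indices))
        self.k = n_sensors
        self.c = c
        self.reward_range = reward_range
        self.is_joint = len(self.sensor_indices) == n_sensors
        self.source: SourceTag = JOINT if self.is_joint else SourceKey(self.sensor_indices)
        p = len(self.sensor_indices)
        self._strides = tuple(n_positions ** (p - 1 - i) for i in range(p))
        cells = n_positions**p
        self._n = np.zeros((cells, n_actions))
        self._sum_r = np.zeros((cells, n_actions))
        self._visits = np.zeros(cells)
        # like the other agents, sources/joint_code describe dominance coding
        self.sources = [] if self.is_joint else [SourceKey(self.sensor_indices)]
        self.joint_code = len(self.sources) if self.is_joint else 0

    def _index(self, state: Sequence[int]) -> int:
        return sum((state[i - 1] - 1) * st for i, st in zip(self.sensor_indices, self._strides))

    def select_action(
        self, state: Sequence[int], rng: np.random.Generator
    ) -> tuple[int, int, np.ndarray]:
        i = self._index(state)
        n = self._n[i]
        big_n = self._visits[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            ucb = np.where(
                n > 0,
                self._sum_r[i] / np.maximum(n, 1.0)
                + np.sqrt(self.c * np.log(max(big_n, 1.0)) / np.maximum(n, 1.0)),
                np.inf,
            )
        a0 = tie_break_argmax(ucb, rng)
        return a0 + 1, self.joint_code, np.zeros(len(self.sources), dtype=bool)

    def learn(self, state: Sequence[int], action: int, r: float) -> None:
        if not self.reward_range.contains(r):
            raise ValueError(f"reward {r} outside declared range")
        i = self._index(state)
        self._n[i, action - 1] += 1.0
        self._sum_r[i, action - 1] += r
        self._visits[i] += 1.0


class BayesObserver:
    """Ideal observer: knows the Gaussian noise SDs, fuses by inverse-variance
    weighting, and ignores pure-noise sensors (their reliability is zero)."""

    def __init__(self, sensors, n_positions: int = 30) -> None:
        self.n_positions = n_positions
        self.gaussian = [(j, s.sigma) for j, s in enumerate(sensors) if s.kind == "gaussian"]
        if not self.gaussian:
            raise ConfigError("Bayes observer needs at least one gaussian sensor")

    def actions_for(self, readings: np.ndarray) -> np.ndarray:
        """Vectorised estimates for a whole run's readings ``(horizon, k)``."""
        num = 0.0
        den = 0.0
        for j, sigma in self.gaussian:
            w = 1.0 / (sigma * sigma)
            num = num + readings[:, j] * w
            den += w
        est = np.floor(num / den + 0.5).astype(np.int64)
        return np.clip(est, 1, self.n_positions)

    def select_action(self, state: Sequence[int], rng: np.random.Generator) -> tuple[int, int, np.ndarray]:
        if len(self.gaussian) == 1:
            j, _ = self.gaussian[0]
            return int(state[j]), 0, np.zeros(0, dtype=bool)
        (ja, sa), (jv, sv) = self.gaussian[0], self.gaussian[1]
        if len(self.gaussian) > 2:
            arr = np.asarray(state, dtype=float)[None, :]
            return int(self.actions_for(arr)[0]), 0, np.zeros(0, dtype=bool)
        return (
            bayes_optimal_estimate(state[ja], state[jv], sa, sv, self.n_positions),
            0,
            np.zeros(0, dtype=bool),
        )

    def learn(self, state, action, r) -> None:  # the oracle does not learn
        pass


def run_lifetime(
    env: LocalizationEnv,
    agent,
    horizon: int,
    seed: int,
    streams: Optional[tuple[np.ndarray, np.ndarray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Drive one agent through ``horizon`` steps of the localization task.

    The world (stimuli and readings) and the agent's tie-breaking draws use
    separate RNG streams derived from ``seed``, so the identical seed and
    configuration reproduce the identical trajectory bit for bit.
    Pre-generated ``streams`` (and a dedicated agent ``rng``) may be passed
    in to pair several agents on the same world.
    """
    if horizon < 1:
        raise ConfigError("horizon must be at least 1")
    if streams is None or rng is None:
        ss = np.random.SeedSequence(seed)
        env_ss, agent_ss = ss.spawn(2)
        if streams is None:
            streams = env.generate_streams(horizon, np.random.default_rng(env_ss))
        if rng is None:
            rng = np.random.default_rng(agent_ss)
    stimuli, readings = streams
    sources = getattr(agent, "sources", [])
    traj = Trajectory(sources, horizon, readings.shape[1])
    traj.states[:] = readings[:horizon]
    radius = env.cfg.reward_radius
    binary = env.cfg.reward_shape == "binary"
    for t in range(horizon):
        state = readings[t]
        action, code, accepts = agent.select_action(state, rng)
        d = abs(action - int(stimuli[t]))
        if d > radius:
            r = 0.0
        elif binary:
            r = 1.0
        else:
            r = (radius + 1 - d) / (radius + 1)
        agent.learn(state, action, r)
        traj.actions[t] = action
        traj.rewards[t] = r
        traj.dominant[t] = code
        if accepts.size:
            traj.accepts[t] = accepts
    return traj
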
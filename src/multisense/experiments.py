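"""Experiment runners and figure/table metrics for the localization task.

The central entry point is :func:`run_experiment`, which drives a roster of
agents over ``runs`` independent lifetimes of the simulator.  Within a run
every agent sees the *identical* stimulus and reading streams (paired
comparison), while tie-breaking draws come from per-agent substreams; run
``i`` derives all of its randomness from ``base_seed + i``, so results are
bit-reproducible from the :class:`RunSpec` alone.

The Bayesian optimal observer is always evaluated on the same streams and
serves as the reference for the learning-speed criterion
(:func:`steps_to_fraction`): the first step at which an agent's accumulated
reward reaches a given fraction of the observer's accumulated reward.

Aggregated outputs mirror the standard presentation of this task: smoothed
average-reward curves, per-sensor generalization-test acceptance rates,
per-source dominance shares, and a summary table of steps-to-fraction with
dominance percentages up to the crossing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentConfig, BayesObserver, MultisensoryAgent, Trajectory, UCB1Agent, run_lifetime
from .environment import EnvConfig, LocalizationEnv, SensorModel
from .policies import JOINT, SourceTag
from .stats import ConfigError
from .subspace import SourceKey

__all__ = [
    "moving_average",
    "dominance_shares",
    "acceptance_rate",
    "steps_to_fraction",
    "RunSpec",
    "ExperimentResult",
    "run_experiment",
    "exp1_spec",
    "exp2_spec",
    "failure_spec",
    "alpha_sweep",
    "tag_label",
]


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average; at step t the mean of the last min(window, t) values.

    Output has the same length as the input; window 1 is the identity.
    """
    if window < 1:
        raise ConfigError("window must be at least 1")
    x = np.asarray(series, dtype=float)
    cs = np.cumsum(x)
    out = np.empty_like(cs)
    w = min(window, len(x))
    out[:w] = cs[:w] / np.arange(1, w + 1)
    if len(x) > w:
        out[w:] = (cs[w:] - cs[:-w]) / w
    return out


def tag_label(tag: SourceTag, sensor_names: Sequence[str]) -> str:
    """Human label for a source: 'I' for the joint space, sensor initials otherwise."""
    if tag == JOINT:
        return "I"
    return "+".join(sensor_names[i - 1] for i in tag.sensor_indices)


def dominance_shares(traj: Trajectory, by_window: Optional[int] = None):
    """Fraction of decisions attributed to each source of information.

    Without ``by_window``: a dict mapping each source tag (sensor subsets
    and the joint space) to its overall share; shares sum to 1.  With
    ``by_window``: ``(tags, array)`` where the array holds the trailing
    windowed share of each tag per step.
    """
    tags = traj.source_tags
    n_tags = len(tags)
    one_hot = np.eye(n_tags)[traj.dominant]
    if by_window is None:
        shares = one_hot.mean(axis=0)
        return {tag: float(s) for tag, s in zip(tags, shares)}
    windowed = np.column_stack([moving_average(one_hot[:, j], by_window) for j in range(n_tags)])
    return tags, windowed


def acceptance_rate(traj: Trajectory, sensor: SourceKey, window: int = 1) -> np.ndarray:
    """Windowed generalization-test acceptance rate of one source for the chosen action."""
    if sensor not in traj.sources:
        raise ConfigError(f"source {sensor} not tracked in this trajectory")
    j = traj.sources.index(sensor)
    return moving_average(traj.accepts[:, j].astype(float), window)


def steps_to_fraction(
    agent_cum: Sequence[float],
    bayes_cum: Sequence[float],
    frac: float,
    mode: str = "sustained",
) -> Optional[int]:
    """Learning-speed criterion against the paired Bayes reference.

    ``mode="first"``: the smallest 1-based step t with
    ``agent_cum[t] >= frac * bayes_cum[t]``.  A lucky early streak can
    trigger this long before learning, so the summary metrics use
    ``mode="sustained"``: the first step from which the condition holds at
    every remaining step of the evaluated horizon.  Returns ``None`` when
    the criterion is never (or never durably) met.
    """
    if not 0.0 < frac <= 1.0:
        raise ConfigError(f"frac must lie in (0, 1], got {frac}")
    a = np.asarray(agent_cum, dtype=float)
    b = np.asarray(bayes_cum, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("cumulative sequences must have equal length")
    ok = a >= frac * b
    if mode == "first":
        idx = np.flatnonzero(ok)
        return int(idx[0]) + 1 if idx.size else None
    if mode == "sustained":
        bad = np.flatnonzero(~ok)
        if bad.size == 0:
            return 1
        last_bad = int(bad[-1])
        if last_bad == len(a) - 1:
            return None
        return last_bad + 2
    raise ConfigError(f"unknown mode {mode!r}")


@dataclass
class RunSpec:
    """Everything needed to reproduce one experiment.

    ``agents`` maps agent names to zero-argument factories producing fresh
    learners; each run instantiates every agent anew.  ``sensor_names``
    label the sensors in reports (e.g. ``("V", "A")``).
    """

    env: EnvConfig
    agents: Dict[str, Callable[[], object]]
    horizon: int
    runs: int = 20
    base_seed: int = 0
    smoothing_window: int = 500
    thresholds: tuple = (0.6, 0.75, 0.9)
    sensor_names: tuple = ("V", "A")
    track_series: bool = True

    def __post_init__(self) -> None:
        if self.runs < 1 or self.horizon < 1 or self.smoothing_window < 1:
            raise ConfigError("runs, horizon and smoothing window must be positive")


@dataclass
class ExperimentResult:
    """Aggregated outcome of :func:`run_experiment`.

    Series are means over runs, one entry per step; ``steps`` holds the
    per-run steps-to-fraction values (``None`` = not reached within the
    horizon) and ``summary`` the table built from them.
    """

    spec: RunSpec
    reward_mean: Dict[str, np.ndarray]
    dominance_mean: Dict[str, np.ndarray]
    dominance_tags: Dict[str, list]
    acceptance_mean: Dict[str, np.ndarray]
    acceptance_sources: Dict[str, list]
    steps: Dict[tuple, list] = field(default_factory=dict)
    summary: Optional[pd.DataFrame] = None

    def smoothed_reward(self, name: str, window: Optional[int] = None) -> np.ndarray:
        return moving_average(self.reward_mean[name], window or self.spec.smoothing_window)

    def dominance_percent(self, name: str) -> Dict[str, float]:
        """Overall dominance share of each source, in percent."""
        labels = [tag_label(t, self.spec.sensor_names) for t in self.dominance_tags[name]]
        shares = self.dominance_mean[name].mean(axis=0) * 100.0
        return dict(zip(labels, shares.tolist()))


def run_experiment(spec: RunSpec, progress: Optional[Callable[[str], None]] = None) -> ExperimentResult:
    """Drive all agents over paired runs and aggregate the metrics."""
    env = LocalizationEnv(spec.env)
    observer = BayesObserver(spec.env.sensors, spec.env.n_positions)
    names = list(spec.agents)
    horizon = spec.horizon

    reward_sum: Dict[str, np.ndarray] = {}
    dom_sum: Dict[str, np.ndarray] = {}
    dom_tags: Dict[str, list] = {}
    acc_sum: Dict[str, np.ndarray] = {}
    acc_sources: Dict[str, list] = {}
    steps: Dict[tuple, list] = {(n, f): [] for n in names for f in spec.thresholds}
    dom_at_cross: Dict[tuple, list] = {(n, f): [] for n in names for f in spec.thresholds}

    for i in range(spec.runs):
        ss = np.random.SeedSequence(spec.base_seed + i)
        children = ss.spawn(1 + len(names))
        stream_rng = np.random.default_rng(children[0])
        streams = env.generate_streams(horizon, stream_rng)
        stimuli, readings = streams
        bayes_actions = observer.actions_for(readings)
        bayes_rewards = env.reward_vector(bayes_actions, stimuli)
        bayes_cum = np.cumsum(bayes_rewards)
        if spec.track_series:
            reward_sum.setdefault("bayes", np.zeros(horizon))
            reward_sum["bayes"] += bayes_rewards

        for name, child in zip(names, children[1:]):
            if progress:
                progress(f"run {i + 1}/{spec.runs}: {name}")
            agent = spec.agents[name]()
            traj = run_lifetime(
                env, agent, horizon, seed=0, streams=streams, rng=np.random.default_rng(child)
            )
            cum = np.cumsum(traj.rewards, dtype=float)
            n_tags = len(traj.source_tags)
            one_hot = np.eye(n_tags)[traj.dominant]
            for frac in spec.thresholds:
                s = steps_to_fraction(cum, bayes_cum, frac)
                steps[(name, frac)].append(s)
                upto = s if s is not None else horizon
                dom_at_cross[(name, frac)].append(one_hot[:upto].mean(axis=0))
            if spec.track_series:
                reward_sum.setdefault(name, np.zeros(horizon))
                reward_sum[name] += traj.rewards
                dom_sum.setdefault(name, np.zeros((horizon, n_tags)))
                dom_sum[name] += one_hot
                dom_tags[name] = traj.source_tags
                if traj.accepts.shape[1]:
                    acc_sum.setdefault(name, np.zeros(traj.accepts.shape))
                    acc_sum[name] += traj.accepts
                    acc_sources[name] = list(traj.sources)
            else:
                dom_tags[name] = traj.source_tags

    runs = float(spec.runs)
    result = ExperimentResult(
        spec=spec,
        reward_mean={k: v / runs for k, v in reward_sum.items()},
        dominance_mean={k: v / runs for k, v in dom_sum.items()},
        dominance_tags=dom_tags,
        acceptance_mean={k: v / runs for k, v in acc_sum.items()},
        acceptance_sources=acc_sources,
        steps=steps,
    )
    result.summary = _summarize(spec, steps, dom_at_cross)
    return result


def _summarize(spec: RunSpec, steps: Dict[tuple, list], dom_at_cross: Dict[tuple, list]) -> pd.DataFrame:
    """Table of mean steps-to-fraction and dominance percentages per agent.

    Runs that never reach a threshold contribute the horizon (a lower
    bound) to the mean; ``n_reached`` records how many runs crossed.
    Dominance percentages are computed over all steps up to each run's
    crossing step, then averaged over runs.
    """
    rows = []
    for (name, frac), vals in steps.items():
        reached = [v for v in vals if v is not None]
        mean_steps = float(np.mean([v if v is not None else spec.horizon for v in vals]))
        row = {
            "agent": name,
            "threshold": frac,
            "mean_steps": mean_steps,
            "n_reached": len(reached),
            "n_runs": len(vals),
        }
        doms = np.mean(dom_at_cross[(name, frac)], axis=0) * 100.0
        # dominance labels depend on the agent's source list; resolved lazily
        row["_dominance"] = doms
        rows.append(row)
    df = pd.DataFrame(rows)
    return df


def summary_table(result: ExperimentResult) -> pd.DataFrame:
    """Expand the summary with per-source dominance-percentage columns."""
    spec = result.spec
    rows = []
    for _, r in result.summary.iterrows():
        name = r["agent"]
        labels = [tag_label(t, spec.sensor_names) for t in result.dominance_tags[name]]
        row = {k: r[k] for k in ("agent", "threshold", "mean_steps", "n_reached", "n_runs")}
        for lab, v in zip(labels, r["_dominance"]):
            row[f"dom_{lab}_pct"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Canned experiment specifications
# ---------------------------------------------------------------------------


def _multi_factory(env: EnvConfig, cfg: AgentConfig) -> Callable[[], MultisensoryAgent]:
    return lambda: MultisensoryAgent(env.n_positions, env.n_positions, env.k, cfg)


def _ucb_factory(env: EnvConfig, sensors: Sequence[int], c: float) -> Callable[[], UCB1Agent]:
    return lambda: UCB1Agent(env.n_positions, env.n_positions, tuple(sensors), env.k, c=c)


def exp1_spec(
    horizon: int = 50_000,
    runs: int = 20,
    base_seed: int = 0,
    alpha: float = 0.05,
    bound: str = "student_t",
    ucb_c: float = 0.2,
    sigma_visual: float = 1.0,
    sigma_auditory: float = 2.0,
    agents: Optional[Sequence[str]] = None,
) -> RunSpec:
    """Two Gaussian sensors (visual and auditory): the core task.

    Roster: single-sensor UCB1 agents, the joint-space UCB1 agent, and the
    interval-selection learners (MOS and LUS) with the requested bound.
    """
    env = EnvConfig(
        sensors=(SensorModel("gaussian", sigma_visual), SensorModel("gaussian", sigma_auditory))
    )
    roster: Dict[str, Callable[[], object]] = {
        "visual": _ucb_factory(env, (1,), ucb_c),
        "auditory": _ucb_factory(env, (2,), ucb_c),
        "joint_ucb1": _ucb_factory(env, (1, 2), ucb_c),
        "mos": _multi_factory(env, AgentConfig(bound=bound, alpha=alpha, policy="mos")),
        "lus": _multi_factory(env, AgentConfig(bound=bound, alpha=alpha, policy="lus")),
    }
    if agents is not None:
        roster = {k: roster[k] for k in agents}
    return RunSpec(env=env, agents=roster, horizon=horizon, runs=runs, base_seed=base_seed,
                   smoothing_window=500, sensor_names=("V", "A"))


def exp2_spec(
    horizon: int = 100_000,
    runs: int = 10,
    base_seed: int = 0,
    alpha: float = 0.05,
    bound: str = "student_t",
    ucb_c: float = 0.2,
    policy: str = "mos",
    powerset: bool = False,
    agents: Optional[Sequence[str]] = None,
) -> RunSpec:
    """Visual and auditory sensors plus a pure-noise third sensor.

    The uninformative sensor blows up the joint space thirty-fold and tests
    whether the generalization test filters an entirely unreliable source.
    ``powerset=True`` tracks every proper sensor pair as well (the
    power-set extension).
    """
    env = EnvConfig(
        sensors=(
            SensorModel("gaussian", 1.0),
            SensorModel("gaussian", 2.0),
            SensorModel("uniform_noise"),
        )
    )
    roster: Dict[str, Callable[[], object]] = {
        "joint_ucb1": _ucb_factory(env, (1, 2, 3), ucb_c),
        policy: _multi_factory(env, AgentConfig(bound=bound, alpha=alpha, policy=policy, powerset=powerset)),
    }
    if agents is not None:
        roster = {k: roster[k] for k in agents}
    return RunSpec(env=env, agents=roster, horizon=horizon, runs=runs, base_seed=base_seed,
                   smoothing_window=1000, sensor_names=("V", "A", "N"))


def failure_spec(
    pre_steps: int = 100_000,
    post_steps: int = 100_000,
    runs: int = 10,
    base_seed: int = 0,
    alpha: float = 0.05,
    bound: str = "student_t",
    policy: str = "mos",
) -> RunSpec:
    """Abrupt sensor failure: the visual sensor becomes uniform noise mid-run.

    The failure is scheduled after the integration-dominant regime has set
    in (``pre_steps``); the run continues for ``post_steps`` more steps.
    """
    env = EnvConfig(
        sensors=(SensorModel("gaussian", 1.0), SensorModel("gaussian", 2.0)),
        failure_schedule=(1, pre_steps),
    )
    roster = {policy: _multi_factory(env, AgentConfig(bound=bound, alpha=alpha, policy=policy))}
    return RunSpec(env=env, agents=roster, horizon=pre_steps + post_steps, runs=runs,
                   base_seed=base_seed, smoothing_window=500, sensor_names=("V", "A"))


def alpha_sweep(
    alphas: Sequence[float] = (0.05, 0.25, 0.45, 0.80),
    horizon: int = 50_000,
    runs: int = 10,
    base_seed: int = 0,
    bound: str = "student_t",
    progress: Optional[Callable[[str], None]] = None,
) -> Dict[float, ExperimentResult]:
    """Sensitivity of the selection-to-integration switch to the confidence
    coefficient: smaller alpha means wider intervals, an easier test for the
    sensors, and a later switch to integration."""
    out = {}
    for a in alphas:
        spec = exp1_spec(horizon=horizon, runs=runs, base_seed=base_seed, alpha=a,
                         bound=bound, agents=("mos",))
        out[a] = run_experiment(spec, progress=progress)
    return out
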
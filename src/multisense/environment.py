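"""Audiovisual localization simulator.

A stimulus appears uniformly at random at one of ``n_positions`` discrete
grid positions (default 30).  Each sensor returns a noisy reading of it:
Gaussian sensors add zero-mean noise with a per-sensor SD (in grid units),
round half-up and clamp to the grid; a ``uniform_noise`` sensor returns a
grid position uniformly at random, independent of the stimulus (a sensor
with no information — the "lowest possible reliability").

The agent then picks one of the ``n_positions`` positions as its localization
response and is rewarded when the response falls within ``reward_radius``
grid units of the stimulus (default 3): binary 1/0 by default, or a linear
graded alternative that decays with distance.

An optional failure schedule models an abrupt non-stationary change: at a
scheduled step one sensor's model is replaced by uniform noise for the rest
of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .stats import ConfigError

__all__ = [
    "SensorModel",
    "EnvConfig",
    "LocalizationEnv",
    "sample_stimulus",
    "observe",
    "reward",
    "apply_failure",
]


@dataclass(frozen=True)
class SensorModel:
    """Noise model of one sensor: Gaussian with SD ``sigma``, or pure uniform noise."""

    kind: str = "gaussian"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "uniform_noise"):
            raise ConfigError(f"unknown sensor kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ConfigError("gaussian sensor requires sigma > 0")


def _default_sensors() -> tuple[SensorModel, ...]:
    # visual (reliable) and auditory (noisier) sensors, SDs in grid units
    return (SensorModel("gaussian", 1.0), SensorModel("gaussian", 2.0))


@dataclass(frozen=True)
class EnvConfig:
    """Localization-task configuration.

    ``failure_schedule`` is ``(sensor_index, step)`` with a 1-based sensor
    index: from ``step`` (0-based) onward that sensor becomes uniform noise.
    """

    n_positions: int = 30
    reward_radius: int = 3
    reward_shape: str = "binary"
    sensors: tuple[SensorModel, ...] = field(default_factory=_default_sensors)
    failure_schedule: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise ConfigError("need at least two positions")
        if self.reward_radius < 0:
            raise ConfigError("reward radius must be non-negative")
        if self.reward_shape not in ("binary", "linear"):
            raise ConfigError(f"unknown reward shape {self.reward_shape!r}")
        if self.failure_schedule is not None:
            sensor, step = self.failure_schedule
            if not 1 <= sensor <= len(self.sensors):
                raise ConfigError(f"failure schedule references sensor {sensor}")
            if step < 0:
                raise ConfigError("failure step must be non-negative")

    @property
    def k(self) -> int:
        return len(self.sensors)


def sample_stimulus(cfg: EnvConfig, rng: np.random.Generator) -> int:
    """Uniform stimulus position on ``[1, n_positions]``."""
    return int(rng.integers(1, cfg.n_positions + 1))


def observe(stimulus: int, model: SensorModel, rng: np.random.Generator, n_positions: int = 30) -> int:
    """One noisy reading of the stimulus under a sensor model.

    Gaussian: round-half-up(stimulus + N(0, sigma)) clamped (not wrapped) to
    the grid.  Uniform noise: a grid position independent of the stimulus.
    """
    if model.kind == "uniform_noise":
        return int(rng.integers(1, n_positions + 1))
    raw = stimulus + rng.normal(0.0, model.sigma)
    pos = int(np.floor(raw + 0.5))
    return min(max(pos, 1), n_positions)


def reward(action: int, stimulus: int, cfg: EnvConfig) -> float:
    """Localization reward: positive iff ``|action - stimulus| <= reward_radius``.

    ``binary``: 1 within the radius, 0 outside.  ``linear``:
    ``(radius + 1 - d) / (radius + 1)`` within the radius — still strictly
    positive at ``d = radius`` and maximal (1) at ``d = 0``.
    """
    for pos in (action, stimulus):
        if not 1 <= pos <= cfg.n_positions:
            raise ValueError(f"position {pos} outside grid [1, {cfg.n_positions}]")
    d = abs(action - stimulus)
    if d > cfg.reward_radius:
        return 0.0
    if cfg.reward_shape == "binary":
        return 1.0
    return (cfg.reward_radius + 1 - d) / (cfg.reward_radius + 1)


def apply_failure(cfg: EnvConfig, step: int) -> EnvConfig:
    """Sensor models in force at a given step under the failure schedule.

    At and after the scheduled step the scheduled sensor's model becomes
    uniform noise; other sensors (and everything else) are unchanged.  With
    no schedule this is the identity.
    """
    if cfg.failure_schedule is None:
        return cfg
    sensor, fail_step = cfg.failure_schedule
    if step < fail_step:
        return cfg
    sensors = list(cfg.sensors)
    sensors[sensor - 1] = SensorModel("uniform_noise")
    return replace(cfg, sensors=tuple(sensors))


class LocalizationEnv:
    """Stream-oriented view of the task: pre-generates paired stimulus and
    reading arrays so every agent in a comparison sees the identical world.
    """

    def __init__(self, cfg: EnvConfig = EnvConfig()) -> None:
        self.cfg = cfg

    def generate_streams(
        self, horizon: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """``(stimuli, readings)`` for a whole run.

        ``stimuli`` has shape ``(horizon,)``; ``readings`` has shape
        ``(horizon, k)``.  The failure schedule, if any, is applied: the
        failed sensor's readings are uniform noise from the scheduled step.
        """
        if horizon < 1:
            raise ConfigError("horizon must be at least 1")
        cfg = self.cfg
        stimuli = rng.integers(1, cfg.n_positions + 1, size=horizon)
        readings = np.empty((horizon, cfg.k), dtype=np.int64)
        for j, model in enumerate(cfg.sensors):
            if model.kind == "uniform_noise":
                readings[:, j] = rng.integers(1, cfg.n_positions + 1, size=horizon)
            else:
                raw = stimuli + rng.normal(0.0, model.sigma, size=horizon)
                readings[:, j] = np.clip(np.floor(raw + 0.5).astype(np.int64), 1, cfg.n_positions)
        if cfg.failure_schedule is not None:
            sensor, step = cfg.failure_schedule
            if step < horizon:
                m = horizon - step
                readings[step:, sensor - 1] = rng.integers(1, cfg.n_positions + 1, size=m)
        return stimuli, readings

    def reward_vector(self, actions: np.ndarray, stimuli: np.ndarray) -> np.ndarray:
        """Vectorised reward for paired action/stimulus arrays."""
        d = np.abs(np.asarray(actions) - np.asarray(stimuli))
        cfg = self.cfg
        if cfg.reward_shape == "binary":
            return (d <= cfg.reward_radius).astype(float)
        out = (cfg.reward_radius + 1 - d) / (cfg.reward_radius + 1)
        return np.where(d <= cfg.reward_radius, out, 0.0)
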
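"""Configuration, RNG stream management and result serialization.

Reproducibility contract: a run is fully determined by (config, seed).
Every afferent fiber draws from its own named, independent RNG substream
(exc_00..exc_19, inh_00..inh_07) derived from the master seed, the
experiment and the condition index, so the exact same input realization
can be delivered to all six model variants and regenerated later.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EXPERIMENT_STREAM_IDS",
    "fiber_seed_sequence",
    "fiber_rngs",
    "RunConfig",
    "load_config",
    "write_tuning_curve",
    "read_tuning_curve",
    "write_criteria_report",
    "read_criteria_report",
    "write_spike_train",
    "read_spike_train",
    "write_voltage_trace",
    "read_voltage_trace",
]

#: Stable stream identifiers keeping the experiments' randomness disjoint.
EXPERIMENT_STREAM_IDS = {"phase": 0, "ild": 1, "am": 2, "isi": 3, "custom": 9}


def fiber_seed_sequence(
    seed: int, experiment_id: int, condition_index: int, fiber_index: int
) -> np.random.SeedSequence:
    """Seed sequence of one fiber's private substream."""
    return np.random.SeedSequence(
        entropy=int(seed),
        spawn_key=(int(experiment_id), int(condition_index), int(fiber_index)),
    )


def fiber_rngs(
    seed: int,
    experiment_id: int,
    condition_index: int,
    n_exc: int = 20,
    n_inh: int = 8,
) -> dict[str, np.random.Generator]:
    """Named independent generators for all afferent fibers of a condition.

    Keys are ``exc_00``..``exc_{n_exc-1}`` and ``inh_00``..; excitatory
    fibers occupy fiber indices 0..n_exc-1, inhibitory the following ones,
    so changing one fiber's stream never perturbs the others.
    """
    rngs: dict[str, np.random.Generator] = {}
    for i in range(n_exc):
        rngs[f"exc_{i:02d}"] = np.random.default_rng(
            fiber_seed_sequence(seed, experiment_id, condition_index, i)
        )
    for i in range(n_inh):
        rngs[f"inh_{i:02d}"] = np.random.default_rng(
            fiber_seed_sequence(seed, experiment_id, condition_index, n_exc + i)
        )
    return rngs


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_VALID_MODELS = ("PLk", "PSp", "PEx", "ALk", "ASp", "AEx")
_VALID_EXPERIMENTS = ("phase", "ild", "am", "isi")


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one experiment run."""

    model: str
    experiment: str
    fm: float = 300.0
    ipsi_level: float = 35.0
    dt: float = 0.002
    duration: float = 40_000.0
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.model not in _VALID_MODELS:
            problems.append(
                f"model: {self.model!r} is not one of {list(_VALID_MODELS)}"
            )
        if self.experiment not in _VALID_EXPERIMENTS:
            problems.append(
                f"experiment: {self.experiment!r} is not one of "
                f"{list(_VALID_EXPERIMENTS)}"
            )
        if not 0 < self.dt <= 0.01:
            problems.append(f"dt: {self.dt} outside (0, 0.01] ms")
        if self.duration <= 0:
            problems.append("duration: must be positive (ms)")
        if self.fm < 0:
            problems.append("fm: must be non-negative (Hz)")
        if problems:
            raise ConfigError(problems)


class ConfigError(ValueError):
    """Invalid run configuration; lists every offending key."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration: " + "; ".join(problems))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing optional keys are filled with defaults; unknown keys are
    rejected.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError([f"{path}: expected a key-value mapping"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError([f"unknown keys: {unknown}"])
    missing = {"model", "experiment"} - set(data)
    if missing:
        raise ConfigError([f"missing required keys: {sorted(missing)}"])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Serialization (CSV/JSON round-trips)
# ---------------------------------------------------------------------------


def write_tuning_curve(curve, path: str | Path) -> None:
    """Tuning curve as CSV with abscissa and rate columns."""
    df = pd.DataFrame(
        {curve.abscissa_name: curve.abscissa, "rate_spk_per_s": curve.rates}
    )
    df.to_csv(path, index=False)


def read_tuning_curve(path: str | Path):
    from .experiments import TuningCurve

    df = pd.read_csv(path)
    name = df.columns[0]
    return TuningCurve(
        abscissa=df[name].to_numpy(float),
        rates=df["rate_spk_per_s"].to_numpy(float),
        abscissa_name=name,
    )


def write_criteria_report(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_criteria_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_spike_train(train, path: str | Path) -> None:
    """Spike train as CSV (one time per row, full float precision)."""
    df = pd.DataFrame({"time_ms": train.times})
    df.to_csv(path, index=False)


def read_spike_train(path: str | Path, duration: float | None = None):
    from .neuron_models import SpikeTrain

    df = pd.read_csv(path)
    times = df["time_ms"].to_numpy(float)
    if duration is None:
        duration = float(times[-1]) if len(times) else 0.0
    return SpikeTrain(times=times, duration=duration)


def write_fiber_trains(trains: dict, path: str | Path) -> None:
    """All fiber trains of one condition as CSV (fiber_id, time_ms)."""
    frames = [
        pd.DataFrame({"fiber_id": name, "time_ms": train.times})
        for name, train in trains.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fiber_trains(path: str | Path, duration: float) -> dict:
    from .neuron_models import SpikeTrain

    df = pd.read_csv(path)
    return {
        str(name): SpikeTrain(
            times=np.sort(group["time_ms"].to_numpy(float)), duration=duration
        )
        for name, group in df.groupby("fiber_id")
    }


def write_voltage_trace(trace, path: str | Path) -> None:
    df = pd.DataFrame({"time_ms": trace.times, "V_mV": trace.values})
    df.to_csv(path, index=False)


def read_voltage_trace(path: str | Path):
    from .neuron_models import VoltageTrace

    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(float)
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return VoltageTrace(dt=dt, values=df["V_mV"].to_numpy(float), t0=float(t[0]))
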
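"""Integrate-and-fire models of LSO principal neurons.

Six single-compartment model variants are supported, spanning two membrane
types and three spike-generation mechanisms:

=========  ========  ==============================================
variant    membrane  spike generation
=========  ========  ==============================================
``PLk``    passive   threshold crossing + voltage reset
``PSp``    passive   threshold crossing + spike-mimicking current
``PEx``    passive   exponential spike-generating current + reset
``ALk``    active    threshold crossing + voltage reset
``ASp``    active    threshold crossing + spike-mimicking current
``AEx``    active    exponential spike-generating current + reset
=========  ========  ==============================================

"Active" membranes carry a low-voltage-activated potassium (KLVA)
conductance with first-order gating; "passive" membranes are plain RC
circuits. The membrane equation

    C dV/dt = I_synE + I_synI + I_L [+ I_K] [+ I_exp] [+ I_spike]

is integrated with the forward Euler method (default step 2 us). All
quantities use mV / ms / nS / pF / pA; spike-current amplitudes quoted in
nA by convention are stored in pA (x1000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._kernels import EXP_ARG_CEIL, integrate_membrane

__all__ = [
    "ModelVariant",
    "MembraneParams",
    "NeuronState",
    "VoltageTrace",
    "SpikeTrain",
    "PRESETS",
    "default_params",
    "load_params",
    "klva_rates",
    "klva_steady_state",
    "exp_current",
    "spike_current",
    "total_current",
    "step",
    "simulate",
    "resting_potential",
    "SimulationError",
]

#: Default Euler step (ms); steps up to MAX_DT remain acceptably accurate.
DEFAULT_DT = 0.002
MAX_DT = 0.01

#: Spike-current onsets older than this many tau_2 are dropped from the
#: explicit per-step state (relative residual < 5e-5).
SPIKE_CURRENT_HORIZON = 10.0

E_SYN_EXC_DEFAULT = 0.0
E_SYN_INH_DEFAULT = -75.0


class SimulationError(RuntimeError):
    """Numerical failure (non-finite voltage) during integration."""


class ModelVariant(str, Enum):
    """The six LSO model variants."""

    PLk = "PLk"
    PSp = "PSp"
    PEx = "PEx"
    ALk = "ALk"
    ASp = "ASp"
    AEx = "AEx"

    @property
    def is_active(self) -> bool:
        """True when the membrane carries the KLVA conductance."""
        return self in (ModelVariant.ALk, ModelVariant.ASp, ModelVariant.AEx)

    @property
    def has_exp_current(self) -> bool:
        return self in (ModelVariant.PEx, ModelVariant.AEx)

    @property
    def has_spike_current(self) -> bool:
        return self in (ModelVariant.PSp, ModelVariant.ASp)

    @property
    def resets_voltage(self) -> bool:
        """Leaky/exponential variants reset and clamp V after a spike;
        spike-current variants leave V free."""
        return not self.has_spike_current


@dataclass(frozen=True)
class MembraneParams:
    """All constants of one model variant.

    Units: C pF, conductances nS, potentials mV, times ms, spike-current
    amplitudes pA.
    """

    C: float = 24.0
    g_L: float = 26.4
    E_L: float = -60.0
    g_K: float = 0.0
    E_K: float = -75.0
    g_T: float = 0.0
    V_T: float = 0.0
    K_T: float = 1.0
    V_th: float = -45.1
    V_ref: float = -60.0
    T_ref: float = 2.0
    A_1: float = 0.0
    A_2: float = 0.0
    tau_1: float = 0.17
    tau_2: float = 0.37

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.g_L > 0):
            raise ValueError("C and g_L must be positive")
        if self.g_K < 0 or self.g_T < 0:
            raise ValueError("conductances must be non-negative")
        if self.g_T > 0 and self.K_T <= 0:
            raise ValueError("K_T must be positive when g_T > 0")
        if self.T_ref < 0:
            raise ValueError("T_ref must be non-negative")
        if self.V_ref >= self.V_th:
            raise ValueError("V_ref must lie below V_th")
        if (self.A_1 != 0 or self.A_2 != 0) and not (
            self.tau_1 > 0 and self.tau_2 > 0
        ):
            raise ValueError("spike-current time constants must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "MembraneParams":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown membrane parameters: {sorted(unknown)}")
        return cls(**data)


def _passive(**kw) -> MembraneParams:
    return MembraneParams(g_L=26.4, E_L=-60.0, **kw)


def _active(**kw) -> MembraneParams:
    return MembraneParams(g_L=14.4, E_L=-56.0, g_K=21.6, E_K=-75.0, **kw)


#: Shipped parameter presets for the six variants.
PRESETS: dict[ModelVariant, MembraneParams] = {
    ModelVariant.PLk: _passive(V_th=-45.1),
    ModelVariant.PSp: _passive(
        V_th=-45.1, A_1=24_000.0, A_2=12_000.0, tau_1=0.17, tau_2=0.37
    ),
    ModelVariant.PEx: _passive(g_T=26.4, V_T=-46.6, K_T=1.8, V_th=-10.0),
    ModelVariant.ALk: _active(V_th=-45.8),
    ModelVariant.ASp: _active(
        V_th=-45.8, A_1=24_000.0, A_2=12_000.0, tau_1=0.15, tau_2=0.30
    ),
    ModelVariant.AEx: _active(g_T=26.4, V_T=-47.3, K_T=1.8, V_th=-10.0),
}


def default_params(variant: ModelVariant | str) -> MembraneParams:
    """Shipped parameter preset for ``variant``."""
    return PRESETS[ModelVariant(variant)]


def load_params(path: str | Path) -> MembraneParams:
    """Load membrane parameters from a YAML or JSON key-value file.

    A string value naming a preset (e.g. ``"ALk"``) may be given under the
    key ``preset``; remaining keys override individual fields.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    preset = data.pop("preset", None)
    if preset is not None:
        base = default_params(preset)
        return replace(base, **data) if data else base
    return MembraneParams.from_dict(data)


@dataclass
class NeuronState:
    """Mutable integration state of one model neuron."""

    V: float
    d: float = 0.0
    refractory_until: float = -np.inf
    spike_onsets: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane-potential trace."""

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) over a simulation of given duration (ms)."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if len(times) and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if len(times) and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return 1000.0 * len(self.times) / self.duration


# ---------------------------------------------------------------------------
# KLVA gating and variant-specific currents
# ---------------------------------------------------------------------------


def klva_rates(V):
    """KLVA opening/closing rates (1/ms) at potential ``V`` (mV)."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    alpha = 0.5 * np.exp((V + 50.0) / 16.0)
    beta = 0.5 * np.exp(-(V + 50.0) / 16.0)
    return alpha, beta


def klva_steady_state(V):
    """Steady-state open fraction and time constant (ms) of KLVA gating."""
    alpha, beta = klva_rates(V)
    return alpha / (alpha + beta), 1.0 / (alpha + beta)


def _klva_dinf_slope(V: float) -> float:
    """dd_inf/dV (1/mV); d_inf is logistic in V with slope scale 8 mV."""
    d_inf, _ = klva_steady_state(V)
    return float(d_inf) * (1.0 - float(d_inf)) / 8.0


def exp_current(V, p: MembraneParams):
    """Exponential spike-generating current (pA); zero when g_T = 0."""
    if p.g_T == 0.0:
        return np.zeros_like(np.asarray(V, dtype=float))[()]
    arg = np.minimum((np.asarray(V, dtype=float) - p.V_T) / p.K_T, EXP_ARG_CEIL)
    return p.g_T * p.K_T * np.exp(arg)


def spike_current(t: float, onsets, p: MembraneParams) -> float:
    """Spike-mimicking current (pA) at time ``t`` from past onsets.

    Onsets more than ``SPIKE_CURRENT_HORIZON * tau_2`` in the past are
    ignored (their contribution has decayed below 5e-5 relative).
    """
    total = 0.0
    for s in onsets:
        lag = t - s
        if lag < 0 or lag > SPIKE_CURRENT_HORIZON * p.tau_2:
            continue
        total += p.A_1 * np.exp(-lag / p.tau_1) - p.A_2 * np.exp(-lag / p.tau_2)
    return total


def total_current(
    state: NeuronState,
    g_E: float,
    g_I: float,
    p: MembraneParams,
    variant: ModelVariant,
    t: float = 0.0,
    e_syn_exc: float = E_SYN_EXC_DEFAULT,
    e_syn_inh: float = E_SYN_INH_DEFAULT,
    bias: float = 0.0,
) -> float:
    """Total membrane current I_all (pA) for the given variant."""
    variant = ModelVariant(variant)
    if g_E < 0 or g_I < 0:
        raise ValueError("synaptic conductances must be non-negative")
    V = state.V
    current = (
        g_E * (e_syn_exc - V)
        + g_I * (e_syn_inh - V)
        + p.g_L * (p.E_L - V)
        + bias
    )
    if variant.is_active:
        current += p.g_K * state.d * (p.E_K - V)
    if variant.has_exp_current:
        current += float(exp_current(V, p))
    if variant.has_spike_current:
        current += spike_current(t, state.spike_onsets, p)
    return current


def step(
    state: NeuronState,
    g_E: float,
    g_I: float,
    p: MembraneParams,
    variant: ModelVariant,
    t: float,
    dt: float,
    e_syn_exc: float = E_SYN_EXC_DEFAULT,
    e_syn_inh: float = E_SYN_INH_DEFAULT,
    bias: float = 0.0,
    detect: bool = True,
) -> tuple[NeuronState, bool]:
    """Advance the state one Euler step from t to t + dt.

    Reference scalar implementation of the integration rule; `simulate`
    runs the identical rule in a compiled loop. During the refractory
    window of resetting variants, V is clamped at V_ref while the KLVA
    gate keeps integrating at the clamped potential.
    """
    variant = ModelVariant(variant)
    if not (0 < dt <= MAX_DT):
        raise ValueError(f"dt must be in (0, {MAX_DT}] ms")
    t_new = t + dt
    clamped = variant.resets_voltage and t_new < state.refractory_until

    if variant.is_active:
        alpha, beta = klva_rates(state.V)
        d_new = state.d + dt * (alpha * (1.0 - state.d) - beta * state.d)
        d_new = min(max(float(d_new), 0.0), 1.0)
    else:
        d_new = state.d

    if clamped:
        v_new = p.V_ref
    else:
        current = total_current(
            state, g_E, g_I, p, variant, t, e_syn_exc, e_syn_inh, bias
        )
        v_new = state.V + dt * current / p.C
    if not np.isfinite(v_new):
        raise SimulationError(f"non-finite V at t={t_new:.6g} ms (dt={dt} ms)")

    onsets = [
        s
        for s in state.spike_onsets
        if t_new - s <= SPIKE_CURRENT_HORIZON * p.tau_2
    ]
    ref_until = state.refractory_until
    spiked = False
    if detect and v_new >= p.V_th and t_new >= ref_until:
        spiked = True
        ref_until = t_new + p.T_ref
        if variant.resets_voltage:
            v_new = p.V_ref
        else:
            onsets.append(t_new)

    return NeuronState(V=v_new, d=d_new, refractory_until=ref_until,
                       spike_onsets=onsets), spiked


# ---------------------------------------------------------------------------
# Resting state and full simulation
# ---------------------------------------------------------------------------


def resting_potential(variant: ModelVariant | str,
                      p: MembraneParams | None = None) -> float:
    """Resting potential (mV): zero of the input-free steady-state current.

    For active variants the KLVA gate is held at its steady state; for
    exponential variants the (tiny, at rest) exponential current is
    included.
    """
    variant = ModelVariant(variant)
    if p is None:
        p = default_params(variant)

    def steady_current(V: float) -> float:
        current = p.g_L * (p.E_L - V)
        if variant.is_active:
            d_inf, _ = klva_steady_state(V)
            current += p.g_K * float(d_inf) * (p.E_K - V)
        if variant.has_exp_current:
            current += float(exp_current(V, p))
        return current

    hi = p.V_T - 1.0 if variant.has_exp_current else -20.0
    return float(brentq(steady_current, -90.0, hi, xtol=1e-10))


def initial_state(variant: ModelVariant | str,
                  p: MembraneParams | None = None) -> NeuronState:
    """Rest-state initial conditions (V at rest, KLVA gate at steady state)."""
    variant = ModelVariant(variant)
    if p is None:
        p = default_params(variant)
    v0 = resting_potential(variant, p)
    d0, _ = klva_steady_state(v0)
    return NeuronState(V=v0, d=float(d0) if variant.is_active else 0.0)


def simulate(
    variant: ModelVariant | str,
    p: MembraneParams | None = None,
    g_exc: np.ndarray | None = None,
    g_inh: np.ndarray | None = None,
    *,
    dt: float = DEFAULT_DT,
    record_voltage: bool = False,
    bias: np.ndarray | None = None,
    detect: bool = True,
    e_syn_exc: float = E_SYN_EXC_DEFAULT,
    e_syn_inh: float = E_SYN_INH_DEFAULT,
    state0: NeuronState | None = None,
) -> tuple[SpikeTrain, VoltageTrace | None]:
    """Integrate one model over sampled conductance traces.

    Parameters
    ----------
    g_exc, g_inh
        Total synaptic conductance traces (nS) sampled on the dt grid; they
        must have equal length n, covering t in [0, n*dt).
    bias
        Optional injected current trace (pA) of the same length.
    detect
        Disable to study the subthreshold membrane alone (no spikes,
        no resets).
    state0
        Initial state; defaults to the variant's resting state.

    Returns
    -------
    (SpikeTrain, VoltageTrace or None)
    """
    variant = ModelVariant(variant)
    if p is None:
        p = default_params(variant)
    if not (0 < dt <= MAX_DT):
        raise ValueError(f"dt must be in (0, {MAX_DT}] ms")
    if g_exc is None and g_inh is None and bias is not None:
        g_exc = np.zeros_like(bias)
    if g_exc is None or g_inh is None:
        if g_exc is None and g_inh is not None:
            g_exc = np.zeros_like(g_inh)
        elif g_inh is None and g_exc is not None:
            g_inh = np.zeros_like(g_exc)
        else:
            raise ValueError("at least one input trace is required")
    g_exc = np.ascontiguousarray(g_exc, dtype=np.float64)
    g_inh = np.ascontiguousarray(g_inh, dtype=np.float64)
    if g_exc.shape != g_inh.shape or g_exc.ndim != 1:
        raise ValueError("conductance traces must be 1-D and equally long")
    if bias is None:
        bias_arr = np.empty(0, dtype=np.float64)
    else:
        bias_arr = np.ascontiguousarray(bias, dtype=np.float64)
        if bias_arr.shape != g_exc.shape:
            raise ValueError("bias trace length must match conductance traces")

    if state0 is None:
        state0 = initial_state(variant, p)

    spike_times, n_spk, v_trace, _d, err = integrate_membrane(
        g_exc,
        g_inh,
        bias_arr,
        dt,
        p.C,
        p.g_L,
        p.E_L,
        p.g_K,
        p.E_K,
        p.g_T,
        p.V_T,
        p.K_T,
        p.V_th,
        p.V_ref,
        p.T_ref,
        p.A_1,
        p.A_2,
        p.tau_1,
        p.tau_2,
        e_syn_exc,
        e_syn_inh,
        variant.is_active,
        variant.has_exp_current,
        variant.has_spike_current,
        state0.V,
        state0.d,
        detect,
        record_voltage,
    )
    if err >= 0:
        raise SimulationError(
            f"non-finite V at t={(err + 1) * dt:.6g} ms (dt={dt} ms)"
        )
    duration = len(g_exc) * dt
    # accumulated step times can exceed n*dt by a few ulp
    train = SpikeTrain(
        times=np.minimum(spike_times[:n_spk], duration), duration=duration
    )
    trace = VoltageTrace(dt=dt, values=v_trace) if record_voltage else None
    return train, trace
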
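"""Common synaptic input stage for the LSO models.

Each model neuron receives 20 excitatory and 8 inhibitory afferent fibers.
Fiber spike trains are (in)homogeneous Poisson processes; phase locking to
the envelope of an amplitude-modulated (AM) tone is modelled with a von
Mises intensity profile whose concentration is chosen to reproduce a
prescribed vector strength. Empirical descriptive functions map stimulus
parameters to per-fiber drive:

* AM tones at fixed level: rate(fm) = 180 - 0.03 fm spikes/s and a
  modulation-frequency-dependent vector strength that vanishes at 2 kHz.
* Unmodulated tones: a sigmoidal rate-level function between 30 and
  270 spikes/s (non-phase-locked).

Each input spike contributes an alpha-function conductance transient; all
fibers of one polarity sum into a single total conductance trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, i0e, i1e

from ._kernels import add_alpha_kernel
from .neuron_models import SpikeTrain

__all__ = [
    "SynapseParams",
    "FiberDrive",
    "EXCITATORY",
    "INHIBITORY",
    "SPONTANEOUS_RATE",
    "am_rate",
    "am_vs",
    "level_rate",
    "vs_to_kappa",
    "bessel_ratio",
    "generate_fiber_train",
    "conductance_trace",
    "synaptic_current",
    "vector_strength",
]

#: Spontaneous afferent rate (spikes/s) used for unstimulated inhibition.
SPONTANEOUS_RATE = 30.0

#: Alpha-function kernels are truncated at this many tau_syn
#: (relative residual < 1e-4).
KERNEL_HORIZON = 12.0


@dataclass(frozen=True)
class SynapseParams:
    """Unitary synapse description: peak conductance A_syn (nS), alpha time
    constant tau_syn (ms), reversal potential E_syn (mV), fiber count."""

    A_syn: float
    tau_syn: float
    E_syn: float
    n_fibers: int

    def __post_init__(self) -> None:
        if self.A_syn <= 0 or self.tau_syn <= 0:
            raise ValueError("A_syn and tau_syn must be positive")
        if self.n_fibers <= 0:
            raise ValueError("n_fibers must be positive")


EXCITATORY = SynapseParams(A_syn=3.5, tau_syn=0.16, E_syn=0.0, n_fibers=20)
INHIBITORY = SynapseParams(A_syn=12.0, tau_syn=0.32, E_syn=-75.0, n_fibers=8)


@dataclass(frozen=True)
class FiberDrive:
    """Statistical description of one afferent fiber.

    rate: mean spikes/s; vs: vector strength in [0, 1); fm: modulation
    frequency in Hz (0 = unmodulated); phase_deg: locking phase in degrees.
    """

    rate: float
    vs: float = 0.0
    fm: float = 0.0
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not (0.0 <= self.vs < 1.0):
            raise ValueError("vector strength must lie in [0, 1)")


def am_rate(fm: float) -> float:
    """Per-fiber mean rate (spikes/s) for an AM tone of modulation
    frequency ``fm`` (Hz): 180 - 0.03 fm."""
    if not 0.0 <= fm <= 6000.0:
        raise ValueError("fm must lie in [0, 6000] Hz to keep the rate positive")
    return 180.0 - 0.03 * fm

def am_vs(fm: float) -> float:
    """Vector strength of AM-driven fibers; decays to 0 at fm = 2 kHz and is
    clipped at 0 beyond."""
    if fm < 0:
        raise ValueError("fm must be non-negative")
    x = (fm - 2000.0) / 500.0
    return max(0.65 * (1.0 - np.exp(x)) / (1.0 + np.exp(x)), 0.0)


def level_rate(s: float) -> float:
    """Per-fiber rate (spikes/s) for an unmodulated tone at level ``s`` dB:
    sigmoid between 30 and 270 with midpoint 20 dB, slope scale 6 dB."""
    if not np.isfinite(s):
        raise ValueError("sound level must be finite")
    return 30.0 + 240.0 * float(expit((s - 20.0) / 6.0))


def bessel_ratio(kappa: float) -> float:
    """I1(kappa)/I0(kappa): vector strength of a von Mises distribution."""
    return float(i1e(kappa) / i0e(kappa))


def vs_to_kappa(vs: float) -> float:
    """Von Mises concentration reproducing vector strength ``vs``.

    Solved to |I1/I0(kappa) - vs| < 1e-10 by bracketed root finding.
    """
    if not 0.0 <= vs < 1.0:
        raise ValueError("vector strength must lie in [0, 1)")
    if vs == 0.0:
        return 0.0
    hi = 4.0
    while bessel_ratio(hi) < vs:
        hi *= 2.0
    return float(brentq(lambda k: bessel_ratio(k) - vs, 1e-12, hi, xtol=1e-12))


def generate_fiber_train(
    drive: FiberDrive, duration: float, rng: np.random.Generator | int
) -> SpikeTrain:
    """Sample one fiber spike train over ``duration`` ms.

    Unmodulated drives (vs = 0 or fm = 0) give a homogeneous Poisson
    process at ``drive.rate``. Phase-locked drives are inhomogeneous
    Poisson with intensity

        lam(t) = rate * exp(kappa * (cos(2 pi fm t - phase) - 1)) / i0e(kappa)

    whose cycle average is ``rate`` and whose spike-phase distribution is
    von Mises with concentration ``kappa`` matched to ``drive.vs``.
    Sampling is by thinning against the intensity maximum, so realizations
    are exactly Poisson and reproducible from the generator state.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rate_per_ms = drive.rate / 1000.0
    if rate_per_ms == 0.0:
        return SpikeTrain(times=np.empty(0), duration=duration)

    if drive.vs == 0.0 or drive.fm == 0.0:
        n = rng.poisson(rate_per_ms * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n))
        return SpikeTrain(times=times, duration=duration)

    kappa = vs_to_kappa(drive.vs)
    # Envelope: lam_max = rate * exp(kappa)/I0(kappa) = rate / i0e(kappa)
    lam_max = rate_per_ms / float(i0e(kappa))
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    theta = 2.0 * np.pi * drive.fm * t_cand / 1000.0 - np.deg2rad(drive.phase_deg)
    accept_p = np.exp(kappa * (np.cos(theta) - 1.0))
    keep = rng.uniform(size=n_cand) < accept_p
    return SpikeTrain(times=t_cand[keep], duration=duration)


def conductance_trace(
    trains: list[SpikeTrain] | SpikeTrain,
    p: SynapseParams,
    dt: float,
    duration: float,
) -> np.ndarray:
    """Total synaptic conductance (nS) on the dt grid from input trains.

    Every spike contributes A_syn * (u/tau) * exp(1 - u/tau) for time lag
    u >= 0; contributions from all spikes of all fibers add linearly.
    Spike times are quantized to the grid; the unitary kernel is truncated
    at ``KERNEL_HORIZON`` tau_syn.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    n = int(round(duration / dt))
    g = np.zeros(n, dtype=np.float64)
    m = int(round(KERNEL_HORIZON * p.tau_syn / dt)) + 1
    lag = dt * np.arange(m) / p.tau_syn
    kernel = p.A_syn * lag * np.exp(1.0 - lag)
    for train in trains:
        if len(train) == 0:
            continue
        if train.times[0] < 0 or train.times[-1] > duration:
            raise ValueError("spike times must lie within [0, duration]")
        idx = np.rint(train.times / dt).astype(np.int64)
        idx = idx[idx < n]
        add_alpha_kernel(g, idx, kernel)
    return g


def synaptic_current(g, V, E_syn: float):
    """Synaptic current (pA) for conductance g (nS) at potential V (mV)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("conductance must be non-negative")
    return (g * (E_syn - np.asarray(V, dtype=float)))[()]


def vector_strength(times: np.ndarray, fm: float) -> float:
    """Empirical vector strength of spike times (ms) at frequency fm (Hz)."""
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return 0.0
    theta = 2.0 * np.pi * fm * times / 1000.0
    return float(np.abs(np.mean(np.exp(1j * theta))))
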
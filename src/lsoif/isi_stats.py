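"""Interspike-interval statistics: histograms, hazard rates, serial means.

The temporal discharge pattern of a sustained-firing LSO neuron is
characterized by three measures computed from a single long spike train:

* the ISI histogram, binned at 0.2 ms and normalized by bin width times
  total ISI count so that the density has units of 1/s;
* the hazard rate H_i = N_i / (T_bin * S_i), where S_i is the survivor
  count (ISIs at least as long as bin i); the calculation stops once S_i
  falls below 2% of the total ISI count;
* the conditional mean of ISI_{n+1} given the bin of ISI_n, reported for
  bins holding more than 0.5% of all intervals. For a renewal process
  this curve is flat at the marginal mean.

The stimulus used for these measures mirrors monaural tonal stimulation:
ipsilateral excitation at a level-dependent homogeneous rate with the
contralateral inhibition at its 30 spikes/s spontaneous floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import io as lsio
from .neuron_models import DEFAULT_DT, ModelVariant, SpikeTrain, simulate
from .synaptic_inputs import (
    EXCITATORY,
    INHIBITORY,
    SPONTANEOUS_RATE,
    FiberDrive,
    conductance_trace,
    generate_fiber_train,
    level_rate,
)

__all__ = [
    "ISIHistogram",
    "HazardFunction",
    "ConditionalMeanCurve",
    "isi_histogram",
    "hazard_rate",
    "conditional_mean",
    "isi_experiment",
]

DEFAULT_BIN_WIDTH = 0.2  # ms
HAZARD_SURVIVOR_FLOOR = 0.02
OCCUPANCY_FLOOR = 0.005


class InsufficientDataError(ValueError):
    """Too few spikes to compute the requested ISI statistic."""


@dataclass(frozen=True)
class ISIHistogram:
    """ISI counts per bin with the 1/s-normalized density.

    Bins start at 0; ``edges`` has one more element than ``counts``;
    density_i = N_i / (bin_width_in_s * sum(N)).
    """

    bin_width: float
    counts: np.ndarray
    density: np.ndarray
    edges: np.ndarray

    @property
    def n_intervals(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + 0.5 * self.bin_width


@dataclass(frozen=True)
class HazardFunction:
    """Hazard values (1/s) per bin up to the survivor-mass truncation."""

    centers: np.ndarray
    values: np.ndarray
    truncation_index: int


@dataclass(frozen=True)
class ConditionalMeanCurve:
    """Mean following interval per preceding-interval bin."""

    bin_left_edges: np.ndarray
    mean_next: np.ndarray
    occupancy: np.ndarray


def _intervals(train: SpikeTrain | np.ndarray) -> np.ndarray:
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train)
    return np.diff(times)


def isi_histogram(
    train: SpikeTrain | np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> ISIHistogram:
    """Histogram of successive interspike intervals.

    Density is normalized with the product of bin size (in seconds) and
    the total interval count, so it integrates to one over time in s.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    isis = _intervals(train)
    if len(isis) < 1:
        raise InsufficientDataError("need at least 2 spikes for an ISI histogram")
    n_bins = int(np.floor(isis.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(isis, bins=edges)
    density = counts / (bin_width * 1e-3 * counts.sum())
    return ISIHistogram(
        bin_width=bin_width, counts=counts, density=density, edges=edges
    )


def hazard_rate(hist: ISIHistogram) -> HazardFunction:
    """Hazard rate H_i = N_i / (T_bin * S_i) in 1/s.

    S_i sums the counts of bin i and all higher bins. Bins from the first
    one whose survivor count drops below 2% of the total are excluded.
    """
    counts = hist.counts.astype(float)
    total = counts.sum()
    survivors = np.cumsum(counts[::-1])[::-1]
    keep = survivors >= HAZARD_SURVIVOR_FLOOR * total
    cut = int(np.argmin(keep)) if not keep.all() else len(counts)
    h = counts[:cut] / (hist.bin_width * 1e-3 * survivors[:cut])
    return HazardFunction(
        centers=hist.centers[:cut], values=h, truncation_index=cut
    )


def conditional_mean(
    train: SpikeTrain | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    occupancy_floor: float = OCCUPANCY_FLOOR,
) -> ConditionalMeanCurve:
    """Mean of ISI_{n+1} conditioned on the bin of ISI_n.

    Only bins holding strictly more than ``occupancy_floor`` of the total
    ISI count are reported.
    """
    isis = _intervals(train)
    if len(isis) < 2:
        raise InsufficientDataError("need at least 3 spikes for serial statistics")
    prev, nxt = isis[:-1], isis[1:]
    idx = np.floor(prev / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    occupancy = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=nxt, minlength=n_bins)
    # occupancy floor counts ISI_n occurrences against the total ISI count
    floor = occupancy_floor * len(isis)
    keep = occupancy > floor
    bins = np.nonzero(keep)[0]
    return ConditionalMeanCurve(
        bin_left_edges=bins * bin_width,
        mean_next=sums[bins] / occupancy[bins],
        occupancy=occupancy[bins],
    )


def isi_experiment(
    variant: ModelVariant | str,
    ipsi_level: float = 35.0,
    duration: float = 40_000.0,
    seed: int = 0,
    *,
    dt: float = DEFAULT_DT,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[SpikeTrain, ISIHistogram, HazardFunction, ConditionalMeanCurve]:
    """Run the monaural-tone ISI characterization of one variant.

    Excitation: 20 homogeneous Poisson fibers at the level-dependent rate
    for ``ipsi_level`` dB; inhibition: 8 fibers at the 30 spikes/s
    spontaneous floor.
    """
    variant = ModelVariant(variant)
    rngs = lsio.fiber_rngs(seed, lsio.EXPERIMENT_STREAM_IDS["isi"], 0)
    exc_drive = FiberDrive(rate=level_rate(ipsi_level))
    inh_drive = FiberDrive(rate=SPONTANEOUS_RATE)
    exc = [
        generate_fiber_train(exc_drive, duration, rng)
        for name, rng in rngs.items()
        if name.startswith("exc")
    ]
    inh = [
        generate_fiber_train(inh_drive, duration, rng)
        for name, rng in rngs.items()
        if name.startswith("inh")
    ]
    g_exc = conductance_trace(exc, EXCITATORY, dt, duration)
    g_inh = conductance_trace(inh, INHIBITORY, dt, duration)
    train, _ = simulate(
        variant,
        None,
        g_exc,
        g_inh,
        dt=dt,
        e_syn_exc=EXCITATORY.E_syn,
        e_syn_inh=INHIBITORY.E_syn,
    )
    hist = isi_histogram(train, bin_width)
    return train, hist, hazard_rate(hist), conditional_mean(train, bin_width)
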
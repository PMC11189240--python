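"""Parameter-selection utilities for the exponential variants and the
refractory-period sensitivity sweep.

The exponential models' free parameters (threshold factor V_T, slope
factor K_T, detection threshold V_th; the spike-generating conductance is
fixed at 26.4 nS) are selected by grid search against the binaural
response criteria: phase-difference tuning at 300 Hz and level-difference
tuning at an ipsilateral level of 35 dB. The search runs coarse-to-fine
in V_T (0.5 mV, then 0.1 mV around coarse passers) and returns every
passing parameter set unranked — multiple combinations typically satisfy
the criteria and no "best fit" is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .experiments import (
    CriteriaRanges,
    DEFAULT_DURATION,
    ild_tuning,
    phase_tuning,
    score_criteria,
    tuning_metrics,
)
from .neuron_models import DEFAULT_DT, MembraneParams, ModelVariant, default_params

__all__ = ["GridSearchSpec", "grid_search", "refractory_sweep"]

_BINAURAL_KEYS = (
    "phase_peak",
    "phase_trough",
    "phase_depth",
    "ild_peak",
    "ild_trough",
    "ild_depth",
)


@dataclass(frozen=True)
class GridSearchSpec:
    """Search ranges for the exponential-model free parameters (mV)."""

    v_t_range: tuple[float, float] = (-50.0, -40.0)
    v_t_coarse_step: float = 0.5
    v_t_fine_step: float = 0.1
    k_t_range: tuple[float, float] = (1.2, 4.0)
    k_t_step: float = 0.2
    v_th_range: tuple[float, float] = (-30.0, 0.0)
    v_th_step: float = 5.0
    g_t: float = 26.4
    ranges: CriteriaRanges = field(default_factory=CriteriaRanges)

    def __post_init__(self) -> None:
        for lo_hi, step in (
            (self.v_t_range, self.v_t_coarse_step),
            (self.k_t_range, self.k_t_step),
            (self.v_th_range, self.v_th_step),
        ):
            if lo_hi[0] > lo_hi[1] or step <= 0:
                raise ValueError("grid ranges must be non-empty with positive steps")

    def grid_axis(self, lo: float, hi: float, step: float) -> np.ndarray:
        return np.round(np.arange(lo, hi + 0.5 * step, step), 6)


def _binaural_metrics(
    variant: ModelVariant,
    p: MembraneParams,
    duration: float,
    seed: int,
    dt: float,
    phase_fm: float,
    ild_ipsi_level: float,
) -> dict[str, float]:
    params = {variant: p}
    phase = phase_tuning(
        variant, fm=phase_fm, duration=duration, seed=seed, dt=dt, params=params
    )
    ild = ild_tuning(
        variant,
        ipsi_level=ild_ipsi_level,
        duration=duration,
        seed=seed,
        dt=dt,
        params=params,
    )
    report = score_criteria(
        tuning_metrics(phase), tuning_metrics(ild), (130.0, 15.0, 115.0)
    )
    return report.values


def _passes_binaural(
    values: dict[str, float], ranges: CriteriaRanges, level: str
) -> bool:
    bands = ranges.targeted if level == "targeted" else ranges.accepted
    return all(bands[k][0] <= values[k] <= bands[k][1] for k in _BINAURAL_KEYS)


def grid_search(
    variant: ModelVariant | str,
    spec: GridSearchSpec | None = None,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    *,
    dt: float = DEFAULT_DT,
    level: str | None = None,
    phase_fm: float = 300.0,
    ild_ipsi_level: float = 35.0,
    refine: bool = True,
) -> pd.DataFrame:
    """Search (V_T, K_T, V_th) of an exponential variant for criteria passes.

    Evaluates the six binaural measures (phase peak/trough/depth at
    ``phase_fm``, ILD peak/trough/depth at ``ild_ipsi_level``) on the
    coarse V_T grid, then (optionally) refines V_T at 0.1 mV around each
    coarse passer. Active exponential models are judged at the targeted
    level, passive ones at the accepted level, unless ``level`` overrides.

    Returns a DataFrame of every passing parameter set with its six
    metrics; the result is independent of grid enumeration order.
    """
    variant = ModelVariant(variant)
    if not variant.has_exp_current:
        raise ValueError("grid search applies to the exponential variants only")
    spec = spec or GridSearchSpec()
    if level is None:
        level = "targeted" if variant.is_active else "accepted"
    if level not in ("targeted", "accepted"):
        raise ValueError("level must be 'targeted' or 'accepted'")
    base = default_params(variant)

    def evaluate(v_t: float, k_t: float, v_th: float) -> dict[str, float] | None:
        if v_th <= -60.0:  # V_ref must stay below V_th
            return None
        p = replace(base, g_T=spec.g_t, V_T=v_t, K_T=k_t, V_th=v_th)
        return _binaural_metrics(
            variant, p, duration, seed, dt, phase_fm, ild_ipsi_level
        )

    k_t_axis = spec.grid_axis(*spec.k_t_range, spec.k_t_step)
    v_th_axis = spec.grid_axis(*spec.v_th_range, spec.v_th_step)
    coarse_axis = spec.grid_axis(*spec.v_t_range, spec.v_t_coarse_step)

    rows = []
    seen: set[tuple[float, float, float]] = set()

    def consider(v_t: float, k_t: float, v_th: float) -> bool:
        key = (round(v_t, 6), round(k_t, 6), round(v_th, 6))
        if key in seen:
            return False
        seen.add(key)
        values = evaluate(v_t, k_t, v_th)
        if values is None or not _passes_binaural(values, spec.ranges, level):
            return False
        rows.append({"V_T": key[0], "K_T": key[1], "V_th": key[2], **values})
        return True

    for v_t in coarse_axis:
        for k_t in k_t_axis:
            for v_th in v_th_axis:
                passed = consider(v_t, k_t, v_th)
                if passed and refine:
                    lo = max(spec.v_t_range[0], v_t - spec.v_t_coarse_step)
                    hi = min(spec.v_t_range[1], v_t + spec.v_t_coarse_step)
                    for v_t_fine in spec.grid_axis(lo, hi, spec.v_t_fine_step):
                        consider(v_t_fine, k_t, v_th)

    df = pd.DataFrame(
        rows, columns=["V_T", "K_T", "V_th", *_BINAURAL_KEYS]
    )
    return df.sort_values(["V_T", "K_T", "V_th"]).reset_index(drop=True)


def refractory_sweep(
    variant: ModelVariant | str,
    t_ref_grid=np.arange(1.2, 2.9, 0.4),
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    *,
    dt: float = DEFAULT_DT,
    phase_fm: float = 300.0,
    ild_ipsi_level: float = 35.0,
) -> pd.DataFrame:
    """Binaural tuning metrics as a function of the refractory period.

    Scans T_ref over the physiological bracket (LSO refractory periods
    span roughly 1.1-2.8 ms) and tabulates the peak and trough of the
    300-Hz phase-difference and 35-dB ILD tuning curves. For the resetting
    variants the ILD peak falls approximately linearly with T_ref, while
    the spike-current variants are insensitive (their recovery is governed
    by the spike-mimicking current, which outlasts the refractory period).
    """
    variant = ModelVariant(variant)
    base = default_params(variant)
    rows = []
    for t_ref in np.asarray(t_ref_grid, dtype=float):
        if t_ref < 0:
            raise ValueError("T_ref must be non-negative")
        p = replace(base, T_ref=float(t_ref))
        values = _binaural_metrics(
            variant, p, duration, seed, dt, phase_fm, ild_ipsi_level
        )
        rows.append(
            {
                "T_ref": float(t_ref),
                "phase_peak": values["phase_peak"],
                "phase_trough": values["phase_trough"],
                "ild_peak": values["ild_peak"],
                "ild_trough": values["ild_trough"],
            }
        )
    return pd.DataFrame(rows)
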
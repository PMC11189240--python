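"""Numba-compiled inner loops: forward-Euler membrane integration and
alpha-function conductance accumulation.

These kernels are implementation detail; the public API lives in
``neuron_models`` and ``synaptic_inputs``. All quantities use the internal
unit system mV / ms / nS / pF / pA (note pA/pF = mV/ms and nS*mV = pA, so
the membrane equation closes without conversion factors).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Overflow guard for the exponential spike-generating current: the argument
# of exp() is clipped here, far above any physical operating point.
EXP_ARG_CEIL = 20.0


@njit(cache=True)
def integrate_membrane(
    g_exc,
    g_inh,
    bias,
    dt,
    c_m,
    g_l,
    e_l,
    g_k,
    e_k,
    g_t,
    v_t,
    k_t,
    v_th,
    v_ref,
    t_ref,
    a_1,
    a_2,
    tau_1,
    tau_2,
    e_syn_exc,
    e_syn_inh,
    use_klva,
    use_exp,
    use_spike_current,
    v0,
    d0,
    detect,
    record_v,
):
    """Forward-Euler integration of the membrane equation.

    ``g_exc``/``g_inh`` sample the total synaptic conductances on the dt
    grid; ``bias`` is an injected-current trace in pA (length 0 = none).
    Step i advances the state from t_i = i*dt to t_{i+1} using the state
    and conductances at t_i. A spike is recorded at the first sample time
    whose voltage reaches ``v_th`` outside the refractory window.

    Returns (spike_times, n_spikes, v_trace, d_last, err_index) where
    err_index >= 0 flags a non-finite voltage at that step.
    """
    n = g_exc.shape[0]
    have_bias = bias.shape[0] == n
    resets = not use_spike_current

    if t_ref > 0.0:
        cap = int(n * dt / t_ref) + 2
    else:
        cap = n + 1
    spike_times = np.empty(cap, np.float64)
    n_spk = 0

    if record_v:
        v_trace = np.empty(n + 1, np.float64)
        v_trace[0] = v0
    else:
        v_trace = np.empty(0, np.float64)

    v = v0
    d = d0
    ref_until = -1.0e30
    # Spike-mimicking current as two exactly-decayed exponential states:
    # x1 - x2 equals the sum of Eq-type double-exponential kernels over all
    # past grid-aligned onsets, with no truncation.
    x1 = 0.0
    x2 = 0.0
    dec1 = np.exp(-dt / tau_1) if tau_1 > 0.0 else 0.0
    dec2 = np.exp(-dt / tau_2) if tau_2 > 0.0 else 0.0

    # Time accumulates additively so a scalar re-implementation stepping
    # t -> t + dt reproduces the refractory boundary comparisons exactly.
    t_new = 0.0
    for i in range(n):
        t_new = t_new + dt
        clamped = resets and (t_new < ref_until)

        if use_klva:
            alpha = 0.5 * np.exp((v + 50.0) / 16.0)
            beta = 0.5 * np.exp(-(v + 50.0) / 16.0)
            d_new = d + dt * (alpha * (1.0 - d) - beta * d)
            if d_new < 0.0:
                d_new = 0.0
            elif d_new > 1.0:
                d_new = 1.0
        else:
            d_new = d

        if clamped:
            v_new = v_ref
        else:
            current = (
                g_exc[i] * (e_syn_exc - v)
                + g_inh[i] * (e_syn_inh - v)
                + g_l * (e_l - v)
            )
            if have_bias:
                current += bias[i]
            if use_klva:
                current += g_k * d * (e_k - v)
            if use_exp:
                arg = (v - v_t) / k_t
                if arg > EXP_ARG_CEIL:
                    arg = EXP_ARG_CEIL
                current += g_t * k_t * np.exp(arg)
            if use_spike_current:
                current += x1 - x2
            v_new = v + dt * current / c_m

        if not np.isfinite(v_new):
            return spike_times, n_spk, v_trace, d, i

        if use_spike_current:
            x1 *= dec1
            x2 *= dec2

        if detect and v_new >= v_th and t_new >= ref_until:
            spike_times[n_spk] = t_new
            n_spk += 1
            ref_until = t_new + t_ref
            if resets:
                v_new = v_ref
            else:
                x1 += a_1
                x2 += a_2

        v = v_new
        d = d_new
        if record_v:
            v_trace[i + 1] = v

    return spike_times, n_spk, v_trace, d, -1


@njit(cache=True)
def add_alpha_kernel(g, spike_indices, kernel):
    """Accumulate a sampled alpha-function kernel at each spike index."""
    n = g.shape[0]
    m = kernel.shape[0]
    for k in range(spike_indices.shape[0]):
        i0 = spike_indices[k]
        stop = m
        if i0 + stop > n:
            stop = n - i0
        for j in range(stop):
            g[i0 + j] += kernel[j]
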
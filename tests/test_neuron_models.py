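"""Membrane equation, gating kinetics, spike mechanisms and integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsoif.neuron_models import (
    MembraneParams,
    ModelVariant,
    NeuronState,
    SpikeTrain,
    default_params,
    exp_current,
    initial_state,
    klva_rates,
    klva_steady_state,
    load_params,
    resting_potential,
    simulate,
    spike_current,
    step,
    total_current,
)

ALL = list(ModelVariant)


# ---------------------------------------------------------------------------
# KLVA gating
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "v, alpha, beta",
    [
        (-50.0, 0.5, 0.5),
        (-34.0, 0.5 * math.e, 0.5 / math.e),
        (-66.0, 0.5 / math.e, 0.5 * math.e),
    ],
)
def test_klva_rates_scalar_oracle(v, alpha, beta):
    a, b = klva_rates(v)
    assert a == pytest.approx(alpha, rel=1e-12)
    assert b == pytest.approx(beta, rel=1e-12)


def test_klva_rates_rejects_nonfinite():
    with pytest.raises(ValueError):
        klva_rates(float("nan"))


@settings(derandomize=True, max_examples=60)
@given(st.floats(min_value=-120.0, max_value=40.0))
def test_klva_gating_symmetry_and_bounds(v):
    a, b = klva_rates(v)
    a_sym, b_sym = klva_rates(-100.0 - v)
    assert a == pytest.approx(b_sym, rel=1e-10)
    assert b == pytest.approx(a_sym, rel=1e-10)
    d_inf, tau = klva_steady_state(v)
    assert 0.0 < d_inf < 1.0
    assert tau > 0.0


def test_klva_steady_state_values():
    d_inf, tau = klva_steady_state(-50.0)
    assert d_inf == pytest.approx(0.5)
    assert tau == pytest.approx(1.0)
    d_60, _ = klva_steady_state(-60.0)
    assert d_60 == pytest.approx(1.0 / (1.0 + math.exp(10.0 / 8.0)), rel=1e-10)
    d_high, _ = klva_steady_state(60.0)
    assert d_high > 0.999


# ---------------------------------------------------------------------------
# Spike-generation currents
# ---------------------------------------------------------------------------


def test_exp_current_at_threshold_factor():
    p = default_params("PEx")
    assert exp_current(p.V_T, p) == pytest.approx(26.4 * 1.8)
    assert exp_current(p.V_T + p.K_T, p) == pytest.approx(26.4 * 1.8 * math.e)


def test_exp_current_zero_and_overflow_guard():
    p = default_params("PLk")
    assert exp_current(-10.0, p) == 0.0
    p_ex = default_params("PEx")
    assert np.isfinite(exp_current(1e4, p_ex))


def test_spike_current_onset_and_downswing():
    p = default_params("PSp")
    assert spike_current(0.0, [0.0], p) == pytest.approx(24_000.0 - 12_000.0)
    # at lag tau_2 the slow hyperpolarizing term dominates (downswing)
    lag = p.tau_2
    expected = 24_000.0 * math.exp(-lag / p.tau_1) - 12_000.0 * math.exp(-1.0)
    value = spike_current(lag, [0.0], p)
    assert value == pytest.approx(expected, rel=1e-12)
    assert value < 0.0
    assert spike_current(100.0, [0.0], p) == 0.0


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def test_presets_follow_variant_structure():
    for variant in ALL:
        p = default_params(variant)
        assert (p.g_K > 0) == variant.is_active
        assert (p.g_T > 0) == variant.has_exp_current
        assert (p.A_1 > 0) == variant.has_spike_current
        assert p.V_ref < p.V_th
        assert p.C == 24.0 and p.V_ref == -60.0 and p.T_ref == 2.0


def test_membrane_params_validation():
    with pytest.raises(ValueError):
        MembraneParams(C=-1.0)
    with pytest.raises(ValueError):
        MembraneParams(V_ref=-40.0, V_th=-45.0)
    with pytest.raises(ValueError):
        MembraneParams(g_T=1.0, K_T=0.0)


def test_load_params_yaml_preset_and_json(tmp_path):
    y = tmp_path / "alk.yaml"
    y.write_text("preset: ALk\nT_ref: 1.6\n")
    p = load_params(y)
    assert p.g_K == 21.6 and p.T_ref == 1.6
    j = tmp_path / "p.json"
    j.write_text('{"g_L": 26.4, "E_L": -60.0, "V_th": -45.1}')
    assert load_params(j).V_th == -45.1
    bad = tmp_path / "bad.yaml"
    bad.write_text("g_X: 3\n")
    with pytest.raises(ValueError):
        load_params(bad)


# ---------------------------------------------------------------------------
# Total current
# ---------------------------------------------------------------------------


def test_total_current_scalar_oracles():
    plk = default_params("PLk")
    state = NeuronState(V=-60.0)
    assert total_current(state, 0.0, 0.0, plk, "PLk") == pytest.approx(0.0)

    alk = default_params("ALk")
    d_inf, _ = klva_steady_state(-60.0)
    state = NeuronState(V=-60.0, d=float(d_inf))
    expected = 14.4 * 4.0 + 21.6 * float(d_inf) * (-15.0)
    assert total_current(state, 0.0, 0.0, alk, "ALk") == pytest.approx(expected)

    aex = default_params("AEx")
    d_t, _ = klva_steady_state(aex.V_T)
    st_t = NeuronState(V=aex.V_T, d=float(d_t))
    alk_part = total_current(st_t, 0.0, 0.0, aex, "ALk")
    assert total_current(st_t, 0.0, 0.0, aex, "AEx") == pytest.approx(
        alk_part + 26.4 * 1.8
    )


def test_total_current_rejects_negative_conductance():
    with pytest.raises(ValueError):
        total_current(NeuronState(V=-60.0), -1.0, 0.0, default_params("PLk"), "PLk")


# ---------------------------------------------------------------------------
# Stepping and integration
# ---------------------------------------------------------------------------


def test_step_equilibrium_passive():
    p = default_params("PLk")
    state = NeuronState(V=p.E_L)
    for i in range(100):
        state, spiked = step(state, 0.0, 0.0, p, "PLk", i * 0.002, 0.002)
        assert not spiked
    assert state.V == pytest.approx(p.E_L)


def test_rc_relaxation_matches_closed_form():
    """Current-step response relaxes with tau = C/g_L toward I/g_L."""
    p = default_params("PLk")
    dt, bias = 0.002, 100.0
    n = int(5.0 / dt)
    b = np.full(n, bias)
    _, trace = simulate("PLk", p, np.zeros(n), np.zeros(n), dt=dt, bias=b,
                        record_voltage=True, detect=False)
    t = trace.times
    tau = p.C / p.g_L
    assert tau == pytest.approx(24.0 / 26.4)
    exact = p.E_L + (bias / p.g_L) * (1.0 - np.exp(-t / tau))
    assert np.max(np.abs(trace.values - exact)) < 0.02


def test_active_resting_potential_matches_root_finder():
    v_root = resting_potential("ALk")
    n = int(50.0 / 0.002)
    _, trace = simulate(
        "ALk",
        None,
        np.zeros(n),
        np.zeros(n),
        dt=0.002,
        record_voltage=True,
        state0=NeuronState(V=-60.0, d=float(klva_steady_state(-60.0)[0])),
    )
    assert abs(trace.values[-1] - v_root) < 0.05


def test_zero_input_yields_empty_train():
    for variant in ALL:
        train, _ = simulate(variant, None, np.zeros(1000), np.zeros(1000), dt=0.002)
        assert len(train) == 0


def test_constant_strong_drive_fires_periodically_at_refractory_floor():
    n = int(100.0 / 0.002)
    g = np.full(n, 100.0)
    train, _ = simulate("PLk", None, g, np.zeros(n), dt=0.002)
    isis = np.diff(train.times)
    assert len(train) > 30
    assert isis.min() >= 2.0 - 1e-9
    assert isis.max() < 2.2
    assert np.ptp(isis) < 0.01  # periodic


@pytest.mark.parametrize("variant", ALL, ids=[v.value for v in ALL])
def test_refractory_floor_under_noisy_drive(variant, drive_traces):
    g_exc, g_inh = drive_traces(300.0, 30.0, duration=1500.0, seed=7)
    train, _ = simulate(variant, None, g_exc, g_inh, dt=0.002)
    assert len(train) > 50
    assert np.diff(train.times).min() >= default_params(variant).T_ref - 1e-9


@pytest.mark.parametrize("variant", ["PLk", "ALk", "PEx", "PSp"])
def test_step_matches_compiled_simulation(variant, drive_traces):
    """The scalar reference stepper and the compiled loop agree."""
    dt = 0.002
    g_exc, g_inh = drive_traces(250.0, 30.0, duration=20.0, seed=3)
    _, trace = simulate(variant, None, g_exc, g_inh, dt=dt, record_voltage=True)
    p = default_params(variant)
    state = initial_state(variant, p)
    vs = [state.V]
    t = 0.0
    for i in range(len(g_exc)):
        state, _ = step(state, g_exc[i], g_inh[i], p, variant, t, dt)
        vs.append(state.V)
        t += dt
    # spike-current variants prune old onsets, the kernel does not
    tol = 5e-3 if ModelVariant(variant).has_spike_current else 1e-8
    assert np.max(np.abs(np.array(vs) - trace.values)) < tol


def test_passive_superposition_of_current_inputs(rng):
    """With spiking disabled the passive membrane is linear in current."""
    dt, n = 0.002, 5000
    b1 = 30.0 * np.sin(2 * np.pi * 0.3 * np.arange(n) * dt)
    b2 = rng.normal(0.0, 10.0, n)
    zeros = np.zeros(n)

    def response(bias):
        _, tr = simulate("PLk", None, zeros, zeros, dt=dt, bias=bias,
                         record_voltage=True, detect=False)
        return tr.values + 60.0

    r12 = response(b1 + b2)
    assert np.max(np.abs(r12 - response(b1) - response(b2))) < 1e-6


def test_subthreshold_trajectories_match_across_passive_variants(drive_traces):
    """Identical inputs give near-identical subthreshold traces."""
    g_exc, g_inh = drive_traces(60.0, 30.0, duration=200.0, seed=5)
    traces = {}
    for variant in ("PLk", "PSp", "PEx"):
        train, tr = simulate(variant, None, g_exc, g_inh, dt=0.002,
                             record_voltage=True)
        assert len(train) == 0  # weak drive stays subthreshold
        traces[variant] = tr.values
    assert np.max(np.abs(traces["PLk"] - traces["PSp"])) < 1e-9
    # PEx differs only by its (tiny, at subthreshold V) exponential current
    assert np.max(np.abs(traces["PLk"] - traces["PEx"])) < 0.5


def test_euler_step_halving_changes_counts_by_under_two_percent(drive_traces):
    """40-s spike counts are stable when dt drops from 2 us to 1 us."""
    duration = 40_000.0
    counts = {}
    for dt in (0.002, 0.001):
        g_exc, g_inh = drive_traces(
            251.79, 31.64, duration=duration, dt=dt, seed=11
        )
        for variant in ("PLk", "ALk"):
            train, _ = simulate(variant, None, g_exc, g_inh, dt=dt)
            counts.setdefault(variant, []).append(len(train))
    for variant, (c1, c2) in counts.items():
        assert abs(c1 - c2) / c1 < 0.02, (variant, c1, c2)


def test_simulate_rejects_mismatched_traces():
    with pytest.raises(ValueError):
        simulate("PLk", None, np.zeros(10), np.zeros(11), dt=0.002)
    with pytest.raises(ValueError):
        simulate("PLk", None, np.zeros(10), np.zeros(10), dt=0.05)


def test_spike_train_validation():
    with pytest.raises(ValueError):
        SpikeTrain(times=np.array([2.0, 1.0]), duration=5.0)
    with pytest.raises(ValueError):
        SpikeTrain(times=np.array([1.0, 6.0]), duration=5.0)
    train = SpikeTrain(times=np.array([1.0, 3.0]), duration=1000.0)
    assert train.rate == pytest.approx(2.0)
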
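"""Tuning experiments, metrics and response-criteria scoring."""

import numpy as np
import pytest

from lsoif.experiments import (
    CriteriaRanges,
    StimulusSpec,
    TuningCurve,
    ild_tuning,
    phase_tuning,
    run_condition,
    score_criteria,
    tuning_metrics,
)
from lsoif.neuron_models import ModelVariant


def test_tuning_metrics_basic():
    curve = TuningCurve(abscissa=np.array([0.0, 1.0, 2.0]),
                        rates=np.array([10.0, 50.0, 30.0]))
    assert tuning_metrics(curve) == (50.0, 10.0, 40.0)
    flat = TuningCurve(abscissa=np.arange(3.0), rates=np.full(3, 7.0))
    assert flat.depth == 0.0


def test_tuning_curve_validation():
    with pytest.raises(ValueError):
        TuningCurve(abscissa=np.array([]), rates=np.array([]))
    with pytest.raises(ValueError):
        TuningCurve(abscissa=np.arange(3.0), rates=np.arange(4.0))


def test_stimulus_spec_validation():
    with pytest.raises(ValueError):
        StimulusSpec(mode="nonsense")
    with pytest.raises(ValueError):
        StimulusSpec(mode="binaural_AM", duration=-1.0)


# ---------------------------------------------------------------------------
# Criteria scoring (published output measures as worked examples)
# ---------------------------------------------------------------------------


def test_score_criteria_active_leaky_reference_metrics():
    report = score_criteria(
        phase_metrics=(118.9, 18.3, 100.6),
        ild_metrics=(128.1, 15.6, 112.5),
        monaural_metrics=(152.4, 10.4, 142.0),
    )
    assert report.n_targeted == 9
    assert report.score == "9/9"
    assert report.all_accepted


def test_score_criteria_passive_leaky_reference_metrics():
    report = score_criteria(
        phase_metrics=(95.1, 14.4, 80.7),
        ild_metrics=(151.3, 14.1, 137.2),
        monaural_metrics=(146.6, 14.9, 131.7),
    )
    assert report.n_targeted == 6
    assert report.score == "6/9"
    assert report.all_accepted
    assert not report.targeted["phase_peak"]
    assert not report.targeted["phase_depth"]
    assert not report.targeted["ild_peak"]


def test_score_criteria_all_zero_metrics():
    report = score_criteria((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
    assert report.n_targeted == 1  # only the monaural trough band reaches 0
    assert report.score == "1/9"
    assert not report.all_accepted


def test_criteria_ranges_accepted_must_contain_targeted():
    bad = CriteriaRanges()
    shrunk = dict(bad.accepted)
    shrunk["phase_peak"] = (120.0, 130.0)
    with pytest.raises(ValueError):
        CriteriaRanges(targeted=bad.targeted, accepted=shrunk)


# ---------------------------------------------------------------------------
# Experiment mechanics (short simulations)
# ---------------------------------------------------------------------------


def test_same_seed_reproduces_spike_trains_exactly():
    spec = StimulusSpec(mode="binaural_AM", fm=300.0, phase_diff=-135.0,
                        duration=2000.0, seed=99)
    a = run_condition("ALk", spec, condition_index=4)
    b = run_condition("ALk", spec, condition_index=4)
    np.testing.assert_array_equal(
        a[ModelVariant.ALk].times, b[ModelVariant.ALk].times
    )


def test_phase_difference_acts_only_through_inhibitory_locking():
    """At VS = 0 (fm = 2 kHz) the phase difference must have no effect."""
    out = {}
    for dphi in (-135.0, 45.0):
        spec = StimulusSpec(mode="binaural_AM", fm=2000.0, phase_diff=dphi,
                            duration=2000.0, seed=5)
        out[dphi] = run_condition("PLk", spec, condition_index=0)
    np.testing.assert_array_equal(
        out[-135.0][ModelVariant.PLk].times, out[45.0][ModelVariant.PLk].times
    )


def test_entrainment_limit_at_150_hz():
    """At 150 Hz models fire at most one spike per modulation cycle."""
    spec = StimulusSpec(mode="binaural_AM", fm=150.0, phase_diff=-135.0,
                        duration=5000.0, seed=17)
    out = run_condition(list(ModelVariant), spec, condition_index=0)
    for variant, train in out.items():
        assert train.rate <= 150.0 + 10.0, variant


def test_phase_peak_location_and_group_ordering():
    """Anticoincidence tuning: peak near -135 deg, active above passive."""
    grid = np.array([-135.0, 45.0])
    curves = phase_tuning(["PLk", "ALk"], fm=300.0, phase_grid=grid,
                          duration=8000.0, seed=23)
    for v, curve in curves.items():
        assert curve.rates[0] > curve.rates[1]  # -135 favorable, +45 suppressed
    assert curves[ModelVariant.ALk].rates[0] > curves[ModelVariant.PLk].rates[0]


def test_klva_compression_orders_ild_peak_across_seeds():
    """Active models respond less than passive ones to intense inputs."""
    wins = 0
    for seed in range(5):
        curves = ild_tuning(["PLk", "ALk"], ild_grid=np.array([-45.0]),
                            duration=8000.0, seed=seed)
        if curves[ModelVariant.PLk].peak > curves[ModelVariant.ALk].peak:
            wins += 1
    assert wins == 5


def test_rate_estimator_variance_shrinks_with_duration():
    rates = {1000.0: [], 4000.0: []}
    for duration in rates:
        for seed in range(12):
            spec = StimulusSpec(mode="binaural_ILD", ipsi_level=35.0, ild=0.0,
                                duration=duration, seed=seed)
            out = run_condition("PLk", spec, condition_index=1)
            rates[duration].append(out[ModelVariant.PLk].rate)
    v_short = np.var(rates[1000.0], ddof=1)
    v_long = np.var(rates[4000.0], ddof=1)
    assert v_long < v_short


def test_empty_grids_rejected():
    with pytest.raises(ValueError):
        phase_tuning("PLk", phase_grid=np.array([]), duration=100.0)
    with pytest.raises(ValueError):
        ild_tuning("PLk", ild_grid=np.array([]), duration=100.0)
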
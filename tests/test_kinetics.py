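"""Smoothing, peak window, half-rise/half-decay, frequency summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcampflux import kinetics, simulate as sim
from tests.conftest import frame_times


# --- smoother ---------------------------------------------------------------

def test_smooth_constant_series_unchanged():
    np.testing.assert_allclose(kinetics.smooth(np.full(50, 3.0)), 3.0)


def test_smooth_unit_impulse_center_is_one_fifth():
    x = np.zeros(51)
    x[25] = 1.0
    s = kinetics.smooth(x)
    assert s[25] == pytest.approx(0.2)
    assert s[23] == pytest.approx(0.2) and s[27] == pytest.approx(0.2)
    assert s[22] == 0.0 and s[28] == 0.0


def test_smooth_edges_use_truncated_windows():
    x = np.arange(10.0)
    s = kinetics.smooth(x)
    assert s[0] == pytest.approx(np.mean(x[0:3]))   # 3 points at the end
    assert s[1] == pytest.approx(np.mean(x[0:4]))
    assert s[-1] == pytest.approx(np.mean(x[-3:]))


def test_smooth_interior_matches_direct_convolution_oracle():
    rng = np.random.default_rng(5)
    x = rng.normal(size=200)
    s = kinetics.smooth(x)
    oracle = np.convolve(x, np.full(5, 0.2), mode="valid")
    np.testing.assert_allclose(s[2:-2], oracle, rtol=1e-12)


def test_smooth_too_short_series_rejected():
    with pytest.raises(ValueError, match="5 frames"):
        kinetics.smooth(np.ones(4))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_smoothed_max_never_exceeds_raw_max(seed):
    x = np.random.default_rng(seed).normal(size=60)
    assert kinetics.smooth(x).max() <= x.max() + 1e-12


# --- peak window ------------------------------------------------------------

def test_max_of_monotone_ramp_sits_at_window_end(protocol20):
    t = frame_times(200)
    ramp = np.clip(t - 1.0, 0, None)
    val, t_at = kinetics.max_dff(ramp, t, protocol20)
    in_window = t[(t >= 1.0) & (t <= 3.0)]
    assert t_at == pytest.approx(in_window[-1])
    assert val == pytest.approx(in_window[-1] - 1.0)


def test_peak_after_window_is_ignored(protocol20):
    t = frame_times(200)
    x = np.zeros(200)
    x[t > 3.5] = 5.0           # a late, larger peak
    x[(t > 1.0) & (t < 3.0)] = 1.0
    val, t_at = kinetics.max_dff(x, t, protocol20)
    assert val == pytest.approx(1.0)
    assert t_at < 3.0


def test_window_extending_past_record_raises():
    prot = sim.StimulusProtocol(frequency=10.0, onset_time=1.0,
                                train_duration=1.0, record_duration=2.5)
    t = frame_times(int(2.5 * 25))
    with pytest.raises(ValueError, match="window"):
        kinetics.max_dff(np.zeros(t.size), t, prot)


# --- half-rise --------------------------------------------------------------

def test_half_rise_of_linear_ramp_is_midpoint(protocol20):
    t = frame_times(200)
    ramp = np.clip((t - 1.0) / 2.0, 0, 1) * 0.8
    val, t_at = kinetics.max_dff(ramp, t, protocol20)
    thr, censored = kinetics.half_rise(ramp, t, protocol20, val, t_at)
    assert not censored
    assert thr == pytest.approx(1.0, abs=0.05)


def test_half_rise_of_saturating_exponential_is_tau_ln2(protocol20):
    tau = 0.4
    t = frame_times(200)
    x = np.where(t >= 1.0, 1 - np.exp(-(t - 1.0) / tau), 0.0)
    x[t > 3.0] = x[t <= 3.0][-1]  # hold plateau so the peak is in-window
    val, t_at = kinetics.max_dff(x, t, protocol20)
    thr, _ = kinetics.half_rise(x, t, protocol20, val, t_at)
    assert thr == pytest.approx(tau * np.log(2), abs=0.04)


def test_half_rise_of_step_is_at_most_one_frame(protocol20):
    t = frame_times(200)
    x = np.where(t >= 1.0, 1.0, 0.0)
    val, t_at = kinetics.max_dff(x, t, protocol20)
    thr, _ = kinetics.half_rise(x, t, protocol20, val, t_at)
    assert thr <= 0.04 + 1e-9


# --- half-decay -------------------------------------------------------------

def test_half_decay_of_exponential_matches_ln2_over_k(protocol20):
    t = frame_times(200)
    k = 1.386
    x = np.where(t < 3.0, np.clip((t - 1.0) / 2.0, 0, 1),
                 np.exp(-k * (t - 3.0)))
    val, censored, ref = kinetics.half_decay(x, t, protocol20)
    assert not censored
    assert ref == pytest.approx(1.0, abs=0.02)
    assert val == pytest.approx(np.log(2) / k, abs=0.04)


def test_plateau_without_decay_is_censored(protocol20):
    t = frame_times(200)
    x = np.clip((t - 1.0) / 2.0, 0, 1)
    val, censored, _ = kinetics.half_decay(x, t, protocol20)
    assert censored
    assert val == pytest.approx(t[-1] - 3.0)  # lower bound to record end


def test_decay_reference_is_train_end_level_for_early_peak(protocol20):
    """A trace peaking mid-train decays relative to its train-end value."""

    t = frame_times(200)
    x = np.zeros(200)
    rise = (t >= 1.0) & (t < 2.0)
    x[rise] = (t[rise] - 1.0) * 1.0            # peak 1.0 at 2 s
    fall = t >= 2.0
    x[fall] = np.exp(-1.0 * (t[fall] - 2.0))   # decays through train end
    _, _, ref = kinetics.half_decay(x, t, protocol20)
    assert ref == pytest.approx(np.exp(-1.0), abs=0.03)


# --- kinetics on simulated traces ------------------------------------------

def test_interpolation_consistency_under_frame_interval_halving(
        protocol20, linear_indicator):
    cal = sim.CalciumModel(ca_rest=50.0, delta_ca_per_ap=4.0, k_leak=1.0,
                           pump_vmax=0.0)
    est = {}
    for fr in (25.0, 50.0):
        truth = sim.simulate_trial(protocol20, sim.ExcitabilityProfile(), cal,
                                   linear_indicator, frame_rate=fr)
        kin = kinetics.analyze_trace(truth.dff, truth.time, protocol20, 1e-9)
        est[fr] = (kin.t_half_rise, kin.t_half_decay)
    assert abs(est[25.0][0] - est[50.0][0]) < 0.04
    assert abs(est[25.0][1] - est[50.0][1]) < 0.04


@pytest.mark.parametrize("k", [1.0, 2.0])
def test_half_decay_recovers_clearance_rate_at_snr10(protocol20,
                                                     linear_indicator, k):
    cal = sim.CalciumModel(ca_rest=50.0, delta_ca_per_ap=4.0, k_leak=k,
                           pump_vmax=0.0)
    truth = sim.simulate_trial(protocol20, sim.ExcitabilityProfile(), cal,
                               linear_indicator)
    sigma = truth.dff.max() / 10.0
    vals = []
    for seed in range(30):
        dff = sim.add_trace_noise(truth.dff, sigma, seed)
        n_b = float(np.std(dff[truth.time < 1.0][-25:]))
        kin = kinetics.analyze_trace(dff, truth.time, protocol20, n_b)
        if kin.responder and not kin.decay_censored:
            vals.append(kin.t_half_decay)
    assert abs(np.median(vals) - np.log(2) / k) < 0.04


def test_mean_peak_nondecreasing_in_frequency(gcamp1, type2_calcium):
    peaks = []
    for f in (2.0, 10.0, 20.0, 40.0):
        prot = sim.StimulusProtocol(frequency=f)
        truth = sim.simulate_trial(prot, sim.ExcitabilityProfile(),
                                   type2_calcium, gcamp1)
        kin = kinetics.analyze_trace(truth.dff, truth.time, prot, 1e-9)
        peaks.append(kin.max_dff)
    assert all(b >= a for a, b in zip(peaks, peaks[1:]))


# --- frequency response -----------------------------------------------------

def _kin_row(freq, nmj, max_dff, responder):
    return {"bouton_id": 0, "nmj_id": nmj, "terminal_type": "Ib",
            "frequency_hz": freq, "max_dff": max_dff, "responder": responder}


def test_all_nonresponding_leaves_threshold_undefined():
    df = pd.DataFrame([_kin_row(f, 0, 0.01, False) for f in (2, 10, 20)])
    fr = kinetics.frequency_response(df)
    assert fr.threshold_frequency is None


def test_single_frequency_all_respond_threshold_equals_saturation():
    df = pd.DataFrame([_kin_row(20, n, 0.5, True) for n in range(3)])
    fr = kinetics.frequency_response(df)
    assert fr.threshold_frequency == 20
    assert fr.saturation_frequency == 20


def test_nmj_grain_averages_within_terminal_first():
    rows = ([_kin_row(20, 0, 0.1, True)] * 3 + [_kin_row(20, 1, 0.4, True)])
    fr = kinetics.frequency_response(pd.DataFrame(rows))
    row = fr.table.iloc[0]
    assert row["nmj_mean_max_dff"] == pytest.approx(0.25)   # (0.1 + 0.4)/2
    assert row["mean_max_dff"] == pytest.approx(0.175)      # bouton-grain pool
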
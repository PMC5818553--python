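"""Trace extraction, baseline/noise statistics, QC and the responder gate."""

import numpy as np
import pytest

from gcampflux import extract, simulate as sim
from tests.conftest import frame_times


def _simple_rois(shape=(20, 20)):
    bmask = np.zeros(shape, bool)
    bmask[4:8, 4:8] = True
    gmask = np.zeros(shape, bool)
    gmask[12:16, 12:16] = True
    return extract.RoiSet(boutons={0: bmask}, backgrounds={0: gmask})


def _movie_from(frames):
    return sim.FrameStack(frames=np.asarray(frames, float), frame_rate=25.0)


def test_uniform_frames_give_zero_f_t():
    movie = _movie_from(np.full((30, 20, 20), 7.0))
    tr, = extract.extract_traces(movie, _simple_rois())
    np.testing.assert_allclose(tr.f_t, 0.0)


def test_constant_offset_appears_directly_in_f_t():
    frames = np.full((30, 20, 20), 5.0)
    frames[:, 4:8, 4:8] += 10.0
    tr, = extract.extract_traces(_movie_from(frames), _simple_rois())
    np.testing.assert_allclose(tr.f_t, 10.0)


def test_empty_roi_raises_with_label():
    rois = _simple_rois()
    rois.boutons[0][:] = False
    with pytest.raises(ValueError, match="0"):
        extract.extract_traces(_movie_from(np.zeros((5, 20, 20))), rois)


def test_bouton_overlapping_background_rejected():
    mask = np.zeros((20, 20), bool)
    mask[4:8, 4:8] = True
    with pytest.raises(ValueError, match="overlap"):
        extract.RoiSet(boutons={0: mask}, backgrounds={0: mask})


def _trace(f_t, frame_rate=25.0):
    n = len(f_t)
    t = frame_times(n, frame_rate)
    z = np.zeros(n)
    return extract.BoutonTrace(bouton_id=0, time=t, f_raw=np.asarray(f_t, float),
                               f_bg=z, f_t=np.asarray(f_t, float))


def test_constant_baseline_has_zero_noise(protocol20):
    tr = extract.compute_baseline(_trace(np.full(200, 100.0)), protocol20)
    assert tr.f_b == pytest.approx(100.0)
    assert tr.n_b == pytest.approx(0.0)


def test_baseline_window_is_25_frames_spanning_one_second(protocol20):
    tr = _trace(np.arange(200.0) + 100.0)
    idx = extract._baseline_index(tr, protocol20, extract.BASELINE_FRAMES)
    assert idx.size == 25
    span = tr.time[idx[-1]] - tr.time[idx[0]] + 1.0 / 25.0
    assert span == pytest.approx(1.0)
    assert tr.time[idx[-1]] < protocol20.onset_time  # onset frame excluded


def test_onset_too_early_for_baseline_raises():
    prot = sim.StimulusProtocol(frequency=10.0, onset_time=0.5, record_duration=4.0)
    with pytest.raises(ValueError, match="pre-stimulus"):
        extract.compute_baseline(_trace(np.full(100, 50.0)), prot)


def test_baseline_noise_estimates_sigma_over_f_b(protocol20):
    """Monte Carlo: mean N_B over many repeats approaches sigma / F_B."""

    rng = np.random.default_rng(0)
    f_b, sigma, reps = 100.0, 5.0, 10_000
    nbs = np.empty(reps)
    for i in range(reps):
        f_t = np.full(60, f_b)
        f_t[:30] += rng.normal(0, sigma, 30)  # noise on baseline frames
        tr = extract.compute_baseline(_trace(f_t), protocol20)
        nbs[i] = tr.n_b
    # E[N_B] ~ sigma/F_B with a small-sample bias below 1 for n=25
    assert abs(nbs.mean() - sigma / f_b) < 0.002


def test_dff_identity_against_elementwise_oracle(protocol20):
    rng = np.random.default_rng(1)
    f_t = 100.0 + rng.normal(0, 5, 200)
    tr = extract.compute_dff(extract.compute_baseline(_trace(f_t), protocol20))
    oracle = np.array([(x - tr.f_b) / tr.f_b for x in f_t])
    np.testing.assert_allclose(tr.dff, oracle, rtol=0, atol=0)
    # baseline window of dF/F averages to zero by construction
    idx = extract._baseline_index(tr, protocol20, 25)
    assert abs(tr.dff[idx].mean()) < 1e-14


def test_qc_flags_and_exclusion_fraction(protocol20):
    traces = []
    for i in range(60):
        tr = extract.compute_baseline(_trace(np.full(100, 100.0)), protocol20)
        tr.bouton_id = i
        traces.append(tr)
    # inject three defects: two low baselines, one high noise
    traces[3].f_b = 0.01
    traces[17].f_b = 0.5
    traces[40].n_b = 0.5
    passing, report = extract.qc_filter(traces, f_b_floor=1.0, n_b_ceiling=0.1)
    assert len(passing) == 57
    assert report.exclusion_fraction == pytest.approx(3 / 60)
    assert "low_baseline" in report.flags[3]
    assert "high_noise" in report.flags[40]
    clean_pass, clean_rep = extract.qc_filter(
        [extract.compute_baseline(_trace(np.full(100, 100.0)), protocol20)])
    assert clean_rep.exclusion_fraction == 0.0


def test_responder_gate_is_strictly_greater_than_twice_noise():
    n_b = 0.02
    assert not extract.classify_responder(0.0, n_b)
    assert not extract.classify_responder(1.9 * n_b, n_b)
    assert not extract.classify_responder(2.0 * n_b, n_b)   # strict inequality
    assert extract.classify_responder(2.1 * n_b, n_b)
    assert extract.classify_responder(2.5 * n_b, n_b)


def test_noiseless_roundtrip_recovers_ground_truth(protocol20, gcamp1,
                                                   type2_calcium, small_imaging):
    truth = sim.simulate_trial(protocol20, sim.ExcitabilityProfile(),
                               type2_calcium, gcamp1, frame_rate=25.0)
    movie = sim.render_movie(np.tile(truth.dff, (3, 1)), small_imaging)
    rois = sim.make_roi_set(small_imaging)
    for tr in extract.extract_traces(movie, rois):
        extract.compute_dff(extract.compute_baseline(tr, protocol20))
        assert np.abs(tr.dff - truth.dff).max() < 1e-6
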
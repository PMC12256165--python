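"""Spike-train statistics, I/O fits, mAHP, sag and spontaneous activity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obephys.core import InputError, ProtocolRecording, StepStimulus, Sweep
from obephys.synth import (
    SynthCellParams,
    simulate_cc_step,
    simulate_izero,
    simulate_mahp_protocol,
    simulate_sag_protocol,
    simulate_train_ladder,
)
from obephys.trains import (
    SweepTrain,
    analyse_train_ladder,
    at_1p5_rheobase,
    detect_spikes,
    io_fit,
    mahp_amplitude,
    rheobase_latency_fahp,
    sag_index,
    spontaneous_activity,
    train_statistics,
)

RATE = 50_000.0


def _cc(signal, onset_ms=100.0, dur_ms=500.0, amplitude=50.0):
    n = len(signal)
    return Sweep(
        time=np.arange(n) / RATE, signal=np.asarray(signal, float),
        sampling_rate=RATE, clamp_mode="current_clamp",
        stimulus=StepStimulus(onset=onset_ms * 1e-3, duration=dur_ms * 1e-3,
                              amplitude=amplitude),
        holding=-60.0,
    )


def test_detect_spikes_finds_region_maxima():
    v = np.full(40000, -60.0)
    for t_ms, peak in ((100.0, 35.0), (150.0, 30.0)):
        k = int(t_ms * 1e-3 * RATE)
        v[k - 5 : k + 6] = np.concatenate([
            np.linspace(-60, peak, 6), np.linspace(peak, -60, 6)[1:],
        ])
    times, peaks = detect_spikes(_cc(v))
    np.testing.assert_allclose(times, [100.0, 150.0])
    np.testing.assert_allclose(peaks, [35.0, 30.0])


def test_detect_spikes_subthreshold_is_empty():
    times, peaks = detect_spikes(_cc(np.full(40000, -60.0)))
    assert times.size == 0 and peaks.size == 0


def test_detect_spikes_matches_generator_ledger(clean_params):
    sw, ledger = simulate_cc_step(clean_params, 70.0, 500.0,
                                  rng=np.random.default_rng(0))
    times, peaks = detect_spikes(sw)
    assert times.size == ledger.spike_times.size
    np.testing.assert_allclose(times, ledger.spike_times, atol=1e-9)
    np.testing.assert_allclose(peaks, ledger.spike_peaks, atol=1e-9)


def test_worked_train_statistics_example():
    """ISIs [10, 20, 30] ms: IF = 100 Hz, CV = 0.5, SFA = 66.67%."""
    st_ = train_statistics([100.0, 110.0, 130.0, 160.0])
    assert st_["IF"] == pytest.approx(100.0)
    assert st_["CV"] == pytest.approx(0.5)
    assert st_["SFA"] == pytest.approx((100 - 100 / 3) / 100 * 100)
    assert round(st_["SFA"], 2) == 66.67


def test_amplitude_adaptation_percentage():
    st_ = train_statistics([0.0, 10.0], spike_peaks=[40.0, 30.0])
    assert st_["SAA"] == pytest.approx(25.0)


def test_homogeneous_train_has_zero_adaptation():
    st_ = train_statistics(
        [0.0, 10.0, 20.0, 30.0], spike_peaks=[35.0] * 4, spike_whh=[0.4] * 4
    )
    assert st_["CV"] == 0.0 and st_["SFA"] == 0.0
    assert st_["SAA"] == 0.0 and st_["SWA"] == 0.0


def test_insufficient_spikes_give_nulls():
    st_ = train_statistics([50.0])
    assert all(st_[k] is None for k in ("IF", "CV", "SFA", "SAA", "SWA"))
    st_ = train_statistics([50.0, 60.0], spike_peaks=[30.0, 29.0])
    assert st_["IF"] is not None and st_["SAA"] is not None
    assert st_["CV"] is None and st_["SFA"] is None


@settings(deadline=None, max_examples=30)
@given(scale=st.floats(0.1, 10.0))
def test_adaptation_statistics_are_scale_free(scale):
    times = np.array([100.0, 112.0, 130.0, 155.0])
    peaks = np.array([38.0, 36.0, 33.0, 31.0])
    whh = np.array([0.36, 0.38, 0.41, 0.45])
    a = train_statistics(times, peaks, whh)
    b = train_statistics(times[0] + (times - times[0]) * scale,
                         peaks * scale, whh * scale)
    assert b["CV"] == pytest.approx(a["CV"], rel=1e-12)
    assert b["SFA"] == pytest.approx(a["SFA"], rel=1e-12)
    assert b["SAA"] == pytest.approx(a["SAA"], rel=1e-12)
    assert b["SWA"] == pytest.approx(a["SWA"], rel=1e-12)


def test_rheobase_latency_fahp_from_ladder(clean_cell, clean_params):
    rec = clean_cell.recordings["trains_500ms"]
    rheo, latency, fahp = rheobase_latency_fahp(rec)
    ledgers = clean_cell.ledgers["trains_500ms"]
    first = next(lg for lg in ledgers if lg.spike_times.size > 0)
    assert rheo == first.current
    onset_ms = 100.0
    assert latency == pytest.approx(first.spike_times[0] - onset_ms, abs=1e-6)
    # trough after the first spike is the pasted reset, fahp_depth below threshold
    assert fahp == pytest.approx(clean_params.fahp_depth, abs=0.2)


def test_rheobase_none_when_no_sweep_spikes(clean_params):
    sw, _ = simulate_cc_step(clean_params, 5.0, 500.0, rng=np.random.default_rng(0))
    rec = ProtocolRecording(protocol_kind="trains_500ms", sweeps=[sw])
    assert rheobase_latency_fahp(rec) == (None, None, None)


def _train(current, n_spikes, if_hz=None, saa=None):
    stats = {"IF": if_hz, "CV": None, "SFA": None, "SAA": saa, "SWA": None,
             "n_spikes": n_spikes}
    return SweepTrain(current=current, spike_times=np.zeros(n_spikes),
                      spike_peaks=np.zeros(n_spikes), spike_whh=np.zeros(n_spikes),
                      stats=stats)


def test_io_fit_recovers_exact_line():
    trains = [
        _train(c, n, if_hz=1.5 * c + 3.0, saa=0.8 * c - 1.0)
        for c, n in [(20, 2), (30, 4), (40, 6), (50, 8), (60, 10)]
    ]
    out = io_fit(trains)
    assert out["max_spike_no"] == 10
    assert out["IF_slope"] == pytest.approx(1.5)
    assert out["SAA_slope"] == pytest.approx(0.8)


def test_io_fit_range_ends_at_80_percent_of_max():
    counts = [1, 2, 3, 4, 5, 10]
    trains = [_train(10 * (i + 1), c, if_hz=float(c)) for i, c in enumerate(counts)]
    out = io_fit(trains)
    # cutoff 8: only the final sweep reaches it, so all six points are fitted
    assert out["max_spike_no"] == 10
    x = np.array([10 * (i + 1) for i in range(6)], float)
    y = np.array(counts, float)
    assert out["IF_slope"] == pytest.approx(np.polyfit(x, y, 1)[0])

    counts = [1, 8, 9, 10, 10]
    trains = [_train(10 * (i + 1), c, if_hz=float(c)) for i, c in enumerate(counts)]
    out = io_fit(trains)
    # cutoff 8 reached on the second sweep: only sweeps 1-2 fall in range -> <3 points
    assert out["IF_slope"] is None


def test_io_fit_single_spike_sweeps_are_null():
    trains = [_train(10 * (i + 1), 1) for i in range(5)]
    out = io_fit(trains)
    assert out["max_spike_no"] == 1
    assert out["IF_slope"] is None and out["SAA_slope"] is None


def test_representative_sweep_selection_near_1p5_rheobase():
    trains = [_train(c, 5) for c in (50.0, 60.0, 70.0)]
    for tr in trains:
        tr.stats.update({"CV": tr.current, "SFA": 1.0, "SWA": 1.0})
    assert at_1p5_rheobase(trains, 40.0)["current"] == 60.0
    # rheobase 44 -> target 66: 70 is nearer than 60
    trains = [_train(c, 5) for c in (60.0, 70.0)]
    for tr in trains:
        tr.stats.update({"CV": 1.0, "SFA": 1.0, "SWA": 1.0})
    assert at_1p5_rheobase(trains, 44.0)["current"] == 70.0
    assert at_1p5_rheobase(trains, None)["CV"] is None
    # exact tie: higher current wins
    trains = [_train(c, 5) for c in (55.0, 65.0)]
    for tr in trains:
        tr.stats.update({"CV": tr.current, "SFA": 1.0, "SWA": 1.0})
    assert at_1p5_rheobase(trains, 40.0)["current"] == 65.0


def test_no_sweep_near_target_gives_null():
    trains = [_train(200.0, 5)]
    trains[0].stats.update({"CV": 1.0, "SFA": 1.0, "SWA": 1.0})
    assert at_1p5_rheobase(trains, 40.0)["CV"] is None


def test_mahp_zero_conductance_is_flat(clean_params):
    p = dataclasses.replace(clean_params, ahp_conductance=0.0)
    rec = simulate_mahp_protocol(p)
    assert mahp_amplitude(rec) == pytest.approx(0.0, abs=1e-9)


def test_mahp_recovers_injected_amplitude(clean_params):
    p = dataclasses.replace(clean_params, ahp_conductance=2.35 / 0.25)
    rec = simulate_mahp_protocol(p)
    assert mahp_amplitude(rec) == pytest.approx(2.35, abs=0.01)


def test_mahp_excludes_sweeps_missing_spikes(clean_params):
    # 3 failing sweeps with 9 spikes are dropped; a tampered amplitude on
    # them must not leak into the average
    rec = simulate_mahp_protocol(clean_params, fail_sweeps=3)
    ok = simulate_mahp_protocol(clean_params, fail_sweeps=0)
    for sw in rec.sweeps[:3]:
        times, _ = detect_spikes(sw)
        assert times.size == 9
        sw.signal[-100:] -= 50.0  # corrupt the excluded sweeps' tails
    assert mahp_amplitude(rec) == pytest.approx(mahp_amplitude(ok), abs=1e-9)


def test_mahp_none_when_no_valid_sweep(clean_params):
    rec = simulate_mahp_protocol(clean_params, n_sweeps=2, fail_sweeps=2)
    assert mahp_amplitude(rec) is None


def test_mahp_invariant_to_sweep_order_and_linear_in_amplitude(clean_params):
    rec = simulate_mahp_protocol(clean_params)
    shuffled = ProtocolRecording(
        protocol_kind="mahp_train", sweeps=list(reversed(rec.sweeps))
    )
    assert mahp_amplitude(shuffled) == pytest.approx(mahp_amplitude(rec), abs=1e-12)
    double = dataclasses.replace(clean_params, ahp_conductance=16.0)
    assert mahp_amplitude(simulate_mahp_protocol(double)) == pytest.approx(
        2 * mahp_amplitude(rec), abs=1e-9
    )


def _sag_step_sweep(v_hold, v_ss, v_sag, amplitude):
    """Plateau at v_ss with a sharp dip to v_sag early in the step."""
    n_pre, n_step, n_post = 2000, 25000, 2000
    v = np.full(n_pre + n_step + n_post, v_hold)
    v[n_pre : n_pre + n_step] = v_ss
    v[n_pre + 500 : n_pre + 700] = v_sag
    return _cc(v, onset_ms=n_pre / RATE * 1e3, dur_ms=n_step / RATE * 1e3,
               amplitude=amplitude)


def test_sag_formula_worked_example():
    rec = ProtocolRecording(
        protocol_kind="sag_steps",
        sweeps=[_sag_step_sweep(-60.0, -100.0, -110.0, -40.0)],
    )
    meas = sag_index(rec)
    assert meas.steps[0][3] == pytest.approx(0.8)
    assert meas.sag_index_at_minus100 == pytest.approx(0.8)


def test_sag_linear_interpolation_between_bracketing_steps():
    # per-step (V_ss, index) = (-95, 0.95) and (-105, 0.91) -> 0.93 at -100
    v_sag_a = -60.0 - (-60.0 + 95.0) / 0.95
    v_sag_b = -60.0 - (-60.0 + 105.0) / 0.91
    rec = ProtocolRecording(
        protocol_kind="sag_steps",
        sweeps=[
            _sag_step_sweep(-60.0, -95.0, v_sag_a, -40.0),
            _sag_step_sweep(-60.0, -105.0, v_sag_b, -50.0),
        ],
    )
    meas = sag_index(rec)
    assert meas.sag_index_at_minus100 == pytest.approx(0.93, abs=1e-6)


def test_sag_without_channel_is_unity():
    rec = ProtocolRecording(
        protocol_kind="sag_steps",
        sweeps=[_sag_step_sweep(-60.0, -100.0, -100.0, -40.0)],
    )
    assert sag_index(rec).steps[0][3] == pytest.approx(1.0)


def test_sag_ladder_not_reaching_target_is_flagged():
    rec = ProtocolRecording(
        protocol_kind="sag_steps",
        sweeps=[_sag_step_sweep(-60.0, -80.0, -82.0, -20.0)],
    )
    meas = sag_index(rec)
    assert meas.sag_index_at_minus100 is None and meas.flag is not None


def test_synthetic_sag_ground_truth_recovery(clean_params):
    rec = simulate_sag_protocol(clean_params, rng=np.random.default_rng(0))
    meas = sag_index(rec)
    assert meas.sag_index_at_minus100 == pytest.approx(
        clean_params.sag_index_true, abs=0.02
    )


def test_spontaneous_activity_classification(clean_params):
    silent = simulate_izero(clean_params, rng=np.random.default_rng(0))
    assert spontaneous_activity(silent.sweeps[0]) is False
    pacer = dataclasses.replace(clean_params, pacemaker_drive=45.0)
    assert pacer.is_spontaneous
    active = simulate_izero(pacer, rng=np.random.default_rng(0))
    assert spontaneous_activity(active.sweeps[0]) is True
    # a single spike in 5 s is enough
    sw = silent.sweeps[0]
    v = sw.signal.copy()
    v[1000:1005] = 20.0
    one = Sweep(time=sw.time, signal=v, sampling_rate=sw.sampling_rate,
                clamp_mode="current_clamp")
    assert spontaneous_activity(one) is True


def test_ladder_analysis_equals_ledger_statistics(clean_cell):
    """Extraction from traces reproduces the generator's own spike ledger."""
    trains = analyse_train_ladder(clean_cell.recordings["trains_500ms"])
    ledgers = sorted(clean_cell.ledgers["trains_500ms"], key=lambda lg: lg.current)
    checked = 0
    for lg, tr in zip(ledgers, trains):
        if lg.collapsed:
            assert tr.n_spikes == 0  # depolarisation block: no detectable spikes
            continue
        assert tr.n_spikes == lg.spike_times.size
        if lg.spike_times.size < 3:
            continue
        ref = train_statistics(lg.spike_times, lg.spike_peaks, lg.spike_whh)
        for key in ("IF", "CV", "SFA", "SAA"):
            assert tr.stats[key] == pytest.approx(ref[key], abs=1e-9), key
        assert tr.stats["SWA"] == pytest.approx(ref["SWA"], abs=0.5)
        checked += 1
    assert checked >= 3
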
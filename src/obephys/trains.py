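"""Spike-train analysis: 500 ms step ladders, mAHP, sag and spontaneous firing.

Spikes are detected as contiguous regions where the membrane voltage
exceeds 0 mV; spike times are the times of the region maxima (inter-spike
intervals run peak-to-peak).  Adaptation statistics follow the standard
first-vs-last-spike percentage definitions:

    IF  = 1 / first ISI
    CV  = SD(ISI) / mean(ISI)                 (sample SD, n-1)
    SFA = (f_first - f_last) / f_first * 100  with f = 1/ISI
    SAA = (Vmax_first - Vmax_last) / Vmax_first * 100
    SWA = (whh_first - whh_last) / whh_first * 100
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import InputError, ProtocolRecording, Sweep
from .waveform import (
    NoThresholdError,
    _threshold_index,
    _width_at_level,
    smooth_derivative,
)

CV_DDOF = 1  # sample SD; the field convention for small-n electrophysiology


def detect_spikes(sweep: Sweep) -> Tuple[np.ndarray, np.ndarray]:
    """Spike times (ms) and peak voltages (mV) of all V > 0 mV regions."""
    v = sweep.signal
    above = v > 0.0
    if not np.any(above):
        return np.array([]), np.array([])
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v) - 1)
    times, peaks = [], []
    for s, e in zip(starts, ends):
        k = s + int(np.argmax(v[s : e + 1]))
        times.append(sweep.time[k] * 1e3)
        peaks.append(v[k])
    return np.asarray(times), np.asarray(peaks)


def spike_widths(sweep: Sweep, dvdt_criterion: float = 10.0) -> np.ndarray:
    """Per-spike width at half height (ms) inside a train.

    Each spike uses its own local threshold (the 10 V/s crossing scanned
    back from its peak, bounded by the previous spike), because later
    spikes ride on accumulated depolarisation.
    """
    v = sweep.signal
    t = sweep.time
    times, _ = detect_spikes(sweep)
    if times.size == 0:
        return np.array([])
    win = max(2, int(round(100e-6 * sweep.sampling_rate)))
    dvdt = smooth_derivative(sweep, window=win)
    peak_idx = np.round((times * 1e-3 - t[0]) * sweep.sampling_rate).astype(int)
    widths = []
    prev = 0
    for k in peak_idx:
        try:
            th = _threshold_index(dvdt[prev:], k - prev, dvdt_criterion) + prev
            half = 0.5 * (v[th] + v[k])
            widths.append(_width_at_level(t, v, th, k, half))
        except (NoThresholdError, InputError):
            widths.append(np.nan)
        prev = k
    return np.asarray(widths)


def train_statistics(
    spike_times_ms: Sequence[float],
    spike_peaks: Optional[Sequence[float]] = None,
    spike_whh: Optional[Sequence[float]] = None,
    ddof: int = CV_DDOF,
) -> dict:
    """IF, CV, SFA, SAA and SWA for one sweep's spike train.

    Metrics whose minimum spike count is not met are returned as ``None``
    (IF/SAA/SWA need >= 2 spikes; CV/SFA need >= 3 spikes, i.e. >= 2 ISIs).
    """
    t = np.asarray(list(spike_times_ms), dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise InputError("spike times must be strictly increasing")
    out = {"IF": None, "CV": None, "SFA": None, "SAA": None, "SWA": None,
           "n_spikes": int(t.size)}
    if t.size >= 2:
        isis_s = np.diff(t) * 1e-3
        out["IF"] = float(1.0 / isis_s[0])  # Hz
        if t.size >= 3:
            out["CV"] = float(np.std(isis_s, ddof=ddof) / np.mean(isis_s))
            f_first = 1.0 / isis_s[0]
            f_last = 1.0 / isis_s[-1]
            out["SFA"] = float((f_first - f_last) / f_first * 100.0)
    if spike_peaks is not None:
        p = np.asarray(list(spike_peaks), dtype=float)
        if p.size >= 2 and p[0] != 0:
            out["SAA"] = float((p[0] - p[-1]) / p[0] * 100.0)
    if spike_whh is not None:
        w = np.asarray(list(spike_whh), dtype=float)
        w = w[np.isfinite(w)]
        if w.size >= 2 and w[0] != 0:
            out["SWA"] = float((w[0] - w[-1]) / w[0] * 100.0)
    return out


@dataclass
class SweepTrain:
    """Per-sweep spike inventory for a 500 ms step ladder."""

    current: float                 # pA
    spike_times: np.ndarray        # ms
    spike_peaks: np.ndarray        # mV
    spike_whh: np.ndarray          # ms
    stats: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def analyse_train_ladder(recording: ProtocolRecording) -> List[SweepTrain]:
    """Spike inventories for every sweep of a 500 ms step ladder, by amplitude."""
    rec = recording.sorted_by_amplitude()
    out = []
    for sw in rec.sweeps:
        times, peaks = detect_spikes(sw)
        whh = spike_widths(sw) if times.size else np.array([])
        st = SweepTrain(
            current=sw.stimulus.amplitude, spike_times=times,
            spike_peaks=peaks, spike_whh=whh,
        )
        st.stats = train_statistics(times, peaks, whh)
        out.append(st)
    return out


def rheobase_latency_fahp(
    recording: ProtocolRecording, dvdt_criterion: float = 10.0
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Rheobase (pA), first-spike latency (ms) and fAHP (mV) from a step ladder.

    All three are measured on the rheobase sweep: the first sweep of the
    increasing ladder that fires at least one spike.  Latency runs from
    step onset to the peak of the first spike; fAHP is the drop from the
    first spike's voltage threshold to the minimum voltage between its
    peak and the next spike's threshold time (or the step end), reported
    positive.  Returns ``(None, None, None)`` when no sweep spikes.
    """
    rec = recording.sorted_by_amplitude()
    for sw in rec.sweeps:
        times, peaks = detect_spikes(sw)
        stim = sw.stimulus
        in_step = (times * 1e-3 >= stim.onset) & (times * 1e-3 <= stim.onset + stim.duration)
        if not np.any(in_step):
            continue
        times = times[in_step]
        rheobase = float(stim.amplitude)
        latency = float(times[0] - stim.onset * 1e3)
        v = sw.signal
        t = sw.time
        win = max(2, int(round(100e-6 * sw.sampling_rate)))
        dvdt = smooth_derivative(sw, window=win)
        k0 = sw.index_at(times[0] * 1e-3)
        try:
            th_idx = _threshold_index(dvdt, k0, dvdt_criterion)
        except NoThresholdError:
            return rheobase, latency, None
        v_thresh = v[th_idx]
        end_idx = sw.index_at(stim.onset + stim.duration) - 1  # last in-step sample
        if times.size > 1:
            k1 = sw.index_at(times[1] * 1e-3)
            try:
                next_th = _threshold_index(dvdt[k0:], k1 - k0, dvdt_criterion) + k0
            except NoThresholdError:
                next_th = k1
            end_idx = min(end_idx, next_th)
        if end_idx <= k0:
            return rheobase, latency, None
        fahp = float(v_thresh - np.min(v[k0 : end_idx + 1]))
        return rheobase, latency, abs(fahp)
    return None, None, None


def io_fit(trains: List[SweepTrain]) -> dict:
    """Input-output fits: IF and SAA slopes over 0-80% of the maximum spike count.

    An ordinary least-squares line (slope + intercept) is fitted to the
    IF-vs-current and SAA-vs-current points from the first suprathreshold
    sweep up to and including the first sweep whose spike count reaches
    80% of the maximum.  Fits with fewer than 3 points return ``None``.
    """
    counts = np.array([tr.n_spikes for tr in trains])
    out = {"max_spike_no": None, "IF_slope": None, "SAA_slope": None}
    if counts.size == 0 or counts.max() == 0:
        return out
    max_n = int(counts.max())
    out["max_spike_no"] = max_n
    first = int(np.nonzero(counts > 0)[0][0])
    cutoff = 0.8 * max_n
    last = first
    for i in range(first, len(trains)):
        last = i
        if counts[i] >= cutoff:
            break
    window = trains[first : last + 1]
    for key, slope_key in (("IF", "IF_slope"), ("SAA", "SAA_slope")):
        pts = [(tr.current, tr.stats[key]) for tr in window if tr.stats.get(key) is not None]
        if len(pts) >= 3:
            x, y = np.array(pts).T
            out[slope_key] = float(np.polyfit(x, y, 1)[0])
    return out


def at_1p5_rheobase(
    trains: List[SweepTrain], rheobase: Optional[float]
) -> dict:
    """Representative CV, SFA and SWA from the sweep nearest 1.5x rheobase.

    Ties are broken toward the higher current.  When no sweep lies within
    50% of the target current the metrics are ``None``.
    """
    out = {"CV": None, "SFA": None, "SWA": None, "current": None}
    if rheobase is None or not trains:
        return out
    target = 1.5 * rheobase
    best = None
    for tr in trains:
        d = abs(tr.current - target)
        if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and tr.current > best[1].current):
            best = (d, tr)
    if best is None or best[0] > 0.5 * target:
        return out
    tr = best[1]
    out.update({"CV": tr.stats["CV"], "SFA": tr.stats["SFA"],
                "SWA": tr.stats["SWA"], "current": tr.current})
    return out


def mahp_amplitude(
    recording: ProtocolRecording, window_ms: float = 250.0
) -> Optional[float]:
    """Medium AHP amplitude (mV) from the mean trace of a 50 Hz pulse-train protocol.

    Sweeps that did not fire exactly one spike per pulse (10 spikes for the
    standard 10-pulse protocol) are excluded; the retained sweeps are
    averaged point-wise and the amplitude is V_hold minus the minimum of
    the mean trace in the ``window_ms`` after the end of the train,
    reported positive.  Returns ``None`` when no sweep qualifies.
    """
    valid = []
    for sw in recording.sweeps:
        times, _ = detect_spikes(sw)
        if times.size == sw.stimulus.n_pulses:
            valid.append(sw)
    if not valid:
        return None
    ref = valid[0]
    mean_trace = np.mean([sw.signal for sw in valid], axis=0)
    stim = ref.stimulus
    i0 = ref.index_at(stim.onset)
    baseline = float(np.mean(mean_trace[:i0]))
    j0 = ref.index_at(stim.train_end)
    j1 = min(ref.index_at(stim.train_end + window_ms * 1e-3), len(mean_trace) - 1)
    trough = float(np.min(mean_trace[j0 : j1 + 1]))
    return abs(baseline - trough)


@dataclass
class SagMeasurement:
    """Per-step sag quantification and the interpolated index at -100 mV."""

    V_hold: float
    steps: list                      # (amplitude pA, V_ss, V_sag, index)
    sag_index_at_minus100: Optional[float]
    flag: Optional[str] = None


def sag_index(
    recording: ProtocolRecording,
    target_vss: float = -100.0,
    ss_fraction: float = 0.10,
    single_step_tol: float = 2.0,
) -> SagMeasurement:
    """Sag index (V_hold - V_ss)/(V_hold - V_sag) per step, interpolated to -100 mV.

    V_ss is the mean voltage over the last ``ss_fraction`` of the step,
    V_sag the minimum voltage during the step.  The index at -100 mV is
    linearly interpolated in V_ss between the two bracketing steps, or
    taken directly from a step whose V_ss lies within ``single_step_tol``
    mV of the target.  A recording whose ladder fails to reach the target
    is flagged and returns ``None`` for the interpolated index.
    """
    rec = recording.sorted_by_amplitude()
    steps = []
    v_hold = None
    for sw in rec.sweeps:
        stim = sw.stimulus
        i0 = sw.index_at(stim.onset)
        i1 = sw.index_at(stim.onset + stim.duration) - 1  # last in-step sample
        hold = float(np.mean(sw.signal[:i0]))
        v_hold = hold if v_hold is None else v_hold
        seg = sw.signal[i0 : i1 + 1]
        n = len(seg)
        v_ss = float(np.mean(seg[n - max(1, int(round(n * ss_fraction))):]))
        v_sag = float(np.min(seg))
        if abs(hold - v_sag) < 1e-12:
            idx = 1.0
        else:
            idx = (hold - v_ss) / (hold - v_sag)
        steps.append((float(stim.amplitude), v_ss, v_sag, idx))
    steps.sort(key=lambda s: s[1], reverse=True)  # V_ss from depolarised to hyperpolarised
    interp = None
    flag = None
    exact = [s for s in steps if abs(s[1] - target_vss) <= single_step_tol]
    bracket = None
    for a, b in zip(steps, steps[1:]):
        if a[1] >= target_vss >= b[1]:
            bracket = (a, b)
            break
    if bracket is not None:
        a, b = bracket
        if a[1] == b[1]:
            interp = a[3]
        else:
            frac = (target_vss - a[1]) / (b[1] - a[1])
            interp = float(a[3] + frac * (b[3] - a[3]))
    elif exact:
        interp = min(exact, key=lambda s: abs(s[1] - target_vss))[3]
    else:
        flag = f"ladder does not bracket V_ss = {target_vss} mV"
    return SagMeasurement(
        V_hold=v_hold if v_hold is not None else np.nan,
        steps=steps, sag_index_at_minus100=interp, flag=flag,
    )


def spontaneous_activity(izero: Sweep) -> bool:
    """True iff the I=0 recording contains at least one spike."""
    times, _ = detect_spikes(izero)
    return bool(times.size >= 1)
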
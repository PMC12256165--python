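"""Single action-potential waveform analysis.

Spikes are evoked by 10 ms depolarising current steps of increasing
amplitude, sampled at 200 kHz.  The voltage is smoothed with a 20-point
(100 us) sliding boxcar before differentiation; spike threshold is the
voltage at which the smoothed rate of rise first exceeds 10 V/s before the
peak, and width at half height (whh) is measured at the midpoint between
threshold and peak with sub-sample linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .core import InputError, Sweep

SMOOTH_WINDOW_S = 100e-6       # 100 us boxcar
DVDT_THRESHOLD = 10.0          # V/s
REFERENCE_RATE = 200_000.0     # Hz


class NoThresholdError(InputError):
    """The smoothed dV/dt never exceeds the threshold criterion."""


@dataclass
class APWaveformFeatures:
    V_thresh: float          # mV
    V_max: float             # mV
    max_dvdt: float          # V/s
    whh: float               # ms
    threshold_time: float    # ms (absolute sweep time * 1e3)
    peak_time: float         # ms
    phase_plane: Tuple[np.ndarray, np.ndarray]  # (V mV, dV/dt V/s)


def boxcar_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding-average of ``window`` samples.

    Interior samples average ``window`` points ([i - w//2, i + w//2 - 1]
    for even windows); near the edges the window shrinks symmetrically.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < window:
        raise InputError("trace shorter than the smoothing window")
    left = window // 2
    right = window - left - 1
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, left), np.minimum(n - 1 - idx, right))
    lo = idx - k
    hi = idx + k
    # interior: full asymmetric window [i-left, i+right]
    interior = (idx >= left) & (idx <= n - 1 - right)
    lo[interior] = idx[interior] - left
    hi[interior] = idx[interior] + right
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _window_samples(sampling_rate: float) -> int:
    if np.isclose(sampling_rate, REFERENCE_RATE):
        return 20
    warnings.warn(
        f"sampling rate {sampling_rate:g} Hz differs from 200 kHz; "
        f"rescaling the smoothing window to {SMOOTH_WINDOW_S*1e6:.0f} us",
        stacklevel=2,
    )
    return max(2, int(round(SMOOTH_WINDOW_S * sampling_rate)))


def smooth_derivative(sweep: Sweep, window: Optional[int] = None) -> np.ndarray:
    """Smoothed dV/dt in V/s (boxcar smoothing, then central differences)."""
    if window is None:
        window = _window_samples(sweep.sampling_rate)
    smoothed = boxcar_smooth(sweep.signal, window)
    # mV/s -> V/s
    return np.gradient(smoothed, sweep.time) * 1e-3


def _spike_in_step(sweep: Sweep) -> bool:
    stim = sweep.stimulus
    i0 = sweep.index_at(stim.onset)
    i1 = sweep.index_at(stim.onset + stim.duration)
    return bool(np.any(sweep.signal[i0 : i1 + 1] > 0.0))


def find_threshold_step(sweeps: List[Sweep]) -> Optional[int]:
    """Index of the first sweep whose voltage exceeds 0 mV inside the step.

    Sweeps must form a ladder of strictly increasing step amplitudes.
    Returns ``None`` when no sweep spikes.
    """
    amps = [sw.stimulus.amplitude for sw in sweeps]
    if any(b <= a for a, b in zip(amps, amps[1:])):
        raise InputError("step amplitudes must be strictly increasing")
    for i, sw in enumerate(sweeps):
        if _spike_in_step(sw):
            return i
    return None


def _threshold_index(dvdt: np.ndarray, peak_idx: int, criterion: float) -> int:
    """First sample of sustained supra-criterion rise before the peak.

    Scans backwards from the peak to the last sample not exceeding the
    criterion; the threshold is the next sample (robust to early noise
    blips that cross the criterion transiently).
    """
    below = np.nonzero(dvdt[: peak_idx + 1] <= criterion)[0]
    if below.size == 0 or below[-1] == peak_idx:
        raise NoThresholdError(f"dV/dt never exceeds {criterion} V/s before the peak")
    return int(below[-1] + 1)


def ap_features(
    sweep: Sweep,
    dvdt_criterion: float = DVDT_THRESHOLD,
    window: Optional[int] = None,
) -> APWaveformFeatures:
    """Threshold, amplitude, maximal rate of rise and width of one spike.

    If several spikes occur in the step, the first is analysed.
    """
    v = sweep.signal
    dvdt = smooth_derivative(sweep, window=window)
    # First spike: first region above 0 mV; fall back to global max.
    above = np.nonzero(v > 0.0)[0]
    if above.size:
        gaps = np.nonzero(np.diff(above) > 1)[0]
        run_end = above[gaps[0]] if gaps.size else above[-1]
        peak_idx = int(above[0] + np.argmax(v[above[0] : run_end + 1]))
    else:
        peak_idx = int(np.argmax(v))
    th_idx = _threshold_index(dvdt, peak_idx, dvdt_criterion)
    v_thresh = float(v[th_idx])
    v_max = float(v[peak_idx])
    if v_max <= v_thresh:
        raise NoThresholdError("no spike: peak does not exceed threshold")
    max_dvdt = float(np.max(dvdt[th_idx : peak_idx + 1]))
    half = 0.5 * (v_thresh + v_max)
    whh = _width_at_level(sweep.time, v, th_idx, peak_idx, half)
    return APWaveformFeatures(
        V_thresh=v_thresh,
        V_max=v_max,
        max_dvdt=max_dvdt,
        whh=whh,
        threshold_time=float(sweep.time[th_idx] * 1e3),
        peak_time=float(sweep.time[peak_idx] * 1e3),
        phase_plane=(v.copy(), dvdt),
    )


def _cross_time(t: np.ndarray, v: np.ndarray, i: int, j: int, level: float) -> float:
    """Linear-interpolated crossing time of ``level`` between samples i and j."""
    if v[j] == v[i]:
        return float(t[i])
    frac = (level - v[i]) / (v[j] - v[i])
    return float(t[i] + frac * (t[j] - t[i]))


def _width_at_level(
    t: np.ndarray, v: np.ndarray, th_idx: int, peak_idx: int, level: float
) -> float:
    """Width (ms) between the upward and downward crossings of ``level``."""
    up = None
    for i in range(peak_idx, th_idx, -1):
        if v[i - 1] <= level < v[i] or (v[i - 1] < level <= v[i]):
            up = _cross_time(t, v, i - 1, i, level)
            break
    down = None
    for i in range(peak_idx, len(v) - 1):
        if v[i] >= level > v[i + 1] or (v[i] > level >= v[i + 1]):
            down = _cross_time(t, v, i, i + 1, level)
            break
    if up is None or down is None:
        raise InputError("half-height level is never crossed on both flanks")
    return (down - up) * 1e3


def phase_plane(
    sweep: Sweep, window: Optional[int] = None, bump_prominence: float = 5.0
) -> dict:
    """Phase-plane trajectory (V, dV/dt) with an optional biphasic-rise flag.

    A second local maximum of dV/dt on the rising phase, below the global
    maximum but with prominence above ``bump_prominence`` V/s, marks a
    candidate axonal initiation 'bump' (biphasic waveform).  Flat traces
    return an empty trajectory and no flag.
    """
    v = sweep.signal
    if not np.any(v > 0.0):
        return {"V": np.array([]), "dvdt": np.array([]), "biphasic_flag": False}
    feats = ap_features(sweep, window=window)
    dvdt = feats.phase_plane[1]
    th_idx = int(round(feats.threshold_time * 1e-3 * sweep.sampling_rate - sweep.time[0] * sweep.sampling_rate))
    peak_idx = int(round(feats.peak_time * 1e-3 * sweep.sampling_rate - sweep.time[0] * sweep.sampling_rate))
    rising = dvdt[th_idx : peak_idx + 1]
    peaks, _ = find_peaks(rising, prominence=bump_prominence)
    # a bump is a secondary local maximum clearly below the main rise
    biphasic = any(rising[p] < 0.95 * rising.max() for p in peaks)
    return {"V": v, "dvdt": dvdt, "biphasic_flag": bool(biphasic)}
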
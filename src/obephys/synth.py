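"""Synthetic protocol generator with exact ground truth.

Each synthetic cell is an adaptive leaky integrate-and-fire neuron
(current-based spike-triggered adaptation) whose spikes are pasted,
stylised waveforms: a piecewise-linear rise/fall whose vertices are
snapped to the sampling grid, so the pasted peak voltage, peak time and
interpolated half-width are *exact* on the sampled trace and can serve as
oracles for the feature extractors.  The voltage-clamp membrane test is
the closed-form response of the two-resistor access circuit (Rs in series
with Ri || Cm).  The mAHP protocol injects an analytic exponential
afterhyperpolarisation and the sag protocol builds an analytic
double-exponential trough, again so the ground truth is exact by
construction.

Target magnitudes follow the recorded population: Ri ~ 870 MOhm,
Cm ~ 20 pF, threshold ~ -34.5 mV, peak ~ +37 mV, whh ~ 0.36 ms,
fAHP ~ 25 mV, mAHP 1-3 mV, sag index ~ 0.92, SFA ~ 40-70%, and
spontaneous pacemaking in a controllable fraction of cells per group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .core import InputError, ProtocolRecording, StepStimulus, Sweep

try:  # numba accelerates the subthreshold integration ~100x
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

V_HOLD = -60.0            # mV, holding potential for all evoked protocols
AHP_MV_PER_NS = 0.25      # stylised mapping: mAHP amplitude per nS of AHP conductance
SAG_PER_NS = 0.01         # stylised mapping: sag index = 1 / (1 + SAG_PER_NS * g_sag)
RATE_PASSIVE = 50_000.0   # Hz
RATE_SINGLE_AP = 200_000.0


@dataclass
class SynthCellParams:
    """Generative ground-truth parameters of one synthetic cell."""

    R_i_true: float = 870.0          # MOhm
    C_m_true: float = 20.0           # pF
    R_s_true: float = 8.0            # MOhm
    E_L: float = -64.0               # mV
    spike_threshold_true: float = -34.5   # mV
    spike_peak: float = 37.0         # mV, first-spike peak
    spike_whh: float = 0.36          # ms, first-spike width at half height
    max_dvdt: float = 430.0          # V/s, nominal rise rate
    fahp_depth: float = 25.0         # mV below threshold (reset = threshold - depth)
    refractory: float = 1.5          # ms beyond the pasted waveform
    adaptation_increment: float = 25.0   # pA per spike (controls SFA)
    adaptation_tau: float = 200.0    # ms
    amp_adaptation: float = 0.9      # mV peak decrement per successive spike (SAA)
    width_adaptation: float = 0.04   # fractional whh increase per successive spike (SWA)
    ahp_conductance: float = 8.0     # nS (mAHP amplitude = 0.25 mV/nS * g)
    ahp_tau: float = 50.0            # ms
    sag_conductance: float = 8.7     # nS (sag index = 1/(1+0.01*g))
    sag_tau: float = 40.0            # ms
    pacemaker_drive: float = 0.0     # pA intrinsic drive; >0 can make the cell spontaneous
    depol_block_current: float = 120.0   # pA ceiling before depolarisation block
    noise_sd: float = 0.1            # mV additive membrane noise (subthreshold)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R_i_true <= 0 or self.C_m_true <= 0:
            raise InputError("R_i_true and C_m_true must be positive")
        if self.R_s_true < 0 or self.R_s_true >= self.R_i_true:
            raise InputError("require 0 <= R_s_true < R_i_true")
        for name in ("adaptation_tau", "ahp_conductance", "ahp_tau",
                     "sag_conductance", "sag_tau", "noise_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @property
    def reset(self) -> float:
        return self.spike_threshold_true - self.fahp_depth

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms (MOhm * pF = us)."""
        return self.R_i_true * self.C_m_true / 1e3

    @property
    def mahp_amplitude_true(self) -> float:
        return self.ahp_conductance * AHP_MV_PER_NS

    @property
    def sag_index_true(self) -> float:
        return 1.0 / (1.0 + SAG_PER_NS * self.sag_conductance)

    @property
    def is_spontaneous(self) -> bool:
        drive_mv = self.pacemaker_drive * self.R_i_true / 1e3
        return self.E_L + drive_mv > self.spike_threshold_true


@dataclass
class SpikeShape:
    """A stylised spike waveform sampled on a fixed grid, with exact features."""

    samples: np.ndarray       # mV, starting at threshold, ending at reset
    peak_offset: int          # samples from waveform start to the peak vertex
    v_thresh: float
    v_max: float
    whh: float                # ms, as measured with linear interpolation
    max_dvdt: float           # V/s, rise slope after grid snapping


def _shape_geometry(
    params: SynthCellParams, dt_ms: float, peak: float, whh: float
) -> tuple[int, int, int]:
    """Grid-snapped (n_rise, n_fall, n_under) sample counts for a spike shape."""
    height = peak - params.spike_threshold_true
    if height <= 0:
        raise InputError("spike peak must exceed threshold")
    t_rise = height / params.max_dvdt  # mV / (V/s) = mV/(mV/ms) = ms
    n_rise = max(1, int(round(t_rise / dt_ms)))
    t_fall = 2.0 * whh - n_rise * dt_ms
    if t_fall <= 0:
        raise InputError("whh too small for the requested rise rate")
    n_fall = max(1, int(round(t_fall / dt_ms)))
    fall_slope = height / (n_fall * dt_ms)
    under = params.spike_threshold_true - params.reset
    n_under = max(1, int(round(under / fall_slope / dt_ms)))
    return n_rise, n_fall, n_under


def make_spike_shape(
    params: SynthCellParams, dt_ms: float,
    peak: Optional[float] = None, whh: Optional[float] = None,
) -> SpikeShape:
    """Triangular rise/fall spike with vertices snapped to the sampling grid.

    Snapping makes the sampled maximum land exactly on the analytic vertex
    and keeps both half-height crossings on pure linear segments, so the
    extractor's interpolated measurements reproduce the declared features
    exactly.
    """
    thresh = params.spike_threshold_true
    peak = params.spike_peak if peak is None else peak
    whh = params.spike_whh if whh is None else whh
    height = peak - thresh
    n_rise, n_fall, n_under = _shape_geometry(params, dt_ms, peak, whh)
    t_rise = n_rise * dt_ms
    t_fall = n_fall * dt_ms
    fall_slope = height / t_fall   # mV/ms
    rise = thresh + (height / t_rise) * dt_ms * np.arange(n_rise + 1)
    fall = peak - fall_slope * dt_ms * np.arange(1, n_fall + n_under + 1)
    samples = np.concatenate([rise, np.maximum(fall, params.reset)])
    samples[-1] = params.reset
    return SpikeShape(
        samples=samples, peak_offset=n_rise, v_thresh=thresh, v_max=peak,
        whh=0.5 * (t_rise + t_fall), max_dvdt=height / t_rise,
    )


@njit(cache=True)
def _lif_core(i_inj, noise, dt, tau_m, ri, e_l, v0, v_thresh, reset,
              b, decay_w, shape_lens, refr_n):  # pragma: no cover - jitted
    n = i_inj.shape[0]
    v = np.empty(n)
    spike_idx = np.empty(n, dtype=np.int64)
    n_spikes = 0
    V = v0
    w = 0.0
    k = 0
    while k < n:
        v[k] = V
        if V >= v_thresh and n_spikes < shape_lens.shape[0]:
            spike_idx[n_spikes] = k
            hold = shape_lens[n_spikes] + refr_n
            n_spikes += 1
            w += b
            end = min(n, k + hold)
            for j in range(k, end):
                v[j] = reset
            w *= decay_w ** (end - k)
            V = reset
            k = end
            continue
        dV = ((e_l - V) + ri * (i_inj[k] - w) / 1000.0) * dt / tau_m
        V += dV + noise[k]
        w *= decay_w
        k += 1
    return v, spike_idx[:n_spikes]


@dataclass
class SweepLedger:
    """Ground-truth spike inventory for one simulated sweep."""

    current: float
    spike_times: np.ndarray   # ms, pasted peak times
    spike_peaks: np.ndarray   # mV
    spike_whh: np.ndarray     # ms
    spike_thresh_times: np.ndarray = field(default_factory=lambda: np.array([]))
    collapsed: bool = False   # depolarisation-block sweep: peaks pasted below 0 mV


def simulate_cc_step(
    params: SynthCellParams,
    amplitude: float,
    duration_ms: float,
    sampling_rate: float = RATE_PASSIVE,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
    rng: Optional[np.random.Generator] = None,
    collapse_spikes: bool = False,
) -> tuple[Sweep, SweepLedger]:
    """One current-clamp step sweep with pasted spikes and its ledger.

    ``collapse_spikes`` emulates depolarisation block: pasted spike
    amplitudes are collapsed to just above threshold (below 0 mV), so the
    detected spike count falls to zero at the highest currents.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    dt_ms = 1e3 / sampling_rate
    n_pre = int(round(pre_ms / dt_ms))
    n_step = int(round(duration_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    n = n_pre + n_step + n_post
    i_hold = (V_HOLD - params.E_L) / params.R_i_true * 1e3 + params.pacemaker_drive
    i_inj = np.full(n, i_hold)
    i_inj[n_pre : n_pre + n_step] += amplitude
    noise = (
        rng.normal(0.0, params.noise_sd, n)
        * np.sqrt(dt_ms / params.tau_m) * np.sqrt(2.0)
        if params.noise_sd > 0 else np.zeros(n)
    )
    max_spikes = 400

    def _spike_geometry(i: int) -> tuple[float, float]:
        peak_i = params.spike_peak - params.amp_adaptation * i
        if collapse_spikes:
            peak_i = params.spike_threshold_true + 1.0
        peak_i = max(peak_i, params.spike_threshold_true + 1.0)
        whh_i = params.spike_whh * (1.0 + params.width_adaptation * i)
        return peak_i, whh_i

    shape_lens = np.empty(max_spikes, dtype=np.int64)
    for i in range(max_spikes):
        n_rise, n_fall, n_under = _shape_geometry(params, dt_ms, *_spike_geometry(i))
        shape_lens[i] = n_rise + n_fall + n_under + 1
    refr_n = int(round(params.refractory / dt_ms))
    decay_w = float(np.exp(-dt_ms / params.adaptation_tau)) if params.adaptation_tau > 0 else 0.0
    v, spike_idx = _lif_core(
        i_inj, noise, dt_ms, params.tau_m, params.R_i_true, params.E_L,
        V_HOLD, params.spike_threshold_true, params.reset,
        params.adaptation_increment, decay_w, shape_lens, refr_n,
    )
    times, peaks, whhs, th_times = [], [], [], []
    t0 = 0.0
    for i, k in enumerate(spike_idx):
        shape = make_spike_shape(params, dt_ms, *_spike_geometry(i))
        seg = shape.samples[: n - k]
        v[k : k + len(seg)] = seg
        peak_k = k + shape.peak_offset
        if peak_k < n:
            times.append(t0 + peak_k * dt_ms)
            peaks.append(shape.v_max)
            whhs.append(shape.whh)
            th_times.append(t0 + k * dt_ms)
    stim = StepStimulus(onset=n_pre * dt_ms * 1e-3, duration=n_step * dt_ms * 1e-3,
                        amplitude=amplitude)
    sweep = Sweep(
        time=np.arange(n) / sampling_rate, signal=v, sampling_rate=sampling_rate,
        clamp_mode="current_clamp", stimulus=stim, holding=V_HOLD,
    )
    ledger = SweepLedger(
        current=amplitude, spike_times=np.array(times), spike_peaks=np.array(peaks),
        spike_whh=np.array(whhs), spike_thresh_times=np.array(th_times),
        collapsed=collapse_spikes,
    )
    return sweep, ledger


def simulate_membrane_test(
    params: SynthCellParams,
    delta_v: float = -10.0,
    sampling_rate: float = RATE_PASSIVE,
    pre_ms: float = 5.0,
    step_ms: float = 10.0,
    post_ms: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> ProtocolRecording:
    """Voltage-clamp test pulse: analytic response of the Rs-(Ri || Cm) circuit.

    The steady-state current deflection is dV/(Rs+Ri) and the transient
    charge approaches Cm * dV * (Ri/(Rs+Ri))^2 (all of it as Rs -> 0).
    Current noise is scaled from the voltage noise through the input
    resistance.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    rs, ri, cm = params.R_s_true, params.R_i_true, params.C_m_true
    dt_ms = 1e3 / sampling_rate
    n_pre = int(round(pre_ms / dt_ms))
    n_step = int(round(step_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    n = n_pre + n_step + n_post
    t = np.arange(n) * dt_ms
    i_base = (V_HOLD - params.E_L) / (rs + ri) * 1e3  # pA
    i_ss = delta_v / (rs + ri) * 1e3
    current = np.full(n, i_base)
    in_step = t - pre_ms
    mask = (in_step >= 0) & (in_step < step_ms)
    after = in_step >= step_ms
    if rs > 0:
        tau = rs * ri / (rs + ri) * cm / 1e3  # ms
        i_peak = delta_v / rs * 1e3
        current[mask] += i_ss + (i_peak - i_ss) * np.exp(-in_step[mask] / tau)
        current[after] += -(i_peak - i_ss) * np.exp(-(in_step[after] - step_ms) / tau)
    else:
        current[mask] += i_ss
    if params.noise_sd > 0:
        current += rng.normal(0.0, params.noise_sd / ri * 1e3 * 5.0, n)
    stim = StepStimulus(onset=pre_ms * 1e-3, duration=step_ms * 1e-3, amplitude=delta_v)
    sweep = Sweep(
        time=np.arange(n) / sampling_rate, signal=current,
        sampling_rate=sampling_rate, clamp_mode="voltage_clamp",
        stimulus=stim, holding=V_HOLD,
    )
    return ProtocolRecording(protocol_kind="membrane_test", sweeps=[sweep])


def simulate_single_ap_protocol(
    params: SynthCellParams,
    increment_pa: float = 10.0,
    max_amplitude: float = 500.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ProtocolRecording, List[SweepLedger]]:
    """10 ms step ladder at 200 kHz, stopped at the first spiking sweep."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    sweeps, ledgers = [], []
    amp = 0.0
    while amp <= max_amplitude:
        sw, led = simulate_cc_step(
            params, amp, 10.0, sampling_rate=RATE_SINGLE_AP,
            pre_ms=5.0, post_ms=15.0, rng=rng,
        )
        sweeps.append(sw)
        ledgers.append(led)
        # stop at the first sweep that fires within the step, judged by the
        # same V > 0 mV rule the analysis applies
        i0 = sw.index_at(sw.stimulus.onset)
        i1 = sw.index_at(sw.stimulus.onset + sw.stimulus.duration)
        if np.any(sw.signal[i0 : i1 + 1] > 0.0):
            break
        amp += increment_pa
    return ProtocolRecording(protocol_kind="single_ap_10ms", sweeps=sweeps), ledgers


def simulate_train_ladder(
    params: SynthCellParams,
    increment_pa: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ProtocolRecording, List[SweepLedger]]:
    """500 ms step ladder, stopped one sweep past the depolarisation-block ceiling."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    sweeps, ledgers = [], []
    amp = 0.0
    while True:
        collapse = amp > params.depol_block_current
        sw, led = simulate_cc_step(
            params, amp, 500.0, sampling_rate=RATE_PASSIVE,
            pre_ms=100.0, post_ms=100.0, rng=rng, collapse_spikes=collapse,
        )
        sweeps.append(sw)
        ledgers.append(led)
        if collapse or len(sweeps) >= 60:
            break
        amp += increment_pa
    return ProtocolRecording(protocol_kind="trains_500ms", sweeps=sweeps), ledgers


def simulate_mahp_protocol(
    params: SynthCellParams,
    n_sweeps: int = 10,
    n_pulses: int = 10,
    pulse_pa: float = 500.0,
    frequency: float = 50.0,
    pulse_width_ms: float = 2.0,
    fail_sweeps: int = 0,
    sampling_rate: float = RATE_PASSIVE,
) -> ProtocolRecording:
    """50 Hz pulse-train protocol with an injected analytic mAHP.

    Each sweep carries ``n_pulses`` pasted spikes at the pulse times; after
    the train the trace is V_hold - A * exp(-t/tau) with
    A = ahp_conductance * 0.25 mV/nS, so the mean-trace trough equals A at
    the train end exactly.  The first ``fail_sweeps`` sweeps are generated
    with one missing spike to exercise the 10-spike exclusion rule.  The
    protocol is noise-free by construction (the post-train minimum is a
    noise-biased statistic; see the methods note).
    """
    dt_ms = 1e3 / sampling_rate
    onset_ms = 100.0
    period_ms = 1e3 / frequency
    train_end_ms = onset_ms + (n_pulses - 1) * period_ms + pulse_width_ms
    total_ms = train_end_ms + 300.0
    n = int(round(total_ms / dt_ms))
    t_ms = np.arange(n) * dt_ms
    amp = params.mahp_amplitude_true
    shape = make_spike_shape(params, dt_ms)
    sweeps = []
    for s in range(n_sweeps):
        v = np.full(n, V_HOLD)
        skip = 3 if s < fail_sweeps else None  # drop the 4th pulse on failing sweeps
        for p in range(n_pulses):
            if p == skip:
                continue
            k = int(round((onset_ms + p * period_ms) / dt_ms))
            seg = shape.samples[: n - k]
            v[k : k + len(seg)] = seg
            # recovery from reset toward holding between pulses
            k_end = k + len(seg)
            k_next = int(round((onset_ms + (p + 1) * period_ms) / dt_ms)) if p + 1 < n_pulses else int(round(train_end_ms / dt_ms))
            span = np.arange(0, max(0, min(n, k_next) - k_end))
            v[k_end : k_end + len(span)] = V_HOLD + (params.reset - V_HOLD) * np.exp(
                -span * dt_ms / params.tau_m
            )
        k_tail = int(round(train_end_ms / dt_ms))
        tail = t_ms[k_tail:] - t_ms[k_tail]
        v[k_tail:] = V_HOLD - amp * np.exp(-tail / params.ahp_tau) if params.ahp_tau > 0 else V_HOLD - amp * (tail == 0)
        stim = StepStimulus(
            onset=onset_ms * 1e-3, duration=(train_end_ms - onset_ms) * 1e-3,
            amplitude=pulse_pa, pulse_width=pulse_width_ms * 1e-3,
            n_pulses=n_pulses, frequency=frequency,
        )
        sweeps.append(Sweep(
            time=np.arange(n) / sampling_rate, signal=v,
            sampling_rate=sampling_rate, clamp_mode="current_clamp",
            stimulus=stim, holding=V_HOLD,
        ))
    return ProtocolRecording(protocol_kind="mahp_train", sweeps=sweeps)


def _sag_trace(
    v_hold: float, v_ss: float, v_sag: float, tau_m: float, tau_sag: float,
    t_ms: np.ndarray,
) -> np.ndarray:
    """Double-exponential hyperpolarising step whose grid minimum is exactly v_sag."""
    from scipy.optimize import brentq

    fast = np.exp(-t_ms / tau_m)
    slow = np.exp(-t_ms / tau_sag)

    def trace(a: float) -> np.ndarray:
        return v_ss + (v_hold - v_ss + a) * fast - a * slow

    if v_sag >= v_ss - 1e-12:
        return trace(0.0)
    lo, hi = 0.0, (v_ss - v_sag) * 10 + 1.0
    while trace(hi).min() > v_sag:
        hi *= 2
    a_star = brentq(lambda a: trace(a).min() - v_sag, lo, hi, xtol=1e-12)
    return trace(a_star)


def simulate_sag_protocol(
    params: SynthCellParams,
    step_pa: float = -10.0,
    target_vss: float = -100.0,
    duration_ms: float = 500.0,
    rng: Optional[np.random.Generator] = None,
    sampling_rate: float = RATE_PASSIVE,
) -> ProtocolRecording:
    """Hyperpolarising step ladder with an analytic sag of known index.

    Each step's steady state is V_hold + I*Ri; the per-step sag index is
    the cell's ground-truth value s = 1/(1 + 0.01 * g_sag) at every step,
    so the index interpolated to V_ss = -100 mV recovers s.  The ladder
    descends in ``step_pa`` increments until V_ss passes ``target_vss``.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if step_pa >= 0:
        raise InputError("sag steps must be hyperpolarising (step_pa < 0)")
    dt_ms = 1e3 / sampling_rate
    pre_ms, post_ms = 100.0, 100.0
    n_pre = int(round(pre_ms / dt_ms))
    n_step = int(round(duration_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    n = n_pre + n_step + n_post
    s = params.sag_index_true
    sweeps = []
    amp = step_pa
    for _ in range(100):
        v_ss = V_HOLD + amp * params.R_i_true / 1e3
        v_sag = V_HOLD - (V_HOLD - v_ss) / s
        t_step = np.arange(n_step) * dt_ms
        seg = _sag_trace(V_HOLD, v_ss, v_sag, params.tau_m, params.sag_tau, t_step)
        v = np.full(n, V_HOLD)
        v[n_pre : n_pre + n_step] = seg
        tail = np.arange(n_post) * dt_ms
        v[n_pre + n_step :] = V_HOLD + (seg[-1] - V_HOLD) * np.exp(-tail / params.tau_m)
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, n)
        stim = StepStimulus(onset=pre_ms * 1e-3, duration=duration_ms * 1e-3, amplitude=amp)
        sweeps.append(Sweep(
            time=np.arange(n) / sampling_rate, signal=v,
            sampling_rate=sampling_rate, clamp_mode="current_clamp",
            stimulus=stim, holding=V_HOLD,
        ))
        if v_ss <= target_vss - 2.0:
            break
        amp += step_pa
    return ProtocolRecording(protocol_kind="sag_steps", sweeps=sweeps)


def simulate_izero(
    params: SynthCellParams,
    duration_s: float = 5.5,
    rate_hz: float = 4.0,
    sampling_rate: float = RATE_PASSIVE,
    rng: Optional[np.random.Generator] = None,
) -> ProtocolRecording:
    """I = 0 recording: flat resting potential, or pacemaking when spontaneous."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    dt_ms = 1e3 / sampling_rate
    n = int(round(duration_s * sampling_rate))
    v = np.full(n, params.E_L)
    if params.is_spontaneous:
        shape = make_spike_shape(params, dt_ms)
        period_ms = 1e3 / rate_hz
        t = period_ms * (0.5 + rng.uniform(-0.1, 0.1))
        while t / dt_ms < n - 1:
            k = int(round(t / dt_ms))
            seg = shape.samples[: n - k]
            v[k : k + len(seg)] = seg
            k_end = k + len(seg)
            span = np.arange(n - k_end)
            v[k_end:] = params.E_L + (params.reset - params.E_L) * np.exp(-span * dt_ms / params.tau_m)
            t += period_ms * (1.0 + rng.uniform(-0.05, 0.05))
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, n)
    sweep = Sweep(
        time=np.arange(n) / sampling_rate, signal=v, sampling_rate=sampling_rate,
        clamp_mode="current_clamp", stimulus=None, holding=None,
    )
    return ProtocolRecording(protocol_kind="spontaneous_izero", sweeps=[sweep])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: spontaneously active fraction per maturation group (observed cohort rates)
SPONTANEOUS_FRACTIONS = {"wpi5": 3 / 23, "wpi9": 8 / 17, "resident": 21 / 53}

#: occlusion effects: additive shifts applied to occluded cells
DEFAULT_TREATMENT_EFFECTS = {"spike_peak": 3.5, "max_dvdt": 40.0}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: groups x treatments with per-group biology."""

    n_per_cell: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {
            g: {"sham": 8, "occluded": 8} for g in ("wpi5", "wpi9", "resident")
        }
    )
    spontaneous_fraction: Dict[str, float] = field(
        default_factory=lambda: dict(SPONTANEOUS_FRACTIONS)
    )
    treatment_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )
    param_means: Dict[str, float] = field(default_factory=dict)
    param_sds: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, d in self.n_per_cell.items():
            for t, n in d.items():
                if n < 0:
                    raise InputError("cell counts must be >= 0")
        for g, f in self.spontaneous_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise InputError("spontaneous fractions must lie in [0, 1]")


# population distributions for the per-cell parameter draws (mean, sd)
_PARAM_DISTRIBUTIONS = {
    "R_i_true": (870.0, 130.0),
    "C_m_true": (20.0, 3.0),
    "R_s_true": (8.0, 1.5),
    "E_L": (-64.0, 3.0),
    "spike_threshold_true": (-34.5, 1.5),
    "spike_peak": (37.0, 3.0),
    "spike_whh": (0.36, 0.03),
    "max_dvdt": (430.0, 40.0),
    "fahp_depth": (25.0, 2.0),
    "adaptation_increment": (25.0, 5.0),
    "ahp_conductance": (8.0, 2.5),
    "sag_conductance": (8.7, 1.2),
}

_PARAM_BOUNDS = {
    "R_i_true": (300.0, 2000.0),
    "C_m_true": (8.0, 40.0),
    "R_s_true": (3.0, 15.0),
    "E_L": (-75.0, -50.0),
    "spike_threshold_true": (-40.0, -28.0),
    "spike_peak": (25.0, 50.0),
    "spike_whh": (0.25, 0.55),
    "max_dvdt": (300.0, 560.0),
    "fahp_depth": (18.0, 30.0),
    "adaptation_increment": (8.0, 45.0),
    "ahp_conductance": (1.0, 16.0),
    "sag_conductance": (4.0, 14.0),
}


@dataclass
class CellBundle:
    """Everything generated for one synthetic cell."""

    cell_id: str
    group: str
    treatment: str
    params: SynthCellParams
    recordings: Dict[str, ProtocolRecording]
    ledgers: Dict[str, List[SweepLedger]]
    rs_measurements: List[float]

    def truth_row(self) -> dict:
        p = self.params
        shape_200k = make_spike_shape(p, 1e3 / RATE_SINGLE_AP)
        return {
            "cell_id": self.cell_id, "group": self.group, "treatment": self.treatment,
            "R_i": p.R_i_true, "C_m": p.C_m_true, "R_s": p.R_s_true,
            "V_rest": p.E_L,
            "V_thresh": shape_200k.v_thresh, "V_max": shape_200k.v_max,
            "max_dvdt": shape_200k.max_dvdt, "whh": shape_200k.whh,
            "fAHP": p.fahp_depth, "mAHP": p.mahp_amplitude_true,
            "sag_index": p.sag_index_true,
            "spontaneous": p.is_spontaneous,
        }


def draw_cell_params(
    rng: np.random.Generator,
    group: str,
    treatment: str,
    spec: CohortSpec,
    spontaneous: bool,
) -> SynthCellParams:
    kwargs = {}
    for name, (mean, sd) in _PARAM_DISTRIBUTIONS.items():
        mean = spec.param_means.get(name, mean)
        sd = spec.param_sds.get(name, sd)
        lo, hi = _PARAM_BOUNDS[name]
        kwargs[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    if treatment == "occluded":
        for name, shift in spec.treatment_effects.items():
            if name in kwargs:
                kwargs[name] += shift
    kwargs["noise_sd"] = spec.noise_sd
    kwargs["seed"] = int(rng.integers(0, 2**31 - 1))
    params = SynthCellParams(**kwargs)
    if spontaneous:
        # drive the resting trajectory just past threshold
        needed = (params.spike_threshold_true - params.E_L) * 1e3 / params.R_i_true
        params = dataclasses.replace(params, pacemaker_drive=needed + 10.0)
    return params


def simulate_cell(params: SynthCellParams, cell_id: str = "cell",
                  group: str = "resident", treatment: str = "sham",
                  protocols: Optional[List[str]] = None) -> CellBundle:
    """All protocol recordings plus ledgers for one cell."""
    if protocols is None:
        protocols = [
            "membrane_test", "single_ap_10ms", "trains_500ms",
            "mahp_train", "sag_steps", "spontaneous_izero",
        ]
    rng = np.random.default_rng(params.seed)
    recordings: Dict[str, ProtocolRecording] = {}
    ledgers: Dict[str, List[SweepLedger]] = {}
    if "membrane_test" in protocols:
        recordings["membrane_test"] = simulate_membrane_test(params, rng=rng)
    if "single_ap_10ms" in protocols:
        rec, led = simulate_single_ap_protocol(params, rng=rng)
        recordings["single_ap_10ms"] = rec
        ledgers["single_ap_10ms"] = led
    if "trains_500ms" in protocols:
        rec, led = simulate_train_ladder(params, rng=rng)
        recordings["trains_500ms"] = rec
        ledgers["trains_500ms"] = led
    if "mahp_train" in protocols:
        recordings["mahp_train"] = simulate_mahp_protocol(params)
    if "sag_steps" in protocols:
        recordings["sag_steps"] = simulate_sag_protocol(params, rng=rng)
    if "spontaneous_izero" in protocols:
        recordings["spontaneous_izero"] = simulate_izero(params, rng=rng)
    for rec in recordings.values():
        rec.cell_id = cell_id
        rec.group = group
        rec.treatment = treatment
    rs = [params.R_s_true * (1.0 + 0.02 * rng.standard_normal()) for _ in range(4)]
    return CellBundle(
        cell_id=cell_id, group=group, treatment=treatment, params=params,
        recordings=recordings, ledgers=ledgers, rs_measurements=rs,
    )


def generate_cohort(spec: CohortSpec, protocols: Optional[List[str]] = None) -> List[CellBundle]:
    """Reproducible cohort of cell bundles under the spec's master seed."""
    root = np.random.SeedSequence(spec.master_seed)
    bundles: List[CellBundle] = []
    groups = sorted(spec.n_per_cell)
    n_total = sum(sum(d.values()) for d in spec.n_per_cell.values())
    children = root.spawn(n_total + 1)
    ci = 0
    for group in groups:
        for treatment in sorted(spec.n_per_cell[group]):
            for j in range(spec.n_per_cell[group][treatment]):
                rng = np.random.default_rng(children[ci])
                ci += 1
                spont = bool(rng.random() < spec.spontaneous_fraction.get(group, 0.0))
                params = draw_cell_params(rng, group, treatment, spec, spont)
                cell_id = f"{group}_{treatment}_{j:03d}"
                bundles.append(
                    simulate_cell(params, cell_id, group, treatment, protocols)
                )
    return bundles


def ground_truth_frame(bundles: List[CellBundle]):
    import pandas as pd

    return pd.DataFrame([b.truth_row() for b in bundles])
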
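"""Passive membrane properties from the voltage-clamp test pulse and I=0 traces.

The test pulse is a 10 ms, -10 mV hyperpolarising voltage step from a
-60 mV holding potential, sampled at 50 kHz.  Series resistance comes from
the peak current transient, input resistance from the steady-state current
deflection, and membrane capacitance from the charge under the decaying
transient between the peak and the steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import InputError, Sweep

# Fraction of the step window whose trailing samples define the
# steady-state current (membrane tau << 2 ms for these cells, so the final
# 20% of a 10 ms step is comfortably settled).
SS_FRACTION = 0.20


@dataclass
class TestPulseMeasurement:
    """All quantities extracted from one voltage-clamp test pulse."""

    I_baseline: float        # pA
    I_peak: float            # pA
    I_ss: float              # pA
    transient_charge: float  # pA*ms
    R_s: float               # MOhm
    R_i: float               # MOhm
    C_m: float               # pF
    ss_warning: bool = False


def _require_vc(sweep: Sweep) -> None:
    if sweep.clamp_mode != "voltage_clamp":
        raise InputError("test-pulse analysis requires a voltage-clamp sweep")
    if sweep.stimulus is None:
        raise InputError("sweep has no stimulus description")


def _baseline(sweep: Sweep) -> float:
    onset_idx = sweep.index_at(sweep.stimulus.onset)
    if onset_idx < 2:
        raise InputError("need >= 1 ms pre-step baseline")
    return float(np.mean(sweep.signal[:onset_idx]))


def _step_window(sweep: Sweep) -> tuple[int, int]:
    """Sample span [onset, onset+duration) — the off-transient is excluded."""
    stim = sweep.stimulus
    i0 = sweep.index_at(stim.onset)
    i1 = sweep.index_at(stim.onset + stim.duration) - 1
    return i0, min(i1, len(sweep.signal) - 1)


def _steady_state(sweep: Sweep) -> float:
    i0, i1 = _step_window(sweep)
    n = i1 - i0
    start = i1 - max(1, int(round(n * SS_FRACTION)))
    return float(np.mean(sweep.signal[start : i1 + 1]))


def series_resistance(sweep: Sweep, delta_v: float) -> float:
    """Series resistance (MOhm) from the peak of the capacitive transient.

    Rs = dV / (I_peak - I_baseline).  ``delta_v`` is the command step in mV.
    """
    _require_vc(sweep)
    if delta_v == 0:
        raise InputError("delta_v must be non-zero")
    base = _baseline(sweep)
    i0, i1 = _step_window(sweep)
    deflect = sweep.signal[i0 : i1 + 1] - base
    peak_idx = int(np.argmax(np.abs(deflect)))
    i_peak = deflect[peak_idx]
    if abs(i_peak) < 1e-12:
        raise InputError("no detectable current transient")
    rs = delta_v / i_peak * 1e3  # mV/pA -> GOhm -> MOhm
    return float(abs(rs))


def input_resistance(sweep: Sweep, delta_v: float) -> float:
    """Input resistance (MOhm) from the steady-state current deflection.

    Ri = dV / (I_ss - I_baseline).  For the two-resistor access model this
    returns Rs + Ri, which is ~Ri whenever Rs << Ri.
    """
    _require_vc(sweep)
    if delta_v == 0:
        raise InputError("delta_v must be non-zero")
    base = _baseline(sweep)
    di = _steady_state(sweep) - base
    if abs(di) < 1e-12:
        raise InputError("zero steady-state deflection: resistance undefined")
    return float(abs(delta_v / di * 1e3))


def membrane_capacitance(sweep: Sweep, delta_v: float) -> float:
    """Membrane capacitance (pF) from the charge under the decaying transient.

    Cm = (integral from the peak sample to the step end of (I - I_ss) dt) / dV,
    by the trapezoidal rule, peak sample inclusive, no extrapolation of the
    charge missed before the sampled peak.
    """
    _require_vc(sweep)
    if delta_v == 0:
        raise InputError("delta_v must be non-zero")
    base = _baseline(sweep)
    i0, i1 = _step_window(sweep)
    seg = sweep.signal[i0 : i1 + 1]
    peak_rel = int(np.argmax(np.abs(seg - base)))
    i_ss = _steady_state(sweep)
    decay = seg[peak_rel:] - i_ss
    t_ms = (sweep.time[i0 + peak_rel : i1 + 1] - sweep.time[i0 + peak_rel]) * 1e3
    charge = float(np.trapezoid(decay, t_ms))  # pA*ms
    cm = charge / delta_v
    if cm <= 0:
        raise InputError("non-positive transient charge: polarity mismatch or flat trace")
    return float(cm)


def measure_test_pulse(sweep: Sweep, delta_v: Optional[float] = None) -> TestPulseMeasurement:
    """Full test-pulse measurement: Rs, Ri and Cm from one VC sweep."""
    _require_vc(sweep)
    if delta_v is None:
        delta_v = sweep.stimulus.amplitude
    base = _baseline(sweep)
    i0, i1 = _step_window(sweep)
    seg = sweep.signal[i0 : i1 + 1]
    peak_rel = int(np.argmax(np.abs(seg - base)))
    i_peak = float(seg[peak_rel])
    i_ss = _steady_state(sweep)
    rs = series_resistance(sweep, delta_v)
    ri_total = input_resistance(sweep, delta_v)
    cm = membrane_capacitance(sweep, delta_v)
    decay = seg[peak_rel:] - i_ss
    t_ms = (sweep.time[i0 + peak_rel : i1 + 1] - sweep.time[i0 + peak_rel]) * 1e3
    charge = float(np.trapezoid(decay, t_ms))
    # Warn when the step is too short for the transient to settle.
    tau_ms = rs * ri_total / (rs + ri_total) * cm * 1e-3 if rs > 0 else 0.0
    step_ms = (sweep.stimulus.duration) * 1e3
    warning = bool(tau_ms > 0 and step_ms < 5 * tau_ms)
    return TestPulseMeasurement(
        I_baseline=base, I_peak=i_peak, I_ss=i_ss, transient_charge=charge,
        R_s=rs, R_i=ri_total, C_m=cm, ss_warning=warning,
    )


def resting_potential(sweep: Sweep, window_s: float = 5.0):
    """Mean voltage over the first ``window_s`` seconds of an I=0 recording.

    Returns the mean in mV, or ``None`` when the trace contains any spike
    (spontaneously active cells are excluded from resting-potential
    estimates).  Raises when the recording is shorter than the window.
    """
    if sweep.clamp_mode != "current_clamp":
        raise InputError("resting potential requires a current-clamp (I=0) sweep")
    span = sweep.time[-1] - sweep.time[0]
    if span + sweep.dt < window_s - 1e-9:
        raise InputError(f"recording shorter than {window_s} s")
    from .trains import detect_spikes  # local import: avoids a cycle

    times, _ = detect_spikes(sweep)
    if len(times) > 0:
        return None
    n = int(round(window_s * sweep.sampling_rate))
    return float(np.mean(sweep.signal[:n]))
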
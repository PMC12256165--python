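"""Shared data model for patch-clamp protocol recordings.

Conventions used throughout the package: voltages in mV, currents in pA,
resistances in MOhm, capacitances in pF, feature times in ms.  Sweep time
grids are stored in seconds (matching the ``time_s`` column of the on-disk
CSV layout); converters live at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

CLAMP_MODES = ("current_clamp", "voltage_clamp")

PROTOCOL_KINDS = (
    "membrane_test",    # 10 ms, -10 mV VC test pulse from -60 mV
    "single_ap_10ms",   # 10 ms depolarising CC steps, 200 kHz
    "trains_500ms",     # 500 ms depolarising CC steps
    "mahp_train",       # 10 x 2 ms / 500 pA pulses at 50 Hz, 10 sweeps
    "sag_steps",        # 500 ms hyperpolarising CC steps
    "spontaneous_izero",  # I = 0 recording, >= 5 s
)

GROUPS = ("wpi5", "wpi9", "resident")
TREATMENTS = ("sham", "occluded")


class InputError(ValueError):
    """Raised when an operation's preconditions on its inputs are violated."""


@dataclass
class StepStimulus:
    """Description of the injected step (or pulse train) in a sweep.

    ``amplitude`` is in pA for current clamp and mV for voltage clamp.
    For pulse trains, ``pulse_width``/``n_pulses``/``frequency`` describe
    the train; plain steps leave them at their defaults.
    """

    onset: float            # s
    duration: float         # s
    amplitude: float        # pA (CC) or mV (VC)
    pulse_width: Optional[float] = None   # s, trains only
    n_pulses: int = 1
    frequency: Optional[float] = None     # Hz, trains only

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InputError("stimulus duration must be positive")
        if self.n_pulses < 1:
            raise InputError("n_pulses must be >= 1")

    @property
    def is_train(self) -> bool:
        return self.n_pulses > 1

    @property
    def train_end(self) -> float:
        """End time (s) of the stimulus: last pulse end for trains."""
        if self.is_train:
            assert self.frequency and self.pulse_width
            return self.onset + (self.n_pulses - 1) / self.frequency + self.pulse_width
        return self.onset + self.duration


@dataclass
class Sweep:
    """One time-series acquired in a single clamp configuration."""

    time: np.ndarray        # s, uniform grid
    signal: np.ndarray      # mV (CC) or pA (VC)
    sampling_rate: float    # Hz
    clamp_mode: str
    stimulus: Optional[StepStimulus] = None
    holding: Optional[float] = None   # mV: V_hold (VC) or baseline V (CC)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.clamp_mode not in CLAMP_MODES:
            raise InputError(f"unknown clamp mode {self.clamp_mode!r}")
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise InputError("time and signal must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise InputError("sweep must contain at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise InputError("time must be strictly increasing")
        expected = 1.0 / self.sampling_rate
        if not np.allclose(dt, expected, rtol=1e-6, atol=expected * 1e-6):
            raise InputError("time grid spacing must equal 1/sampling_rate")
        if not np.all(np.isfinite(self.signal)):
            raise InputError("signal contains non-finite values")
        if self.stimulus is not None:
            if self.stimulus.onset < self.time[0] or self.stimulus.train_end > self.time[-1]:
                raise InputError("stimulus window must lie inside the sweep")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the grid sample nearest to time ``t`` (s)."""
        return int(round((t - self.time[0]) * self.sampling_rate))


@dataclass
class ProtocolRecording:
    """Ordered set of sweeps from one protocol on one cell."""

    protocol_kind: str
    sweeps: list
    cell_id: str = ""
    group: Optional[str] = None
    treatment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protocol_kind not in PROTOCOL_KINDS:
            raise InputError(f"unknown protocol kind {self.protocol_kind!r}")
        if self.sweeps:
            mode = self.sweeps[0].clamp_mode
            rate = self.sweeps[0].sampling_rate
            for sw in self.sweeps:
                if sw.clamp_mode != mode:
                    raise InputError("all sweeps in a recording must share clamp mode")
                if not np.isclose(sw.sampling_rate, rate):
                    raise InputError("all sweeps in a recording must share sampling rate")

    def sorted_by_amplitude(self) -> "ProtocolRecording":
        """Copy with sweeps ordered by stimulus amplitude (incremental protocols)."""
        sweeps = sorted(
            self.sweeps,
            key=lambda sw: sw.stimulus.amplitude if sw.stimulus else 0.0,
        )
        return dataclasses.replace(self, sweeps=sweeps)

    def amplitudes(self) -> np.ndarray:
        return np.array(
            [sw.stimulus.amplitude if sw.stimulus else np.nan for sw in self.sweeps]
        )


# Columns of the per-cell feature table, in output order.
FEATURE_FIELDS = [
    "R_i", "C_m", "V_rest", "R_s_before", "R_s_after",
    "V_thresh", "V_max", "max_dvdt", "whh",
    "rheobase", "latency_first_spike", "fAHP", "mAHP", "sag_index",
    "max_spike_no", "IF_slope", "SAA_slope", "ISI_CV", "SFA", "SWA",
]


@dataclass
class CellFeatureRecord:
    """All extracted intrinsic properties for one cell (one feature-table row).

    Missing features (protocol absent or measurement excluded) are ``None``,
    never zero.
    """

    cell_id: str
    group: Optional[str] = None
    treatment: Optional[str] = None
    R_i: Optional[float] = None                 # MOhm
    C_m: Optional[float] = None                 # pF
    V_rest: Optional[float] = None              # mV
    R_s_before: Optional[float] = None          # MOhm
    R_s_after: Optional[float] = None           # MOhm
    V_thresh: Optional[float] = None            # mV
    V_max: Optional[float] = None               # mV
    max_dvdt: Optional[float] = None            # V/s
    whh: Optional[float] = None                 # ms
    rheobase: Optional[float] = None            # pA
    latency_first_spike: Optional[float] = None  # ms
    fAHP: Optional[float] = None                # mV
    mAHP: Optional[float] = None                # mV
    sag_index: Optional[float] = None           # unitless
    max_spike_no: Optional[float] = None        # count
    IF_slope: Optional[float] = None            # Hz/pA
    SAA_slope: Optional[float] = None           # %/pA
    ISI_CV: Optional[float] = None              # unitless
    SFA: Optional[float] = None                 # %
    SWA: Optional[float] = None                 # %
    spontaneous: Optional[bool] = None
    qc_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.whh is not None and self.whh <= 0:
            raise InputError("whh must be positive when a spike exists")
        if self.SFA is not None and self.SFA > 100 + 1e-9:
            raise InputError("SFA cannot exceed 100%")
        if self.ISI_CV is not None and self.ISI_CV < 0:
            raise InputError("ISI CV cannot be negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class QCRule:
    """Series-resistance quality control thresholds.

    Recordings are rejected when Rs exceeds ``rs_max`` at any point or
    changes by more than ``rs_change_max`` (as a fraction of the first
    measurement) during the recording.
    """

    rs_max: float = 30.0          # MOhm
    rs_change_max: float = 0.20   # fraction of the first measurement

    def __post_init__(self) -> None:
        if self.rs_max <= 0 or self.rs_change_max <= 0:
            raise InputError("QC thresholds must be positive")


def qc_series_resistance(rs_values: Sequence[float], rule: QCRule = QCRule()) -> bool:
    """Apply the series-resistance QC rule to all Rs measurements of a cell.

    Passes iff every value is <= ``rule.rs_max`` and the total excursion
    (max - min), referenced to the first measurement, is <= ``rule.rs_change_max``.
    """
    rs = np.asarray(list(rs_values), dtype=float)
    if rs.size == 0:
        raise InputError("at least one Rs measurement is required")
    if np.any(~np.isfinite(rs)) or np.any(rs <= 0):
        raise InputError("Rs measurements must be positive and finite")
    if np.any(rs > rule.rs_max):
        return False
    change = (rs.max() - rs.min()) / rs[0]
    return bool(change <= rule.rs_change_max + 1e-12)
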
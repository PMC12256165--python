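"""Reading and writing the on-disk layouts.

Sweeps are plain CSV files (columns ``time_s``, ``signal``) grouped in one
directory per cell and protocol, with a JSON sidecar (``protocol.json``)
carrying the stimulus metadata, clamp mode and sampling rate.  The feature
table is a single CSV with one row per cell; missing features are written
as empty fields and read back as ``None``.

ABF and NWB readers are exposed as hooks only: they delegate to ``pyabf`` /
``pynwb`` when those libraries are importable and raise a clear error
otherwise.  The CSV/JSON layout is the supported interchange format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import (
    CellFeatureRecord,
    FEATURE_FIELDS,
    InputError,
    ProtocolRecording,
    StepStimulus,
    Sweep,
)

_META_COLUMNS = ["cell_id", "group", "treatment"]
_BOOL_COLUMNS = ["spontaneous", "qc_pass"]
TABLE_COLUMNS = _META_COLUMNS + FEATURE_FIELDS + _BOOL_COLUMNS

# Numeric fields are serialized with enough digits for a bit-exact
# round-trip at double precision.
_FLOAT_FMT = "%.17g"


def write_feature_table(records: List[CellFeatureRecord], path) -> Path:
    """Write one CSV row per cell; empty cells encode missing features."""
    path = Path(path)
    rows = []
    for rec in records:
        d = rec.to_dict()
        rows.append({c: d[c] for c in TABLE_COLUMNS})
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path) -> List[CellFeatureRecord]:
    df = pd.read_csv(
        Path(path),
        dtype={c: object for c in _META_COLUMNS + _BOOL_COLUMNS},
        float_precision="round_trip",
    )
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in TABLE_COLUMNS:
            val = row[col]
            if pd.isna(val):
                kwargs[col] = None
            elif col in _BOOL_COLUMNS:
                kwargs[col] = str(val) == "True"
            elif col in _META_COLUMNS:
                kwargs[col] = str(val)
            else:
                kwargs[col] = float(val)
        records.append(CellFeatureRecord(**kwargs))
    return records


def feature_table_frame(records: List[CellFeatureRecord]) -> pd.DataFrame:
    """Feature records as a DataFrame (None -> NaN) for the stats module."""
    return pd.DataFrame([r.to_dict() for r in records], columns=TABLE_COLUMNS)


def _stimulus_to_dict(stim: Optional[StepStimulus]) -> Optional[dict]:
    return dataclasses.asdict(stim) if stim is not None else None


def write_recording(recording: ProtocolRecording, directory) -> Path:
    """Write a protocol recording as sweep CSVs plus a ``protocol.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "protocol_kind": recording.protocol_kind,
        "cell_id": recording.cell_id,
        "group": recording.group,
        "treatment": recording.treatment,
        "clamp_mode": recording.sweeps[0].clamp_mode if recording.sweeps else None,
        "sampling_rate": recording.sweeps[0].sampling_rate if recording.sweeps else None,
        "sweeps": [],
    }
    for i, sw in enumerate(recording.sweeps):
        name = f"sweep_{i:03d}.csv"
        arr = np.column_stack([sw.time, sw.signal])
        np.savetxt(
            directory / name, arr, delimiter=",", header="time_s,signal",
            comments="", fmt=_FLOAT_FMT,
        )
        meta["sweeps"].append(
            {"file": name, "stimulus": _stimulus_to_dict(sw.stimulus), "holding": sw.holding}
        )
    (directory / "protocol.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_recording(directory) -> ProtocolRecording:
    """Read back a recording written by :func:`write_recording`."""
    directory = Path(directory)
    meta_path = directory / "protocol.json"
    if not meta_path.exists():
        raise InputError(f"no protocol.json sidecar in {directory}")
    meta = json.loads(meta_path.read_text())
    sweeps = []
    for entry in meta["sweeps"]:
        arr = np.loadtxt(directory / entry["file"], delimiter=",", skiprows=1, ndmin=2)
        stim = StepStimulus(**entry["stimulus"]) if entry["stimulus"] else None
        sweeps.append(
            Sweep(
                time=arr[:, 0],
                signal=arr[:, 1],
                sampling_rate=meta["sampling_rate"],
                clamp_mode=meta["clamp_mode"],
                stimulus=stim,
                holding=entry.get("holding"),
            )
        )
    return ProtocolRecording(
        protocol_kind=meta["protocol_kind"],
        sweeps=sweeps,
        cell_id=meta["cell_id"],
        group=meta["group"],
        treatment=meta["treatment"],
    )


def read_abf(path):  # pragma: no cover - optional hook
    """Load an ABF file as a list of Sweeps (requires the optional ``pyabf``)."""
    try:
        import pyabf  # type: ignore
    except ImportError as exc:
        raise ImportError(
            "reading ABF files requires the optional dependency 'pyabf'; "
            "convert to the CSV/JSON sweep layout instead"
        ) from exc
    abf = pyabf.ABF(str(path))
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        sweeps.append(
            Sweep(
                time=abf.sweepX,
                signal=abf.sweepY,
                sampling_rate=abf.dataRate,
                clamp_mode="current_clamp" if "mV" in (abf.sweepUnitsY or "") else "voltage_clamp",
            )
        )
    return sweeps


def read_nwb(path):  # pragma: no cover - optional hook
    """Load an NWB acquisition series (requires the optional ``pynwb``)."""
    try:
        import pynwb  # type: ignore  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "reading NWB files requires the optional dependency 'pynwb'; "
            "convert to the CSV/JSON sweep layout instead"
        ) from exc
    raise NotImplementedError("NWB reading is an interface hook only")
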
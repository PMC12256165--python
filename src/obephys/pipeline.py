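"""End-to-end orchestration: traces -> per-cell features -> statistics report.

The pipeline extracts one :class:`~obephys.core.CellFeatureRecord` per
cell from whatever protocols are present (missing protocols yield nulls
for the affected features only), applies the series-resistance QC rule,
and runs the group-comparison ladder over the QC-passing cells.  Given a
seed the whole run is deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import (
    CellFeatureRecord,
    FEATURE_FIELDS,
    InputError,
    ProtocolRecording,
    QCRule,
    qc_series_resistance,
)
from . import io as obio
from . import passive as ppv
from . import trains as trn
from . import waveform as wvf
from .stats import GroupComparison

# Features compared across groups in the standard report.
REPORT_FEATURES = [
    "R_i", "C_m", "V_rest", "sag_index", "V_thresh", "V_max", "max_dvdt",
    "whh", "rheobase", "latency_first_spike", "fAHP", "mAHP",
    "max_spike_no", "IF_slope", "SAA_slope", "ISI_CV", "SFA", "SWA",
]


def extract_cell_features(
    recordings: Dict[str, ProtocolRecording],
    cell_id: str,
    group: Optional[str] = None,
    treatment: Optional[str] = None,
    rs_measurements: Optional[List[float]] = None,
    qc_rule: QCRule = QCRule(),
) -> CellFeatureRecord:
    """All intrinsic properties extractable from one cell's protocol set."""
    rec = CellFeatureRecord(cell_id=cell_id, group=group, treatment=treatment)

    if rs_measurements:
        rec.qc_pass = qc_series_resistance(rs_measurements, qc_rule)
        rec.R_s_before = float(rs_measurements[0])
        rec.R_s_after = float(rs_measurements[-1])

    mt = recordings.get("membrane_test")
    if mt is not None and mt.sweeps:
        try:
            m = ppv.measure_test_pulse(mt.sweeps[0])
            rec.R_i = m.R_i
            rec.C_m = m.C_m
            if rec.R_s_before is None:
                rec.R_s_before = m.R_s
        except InputError:
            pass

    izero = recordings.get("spontaneous_izero")
    if izero is not None and izero.sweeps:
        rec.spontaneous = trn.spontaneous_activity(izero.sweeps[0])
        try:
            rec.V_rest = ppv.resting_potential(izero.sweeps[0])
        except InputError:
            pass

    single = recordings.get("single_ap_10ms")
    if single is not None and single.sweeps:
        ladder = single.sorted_by_amplitude().sweeps
        try:
            idx = wvf.find_threshold_step(ladder)
        except InputError:
            idx = None
        if idx is not None:
            try:
                feats = wvf.ap_features(ladder[idx])
                rec.V_thresh = feats.V_thresh
                rec.V_max = feats.V_max
                rec.max_dvdt = feats.max_dvdt
                rec.whh = feats.whh
            except InputError:
                pass

    trains_rec = recordings.get("trains_500ms")
    if trains_rec is not None and trains_rec.sweeps:
        rheo, latency, fahp = trn.rheobase_latency_fahp(trains_rec)
        rec.rheobase = rheo
        rec.latency_first_spike = latency
        rec.fAHP = fahp
        sweep_trains = trn.analyse_train_ladder(trains_rec)
        fits = trn.io_fit(sweep_trains)
        rec.max_spike_no = fits["max_spike_no"]
        rec.IF_slope = fits["IF_slope"]
        rec.SAA_slope = fits["SAA_slope"]
        rep = trn.at_1p5_rheobase(sweep_trains, rheo)
        rec.ISI_CV = rep["CV"]
        rec.SFA = rep["SFA"]
        rec.SWA = rep["SWA"]

    mahp_rec = recordings.get("mahp_train")
    if mahp_rec is not None and mahp_rec.sweeps:
        rec.mAHP = trn.mahp_amplitude(mahp_rec)

    sag_rec = recordings.get("sag_steps")
    if sag_rec is not None and sag_rec.sweeps:
        rec.sag_index = trn.sag_index(sag_rec).sag_index_at_minus100

    return rec


def extract_cohort(bundles, qc_rule: QCRule = QCRule()) -> List[CellFeatureRecord]:
    """Feature records for a list of synthetic cell bundles."""
    return [
        extract_cell_features(
            b.recordings, b.cell_id, b.group, b.treatment,
            rs_measurements=b.rs_measurements, qc_rule=qc_rule,
        )
        for b in bundles
    ]


def statistics_report(
    records: List[CellFeatureRecord],
    features: Optional[List[str]] = None,
    design: str = "auto",
) -> dict:
    """Group-comparison report over QC-passing cells, one entry per feature.

    Includes the spontaneous-firing proportion battery (overall exact test
    across groups plus pairwise contrasts at Bonferroni-corrected alpha).
    """
    from .stats import bonferroni_alpha, fisher_2x2, fisher_2xk

    kept = [r for r in records if r.qc_pass is not False]
    df = obio.feature_table_frame(kept)
    features = features or [f for f in REPORT_FEATURES if f in df.columns]
    comparison = GroupComparison(df, features).fit(design=design)
    report = {"n_cells": len(kept), "n_excluded_qc": len(records) - len(kept),
              "features": comparison.to_dict()}

    spont = df.dropna(subset=["spontaneous"])
    if not spont.empty and spont["group"].nunique() >= 2:
        groups = sorted(spont["group"].unique())
        succ = [int((spont.loc[spont["group"] == g, "spontaneous"] == True).sum())  # noqa: E712
                for g in groups]
        tot = [int((spont["group"] == g).sum()) for g in groups]
        pairs = {}
        m = len(groups) * (len(groups) - 1) // 2
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairs[f"{groups[i]} vs {groups[j]}"] = fisher_2x2(
                    succ[i], tot[i], succ[j], tot[j]
                )
        report["spontaneous_firing"] = {
            "groups": groups, "successes": succ, "totals": tot,
            "overall_p": fisher_2xk(succ, tot),
            "pairwise_p": pairs,
            "pairwise_alpha": bonferroni_alpha(0.05, m) if m else None,
        }
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Intrinsic-properties statistics report", ""]
    lines.append(f"Cells analysed: {report['n_cells']} "
                 f"(excluded by QC: {report['n_excluded_qc']})")
    lines.append("")
    lines.append("| feature | test | transform | p (factors) |")
    lines.append("|---|---|---|---|")
    for feat, res in report["features"].items():
        if res.get("terms"):
            p_txt = ", ".join(f"{k}: {v['p']:.3g}" for k, v in res["terms"].items())
        elif res.get("p") is not None:
            p_txt = f"{res['p']:.3g}"
        else:
            p_txt = "-"
        lines.append(f"| {feat} | {res['test']} | {res['transform']} | {p_txt} |")
    if "spontaneous_firing" in report:
        sp = report["spontaneous_firing"]
        lines.append("")
        counts = ", ".join(
            f"{g}: {s}/{t}" for g, s, t in zip(sp["groups"], sp["successes"], sp["totals"])
        )
        lines.append(f"Spontaneous firing ({counts}): overall exact p = "
                     f"{sp['overall_p']:.3g}; pairwise alpha = {sp['pairwise_alpha']}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: dict) -> dict:
    """Run the full pipeline from a config dictionary.

    Config keys: either ``input_dir`` (a directory of per-cell/protocol
    CSV+JSON recordings) or ``synthetic`` (a block passed to
    :class:`~obephys.synth.CohortSpec`); ``output_dir``; optional
    ``seed`` (overrides the synthetic master seed) and ``qc`` thresholds.
    Writes ``features.csv``, ``stats_report.json`` and ``report.md``.
    """
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    qc_cfg = config.get("qc", {})
    qc_rule = QCRule(
        rs_max=qc_cfg.get("rs_max", 30.0),
        rs_change_max=qc_cfg.get("rs_change_max", 0.20),
    )

    if "synthetic" in config:
        from .synth import CohortSpec, generate_cohort, ground_truth_frame

        synth_cfg = dict(config["synthetic"])
        if "seed" in config:
            synth_cfg["master_seed"] = int(config["seed"])
        spec = CohortSpec(**synth_cfg)
        bundles = generate_cohort(spec)
        records = extract_cohort(bundles, qc_rule)
        ground_truth_frame(bundles).to_csv(out_dir / "ground_truth.csv", index=False)
    elif "input_dir" in config:
        records = []
        root = Path(config["input_dir"])
        for cell_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            recs = {}
            for proto_dir in sorted(p for p in cell_dir.iterdir() if p.is_dir()):
                rec = obio.read_recording(proto_dir)
                recs[rec.protocol_kind] = rec
            if not recs:
                continue
            any_rec = next(iter(recs.values()))
            rs_path = cell_dir / "rs_measurements.json"
            rs = json.loads(rs_path.read_text()) if rs_path.exists() else None
            records.append(
                extract_cell_features(
                    recs, cell_dir.name, any_rec.group, any_rec.treatment,
                    rs_measurements=rs, qc_rule=qc_rule,
                )
            )
    else:
        raise InputError("config needs either 'input_dir' or a 'synthetic' block")

    obio.write_feature_table(records, out_dir / "features.csv")
    report = statistics_report(records, design=config.get("design", "auto"))
    (out_dir / "stats_report.json").write_text(
        json.dumps(report, indent=1, default=_json_default, sort_keys=True)
    )
    (out_dir / "report.md").write_text(_report_markdown(report))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
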
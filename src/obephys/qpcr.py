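"""Relative qPCR quantification: standard-curve efficiency and 2^(-ddCt).

Amplification efficiency is estimated from a serial-dilution standard
curve as E = 10^(-1/slope) - 1, where the slope comes from an ordinary
least-squares regression of Ct on log10(dilution).  Relative expression
uses the classic 2^(-ddCt) method: technical replicates are averaged on
the Ct scale, each sample's target Ct is normalised to the housekeeping
gene (dCt), then to the mean of the control condition (ddCt), and the
fold change is 2^(-ddCt).  The classic method assumes E = 1; an
efficiency-corrected variant ((1+E_target)^-dCt_target /
(1+E_hk)^-dCt_hk style) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InputError

#: slope of a perfectly doubling standard curve (Ct per log10 dilution)
PERFECT_DOUBLING_SLOPE = -1.0 / np.log10(2.0)   # ~ -3.3219


@dataclass
class StandardCurve:
    dilutions: np.ndarray
    cts: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    flagged: bool = False   # non-negative slope: not a valid curve


def efficiency_from_curve(dilutions: Sequence[float], cts: Sequence[float]) -> StandardCurve:
    """Amplification efficiency from a serial-dilution standard curve."""
    d = np.asarray(list(dilutions), dtype=float)
    c = np.asarray(list(cts), dtype=float)
    if d.size != c.size or d.size < 3:
        raise InputError("standard curve needs >= 3 dilution points")
    if np.any(d <= 0):
        raise InputError("dilution factors must be positive")
    res = sps.linregress(np.log10(d), c)
    slope = float(res.slope)
    flagged = slope >= 0
    eff = float(10.0 ** (-1.0 / slope) - 1.0) if slope != 0 else np.nan
    return StandardCurve(
        dilutions=d, cts=c, slope=slope, intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), efficiency=eff, flagged=flagged,
    )


def _mean_ct(frame: pd.DataFrame, sample_col: str, ct_col: str) -> pd.Series:
    """Technical replicates averaged on the Ct scale, per sample."""
    return frame.groupby(sample_col)[ct_col].mean()


def ddct_fold_changes(
    records: pd.DataFrame,
    control: str = "sham",
    sample_col: str = "sample",
    condition_col: str = "condition",
    gene_col: str = "gene",
    ct_col: str = "Ct",
    target_gene: str = "Th",
    housekeeping_gene: str = "ActB",
    normalise: str = "dct_mean",
    efficiencies: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-sample fold changes by the 2^(-ddCt) method.

    ``records`` is a long table (sample, condition, gene, replicate Ct).
    ``normalise`` selects the control reference: ``"dct_mean"`` (default)
    subtracts the mean control dCt before exponentiation; ``"fold_mean"``
    exponentiates each sample's dCt and divides by the mean control fold.
    Passing per-gene ``efficiencies`` ({gene: E}) switches to the
    efficiency-corrected variant using (1+E) as the amplification base.
    """
    df = records.copy()
    for col in (sample_col, condition_col, gene_col, ct_col):
        if col not in df.columns:
            raise InputError(f"missing column {col!r}")
    tgt = df[df[gene_col] == target_gene]
    hk = df[df[gene_col] == housekeeping_gene]
    if hk.empty:
        raise InputError(f"no housekeeping ({housekeeping_gene}) Ct values")
    if tgt.empty:
        raise InputError(f"no target ({target_gene}) Ct values")
    ct_t = _mean_ct(tgt, sample_col, ct_col)
    ct_h = _mean_ct(hk, sample_col, ct_col)
    samples = ct_t.index.intersection(ct_h.index)
    missing = ct_t.index.difference(ct_h.index)
    if len(missing):
        raise InputError(f"samples missing housekeeping Ct: {list(missing)}")
    cond = df.drop_duplicates(sample_col).set_index(sample_col)[condition_col]
    out = pd.DataFrame(index=samples)
    out["condition"] = cond.loc[samples]
    if control not in set(out["condition"]):
        raise InputError(f"no samples in control condition {control!r}")

    if efficiencies:
        base_t = 1.0 + efficiencies.get(target_gene, 1.0)
        base_h = 1.0 + efficiencies.get(housekeeping_gene, 1.0)
        # efficiency-corrected relative quantity on a log2-equivalent scale
        out["dCt"] = (np.log2(base_t) * ct_t.loc[samples]
                      - np.log2(base_h) * ct_h.loc[samples])
    else:
        out["dCt"] = ct_t.loc[samples] - ct_h.loc[samples]

    ctrl_mask = out["condition"] == control
    if normalise == "dct_mean":
        ref = out.loc[ctrl_mask, "dCt"].mean()
        out["ddCt"] = out["dCt"] - ref
        out["fold_change"] = 2.0 ** (-out["ddCt"])
    elif normalise == "fold_mean":
        raw_fold = 2.0 ** (-out["dCt"])
        ref = raw_fold[ctrl_mask].mean()
        out["fold_change"] = raw_fold / ref
        out["ddCt"] = -np.log2(out["fold_change"])
    else:
        raise InputError("normalise must be 'dct_mean' or 'fold_mean'")
    out.attrs["normalise"] = normalise
    out.attrs["efficiency_corrected"] = bool(efficiencies)
    return out.reset_index().rename(columns={"index": sample_col})
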
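"""Relative gene expression by the 2^-ddCt method.

Duplicate cycle thresholds are averaged on the Ct scale per sample/gene;
dCt = Ct_target - Ct_reference within each sample; ddCt subtracts the
arithmetic mean dCt of the calibrator group, by default within the matching
time stratum (each time's saline controls calibrate that time); relative
expression is 2^-ddCt.  By construction the geometric mean of the
calibrator group's relative expression is exactly 1 in every stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct", "ExpressionError"]

REQUIRED_COLUMNS = ["sample_id", "group", "time_h", "gene", "role",
                    "replicate", "ct"]


class ExpressionError(ValueError):
    pass


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ExpressionError(f"missing columns: {missing}")
    df = records.copy()
    bad = ~((df["ct"] > 0) & (df["ct"] <= 45))
    if bad.any():
        raise ExpressionError(
            f"Ct values outside (0, 45] at rows {list(df.index[bad])}")
    if not df["role"].isin(["target", "reference"]).all():
        raise ExpressionError("role must be 'target' or 'reference'")
    return df


def ddct(records: pd.DataFrame, calibrator: str,
         per_time: bool = True) -> pd.DataFrame:
    """Per-sample relative expression for every target gene.

    Parameters
    ----------
    records : long table with columns sample_id, group, time_h, gene,
        role (target|reference), replicate, ct.
    calibrator : group label whose mean dCt anchors ddCt = 0.
    per_time : calibrate within each time stratum (default) or against the
        calibrator group pooled over all times.

    Returns a tidy frame: sample_id, group, time_h, gene, rel_expr.
    """
    df = _validate(records)
    # duplicate wells averaged on the Ct scale before any differencing
    ct = (df.groupby(["sample_id", "group", "time_h", "gene", "role"],
                     sort=False)["ct"].mean().reset_index())
    ref = ct[ct["role"] == "reference"]
    dup_ref = ref.duplicated(subset=["sample_id"], keep=False)
    if dup_ref.any():
        raise ExpressionError(
            f"multiple reference genes for samples "
            f"{sorted(ref.loc[dup_ref, 'sample_id'].unique())}")
    ref = ref.set_index("sample_id")["ct"]
    tgt = ct[ct["role"] == "target"].copy()
    no_ref = ~tgt["sample_id"].isin(ref.index)
    if no_ref.any():
        raise ExpressionError(
            f"samples without a reference gene: "
            f"{sorted(tgt.loc[no_ref, 'sample_id'].unique())}")
    tgt["dct"] = tgt["ct"].to_numpy() - ref.loc[tgt["sample_id"]].to_numpy()

    strata = ["gene", "time_h"] if per_time else ["gene"]
    calib = tgt[tgt["group"] == calibrator]
    if calib.empty:
        raise ExpressionError(f"calibrator group {calibrator!r} is empty")
    means = calib.groupby(strata)["dct"].mean()
    key = pd.MultiIndex.from_frame(tgt[strata]) if len(strata) > 1 \
        else tgt[strata[0]]
    anchor = means.reindex(key).to_numpy()
    if np.any(~np.isfinite(anchor)):
        missing = tgt.loc[~np.isfinite(anchor), strata].drop_duplicates()
        raise ExpressionError(
            f"empty calibrator stratum for:\n{missing.to_string(index=False)}")
    tgt["rel_expr"] = np.exp2(-(tgt["dct"].to_numpy() - anchor))
    return tgt[["sample_id", "group", "time_h", "gene", "rel_expr"]
               ].reset_index(drop=True)
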
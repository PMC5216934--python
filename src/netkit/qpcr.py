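"""Relative quantification of qPCR validation targets by 2^-ddCt.

Replicate wells are averaged on the Ct scale (Livak convention), the target
Ct is normalized against a reference gene (dCt = Ct_target - Ct_reference),
and the tumor/normal contrast per tissue pair is ddCt with relative fold
2^-ddCt. Per-target significance is a two-sided paired t-test on dCt
(equivalently a one-sample t on ddCt); the fold-scale test is reported
alongside since fold values are log-normal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

from .dataio import DataIOError

__all__ = ["read_ct", "ddct", "qpcr_test", "CT_COLUMNS"]

CT_COLUMNS = ["target_id", "pair_id", "condition", "replicate_index",
              "ct_target", "ct_reference"]


def read_ct(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise DataIOError(f"Ct table missing columns: {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise DataIOError(f"{col} values must be finite and positive")
    bad = set(table["condition"]) - {"tumor", "normal"}
    if bad:
        raise DataIOError(f"unknown conditions in Ct table: {sorted(bad)}")
    return table


def ddct(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-target, per-pair relative fold 2^-ddCt.

    Replicates are averaged per (target, pair, condition) before dCt.
    Pairs missing one condition are dropped with a warning. Returns columns
    target_id, pair_id, dct_tumor, dct_normal, ddct, fold.
    """
    means = (ct.groupby(["target_id", "pair_id", "condition"])
             [["ct_target", "ct_reference"]].mean().reset_index())
    means["dct"] = means["ct_target"] - means["ct_reference"]
    wide = means.pivot_table(index=["target_id", "pair_id"],
                             columns="condition", values="dct",
                             aggfunc="first").reset_index()
    incomplete = wide[wide.get("tumor").isna() | wide.get("normal").isna()] \
        if {"tumor", "normal"}.issubset(wide.columns) else wide
    if {"tumor", "normal"} - set(wide.columns) or len(incomplete):
        dropped = incomplete[["target_id", "pair_id"]].to_records(index=False) \
            if {"tumor", "normal"}.issubset(wide.columns) else None
        warnings.warn(f"dropping pairs missing a condition: {dropped}",
                      stacklevel=2)
        if not {"tumor", "normal"}.issubset(wide.columns):
            return pd.DataFrame(columns=["target_id", "pair_id", "dct_tumor",
                                         "dct_normal", "ddct", "fold"])
        wide = wide.dropna(subset=["tumor", "normal"])
    out = pd.DataFrame({
        "target_id": wide["target_id"],
        "pair_id": wide["pair_id"],
        "dct_tumor": wide["tumor"],
        "dct_normal": wide["normal"],
    })
    out["ddct"] = out["dct_tumor"] - out["dct_normal"]
    out["fold"] = 2.0 ** (-out["ddct"])
    return out.sort_values(["target_id", "pair_id"],
                           kind="mergesort").reset_index(drop=True)


def qpcr_test(folds: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-target summary: mean +/- SD of fold and paired significance.

    ``folds`` is the output of :func:`ddct`. The primary p-value is a
    two-sided paired t-test on dCt (tumor vs normal); ``p_value_fold``
    tests the fold values against 1 on the linear scale. Requires >= 3
    pairs per target.
    """
    rows = []
    for target, grp in folds.groupby("target_id", sort=True):
        if len(grp) < 3:
            raise ValueError(f"{target}: qPCR test needs >= 3 pairs, "
                             f"got {len(grp)}")
        res = st.ttest_rel(grp["dct_tumor"], grp["dct_normal"])
        p_dct = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        res_fold = st.ttest_1samp(grp["fold"], 1.0)
        p_fold = float(res_fold.pvalue) if np.isfinite(res_fold.pvalue) else 1.0
        rows.append({
            "target_id": target,
            "n_pairs": len(grp),
            "mean_fold": float(grp["fold"].mean()),
            "sd_fold": float(grp["fold"].std(ddof=1)),
            "median_fold": float(grp["fold"].median()),
            "mean_ddct": float(grp["ddct"].mean()),
            "p_value": p_dct,
            "p_value_fold": p_fold,
            "significant": p_dct < alpha,
        })
    return pd.DataFrame(rows)
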
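"""Differential expression for paired tumor/normal microarray profiles.

The screening rule applied throughout the pipeline retains a transcript when
fold change >= 2.0 (inclusive), p < 0.05 and FDR < 0.05 (both strict), with
the p-value from a two-sided paired t-test on per-pair log2 differences and
the FDR from Benjamini-Hochberg, computed within a transcript class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .dataio import DataIOError, ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "de_test",
    "bh_fdr",
    "apply_filter",
    "fc_tier",
    "cluster_order",
]

DE_COLUMNS = [
    "transcript_id", "mean_log2_tumor", "mean_log2_normal", "log2fc",
    "fold_change", "p_value", "fdr", "direction", "zero_var",
]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the cross-column rank-mean distribution.

    Ties within a column receive the mean of the reference values across the
    tied span, so permutation-equivalent columns map to identical output.
    """
    vals = m.values.to_numpy(dtype=float)
    n, k = vals.shape
    if k < 2:
        raise DataIOError("quantile normalization needs >= 2 samples")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = reference.copy()
        sorted_col = col[order]
        # average the reference over each run of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[s:e] = reference[s:e].mean()
        out[order, j] = ranked
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.samples.copy())


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(m: ExpressionMatrix, fc_min: float = 2.0, p_max: float = 0.05,
            fdr_max: float = 0.05, paired: bool = True) -> pd.DataFrame:
    """Per-transcript differential expression table for one transcript class.

    Returns a DataFrame with columns ``DE_COLUMNS``. ``fold_change`` is the
    ratio reported >= 1 (2**|log2fc|) with the sign carried by ``log2fc`` and
    ``direction``. Zero-variance difference vectors are flagged and given
    p = 1 rather than raising, so constant null fixtures flow through.
    """
    tum_cols, nrm_cols = m.paired_columns()
    if len(tum_cols) < 2:
        raise DataIOError("differential expression needs >= 2 pairs")
    tum = m.values[tum_cols].to_numpy(dtype=float)
    nrm = m.values[nrm_cols].to_numpy(dtype=float)
    mean_t = tum.mean(axis=1)
    mean_n = nrm.mean(axis=1)
    log2fc = mean_t - mean_n

    if paired:
        diffs = tum - nrm
        sd = diffs.std(axis=1, ddof=1)
        zero_var = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            res = st.ttest_rel(tum, nrm, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        sd_t = tum.std(axis=1, ddof=1)
        sd_n = nrm.std(axis=1, ddof=1)
        zero_var = (sd_t == 0) & (sd_n == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = st.ttest_ind(tum, nrm, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    p[zero_var | ~np.isfinite(p)] = 1.0

    fdr = bh_fdr(p)
    table = pd.DataFrame({
        "transcript_id": m.transcript_ids,
        "mean_log2_tumor": mean_t,
        "mean_log2_normal": mean_n,
        "log2fc": log2fc,
        "fold_change": 2.0 ** np.abs(log2fc),
        "p_value": p,
        "fdr": fdr,
        "zero_var": zero_var,
    })
    lfc_min = np.log2(fc_min)
    passes = (p < p_max) & (fdr < fdr_max)
    direction = np.where(passes & (log2fc >= lfc_min), "up",
                         np.where(passes & (log2fc <= -lfc_min), "down", "ns"))
    table["direction"] = direction
    return table[DE_COLUMNS]


def apply_filter(records: pd.DataFrame, fc_min: float = 2.0,
                 p_max: float = 0.05, fdr_max: float = 0.05
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split DE records into (up, down) by the screening rule.

    Fold-change comparison is inclusive (>= fc_min), p and FDR strict (<).
    """
    lfc_min = np.log2(fc_min)
    passes = (records["p_value"] < p_max) & (records["fdr"] < fdr_max)
    up = records[passes & (records["log2fc"] >= lfc_min)]
    down = records[passes & (records["log2fc"] <= -lfc_min)]
    return up.reset_index(drop=True), down.reset_index(drop=True)


def fc_tier(records: pd.DataFrame, fc_min: float = 10.0,
            p_max: float = 0.05, fdr_max: float = 0.05
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """High-magnitude tier of already-screened records (default FC >= 10)."""
    return apply_filter(records, fc_min=fc_min, p_max=p_max, fdr_max=fdr_max)


def _correlation_distance(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1 - Pearson r between rows; constant rows get distance 1 to everything."""
    sd = rows.std(axis=1)
    constant = sd == 0
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return dist, constant


def cluster_order(m: ExpressionMatrix, subset_ids=None):
    """Average-linkage leaf order for transcripts and samples.

    Distance is 1 - Pearson r; ids are lexicographically pre-sorted so equal
    distances break ties deterministically. Returns
    ``(transcript_order, sample_order, flagged_constant_ids)``.
    """
    ids = sorted(subset_ids) if subset_ids is not None else sorted(m.transcript_ids)
    if not ids:
        raise DataIOError("cluster_order needs a nonempty transcript subset")
    sub = m.values.loc[ids]
    rows = sub.to_numpy(dtype=float)

    def _leaves(matrix: np.ndarray, labels: list[str]) -> tuple[list[str], list[str]]:
        dist, constant = _correlation_distance(matrix)
        flagged = [lbl for lbl, c in zip(labels, constant) if c]
        if len(labels) == 1:
            return list(labels), flagged
        link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
        return [labels[i] for i in sch.leaves_list(link)], flagged

    tx_order, tx_flagged = _leaves(rows, ids)
    cols = list(sub.columns)
    sample_order, _ = _leaves(rows.T, cols)
    return tx_order, sample_order, tx_flagged
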
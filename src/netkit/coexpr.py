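"""Coding-noncoding co-expression (CNC) network from Pearson correlation.

An edge between a noncoding transcript and an mRNA is retained when
|PCC| >= 0.90, p < 0.01 and BH-FDR < 0.01, with the p-value from the
standard t-transform of the sample correlation (df = n - 2) and the FDR
taken over the full family of tested pairs. Positive and negative edges
carry distinct sign labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .dataio import DataIOError, ExpressionMatrix
from .diffexpr import bh_fdr

__all__ = ["pcc", "pcc_test", "build_cnc", "EDGE_COLUMNS"]

EDGE_COLUMNS = ["id_a", "id_b", "pcc", "p_value", "fdr", "sign"]


def pcc(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def pcc_test(r: float, n: int) -> float:
    """Two-sided p for a sample correlation via t = r*sqrt((n-2)/(1-r^2))."""
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0  # degenerate limit
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * st.t.sf(abs(t), df=n - 2))


def _row_standardize(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    norms[constant] = 1.0
    return centered / norms[:, None], constant


def build_cnc(noncoding: ExpressionMatrix, coding: ExpressionMatrix,
              pcc_min: float = 0.90, p_max: float = 0.01,
              fdr_max: float = 0.01, sample_ids=None) -> pd.DataFrame:
    """Test all noncoding x coding pairs and return the retained edge table.

    Both matrices must share identical sample columns; correlations are
    computed across all arrays jointly (tumor and normal) unless
    ``sample_ids`` restricts the columns. Constant transcripts have no
    defined correlation and contribute no edges. Edges are deduplicated
    and sorted by (id_a, id_b).
    """
    if list(noncoding.values.columns) != list(coding.values.columns):
        raise DataIOError("noncoding and coding matrices must share samples")
    cols = list(noncoding.values.columns)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in cols]
        if missing:
            raise DataIOError(f"unknown sample ids: {missing}")
        cols = list(sample_ids)
    n = len(cols)
    if n < 3:
        raise DataIOError("correlation needs >= 3 arrays")

    x = noncoding.values[cols].to_numpy(dtype=float)
    y = coding.values[cols].to_numpy(dtype=float)
    xs, x_const = _row_standardize(x)
    ys, y_const = _row_standardize(y)
    corr = np.clip(xs @ ys.T, -1.0, 1.0)

    nc_ids = np.asarray(noncoding.transcript_ids)
    c_ids = np.asarray(coding.transcript_ids)
    valid = ~x_const[:, None] & ~y_const[None, :]
    r_flat = corr[valid]
    ai, bi = np.nonzero(valid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_flat * np.sqrt((n - 2) / np.maximum(1.0 - r_flat ** 2, 0.0))
    p_flat = 2.0 * st.t.sf(np.abs(t), df=n - 2)
    p_flat[np.abs(r_flat) == 1.0] = 0.0
    fdr_flat = bh_fdr(p_flat)

    keep = (np.abs(r_flat) >= pcc_min) & (p_flat < p_max) & (fdr_flat < fdr_max)
    edges = pd.DataFrame({
        "id_a": nc_ids[ai[keep]],
        "id_b": c_ids[bi[keep]],
        "pcc": r_flat[keep],
        "p_value": p_flat[keep],
        "fdr": fdr_flat[keep],
    })
    edges["sign"] = np.where(edges["pcc"] >= 0, "positive", "negative")
    edges = edges.drop_duplicates(["id_a", "id_b"])
    edges = edges.sort_values(["id_a", "id_b"], kind="mergesort")
    return edges.reset_index(drop=True)[EDGE_COLUMNS]


def coexpressed_partners(edges: pd.DataFrame) -> dict[str, set[str]]:
    """Map each noncoding id to its set of co-expressed coding partners."""
    out: dict[str, set[str]] = {}
    for id_a, id_b in zip(edges["id_a"], edges["id_b"]):
        out.setdefault(id_a, set()).add(id_b)
    return out
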
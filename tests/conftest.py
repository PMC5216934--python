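"""Shared fixtures: synthetic bundles at two scales and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netkit import SimConfig, generate_bundle
from netkit.dataio import ExpressionMatrix

SMALL_CONFIG = SimConfig(
    n_pairs=4, n_lnc=80, n_circ=40, n_mrna=160, n_mirna=8,
    frac_de=0.3, n_coexpr_pairs=4, n_cerna_triples=4, n_cis_pairs=3,
    n_tf_modules=2, tf_module_n_lnc=2, tf_module_n_mrna=6, n_decoy_tfs=3,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One compact bundle reused by read-only unit tests."""
    return generate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    """A bundle at the default study conditions (4 tumor/normal pairs)."""
    return generate_bundle(SimConfig(rng_seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_matrix(values: np.ndarray, n_pairs: int,
               ids: list[str] | None = None) -> ExpressionMatrix:
    """Wrap a raw array as a paired tumor/normal ExpressionMatrix."""
    n, k = values.shape
    assert k == 2 * n_pairs
    cols, rows = [], []
    for p in range(n_pairs):
        pid = f"P{p + 1:02d}"
        cols += [f"{pid}T", f"{pid}N"]
        rows += [(f"{pid}T", pid, "tumor"), (f"{pid}N", pid, "normal")]
    samples = pd.DataFrame(rows, columns=["sample_id", "pair_id", "condition"])
    if ids is None:
        ids = [f"T{i:03d}" for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index(ids, name="transcript_id"),
                      columns=cols)
    return ExpressionMatrix(df, samples)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition applied literally: q_i = min_{p_(j) >= p_i} p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * n / j
                      for j in range(rank_pos, n + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_force_seed_scan(seq: str, mir: str):
    """Test every offset of the transcript for a typed seed match."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    core = "".join(comp[b] for b in reversed(mir[1:7]))
    hits = []
    for i in range(len(seq) - 5):
        if seq[i:i + 6] != core:
            continue
        m8 = i >= 1 and seq[i - 1] == comp[mir[7]]
        a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if m8 and a1:
            hits.append((i - 1, "8mer"))
        elif m8:
            hits.append((i - 1, "7mer-m8"))
        elif a1:
            hits.append((i, "7mer-A1"))
        else:
            hits.append((i, "6mer"))
    return hits


def paired_t_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook paired t-test, independent of scipy.ttest_rel."""
    import scipy.stats as st

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n))
    return float(2.0 * st.t.sf(abs(t), df=n - 1))


def naive_average_linkage(dist: np.ndarray):
    """O(n^3) agglomeration; returns merge steps as (set, set, height)."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    steps = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        a, b = clusters.pop(i), clusters.pop(j)
        merged = a | b
        steps.append((a, b, h))
        for k in list(clusters):
            da = d.pop((min(i, k), max(i, k)))
            db = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (
                len(a) * da + len(b) * db) / len(merged)
        d = {key: v for key, v in d.items() if i not in key and j not in key}
        clusters[next_id] = merged
        next_id += 1
    return steps
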
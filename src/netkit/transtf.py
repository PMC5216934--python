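"""Trans-regulation prediction through transcription factors.

For each differentially expressed lncRNA, the set of mRNAs it is
co-expressed with is tested against every TF's target set by the upper-tail
(cumulative) hypergeometric test; pairs retained at p < 0.01 and
BH-FDR < 0.01 form the lncRNA-TF binary network, expanded into the
lncRNA-TF-mRNA ternary network by attaching the overlap genes. TF target
sets are either supplied directly (GMT) or derived by scanning promoter
sequences with position frequency matrices.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .dataio import GeneSetCollection, PFM, revcomp
from .diffexpr import bh_fdr

__all__ = [
    "hypergeom_upper",
    "pfm_targets",
    "tf_enrich",
    "ternary_network",
    "ENRICH_COLUMNS",
]

ENRICH_COLUMNS = ["lnc_id", "tf_name", "k", "K", "n", "N",
                  "p_value", "fdr", "overlap_genes"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: marked genes, n: drawn genes, k: marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(st.hypergeom.sf(k - 1, N, K, n))


def _pwm_log_odds(pfm: PFM, pseudocount: float = 0.25) -> np.ndarray:
    counts = pfm.counts + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(probs / 0.25)


def _best_window_score(seq: str, pwm: np.ndarray) -> float:
    L = pwm.shape[1]
    if len(seq) < L:
        return -np.inf
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    best = -np.inf
    for strand_seq in (idx, np.array([_BASE_INDEX.get(b, -1)
                                      for b in revcomp(seq)])):
        valid = strand_seq >= 0
        for i in range(len(strand_seq) - L + 1):
            window = strand_seq[i:i + L]
            if not valid[i:i + L].all():
                continue
            score = pwm[window, np.arange(L)].sum()
            if score > best:
                best = score
    return best


def pfm_targets(pfms: Sequence[PFM], promoter_seqs: Mapping[str, str],
                pseudocount: float = 0.25, score_quantile: float = 0.99,
                rng_seed: int = 0) -> GeneSetCollection:
    """Derive TF target sets by log-odds PWM scanning of promoters.

    A gene is a target of a TF when the best window score of the TF's PWM
    on either strand of the gene's promoter reaches the ``score_quantile``
    of that PWM's null distribution (best-window scores on mononucleotide-
    shuffled promoters, fixed seed). Promoters shorter than the motif are
    skipped. TFs with no targets are dropped (gene sets must be nonempty).
    """
    rng = np.random.default_rng(rng_seed)
    shuffled = {g: "".join(rng.permutation(list(s)))
                for g, s in promoter_seqs.items()}
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for pfm in pfms:
        pwm = _pwm_log_odds(pfm, pseudocount)
        null_scores = [s for s in
                       (_best_window_score(shuffled[g], pwm)
                        for g in promoter_seqs)
                       if np.isfinite(s)]
        if not null_scores:
            continue
        threshold = float(np.quantile(null_scores, score_quantile))
        targets = tuple(sorted(
            g for g, seq in promoter_seqs.items()
            if len(seq) >= pfm.length
            and _best_window_score(seq, pwm) >= threshold
        ))
        if targets:
            sets[pfm.tf_name] = (f"PWM targets of {pfm.motif_id}", targets)
    return GeneSetCollection(sets)


def tf_enrich(lnc_coexpressed: Mapping[str, set[str]],
              tf_targets: GeneSetCollection, universe: set[str],
              p_max: float = 0.01, fdr_max: float = 0.01) -> pd.DataFrame:
    """Hypergeometric TF-target enrichment per (lncRNA, TF) pair.

    All sets are intersected with the universe first; BH-FDR is taken over
    the full family of tests; a pair is retained when p < p_max and
    fdr < fdr_max. Returns the retained rows sorted by (lnc_id, p, tf).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("enrichment universe is empty")
    N = len(universe)
    targets = {tf: tf_targets.members(tf) & universe
               for tf in tf_targets.names()}
    rows = []
    for lnc_id in sorted(lnc_coexpressed):
        genes = set(lnc_coexpressed[lnc_id]) & universe
        n = len(genes)
        if n == 0:
            continue
        for tf in sorted(targets):
            K = len(targets[tf])
            if K == 0:
                continue
            overlap = sorted(genes & targets[tf])
            k = len(overlap)
            p = hypergeom_upper(k, K, n, N)
            rows.append((lnc_id, tf, k, K, n, N, p, ",".join(overlap)))
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    table = pd.DataFrame(rows, columns=["lnc_id", "tf_name", "k", "K", "n",
                                        "N", "p_value", "overlap_genes"])
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    retained = table[(table["p_value"] < p_max) & (table["fdr"] < fdr_max)]
    retained = retained.sort_values(["lnc_id", "p_value", "tf_name"],
                                    kind="mergesort")
    return retained.reset_index(drop=True)[ENRICH_COLUMNS]


def ternary_network(enrichments: pd.DataFrame
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expand retained lncRNA-TF enrichments into the ternary edge table.

    Edges: ``lnc_tf`` from lncRNA to TF, ``tf_gene`` from TF to each gene in
    that pair's overlap. Returns the edge table and node/edge counts.
    """
    import networkx as nx

    rows = []
    for e in enrichments.itertuples(index=False):
        rows.append((e.lnc_id, e.tf_name, "lnc_tf"))
        genes = e.overlap_genes.split(",") if e.overlap_genes else []
        for g in genes:
            rows.append((e.tf_name, g, "tf_gene"))
    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type"])
    edges = edges.drop_duplicates().sort_values(
        ["edge_type", "source", "target"], kind="mergesort").reset_index(drop=True)

    graph = nx.from_pandas_edgelist(edges, "source", "target") if len(edges) \
        else nx.Graph()
    lnc_nodes = set(enrichments["lnc_id"]) if len(enrichments) else set()
    tf_nodes = set(enrichments["tf_name"]) if len(enrichments) else set()
    gene_nodes = set(graph.nodes) - lnc_nodes - tf_nodes
    counts = {
        "n_lnc": len(lnc_nodes),
        "n_tf": len(tf_nodes),
        "n_gene": len(gene_nodes),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": int(len(edges)),
    }
    return edges, counts
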
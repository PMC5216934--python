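"""Flat term enrichment (GO/KEGG-style) with -log10(p) enrichment scores.

Term sets are supplied as flat GMT files (no ontology DAG propagation);
significance is the upper-tail hypergeometric test against a platform
universe, corrected by Benjamini-Hochberg across terms. The enrichment
score is -log10 of the raw p-value; reports list the top-k terms per
direction (up/down) and domain.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataio import GeneSetCollection, TranscriptRecord
from .diffexpr import bh_fdr
from .transtf import hypergeom_upper

__all__ = ["term_enrich", "top_terms", "circ_host_enrich", "TERM_COLUMNS"]

TERM_COLUMNS = ["term_id", "term_name", "domain", "k", "K", "n", "N",
                "p_value", "fdr", "score"]

DOMAINS = ("biological_process", "cellular_component", "molecular_function",
           "pathway")


def _parse_description(desc: str) -> tuple[str, str]:
    """GMT description optionally carries ``domain|free text``."""
    if "|" in desc:
        domain, name = desc.split("|", 1)
        if domain in DOMAINS:
            return domain, name
    return "pathway", desc


def term_enrich(gene_list: Iterable[str], term_sets: GeneSetCollection,
                universe: Iterable[str]) -> pd.DataFrame:
    """Score every term set against one gene list.

    Terms come back sorted by score (descending), ties broken by term id.
    """
    universe = set(universe)
    genes = set(gene_list) & universe
    if not genes:
        raise ValueError("gene list is empty after intersection with universe")
    N = len(universe)
    n = len(genes)
    rows = []
    for term_id in sorted(term_sets.names()):
        desc, _members = term_sets.sets[term_id]
        members = term_sets.members(term_id) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        p = hypergeom_upper(k, K, n, N)
        domain, name = _parse_description(desc)
        rows.append((term_id, name, domain, k, K, n, N, p))
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "domain",
                                        "k", "K", "n", "N", "p_value"])
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["score"] = -np.log10(table["p_value"])
    table = table.sort_values(["score", "term_id"],
                              ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True)[TERM_COLUMNS]


def top_terms(terms: pd.DataFrame, k: int = 10,
              per_domain: bool = True) -> pd.DataFrame:
    """Top-k terms by enrichment score, per domain (and per direction if a
    ``direction`` column is present). Ties break lexicographically by id."""
    if terms.empty:
        return terms.copy()
    group_cols = []
    if "direction" in terms.columns:
        group_cols.append("direction")
    if per_domain:
        group_cols.append("domain")
    ordered = terms.sort_values(["score", "term_id"],
                                ascending=[False, True], kind="mergesort")
    if group_cols:
        out = ordered.groupby(group_cols, group_keys=False, sort=True).head(k)
    else:
        out = ordered.head(k)
    return out.reset_index(drop=True)


def circ_host_enrich(de_circ: pd.DataFrame,
                     annotation: Sequence[TranscriptRecord],
                     term_sets: GeneSetCollection,
                     universe: Iterable[str]) -> pd.DataFrame:
    """Term enrichment on host genes of DE circRNAs, per direction.

    ``de_circ`` is a DE table with ``transcript_id`` and ``direction``
    columns restricted to retained circRNAs. Host genes are deduplicated
    within each direction before testing.
    """
    if de_circ.empty:
        raise ValueError("no differentially expressed circRNAs supplied")
    host_by_id = {r.id: r.host_gene_id for r in annotation
                  if r.transcript_class == "circRNA"}
    missing = [t for t in de_circ["transcript_id"]
               if not host_by_id.get(t)]
    if missing:
        raise ValueError(f"circRNAs without a host gene: {sorted(missing)}")
    frames = []
    for direction in ("up", "down"):
        ids = de_circ.loc[de_circ["direction"] == direction, "transcript_id"]
        hosts = sorted({host_by_id[t] for t in ids})
        if not hosts:
            continue
        scored = term_enrich(hosts, term_sets, universe)
        scored.insert(0, "direction", direction)
        frames.append(scored)
    if not frames:
        return pd.DataFrame(columns=["direction", *TERM_COLUMNS])
    return pd.concat(frames, ignore_index=True)
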
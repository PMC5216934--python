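"""miRNA seed-site scanning and ceRNA (lncRNA/circRNA-miRNA-mRNA) inference.

A miRNA response element (MRE) on a transcript is an exact match to the
reverse complement of the miRNA seed, typed by the TargetScan taxonomy:

* ``6mer``    — reverse complement of miRNA positions 2-7;
* ``7mer-m8`` — the 6mer extended by a match to miRNA position 8 at the
  site's 5' end;
* ``7mer-A1`` — the 6mer plus an ``A`` on the transcript opposite miRNA
  position 1 (3' end of the site);
* ``8mer``    — both extensions at once.

Two transcripts that each carry at least one MRE for the same miRNA can
compete for it; the ceRNA network links differentially expressed
lncRNAs/circRNAs to differentially expressed mRNAs through such shared
miRNAs, gated on a retained positive co-expression edge (competition
implies co-directional expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .dataio import normalize_sequence, revcomp

__all__ = [
    "MRESite",
    "find_seed_sites",
    "scan_sites",
    "shared_mirnas",
    "build_cerna",
    "SITE_COLUMNS",
    "TRIPLE_COLUMNS",
]

SITE_COLUMNS = ["transcript_id", "mirna_id", "offset", "site_type"]
TRIPLE_COLUMNS = ["ce_id", "mirna_id", "mrna_id", "n_shared_mirnas",
                  "pcc", "p_value", "fdr"]

_SITE_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MRESite:
    transcript_id: str
    mirna_id: str
    offset: int  # 0-based start of the full site on the transcript
    site_type: str

    @property
    def length(self) -> int:
        return _SITE_LENGTH[self.site_type]


def _check_nucleotides(seq: str, what: str) -> str:
    seq = normalize_sequence(seq)
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-nucleotide characters: {sorted(bad)}")
    return seq


def find_seed_sites(transcript_seq: str, mirna_seq: str,
                    transcript_id: str = "", mirna_id: str = ""
                    ) -> list[MRESite]:
    """All seed matches of one miRNA on one transcript, overlapping included.

    The transcript is read 5'->3'; a site's core is the reverse complement
    of miRNA positions 2-7. Offsets point at the 5'-most base of the full
    typed site.
    """
    seq = _check_nucleotides(transcript_seq, "transcript")
    mir = _check_nucleotides(mirna_seq, "miRNA")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core = revcomp(mir[1:7])          # matches miRNA positions 2-7
    m8_base = _COMP[mir[7]]           # transcript base pairing miRNA pos 8
    sites: list[MRESite] = []
    i = seq.find(core)
    while i != -1:
        has_m8 = i >= 1 and seq[i - 1] == m8_base
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append(MRESite(transcript_id, mirna_id, i - 1, "8mer"))
        elif has_m8:
            sites.append(MRESite(transcript_id, mirna_id, i - 1, "7mer-m8"))
        elif has_a1:
            sites.append(MRESite(transcript_id, mirna_id, i, "7mer-A1"))
        else:
            sites.append(MRESite(transcript_id, mirna_id, i, "6mer"))
        i = seq.find(core, i + 1)
    return sites


def scan_sites(transcript_seqs: Mapping[str, str],
               mirna_seqs: Mapping[str, str]) -> pd.DataFrame:
    """Seed-site table over all transcript x miRNA combinations."""
    rows = []
    for tid, tseq in transcript_seqs.items():
        for mid, mseq in mirna_seqs.items():
            for s in find_seed_sites(tseq, mseq, tid, mid):
                rows.append((s.transcript_id, s.mirna_id, s.offset, s.site_type))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def shared_mirnas(sites_a: Iterable, sites_b: Iterable) -> set[str]:
    """miRNA ids with at least one site on both transcripts."""

    def _ids(sites) -> set[str]:
        if isinstance(sites, pd.DataFrame):
            return set(sites["mirna_id"])
        return {s.mirna_id for s in sites}

    return _ids(sites_a) & _ids(sites_b)


def build_cerna(de_ce: Iterable[str], de_mrna: Iterable[str],
                site_index: pd.DataFrame, coexpr_edges: pd.DataFrame,
                min_shared: int = 1) -> pd.DataFrame:
    """Infer ceRNA triples from shared MREs plus positive co-expression.

    Emits one row per (ce, miRNA, mRNA) where the differentially expressed
    ce-transcript and mRNA are joined by a retained positive co-expression
    edge and share >= ``min_shared`` miRNA seed families. Correlation
    evidence is copied from the co-expression edge.
    """
    de_ce = set(de_ce)
    de_mrna = set(de_mrna)
    mir_by_tx: dict[str, set[str]] = {
        tid: set(grp["mirna_id"])
        for tid, grp in site_index.groupby("transcript_id")
    }
    rows = []
    for edge in coexpr_edges.itertuples(index=False):
        if edge.sign != "positive":
            continue
        if edge.id_a not in de_ce or edge.id_b not in de_mrna:
            continue
        shared = mir_by_tx.get(edge.id_a, set()) & mir_by_tx.get(edge.id_b, set())
        if len(shared) < min_shared:
            continue
        for mir in sorted(shared):
            rows.append((edge.id_a, mir, edge.id_b, len(shared),
                         edge.pcc, edge.p_value, edge.fdr))
    triples = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    triples = triples.sort_values(["ce_id", "mrna_id", "mirna_id"],
                                  kind="mergesort")
    return triples.reset_index(drop=True)


def cerna_network_edges(triples: pd.DataFrame) -> pd.DataFrame:
    """Bipartite edge list: ce-transcripts and mRNAs connect only via miRNAs."""
    rows = []
    for t in triples.itertuples(index=False):
        rows.append((t.ce_id, t.mirna_id, "ce_mirna"))
        rows.append((t.mirna_id, t.mrna_id, "mirna_mrna"))
    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type"])
    edges = edges.drop_duplicates().sort_values(
        ["edge_type", "source", "target"], kind="mergesort")
    return edges.reset_index(drop=True)
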
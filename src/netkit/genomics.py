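"""Genomic-context classification of lncRNAs and cis nearby-gene analysis.

Differentially expressed lncRNAs are placed into six categories by their
relationship with protein-coding genes (Arraystar-style nomenclature):
exon sense-overlapping, intron sense-overlapping, natural antisense,
intronic antisense, bidirectional and intergenic, with ``unknown`` for
incomplete annotation. A coding gene within 300 kb of a differentially
expressed lncRNA that is also co-expressed with it is a candidate
cis-regulated target ("less than 300 kb" is a strict bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dataio import TranscriptRecord

__all__ = [
    "CATEGORY_PRIORITY",
    "LncClassification",
    "classify_lncrna",
    "class_counts",
    "nearby_coding_genes",
    "build_cis_network",
    "CIS_COLUMNS",
]

CATEGORY_PRIORITY = (
    "exon_sense_overlapping",
    "intron_sense_overlapping",
    "natural_antisense",
    "intronic_antisense",
    "bidirectional",
    "intergenic",
    "unknown",
)

CIS_COLUMNS = ["lnc_id", "gene_id", "distance", "same_chrom", "pcc", "sign"]


@dataclass
class LncClassification:
    lnc_id: str
    categories: set[str]
    supporting: dict[str, set[str]]  # category -> coding gene ids

    def exclusive(self) -> str:
        """Single top-priority category for percentage tables."""
        for cat in CATEGORY_PRIORITY:
            if cat in self.categories:
                return cat
        raise ValueError(f"{self.lnc_id}: empty category set")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _introns(gene: TranscriptRecord) -> list[tuple[int, int]]:
    exons = sorted(gene.exon_intervals())
    return [(exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i][1] < exons[i + 1][0]]


def classify_lncrna(lnc: TranscriptRecord,
                    coding: Sequence[TranscriptRecord],
                    bidirectional_gap: int = 1000) -> LncClassification:
    """Assign the six-category genomic context of one lncRNA.

    A lncRNA may hold several overlap categories simultaneously (one per
    associated coding gene); ``intergenic`` means it holds none of the
    overlap/bidirectional relationships with any coding gene.
    """
    if lnc.strand not in ("+", "-"):
        return LncClassification(lnc.id, {"unknown"}, {"unknown": set()})
    categories: dict[str, set[str]] = {}

    def add(cat: str, gene_id: str) -> None:
        categories.setdefault(cat, set()).add(gene_id)

    for gene in coding:
        if gene.chrom != lnc.chrom or gene.strand not in ("+", "-"):
            continue
        same_strand = gene.strand == lnc.strand
        span_overlap = _overlap(lnc.start, lnc.end, gene.start, gene.end)
        if span_overlap:
            exon_hit = any(_overlap(lnc.start, lnc.end, s, e)
                           for s, e in gene.exon_intervals())
            contained = gene.start <= lnc.start and lnc.end <= gene.end
            in_intron = contained and any(
                s <= lnc.start and lnc.end <= e for s, e in _introns(gene))
            if same_strand:
                if exon_hit:
                    add("exon_sense_overlapping", gene.id)
                elif in_intron or (contained and not exon_hit):
                    add("intron_sense_overlapping", gene.id)
                else:
                    # partial overlap touching no exon: still sense overlap
                    add("exon_sense_overlapping", gene.id)
            else:
                if in_intron:
                    add("intronic_antisense", gene.id)
                else:
                    add("natural_antisense", gene.id)
        else:
            if not same_strand:
                plus, minus = (lnc, gene) if lnc.strand == "+" else (gene, lnc)
                gap = plus.start - minus.end
                if 0 <= gap <= bidirectional_gap:
                    add("bidirectional", gene.id)
    if not categories:
        categories = {"intergenic": set()}
    return LncClassification(lnc.id, set(categories), categories)


def class_counts(classifications: Iterable[LncClassification],
                 annotation: Sequence[TranscriptRecord] | None = None,
                 directions: dict[str, str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Category count/percentage tables and the per-chromosome DE table.

    Returns ``(exclusive_table, multiset_table, chromosome_table)``. The
    exclusive table counts each lncRNA once under the documented priority
    and its percentages sum to 100; the multiset table counts every held
    category (Venn-style overlap view).
    """
    classifications = list(classifications)
    n = len(classifications)
    excl_counts = {c: 0 for c in CATEGORY_PRIORITY}
    multi_counts = {c: 0 for c in CATEGORY_PRIORITY}
    for cl in classifications:
        excl_counts[cl.exclusive()] += 1
        for cat in cl.categories:
            multi_counts[cat] += 1
    exclusive = pd.DataFrame({
        "category": list(CATEGORY_PRIORITY),
        "count": [excl_counts[c] for c in CATEGORY_PRIORITY],
    })
    exclusive["percent"] = (
        100.0 * exclusive["count"] / n if n else 0.0)
    multiset = pd.DataFrame({
        "category": list(CATEGORY_PRIORITY),
        "count": [multi_counts[c] for c in CATEGORY_PRIORITY],
    })

    chrom_rows: list[tuple[str, int, int]] = []
    if annotation is not None and directions is not None:
        by_id = {r.id: r for r in annotation}
        per_chrom: dict[str, list[int]] = {}
        for cl in classifications:
            rec = by_id.get(cl.lnc_id)
            if rec is None:
                continue
            d = directions.get(cl.lnc_id, "ns")
            row = per_chrom.setdefault(rec.chrom, [0, 0])
            if d == "up":
                row[0] += 1
            elif d == "down":
                row[1] += 1
        chrom_rows = [(c, u, d) for c, (u, d) in sorted(per_chrom.items())]
    chrom_table = pd.DataFrame(chrom_rows, columns=["chrom", "up", "down"])
    return exclusive, multiset, chrom_table


def _gap_bp(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Distance between closest interval ends; 0 when overlapping."""
    if _overlap(a.start, a.end, b.start, b.end):
        return 0
    if b.start >= a.end:
        return b.start - a.end
    return a.start - b.end


def nearby_coding_genes(lnc: TranscriptRecord,
                        coding: Sequence[TranscriptRecord],
                        window: int = 300_000) -> list[tuple[str, int]]:
    """Coding genes with gap < window on the lncRNA's chromosome.

    The signed distance is negative when the gene lies upstream of the
    lncRNA's 5' end with respect to the lncRNA's strand, 0 on overlap.
    Results are sorted by |distance| then gene id.
    """
    out = []
    for gene in coding:
        if gene.chrom != lnc.chrom:
            continue
        gap = _gap_bp(lnc, gene)
        if gap >= window:
            continue
        if gap == 0:
            signed = 0
        else:
            gene_is_left = gene.end <= lnc.start
            upstream = gene_is_left if lnc.strand != "-" else not gene_is_left
            signed = -gap if upstream else gap
        out.append((gene.id, signed))
    return sorted(out, key=lambda t: (abs(t[1]), t[0]))


def build_cis_network(de_lnc: Iterable[str], de_mrna: Iterable[str],
                      coexpr_edges: pd.DataFrame,
                      annotation: Sequence[TranscriptRecord],
                      window: int = 300_000) -> pd.DataFrame:
    """Cis pairs: DE lncRNA and DE mRNA, co-expressed, within the window.

    ``coexpr_edges`` must already be thresholded (retained CNC edges).
    Output is sorted by lnc_id then |distance|.
    """
    de_lnc = set(de_lnc)
    de_mrna = set(de_mrna)
    by_id = {r.id: r for r in annotation}
    rows = []
    for edge in coexpr_edges.itertuples(index=False):
        if edge.id_a not in de_lnc or edge.id_b not in de_mrna:
            continue
        lnc = by_id.get(edge.id_a)
        gene = by_id.get(edge.id_b)
        if lnc is None or gene is None or lnc.chrom != gene.chrom:
            continue
        gap = _gap_bp(lnc, gene)
        if gap >= window:
            continue
        if gap == 0:
            signed = 0
        else:
            gene_is_left = gene.end <= lnc.start
            upstream = gene_is_left if lnc.strand != "-" else not gene_is_left
            signed = -gap if upstream else gap
        rows.append((lnc.id, gene.id, signed, True, edge.pcc, edge.sign))
    table = pd.DataFrame(rows, columns=CIS_COLUMNS)
    table["abs_distance"] = table["distance"].abs()
    table = table.sort_values(["lnc_id", "abs_distance", "gene_id"],
                              kind="mergesort").drop(columns="abs_distance")
    return table.reset_index(drop=True)
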
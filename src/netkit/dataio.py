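"""Readers and writers for every external format the pipeline touches.

Conventions enforced here, once, for the whole package:

* genomic intervals are 0-based, half-open internally; only the GFF3
  boundary converts (GFF3 is 1-based, closed per its spec);
* nucleotide sequences are upper-cased and RNA ``U`` is normalized to ``T``
  on read;
* tables are tab-separated (TSV), UTF-8, newline-terminated.

The BED mirror of the transcript annotation is BED12; because BED has no
attribute column, the transcript class, gene symbol and circRNA host gene
are packed into the name field as ``id|class|symbol|host`` (``.`` for an
empty host gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "DataIOError",
    "ExpressionMatrix",
    "TranscriptRecord",
    "GeneSetCollection",
    "PFM",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_pfm_jaspar",
    "write_pfm_jaspar",
    "read_edges",
    "write_edges",
]

VALID_CLASSES = ("lncRNA", "circRNA", "mRNA")
VALID_STRANDS = ("+", "-", ".")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DataIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Transcripts x samples grid of log2 intensities with paired metadata.

    ``values`` is indexed by transcript id with one column per sample;
    ``samples`` has columns ``sample_id``, ``pair_id``, ``condition``
    (``tumor``/``normal``) in the same order as the value columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dups = sorted(set(ids[ids.duplicated()]))
            raise DataIOError(f"duplicate transcript ids: {dups}")
        required = {"sample_id", "pair_id", "condition"}
        if not required.issubset(self.samples.columns):
            raise DataIOError(
                f"sample sheet must have columns {sorted(required)}"
            )
        sheet_ids = list(self.samples["sample_id"])
        if list(self.values.columns) != sheet_ids:
            raise DataIOError(
                "matrix columns do not match sample sheet order: "
                f"{list(self.values.columns)} vs {sheet_ids}"
            )
        bad = set(self.samples["condition"]) - {"tumor", "normal"}
        if bad:
            raise DataIOError(f"unknown condition labels: {sorted(bad)}")
        for pair_id, grp in self.samples.groupby("pair_id"):
            conds = sorted(grp["condition"])
            if conds != ["normal", "tumor"]:
                raise DataIOError(
                    f"pair {pair_id!r} must have exactly one tumor and one "
                    f"normal sample, got {conds}"
                )
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DataIOError("expression values must be finite")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    def paired_columns(self) -> tuple[list[str], list[str]]:
        """Tumor and normal sample ids, aligned by pair, sorted by pair id."""
        tum, nrm = [], []
        sheet = self.samples.set_index(["pair_id", "condition"])["sample_id"]
        for pair_id in sorted(self.samples["pair_id"].unique()):
            tum.append(sheet[(pair_id, "tumor")])
            nrm.append(sheet[(pair_id, "normal")])
        return tum, nrm

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [t for t in transcript_ids if t not in self.values.index]
        if missing:
            raise DataIOError(f"unknown transcript ids: {missing}")
        return ExpressionMatrix(self.values.loc[list(transcript_ids)].copy(),
                                self.samples.copy())


def read_expression(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a transcripts x samples TSV plus its sample sheet.

    Columns are reordered to sample-sheet order; pairing is validated.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dups = sorted(set(values.index[values.index.duplicated()]))
        raise DataIOError(f"duplicate transcript ids in {matrix_path}: {dups}")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataIOError(f"non-numeric cell in {matrix_path}: {exc}") from exc
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    missing = [c for c in values.columns if c not in set(samples["sample_id"])]
    if missing:
        raise DataIOError(
            f"sample sheet {sample_sheet_path} is missing matrix columns: "
            f"{missing}"
        )
    extra = [s for s in samples["sample_id"] if s not in values.columns]
    if extra:
        raise DataIOError(f"sample sheet lists unknown samples: {extra}")
    values = values[list(samples["sample_id"])]
    return ExpressionMatrix(values, samples.reset_index(drop=True))


def write_expression(m: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    m.values.to_csv(matrix_path, sep="\t", float_format="%.10g",
                    index_label="transcript_id")
    m.samples.to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript; coordinates 0-based half-open."""

    id: str
    transcript_class: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_symbol: str = ""
    host_gene_id: str = ""
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.transcript_class not in VALID_CLASSES:
            raise DataIOError(
                f"{self.id}: unknown transcript class {self.transcript_class!r}"
            )
        if not (0 <= self.start < self.end):
            raise DataIOError(
                f"{self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise DataIOError(f"{self.id}: unknown strand {self.strand!r}")
        if self.transcript_class == "circRNA" and not self.host_gene_id:
            raise DataIOError(f"{self.id}: circRNA requires a host gene id")
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise DataIOError(
                    f"{self.id}: exon [{s}, {e}) outside transcript span"
                )

    @property
    def tss(self) -> int:
        """Transcription start: left end on '+', right end on '-'."""
        return self.start if self.strand != "-" else self.end

    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.exons else ((self.start, self.end),)


def _record_to_gff3_lines(rec: TranscriptRecord) -> list[str]:
    attrs = [f"ID={rec.id}", f"transcript_class={rec.transcript_class}"]
    if rec.gene_symbol:
        attrs.append(f"gene_symbol={rec.gene_symbol}")
    if rec.host_gene_id:
        attrs.append(f"host_gene={rec.host_gene_id}")
    lines = ["\t".join([
        rec.chrom, "netkit", "transcript", str(rec.start + 1), str(rec.end),
        ".", rec.strand, ".", ";".join(attrs),
    ])]
    for i, (s, e) in enumerate(rec.exon_intervals(), start=1):
        lines.append("\t".join([
            rec.chrom, "netkit", "exon", str(s + 1), str(e), ".", rec.strand,
            ".", f"ID={rec.id}.exon{i};Parent={rec.id}",
        ]))
    return lines


def _record_to_bed12_line(rec: TranscriptRecord) -> str:
    exons = rec.exon_intervals()
    name = "|".join([rec.id, rec.transcript_class, rec.gene_symbol or ".",
                     rec.host_gene_id or "."])
    sizes = ",".join(str(e - s) for s, e in exons)
    starts = ",".join(str(s - rec.start) for s, e in exons)
    return "\t".join([
        rec.chrom, str(rec.start), str(rec.end), name, "0", rec.strand,
        str(rec.start), str(rec.end), "0", str(len(exons)), sizes, starts,
    ])


def write_annotation(records: Sequence[TranscriptRecord], path,
                     dialect: str = "gff3") -> None:
    path = Path(path)
    if dialect == "gff3":
        lines = ["##gff-version 3"]
        for rec in records:
            lines.extend(_record_to_gff3_lines(rec))
    elif dialect == "bed":
        lines = [_record_to_bed12_line(rec) for rec in records]
    else:
        raise DataIOError(f"unknown annotation dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_gff3(path) -> list[TranscriptRecord]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True)
    records = []
    for feat in db.features_of_type("transcript", order_by="start"):
        exons = tuple(sorted(
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon")
        ))
        start, end = feat.start - 1, feat.end
        if start >= end:
            raise DataIOError(f"{feat.id}: start >= end after conversion")
        records.append(TranscriptRecord(
            id=feat.id,
            transcript_class=feat.attributes["transcript_class"][0],
            chrom=feat.seqid,
            start=start,
            end=end,
            strand=feat.strand,
            gene_symbol=feat.attributes.get("gene_symbol", [""])[0],
            host_gene_id=feat.attributes.get("host_gene", [""])[0],
            exons=exons,
        ))
    return records


def _read_bed(path) -> list[TranscriptRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise DataIOError(f"{path}:{lineno}: expected BED12")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            parts = name.split("|")
            if len(parts) != 4:
                raise DataIOError(
                    f"{path}:{lineno}: name field must be id|class|symbol|host"
                )
            tid, tclass, symbol, host = parts
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offs = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offs) != n_blocks:
                raise DataIOError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            records.append(TranscriptRecord(
                id=tid, transcript_class=tclass, chrom=chrom, start=start,
                end=end, strand=strand,
                gene_symbol="" if symbol == "." else symbol,
                host_gene_id="" if host == "." else host,
                exons=exons,
            ))
    return records


def read_annotation(path, dialect: str = "gff3") -> list[TranscriptRecord]:
    """Parse transcript annotation; GFF3 converts to 0-based half-open."""
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed":
        return _read_bed(path)
    raise DataIOError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> id->sequence; upper-case, U normalized to T."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DataIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets: set_name -> (description, ordered member ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise DataIOError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataIOError(f"gene set {name!r} has duplicate members")

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a universe; drop sets that become empty."""
        out = {}
        for name, (desc, members) in self.sets.items():
            kept = tuple(m for m in members if m in universe)
            if kept:
                out[name] = (desc, kept)
        return GeneSetCollection(out)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIOError(
                    f"{path}:{lineno}: GMT row needs name, description and "
                    f"at least one member"
                )
            name, desc = fields[0], fields[1]
            members, seen = [], set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            if not members:
                raise DataIOError(f"{path}:{lineno}: gene set {name!r} empty")
            if name in sets:
                raise DataIOError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices
# ---------------------------------------------------------------------------

@dataclass
class PFM:
    """Position frequency matrix over A,C,G,T (rows) x motif length (cols)."""

    motif_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise DataIOError(
                f"{self.motif_id}: PFM must be 4 x L with L >= 4, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise DataIOError(f"{self.motif_id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise DataIOError(
                f"{self.motif_id}: every PFM column needs a positive count"
            )

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))


def read_pfm_jaspar(path) -> list[PFM]:
    """Parse JASPAR-format PFM text (">id name" then four labeled rows)."""
    with open(path, encoding="utf-8") as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
            out.append(PFM(motif_id=m.matrix_id or m.name, tf_name=m.name,
                           counts=counts))
    if not out:
        raise DataIOError(f"no motifs parsed from {path}")
    return out


def write_pfm_jaspar(pfms: Sequence[PFM], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.tf_name}\n")
            for base, row in zip("ACGT", p.counts):
                cells = " ".join(f"{int(v)}" if float(v).is_integer()
                                 else f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# Edge / generic tables
# ---------------------------------------------------------------------------

def write_edges(table: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    """Write an edge table as TSV with a fixed, documented column order."""
    if columns is not None:
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise DataIOError(f"edge table missing columns: {missing}")
        table = table[list(columns)]
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
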
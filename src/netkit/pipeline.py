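"""End-to-end orchestration of all analysis stages with one configuration.

Stage order: normalize -> differential expression -> classification -> CNC
co-expression -> ceRNA -> cis -> trans (TF) -> term enrichment -> qPCR.
Every stage's table is written before the next starts; the run manifest
records every output path, summary counts and the full parameter set.
Defaults are the screening thresholds the analysis is defined by
(FC >= 2.0, p < 0.05, FDR < 0.05; |PCC| >= 0.90, p < 0.01, FDR < 0.01;
cis window 300 kb; TF/term gates p < 0.01, FDR < 0.01).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cerna as cerna_mod
from . import coexpr as coexpr_mod
from . import diffexpr, enrich, genomics, qpcr, transtf
from .dataio import (
    ExpressionMatrix,
    read_annotation,
    read_expression,
    read_fasta,
    read_gmt,
    write_edges,
)
from .synthdata import Bundle, SimConfig, generate_bundle, truth_report, write_bundle

__all__ = ["RunConfig", "run_all", "demo"]

log = logging.getLogger("netkit")


@dataclass
class RunConfig:
    """Paths to all inputs plus every stage threshold."""

    expression_lnc: str = ""
    expression_circ: str = ""
    expression_mrna: str = ""
    sample_sheet: str = ""
    annotation_gff3: str = ""
    transcript_fasta: str = ""
    mirna_fasta: str = ""
    tf_targets_gmt: str = ""
    terms_gmt: str = ""
    ct_table: str = ""
    out_dir: str = "netkit_out"

    fc_min: float = 2.0
    p_max: float = 0.05
    fdr_max: float = 0.05
    fc_tier_min: float = 10.0
    pcc_min: float = 0.90
    coexpr_p_max: float = 0.01
    coexpr_fdr_max: float = 0.01
    cis_window: int = 300_000
    bidirectional_gap: int = 1000
    min_shared_mirnas: int = 1
    tf_p_max: float = 0.01
    tf_fdr_max: float = 0.01
    enrich_top_k: int = 10
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("p_max", "fdr_max", "coexpr_p_max", "coexpr_fdr_max",
                     "tf_p_max", "tf_fdr_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.pcc_min <= 1.0:
            raise ValueError("pcc_min must lie in [0, 1]")
        if self.fc_min < 1.0 or self.fc_tier_min < 1.0:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.cis_window <= 0 or self.enrich_top_k <= 0:
            raise ValueError("cis_window and enrich_top_k must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8")


def _stage(name: str, t0: float, **counts) -> None:
    msg = ", ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage %-10s %s (%.2fs)", name, msg, time.perf_counter() - t0)


def run_all(config: RunConfig, bundle: Bundle | None = None) -> dict:
    """Run every stage; returns (and writes) the run manifest.

    Inputs are either read from the configured paths or taken from an
    in-memory synthetic bundle. Any stage failure aborts with the stage
    name and cause; outputs of completed stages are retained on disk.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "outputs": {},
        "counts": {},
    }

    def _write(name: str, table: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        write_edges(table, path)
        manifest["outputs"][name] = path.name

    stage = "load"
    try:
        if bundle is not None:
            expr = {k: v for k, v in bundle.expression.items()}
            annotation = bundle.annotation
            tx_seqs = bundle.transcript_seqs
            mir_seqs = bundle.mirna_seqs
            tf_targets = bundle.tf_targets
            term_sets = bundle.term_sets
            ct = bundle.ct_table
        else:
            expr = {
                "lncRNA": read_expression(config.expression_lnc,
                                          config.sample_sheet),
                "circRNA": read_expression(config.expression_circ,
                                           config.sample_sheet),
                "mRNA": read_expression(config.expression_mrna,
                                        config.sample_sheet),
            }
            annotation = read_annotation(config.annotation_gff3, "gff3")
            tx_seqs = read_fasta(config.transcript_fasta)
            mir_seqs = read_fasta(config.mirna_fasta)
            tf_targets = read_gmt(config.tf_targets_gmt)
            term_sets = read_gmt(config.terms_gmt)
            ct = qpcr.read_ct(config.ct_table) if config.ct_table else None

        # ---- normalize + differential expression, per class -------------
        stage = "de"
        t0 = time.perf_counter()
        de_tables: dict[str, pd.DataFrame] = {}
        up_down: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
        for cls, m in expr.items():
            norm = diffexpr.quantile_normalize(m)
            table = diffexpr.de_test(norm, fc_min=config.fc_min,
                                     p_max=config.p_max,
                                     fdr_max=config.fdr_max)
            de_tables[cls] = table
            up, down = diffexpr.apply_filter(table, config.fc_min,
                                             config.p_max, config.fdr_max)
            up_down[cls] = (up, down)
            _write(f"de_{cls}", table)
            manifest["counts"][f"n_up_{cls}"] = int(len(up))
            manifest["counts"][f"n_down_{cls}"] = int(len(down))
            tier_up, tier_down = diffexpr.fc_tier(
                table, config.fc_tier_min, config.p_max, config.fdr_max)
            manifest["counts"][f"n_fc_tier_{cls}"] = int(
                len(tier_up) + len(tier_down))
        _stage("de", t0, **{k: v for k, v in manifest["counts"].items()})

        de_ids = {cls: set(pd.concat(up_down[cls])["transcript_id"])
                  for cls in expr}
        directions = {}
        for cls in expr:
            up, down = up_down[cls]
            directions.update({t: "up" for t in up["transcript_id"]})
            directions.update({t: "down" for t in down["transcript_id"]})

        # ---- lncRNA classification --------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        coding = [r for r in annotation if r.transcript_class == "mRNA"]
        lnc_records = {r.id: r for r in annotation
                       if r.transcript_class == "lncRNA"}
        classifications = [
            genomics.classify_lncrna(lnc_records[t], coding,
                                     config.bidirectional_gap)
            for t in sorted(de_ids["lncRNA"]) if t in lnc_records]
        exclusive, multiset, chrom_table = genomics.class_counts(
            classifications, annotation, directions)
        _write("lnc_classes_exclusive", exclusive)
        _write("lnc_classes_multiset", multiset)
        _write("lnc_chromosomes", chrom_table)
        class_rows = pd.DataFrame(
            [(c.lnc_id, ",".join(sorted(c.categories)), c.exclusive())
             for c in classifications],
            columns=["lnc_id", "categories", "exclusive_category"])
        _write("lnc_classifications", class_rows)
        manifest["counts"]["n_classified_lnc"] = len(classifications)
        _stage("classify", t0, n=len(classifications))

        # ---- CNC co-expression ------------------------------------------
        stage = "cnc"
        t0 = time.perf_counter()
        noncoding = ExpressionMatrix(
            pd.concat([expr["lncRNA"].values, expr["circRNA"].values]),
            expr["lncRNA"].samples.copy())
        edges = coexpr_mod.build_cnc(noncoding, expr["mRNA"],
                                     pcc_min=config.pcc_min,
                                     p_max=config.coexpr_p_max,
                                     fdr_max=config.coexpr_fdr_max)
        _write("cnc_edges", edges)
        manifest["counts"]["n_cnc_edges"] = int(len(edges))
        _stage("cnc", t0, n_edges=len(edges))

        # ---- ceRNA -------------------------------------------------------
        stage = "cerna"
        t0 = time.perf_counter()
        site_index = cerna_mod.scan_sites(tx_seqs, mir_seqs)
        _write("mre_sites", site_index)
        de_ce = de_ids["lncRNA"] | de_ids["circRNA"]
        triples = cerna_mod.build_cerna(de_ce, de_ids["mRNA"], site_index,
                                        edges,
                                        min_shared=config.min_shared_mirnas)
        _write("cerna_triples", triples)
        cerna_edges = cerna_mod.cerna_network_edges(triples)
        _write("cerna_network", cerna_edges)
        manifest["counts"]["n_mre_sites"] = int(len(site_index))
        manifest["counts"]["n_cerna_triples"] = int(len(triples))
        _stage("cerna", t0, n_sites=len(site_index), n_triples=len(triples))

        # ---- cis ---------------------------------------------------------
        stage = "cis"
        t0 = time.perf_counter()
        cis = genomics.build_cis_network(de_ids["lncRNA"], de_ids["mRNA"],
                                         edges, annotation,
                                         window=config.cis_window)
        _write("cis_pairs", cis)
        manifest["counts"]["n_cis_pairs"] = int(len(cis))
        _stage("cis", t0, n_pairs=len(cis))

        # ---- trans (TF enrichment) --------------------------------------
        stage = "trans"
        t0 = time.perf_counter()
        universe = {r.id for r in coding}
        partners = coexpr_mod.coexpressed_partners(edges)
        lnc_partners = {k: v for k, v in partners.items()
                        if k in de_ids["lncRNA"]}
        enr = transtf.tf_enrich(lnc_partners, tf_targets, universe,
                                p_max=config.tf_p_max,
                                fdr_max=config.tf_fdr_max)
        _write("tf_enrichment", enr)
        ternary, net_counts = transtf.ternary_network(enr)
        _write("tf_ternary_network", ternary)
        manifest["counts"]["n_tf_enrichments"] = int(len(enr))
        manifest["counts"].update(
            {f"ternary_{k}": v for k, v in net_counts.items()})
        _stage("trans", t0, n_enrich=len(enr), **net_counts)

        # ---- term enrichment --------------------------------------------
        stage = "enrich"
        t0 = time.perf_counter()
        frames = []
        for direction in ("up", "down"):
            genes = [t for t in de_ids["mRNA"]
                     if directions.get(t) == direction]
            if not genes:
                continue
            scored = enrich.term_enrich(genes, term_sets, universe)
            scored.insert(0, "direction", direction)
            frames.append(scored)
        terms = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["direction", *enrich.TERM_COLUMNS]))
        _write("term_enrichment", terms)
        _write("term_top", enrich.top_terms(terms, k=config.enrich_top_k))
        de_circ_table = pd.concat(up_down["circRNA"]) \
            if any(len(x) for x in up_down["circRNA"]) else pd.DataFrame()
        if len(de_circ_table):
            host_terms = enrich.circ_host_enrich(de_circ_table, annotation,
                                                 term_sets, universe)
            _write("circ_host_enrichment", host_terms)
            manifest["counts"]["n_circ_host_terms"] = int(len(host_terms))
        manifest["counts"]["n_term_tests"] = int(len(terms))
        _stage("enrich", t0, n_terms=len(terms))

        # ---- qPCR --------------------------------------------------------
        if ct is not None and len(ct):
            stage = "qpcr"
            t0 = time.perf_counter()
            folds = qpcr.ddct(ct)
            _write("qpcr_folds", folds)
            summary = qpcr.qpcr_test(folds)
            _write("qpcr_summary", summary)
            manifest["counts"]["n_qpcr_targets"] = int(len(summary))
            manifest["counts"]["n_qpcr_significant"] = int(
                summary["significant"].sum())
            _stage("qpcr", t0, n_targets=len(summary))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest


def demo(seed: int, outdir, sim_config: SimConfig | None = None) -> dict:
    """Simulate a bundle, run the full pipeline, score against the truth.

    Returns the run manifest extended with the truth-report table.
    """
    outdir = Path(outdir)
    cfg = sim_config if sim_config is not None else SimConfig(rng_seed=seed)
    if cfg.rng_seed != seed:
        cfg = dataclasses.replace(cfg, rng_seed=seed)
    bundle = generate_bundle(cfg)
    write_bundle(bundle, outdir / "bundle")
    run_cfg = RunConfig(out_dir=str(outdir / "results"), rng_seed=seed)
    manifest = run_all(run_cfg, bundle=bundle)

    de_pred = set()
    for name in ("de_lncRNA", "de_circRNA", "de_mRNA"):
        table = pd.read_csv(outdir / "results" / f"{name}.tsv", sep="\t")
        de_pred |= set(table.loc[table["direction"] != "ns", "transcript_id"])
    edges = pd.read_csv(outdir / "results" / "cnc_edges.tsv", sep="\t")
    triples = pd.read_csv(outdir / "results" / "cerna_triples.tsv", sep="\t")
    cis = pd.read_csv(outdir / "results" / "cis_pairs.tsv", sep="\t")
    report = truth_report(bundle.truth, {
        "de": de_pred,
        "coexpr": {(a, b) for a, b in zip(edges["id_a"], edges["id_b"])},
        "cerna": {(c, m, g) for c, m, g in zip(
            triples["ce_id"], triples["mirna_id"], triples["mrna_id"])},
        "cis": {(l, g) for l, g in zip(cis["lnc_id"], cis["gene_id"])},
    })
    report.to_csv(outdir / "results" / "truth_report.tsv", sep="\t",
                  index=False, float_format="%.10g")
    manifest["truth_report"] = {
        row["stage"]: {"precision": row["precision"], "recall": row["recall"]}
        for _, row in report.iterrows()}
    (outdir / "results" / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest
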
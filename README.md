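# netkit

Integrative network analysis of lncRNA, circRNA and mRNA expression
profiles from paired tumor/normal microarray designs — for computational
biologists who want the full chain from a screened differential-expression
table to ceRNA, cis and TF-mediated regulation networks as one tested,
scriptable pipeline, exercisable end-to-end on synthetic data with planted
ground truth.

## What it computes

Given log2 intensity matrices for three transcript classes over paired
tumor/normal arrays, plus annotation, sequences and gene sets:

1. **Differential expression** — quantile normalization, two-sided paired
   t-test on per-pair log2 differences, Benjamini–Hochberg FDR per class;
   screening rule: fold change ≥ 2.0, p < 0.05, FDR < 0.05 (with a FC ≥ 10
   tier); average-linkage clustering on 1 − r for heat-map ordering.
2. **Genomic context** — each DE lncRNA classified against coding genes
   into exon sense-overlapping / intron sense-overlapping / natural
   antisense / intronic antisense / bidirectional / intergenic (plus
   `unknown`), with count and percentage tables.
3. **Coding–noncoding co-expression (CNC)** — all noncoding × coding pairs,
   sample Pearson correlation r with p from t = r·√((n−2)/(1−r²)); edges
   retained at |PCC| ≥ 0.90, p < 0.01, FDR < 0.01, signed.
4. **ceRNA network** — local miRNA seed-site scanning (6mer / 7mer-A1 /
   7mer-m8 / 8mer, reverse complement of miRNA positions 2–8); a triple
   (lncRNA-or-circRNA, miRNA, mRNA) needs a shared seed family on both DE
   partners plus a retained positive CNC edge.
5. **Cis regulation** — co-expressed DE lncRNA–mRNA pairs with interval gap
   strictly below 300 kb on one chromosome, signed distances.
6. **Trans regulation** — per lncRNA, upper-tail cumulative hypergeometric
   enrichment of its co-expressed mRNAs in each TF's target set
   (P(X ≥ k) for X ~ Hypergeom(N, K, n)); retained at p < 0.01,
   FDR < 0.01; expanded to the lncRNA–TF–mRNA ternary network. TF targets
   from GMT or from JASPAR-PFM promoter scanning.
7. **Term enrichment** — hypergeometric over flat GMT sets, score
   −log10(p), top-k per direction and domain; also applied to host genes
   of DE circRNAs.
8. **qPCR validation** — 2^−ΔΔCt relative quantification against a
   reference gene with paired t-tests per target.

The `synthdata` module generates a complete study bundle (expression,
GFF3/BED annotation, FASTA sequences, GMT gene sets, JASPAR motifs,
promoters, Ct tables) with planted fold changes, co-expression factors,
seed sites, cis distances and TF modules, and `truth_report` scores any
stage's output against what was planted.

## Worked example

One command simulates a bundle at the default study design (4 tumor/normal
pairs), runs every stage and scores the results against the planted truth:

```sh
netkit demo --seed 7 --out demo_out
```

prints one log line per stage and then the recovery table:

```
de      precision=1.000  recall=0.914
coexpr  precision=0.227  recall=0.753
cerna   precision=1.000  recall=0.250
cis     precision=1.000  recall=0.667
```

Reading this: at 4 pairs the paired t-test recovers 91% of planted DE
transcripts with no false screening calls, but a |PCC| ≥ 0.90 gate at
8 arrays is noisy — co-expression recall is 75% (precision is low because
condition-driven correlation between strongly DE transcripts is real
signal the generator did not plant pairwise), and only a quarter of the
planted ceRNA triples survive all three gates. At 10 pairs (the
evaluation condition used by the test suite) all of these recoveries reach
≥ 0.9. Among the outputs in `demo_out/results/`, the triple table looks
like:

```
ce_id     mirna_id  mrna_id   n_shared_mirnas  pcc     p_value   fdr
CIRC0059  MIR006    MRNA0416  1                0.990   2.3e-06   3.9e-03
LNC0153   MIR003    MRNA0209  1                0.988   4.1e-06   5.4e-03
```

and `qpcr_summary.tsv` confirms the planted validation targets
(e.g. `LNC0153  mean_fold 0.21 ± 0.06, significant` — a planted ~4.7-fold
down-regulation recovered as 2^−ΔΔCt ≈ 0.21 over 30 tissue pairs).

Every stage is also a library call (`netkit.diffexpr.de_test`,
`netkit.coexpr.build_cnc`, `netkit.cerna.build_cerna`, ...) and a
subcommand (`netkit de`, `netkit cnc`, `netkit cerna`, `netkit cis`,
`netkit trans`, `netkit enrich`, `netkit qpcr`, `netkit pfm-targets`,
`netkit run --config run.yaml`).

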
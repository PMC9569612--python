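# tfmeth

Differential DNA methylation near transcription-factor binding sites.

`tfmeth` is an analysis pipeline for cohorts profiled with methylation
arrays (beta-values in [0, 1]) and RNA-seq. It targets a specific question
from AML epigenomics: when a hematopoietic transcription factor such as
RUNX1 or CEBPA is mutated, do the CpGs around its binding sites gain
methylation, and are the associated target genes silenced? Mechanistically,
these factors recruit the TET2 demethylase to their binding sites; a
disabled factor leaves those sites unprotected and they drift toward
hypermethylation.

The pipeline chains the analyses such a study needs:

1. **Motif scanning** — PWM log-odds scanning of CpG-centered ±100 bp
   windows on both strands, with the score threshold derived from the
   *exact* distribution of background scores (dynamic programming over
   per-position score distributions) at a target p-value (default
   p < 0.001), and optional filtering of predicted sites by ChIP-seq peak
   overlap.
2. **CpG traffic lights (TL)** — per CpG–gene pair, the Spearman
   correlation ρ between methylation and expression across samples;
   Benjamini–Hochberg adjustment; a pair with FDR < 0.005 is a CpG TL
   (ρ < 0 means methylation up, expression down).
3. **Differential methylation/expression** — pooled-variance Student's
   t between mutated and wild-type groups with BH FDR < 0.05 (DM CpGs,
   DEGs); a DM CpG with Δmeth = mean(mut) − mean(wt) > 0.15 is
   differentially hypermethylated (DHM).
4. **TFBS-proximity effects** — Δmeth stratified by motif proximity
   (Mann–Whitney), hypermethylated-CpG proportions (Fisher exact),
   TET2-style coverage metaprofiles around CpG classes, and
   hematopoiesis-stage methylation profiles.
5. **Strong TLs and gene prioritization** — a strong CpG TL is a TL whose
   CpG is DM and whose gene is differentially expressed; genes are
   retained at the gates |log2 FC| > 1, expression FDR < 0.05, group mean
   expression > 0.5.
6. **Cell-type deconvolution** — constrained least squares
   (w ≥ 0, Σw = 1) against a reference methylation atlas, with per-type
   group comparison.
7. **Landmark survival** — Kaplan–Meier and two-group log-rank between
   methylation-dichotomized patients, overall and conditional on surviving
   past a landmark (default 500 days, clocks re-origined).

Because the real cohort data cannot ship with the code, the package
includes a first-class synthetic study generator (`tfmeth.simulate`) that
plants all of these effects with known truth — motif instances in
generated sequence, group beta shifts of +0.18 near planted sites and
+0.06 elsewhere (RUNX1 preset; 0.13/0.09 for CEBPA), monotone
methylation–expression coupling, coverage enrichment, known cell-type
mixtures, and late-divergence survival — so every stage is testable
against ground truth.

## Worked example

Simulate a study with the RUNX1 preset (17 mutated patients, planted
Δmeth 0.18 near motifs / 0.06 elsewhere, 12 silenced target genes), run
the full pipeline, and summarize:

```bash
tfmeth simulate --preset runx1 --seed 7 --outdir demo/study --n-cpgs 600 --n-samples 120
tfmeth run --indir demo/study --outdir demo/results
```

which prints the per-stage record counts

```
{
  "manifest_cpgs": 600,
  "samples": 120,
  "predicted_sites": 60,
  "cpgs_near_tfbs": 60,
  "traffic_lights": 60,
  "dm_cpgs": 226,
  "dhm_cpgs": 60,
  "deg_genes": 12,
  "strong_tls": 12,
  "prioritized_genes": 12
}
```

The scanner found all 60 planted motif-proximal CpGs; all 60 planted
traffic lights were called; and the prioritized gene table recovered
exactly the 12 planted silenced targets. `demo/results/strata.tsv` holds
the headline stratification — the mean methylation gain of differentially
methylated CpGs near binding sites versus the rest of the genome:

```
  stratum   n  mean_delta  prop_hypermethylated  rank_test_p  fisher_p
near_tfbs  60      0.1810                   1.0          0.0       0.0
     rest 166      0.0561                   0.0          0.0       0.0
```

i.e. the planted 0.18 / 0.06 contrast is recovered, every near-TFBS DM CpG
crosses the 0.15 hypermethylation bar, and none of the others do. The gene
table shows each retained gene with its fold change (silenced, FC ≈ 0.3,
so ~3-fold down in mutated patients) and group means, e.g.

```
  gene     fc  expr_q  mean_expr_mut  mean_expr_wt
G00066 0.3482     0.0         1.4362        4.1249
G00073 0.3448     0.0         1.3954        4.0472
...
```

Individual stages are also exposed (`tfmeth scan`, `tfmeth trafficlights`,
`tfmeth deconvolve`, `tfmeth survival`, `tfmeth summary`), and everything
is importable as a library (`tfmeth.motifs`, `tfmeth.trafficlights`,
`tfmeth.differential`, `tfmeth.effects`, `tfmeth.deconvolve`,
`tfmeth.survival`, `tfmeth.simulate`, `tfmeth.pipeline`).

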
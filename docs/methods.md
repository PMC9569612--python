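# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic study generator the tests rely on, and the numerical and design
choices that were genuinely open.

## Coordinates, containers, missing data

All genomic coordinates are 0-based half-open internally; BED and bedGraph
already use this convention so their readers do no conversion. Matrices are
pandas DataFrames (CpG × sample, gene × sample) with NaN for missing
values; readers never impute — each statistic declares its own policy
(pairwise-complete deletion for Spearman, per-feature omission for
t-tests, per-sample marker dropping for deconvolution). Beta-values
outside [0, 1] and negative expression are rejected at parse time with the
offending row and column named; unparseable cells become missing.

## Motif model and exact score threshold

A PWM with counts `c[j,b]` becomes a log2-odds matrix
`log2(p[j,b] / bg[b])` after adding a pseudocount (default 0.01 per cell;
HOCOMOCO-style matrices may contain zeros) and row-normalizing. The
background defaults to uniform 0.25 per base.

The scan threshold for a target p-value (default 0.001) is taken from the
exact distribution of the score of a random background L-mer, computed by
convolving the per-position score distributions:

* **exact backend** (default for L ≤ 10): the convolution is carried over
  the exact achievable score sums (keyed on a 1e-9 rounding grid), so the
  threshold equals what exhaustive enumeration of all 4^L sequences gives.
  The state space is bounded by 4^L and is small for the motif lengths
  where enumeration is even conceivable.
* **binned backend** (longer motifs): per-position scores are rounded *up*
  onto a 1000-bin grid spanning the achievable score range before
  convolution. Rounding up biases sums upward, hence tail probabilities
  upward, hence the chosen threshold is conservative: the exact tail
  probability at the reported threshold never exceeds the target. The
  discretization error is at most L × (score range)/1000.

The threshold is the smallest achievable score `s` with
`P(score ≥ s) ≤ target`; when no achievable score is rare enough (short or
uninformative motifs at p = 0.001) the threshold is set above the maximum
score and the scan correctly returns nothing.

Scanning covers both strands of every CpG-centered window
`[pos − hw, pos + hw)` (default hw = 100, i.e. 200 bp windows), truncated
at contig edges. The minus strand is scored by applying the
reverse-complemented matrix to the forward sequence. Ambiguous bases (N)
contribute −∞. Peak co-location uses ≥ 1 bp overlap ("co-locate" is
otherwise unquantified; this is the weakest defensible criterion and is
what `--require-peak` filters on).

## CpG traffic lights

For each manifest CpG–gene pair present in both matrices, Spearman ρ is
computed with average ranks for ties and pairwise-complete deletion, with
a floor of 8 complete pairs (below that, or for constant vectors, the
record carries NaN and is excluded from the BH family). The p-value uses
the t-approximation `t = ρ√((n−2)/(1−ρ²))` on n−2 df; strictly monotone
pairs give ρ = ±1 and p = 0. BH adjustment is the step-up procedure
applied to all testable pairs of the current run — the family must match
the data actually tested, not any fixed historical count. Both correlation
signs qualify a TL; the sign is kept in the output (negative = silencing
direction).

## Differential calls

The two-group test is pooled-variance Student's t (a Welch switch exists
but the named test is the default), two-sided, with per-feature missing
dropping. Zero-variance features use the conventions p = 1 for equal
means, p = 0 (infinite t) for unequal means. DM requires BH FDR < 0.05;
DHM additionally Δmeth > 0.15 strictly. DEGs use the same machinery on
expression rows with a linear-scale fold change mean(mut)/mean(wt); a
0.01 floor replaces a zero wild-type mean so the ratio stays defined while
exact means give exact ratios.

A strong CpG TL is a TL whose CpG is DM (a config switch can demand DHM)
and whose gene is a DEG. The prioritized gene table keeps genes with ≥ 1
strong TL, |log2 FC| > log2(2), expression FDR < 0.05 and
max(group means) > 0.5 on the linear RPKM-like scale (the gate's purpose
is excluding never-expressed genes; per-sample minima and log-scale
readings are defensible alternatives). By default the strong TLs feeding
the table are restricted to motif-proximal CpGs — that is the population
the target-gene question is about — and this also prevents chance
methylation differences at distal TLs from being amplified through the
methylation–expression coupling into spurious fold changes; a config
switch lifts the restriction.

## TFBS-proximity effects

`stratify_delta` compares Δmeth between motif-proximal CpGs and the rest,
by default over DM CpGs (the population the headline figures plot), with
`all` and TL-restricted variants; the stratum contrast uses a two-sided
Mann–Whitney test because deltas are bounded and skewed. The
hypermethylation contrast is a two-sided Fisher exact test on the 2×2
table (DHM yes/no × near/rest). Coverage metaprofiles average the
length-weighted mean coverage in 50 bins over ±2000 bp around each anchor
(bin count, flank and reference point are free parameters of the
underlying tool re-implemented here); bins falling off a contig are
dropped from that anchor's average. Stage profiles are simple means over
strong-TL CpGs per maturation stage and per patient group with percentile
bootstrap CIs (1000 resamples over CpGs).

## Deconvolution

Cell-type fractions solve min ‖Aw − b‖² s.t. w ≥ 0, Σw = 1 per sample over
the marker CpGs shared with the atlas. The equality constraint is imposed
by appending a ×1000-weighted sum-to-one row to the non-negative
least-squares system and renormalizing, which recovers noiseless mixtures
to machine precision; rank-deficient atlases are rejected with the
collinear columns named (pivoted QR). Group comparison is a per-type
two-sided Mann–Whitney with BH across types.

## Survival

Kaplan–Meier is the standard product-limit estimator; censored times
reduce the risk set without dropping the curve. The two-group log-rank
uses the hypergeometric variance form. The landmark variant at L keeps
subjects with time > L and re-origins their clocks at L (conditional
survival) — the construction that makes "survival beyond day 500" a valid
comparison; landmark 0 is identical to the overall test. Patients are
dichotomized at the cohort median beta of the chosen CpG (ties to hypo;
the least parameterized rule, with a fixed-threshold alternative).

## Synthetic study generator

The generator is the package's testing instrument: every default is a
study condition, not a tuning knob.

* **Cohort**: 186 samples, 17 mutated (RUNX1 preset) or 13 (CEBPA).
* **Sequence**: one synthetic chromosome; each CpG owns a locus (default
  spacing 5000 bp) with the CpG dinucleotide at its center. Background
  windows are rejection-sampled until they contain no motif match at the
  scan threshold on either strand; for the motif-proximal fraction, an
  instance sampled from the PWM (conditioned on passing threshold) is
  embedded at an offset clear of the central CpG. The scanner run on the
  generated genome is therefore an exact oracle for the truth table.
* **Methylation**: per-CpG baselines follow the array-like bimodal mixture
  Beta(2,10)/Beta(10,2); motif-proximal CpGs draw from the hypomethylated
  component, reflecting sites kept demethylated in normal cells — which
  also keeps the planted +0.18 shift clear of the upper clip. Per-sample
  betas are Beta-distributed around the baseline with concentration 100
  (per-sample sd ≈ 0.04 at low baselines, array-realistic). Mutated
  samples gain +0.18 at motif-proximal CpGs and +0.06 at a 30% fraction of
  the rest (0.13/0.09 for CEBPA; the responsive-fraction has no literature
  value and is a free parameter). Shifts are clipped to [0, 1], never
  wrapped, and the realized group difference is recorded as truth.
* **Expression**: coupled rows use a Gaussian copula on the beta ranks —
  latent `y = ρ_l z + √(1−ρ_l²) ε` with `ρ_l = 2 sin(π ρ_s/6)` chosen so
  the Spearman magnitude hits the target (default |ρ_s| = 0.7 for ordinary
  TLs, 0.9 for planted strong genes; coupling 1 with zero residual gives
  Spearman exactly −1). Ordinary TL genes map the latent through a
  log-linear link; the planted strong silenced targets use a saturating
  sigmoid link (slope 3, midpoint 0.8 latent units above the wild-type
  mean): expression sits on an active plateau in unshifted samples and
  falls to a floor once methylation rises, the switch-like behavior of a
  silenced target. This gives the planted genes ~3–5-fold silencing with
  tight within-group spread; uncoupled genes are lognormal noise around a
  lognormal baseline level. Ordinary TLs are placed on CpGs without group
  shifts, so the planted strong set is exactly the set of genes that
  should pass the prioritization gates.
* **Coverage**: Poisson counts in 25 bp bins over a flat baseline plus
  Gaussian bumps (σ = 150 bp) at motif-proximal CpGs scaled so the peak
  equals the requested fold enrichment (default 5).
* **Mixtures**: a 5-type reference atlas with 50 markers per type
  (markers hypomethylated in their own type, ~0.85 elsewhere); per-sample
  fractions are Dirichlet around group means with concentration 200;
  mutated patients have a depleted macrophage compartment and expanded
  blasts. Bulk marker betas are atlas × fractions + N(0, 0.02), clipped.
* **Stages**: strong-TL CpGs follow a monotone demethylation gradient
  from 0.85 (most immature) to 0.15 (mature) across five stages; other
  CpGs stay at baseline.
* **Survival**: piecewise exponential — a shared hazard before the
  500-day changepoint, then a hazard ratio (default 3) against the
  beta-dichotomized hyper group, with administrative censoring.

The dedicated late-divergence demonstration cohort (for the
overall-quiet / landmark-significant contrast) was sized by an a-priori
power calculation: with a shared early phase, the overall log-rank Z is
approximately the landmark Z shrunk by √(1 + V_pre/V_post), so the design
needs many early (uninformative) events and few but strongly contrasted
late events. The defaults — n = 4000, 85% of events before day 500, late
hazard 9×10⁻⁵/day versus 3-fold that, follow-up 1000 days — give ~95%
landmark power with ~95% probability the overall test stays above 0.05
(Monte-Carlo verified during design).

### What the generator does not emulate

No linkage between neighboring CpGs (each is independent), no tumor
purity or copy-number effects, no batch structure, no read-level noise,
and one gene per CpG. Passing the recovery tests therefore shows the
statistics are implemented correctly and have the expected operating
characteristics under the stated effect sizes — not that real cohorts,
with correlated probes and confounding, would behave as cleanly.

## Known limitations

* The BH family for traffic lights is the pairs tested in the run;
  results are not comparable across runs with different manifests.
* The binned threshold backend is conservative by design; at p = 0.001 the
  effective threshold can be slightly stricter than exact for very long
  motifs.
* The expression fold-change gate operates on linear-scale means, which is
  what the t-test also sees; heavy-tailed expression rows reduce its
  power, and the Welch switch does not change the FC itself.
* Deconvolution assumes the atlas spans the sample's true composition;
  unmodeled cell types bias fractions toward their nearest profile
  (residual norms are reported for diagnosis).

## Problem sizes used by the test suite and acceptance script

Traffic-light calibration runs at 5000 CpGs × 186 samples (plus a
4000-CpG null cohort); effect-size recovery at 20 000 CpGs; sequence-level
truth recovery at a few hundred loci; the survival contrast over 20 seeds
of the n = 4000 demo cohort. These sizes make every recovery check
well-powered while a full suite run stays around half a minute.
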
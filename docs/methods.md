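# Methods

## Pipeline

The analysis operates on three inputs: an ortholog set (one protein — and
optionally CDS — per gene per species), a gene-order table per reference
genome, and a species table with clade labels and pairwise divergence times.
Only genes present in at least one Eutherian and one Metatherian species are
retained, excluding lineage-specific genes.

**Alignment and divergence.** Orthologous proteins are aligned globally with
BLOSUM62 and affine gap penalties (defaults: open 12, extend 2; a gap of
length L costs `open + (L−1)·extend`; end gaps are penalized). Alignment is
delegated to Biopython's `PairwiseAligner`; the test suite verifies its
scores against an independent brute-force affine-gap DP on hundreds of random
sequence pairs, itself cross-checked against exhaustive enumeration at tiny
lengths. Identity is `matches / (alignment length − gap-containing columns)`
— the denominator excludes gap columns so that incomplete sequences do not
masquerade as divergent ones — and columns pairing X with X count as
mismatch. Identities below 30% are discarded; divergence is
`PD% = 100 − identity%`. Among co-optimal alignments the aligner's own
tie-break decides which is reported; the score is the tested contract and
identity is only asserted on fixtures without co-optimal ambiguity.

**Clock and normalization.** For each species pair, `PDᵃᵛ%` is the arithmetic
mean of included PD values. The clock constant is fitted through the origin
(`kᵃᵛ = Σ t·PDᵃᵛ / Σ t²`), the line a strict neutral clock predicts; a
free-intercept fit is available by flag. R² is the squared Pearson
correlation of observed versus fitted values, which remains well behaved for
origin-anchored fits. `nPD% = PD%/PDᵃᵛ%` per (gene, pair); by construction
its mean over included genes is exactly 1 for every pair, which the suite
asserts end-to-end.

**Landscapes.** A genome order ranks genes by (chromosome in file order,
start position, gene id). The windowed value at rank k is the mean over ranks
k−50..k+50. By default windows run over the concatenated ranked list,
truncating only at the two genome ends ("concatenated"); a
"per-chromosome-truncated" mode restarts windows at chromosome boundaries.
The window is defined purely on ranked location, so the concatenated mode is
the default; both are constructions, since window behavior at boundaries is
not otherwise determined. Missing per-gene values are dropped from the window
mean rather than imputed; a window is missing only when all contributors are.

**Acceleration.** Clade-mean landscapes average the windowed nPD% tracks of
all pairs in a class (66 intra-Eutherian, 6 intra-Metatherian), one weight
per pair. The null distribution permutes the per-gene clade-mean values
uniformly over the same chromosome partition (3 replicates by default),
recomputes the windows, and pools all replicate window values; the threshold
is pooled mean + 3·SD (a per-replicate mean-of-SDs mode exists). Exceedance
is strict (`value > threshold`), and since every gene centers one window,
"windows above threshold" and "genes above threshold" coincide. Subtelomeres
are the first and last 50 genes of each chromosome; enrichment compares the
subtelomeric fraction of exceeding windows with the genome-wide subtelomeric
fraction. Each lineage analysis draws its random orders from a seed derived
from (run seed, analysis tag), so lineages are independent yet reproducible.

**Concordance.** A gene set is mapped between two genome orders; each shared
gene becomes a link, green iff subtelomeric in both orders under the same
50-gene margin. Gene-rank margins (rather than physical base-pair windows)
keep the definition consistent across the pipeline; links are exported as
tab-separated Circos-style records rather than rendered.

## Synthetic-data generator

The generator emulates the study design, not any particular genome:

* **Species and times.** 16 species — three Eutherian clades of four plus
  four Metatheria — on a fixed 4-level ultrametric tree: 70 My within
  Eutherian clades, 96 My Euarchontoglires–Laurasiatheria, 104 My to
  Afrotheria, 60 My within Metatheria, 158.5 My Eutheria–Metatheria. The
  three deep splits are the study's calibration means; the within-clade
  levels are plausible stand-ins and all are configurable.
* **Genome orders.** Order A: 23 chromosomes with sizes proportional to human
  protein-coding gene counts. Order B: an opossum-like karyotype (8 large
  autosomes + X), by default populated by uniform reshuffling of the gene
  set, reflecting that human and opossum subtelomeres are discordant. A
  "subtelomere-preserving" mode instead re-pairs chromosome arms with their
  telomeric ends kept outward (fusion/fission with conserved subtelomeres),
  used as the pig-like second Eutherian order.
* **Rates.** Per-gene clock rates are lognormal with mean 0.13 %/My and
  σ = 1.0 on the log scale, giving a ~100-fold spread between the 1st and
  99th percentiles ("up to two orders of magnitude" of rate variation).
* **Acceleration.** Default planted blocks multiply rates by 1.75 for one
  lineage: ~1,800 Eutherian genes in order-A subtelomeric blocks and ~1,500
  Metatherian genes in order-B blocks. Blocks are paired across chromosome
  joins because in the emulated genomes accelerated subtelomeres typically
  flank a join on both sides — with terminal-only blocks the concatenated
  window dilutes every block with background genes from the neighbouring
  chromosome and subtelomeric windows paradoxically deplete. At these
  defaults the pipeline flags ~9% of Eutherian genes (study scale: 12%) with
  ~55% of flagged windows subtelomeric (study: 50%). Cross-lineage pairs
  average the two lineage multipliers, since each regional effect acts on its
  own branch.
* **Divergences.** Expected divergence is linear in time, `d = k·mult·t`,
  capped at 95%, with binomial site-sampling noise over 450 sites (a typical
  protein length). There is no explicit substitution model here — uncorrected
  PD is linear-with-cap by design; the slower sequence-level path (Poisson
  substitutions with uniform replacement along the dated tree) exists for
  end-to-end tests of the alignment stage. The 30% identity floor is a
  correction for incomplete real sequence data and is not applied to directly
  generated matrices (the cap already bounds them).
* **GC/GARP.** Both tracks share, at every level (mammal-common regional,
  lineage-specific regional, per-gene noise), components correlated at
  ρ = 0.93, so the within-species gene-level and windowed GC–GARP
  correlations are ≈0.93 as in the emulated data. Lineage-specific regional
  profiles are generated on the lineage's own reference order, and
  acceleration blocks carry a small GC/GARP elevation, producing
  lineage-specific landscape signatures and inter-species windowed
  correlations of ~0.75–0.85.

## Numerical choices

* Origin-anchored regression reports R² = 1 exactly for exact fits; degenerate
  correlation (zero-variance fitted values) yields NaN rather than an error.
* The null SD is the sample SD (ddof = 1) over pooled replicate window values.
* Window means use a convolution with explicit centered slicing, so windows
  wider than the track truncate correctly; equality with a direct-loop oracle
  is asserted up to 2,000 genes including edges and missing values.
* Gene-order ties (equal start) break lexicographically by gene id;
  chromosome display order is file order of first appearance.
* Seeds: every analysis derives its generator from
  `(seed · 2654435761 + crc32(tag)) mod 2³¹`, keeping runs reproducible and
  sub-analyses independent.

## What the defaults do and do not show

The fitted genome-wide clock on the default cohort sits ~1–2% above the
nominal 0.13 %/My: planted acceleration inflates the mean rate by ~8% while
the 95% cap censors the fastest genes preferentially at the deepest split
(−5%), and the two effects largely cancel — as they implicitly do in the real
measurement the generator emulates. Measured against the cohort's effective
mean rate (including multipliers), the origin-anchored slope is biased low by
2–6% depending on the rate spread; this saturation bias is a property of the
linear-with-cap generative law, not of the estimator.

Passing tests on synthetic data show the pipeline's arithmetic, invariances
and recovery behavior; they cannot show robustness to features the generator
omits: orthology errors, alignment ambiguity from indels and domain shuffling,
assembly- and annotation-quality differences between species, gene-density
variation along chromosomes, and any correlation between rate and gene
function. Sequence-level simulation omits indels and uses a uniform
replacement model rather than an empirical amino-acid matrix, so realized
divergence falls below k·t at deep splits (multiple hits); the end-to-end
aligner test therefore checks the slope at moderate divergence only.

## Limitations

* The mean + 3 SD rule is the study's decision criterion, not a calibrated
  multiple-testing procedure; windowed values are strongly autocorrelated, so
  exceedance counts should be read as descriptive.
* Subtelomere margins are in gene ranks; physical distances are not modeled.
* Divergence times enter as fixed constants; their uncertainty is ignored.
* The default 3-replicate null matches the study design but estimates the SD
  from limited data; increase `n_random_orders` for tighter thresholds.
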
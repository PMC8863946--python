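# Methods

This note documents the models, parameter choices and numerical conventions
behind `cilseq`, and what the synthetic data generator does and does not
emulate.

## Somatic SNV model

Candidate variants are caller-labelled observations
(sample, site, depth, alt reads); the callers themselves are upstream and
are treated as metadata.  The six filters run in a fixed order and are
idempotent.  Boundary semantics follow strict readings throughout:
population AF must be *greater than* 0.01 to remove; depth must be
*greater than* 10; allele fraction *greater than* 0.05; "at least two
reads" is ≥ 2.  The proximity rule removes *both* members of any candidate
pair ≤ 10 bp apart and operates on the union of sites across samples,
because library-preparation artifacts recur across independently amplified
samples.  The recurrence rule is per patient and optional, since it is
only meaningful when a patient contributes several samples.

The mutation matrix adjustment addresses MDA allele dropout: a 0 or 1
observed at ≤ 5× coverage is weak evidence, so the entry is shrunk toward
the majority genotype of the *other* samples in the same pathology group
(0.9 toward carrier, 0.1 toward wild-type).  Ties keep the observed value
— the shrinkage is only defined for strict majorities.  Missing coverage
records count as 0× and are therefore adjustment-eligible.

All dendrograms in the package use average linkage (UPGMA).  Leaves are
sorted lexicographically before linkage so merge order, and hence the
serialized Newick tree, is deterministic.

The SNV-overlap test is an upper-tail hypergeometric
P(X ≥ |A∩B|) with the universe defaulting to the set of all detected SNVs;
a callable-sites universe can be supplied instead (the choice changes the
p-value's absolute scale but rarely its verdict).

## Copy-number amplifications

Segmentation is out of scope: the input is a gene-level log2(CN/2) table
from any upstream tool.  When only per-bin coverage is available,
`compute_gene_log2` normalizes each library by its genome-wide *median*
bin coverage and takes the log2 ratio of per-gene median bin coverages.
Median normalization (rather than total-count) is the CNV-caller
convention; it keeps focal gains visible when the target set is small.
"Covering target regions" means ≥ 1 read over a target base; samples below
50 % are dropped.  Calls use log2 ≥ 1.0 inclusive (CN ≥ 4); deletions
never produce calls.  "Three more amplifications in tumor than paratumor"
is a count difference (≥ 3), not a fraction, matching the printed wording.

## Methylome analysis

Conversion rate is estimated read-wise from non-CpG cytosines:
failure = Σ meth / Σ coverage, conversion = 1 − failure.  Bases outside
3–500× are discarded (both bounds kept).  CpG dyads are merged (+/− strand
records summed per site) before tiling — standard CX-report handling — so
"covered by less than three bases" counts CpG *sites*.  Tiles are
non-overlapping (step = width): 300 bp for fresh-frozen, 1 Mb for FFPE.

The DMR test pools counts within each compared group (the contrast is
between groups, not sample pairs) and applies the closed-form 2×2 Pearson
chi-square with 1 df and no continuity correction; p-values are
Benjamini–Hochberg adjusted across tested tiles.  Only tiles covered by
≥ 2 samples per group are tested.  A DMR requires q < 0.05 *and*
|Δlevel| > 0.25, both strict.  With `call_dmrs(tiles, A, B)` the sign
convention is diff = level(A) − level(B); "hyper" means B is
hypermethylated relative to A.

Chromatin-state annotation assigns each tile the state of maximal base
overlap, ties to the lowest state index, `none` when no interval overlaps.
Enrichment is a two-sided Fisher exact test per state and direction over
all common tiles, BH-adjusted within direction, significant at q < 0.01
with odds ratio > 1.  DMR frequency is
100 × |DMR tiles| / |common tiles|, optionally restricted to one state.

## Spatial expression

Spots are scaled so each total equals the median of the original spot
totals (zero-total spots dropped first), preserving within-spot
proportions exactly.  K-means uses 10 seeded k-means++ restarts, best
inertia wins; results are bit-reproducible for a fixed seed and input
order.  Panel clustering operates on median-normalized, log1p-transformed
marker expression with Euclidean average linkage; the log transform is a
package choice (counts are heavy-tailed and the panel spans two orders of
magnitude).

## The synthetic generator

The generator emulates one mixed-differentiation specimen with five
microdissected populations (2–4 samples each, 16 by default) and a bulk
immune control:

* **Clone tree** — root → {PL, PDR, truncal} with truncal → {LCSL,
  HCC/CCA-shared → {HCC, CCA}}.  Default branch SNV payloads are
  17/35/21/18/11/43, chosen so the leaf genotype sizes and overlaps equal
  the headline set sizes (73, 70, 52, 28, 17, 43).  SNV sets are nested
  along every root-to-leaf path by construction.  LCSL-private sites are
  *heterogeneous*: each is carried by 2 consecutive LCSL samples
  (round-robin), so LCSL samples differ among themselves while each site
  still survives a ≥ 2-samples recurrence filter.
* **Observation model** — depth is negative-binomial around a 30× mean
  (dispersion 8); carriers are heterozygous (alt fraction 1/2) unless an
  allele drops out.  Dropout is per-site per-sample with probability
  1 − (1 − r)^w, w = 2·mean/(mean + depth): equal to the configured rate
  r (default 0.2) at mean depth, rising toward ~2r as depth falls — the
  MDA failure mode the ≤ 5× matrix adjustment targets — and certain when
  r = 1.  The lost allele is chosen uniformly.  Sequencing error 10⁻³;
  5 % of calls carry a single caller label; germline-polymorphic and
  close-pair artifact sites are planted for the cascade to remove.
  Substitution classes put 70 % of mass on C>T.
* **Methylomes** — a toy contig tiled by a 15-state chromatin track whose
  footprints are weighted like a real genome (quiescent ×8,
  heterochromatin ×3, weak transcription ×3, transcription and weak
  Polycomb ×2): the broad repressed states dominate, so planting
  demethylation there (−0.40 in 9_Het and 15_Quies for HCC/CCA) lowers
  tumor *global* methylation even though the narrow promoter/bivalent
  states gain methylation (+0.30 in 1_TssA, +0.40 in 10_TssBiv,
  11_BivFlnk, 12_EnhBiv).  The stem-like population shifts only its
  bivalent/Polycomb states (+0.30 in 10_TssBiv and 13_ReprPC).  Counts
  are beta-binomial (concentration 60) around the clone/state mean at
  ~30× coverage; CpG dyads are emitted as two strand records; non-CpG
  cytosines fail conversion at rate 1 − 0.98.
* **CNA and spots** — amplified segments ride tree branches; the defaults
  place a chr8q-like amplicon on the HCC/CCA-shared branch and a private
  gain in HCC, both at copy number 6.  CN 6 (log2 ratio ≈ 1.58) is used
  rather than CN 4 because log2(4/2) = 1.0 sits exactly on the calling
  threshold and calls would be coin flips under ratio noise (σ = 0.1);
  CN 4 remains available via configuration and is the worked noise-free
  example in the tests.  A cohort-frequency table marks most amplified
  genes as common (10 %) with one low-frequency decoy (2 %) for the
  recurrence filter to reject.  Spots are cell-type-pure with
  liver-lineage marker logic: panel expression high in LCSL/PDR,
  intermediate in PL, low in HCC/CCA, plus a type-specific program over a
  block of background genes; counts are Poisson with log-normal library
  sizes.
* **Noise-free mode** (`noise="off"`) replaces every stochastic draw with
  its rounded mean (depth = mean, alt = depth/2, meth = round(level·cov)).
  It exists so end-to-end identity can be asserted: the filter cascade
  returns exactly the truth genotypes, amplification calls equal the truth
  table, and DMRs equal the planted tiles with their planted directions.

What the generator does **not** emulate: read-level data (no FASTQ,
alignment or duplicate structure), real human coordinates (toy contigs),
subclonal copy-number mosaicism within a population, methylation
heterogeneity *within* a clone beyond beta-binomial dispersion, spot
mixtures or spatial autocorrelation, and the inter-patient variability of
a cohort.  Passing tests therefore demonstrate that the statistics and
filters behave as specified under the assumed generative model — not that
the biological conclusions would survive on arbitrary real specimens.

## Problem sizes and calibration checks

The default simulated methylome uses 20 000 CpGs (2 000 tiles of 300 bp)
at 30×, 2 samples per population; the SNV stage uses 145 truth sites over
16 samples plus a control.  The DMR calibration check uses the 2 000-tile,
2 + 2-sample, 30×-per-sample configuration: under a global null the
expected number of seeds with any BH discovery is ≈ α, and the discrete
chi-square p-values at pooled 60 + 60 reads are conservative, so ≥ 95 % of
seeds yield zero DMRs while planted |Δ| = 0.4 tiles are recovered with
> 90 % sensitivity.  Clonal-topology recovery is evaluated over 100 seeds
of the default configuration.

On simulated data the DMR frequency of the tumor-vs-paratumor contrast
(≈ 40–55 %, depending on seed) exceeds the within-compartment
LCSL-vs-paratumor contrast (≈ 7–12 %); only this *ordering* is a claim of
the package — the absolute frequencies are set by the planted shift
footprints, not fit to any external dataset.

## Known limitations

* The chi-square DMR test on pooled counts ignores between-sample
  (biological) overdispersion; with strongly variable replicates it is
  anti-conservative.  The ≥ 2-samples-per-group rule and the 0.25 effect
  floor mitigate but do not remove this.
* The hypergeometric overlap test conditions on detected sets; with a
  callable-sites universe p-values shrink dramatically.
* `compute_gene_log2` is a deliberately simple stand-in for a real
  segmentation caller and has no GC or mappability correction.
* The proximity filter removes true variants that genuinely occur within
  10 bp of each other (e.g. dinucleotide substitutions).
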
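# Methods

`eqtlcross` implements a combinatorial expression-QTL analysis for biparental
crosses (F2 and selfed recombinant inbred lines): multiple scan engines per
transcript, permutation-derived significance thresholds, a two-method
consensus merge with cis/trans classification, trans-hotspot detection,
co-expression networks, term enrichment, and a candidate-variant filter
cascade.  This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## Linkage map

Markers are ordered strictly by physical position (chromosome, bp); no
de novo ordering or grouping is attempted.  Adjacent-marker recombination
fractions are estimated from the genotypes:

* **RIL** — the observed recombinant fraction between near-homozygous inbred
  lines is inflated by repeated selfing; the meiotic fraction is recovered by
  inverting r_obs = 2r/(1+2r).
* **F2** — maximum likelihood over the nine two-marker genotype classes by
  EM; the double heterozygote is the only class with latent phase, and its
  expected recombinant-gamete count at the current estimate is
  2r²/(r² + (1−r)²).  Estimates are clamped to [0, 0.4999].  Missing calls
  are excluded pairwise; no imputation is performed here.

Distances use the Kosambi function d = 25·ln((1+2r)/(1−2r)) cM, with the
closed-form inverse r = tanh(d/50)/2 (round-trip error < 1e−10 across the
domain).  A chromosome splits into separate linkage groups wherever an
adjacent gap **strictly exceeds** `split_gap_cM` (default 30 cM; a gap of
exactly 30 stays joined), and split groups get letter suffixes ("13a",
"13b").  Duplicate physical positions are tie-broken by marker id with a
warning.

## Scan engines

All three engines share a **scan grid**: positions every `step_cM`
(default 1 cM) along each linkage group, plus the last marker.  At each
position the putative QTL genotype expectation is computed from the flanking
markers (Haley–Knott): for F2, conditional probabilities are derived by
enumerating ordered gamete pairs consistent with the observed flanking
genotypes, giving an additive score x = P(BB) − P(AA) and a dominance score
z = P(H); for RIL, a two-state chain with selfing-expanded recombination
gives x = P(B) − P(A).  Recombination between a grid position and its flanks
comes from the map distances through the inverse Kosambi function; the
marker-to-marker fraction uses the summed distance, keeping the enumeration
internally consistent.  A line missing one flank is conditioned on the other
alone; a line missing both is dropped for that interval.

* **IM** — regression of the phenotype on [1, x, z] (z omitted for RIL);
  LOD = (n/2)·log10(RSS0/RSS1); PVE = 100·(1 − RSS1/RSS0) at the peak;
  the additive effect is the coefficient on x (half the homozygote
  difference) and dominance the coefficient on z.  One peak is reported per
  linkage group — the LOD maximum above threshold, bounded by its flanking
  markers.  This undercounts genes with two linked QTL on one group, a known
  limitation.
* **ICIM** — stage 1 selects cofactor markers by forward–backward stepwise
  regression on additive marker codes (entry/exit p-values 0.001/0.002, the
  customary defaults; at most min(n/5, 50) terms).  Stage 2 subtracts the
  jointly fitted contributions of all selected cofactors *except* the two
  markers flanking the interval being scanned.  Stage 3 is IM on the
  adjusted phenotype.  With no cofactors selected the profile equals the IM
  profile exactly (asserted in tests).
* **GCIM** — an explicitly simplified two-stage stand-in for genome-wide
  composite interval mapping; its validation is simulation-based, never
  numeric agreement with any external tool.  Stage 1 scans the grid with a
  polygenic control: `fixed` regresses on the top-k markers by marginal
  correlation (k = 5, flanks of the scanned interval excluded);
  `fixed_REML` fits a single-variance-component polygenic term with a
  marker-derived kinship (standardized GRM) by bounded REML over the
  heritability ratio and scans on the whitened data.  Per linkage group, the
  maximum passing a liberal cut (LOD 2.5) becomes a candidate.  Stage 2
  refits all candidates jointly with an L1-penalized regression (penalty
  0.05 × the smallest penalty that zeroes all coefficients); survivors are
  reported with LOD from the joint-model likelihood ratio (drop-one RSS).
  A failed kinship eigendecomposition falls back to `fixed` with a warning.
  With few markers the kinship is dominated by any single strong QTL and the
  REML polygenic term absorbs it — a known behavior of polygenic control at
  toy scale, visible in the test fixtures.

Population-level defaults follow the design the package emulates: GCIM LOD
cutoffs 7.5 (F2) and 4.0 (RIL); IM/ICIM thresholds permutation-derived.

## Permutation thresholds

The genome-wide null is built from a random sample of transcripts
(default 100) with `n_perm` (default 1,000) phenotype permutations each,
recording the genome-wide maximum LOD per permutation and pooling all
n_sample × n_perm maxima (100,000 at the defaults).  The threshold is the
empirical (1 − α) percentile with linear interpolation between order
statistics.  Both IM and ICIM use the IM scan kernel for the null: under
permutation no marker passes the stepwise entry test at p = 0.001, so the
ICIM null coincides with the IM null; this also keeps the bookkeeping
tractable.  GCIM uses fixed configuration cutoffs, not permutations.

## Consensus merge and cis/trans classification

An interaction is **cis** when its region is on the target gene's chromosome
and the distance from the transcription start site to the [start, end]
interval is at most 1 Mbp (0 if the TSS is inside; the boundary exactly at
1 Mbp is cis), otherwise **trans**.  Two interactions from different methods
co-validate when they share gene, class and chromosome and their intervals,
each padded by 500 kb per side (clamped to [1, chromosome length]),
intersect — equivalent to an edge-to-edge distance of at most 1 Mbp.  The
three pairwise comparisons (ICIM–IM, ICIM–GCIM, IM–GCIM) are realized as a
union-find over the per-gene, per-class interaction pool, so a pair found in
more than one comparison collapses to one consensus record and chained
overlaps union-merge.  Consensus coordinates are the union of the
*un-padded* contributing regions (raw union avoids systematic 1-Mbp
inflation).  Finally, any trans consensus region whose padded interval
intersects a cis consensus region of the same gene is reclassified cis; the
check is against consensus-level cis regions, the conservative reading since
only consensus regions survive the merge.  Merging is gene-wise only —
interactions for different genes never merge, as implied by the per-gene
codification string `class_gene_chrom start end` that the module reads and
writes.

## Hotspots

Each distinct regulating region (chromosome, left marker bp, right marker
bp) accumulates the trans interactions it drives.  Density is
count/(size/1000) interactions per kbp, reported to 2 decimals.  Count
thresholds are the 95th (minor) and 99th (major) percentiles of per-region
counts across all consensus trans regions of the population; the density
threshold is the 80th percentile of defined densities.  Percentiles use
linear interpolation and "above the Nth percentile" is inclusive
(≥ threshold) — the published bracket for minor hotspots includes its
boundary value, and with identical regions every region sits at the 100th
percentile and classifies major (documented degenerate case).  **Both
criteria are mandatory**: a region above the count cut but below the density
cut is not a hotspot.  Zero-width regions stay in the count pool but have
undefined density and can never qualify.  Hotspots sharing a boundary marker
merge (counts summed, density recomputed, class = stronger), and regions are
named `<TAG>_<CHROM>:<start>-<end>` with thousands separators.

Because scan peaks scatter to the marker pairs on either side of a causal
marker, a planted regulator typically produces two adjacent high-count pairs
that the merge step joins — the same pattern the merged-region naming was
designed for.

## Expression processing

A gene is expressed when its raw count is ≥ 2 in at least ⌈25% of lines⌉
(both boundaries inclusive).  Size factors are median-of-ratios: per line,
the median over genes with nonzero counts in every line of
count/geometric-mean, rescaled to geometric mean 1 — downstream statistics
are scale-invariant and the rescaling makes normalization exactly idempotent
(renormalizing returns unit factors).  The parental DE screen is a Welch
t-test on log2(normalized + 1) with Benjamini–Hochberg adjustment; a gene is
differentially expressed iff adjusted p ≤ 0.05 AND linear fold change ≥ 2.0
in either direction — a deliberate lightweight stand-in for a
negative-binomial Wald test that preserves the FC/FDR gating downstream
steps consume (a gene at fold change 1.9 with a tiny p-value is not a DEG).

## Co-expression and enrichment

CENs compute pairwise Pearson correlations over lines and cluster genes by
average linkage on 1 − PCC — chosen to emulate the defaults of the common
heatmap-clustering tools on correlation distances.  The cluster count
defaults to cutting the dendrogram at the largest merge-height gap
(overridable with a fixed k); labels C1, C2, … are ordered by descending
size.  Constant-expression genes have undefined PCC and are dropped with a
warning.  TWCENs threshold a single query gene's correlations at ≥ 0.85
(positive set) and ≤ −0.85 (negative set), boundaries included.

Enrichment uses one-sided hypergeometric tails with the direction chosen by
the sign of observed − expected (over and under verdicts are mutually
exclusive per term).  The correction multiplies — never clips — the raw p by
a multiplier, by default the number of scanned (query) genes, following the
unusual but explicitly stated multiplicative convention of the soybean
annotation service the package mirrors (corrected p-values may exceed 1);
a terms-count Bonferroni is available by passing the term count.  The
significance cutoff is 0.01.  The curated-term filter retains
biological-process terms on the supplied list only.

## Variant cascade

Retained variants satisfy (consequence ∈ {MODERATE, HIGH}) OR (location ∈
{3'UTR, 5'UTR}); missense variants carry a SIFT verdict with the boundary at
exactly 0.05 tolerated.  The single-parent rule keeps variants whose
alternate allele is **fixed (homozygous) in exactly one parental line**; the
other parent may be reference or heterozygous — heterozygous calls are
flagged and rendered as `*` — but never homozygous for the alternate.  This
admits the observed pattern of one het parent with one fixed-alt parent
while excluding shared alternates.  Candidates map to regions within a
configurable proximity window of the gene TSS (default 300 kbp, wide enough
to admit a TF just outside a hotspot).  The cascade is idempotent and
order-independent, and every output row re-satisfies both rules by
construction.

## Synthetic data

The generator emulates the study conditions the analysis assumes: two
population designs (F2 with 176 lines, RIL with 162), 20 chromosomes,
evenly spaced markers at a uniform 2.5 cM/Mb, planted cis effects at the
marker nearest each cis gene's TSS, and one or more trans regulators each
driving a block of target genes.  Factory configurations
(`SimulationConfig.f2_study` / `ril_study`) carry the full scales (~1,600
and ~2,740 markers; 38,692 and 40,218 expressed genes); tests and examples
use reduced marker/gene counts with the study's line counts and effect
sizes — the sizes quoted in test docstrings are the package's own choices.

* **Genotypes** — F2 lines are two independent gametes with crossovers
  placed as independent inter-marker recombination events (no interference:
  Kosambi interference affects map construction, not generation fidelity at
  this scale).  RILs are a single chain with the selfed expansion
  r* = 2r/(1+2r) and zero residual heterozygosity (pipelines remove
  het-heavy markers anyway).
* **Counts** — gene baselines are shared log-normal (heavy-tailed library
  structure, which median-of-ratios expects); per-line library totals are
  uniform in `library_size_range`; counts are negative binomial with
  dispersion α (variance μ + αμ², default α = 0.1, a typical bulk RNA-seq
  value; the noise family is a modeling choice, α → 0 recovers Poisson).
  Planted effects act on the log-mean in units of the gene's residual SD
  (√(α + 1/μ)), so `effect_sd = 1` means a one-residual-SD additive shift
  per allele.  **Effect signs are random**: regulators both activate and
  repress targets.  Besides realism, this keeps the count composition
  balanced — at reduced test scale a same-signed 200-target hotspot would
  be >50% of all genes and would bias the median-of-ratios size factors
  toward the regulator genotype, an artifact of scale, not of the method
  (in a ~40k-gene transcriptome targets are <1%).
* **Variants** — consequence classes, UTR flags, SIFT scores and per-parent
  alleles with both single-parent and shared-alternate patterns; planted
  exemplars guarantee one variant that must survive the cascade and one that
  must not.

What the generator does **not** emulate: linkage disequilibrium decay beyond
the marker grid, segregation distortion, missing genotype calls, batch or
library-preparation structure, GC/length biases, isoforms, and
sequence-level data.  Passing recovery tests therefore demonstrates the
pipeline's statistical machinery under its own assumptions, not robustness
to those real-data artifacts.

## Numerical conventions

Seeds fully determine all outputs; the pipeline derives per-stage substreams
from one root seed, runs single-process, and a rerun is byte-identical.
LOD is clamped at 0 and RSS ratios guarded (RSS1 floored at RSS0·1e−12;
constant phenotypes give an all-zero profile and no peaks).  Percentiles are
linear-interpolation throughout.  The Soybase-style corrected p is never
clipped.  Degenerate designs (monomorphic scores at a grid position) drop
out of the regression basis and contribute LOD 0.

## Reduced-scale choices in the test suite

Recovery tests use 2–4 chromosomes with 15–50 markers and 30–520 genes;
permutation checks pool 1,000–10,000 null maxima instead of 100,000.  The
acceptance script's reported quantities are closed-form density arithmetic
on published marker coordinates and counts, so they are exact at any scale.
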
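# Methods

This note documents the statistical models, the synthetic-data generator,
and the design choices behind `cryptorf`. It describes what the code does
and why; every empirical number it mentions is computed by the test suite
or `scripts/acceptance.py`, not asserted from memory.

## The analysis model

The pipeline nominates cancer-dependency cryptic ORFs by intersecting
independent evidence layers. Internally all genomic and transcript
coordinates are 0-based half-open; GTF is converted at the I/O boundary
(1-based inclusive on disk), BED is used as-is.

### Translation evidence

P-sites are assigned at 5′ position + a fixed offset (default 12 nt,
configurable), keeping reads of 25–34 nt. A single offset rather than
length-stratified offsets is a deliberate simplification: the downstream
test only needs the frame of each P-site relative to an ORF start, and the
generator produces footprints whose offset is exact by construction.

ORF enumeration reports, per (frame, stop codon), the single maximal ORF
starting at the most 5′ ATG since the previous in-frame stop — the
longest-isoform convention — with a minimum translated length (default
10 aa; the generator plants ORFs of 21–81 aa).

Translation calling is an exact one-sided binomial test: among the *n*
P-sites inside [start, end), the frame-0 count *x₀* is compared against
Binomial(*n*, ⅓); candidates with *n* below `min_psites` (default 10) are
reported untested and excluded from the BH pass, so sparse ORFs do not
dilute the FDR correction. This is a stand-in for full ORF-prediction
models (initiation-site selection, overlapping-ORF resolution and
negative-binomial coverage models are out of scope); it preserves the
inferential role — 3-nt periodicity as the signature of translation — and
is exactly calibratable: because the binomial tail is discrete, the test
is conservative, which the calibration check quantifies (null rejection
≈ 3–5% at α = 0.05). Overlapping candidates are tested independently and
deduplication then collapses near-identical products: greedy clustering in
(n_psites desc, orf_id asc) order, joining the first representative with
global amino-acid identity ≥ 0.9 (edit-distance based; ties broken
lexicographically for determinism).

### Screen analysis

Counts are normalized so each sample's median negative-control count
equals the geometric mean of those medians across samples (total-count
scaling is available); the negative controls are the natural invariant set
because they should not change between day 0 and day 21. Per guide,
lfc = log₂((mean day21 + 1)/(mean day0 + 1)); replicates are averaged
before the ratio. The per-guide p-value is the +1-corrected empirical tail
against the negative-control lfc distribution, tie-inclusive:
p = (1 + #{controls ≤ observed})/(1 + m). The +1 correction keeps p in
(0, 1] and exact by construction; no distributional assumption is made.
Hits require ≥ 2 guides at lfc ≤ −log₂(1.5) (inclusive, per the printed
"≤") and p < 0.05 (strict). QC reports per-class median lfc and a
one-sided rank-sum test that positive controls deplete relative to
negatives (pass at p < 0.01).

### Expression, survival, overlap

Differential expression uses the two-sided Wilcoxon rank-sum on log₂
values (Welch-t optional); the thresholds, not the test, carry the
analysis content, and rank-sum is robust at cohort sizes of tens per
group. Constant genes get p = 1 and a flag. Selection applies printed
boundary semantics exactly: lfc ≥ threshold, FDR < threshold.

Survival uses the standard two-group log-rank accumulated over distinct
event times, χ² = (Σ(O−E))²/ΣV with the hypergeometric variance and V = 0
when one subject remains at risk; strata are an expression median split
(≥ median = high), with a configurable cut. Set overlaps use Fisher's
exact test on the 2×2 membership table with an explicitly supplied
universe — no silent default, since overlap significance is meaningless
without one — and a 0.5 Haldane correction for zero cells in the odds
ratio only.

### Regulatory triage

Peak categories are decided at the peak midpoint with precedence
promoter-proximal (≤ 3 kb of a TSS) > TTS-proximal (≤ 3 kb of a TTS) >
exonic > intronic > distal intergenic; midpoint assignment guarantees one
category per peak. Common binding sites are the coordinate intersection of
the merged peak sets (positions covered by every set), the default
reading of "shared" sites; a peak-level ≥ 1 bp overlap flag supports
Venn-style counts. Window assignment is strand-aware: −30 kb/+10 kb
around the TSS in transcription direction (on − genes upstream extends
rightward); a strand-agnostic mode exists because the convention is not
universal. The final triage requires all four flags — co-upregulated by
both factors, tumor-upregulated, ≥ 1 common site in the window,
gene-effect < −0.2 (strict) in every required cell line — and orders
targets by ascending mean gene-effect. The triage universe is
protein-coding genes; the tumor-up criterion reuses the lncRNA
upregulation thresholds (lfc ≥ log₂(1.2), FDR < 0.01) since the analysis
does not print a separate one for this step.

### Closed forms

qPCR fold change 2^−ΔΔCT with ΔΔCT = (CT_target − CT_ref)_treated −
(CT_target − CT_ref)_control, and xenograft volume L·W²/2 (warn when
W > L).

## The synthetic study

`FixtureConfig` parameterizes one fictional chromosome with genes every
100 kb (so −30 kb/+10 kb windows never collide), each a two-exon model
whose concatenated exons are the transcript. Defaults: 120 lncRNA and 60
coding transcripts; half the lncRNAs carry a planted ATG→stop ORF
preceded by an in-frame stop so enumeration recovers the planted
coordinates exactly.

- **Ribo-seq**: per-transcript Gamma rates (negative-binomial marginals,
  dispersion 0.1) shared across 3 replicates with Poisson replicate
  counts; P-sites on planted ORFs/CDSs fall in frame 0 with probability
  periodicity + (1−periodicity)/3 (default periodicity 0.8, mean depth
  100, frame-uniform background 30 on unplanted lncRNAs); coding
  transcripts get an 8% initiation spike at the start codon and no stop
  codon P-sites, producing the expected metagene shape.
- **Screen**: per-guide Gamma abundance shared between timepoints;
  day-21 rates of essential-ORF guides (20% of ORFs) and positive
  controls divided by `depletion_fold` (default 3). The reference library
  geometry (3,913 targeting / 636 positive / 1,064 negative guides) is a
  config the tests exercise; the default study uses 5 guides per ORF with
  1,064 + 636 controls at 500× depth and 2 replicates per timepoint
  (replicate structure is exposed because it is an assumption, not a
  datum).
- **Cohort**: Gaussian log₂ expression (gene baseline N(5, 1.5²), noise
  sd 1), planted tumor-up genes shifted by +2; survival exponential with
  median 60 months, hazard × 2.5 for the above-median stratum of a
  designated gene, administrative censoring at 120 months. Sample sizes
  50/50 emulate a modest cohort.
- **AP-MS**: true interactors get ≥ 2 unique peptides in every bait run
  and 0 in controls; background proteins get overlapping Poisson counts
  with ≥ 1 control peptide, so the bait-specific filter separates classes
  by construction — the filter, not the separation, is under test.
- **Knockout contrasts**: two expression matrices (factor-A KO, factor-B
  KD vs control, 6 + 6 samples) with co-regulated genes shifted −2 in KO
  samples; residual sd 0.3, reflecting that cell-line replicates vary far
  less than tumor cohorts.
- **Regulatory**: planted driver genes get one peak per factor at a
  shared locus inside their window and effects in U(−1.0, −0.3) in both
  cell lines; five decoy classes each break exactly one triage link
  (weak dependency, single-factor binding, out-of-window binding, no
  tumor upregulation, no co-regulation); background peaks are
  factor-specific and kept clear of all windows so the common set
  contains only planted loci. This makes "final targets = planted
  drivers" a sharp, decoy-resistant oracle.

Every generator draws from its own seeded stream (`default_rng([seed,
stream])`); identical config + seed gives byte-identical files.

**What passing does not show.** The generator omits read-level errors,
alignment ambiguity, batch effects, copy-number confounding in screens,
overlapping genes, multi-isoform loci, and realistic survival-covariate
structure. Passing tests demonstrate that the inference machinery is
correct and calibrated under the stated generative model, not that the
thresholds are optimal for any particular real dataset.

## Problem sizes and numerical choices

The calibration/power checks use the sizes at which the properties are
stated: ≥ 2,000 frame-uniform ORFs at ~60 P-sites for null calibration;
500 periodic + 500 null ORFs at ~80 P-sites for power/FDR; 500 screened
ORFs with 50 essentials for recovery; 1,000 log-rank simulations at n = 80
for type-I error and 100 cohorts of n = 200 for power. These complete in
seconds and estimate rates to ~1% Monte-Carlo error. Exactness checks
(empirical p, Fisher, BH, interval operations) compare against
enumeration/brute-force oracles to 1e-10–1e-12.

Degenerate inputs are contracts, not crashes: zero transcripts, group
sizes < 2, missing negative controls, all-zero samples, empty strata and
empty `required_lines` raise typed errors; empty read tables, missing CDS
annotations and unplaced peaks degrade with warnings that are captured in
the run report.

## Known limitations

The ORF caller ignores near-cognate starts and overlapping-ORF evidence
sharing; the screen model has no guide-efficiency or copy-number terms;
differential expression is not a count model (no dispersion shrinkage);
the survival analysis is a single-gene dichotomy, not a multivariate Cox
model; peak-set intersection treats peaks as unweighted intervals. Each
is an explicit scope decision documented above.
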
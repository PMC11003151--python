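# Methods

This note records the models, conventions and design choices behind
`ernanet`, in the order the pipeline applies them, followed by an account of
what the synthetic-data generator does and does not emulate.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read. Merging requires at least 1 bp of overlap — intervals
that merely touch stay separate, matching the default semantics of the
interval-merge command the algebra mirrors. The midpoint of an even-length
region is the floor of (start+end)/2, and windows are clipped to chromosome
bounds rather than rejected so edge regions survive. Replicate-consistent
peaks are the *merge of all pairwise intersections* of the two replicates'
peak sets; whether replicate consistency should be intersection or union is
genuinely open, and the intersection reading follows the quoted command
order (intersect, then merge).

## Enhancer catalog

Enhancer activity is RPM(IP)/RPM(INPUT) over the center ±1 kb window, with
RPM = count/library-size × 10⁶. A zero INPUT RPM leaves the fold change
undefined (logged), rather than producing an infinity that would propagate.

Super-enhancers are a deliberately simplified ROSE: stitch enhancers whose
gap is ≤ 12,500 bp, rank stitched regions ascending by total signal, scale
both axes of the rank–signal curve to [0, 1], estimate slopes by centered
finite differences (one-sided at the ends), and flag regions *above* the
first rank whose slope exceeds 1. The signal used for ranking is the
background-corrected max(IP_RPM − INPUT_RPM, 0) summed over members; TSS-aware
stitching exceptions and gene mapping are out of scope because only SE
membership is consumed downstream. With fewer than 3 stitched regions the
curve is undefined and everything is non-super (warned). The calls are
invariant to uniform signal rescaling; note that on noisy rank curves the
first slope-1 crossing can sit well below the elbow, so the super fraction
is larger than classic ROSE would give — acceptable here because downstream
use is membership, not counts.

## eRNA definition and quantification

The transcription region is the enhancer center ±3 kb. Quantification
windows are that region minus every annotated gene/ncRNA body expanded by
±1 kb; records with no remaining window are dropped. RPM sums both strands
over the windows. The plus-strand fraction is computed per (breed, tissue)
from replicate-pooled counts; a record's single direction label comes from
the tissue where it is detectable with the highest mean RPM, because
direction proportions are a per-tissue quantity while each eRNA carries one
class. The 5–95% bidirectionality bounds are inclusive — a measure-zero
choice, but pinned and tested. Detectability (mean replicate RPM ≥ 1) is
inclusive at the boundary ("≥"). GC content counts N in the denominator,
mirroring length-based GC. The activity–expression relationship is
summarized by sorting detectable eRNAs by expression (descending), splitting
into eight near-equal bins (earlier bins absorb remainders), and correlating
per-bin mean expression with per-bin mean activity (Pearson).

Read counts are accepted as window-filtered per-strand totals per sample;
the exact fragment-counting convention of the original quantifier is not
recoverable, so the documented rule (reads summed over windows, both mates
of a pair as one fragment if a BAM adapter supplies them) stands in.

## Tissue specificity

TSI = Σᵢ (1 − xᵢ)/(N − 1) with xᵢ max-normalized per replicate. Without
normalization the index is unbounded; max-normalization yields the standard
tau index on [0, 1], consistent with the 0.8 threshold. The index is
computed separately for replicates 1 and 2; a feature is specific when
TSI > 0.8 (strict) in both replicates *and* both replicates agree on the
argmax tissue, which is then the assignment — agreement is the weakest rule
that yields a unique tissue. Gene detectability for downstream tests mirrors
the eRNA rule (mean TPM ≥ 1 over the tissue's replicates).

## Enrichment machinery

Hypergeometric enrichment is the exact upper tail P(X ≥ m) for m marked
among t draws from a universe of T with M marked. Permutation enrichment
counts query elements overlapping ≥ 1 feature (an element overlapping three
features counts once), and re-places every element uniformly at random per
null draw: chromosome sampled proportional to length, start uniform on
[0, chrom_len − element_len] so placement is clip-free and lengths are
preserved; assembly gaps are not excluded (the background rule must be
stated to be reproducible). The Monte-Carlo p is (1 + #{null ≥ obs})/(R + 1)
— never zero. QTL intervals are used as features without expansion (they
are already long); GWAS hits are expanded ±20 kb before overlap. FDR is
Benjamini–Hochberg throughout. With a discrete overlap statistic the
attainable p-values are coarse, so null rejection at 5% runs slightly
conservative; the calibration test uses 80 × 500 bp query elements against
80 × 1.5 kb features on a 1 Mb background, a configuration whose exact
binomial tail sits at 0.046.

Transposon analysis: enhancers are TEn when they contain ≥ 1 detectable
eRNA center. The insertion comparison is a two-sided Fisher test on the
2×2 (TEn/non-TEn × has/has-no repeat overlap) table; per-class base
fractions are repeat bases over enhancer bases; per-family enrichment runs
the permutation test separately in each group with BH correction across all
family × group tests.

## Motif scanning

HOMER-format PWMs; probabilities are floored at 10⁻³ and renormalized.
Scores are natural-log odds against a fixed uniform 0.25 background (the
threshold's log base is not externally pinned; natural log is used and the
synthetic motif files are generated in the same convention, so the system
is self-consistent). Both strands are scanned; reverse-strand hits are
reported at the forward-strand offset of the site's leftmost base; any
window containing N is unscoreable. Known-motif enrichment is a one-sided
Fisher test on per-set counts of sequences with ≥ 1 hit against a
caller-supplied background (e.g. non-specific eRNAs), BH-corrected — a
ranking-faithful simplification of the original tool's statistic.

## eGRN construction

Correlations are Spearman with average ranks for ties and the
t-approximation p-value, computed across all 20 samples (2 breeds × 5
tissues × 2 replicates); eRNA rows are RPM, TF/gene rows TPM. FDR families
are per linking task: all tested TF–eRNA pairs form one BH batch, all
eRNA–gene candidates another — the most defensible reading of a global
"corrected for multiple testing". Thresholds are strict: Rs > 0.5 (TF),
Rs > 0.3 (gene), q < 0.05. "Expressed in the tissue" for a TF means mean
TPM ≥ 1 over the tissue's replicates, mirroring the detectability rule.
Anchors for the 1 Mb rule are the gene TSS and the enhancer center; TAD
membership requires both anchors strictly inside one TAD, nested TADs
resolved to the smallest containing interval. The GWAS filter keeps eRNA
nodes whose region overlaps any hit ±20 kb and is applied to nodes after
edge inference — the final network is the same either way, since edge tests
do not depend on the filter. STARR refinement drops every eRNA whose region
contains no regulatory SNP, then prunes orphaned TF/gene nodes; it never
adds nodes or edges. An independent validator recomputes rho, distance,
TAD, motif and FDR conditions for every emitted edge from the raw inputs;
the pipeline fails if it reports any violation.

## STARR-seq allelic testing

The four output sequencing libraries collapse to two biological replicates
(each replicate's two libraries summed) before the replicates are merged;
the merge QC is the Pearson correlation of per-SNP total counts (warning
below 0.8). Coverage is ref+alt per library and "exceeding 20" is strict.
The effect size is the output/input allele-ratio fold change; significance
is the two-sided Fisher exact test on [[input_ref, input_alt],
[output_ref, output_alt]], defined as the sum of probabilities of all
same-margin tables with point probability ≤ the observed table's. The
regulatory cutoff is BH q < 0.05, matching the FDR conventions used
elsewhere; a zero cell leaves the effect size undefined but the test still
runs.

## Synthetic data: what it emulates, and what it does not

The generator lays out 2 feature chromosomes on a 15 kb slot grid (6 slots
per 90 kb TAD) plus a featureless background chromosome, with i.i.d.
uniform-base sequence. Defaults: 240 enhancers (2 kb, one per slot, ≥ 13 kb
apart so nothing stitches), 70 genes, 30 TFs, 8 ncRNAs, 50 TF→eRNA→gene
chains (each chain's enhancer and gene in the same TAD, TFs shared
round-robin), 20 samples (2 breeds × 5 tissues × 2 replicates).

* **Peaks**: each enhancer appears in every tissue/replicate peak file with
  outward jitter ≤ 200 bp, so replicate intersection-then-merge retains all
  planted enhancers; the generator derives the final enhancer ids through
  the same code path as the pipeline, making ground truth id-stable.
* **Expression**: baseline lognormal (meanlog 1, sdlog 0.7). Chain members
  share a per-TF latent normal factor with mixing weight a = √r where
  r = 2 sin(π·ρ_s/6) (Gaussian-copula relation), giving pairwise Spearman
  ≈ 0.9 at the latent level; the lognormal transform is monotone so ranks
  are preserved. This closed form replaces per-seed empirical calibration —
  simpler, deterministic, and within ±0.1 of target at n = 20. Planted
  tissue-specific features are multiplied by 20 in one tissue of both
  breeds. With i.i.d. replicate noise at sdlog 0.7, a fold-20 feature's TSI
  occasionally dips below 0.8 in one replicate, so specificity recall is
  high (≈ 0.96 across seeds) but not exactly 1 — real replicate noise
  behaves the same way, and the tests assert the attainable property.
* **eRNA counts**: strand split from a per-eRNA plus-fraction drawn from
  Beta(8,1) (unidirectional group, 30%) or Beta(5,5); 25% of decoy eRNAs
  are "non-transcribed" (signal × 0.01, undetectable everywhere). Library
  sizes ≈ 1.2 × 10⁷ so integer rounding barely perturbs ranks.
* **Motifs**: one 12-mer PWM per TF (0.997 consensus probability,
  threshold 12 natural-log units, so only exact consensus matches score);
  the genome is scrubbed of accidental matches and the consensus planted at
  each chain enhancer's center — hits occur exactly in chain-linked
  enhancers, verified at generation time.
* **GWAS/QTL**: one hit within ±20 kb of each chain eRNA, background hits
  on the featureless chromosome, six 200 kb QTL intervals.
* **STARR**: input alt fraction 0.5 at depth 500; each of four output
  libraries binomial at p = e/(1+e) with e = 3 for the 40 true SNPs, 0.5
  for the 60 nulls; pathological records (coverage 10, zero alt cell) are
  included to exercise error paths.

Not emulated: read-level data (FASTQ/BAM), realistic GC/repeat landscapes,
linkage disequilibrium, correlated replicate noise, breed-differential
expression, or assembly gaps. Passing tests therefore demonstrate that the
statistics and filters recover planted structure under the stated noise
model — not that the pipeline is robust to alignment artifacts or
covariance structures absent from the generator.

## Problem sizes and numerics

Default sizes (≈ 6.5 Mb genome, 240 enhancers, 50 chains, 20 samples) keep
a full generate-plus-run cycle around ten seconds, so every stage is
exercised end to end in routine test runs. Permutation tests default to
R = 1000 with the (k+1)/(R+1) estimator. Ties in Spearman use average
ranks; constant expression vectors are dropped from correlation with a
warning (the all-zero decoy row exercises this). Degenerate inputs are
handled explicitly: empty quantification windows drop the record, zero
INPUT leaves fold change undefined, all-zero expression leaves TSI
undefined, zero STARR cells leave the effect size undefined while the test
still runs, and sub-coverage SNPs are excluded before testing.
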
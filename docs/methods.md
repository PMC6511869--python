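# Methods

## Coordinate model and overlap semantics

All genomic regions use the BED convention: 0-based, half-open `[start, end)`.
Two intervals *overlap* when they share at least `min_bp` bases of their
half-open intersection; the default `min_bp = 1` matches the behaviour of
`bedtools intersect` with default options, which is the operation the
filtering steps model. Adjacent intervals (`[0,10)` vs `[10,20)`) do not
overlap. Overlap queries run on per-chromosome interval trees
(`intervaltree`); the test suite checks every tree-backed result against an
O(n·m) all-pairs enumeration on randomized sets of up to 200 intervals.

## Peak specificity pipeline

`specificity_pipeline` applies three filters in a fixed order:

1. **Blacklist**: any peak overlapping a blacklist region is removed, and
   the removed count is reported so a "no peaks were blacklisted" claim can
   be verified as `removed == 0`.
2. **Control subtraction**: multiple control sets are unioned first — any
   control evidence disqualifies a peak — and overlapping target peaks are
   removed *whole*, never clipped. Removing rather than clipping is the
   right semantics for specificity filtering: a peak co-occurring with
   non-targeting background is not locus-specific anywhere along its length.
3. **Replicate intersection**: peaks shared between replicates are kept.
   The default reporting frame is the first replicate's coordinates
   (`report="first"`); a peak overlapping several peaks of the other
   replicate counts once. Because no published convention pins down whether
   shared peaks should be reported in rep1 coordinates, rep2 coordinates, or
   as merged intersection regions, the alternative conventions are exposed
   via `report="second"` / `report="merged"` rather than silently chosen.
   With more than two replicates the intersection is a left fold.

Output ordering is deterministic (chromosome lexicographic, then start, then
end). `tn5_offset` shifts a stranded read interval by +4 bp (`+`) or −5 bp
(`−`) to recover the Tn5 insertion site, clamping at the chromosome origin
with length preserved; shifting the whole interval (rather than only the
5′ cut site) is the default because downstream peak calling consumes whole
fragments.

## Interaction sensitivity and accuracy

`compare()` scores a predicted interaction set against a reference with a
single overlap count shared by both ratios: SE = n_overlap / n_reference,
AC = n_overlap / n_predicted. The numerator counts *predicted* intervals
with at least one reference overlap, each at most once. This convention is
adopted because the printed percentages of the motivating comparison are
consistent with a single numerator (69 = round(0.46 × 150) =
round(0.154 × 448)); counting on the reference side instead is available via
`side="reference"`, since one predicted interval spanning several reference
intervals makes the two conventions diverge. SE is reported to one decimal
place as a percentage.

## qPCR relative enrichment

The equation is evaluated in log space (sums of `log(quantity)`) so extreme
dilution ratios neither overflow nor underflow; the result is exactly the
double ratio

(T_pd/T_in ÷ R_pd/R_in) under the targeting guide, divided by the same
quantity under the control guide. Two identities follow and are tested:
multiplying all eight quantities of a replicate by a constant changes
nothing, and swapping the guide labels inverts the result.

Quantities can be measured directly or derived from Ct through a per-assay
standard curve (least-squares line of Ct on log10 quantity; efficiency
`10^(−1/slope) − 1`); ΔΔCt shortcuts are deliberately not used because a
standard curve per assay is the stated protocol. Replicates are summarized
as mean ± SEM (sd/√n) with a **two-sided one-sample t-test of log2
enrichment against 0**. The one-sample log-scale test was chosen because the
enrichment is a ratio already normalized to the control condition — its null
is exactly "fold = 1" — and because multiplicative errors are closer to
normal on the log scale; a two-sample test would require the unnormalized
per-condition values, which the equation consumes internally.

## TERRA motif counting

A read is a TERRA candidate iff it contains `(TTAGGG)×4` or `(CCCTAA)×4` as
an exact, contiguous, case-insensitive substring (24 nt). No mismatches are
allowed and `N` never matches, since no mismatch tolerance is part of the
definition. The second motif is the reverse complement of the first, so
scanning both strings covers both read strands without a separate
reverse-complement pass. Reads are counted, not motif instances: a read
containing both motifs counts once. The sample statistic is motif reads over
total reads supplied; read cleaning (adapter/quality trimming) is upstream
of this package. The fold between two samples is the ratio of fractions,
with 0-control flagged as +inf and 0/0 reported as 1 with a warning.

## Transcript fold enrichment

Counts are scaled to counts-per-million by default ("estimated read counts"
from pseudoalignment are library-size dependent, and the raw-count mode is
retained for fidelity); fold = normalized target / normalized control, and
transcripts at or above the threshold (default 3, boundary inclusive) are
enriched. rRNA transcripts are dropped *before* classification. A transcript
absent from the control gets fold +inf and is called enriched only if its
normalized target count reaches a floor (default 5), so single-read noise is
not promoted to an infinite fold.

## SILAC normalization and calling

The detected members of a supplied cytoplasmic false-positive list define
the background: every raw H/L ratio is divided by the **median of the
detected FP raw ratios** (midpoint of the central pair for even counts),
which makes the FP median exactly 1 after normalization — an identity the
tests assert, along with idempotence and scale invariance. Proteins with
missing or non-positive ratios are dropped with a logged count. Enrichment
is normalized H/L ≥ cutoff, inclusive, with default cutoff 1.5 as a fixed
parameter; `derive_cutoff(q)` alternatively returns the (1−q) FP quantile
for a chosen leak rate. The fraction of false positives strictly below the
cutoff is always reported alongside the calls as the cutoff's empirical
justification, and false positives that clear the cutoff stay flagged
rather than silently removed.

## Synthetic data

The generators produce the study conditions the analyses expect, not
realistic sequence data, and every generator is a pure function of
(parameters, seed) via a private `numpy` Generator — no global random state.

- **Capture peaks**: a target region plus interaction loci (default 5) and
  background peaks (default 20, width 600 bp) placed by rejection sampling
  with ≥1 kb between any two planted/background peaks, so truth membership
  is unambiguous. Planted peaks enter each replicate independently with
  probability `reproducibility` and per-replicate jitter; background peaks
  appear in both replicates *and* the control, so control subtraction
  removes them.
- **Telomeric reads**: exactly `round(n·fraction)` reads carry one 24-nt
  motif at a uniform offset; background reads are rejection-sampled to be
  motif-free (vanishingly rare at the default 100 nt anyway).
- **Transcript counts**: lognormal per-transcript baselines, planted
  multiplicative folds drawn from `fold_range` (default 4–8) for enriched
  transcripts, gamma-Poisson (negative binomial) sampling at the given
  dispersion. `dispersion = 0` is defined as the noise-free mode in which
  counts equal their means exactly (a literal NB limit would still be
  Poisson-noisy, which would defeat exact truth-table recovery). The default
  fold range starts at 4 rather than the calling threshold 3 because CPM
  normalization multiplies every fold by total_control/total_target, a
  factor slightly below 1 when positives are planted; defaults keep planted
  folds separably above the threshold after normalization. The biotype mix
  defaults to pseudogene/lincRNA/antisense-dominated non-coding classes with
  a 5% rRNA stratum that is never marked enriched.
- **SILAC ratios**: FP ratios lognormal with the stated median and
  `fp_log_sigma` default 0.425 — the log-sd that puts ≈83% of false
  positives below a normalized ratio of 1.5, the background shape against
  which the 1.5 cutoff is judged; TP ratios are a fresh FP-like draw times
  `tp_fold`.
- **qPCR**: the eight quantities per replicate are 1 except the target
  pulldown under the targeting guide, which equals `true_fold`. `cv` is the
  coefficient of variation of the *replicate-level enrichment*: the matching
  log-variance `ln(1+cv²)` is split equally over the eight quantities as
  median-preserving lognormal noise. Parameterizing at the replicate level
  keeps the recovered enrichment unbiased in the median and only mildly
  biased in the mean (`√(1+cv²)`, ≈2% at cv = 0.2); putting CV = cv on each
  quantity independently would inflate the mean enrichment by
  `(1+cv²)⁴ ≈ 17%`, an artifact of the ratio form rather than a property of
  the assay.

What passing tests on these generators shows: the filtering, counting and
normalization logic is correct against known truth. What it does not show:
robustness to alignment artifacts, peak-caller idiosyncrasies, adapter
contamination, ratio compression in MS, or any other upstream effect the
generators do not model.

## Problem sizes and tolerances

The randomized oracle suites use ≤200 intervals per set and 10⁴ reads; the
parameter-recovery suites use 2000 transcripts (50 planted), 10³ false
positives for median recovery (tolerance 5%, ~3× the sampling sd of a
lognormal median at that n), and 50 qPCR replicates (tolerance 10% on the
mean, against a ~2% structural bias plus ~3% sampling sd). SILAC recall and
leak-rate checks are held to ±3 binomial standard errors of the
expectations implied by the generating lognormal. The full suite runs in a
few seconds on one CPU.

## Known limitations

- The filtering pipeline consumes called peaks; peak calling, alignment and
  duplicate removal are out of scope.
- The SE/AC comparison counts binary overlaps; it does not weight by overlap
  length or interaction strength.
- Standard-curve fitting assumes a single linear dynamic range; no outlier
  rejection of dilution points is attempted.
- The FP-median normalization assumes the false-positive list is large
  enough for a stable median; the error surfaced when no FP protein is
  detected is the only guard.
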
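# Methods and design notes

This note records the statistical models implemented in `cardmpra`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer would want
written down.

## Assay model

A barcoded reporter library is sequenced as paired DNA (plasmid/integrant
abundance) and RNA (transcriptional output) libraries over k biological
replicates. The activity of a design is the depth-normalized log ratio

    activity = log2((RNA_FPM + 1) / (DNA_FPM + 1)),

averaged over replicates; FPM is reads per million within one
replicate-material library, and the +1 pseudocount keeps zero-RNA designs
finite. Designs are analyzed only when covered at >= 20 FPM in at least
one DNA library — the filter is on DNA only, so a design with no RNA
signal is scored (as strongly negative), not dropped.

## Count model and active calling (`active`)

Counts for one design across the 2k libraries are modeled as negative
binomial with variance mu + alpha * mu^2. Libraries are scaled by
median-of-ratios size factors (the median, over designs nonzero in every
library, of the count over the design's geometric mean; total-count
scaling is the fallback when no such design exists). Dispersion is a
per-design method-of-moments estimate on normalized counts, pooled across
the two materials after removing each material's mean, floored at
`alpha_floor = 0.01`. No shrinkage toward a mean-dispersion trend is
applied; correctness is asserted through calibration properties rather
than agreement with any particular reference tool.

The test is a NB log-linear model with replicate fixed effects plus an
RNA-vs-DNA material effect (fit by IRLS via statsmodels GLM with a
library-size offset), a two-sided Wald test on the material coefficient,
and BH correction across designs; "active" requires padj < 0.05 and a
positive RNA/DNA log2 fold change. Two small-sample choices matter:

- **Reference distribution.** The Wald statistic is referred to a t
  distribution with 2(k-1) degrees of freedom — the degrees of freedom
  available to the dispersion estimate — rather than a normal. At k = 4
  replicates the normal reference is visibly anti-conservative (empirical
  type-I error near 0.09 at nominal 0.05 in null simulations), while the
  t(2(k-1)) reference lands within Monte-Carlo error of nominal.
- **The dispersion floor.** When the true dispersion sits at or below the
  floor, estimated dispersions are biased up and the caller is deliberately
  conservative (empirically ~0.01 at nominal 0.05). The calibration test
  suite therefore simulates null data at dispersion 0.05, above the floor,
  where the estimator is in its regular regime; a separate test asserts
  that at-the-floor behavior errs conservative, never inflated.

## Paired variant classification (`pairs`)

REF/ALT (or wild-type/deletion) pairs are compared by a paired two-sided
t-test on per-replicate activity differences (ALT minus REF), with BH
applied jointly across all pairs in the experiment. A pair is MPRA-DA
when log2FC <= -0.58, MPRA-IA when log2FC >= +0.58, in both cases with
padj < 0.05 and detectable activity in at least one pair member;
otherwise MPRA-NS. log2FC is the mean of per-replicate differences,
consistent with the paired test. "Detectable activity" defaults to
requiring at least one member among the NB active calls; an alternative
reading (positive mean activity in a member) is available via the
`detectable="nonzero_rna"` switch. Fewer than three complete replicate
pairs flags the pair "undertested" with p = 1. For tiling-deletion
libraries, fragments without a covered wild-type oligo are dropped
entirely before summarizing per-deletion effects.

## Rank enrichment (`enrich`)

For a library of N designs ranked by activity and a subset R of n
members, the enrichment score at rank i is the cumulative membership
fraction minus the cumulative library fraction,
ES_i = (1/n) * sum_{t<=i} 1[r_t in R] - i/N, so ES_N = 0 identically.
The test statistic is the mean of the ES curve; its p-value is the plain
proportion (no +1 smoothing) of B = 2,000 random same-size subsets with a
mean ES at least as extreme in the direction of the observed sign
(one-sided by construction), with an optional Bonferroni multiplier for
batches of subsets. Because the tail is chosen by the observed sign, the
null p is uniform on [0, 1/2]; calibration tests therefore check that the
doubled p is uniform on [0, 1]. Permutations are vectorized through the
closed form mean ES = (1/(nN)) * sum_t (N - rank_t + 1) - (N+1)/(2N).

## Motif analysis (`motifs`)

PWM matches are scored as log2 odds against the background base model,
with a pseudocount of 1e-3 per matrix cell. Scores are discretized to
1e-3 log2-odds units and background probabilities to integer weights on a
2^-20 grid; the distribution of the discretized match score under the
background is then built by dynamic programming in exact integer
arithmetic. Match p-values (the tail probability of the best hit's score)
are therefore *exactly* what exhaustive enumeration over all k-mers would
produce at the same discretization — the test suite checks bit-identity
for motifs up to 6 bp. A single big-integer division per lookup produces
the correctly rounded float.

The reported motif score is -log10(p) of the best hit on either strand
whose span overlaps the scan window (+-8 bp around a variant for
substitution libraries, +-10 bp for deletion libraries). A variant
changes a motif when |score_alt - score_ref| >= 2 — at least a 100-fold
change in match p-value — and the motif matched at p < 1e-3 in at least
one allele; the sign of the change gives loss (LoM) or gain (GoM).

A note on what an SNV can do to a *uniform* strict-consensus PWM: a
single mismatch moves the match p-value by only a factor of 1 + 3L (all
single-mismatch k-mers score identically), so a >= 100-fold change
requires either motifs with heterogeneous position information — where a
mismatch at a critical position falls below a large mass of k-mers — or
multi-base changes such as deletions. The tests plant a mixed
strict/moderate motif for exactly this reason.

The signed odds ratio for motif m and direction class (MPRA-IA or
MPRA-DA) compares the proportion of effect-class pairs with a motif
change (P_mc) to the proportion among MPRA-NS control pairs (P_mn):
OR = n * [P_mc (1 - P_mn)] / [P_mn (1 - P_mc)], with n = +1 for
activator-consistent patterns (score up in MPRA-IA, down in MPRA-DA) and
n = -1 otherwise; zero cells get Haldane 0.5 smoothing with a flag. The
direction n is determined from the mean score change among changed
effect-class pairs.

## EpiCard (`epicard`)

Each genomic window receives, per annotation track, the overlap length in
bp and — for tracks with a quantitative value — the length-weighted mean
value and the total value x overlap. Interval intersection is computed
directly with vectorized coordinate arithmetic (the operations involved
are two clips and a sum; no interval-tree library is needed at these
scales).

Activity models are LASSO fits on z-scored features: the continuous
family regresses log activity by least squares (`LassoCV` path, 100
penalties); the binary family is L1-penalized logistic regression on
active/inactive labels (`LogisticRegressionCV`, log-loss scoring).
Following the rule that the final model deliberately under-penalizes to
reduce overfitting, the shipped penalty is the cross-validated lambda
divided by ten. Consequences worth knowing: support size inflates well
beyond the truly informative features (as it did for the real-data models
of this design, which retained roughly half the annotation compendium),
so the model should be read as a *scorer*, not a variable selector.
Recovery of planted informative annotations and active/inactive
separation (AUC > 0.9) are the asserted guarantees. Coefficients are
reported on the original feature scale.

The EpiCard score of a variant is the binary model's linear predictor on
the 200 bp window centered on it. The linear-predictor (link) scale is
used rather than predicted probability because meaningful score cutoffs
can exceed 1 on this scale. Cohort burden statistics combine a two-sided
t-test on mean scores, a 2x2 table of scores above/below the 95th
percentile of the *control* cohort (linear-interpolation percentile),
reported as the sample odds ratio ad/bc with Fisher's exact p, and the
same table on per-participant maximum scores.

## Synthetic data (`sim`)

One global seed expands into independent substreams (genome, truth,
counts, annotations, cohort), so identical configurations give
byte-identical outputs and components can be regenerated in isolation.
Coordinates are 0-based half-open internally and BED on disk.

What the generators emulate, and the defaults:

- **Counts.** Design abundances are lognormal (sigma 0.5); DNA counts are
  NB around relative abundance x depth (2e6 per library); RNA means are
  the DNA relative abundance x 2^(true log2 multiplier) x depth. The
  count noise model of real assays is not published; NB is an assumption.
  The default dispersion 0.01 is calibrated so that replicate activity
  correlations match the r ~ 0.95 reproducibility reported for
  well-behaved assays of this design; 30% of regions are active with
  log2 multipliers uniform on (1, 3).
- **Variant effects.** A configurable fraction of REF/ALT pairs carries a
  +-1.5 log2 effect on the ALT allele.
- **Annotations.** Informative tracks overlap a region with probability
  sigmoid(logit(0.15) + 3 * 1[active]) — an overlap odds ratio of ~20 for
  active regions — while uninformative tracks overlap at the base rate;
  interval values are gamma-distributed.
- **Cohorts.** Per-participant ncDNV counts are negative binomial
  (size 12.0, mean 8.6), chosen so the integer quartiles are exactly
  (6, 8, 11) with >= 0.03 probability margin at each quartile boundary —
  stable under finite cohorts. A configurable fraction of case-cohort
  variants is relocated into active regions to simulate enrichment.

What they do *not* emulate: sequencing error beyond barcode mismatches,
GC or fragment-length bias, barcode hopping between similar constructs,
position effects of lentiviral integration, linkage between variants, or
realistic genome composition. Passing tests demonstrate that the
*analysis* is correct and calibrated under the stated model, not that the
model captures every artifact of real libraries.

## Problem sizes used by the validation suites

Null calibration of the NB caller uses 1,000 null designs; paired-test
error and power use 30 simulated assays of 100 pairs each (~1,400 effect
pairs and ~2,000 null pairs); enrichment calibration uses 200 null runs of
500 permutations plus a floor check at 2,000; LASSO recovery uses 1,000
regions x 200 tracks with 5 informative; Monte-Carlo means over 200
repeated simulations back the activity-recovery checks. These sizes put
Monte-Carlo error comfortably inside the asserted bounds.

## Known limitations

- The NB caller's t-reference is a pragmatic small-sample calibration,
  not an exact distributional result; at many replicates it converges to
  the usual normal Wald test.
- Dispersion is estimated per design without information sharing;
  at 2-3 replicates the estimates are noisy and the floor does most of
  the regularization.
- The barcode counter is a reference implementation (exact hash plus
  linear Hamming scan); for very large FASTQ inputs a specialized matcher
  would be faster.
- `prioritize_variants` uses linear TSS distance only; no
  promoter-interaction data is consulted.
- The enrichment permutation test reuses one null sample per observed
  subset; p-values below 1/B are reported as their floor.
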
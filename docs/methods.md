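# Methods

`conexic` re-implements an integrative copy-number + expression driver-gene
analysis as a tested, reusable pipeline.  The scientific question it serves:
given gene-level aCGH log2 ratios and log2 expression for the same tumors,
which genes inside recurrently gained or lost genomic regions are *drivers*
— genes whose expression level controls downstream transcriptional modules —
as opposed to passengers that are merely swept along in the same aberration?
The method's two working assumptions are that (i) a driver should modulate
the expression of its gene modules and (ii) it is the driver's *expression*,
not its copy number per se, that carries the phenotype (copy number is one
of several routes to altered expression).

## Pipeline overview

1. **Preprocessing** (`conexic.preprocess`): genes with log2 expression SD
   below 0.25 are removed (strict inequality: SD exactly at the threshold is
   retained); multi-probe genes are merged by the per-sample mean when their
   probes agree (minimum pairwise Pearson r >= 0.7, configurable; probes
   that disagree mark the gene "inconsistent" and it is dropped); genes
   without copy-number data are filtered out by intersecting the matrices.
2. **Recurrent-aberration calling** (`conexic.aberrations`).
3. **Driver learning** (`conexic.learning`): candidate selection,
   Single-Modulator association, Module-Network refinement, both learning
   stages under bootstrap stability selection, CONEXIC-score ranking.
4. **Downstream statistics** (`conexic.activity`, `conexic.stats`):
   rank-based module activity, split-value stratification, Fisher/Wilcoxon
   comparisons, hypergeometric enrichment, Kaplan-Meier/log-rank survival.

## Recurrent-aberration calling

Per gene g and direction, the G-score combines frequency and magnitude of
alteration: `G_g = sum_s max(0, +/-c_gs - theta)` with amplitude threshold
`theta = 0.1` (a conventional noise floor for log2 ratios; configurable).
The null distribution permutes each sample's gene-level values across genes
independently, P = 1000 times, and pools all permuted G-scores;
`p_g = (1 + #{null >= G_g}) / (1 + P x n_genes)`, with Benjamini-Hochberg
q-values and a q < 0.25 call threshold (the permissive cutoff conventional
for this score family).  Significant genes are grouped into maximal
contiguous runs per chromosome (genes, not markers, are the positional
unit, since inputs are gene-level).  A *peel-off* pass then zeroes the
recorded genes' values in the samples where they exceed theta and repeats
scoring, so a strong focal event no longer masks secondary peaks; regions
found on later passes carry a higher `pass_index`.  Note the pooled null is
contaminated by true signal (the permutations scatter real aberrant values
across genes), which makes the test conservative for background genes —
the same behavior that makes this score family robust in practice.

## The Bayesian score

A module's expression at a tree leaf is modeled as Normal with unknown mean
and precision under a conjugate Normal-Gamma prior
NG(mu0=0, kappa0=1, alpha0=1, beta0=1).  The leaf marginal likelihood has
the closed form

    log p(x) = -(n/2) log 2pi + (1/2) log(kappa0/(kappa0+n))
               + lgGamma(alpha_n) - lgGamma(alpha0)
               + alpha0 log beta0 - alpha_n log beta_n

with `alpha_n = alpha0 + n/2` and
`beta_n = beta0 + Sxx/2 + kappa0 n (xbar - mu0)^2 / (2(kappa0+n))`.
The defaults are weakly informative for median-centered log2 expression
with roughly unit variance; data on a very different scale should be
standardized first, since beta0 fixes the prior's variance scale.  The
implementation is validated against direct 2-D numerical integration of the
likelihood against the prior density (< 1e-6 relative error).

A *regulatory program* is a regression tree of depth <= 2 over modulator
expression: the root (modulator, split value) partitions tumors into
driver-low (<= split) and driver-high (> split) groups, and each branch may
be split once more.  A program's score is the summed leaf marginals of its
module genes minus a structure penalty per internal node.  The penalty is
the log of the number of (modulator, split-point) candidates evaluated — a
Bayes-factor multiplicity correction standing in for an explicit structure
prior.  Candidate split points are midpoints between consecutive distinct
sorted modulator values whose leaves both hold at least `min_leaf_size = 5`
samples, so ties can never straddle a split.

## Learning

**Candidates.** All genes inside significant regions are candidates,
inheriting the region's direction (amplified/deleted); regions larger than
20 genes are trimmed to the members with the largest |Spearman correlation|
between their own copy number and expression (the genes whose expression
actually responds to dosage).

**Single Modulator.** For each non-candidate gene and candidate, the best
depth-1 split gain is computed; the gene joins the argmax candidate when
the penalized gain is positive.  Modules below `min_module_size = 5`
dissolve.  Each surviving module is split into positively and negatively
correlated halves (Pearson r >= 0 counts positive; exact zero and
zero-variance genes go positive by the documented tie rule).

**K-means seeding.** Unassigned genes are z-scored and clustered
(k = clip(n/100, 2, 20) unless set; 20 seeded restarts); a cluster of the
best-inertia run becomes a seed module when its mean best-match Jaccard
against the other restarts reaches 0.6.  On i.i.d. noise almost no cluster
passes, so passenger genes stay unassigned.

**Module Network.** Iteratively alternates (a) program refits per module —
searching kept candidates x admissible splits, accepting strict
improvements only — and (b) gene moves to the container (module or
unassigned background, scored as a single leaf) with the best contribution.
Membership in a programmed module carries a per-gene *assignment charge*
equal to the structure penalty: adopting a module's split structure is the
same model event as joining a module in the Single-Modulator step, and
charging it symmetrically keeps passenger genes from drifting into modules
(without it the move step dilutes module precision several-fold on the
synthetic cohorts).  Strict-improvement acceptance everywhere makes the
emitted total-score trace monotone non-decreasing and guarantees
termination; undersized modules dissolve mid-run only when that does not
lower the score, and a final cleanup removes undersized, program-less and
non-positive-gain modules.  Second-level splits are added greedily per
branch when their improvement clears one more penalty unit.

**Bootstrap stability selection.** Both learning stages run under
non-parametric bootstrap (default 100 draws; keep thresholds 0.90 after
Single Modulator, 0.40 after Module Network).  Each draw is scored on its
distinct-sample support: with-replacement duplicates carry no independent
evidence under a conjugate marginal likelihood and demonstrably inflate
split gains (on null data they hand every candidate a spurious module), so
the selector uses the unique samples of each draw — a subsampling-flavored
stability selection.  A candidate is "selected" in a draw when it regulates
at least one surviving module; network-stage draws run depth-1 programs
with a small iteration cap (4), since they only assess root-driver
stability, and full-depth refinement happens on the final full-data run.

**Ranking.** A driver's CONEXIC score sums the score *gains* (program score
minus unsplit score) of the modules whose program it roots, so the quantity
is non-negative and comparable across drivers; drivers are ranked by
descending score with gene-id tie-break.  The driver table carries gene,
direction, cytoband, score, bootstrap frequency and module ids.

## Module activity and stratification

The per-sample activity of a gene set ranks all G genes within the sample
(average ranks for ties) and standardizes the mean member rank against the
random-set null: `z = (mean rank - (G+1)/2) / sqrt((G+1)(G-m)/(12m))`.
This makes random sets score ~N(0,1) with no reference-cohort fitting and
is invariant under monotone transforms of a sample's values.  Note a
mean-rank score is blind to sign-balanced sets by construction; signatures
should be supplied as up- and down-regulated halves.  Group comparisons use
the Wilcoxon rank-sum test (tie-corrected normal approximation with
continuity correction) with BH adjustment across sets.

Tumors are stratified at a driver's *split value* — the root threshold of
its top-scoring module; expression strictly above the split goes high, the
boundary goes low.  Samples unseen in training are assigned by the same
rule, so the split transfers to new cohort members.  Survival uses the
Kaplan-Meier product-limit estimator and the 1-df log-rank test on DMFS
(distant metastasis-free survival, months); Fisher's exact test
(probability-ordering two-sided) associates groups with categorical labels,
and module/driver correlation is validated by a rank-sum comparison of
|Pearson r| in-module vs background.

## Synthetic cohorts

The generator (`conexic.simulate`) emulates a small two-platform breast
tumor cohort: background copy number N(0, 0.05^2) with contiguous planted
regions shifted by +/-0.8 in 35% of samples; driver expression = 0.7 x own
copy number + N(0,1); per driver a 40-gene module whose genes shift by
+/-1.5 noise-SD (half up, half down) in samples where the driver exceeds
its true split (the median of driver expression, giving balanced groups);
passengers are independent noise; survival is exponential with hazard ratio
3.0 between high/low groups of the first driver and ~30% uniform censoring
(baseline hazard 0.01/month, median ~70 months).  The documented fixture is
60 samples x 2,000 genes, 3 gain + 2 loss regions of width 15, seed 17; a
single shared RNG stream per dataset makes fixtures bit-reproducible.

What the generator does **not** emulate: probe-level noise, batch effects,
intrinsic-subtype structure, correlated passenger blocks, dosage response
in non-driver region genes, or copy-number-independent regulation.  Passing
recovery tests therefore show the machinery is correct and calibrated on
its stated model, not that real cohorts will yield equally clean driver
lists.

## Numerical choices and edge cases

* Missing values: only the literal `NA`; scoring requires complete data
  (drop or impute upstream); G-scores treat NA as zero contribution.
* SD filter uses the n-1 denominator, NA-omitting; genes with fewer than
  two observed values are removed and logged.
* All ties documented: boundary sample at a split goes low; zero
  correlation counts positive in sign splitting; equal CONEXIC scores order
  by gene id; equal move contributions keep the current assignment
  (oscillation guard).
* Degenerate inputs: empty leaves are impossible by construction
  (`min_leaf_size`); a modulator with all-tied values offers no admissible
  split and returns a sentinel; zero-margin Fisher tables give p = 1 with a
  warning; zero-event survival comparisons give p = NA with a warning.
* Convergence: relative total-score improvement below 1e-6 stops the
  network iteration (cap 50 iterations).
* Determinism: one global seed fans out to per-stage seeds by hashing the
  stage name; identical config + seed reproduces outputs byte-for-byte.

## Problem sizes used in validation

The automated checks run the full pipeline on the 60 x 2,000 fixture with
bootstrap_runs = 25 over 10 dataset seeds (driver precision/recall and
module F1), 10 null cohorts (effect size 0), 20 smaller cohorts
(40 x 400) for monotonicity, 100 instances each for split-search exactness
and split-value recovery, all 2x2 tables with margins <= 12 for the Fisher
oracle, and 100 survival simulations at hazard ratio 3 for log-rank power.
These sizes were chosen so the whole validation runs comfortably on one
CPU while leaving each check statistically meaningful.

## Known limitations

* The structure penalty and assignment charge are multiplicity heuristics,
  not a generative structure prior; absolute CONEXIC scores are therefore
  tool-internal and only ranks should be compared across runs.
* The aberration caller is a reconstruction of the G-score/peel-off family,
  not a numerical replica of any released implementation; arm-level vs
  focal classification is out of scope.
* Depth is capped at 2 and leaves are Normal; no heavy-tailed or
  regression leaves.
* With ~40 distinct samples per bootstrap draw, stability selection on
  cohorts much smaller than ~30 samples becomes unreliable (too few
  admissible splits); the caller logs and redraws degenerate replicates.
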
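# Methods

This note records the models behind each stage of the pipeline, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data can and cannot establish about real GBS experiments.

## Synthetic F2 populations (`simpop`)

**Meiosis.** Crossovers per gamete per chromosome are Poisson with mean
equal to the genetic length in Morgans; positions are uniform on the
physical span and parental origin alternates at each crossover.  This is the
Haldane (no-interference) process.  The map-construction stage reports
Kosambi distances, which assume interference; the mismatch is deliberate —
the generator is kept as simple as possible and the map stage is tested for
internal consistency and approximate length recovery, not for agreement with
the generator's metric (see "Known limitations").

**Genome.** `GenomeSpec.maize(scale)` gives ten chromosomes with physical
lengths close to the maize reference assembly and genetic lengths matching a
published F2 maize map, both multiplied by `scale`.  The test suite and the
acceptance script use `scale=0.1` (about 206 Mb, 224 cM): this preserves the
cM/bp rate, and the default SNP density of 15 SNPs/Mb preserves the filtered
SNP density of the emulated study (~29.9k SNPs over ~2,060 Mb), while keeping
one replicate of the full pipeline near one second of CPU.  SNP positions
are drawn uniformly per run from the seeded generator.

**Observation noise.** Three sequential perturbations of the true calls:
heterozygote undercall (true AB observed as AA or BB with equal odds — the
dominant artefact of sampling roughly one allele at far-below-1x depth, and
symmetric for that reason), random error (call replaced by one of the two
wrong categories), missing masking.  Defaults: undercall 0.30, error 0.01,
missing 0.10.  These are plausibility choices for low-pass GBS, not
estimates from any particular dataset; tests vary them where the behaviour
under other regimes matters.  Rates are per-call and independent —
no depth model, no site- or individual-level covariance.

**Phenotypes.** `y = mu + sum_k (a_k x_k + d_k z_k) + e` with x in
{+1, 0, -1} for {P1-homozygote, het, P2-homozygote} and z = 1 for hets.  One
QTL at exact F2 frequencies contributes variance `a^2/2 + d^2/4`; the
residual variance is set so the summed (linkage-equilibrium) genetic
variance is the requested h^2 of the total.  `effects_for_r2` inverts this
to produce effects with a target variance share.  Traits are independent
columns; trait-trait correlation arises only through shared QTLs.
Requesting h^2 = 0 alongside nonzero effects raises, as contradictory.

## Marker filtering (`markers`)

Filters run in a fixed order — segregation pattern, abnormal token, missing
fraction, distortion — so each removed SNP carries exactly one primary
reason code; the order does not change the retained set.  Heterozygous calls
count once toward the AB cell; missing calls are excluded from the
chi-square total (df = 2 throughout).  "Abnormal" means any call token
outside {AA, AB, BB, NA}.  Exactly 25% missing is retained (removal requires
strictly more).  The distortion test uses `scipy.stats.chi2`; tests verify
it against the df-2 closed form exp(-chi2/2).

A consequence worth knowing: at the default 30% heterozygote undercall the
*observed* genotype distribution is genuinely distorted (AB frequency drops
from 0.50 to 0.35), so at n = 199 the p < 0.001 filter removes most SNPs,
and — because linked SNPs share one genotype realization — whole chromosomes
can hover near the threshold and pass or fail nearly together.  That is the
filter behaving as published under a harsh noise setting, not a defect; the
downstream scans remain well-powered on the surviving markers, and the
window-robustness checks feed the caller the pre-filter matrix because they
test the caller.

## Bin construction (`binmap`)

Per-SNP consensus calls come from the 15-SNP window centred on the SNP
(centre offset ceil(15/2); chromosome ends reuse the nearest complete
window; chromosomes shorter than one window use a single truncated window).
The homozygosity rule is proportional: parent score >= (11/15) x
(non-missing total), with AB contributing 0.5 to each parent (a flag
switches to call-counting for sensitivity analysis).  The >= comparison
reproduces the "11 or more of 15" supermajority exactly on full windows.
All-missing windows defer their call and inherit it from the neighbouring
blocks (forward then backward fill).

Breakpoints are midpoints between the last SNP of one block and the first of
the next.  The 100-kb grid is anchored at coordinate 0 with half-open
intervals; a 1-based position p maps to interval (p-1) div 100000.  A
breakpoint-bearing ("hot") interval is assigned to the *downstream* bin — a
documented convention, not an inference about any particular study.  Bins
are trimmed to their first/last constituent SNP, which is why bins shorter
than 100 kb can occur.  Per-individual bin genotypes are the majority
consensus call over the bin's SNPs (ties to the last SNP): disagreement is
only possible inside the single hot interval that opens a bin, so the
majority is the block covering the bin body.

## Genetic map (`linkmap`)

Adjacent-bin recombination fractions maximize the F2 two-locus multinomial
likelihood (9-cell table; the double-het cell is the coupling/repulsion
mixture).  The default maximizer is bounded Brent on [0, 0.5] with xatol
1e-10; a classical recombinant-counting EM (tolerance 1e-8, max 200
iterations, likelihood provably non-decreasing) is available and tested to
agree.  An all-concordant table short-circuits to r = 0 exactly.  Pairs with
fewer than two informative individuals are undefined and raise; pairs with
r >= 0.49 are flagged as gaps but kept — chromosome assignment is physical,
so linkage groups are never re-estimated, and r is capped at 0.4999 before
the Kosambi transform.  Map positions are cumulative Kosambi distances in
physical order, hence monotone by construction.

The estimated total map length runs ~8% below the generator's genetic length
even without noise: Kosambi compresses distances generated by a Haldane
process, tight double crossovers are smoothed away by the window, and
crossovers outside the SNP-covered span are invisible.  Recovery is
therefore asserted at the 15% level on replicate means, not as an unbiased
estimate.

## QTL scans (`qtlscan`)

**Flanking probabilities.** QTL genotype priors given the flanking bins come
from the no-interference F2 transition model, computed by convolving two
independent gamete Markov chains; missing flanks are marginalized and two
missing flanks give the (1/4, 1/2, 1/4) prior.

**CIM.** The scan walks a 1-cM grid.  At each position the three-component
mixture is fit by EM: posterior-weighted least squares on the stacked
design, ML variance, tolerance 1e-8, at most 100 iterations, observed-data
log-likelihood monotone (asserted in tests); initialization is the
Haley-Knott regression on expected genotype codes.  LOD compares against the
cofactor-only OLS fit; at a fully observed bin with no cofactors this
collapses to the single-marker ANOVA LOD (numerical identity tested at
1e-8).  The chi-square df=2 p-value of the LRT is reported for plotting
only — the mixture's non-regularity makes it approximate — and declaration
uses the permutation threshold.  Cofactors: forward-backward stepwise on
2-df (additive+dominance) bin terms, entry/stay at alpha = 0.05 on the
partial F, capped at 5; under a pure-noise trait this rule (deliberately
per-term, as in common CIM software) still admits cofactors, since the
minimum p over hundreds of markers is almost surely below 0.05.
`max_cofactors=0` reduces the scan to plain interval mapping.

**Permutations.** Trait values are shuffled with genotypes fixed and the
cofactor set frozen (re-selection per permutation would multiply cost by the
marker count for little calibration benefit).  Permutation LODs use the
vectorized Haley-Knott approximation — the standard fast path for
permutation thresholds — which matches the EM LOD closely on near-complete
bins; the threshold is the empirical (1-alpha) quantile of genome-wide
maxima.  Calibration is verified: genome-wide type-I error within
[0.02, 0.09] at alpha = 0.05 over 200 null replicates.

**LASSO.** One joint fit of the 2M-column standardized design; penalty
chosen at minimum cross-validated error (10 seeded folds, 30-point path down
to 0.05 of lambda_max — CV minima in this regime sit well above the path
floor, and short paths keep coordinate descent off its slow, heavily
correlated tail).  The kept solution is re-solved at tolerance 1e-9 so the
KKT/soft-threshold conditions hold to ~1e-6 (tested).  Inference: selected
columns are re-fitted by OLS with Wald tests; because adjacent bins are
near-duplicate predictors and the LASSO often spreads one QTL over several,
selected columns of the same track with genotype correlation >= 0.8 are
grouped and only the strongest member is refitted — refitting near-copies
together dilutes every individual test to meaninglessness.  Absorbed and
unselected columns get p = 1.  Declaration at -log10(p) >= 1.3, i.e. nominal
0.05: a multiple-regression model with strong shrinkage needs no genome-wide
adjustment.  `prune_r > 1` restores the ungrouped refit.

**QTL calling.** CIM peaks are maxima of contiguous above-threshold runs,
merged within 20 cM (higher LOD wins); the support interval is the 1.5-LOD
descent on each side, reported via flanking bins and their physical span —
both the merge radius and the drop rule are conventional defaults, exposed
as parameters.  Additive effects are signed so that positive means the P1
allele increases the trait; R^2 is the percent reduction in residual
variance from adding the QTL term to the cofactor model, relative to total
phenotypic variance.  LASSO hits are individual markers with their own bin
as the interval.

## Reporting (`report`)

Descriptives use the sample standard deviation and the publication column
order (parents, min, max, mean, sd).  Correlations are pairwise-complete
Pearson with unadjusted two-sided t-tests at alpha = 0.05 (published
correlation tables report unadjusted flags).  Gene lookup treats both the
QTL interval and gene spans as closed intervals — an abutting gene counts as
overlapping — strand-agnostic, with an optional biotype filter.

## Problem sizes in the test suite

The suite runs the full recovery protocol (50 replicates, 10 scaled
chromosomes, n = 199, three QTL at 8/12/18% variance, 200 permutations per
replicate), 50-replicate window-robustness and 200-replicate calibration
studies, and ~150 unit/property tests, in under two minutes of CPU total;
the acceptance script repeats the headline measurements at 20 replicates.

## Known limitations

- The generator has no crossover interference, no depth-aware likelihoods,
  no read-level artefacts (barcodes, restriction sites), and no
  site-specific error covariance; passing tests show the pipeline recovers
  structure under this idealized noise, not that it is robust to every
  artefact of real GBS libraries.
- Map lengths are conservatively biased (see `linkmap` above).
- Post-selection LASSO p-values are conditional on selection and liberal in
  the classical sense; they mirror the field's practice, not a formal
  selective-inference procedure.
- The CIM support interval (1.5-LOD drop) and peak-merge radius (20 cM) are
  conventions; physical interval widths depend on them.
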
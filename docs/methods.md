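# Methods

`tipclock` reproduces, as a tested pipeline, a simulation study of how
well fast phylogenetic methods recover the substitution rate from
time-structured ("tip-dated") sequence data of the kind produced by
ancient-DNA studies of vertebrate mitogenomes. This note documents the
models, the defaults and why they were chosen, the numerical choices, and
what the synthetic data do and do not capture.

## Simulation model

**Genealogies.** Trees are drawn from a constant-size serial
(heterochronous) coalescent: going backward in time, lineages enter at
their sampling ages; while k lineages are active the next coalescence
waits an Exponential time with rate k(k−1)/(2N), truncated at the next
tip-entry epoch, and the merging pair is uniform. N (`effective_size`) is
a haploid time scale in years.

The default study conditions are 100 tips, half sampled at the present
and half at ages uniform on (0, 50,000] years, with the root age fixed at
500,000 years and sequences of 15,000 nt — sizes typical of ancient
mitogenome data sets. Two levels of *phylo-temporal clustering* are
imposed: `high` forces all present-day tips into a single clade, `low`
forces the lexicographically first half of them. The constrained subset
is coalesced to its MRCA first and that MRCA then enters the serial
coalescent of the remaining lineages as one lineage; no anti-monophyly
constraint is placed on the unconstrained modern tips.

**Root conditioning.** The root age is fixed by rescaling all internal
node ages (measured from the present) by f = target/current, leaving tip
ages untouched; if rescaling would make an internal node younger than a
descendant tip (possible when f < 1) the genealogy is rejected and
redrawn. The default N = 250,000 puts the unconditioned expected root age
near the 500,000-year target, so f is typically close to 1 and rejections
are rare. An exact mechanism for this conditioning is not uniquely
determined by the study design; rescale-plus-rejection was chosen because
it preserves tip ages exactly, is cheap, and changes the coalescent shape
only by a time dilation.

**Branch rates (white-noise clock).** Each branch receives an independent
rate r_i with mean μ and variance v·μ/(d_i·L), where d_i is the branch
duration in years and L the sequence length. This calibration makes the
variance of the expected substitution count n_i = r_i·d_i·L equal to
v·E[n_i], i.e. "variance equal to a fraction v of the expected number of
substitutions", with the inverse-duration scaling that defines a
white-noise clock. The grid uses v ∈ {0.001, 0.01, 0.1} and
μ ∈ {10⁻⁷, 10⁻⁸} subs/site/year. Rates are Gamma-distributed (two
parameters match the mean and variance exactly, support is positive); a
lognormal is deliberately not offered to keep the moment matching exact.
An alternative constant-CV reading, Var(r_i) = v·μ², is available via
`mode="rate_cv"`; the per-duration reading is the default because it is
the one consistent with tying the variance to the expected substitution
count. The calibration uses the configured L; rates are not redrawn if
sequences of another length are simulated afterwards.

**Sequences.** HKY85 with discrete-gamma rate variation. The generator is
normalized so branch lengths are expected substitutions per site. The
study conditions do not pin down κ, π, or α, so the defaults are
mitogenome-like and configurable: κ = 10,
π = (0.31, 0.31, 0.13, 0.25) (A, C, G, T), α = 0.5 with 4
equal-probability categories represented by their conditional means
(normalized to mean 1). Site categories are i.i.d. per site and fixed
across the tree. No indels, partitions, or post-mortem damage are
simulated.

## Estimators

**Phylogram inference (tree stand-in).** The study's two-stage design —
infer a phylogram from the alignment, then estimate the rate from the
phylogram plus tip dates — is preserved, but full maximum-likelihood tree
search is out of scope. The stand-in is neighbor joining on closed-form
TN93 distances computed with the model's stationary frequencies and the
standard gamma-rates correction (−ln w → α(w^(−1/α) − 1)); negative NJ
branch lengths are clamped to zero and saturated distances capped at 5
subs/site. Externally inferred phylograms can be supplied as Newick, which
reproduces the original two-stage design exactly.

**Root-to-tip regression.** Ordinary least squares of root-to-tip
distance on forward time (−age); the slope is the rate, the x-intercept
gives the TMRCA. The root is placed by exact minimization of the
regression residual sum of squares: on each edge the RTT distances are
affine in the root position, so the RSS is a quadratic whose constrained
minimum is found in closed form; the global optimum over edges is taken,
with ties broken by preorder edge index. RSS minimization is fixed as the
rooting objective (other conventions minimize residual mean squares or
maximize R²; all are monotone transforms of RSS for a fixed tip set).
A negative slope is reported as-is with a warning — absence of temporal
signal is a result, not an error.

**Least-squares dating.** Minimizes Σ w_i (b_i − r·(τ_c − τ_p))² over the
rate r > 0 and internal forward times τ, with tips fixed at τ = −age and
τ_c ≥ τ_p on every edge; w_i = 1/(b_i + c/s) with s the site count and
c = 10 by default (the variance model of the published least-squares
dating method). With the substitution u = r·τ the problem is a strictly
convex quadratic program in (u, r): the unconstrained optimum is the
weighted linear least-squares solution and is used when feasible;
otherwise the Lagrangian dual — a smooth bound-constrained quadratic — is
solved by L-BFGS-B (ftol 1e-18, gtol 1e-14) and the primal recovered from
stationarity. Solver round-off in recovered node ages is absorbed by a
final exact precedence clamp (parent age ← max of children). Rate
positivity is enforced by projection to 1e-15; dates are handled
internally as forward times and reported as years BP.

**Bootstrap intervals.** Non-Bayesian analogues of credibility intervals:
alignment columns are resampled with replacement, the full pipeline
(distances → NJ → RTT-optimal root → estimator) is re-run per replicate,
and a percentile interval is taken. Replicate failures are tolerated up
to 50%.

## Diagnostics

**Phylo-temporal clustering.** ρ is the Pearson correlation, over all tip
pairs, between path length in edges and absolute age difference. "Number
of nodes separating" two tips is implemented as the edge count of the
path (the internal-node count differs by one per pair, a constant shift
that leaves the permutation test unchanged). The null permutes ages
across tips (preserving the age multiset) 1,000 times by default;
P = (1 + #{|ρ*| ≥ |ρ|})/(1 + n_perm), the add-one correction avoiding
zero P. The test is two-sided by default with a one-sided `greater` mode.
Raw pairs are used despite their non-independence; the permutation null
absorbs the dependence.

**Date-randomization test.** The estimate (with bootstrap interval) from
the true dates is compared against estimates from 20 (default) uniform
permutations of the ages. CR1 passes when the original point estimate
lies outside *all* replicate intervals (a lenient "outside ≥ 95%" mode is
available); CR2 when the original interval is disjoint from all replicate
intervals. The original interval is widened, if necessary, to contain its
own point estimate so that CR2 implies CR1 structurally.

**Stemminess.** Internal-branch length divided by total tree length; high
stemminess means short terminal branches and hence less information per
tip for calibration.

## Evaluation statistics

Standardized error is (estimate − truth)/truth. Per scenario the pipeline
reports the median and IQR of errors ("spread" is operationalized as
IQR), a two-sided one-sample Wilcoxon test against zero, the proportion
of estimates above the truth, and interval width divided by the truth.
Across scenarios it reports Kruskal-Wallis (d.f. = groups − 1, tie
corrected) on the raw per-replicate errors and pairwise Mann-Whitney
tests, Holm-corrected by default (raw P optional; both are emitted since
the original tables are uncorrected). Cross-method congruence uses the
per-pair proportional difference (y − x)/x and the bias, the fraction of
pairs with x > y. Replicates whose estimator fails contribute missing
records, never sentinel values.

## Problem sizes

Defaults in the library are the full study conditions (100 replicates per
scenario, 15,000 nt). The bundled analyses, tests, and the acceptance
script use reduced sizes chosen as the package's own trade-off between
statistical resolution and turnaround: the cross-scenario rank tests run
the 12 scenarios at 5 replicates × 2,000 nt; the parameter-recovery check
runs 20 replicates of the favorable scenario (μ = 10⁻⁷, v = 0.001, low
clustering) at the full 15,000 nt; the directional-bias check runs 20
replicates × 3 variance levels at μ = 10⁻⁸ with high clustering. At these
sizes the qualitative findings (accurate recovery in favorable
conditions; systematic LSD underestimation at low rate with high
clustering) are stable across seeds, but per-scenario medians carry
Monte-Carlo noise of a few percent.

## What the synthetic data do not capture

Constant population size only (no growth, bottlenecks, or skyline
dynamics); no sequencing error or ancient-DNA damage; no model
misspecification between simulation and inference beyond the NJ/TN93
stand-in for ML tree search; dates known without error. Passing tests
therefore show correctness of the algorithms and reproduction of the
simulation study's qualitative behaviour, not robustness of the
estimators on real ancient-DNA data. Bayesian inference — the third
method of the original comparison — is out of scope, as are the six
empirical mitogenome data sets; externally produced trees and alignments
in standard formats can be ingested for such analyses.
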
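# Methods

`hatchtrace` quantifies introgression of hatchery-derived genotypes into
wild populations from co-dominant microsatellite panels.  This note
documents the models, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Study design being implemented

The workflow assumes a set of wild populations and a set of hatchery
strains genotyped at the same diploid loci (twelve in the emulated
system).  Rather than assigning fish among dozens of putative source
populations — which biases assignment toward large, diverse samples — each
fish is assigned between exactly two *population centroids*: simulated
reference populations carrying the average allele frequencies of the wild
group and of the hatchery group.  A fish's posterior mean ancestry in the
wild cluster, written p(wild), is the quantity of interest; thresholds on
p(wild) calibrated from simulated first-generation (F1) wild x hatchery
crosses split fish into wild, introgressed and hatchery classes.

## Genotype statistics (`genotypes`, `popgen`)

* **Allele frequencies** are gene-copy proportions over non-missing calls;
  missing data are excluded locus-wise everywhere.  Individuals missing
  more than half their loci are worth flagging (`missing_fraction`), but
  are retained.
* **Diversity**: N_A is the mean observed allele count per locus; H_E is
  Nei's unbiased expected heterozygosity `(2n/(2n-1)) (1 - sum p^2)` with
  `2n` the gene-copy count, averaged over loci.
* **Hardy-Weinberg**: chi-square goodness of fit of genotype-class counts
  against `n p_i^2` / `2 n p_i p_j`, `df = G - A` with `G = A(A+1)/2`
  genotype classes; no pooling of rare classes.  Family-wise control is a
  plain Bonferroni `alpha / n_tests`.  An exact test is out of scope.
* **FST**: Weir & Cockerham's theta with per-locus variance components
  combined ratio-of-sums; slightly negative estimates for undifferentiated
  pairs are reported as-is in tables.  A Nei-style GST
  (`(HT - HS) / HT`, unweighted two-sample means) is available because the
  original analysis's software dialect is not pinned down.  Significance,
  when requested, is a one-sided permutation test shuffling individuals
  between the pair.
* **PCoA**: classical metric scaling (double-centering of `-D^2/2`,
  symmetric eigendecomposition).  Negative input distances are truncated
  to zero only when building the embedding; axes are reported for positive
  eigenvalues and percent variance is normalised by the positive
  eigenvalues only.
* **PID**: per locus `2 (sum p_i^2)^2 - sum p_i^4`, multiplied across
  loci — the probability two unrelated individuals share a multilocus
  genotype, used to justify removing duplicate genotypes as repeat
  captures.  Duplicate detection compares unordered calls at mutually
  typed loci with a configurable minimum overlap.

## Centroid simulation (`mating`)

Centroids are built by subsampling a fixed number of fish per population
without replacement (defaults: 22 per wild population, 50 per hatchery
strain; undersized populations must be excluded explicitly), pooling the
subsamples within each group, and simulating 500 individuals per group by
drawing, at each locus independently, two alleles from the pooled
frequencies.  Offspring are simulated from frequencies, not by pairing
individual parents, and loci are unlinked — the behaviour of
frequency-conditioned hybrid simulators used with microsatellite panels.
Simulated individuals are fully typed.  `centroid_precision` repeats the
construction with fresh subsamples and summarises FST among replicate
centroids (within-group values should be well below 0.001 at these sizes).

## Per-individual ancestry (`admixture`)

Each sampled fish is analysed in its own run: a panel of the 500 + 500
centroid individuals plus that single fish, under a two-cluster admixture
model with no prior population information.  The Gibbs sampler alternates

1. per-gene-copy origin indicators `z ~ Cat(q_i,k * P_k,l,a)`,
2. cluster allele frequencies `P_k,l ~ Dirichlet(lambda + counts)`
   (independent-frequency model, `lambda = 1`),
3. per-individual ancestry `q_i ~ Dirichlet(alpha + n_i)`,
4. the symmetric ancestry concentration `alpha`, by Gaussian random-walk
   Metropolis under a uniform prior on `(0, 10]`.

After sampling, the cluster with the higher posterior-mean ancestry among
the wild-centroid individuals is labelled wild; p(wild) is the query's
posterior-mean ancestry there, with a 2.5–97.5% interval from the thinned
chain.  Swapping the two centroid arguments maps p(wild) to 1 − p(wild).

Two chain profiles are built in: the replication profile
(50,000 burn-in / 100,000 kept sweeps, matching the emulated study) and a
desk profile (2,000 / 5,000) used throughout the tests and the validation
studies.  Numerical choices that matter:

* **Alpha dynamics.** With a thousand pure reference individuals the
  posterior for `alpha` concentrates near very small values, making the
  ancestry prior strongly bimodal.  The proposal step is deliberately
  small (0.025, the reference program's default) and not adapted;
  step-size adaptation is available but off, because faster alpha mixing
  pushes the sampler into the bimodal regime within a few hundred sweeps.
  Low Metropolis acceptance for alpha is expected and only triggers a
  diagnostic warning outside (0.05, 0.95).
* **Mode-swap move.** Once `alpha` is small, a weakly informative query's
  ancestry posterior has modes near q = 0 and q = 1, and plain Gibbs
  crosses between them too rarely for short chains to average correctly
  (posterior means snap to whichever corner the chain entered).  Each
  sweep therefore also proposes, per individual, jointly flipping all of
  its origin indicators and mirroring its ancestry vector.  The ancestry
  prior and the `P(z|q)` terms cancel, so the move accepts with the
  allele-emission likelihood ratio; it leaves the target distribution
  unchanged and makes desk-profile posterior means agree with long-chain
  ones.
* **Seeding.** `batch_assign` derives one chain seed per individual from
  the master seed, so results are independent of batch partitioning.
  Missing calls contribute nothing to the likelihood (no imputation); a
  fully missing query returns the prior mean, p(wild) near 0.5.
* The sweep kernel is numba-compiled and uses an inlined xorshift64*
  uniform stream for the per-copy draws; chains are random-number bound.

## Threshold calibration and classification (`thresholds`)

The F1 null is built once per dataset: `n_f1` simulated crosses between
the pooled wild and pooled hatchery frequencies (500 in the replication
profile, 100 at desk scale), each pushed through the same single-fish
assignment.  Cutoffs are the 2.5 and 97.5 empirical percentiles
(linear interpolation between order statistics; the rule is stored with
the calibration).  Classification: hatchery below `t_lo`, wild above
`t_hi`, introgressed inside — boundary values count as introgressed,
conservative toward detecting introgression.  The calibration object
stores its F1 sample so cutoffs can be re-derived at other ranks (e.g.
5/95) without re-running chains, which is how the known-truth studies
compare rank pairs.  Widening the rank interval can only grow the set
classified introgressed.

## Hybrid-category model (`hybrids`)

The six-class model assigns each query a pedigree class (pure wild, pure
hatchery, F1, F2, backcross x wild, backcross x hatchery) through the
fixed per-class probabilities that a locus's two gene copies descend from
(wild,wild), (wild,hatchery) or (hatchery,hatchery).  Gibbs sampling
alternates class membership, per-locus origin pairs, cluster frequencies
`theta` and mixing proportions `pi`, the latter two under Jeffreys
`Dirichlet(1/2)` priors.  Reference individuals enter as data of known
pure class: they contribute fixed counts to `theta` and are excluded from
the mixture (an unsupervised mode frees them and anchors cluster labels to
the wild references per chain).  Four chains (two in the desk profile) are
pooled after anchoring; individuals whose per-category probabilities
differ across chains by more than 0.2 are flagged.  Reporting aggregates
F2 and both backcrosses into a post-F1 category; a category call requires
0.80 posterior probability, ties and sub-threshold maxima are
inconclusive.

## Environmental models (`envmodel`)

The probability that a wild-caught, non-hatchery-assigned fish is
introgressed is modelled by logistic regression with a site random
intercept.  The marginal likelihood integrates the intercept out by
adaptive Gauss-Hermite quadrature (9 nodes by default; each site's
integrand is recentred on its conditional mode and rescaled by the local
curvature, so unbalanced sites are handled accurately).  Optimization is
BFGS on (coefficients, log sigma); standard errors come from the
finite-difference observed information; complete separation triggers a
weak-ridge refit that is flagged as penalized.  Four candidate covariate
sets are standard (multiscale, site-level, watershed-level,
literature-supported; land use excluded by default as near-constant
across forested sites); covariates are z-scored with the sample (n−1) SD
and pairs with |Pearson r| > 0.7 may not enter the same model (the
first-listed member of a flagged pair is kept).  Model comparison uses
AICc with n = number of fish; Akaike weights are computed over all
candidates; the consensus model averages the top two (configurable by
count or ΔAICc cutoff) with zero substituted for absent covariates (full
averaging) and unconditional standard errors
`sum_i w_i sqrt(se_i^2 + (b_i − b̄)^2)`.  The reported marginal R² is the
latent-scale variance-partition definition,
`var(Xb) / (var(Xb) + sigma² + pi²/3)`.

## Synthetic data (`simulate`)

The generator emulates the statistical structure of the studied system
with known truth labels:

* 30 wild populations and 5 hatchery strains, 50 fish each, 12 loci.
* Ancestral spectra: 12 alleles, Dirichlet(0.5), alleles rarer than 0.015
  dropped and renormalised (keeping nested drift attainable).
* Balding-Nichols divergence: group branches F = 0.02 (wild) and 0.10
  (hatchery) from the ancestral pool; wild populations F = 0.075 within
  their group; hatchery strains take the heterogeneous profile
  (0.04, 0.04, 0.26, 0.26, 0.26) — two diverse strains and three strongly
  drifted ones, mirroring the emulated hatchery system.  The divergence
  that separates hatchery fish from wild fish rides mostly on the shared
  hatchery branch, so even the diverse strains remain clearly
  attributable to the hatchery group (placing it on low strain drift
  instead makes diverse-strain fish near-exchangeable with wild fish).
* Broodstock exchange: every hatchery frequency vector is blended with
  15% of its parent pool (strains with the hatchery group, the group with
  the ancestral spectrum).  This emulates the documented movement of fish
  among hatcheries and matters a great deal: pure drift at the divergence
  above permanently loses rare ancestral alleles from the hatchery side,
  and a hatchery panel missing alleles makes wild-inherited rare alleles
  overwhelmingly informative, visibly skewing the simulated-F1 p(wild)
  null toward the wild side.  The blend keeps hatchery panels
  allele-complete (rare alleles at low frequency) while still
  frequency-drifted.  Realized values across seeds: wild ~6.6
  alleles/locus and H_E ~0.70, hatchery ~5.6 and ~0.60, pooled
  wild-vs-hatchery theta ~0.07 (seed-to-seed spread roughly 0.05–0.09
  with 12 loci).  The strain-profile choice matters beyond summary
  statistics: a homogeneous, strongly bottlenecked hatchery group loses
  too many alleles, which makes wild-derived alleles far more informative
  than hatchery-derived ones and visibly skews F1 p(wild) toward the wild
  side.
* Pedigree classes are built by gamete sampling: each gene copy comes from
  the wild or hatchery pool with the class's per-copy probability
  (F1: (1,0); F2: (1/2,1/2); backcrosses: (1,1/2) / (0,1/2)).  Planted
  non-wild fish in a wild population cross that population with one
  randomly chosen *stocked* strain — by default the above-average-drift
  production strains, since in the emulated system the diverse strains
  exist in the reference panel only (they cover undocumented private
  stocking) and are not released where the wild populations are sampled.
* Site covariates are z-scored standard normals; introgression flags are
  drawn from a logistic model with configurable effects (+0.5 temperature,
  −0.5 pH by default), intercept −2.9 (about 5% prevalence) and site
  random-intercept SD 0.5; flagged fish become F1s.  Alternatively,
  explicit per-population class fractions can be planted.

What the generator does **not** emulate: microsatellite mutation
(stepwise or otherwise), linkage, genotyping error and allelic dropout,
family structure within sites, unequal sample sizes, and real covariate
correlation structure.  Passing tests on this generator therefore show
the pipeline recovers truth under its own model assumptions at realistic
divergence and diversity — not robustness to those unmodelled features.

## Known-truth validation (`evaluation`)

`run_truth_study` generates a scenario with planted F1 and hatchery fish
(two per wild population by default), builds centroids and the F1 null
from the full dataset (planted fish included, mirroring field practice
where the wild pool may carry undetected non-wild genotypes), assigns 50
known-truth queries per class at the desk chain profile, and reports
misclassification rates per percentile-rank pair: missed introgressed
(truly F1 not classified introgressed), false introgressed (pure fish
classified introgressed), overall error.  `glmm_recovery_study` refits
the mixed model on replicate simulated datasets (30 sites x 50 fish) and
reports sign recovery and CI coverage.  The acceptance script
(`scripts/acceptance.py`) runs exactly these two studies and writes the
measured quantities as JSON.

Desk-scale expectations worth stating plainly: with thresholds taken as
the central-95% band of a finite F1 null, a new F1 from the same process
falls outside the band about 5% of the time by construction, so the
missed-introgressed rate over 50 planted F1s has expectation near 5% even
for a perfectly calibrated classifier; per-run values of 0 occur but are
not guaranteed.  Short chains also retain some extra tail mass in the F1
null relative to full-length chains.  Both effects are visible in the
reported rates.

## Known limitations

* Only the two-cluster (wild vs hatchery) model is implemented; K > 2 and
  the correlated-frequencies model are out of scope.
* The HWE test is asymptotic chi-square; with many rare alleles its null
  distribution is approximate.
* The GLMM supports one random intercept (site); crossed or nested random
  effects are out of scope.
* Replication-profile chain lengths are hours of CPU per dataset; all
  shipped studies use the desk profile and state so.
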
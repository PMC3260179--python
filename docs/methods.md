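# Methods

`aimpanel` implements the complete statistical analysis cycle of a compact
panel of ancestry-informative INDEL markers (AIM-INDELs): descriptive
marker statistics, model-based admixture inference, likelihood-based
population assignment, PCA, and a simulator that generates cohorts under
the same generative model the inference assumes.  This note records the
models, the parameters that matter, the numerical choices, and the limits
of what the test suite demonstrates.

## Data model

Genotypes are diploid calls at autosomal biallelic (occasionally
triallelic) INDEL loci, coded `1` (short allele), `2` (long allele) and
`3` for rare additional length variants; `-9` marks missing data.  Files
use the STRUCTURE text layout (header of marker names; one line per
individual with two columns per locus, or two lines with one column per
locus).  Missingness is whole-genotype: a half-missing call is promoted to
fully missing with a warning, since every downstream statistic treats the
two allele copies of a genotype as jointly observed.  Population codes map
to continental groups (AFR/EUR/EAS/NAM/OCE) through a user-supplied label
map; a `popflag` column marks training individuals for supervised runs.

## Marker informativeness

The allele-frequency differential of a locus between groups A and B is the
half-L1 (total-variation) distance

    δ(A,B) = ½ Σ_j |p_Aj − p_Bj|,

which reduces to the absolute difference of one allele's frequencies at a
biallelic locus.  Loci are ranked by the maximum δ over all unordered
group pairs, ties broken by marker id.  The half-L1 convention is a
design choice for the two triallelic loci; published marker counts based
on a different pooling of the third allele can differ by about one marker,
so the informativeness counts carry a ±1-marker caveat at those loci.

Pairwise differentiation uses the Weir–Cockerham (1984) θ estimator from
two-population variance components a (between populations), b (between
individuals within populations) and c (within individuals), computed from
genotype counts, summed over alleles at multiallelic loci, with the
multi-locus estimate the ratio of sums Σa / Σ(a+b+c).  Loci monomorphic
across both groups contribute zero components and are excluded from the
per-locus ratio rather than producing NaNs in the sum.  θ is the standard
open re-implementation of AMOVA-style pairwise F_ST; exact numerical
parity with any particular program's variant is not claimed.

## Exact tests

**Hardy–Weinberg.**  For biallelic counts the conditional exact test
enumerates every heterozygote count h compatible with the observed allele
counts; the p-value is the total probability of tables no more probable
than the observed one (inclusive, with a 1e−12 relative tolerance for
float ties).  For three or more alleles the same ordering rule is applied
by Monte Carlo: the 2n allele copies are shuffled and re-paired
(Guo–Thompson style), default 100,000 seeded permutations, and
p = (1 + exceedances)/(B + 1) so p ∈ (0, 1].  An all-missing locus
returns NaN with a warning, never 1.0.

**Linkage disequilibrium.**  The two-locus test statistic is the
likelihood-ratio of gametic association: haplotype frequencies are fitted
by EM from unphased genotype pairs (double heterozygotes split between
the two phasings in the E-step) and compared against linkage equilibrium
(the product of single-locus allele frequencies).  The null distribution
permutes one locus's genotypes across individuals within a group;
p = (1 + #{LR_perm ≥ LR_obs})/(n_perm + 1).  Tests run within each
reference group separately — pooling groups would manufacture spurious LD
from population structure.  The scan default is 10,000 permutations per
pair with an early-stopping rule (a pair stops once 20 exceedances have
accumulated, at which point its p-value is orders of magnitude above any
Bonferroni threshold); single-pair calls default to 100,000 permutations
with no early stop.  Both scans report Bonferroni-corrected significance
alongside raw p-values.

## Admixture model

The sampler implements the standard admixture model: individual i has
membership vector q_i ~ Dirichlet(α,…,α); each allele copy draws a latent
cluster z ~ Categorical(q_i) and then an allele from the cluster's
frequency vector P_{k,l}.  Updates per sweep:

1. z | q, P — multinomial with Pr(z = k) ∝ q_{ik} P_{k,l,a};
2. q_i | z ~ Dirichlet(α + n_{i·}); flagged individuals in supervised
   mode keep q fixed at the indicator of their labeled cluster;
3. P_{k,l} | z ~ Dirichlet(λ + m_{k,l·}) under the independent frequency
   model; under the correlated model
   P_{k,l} ~ Dirichlet(p_{A,l}(1−F_k)/F_k + m_{k,l·}), with Metropolis
   updates of each drift parameter F_k (log-normal proposal, step 0.2 on
   the log scale; Gamma prior with mean 0.01 and sd 0.05) and of the
   ancestral frequencies p_{A,l} (Dirichlet random-walk proposal with
   concentration 200, Dirichlet(λ) prior);
4. α — Metropolis with normal proposal (sd 0.025) and uniform prior on
   (0, 10), likelihood the Dirichlet(α) density of the unflagged q's.

Defaults: λ = 1, α₀ = 1, correlated frequency model.  Missing genotypes
contribute to no count (marginalized by omission).  Sampled frequency
vectors are floored at 1e−9 and renormalized to keep log-densities finite.
`pfrompopflagonly` restricts the m counts in step 3 to flagged
individuals' copies — the configuration used when estimating test samples
against a fixed reference.  Chain-length defaults are sized for testing
(2,000 burn-in + 5,000 reps); the acceptance script uses 10,000 + 20,000,
and 100,000 + 100,000 remains available through the config for
publication-scale runs.  Per-sweep cost is vectorized over all observed
allele copies, ~3.5 ms for 240 individuals × 46 loci at K = 4.

Model choice across K uses lnP(D) ≈ mean(trace) − var(trace)/2 computed
from the post-burn-in log-likelihood trace (sample variance, n−1
denominator).  Replicate runs (seeded seed + r for run r) are reconciled
by permuting each run's cluster columns to minimize the summed squared
difference to the first run; because that objective is linear in the
assignment, the exact optimum is found with the Hungarian algorithm
rather than an exhaustive K! search, removing any practical ceiling on K.

**Label symmetry.**  The model is exchangeable in cluster labels, and the
test suite verifies that independently seeded replicates agree after
alignment.  Path-wise equivariance — permuting the initial state and
obtaining the identically permuted chain from the same seed — does not
hold and cannot hold with inverse-CDF categorical sampling and
shape-dependent gamma generation, where the random-number stream's
consumption depends on cluster order; equivariance here is a property of
the distribution, not of individual sample paths.

**Boundary bias.**  For test individuals whose true membership has zero
components, posterior means of those components are biased upward (a
simplex-boundary effect, amplified when a homogeneous test cohort pulls
the inferred α up).  This is a property of the model shared with the
original program — it is exactly why four-group analyses of tri-hybrid
admixed populations show a small spurious fourth component, and why a
three-group re-analysis is recommended in that situation.  Recovery tests
therefore quantify (i) population-mean recovery for cohorts with variable
(Dirichlet) admixture, where the model is well-specified, and (ii) RMSE
of individual memberships under the same law, rather than asserting
unbiasedness at the simplex boundary.

## Classifier

The naive-Bayes assignment treats loci as independent and groups as being
in Hardy–Weinberg equilibrium: the log-likelihood of a profile under a
group is Σ ln p̃_a² (homozygotes) + Σ ln 2 p̃_a p̃_b (heterozygotes) over
non-missing loci, with smoothed frequencies
p̃_j = (count_j + c)/(2n + c|alleles|), default pseudocount c = 1.
Smoothing keeps alleles unseen in a group's training data (e.g. the
group-private third alleles) at positive probability, so likelihoods stay
finite.  The reported LR is best vs second-best group; exact ties break
lexicographically and are flagged.  Group priors are uniform.  Leave-one-
out cross-validation decrements the held-out individual's allele copies
from its group's counts instead of retraining (verified identical to full
retraining), making the full scan O(n·L·G).  Because the published web
tool's smoothing convention is not documented, error counts compared
against published figures carry a ±3-individual tolerance.

## PCA

Genotypes are encoded as per-allele dosage columns (copies of each
non-reference allele; a biallelic locus contributes one column, a
triallelic locus two), missing cells imputed with the column mean before
scaling, constant columns dropped.  Columns are centered and by default
scaled to unit variance (the unscaled variant is a flag, since the
convention of the original analysis tool is unstated — the variance
percentages shift by a couple of points between the two).  The
decomposition is a plain SVD; percent variance of component i is
σ_i²/Σσ_j²·100, and component signs are fixed by making each component's
largest-magnitude loading positive so scores are reproducible across BLAS
backends.

## Simulator

`simulate_cohort` draws cohorts under exactly the admixture generative
model: per-individual q (fixed group indicator, fixed vector, or
Dirichlet(α) draw), per-copy latent ancestry, per-copy allele from the
ancestral group's frequencies, Hardy–Weinberg within groups, loci
independent given q, whole genotypes masked at a configurable missing
rate.  All randomness flows through numpy's PCG64 `default_rng`, so
cohorts are bit-reproducible for a fixed seed.

`make_panel_frequencies` constructs biallelic frequency tables whose
per-locus max pairwise δ equals a requested profile exactly: the extreme
pair of groups (rotating across loci) sits at the ends of an interval of
the requested width, remaining groups drawn uniformly inside it.

`reference_like_fixture` is the packaged test surface: five groups
(AFR/EUR/EAS/NAM/OCE) × 60 individuals, 46 loci whose δ profile over the
four primary groups has 39 loci ≥ 0.4, five in [0.3, 0.4) and two below —
the informativeness structure of a panel selected for δ ≥ 0.4 whose
markers partly regress on an independent reference sample — plus two
strongly differentiated loci carrying group-private third alleles (one
AFR-private at frequency 0.08, one EUR-private at 0.06), OCE frequencies
drawn uniformly, and a 0.5% missing-data rate.  Sample size follows the
package default of 60 per group, chosen as a realistic per-continent
reference size that keeps every stage fast.

**What the fixture does not emulate:** real linkage between markers,
mutation/genotyping error, within-continent substructure (each group is a
single random-mating unit), unequal group sizes, and the specific
published allele frequencies (transcribing them from a PDF supplement
would be error-prone; a loader for a user-transcribed frequency TSV is
provided instead).  Consequently, passing tests demonstrate correctness
of the machinery under the model's own assumptions, not the numerical
values any particular real dataset produces.  On real reference data the
same pipeline applies unchanged from a STRUCTURE-format file plus a label
map.

## Numerical and design choices

- δ for triallelic loci: half-L1; alternative poolings differ by ≤ one
  marker in threshold counts.
- HWE tail rule: inclusive (tables with probability equal to the observed
  count toward the tail), the standard exact-test convention.
- F_ST: two-population Weir–Cockerham θ, ratio-of-sums across loci;
  within-group θ defined as 0.
- EM for LD: convergence on max |Δh| < 1e−8, cap 100 iterations; the LR is
  floored at 0 (EM starts at the null, so its likelihood never falls
  below it).
- Permutation p-values use the +1 correction on both numerator and
  denominator, so no test ever reports p = 0.
- Cluster alignment: Hungarian assignment on the Q-matrix cross-product —
  exact for the least-squares relabeling objective at any K.
- Supervised cluster order: clusters are indexed by the sorted group
  labels of flagged individuals; K must equal the number of labeled
  groups.
- Report tables print at three decimals; identical seeds and configs
  reproduce every table byte-for-byte.

## Known limitations

- No linkage model, LOCPRIOR, or migrant-generation inference in the
  sampler; no haplotype phasing beyond the two-locus EM.
- lnP(D) is a rough model-choice heuristic; the tests assert only the
  plateau behavior that practitioners rely on.
- The LD scan's early stopping makes far-from-threshold p-values
  conservative approximations; single-pair tests with full permutation
  counts are exact (up to Monte Carlo error).
- PCA assumes mean imputation is adequate at the low missingness typical
  of reference panels; heavy missingness would call for a likelihood-based
  approach.
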
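# aimpanel

Analysis toolkit for compact panels of ancestry-informative INDEL markers
(AIM-INDELs) — the small sets of insertion/deletion polymorphisms with
large allele-frequency differences between continental population groups
that forensic and population-genetics laboratories use to infer the likely
ancestry of an individual or the admixture proportions of a cohort.

The package implements the complete analysis cycle such a panel goes
through, for cohorts of diploid genotypes in STRUCTURE text format
(alleles coded 1 = short, 2 = long, occasionally 3 for extra length
variants; −9 missing):

- **Marker informativeness** — per-group allele frequencies, pairwise
  frequency differentials δ = ½ Σ|p_A − p_B| with ranking by maximum δ,
  and Weir–Cockerham θ (F_ST) from two-population variance components.
- **Exact tests** — conditional exact Hardy–Weinberg tests (full
  enumeration for biallelic loci, seeded Monte-Carlo shuffling for
  triallelic ones) and a two-locus likelihood-ratio test of gametic
  association with EM haplotype frequencies and a permutation null, both
  with Bonferroni-controlled scans.
- **Admixture inference** — a Gibbs sampler for the admixture model
  (q_i ~ Dirichlet(α); allele copies drawn from cluster frequencies
  P_{k,l} with independent or correlated priors), supervised training
  mode (POPFLAG-anchored clusters, frequencies updated from training
  individuals only), the lnP(D) ≈ mean − var/2 model-choice diagnostic,
  and least-squares cluster relabeling across replicate runs.
- **Population assignment** — Hardy–Weinberg naive-Bayes classification
  with likelihood ratios and leave-one-out cross-validation.
- **PCA** — dosage-encoded genotype matrix, unit-variance scaling, and
  per-component "information percentage" values.
- **Simulator** — cohorts generated under the admixture model itself
  (Hardy–Weinberg within groups, independent loci, Dirichlet admixture,
  controllable δ profile, group-private third alleles, missing data), so
  every stage is verifiable against ground truth without external
  downloads.

## Worked example

The packaged synthetic reference cohort mimics a 46-locus, four-group
continental panel (plus Oceania), with 60 individuals per group:

```python
from aimpanel.synthetic_data import reference_like_fixture
from aimpanel.popgen_stats import allele_frequencies, rank_markers, pairwise_fst
from aimpanel.classifier import loocv
from aimpanel.pca import encode_dosage, pca
from aimpanel.admixture import (
    AdmixConfig, run_replicates, align_runs, group_mean_memberships,
)

cohort = reference_like_fixture()
table = cohort.table.restrict_groups(["AFR", "EUR", "EAS", "NAM"])

ranked = rank_markers(allele_frequencies(table))
print("loci with max delta >= 0.4:", int((ranked["max_delta"] >= 0.4).sum()))

fst = pairwise_fst(table, "AFR", "EUR")
print(f"multi-locus theta AFR vs EUR: {fst.theta:.3f}")

res = loocv(table)
print(f"LOOCV errors: {res.n_errors}/{res.n_total} ({100*res.error_rate:.2f}%)")

p = pca(encode_dosage(table))
print(f"PC1-3 variance: {p.percent_variance[:3].sum():.1f}%")

cfg = AdmixConfig(K=4, burnin=2_000, reps=5_000, n_runs=3, seed=1)
aligned = align_runs(run_replicates(table, cfg))
print(group_mean_memberships(aligned.Q_avg, table.samples["group"],
                             aligned.cluster_names).round(3))
```

prints

```
loci with max delta >= 0.4: 40
multi-locus theta AFR vs EUR: 0.393
LOOCV errors: 0/240 (0.00%)
PC1-3 variance: 44.9%
        C1     C2     C3     C4
AFR  0.023  0.934  0.017  0.026
EAS  0.023  0.019  0.018  0.941
EUR  0.016  0.018  0.949  0.017
NAM  0.941  0.020  0.019  0.021
```

Reading the output: 40 of 46 markers show a sample max-δ ≥ 0.4 between at
least two groups (the generative truth is 39); between-continent θ is far
above what random markers give; every individual is re-assigned to its own
group under leave-one-out cross-validation; the first three principal
components carry about half the genotypic variance (the three axes that
separate four clusters); and the aligned three-run admixture analysis at
K = 4 gives each group ≈ 0.93–0.95 mean membership in its own cluster with
small symmetric spillover — the diagonal structure expected of a
well-differentiated reference panel.

For real data, the same workflow starts from a STRUCTURE-format file and
a population→group label map:

```sh
aimpanel report genotypes.str --label-map groups.tsv --out report/
```

which writes frequency/δ/F_ST tables, HWE and LD scan reports, the
lnP(D)-by-K table, aligned Q-matrices with a membership bar plot, PCA
scores/variances, the LOOCV confusion matrix, and a provenance block.
`aimpanel simulate`, `stats`, `admix`, `classify` and `pca` expose the
individual stages.

## Layout

```
src/aimpanel/
  data_io.py         STRUCTURE-format I/O, panel metadata, frequency tables
  popgen_stats.py    delta, F_ST, HWE exact tests, LD permutation test
  admixture.py       admixture-model Gibbs sampler + alignment + lnP(D)
  classifier.py      naive-Bayes assignment, likelihood ratios, LOOCV
  pca.py             dosage encoding and PCA
  synthetic_data.py  cohort simulator and packaged reference-like fixture
  pipeline.py        end-to-end workflows and report export
  cli.py             command-line entry points
docs/methods.md      models, assumptions, numerical choices, limitations
```
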
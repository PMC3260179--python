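"""End-to-end analysis workflows and report export.

Two workflows mirror how an ancestry-informative panel is actually used:

* :func:`run_reference_analysis` characterizes a labeled reference cohort —
  allele frequencies, δ ranking, pairwise F_ST, HWE and LD scans,
  unsupervised admixture runs over a range of K with replicate alignment,
  PCA and leave-one-out classification — and writes every table to a report
  directory.
* :func:`run_test_samples` estimates ancestry of unlabeled test samples
  against a flagged reference (supervised mode), optionally rerunning with
  one or more ancestral groups excluded (the three-contributor analysis
  used for admixed American populations).

All tables are TSV with values printed at three decimals; a provenance
block records configuration, seeds and library versions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import (
    AdmixConfig,
    AlignedRuns,
    SupervisedResult,
    align_runs,
    group_mean_memberships,
    run_replicates,
    supervised_estimate,
)
from .classifier import LoocvResult, loocv
from .data_io import GenotypeTable, concat_tables, write_frequency_tsv
from .pca import PcaResult, encode_dosage, pca
from .popgen_stats import (
    allele_frequencies,
    hwe_scan,
    ld_scan,
    pairwise_fst,
    rank_markers,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.3f"


@dataclass
class AnalysisReport:
    """Everything the reference-cohort workflow computes."""

    frequencies: object
    delta_table: pd.DataFrame
    fst_per_locus: pd.DataFrame
    fst_multilocus: pd.DataFrame
    hwe: pd.DataFrame
    ld: pd.DataFrame | None
    lnpd_by_k: pd.DataFrame
    aligned: AlignedRuns | None
    group_means: pd.DataFrame | None
    pca_result: PcaResult
    loocv_result: LoocvResult
    provenance: dict


def _provenance(config: dict) -> dict:
    return {
        "aimpanel_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config,
    }


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)


def run_reference_analysis(
    table: GenotypeTable,
    outdir: str | Path | None = None,
    k_values: Sequence[int] | None = None,
    admix: AdmixConfig | None = None,
    ld_n_perm: int = 10_000,
    ld_early_stop: int | None = 20,
    hwe_n_perm: int = 100_000,
    seed: int = 0,
    run_ld: bool = True,
    run_admixture: bool = True,
) -> AnalysisReport:
    """Full characterization of a labeled reference cohort.

    ``k_values`` defaults to 1 .. (number of groups + 3), following the
    usual model-choice sweep; the admixture stage runs ``admix.n_runs``
    replicates per K, aligns them and also reports the lnPD-by-K table.
    The K equal to the number of groups provides the aligned Q-matrix and
    per-group mean memberships in the report.
    """
    groups = table.groups
    n_groups = len(groups)
    if admix is None:
        admix = AdmixConfig(K=n_groups, seed=seed)
    if k_values is None:
        k_values = (
            list(range(1, n_groups + 4)) if run_admixture else []
        )

    freqs = allele_frequencies(table, "group")
    delta_table = rank_markers(freqs)

    fst_cols = {}
    multilocus_rows = []
    for a, b in itertools.combinations(groups, 2):
        res = pairwise_fst(table, a, b)
        fst_cols[f"{a}|{b}"] = res.per_locus
        multilocus_rows.append(
            {"group_a": a, "group_b": b, "theta": res.theta}
        )
    fst_per_locus = pd.DataFrame(fst_cols)
    fst_multilocus = pd.DataFrame(multilocus_rows)

    hwe = hwe_scan(table, "group", n_perm=hwe_n_perm, seed=seed)
    ld = (
        ld_scan(table, "group", n_perm=ld_n_perm, seed=seed,
                early_stop=ld_early_stop)
        if run_ld
        else None
    )

    aligned = None
    group_means = None
    lnpd_rows = []
    for K in k_values:
        cfg = AdmixConfig(**{**admix.__dict__, "K": K, "seed": seed})
        runs = run_replicates(table, cfg)
        for r_i, run in enumerate(runs):
            lnpd_rows.append({"K": K, "run": r_i, "lnPD": run.lnPD})
        al = align_runs(runs)
        if K == n_groups:
            aligned = al
            group_means = group_mean_memberships(
                al.Q_avg, table.samples["group"], al.cluster_names
            )
    lnpd_by_k = pd.DataFrame(lnpd_rows, columns=["K", "run", "lnPD"])

    pca_result = pca(encode_dosage(table))
    loocv_result = loocv(table, "group")

    provenance = _provenance(
        {
            "seed": seed,
            "k_values": list(k_values),
            "admix": dict(admix.__dict__),
            "ld_n_perm": ld_n_perm,
            "hwe_n_perm": hwe_n_perm,
            "n_individuals": table.n_individuals,
            "n_loci": table.n_loci,
            "groups": groups,
        }
    )
    report = AnalysisReport(
        freqs, delta_table, fst_per_locus, fst_multilocus, hwe, ld,
        lnpd_by_k, aligned, group_means, pca_result, loocv_result,
        provenance,
    )
    if outdir is not None:
        write_report(report, table, Path(outdir))
    return report


def write_report(
    report: AnalysisReport, table: GenotypeTable, outdir: Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_frequency_tsv(report.frequencies, outdir / "allele_frequencies.tsv")
    _write(report.delta_table, outdir / "delta_ranking.tsv", index=False)
    _write(report.fst_per_locus, outdir / "fst_per_locus.tsv",
           index_label="marker_id")
    _write(report.fst_multilocus, outdir / "fst_multilocus.tsv", index=False)
    _write(report.hwe, outdir / "hwe_scan.tsv", index=False)
    if report.ld is not None:
        _write(report.ld, outdir / "ld_scan.tsv", index=False)
    if len(report.lnpd_by_k):
        _write(report.lnpd_by_k, outdir / "lnpd_by_k.tsv", index=False)
    if report.aligned is not None:
        q = pd.DataFrame(
            report.aligned.Q_avg, columns=report.aligned.cluster_names
        )
        q.insert(0, "group", table.samples["group"].values)
        q.insert(0, "population", table.samples["population"].values)
        q.insert(0, "sample_id", table.samples["sample_id"].values)
        _write(q, outdir / "q_matrix.tsv", index=False)
        _write(report.group_means, outdir / "group_mean_memberships.tsv",
               index_label="group")
        export_barplot(
            report.aligned.Q_avg,
            table.samples["population"],
            outdir / "membership_barplot.png",
            outdir / "membership_barplot.tsv",
            cluster_names=report.aligned.cluster_names,
        )
    scores = report.pca_result.scores_frame(
        table.samples["sample_id"], table.samples["group"]
    )
    _write(scores, outdir / "pca_scores.tsv", index=False)
    var = pd.DataFrame(
        {
            "component": np.arange(len(report.pca_result.percent_variance))
            + 1,
            "percent_variance": report.pca_result.percent_variance,
        }
    )
    _write(var, outdir / "pca_variance.tsv", index=False)
    _write(report.loocv_result.confusion, outdir / "loocv_confusion.tsv",
           index_label="true_group")
    _write(report.loocv_result.assignments, outdir / "loocv_assignments.tsv",
           index=False)
    (outdir / "provenance.yaml").write_text(
        yaml.safe_dump(report.provenance, sort_keys=False)
    )


@dataclass
class TestSampleReport:
    supervised: SupervisedResult
    pop_means: pd.DataFrame
    excluded_rerun: "TestSampleReport | None" = None


def run_test_samples(
    reference: GenotypeTable,
    tests: GenotypeTable,
    admix: AdmixConfig | None = None,
    exclude_groups: Sequence[str] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> TestSampleReport:
    """Supervised ancestry estimation of test samples against a reference.

    Reference individuals are flagged as training data and anchor the
    clusters; allele frequencies are updated from flagged individuals only.
    ``exclude_groups`` triggers a rerun with those ancestral groups removed
    from the reference and K reduced accordingly.
    """
    ref = reference.subset(np.ones(reference.n_individuals, dtype=bool))
    ref.samples["popflag"] = 1
    tst = tests.subset(np.ones(tests.n_individuals, dtype=bool))
    tst.samples["popflag"] = 0
    combined = concat_tables(ref, tst)
    K = len(ref.groups)
    if admix is None:
        admix = AdmixConfig(K=K, seed=seed)
    cfg = AdmixConfig(
        **{
            **admix.__dict__,
            "K": K,
            "use_popinfo": True,
            "pfrompopflagonly": True,
            "seed": seed,
        }
    )
    sup = supervised_estimate(combined, cfg)
    report = TestSampleReport(sup, sup.pop_means)
    if exclude_groups:
        kept = [g for g in ref.groups if g not in set(exclude_groups)]
        if len(kept) < 2:
            raise ValueError("exclusion leaves fewer than two clusters")
        report.excluded_rerun = run_test_samples(
            ref.restrict_groups(kept), tst, admix=admix, seed=seed
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write(sup.test_q, outdir / "test_q.tsv", index=False)
        _write(sup.pop_means, outdir / "test_pop_means.tsv",
               index_label="population")
        if report.excluded_rerun is not None:
            _write(
                report.excluded_rerun.supervised.test_q,
                outdir / "test_q_excluded.tsv", index=False,
            )
            _write(
                report.excluded_rerun.pop_means,
                outdir / "test_pop_means_excluded.tsv",
                index_label="population",
            )
    return report


def export_barplot(
    Q: np.ndarray,
    labels,
    path_png: str | Path,
    path_tsv: str | Path | None = None,
    order: Sequence[int] | None = None,
    cluster_names: Sequence[str] | None = None,
) -> None:
    """Stacked-bar membership plot (one equal-width segment per individual).

    Individuals are sorted by their label (population) and input order
    within labels unless an explicit ``order`` is given; colors follow the
    cluster index deterministically.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Q = np.asarray(Q, float)
    n, K = Q.shape
    labels = pd.Series(list(labels))
    if order is None:
        order = np.argsort(labels.to_numpy(), kind="stable")
    order = np.asarray(order)
    Qs = Q[order]
    names = list(cluster_names or [f"C{k+1}" for k in range(K)])
    cmap = matplotlib.colormaps["tab10"]
    fig, ax = plt.subplots(figsize=(max(6, n / 20), 2.5))
    bottom = np.zeros(n)
    x = np.arange(n)
    for k in range(K):
        ax.bar(
            x, Qs[:, k], bottom=bottom, width=1.0,
            color=cmap(k % 10), label=names[k],
        )
        bottom += Qs[:, k]
    # population boundaries
    lab_sorted = labels.iloc[order].to_numpy()
    changes = np.nonzero(lab_sorted[1:] != lab_sorted[:-1])[0]
    for c in changes:
        ax.axvline(c + 0.5, color="black", lw=0.6)
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("membership")
    ax.legend(fontsize=6, ncol=min(K, 6), loc="upper center",
              bbox_to_anchor=(0.5, -0.08))
    fig.tight_layout()
    fig.savefig(path_png, dpi=150)
    plt.close(fig)
    if path_tsv is not None:
        df = pd.DataFrame(Qs, columns=names)
        df.insert(0, "label", lab_sorted)
        df.to_csv(path_tsv, sep="\t", index=False)
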
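"""Hardy–Weinberg naive-Bayes population assignment with likelihood ratios.

Each candidate group is summarized by smoothed per-locus allele frequencies;
a query profile's likelihood under a group is the product over loci of
Hardy–Weinberg genotype probabilities (``p̃_a²`` for a homozygote,
``2 p̃_a p̃_b`` for a heterozygote), loci being treated as independent.  The
reported likelihood ratio compares the best against the second-best group,
and panel performance is estimated by leave-one-out cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MAX_ALLELE, GenotypeTable

__all__ = [
    "ClassifierModel",
    "AssignmentResult",
    "train",
    "profile_loglik",
    "classify",
    "loocv",
    "LoocvResult",
]


@dataclass
class ClassifierModel:
    """Per-group training allele-copy counts plus an additive smoother.

    The smoothed frequency of allele ``j`` in a group at a locus is
    ``(count_j + c) / (2n + c * |alleles|)`` with pseudocount ``c`` shared
    across the locus's declared alleles, so alleles never seen in training
    (group-private variants elsewhere) keep strictly positive probability
    whenever ``c > 0``.
    """

    groups: list[str]
    panel: list
    counts: np.ndarray  # (G, L, MAX_ALLELE) allele-copy counts
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self._valid = np.zeros((len(self.panel), MAX_ALLELE), dtype=bool)
        for li, loc in enumerate(self.panel):
            for code in loc.allele_codes:
                self._valid[li, code - 1] = True

    def frequencies(self) -> np.ndarray:
        """Smoothed frequencies, zero at undeclared allele codes."""
        c = self.pseudocount
        valid = self._valid[None, :, :]
        num = (self.counts + c) * valid
        denom = num.sum(axis=2, keepdims=True)
        if (denom == 0).any():
            bad = np.argwhere(denom[:, :, 0] == 0)[0]
            raise ValueError(
                f"group {self.groups[bad[0]]!r} has no information at locus "
                f"{self.panel[bad[1]].marker_id} and pseudocount is 0"
            )
        return num / denom


@dataclass
class AssignmentResult:
    logliks: dict[str, float]
    best: str
    lr: float  # best vs second-best likelihood ratio, >= 1
    tie: bool
    n_loci_used: int
    undefined: bool = False  # all loci missing


def train(
    table: GenotypeTable, grouping: str = "group", pseudocount: float = 1.0
) -> ClassifierModel:
    """Fit per-group smoothed allele frequencies from a training table."""
    labels = table.samples[grouping]
    groups = sorted(labels.unique())
    aidx = table.allele_index()
    L = table.n_loci
    counts = np.zeros((len(groups), L, MAX_ALLELE))
    for g, grp in enumerate(groups):
        rows = (labels == grp).to_numpy()
        sub = aidx[rows].reshape(-1, 2)
        for j in range(L):
            obs = aidx[rows, j, :].ravel()
            obs = obs[obs >= 0]
            counts[g, j] = np.bincount(obs, minlength=MAX_ALLELE)
    model = ClassifierModel(groups, list(table.panel), counts, pseudocount)
    if pseudocount == 0 and (counts.sum(axis=2) == 0).any():
        raise ValueError(
            "a group has zero observed copies at some locus; "
            "use pseudocount > 0"
        )
    return model


def _profile_logliks(
    freqs: np.ndarray, aidx_row: np.ndarray
) -> tuple[np.ndarray, int]:
    """Log-likelihood per group for one profile of 0-based allele indices."""
    obs = aidx_row[:, 0] >= 0
    loci = np.nonzero(obs)[0]
    if loci.size == 0:
        return np.zeros(freqs.shape[0]), 0
    a = aidx_row[loci, 0]
    b = aidx_row[loci, 1]
    pa = np.log(np.maximum(freqs[:, loci, a], 1e-300))
    pb = np.log(np.maximum(freqs[:, loci, b], 1e-300))
    het = (a != b).astype(float) * math.log(2.0)
    return (pa + pb + het).sum(axis=1), int(loci.size)


def profile_loglik(
    model: ClassifierModel, calls: np.ndarray
) -> dict[str, float]:
    """HWE genotype log-likelihood of one profile under each group.

    ``calls`` is a ``(L, 2)`` array of allele codes (``-9`` missing);
    missing loci are skipped.
    """
    from .data_io import MISSING

    calls = np.asarray(calls)
    aidx = calls.astype(np.int64) - 1
    aidx[calls == MISSING] = -1
    ll, _ = _profile_logliks(model.frequencies(), aidx)
    return dict(zip(model.groups, ll.tolist()))


def _assign(ll: np.ndarray, groups: list[str], n_used: int) -> AssignmentResult:
    if n_used == 0:
        return AssignmentResult(
            dict(zip(groups, ll.tolist())), groups[0], 1.0, True, 0,
            undefined=True,
        )
    order = np.argsort(-ll, kind="stable")
    best_ll = ll[order[0]]
    tied = np.nonzero(np.abs(ll - best_ll) < 1e-9)[0]
    tie = len(tied) > 1
    best = min(groups[i] for i in tied)  # lexicographic tie-break
    second = ll[order[1]] if len(groups) > 1 else best_ll
    lr = float(np.exp(min(best_ll - second, 700.0)))
    return AssignmentResult(
        dict(zip(groups, ll.tolist())), best, max(lr, 1.0), tie, n_used
    )


def classify(model: ClassifierModel, calls: np.ndarray) -> AssignmentResult:
    """Assign one profile to its maximum-likelihood group."""
    from .data_io import MISSING

    calls = np.asarray(calls)
    aidx = calls.astype(np.int64) - 1
    aidx[calls == MISSING] = -1
    ll, n_used = _profile_logliks(model.frequencies(), aidx)
    return _assign(ll, model.groups, n_used)


@dataclass
class LoocvResult:
    confusion: pd.DataFrame  # true group x predicted group counts
    assignments: pd.DataFrame  # per-individual report
    n_errors: int
    n_total: int
    per_group_errors: dict[str, int]

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.n_total if self.n_total else 0.0


def loocv(
    table: GenotypeTable,
    grouping: str = "group",
    pseudocount: float = 1.0,
) -> LoocvResult:
    """Leave-one-out cross-validation of the naive-Bayes assignment.

    For each individual the training counts are decremented by that
    individual's own allele copies before classification (equivalent to a
    full retrain without it, but O(1) per fold).  Individuals with no
    observed genotypes are reported as undefined and excluded from the
    error tally.
    """
    labels = table.samples[grouping]
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 individuals: {small}")
    model = train(table, grouping, pseudocount)
    groups = model.groups
    aidx = table.allele_index()
    L = table.n_loci
    records = []
    confusion = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    per_group_errors = {g: 0 for g in groups}
    n_errors = 0
    n_total = 0
    for i in range(table.n_individuals):
        true_grp = labels.iloc[i]
        g = groups.index(true_grp)
        row = aidx[i]
        obs = np.nonzero(row[:, 0] >= 0)[0]
        # decrement this individual's copies out of its group's counts
        for j in obs:
            model.counts[g, j, row[j, 0]] -= 1
            model.counts[g, j, row[j, 1]] -= 1
        ll, n_used = _profile_logliks(model.frequencies(), row)
        res = _assign(ll, groups, n_used)
        for j in obs:
            model.counts[g, j, row[j, 0]] += 1
            model.counts[g, j, row[j, 1]] += 1
        records.append(
            {
                "sample_id": table.samples["sample_id"].iloc[i],
                "true_group": true_grp,
                "predicted": res.best if not res.undefined else "",
                "log10_lr": math.log10(res.lr) if res.lr > 0 else 0.0,
                "tie": res.tie,
                "n_loci_used": res.n_loci_used,
            }
        )
        if res.undefined:
            continue
        n_total += 1
        confusion.loc[true_grp, res.best] += 1
        if res.best != true_grp:
            n_errors += 1
            per_group_errors[true_grp] += 1
    return LoocvResult(
        confusion, pd.DataFrame(records), n_errors, n_total, per_group_errors
    )
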
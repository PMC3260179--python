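"""Marker-level population-genetics statistics.

Covers the descriptive side of an ancestry-informative marker panel:

* sample allele frequencies per group/population;
* allele-frequency differentials δ (half-L1 distance, which reduces to the
  absolute frequency difference at biallelic loci) and marker ranking by the
  largest pairwise δ;
* pairwise Weir–Cockerham θ (F_ST) from two-population variance components,
  with a ratio-of-sums multi-locus estimate;
* exact tests of Hardy–Weinberg equilibrium (full enumeration for biallelic
  counts, seeded Monte-Carlo allele shuffling for multiallelic counts);
* a two-locus likelihood-ratio test of gametic association with an EM
  haplotype-frequency estimate and a permutation null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import MAX_ALLELE, MISSING, FrequencyTable, GenotypeTable

__all__ = [
    "allele_frequencies",
    "delta",
    "rank_markers",
    "pairwise_fst",
    "FstResult",
    "genotype_counts",
    "hwe_exact",
    "hwe_scan",
    "ld_test",
    "ld_scan",
]


# ---------------------------------------------------------------------------
# allele frequencies and δ
# ---------------------------------------------------------------------------

def allele_frequencies(
    table: GenotypeTable, grouping: str = "group"
) -> FrequencyTable:
    """Observed allele frequencies per group (or population) per locus.

    ``p̂(allele) = observed copies / 2 n_observed``; loci with no observed
    copies in a group keep a zero vector and ``n_copies = 0``.
    """
    if grouping not in ("group", "population"):
        raise ValueError("grouping must be 'group' or 'population'")
    labels = table.samples[grouping]
    groups = sorted(labels.unique())
    if not groups:
        raise ValueError("table has no individuals")
    G, L = len(groups), table.n_loci
    freqs = np.zeros((G, L, MAX_ALLELE))
    n_copies = np.zeros((G, L))
    aidx = table.allele_index()  # (n, L, 2), -1 missing
    for g, grp in enumerate(groups):
        rows = (labels == grp).to_numpy()
        if not rows.any():
            raise ValueError(f"empty group {grp!r}")
        sub = aidx[rows].reshape(-1, L, 2)
        for j in range(L):
            obs = sub[:, j, :].ravel()
            obs = obs[obs >= 0]
            n_copies[g, j] = obs.size
            if obs.size:
                counts = np.bincount(obs, minlength=MAX_ALLELE)
                freqs[g, j] = counts / obs.size
    return FrequencyTable(groups, list(table.panel), freqs, n_copies)


def delta(pA: np.ndarray, pB: np.ndarray) -> float:
    """Allele-frequency differential δ = ½ Σ_j |pA_j − pB_j|.

    For a biallelic locus this is the absolute difference of one allele's
    frequencies; the half-L1 (total-variation) form extends it to loci with
    a third allele.
    """
    pA = np.asarray(pA, float)
    pB = np.asarray(pB, float)
    if pA.shape != pB.shape:
        raise ValueError("mismatched allele sets")
    return float(0.5 * np.abs(pA - pB).sum())


def rank_markers(
    freqs: FrequencyTable, groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-locus pairwise δ table sorted by max pairwise δ (descending).

    Returns a DataFrame with one ``delta:{A}|{B}`` column per unordered
    group pair, plus ``max_delta`` and ``best_pair``; ties in ``max_delta``
    break by ``marker_id``.
    """
    if groups is None:
        groups = freqs.groups
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups to rank markers")
    gi = [freqs.group_index(g) for g in groups]
    rows = []
    for li, loc in enumerate(freqs.panel):
        entry: dict = {"marker_id": loc.marker_id}
        best, best_pair = 0.0, ""
        for (a, ga), (b, gb) in itertools.combinations(zip(groups, gi), 2):
            d = delta(freqs.freqs[ga, li], freqs.freqs[gb, li])
            entry[f"delta:{a}|{b}"] = d
            if d > best:
                best, best_pair = d, f"{a}|{b}"
        entry["max_delta"] = best
        entry["best_pair"] = best_pair
        rows.append(entry)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["max_delta", "marker_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-locus θ estimates and the ratio-of-sums multi-locus θ."""

    group_a: str
    group_b: str
    per_locus: pd.Series  # indexed by marker_id; NaN where undefined
    components: pd.DataFrame  # columns a, b, c summed over alleles
    theta: float  # multi-locus ratio of sums


def _wc_components(
    counts_a: np.ndarray, counts_b: np.ndarray,
    het_a: np.ndarray, het_b: np.ndarray,
    n_a: int, n_b: int,
) -> tuple[float, float, float]:
    """Weir–Cockerham (1984) variance components for one locus, r=2 pops.

    ``counts_*``: allele-copy counts per allele; ``het_*``: per allele, the
    number of individuals heterozygous for that allele; ``n_*``: individuals
    with data.  Components are summed over alleles.
    """
    r = 2
    nbar = (n_a + n_b) / r
    if nbar <= 1 or min(n_a, n_b) == 0:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for j in range(len(counts_a)):
        p_a = counts_a[j] / (2 * n_a)
        p_b = counts_b[j] / (2 * n_b)
        pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue  # monomorphic across both groups: zero components
        s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / (
            (r - 1) * nbar
        )
        hbar = (het_a[j] / n_a * n_a + het_b[j] / n_b * n_b) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A, B, C


def pairwise_fst(
    table: GenotypeTable, group_a: str, group_b: str, grouping: str = "group"
) -> FstResult:
    """Two-population Weir–Cockerham θ per locus and over loci.

    Multiallelic loci sum the a/b/c components over alleles; the multi-locus
    estimate is ``Σa / Σ(a+b+c)`` over loci.  Loci monomorphic across both
    groups contribute nothing (NaN per-locus, excluded from the ratio).
    """
    if group_a == group_b:
        per = pd.Series(0.0, index=table.marker_ids)
        comp = pd.DataFrame(0.0, index=table.marker_ids, columns=list("abc"))
        return FstResult(group_a, group_b, per, comp, 0.0)
    labels = table.samples[grouping]
    aidx = table.allele_index()
    rows_a = (labels == group_a).to_numpy()
    rows_b = (labels == group_b).to_numpy()
    if rows_a.sum() < 2 or rows_b.sum() < 2:
        raise ValueError("both groups need at least two individuals")
    comp_rows = []
    theta = []
    for j in range(table.n_loci):
        stats = []
        for rows in (rows_a, rows_b):
            sub = aidx[rows, j, :]
            ok = sub[:, 0] >= 0
            sub = sub[ok]
            counts = np.bincount(sub.ravel(), minlength=MAX_ALLELE)
            het = np.array(
                [
                    ((sub[:, 0] != sub[:, 1]) & np.any(sub == al, axis=1)).sum()
                    for al in range(MAX_ALLELE)
                ]
            )
            stats.append((counts, het, len(sub)))
        (ca, ha, na), (cb, hb, nb) = stats
        a, b, c = _wc_components(ca, cb, ha, hb, na, nb)
        comp_rows.append((a, b, c))
        denom = a + b + c
        theta.append(a / denom if denom > 0 else np.nan)
    comp = pd.DataFrame(comp_rows, index=table.marker_ids, columns=list("abc"))
    per = pd.Series(theta, index=table.marker_ids, name="theta")
    denom = comp.to_numpy().sum()
    multi = float(comp["a"].sum() / denom) if denom > 0 else float("nan")
    return FstResult(group_a, group_b, per, comp, multi)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def genotype_counts(
    table: GenotypeTable, group: str, marker_id: str, grouping: str = "group"
) -> dict[tuple[int, int], int]:
    """Observed genotype counts (sorted allele-code pairs) for one locus."""
    li = table.marker_ids.index(marker_id)
    rows = (table.samples[grouping] == group).to_numpy()
    sub = table.calls[rows, li, :]
    sub = sub[sub[:, 0] != MISSING]
    out: dict[tuple[int, int], int] = {}
    for a, b in np.sort(sub, axis=1):
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


def _biallelic_exact_p(n_het: int, n1: int, n2: int) -> float:
    """Conditional exact HWE p-value at a biallelic locus, full enumeration.

    Under the null, the probability of ``h`` heterozygotes given allele
    counts ``n1, n2`` in ``n = (n1+n2)/2`` diploids is

        P(h) = C * n! / (n11! h! n22!) * 2^h,   n11=(n1-h)/2, n22=(n2-h)/2.

    Tables with probability ≤ that of the observed table (inclusive) count
    toward the tail.
    """
    n = (n1 + n2) // 2
    hs = np.arange(n1 % 2, min(n1, n2) + 1, 2)
    n11 = (n1 - hs) // 2
    n22 = (n2 - hs) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n11 + 1)
        - gammaln(hs + 1)
        - gammaln(n22 + 1)
        + hs * math.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hs == n_het][0]
    return float(min(p[p <= obs * (1 + 1e-12)].sum(), 1.0))


def _table_logprob_stat(
    cell_counts: np.ndarray, het_mask: np.ndarray
) -> np.ndarray:
    """Monotone transform of the conditional genotype-table probability.

    Up to terms fixed by the allele counts, ``ln P(table) =
    -Σ ln n_cell! + H ln 2`` where H is the heterozygote count.  Works on a
    trailing cells axis so permutation batches vectorize.
    """
    return (-gammaln(cell_counts + 1.0)).sum(axis=-1) + math.log(2.0) * (
        cell_counts * het_mask
    ).sum(axis=-1)


def hwe_exact(
    counts: Mapping[tuple[int, int], int],
    n_perm: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Exact test of Hardy–Weinberg equilibrium for one locus in one group.

    Biallelic counts use full enumeration over heterozygote numbers;
    counts with three or more alleles use a seeded Monte-Carlo shuffle of
    the allele copies (Guo–Thompson style) with the same inclusive
    probability-ordering rule, returning ``(1 + exceedances) / (n_perm + 1)``.

    Returns NaN (with a warning) when no genotypes are observed.
    """
    total = sum(counts.values())
    if total == 0:
        warnings.warn("HWE test undefined: no observed genotypes", stacklevel=2)
        return float("nan")
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) == 1:
        return 1.0
    if len(alleles) == 2:
        a1, a2 = alleles
        n11 = counts.get((a1, a1), 0)
        het = counts.get((a1, a2), 0) + counts.get((a2, a1), 0)
        n22 = counts.get((a2, a2), 0)
        n1 = 2 * n11 + het
        n2 = 2 * n22 + het
        return _biallelic_exact_p(het, n1, n2)
    return _hwe_monte_carlo(counts, alleles, n_perm, seed)


def _hwe_monte_carlo(
    counts: Mapping[tuple[int, int], int],
    alleles: list[int],
    n_perm: int,
    seed: int | None,
) -> float:
    rng = np.random.default_rng(seed)
    amap = {a: i for i, a in enumerate(alleles)}
    J = len(alleles)
    ncell = J * (J + 1) // 2
    cell_of = {}
    het_mask = np.zeros(ncell)
    k = 0
    for i in range(J):
        for j in range(i, J):
            cell_of[(i, j)] = k
            het_mask[k] = 1.0 if i != j else 0.0
            k += 1
    obs_cells = np.zeros(ncell)
    pool = []
    for (a, b), c in counts.items():
        i, j = sorted((amap[a], amap[b]))
        obs_cells[cell_of[(i, j)]] += c
        pool.extend([i] * c + [j] * c)
    obs_stat = _table_logprob_stat(obs_cells, het_mask)
    pool_arr = np.array(pool, dtype=np.int8)
    n = len(pool_arr) // 2
    exceed = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(len(pool_arr), 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        mat = np.tile(pool_arr, (b, 1))
        mat = rng.permuted(mat, axis=1)
        lo = np.minimum(mat[:, ::2], mat[:, 1::2]).astype(np.int64)
        hi = np.maximum(mat[:, ::2], mat[:, 1::2]).astype(np.int64)
        # unordered-pair cell index: offset(lo) + (hi - lo)
        offset = (lo * (2 * J - lo + 1)) // 2
        cell = offset + (hi - lo)
        flat = cell + (np.arange(b)[:, None] * ncell)
        tables = np.bincount(flat.ravel(), minlength=b * ncell).reshape(
            b, ncell
        )
        stats = _table_logprob_stat(tables.astype(float), het_mask)
        exceed += int((stats <= obs_stat + 1e-9).sum())
        done += b
    return (1 + exceed) / (n_perm + 1)


def hwe_scan(
    table: GenotypeTable,
    grouping: str = "group",
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """HWE exact test for every (group, locus); adds Bonferroni threshold.

    Returns a DataFrame (group, marker_id, n, p_value, bonferroni_alpha,
    significant) where the Bonferroni level is 0.05 / number of defined
    tests.
    """
    groups = sorted(table.samples[grouping].unique())
    rows = []
    for gi, grp in enumerate(groups):
        for mid in table.marker_ids:
            counts = genotype_counts(table, grp, mid, grouping)
            n = sum(counts.values())
            if n == 0:
                p = float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = hwe_exact(
                        counts, n_perm=n_perm,
                        seed=seed + 7919 * gi + hash(mid) % 1000,
                    )
            rows.append({"group": grp, "marker_id": mid, "n": n, "p_value": p})
    df = pd.DataFrame(rows)
    n_tests = int(df["p_value"].notna().sum())
    alpha = 0.05 / max(n_tests, 1)
    df["bonferroni_alpha"] = alpha
    df["significant"] = df["p_value"] < alpha
    return df


# ---------------------------------------------------------------------------
# two-locus LD: EM haplotype frequencies + permutation LR test
# ---------------------------------------------------------------------------

def _phase_decomposition(JA: int, JB: int):
    """Enumerate genotype-pair cells and their haplotype phasings.

    Returns (cells, phasings) where ``cells`` maps an (gA, gB) genotype-cell
    pair index to its list of phasings; each phasing is
    ``(hap1, hap2, weight)`` with haplotypes as flat indices ``x * JB + y``
    and weight 2 for an unordered pair of distinct haplotypes, 1 for a
    homozygous pair.
    """
    gA = [(i, j) for i in range(JA) for j in range(i, JA)]
    gB = [(i, j) for i in range(JB) for j in range(i, JB)]
    cells = []
    for ia, (a1, a2) in enumerate(gA):
        for ib, (b1, b2) in enumerate(gB):
            phasings = []
            if a1 == a2 and b1 == b2:
                phasings.append((a1 * JB + b1, a1 * JB + b1, 1.0))
            elif a1 == a2:
                phasings.append((a1 * JB + b1, a1 * JB + b2, 2.0))
            elif b1 == b2:
                phasings.append((a1 * JB + b1, a2 * JB + b1, 2.0))
            else:
                phasings.append((a1 * JB + b1, a2 * JB + b2, 2.0))
                phasings.append((a1 * JB + b2, a2 * JB + b1, 2.0))
            cells.append(((ia, ib), phasings))
    return gA, gB, cells


def _em_lr_batch(
    N: np.ndarray, JA: int, JB: int, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Likelihood-ratio statistics for a batch of genotype-pair count tables.

    ``N`` has shape (B, nGA, nGB).  For each table the EM algorithm fits
    unrestricted haplotype frequencies; the null fixes haplotype frequencies
    at the product of the marginal allele frequencies.  Returns
    ``2 (l1 - l0)`` per table.
    """
    B = N.shape[0]
    gA, gB, cells = _phase_decomposition(JA, JB)
    ntot = N.sum(axis=(1, 2))  # individuals per table
    two_n = 2.0 * ntot
    # marginal allele frequencies (invariant under permutation of locus B)
    pA = np.zeros((B, JA))
    for ia, (a1, a2) in enumerate(gA):
        cnt = N[:, ia, :].sum(axis=1)
        pA[:, a1] += cnt
        pA[:, a2] += cnt
    pB = np.zeros((B, JB))
    for ib, (b1, b2) in enumerate(gB):
        cnt = N[:, :, ib].sum(axis=1)
        pB[:, b1] += cnt
        pB[:, b2] += cnt
    pA /= two_n[:, None]
    pB /= two_n[:, None]

    H = JA * JB
    h0 = (pA[:, :, None] * pB[:, None, :]).reshape(B, H)

    def loglik(h: np.ndarray) -> np.ndarray:
        ll = np.zeros(B)
        for (ia, ib), phasings in cells:
            n_cell = N[:, ia, ib]
            if not n_cell.any():
                continue
            prob = np.zeros(B)
            for u, v, w in phasings:
                prob += w * h[:, u] * h[:, v]
            mask = n_cell > 0
            ll[mask] += n_cell[mask] * np.log(np.maximum(prob[mask], 1e-300))
        return ll

    active = [
        (cell, phasings) for cell, phasings in cells
        if N[:, cell[0], cell[1]].any()
    ]
    h = h0.copy()
    for _ in range(max_iter):
        newc = np.zeros((B, H))
        for (ia, ib), phasings in active:
            n_cell = N[:, ia, ib]
            probs = [w * h[:, u] * h[:, v] for u, v, w in phasings]
            tot = np.maximum(sum(probs), 1e-300)
            for (u, v, _w), pr in zip(phasings, probs):
                share = n_cell * pr / tot
                newc[:, u] += share
                newc[:, v] += share
        h_new = newc / np.maximum(two_n[:, None], 1.0)
        # keep each row on the simplex despite float rounding
        h_new /= np.maximum(h_new.sum(axis=1, keepdims=True), 1e-300)
        delta_h = np.max(np.abs(h_new - h))
        h = h_new
        if delta_h < 1e-8:
            break
    lr = 2.0 * (loglik(h) - loglik(h0))
    return np.maximum(lr, 0.0)


def _pair_genotype_codes(
    table: GenotypeTable, group: str, li: int, lj: int, grouping: str,
    aidx_full: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-individual genotype-cell codes at two loci (complete cases only)."""
    rows = (table.samples[grouping] == group).to_numpy()
    if aidx_full is None:
        aidx_full = table.allele_index()
    aidx = aidx_full[rows][:, [li, lj], :]
    ok = (aidx[:, 0, 0] >= 0) & (aidx[:, 1, 0] >= 0)
    aidx = aidx[ok]
    JA = max(table.panel[li].allele_codes)
    JB = max(table.panel[lj].allele_codes)

    def codes(pairs: np.ndarray, J: int) -> np.ndarray:
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        return (lo * (2 * J - lo + 1)) // 2 + (hi - lo)

    return codes(aidx[:, 0, :], JA), codes(aidx[:, 1, :], JB), JA, JB


def _count_tables(
    cA: np.ndarray, cB: np.ndarray, nGA: int, nGB: int
) -> np.ndarray:
    """Joint genotype-cell count tables; cB may be (B, n) permutation rows."""
    if cB.ndim == 1:
        cB = cB[None, :]
    B = cB.shape[0]
    joint = cA[None, :] * nGB + cB
    joint = joint + np.arange(B)[:, None] * (nGA * nGB)
    return np.bincount(joint.ravel(), minlength=B * nGA * nGB).reshape(
        B, nGA, nGB
    ).astype(float)


def ld_test(
    table: GenotypeTable,
    group: str,
    marker_a: str,
    marker_b: str,
    n_perm: int = 100_000,
    seed: int = 0,
    grouping: str = "group",
    _early_stop: int | None = None,
    _aidx: np.ndarray | None = None,
) -> float:
    """Permutation LR test of gametic association between two loci.

    The observed statistic is twice the log-likelihood gain of EM-fitted
    haplotype frequencies over linkage equilibrium (product of single-locus
    frequencies).  The null distribution permutes one locus's genotypes
    across individuals; ``p = (1 + #{perm LR ≥ observed}) / (n_perm + 1)``.

    With ``_early_stop = m`` the permutation stream stops once ``m``
    exceedances accumulate (the p-value is then conservative but already far
    above any scan threshold); used by :func:`ld_scan`.
    """
    li = table.marker_ids.index(marker_a)
    lj = table.marker_ids.index(marker_b)
    cA, cB, JA, JB = _pair_genotype_codes(table, group, li, lj, grouping, _aidx)
    n = len(cA)
    if n < 5:
        raise ValueError(
            f"fewer than 5 complete observations for {marker_a}/{marker_b} "
            f"in {group}"
        )
    nGA = JA * (JA + 1) // 2
    nGB = JB * (JB + 1) // 2
    if len(np.unique(cA)) == 1 or len(np.unique(cB)) == 1:
        warnings.warn(
            f"monomorphic locus in {group}: LD test for "
            f"{marker_a}/{marker_b} returns p = 1",
            stacklevel=2,
        )
        return 1.0
    obs = _em_lr_batch(_count_tables(cA, cB, nGA, nGB), JA, JB)[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    # small first batches let clearly-null pairs stop early during scans
    schedule = [64, 192, 768] if _early_stop is not None else []
    while done < n_perm:
        batch = schedule.pop(0) if schedule else 2000
        b = min(batch, n_perm - done)
        perm = rng.permuted(np.tile(cB, (b, 1)), axis=1)
        lrs = _em_lr_batch(_count_tables(cA, perm, nGA, nGB), JA, JB)
        exceed += int((lrs >= obs - 1e-9).sum())
        done += b
        if _early_stop is not None and exceed >= _early_stop:
            break
    return (1 + exceed) / (done + 1)


def ld_scan(
    table: GenotypeTable,
    grouping: str = "group",
    n_perm: int = 10_000,
    seed: int = 0,
    early_stop: int | None = 20,
) -> pd.DataFrame:
    """All-pairs within-group LD permutation scan with Bonferroni control.

    Pairs are tested separately within each reference group (pooling groups
    would manufacture associations from population structure).  Monomorphic
    or data-poor pairs are skipped with ``p = NaN``.
    """
    groups = sorted(table.samples[grouping].unique())
    mids = table.marker_ids
    aidx = table.allele_index()
    rows = []
    test_id = 0
    for grp in groups:
        for a, b in itertools.combinations(mids, 2):
            test_id += 1
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = ld_test(
                        table, grp, a, b,
                        n_perm=n_perm,
                        seed=seed + test_id,
                        grouping=grouping,
                        _early_stop=early_stop,
                        _aidx=aidx,
                    )
            except ValueError:
                p = float("nan")
            rows.append(
                {"group": grp, "marker_a": a, "marker_b": b, "p_value": p}
            )
    df = pd.DataFrame(rows)
    n_tests = int(df["p_value"].notna().sum())
    alpha = 0.05 / max(n_tests, 1)
    df["bonferroni_alpha"] = alpha
    df["significant"] = df["p_value"] < alpha
    return df
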
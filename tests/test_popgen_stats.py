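"""Marker statistics: frequencies, delta, Fst, HWE and LD tests."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from aimpanel.data_io import GenotypeTable, LocusDef
from aimpanel.popgen_stats import (
    _biallelic_exact_p,
    _wc_components,
    allele_frequencies,
    delta,
    genotype_counts,
    hwe_exact,
    hwe_scan,
    ld_test,
    pairwise_fst,
    rank_markers,
)
from aimpanel.synthetic_data import (
    SimBlock,
    SimConfig,
    make_panel_frequencies,
    simulate_cohort,
)


def table_from_genotypes(genos, group="G", panel=None):
    """Build a one-locus-per-column table from a dict group -> list of calls."""
    loci = panel or [LocusDef(f"L{j+1}") for j in range(len(next(iter(genos.values()))[0]))]
    rows, calls = [], []
    i = 0
    for grp, inds in genos.items():
        for pairs in inds:
            rows.append((f"s{i}", grp, grp, 0))
            calls.append(pairs)
            i += 1
    samples = pd.DataFrame(
        rows, columns=["sample_id", "population", "group", "popflag"]
    )
    return GenotypeTable(loci, samples, np.array(calls, dtype=np.int16))


# ---------------------------------------------------------------- frequencies

def test_allele_frequencies_small_counts():
    t = table_from_genotypes({"G": [[(1, 1)]]})
    ft = allele_frequencies(t)
    assert ft.freqs[0, 0, 0] == 1.0
    t2 = table_from_genotypes({"G": [[(1, 2)], [(1, 1)]]})
    ft2 = allele_frequencies(t2)
    assert ft2.freqs[0, 0, 0] == pytest.approx(0.75)
    assert ft2.n_copies[0, 0] == 4


def test_allele_frequencies_consistent_at_large_n():
    ft = make_panel_frequencies(1, [0.4], K=2, seed=5)
    ft.freqs[0, 0] = [0.3, 0.7, 0.0]
    cohort = simulate_cohort(
        SimConfig(ft, [SimBlock(n=5000, label="G1", group="G1")], seed=11)
    )
    est = allele_frequencies(cohort.table)
    assert abs(est.freqs[0, 0, 0] - 0.3) < 0.02


# ---------------------------------------------------------------------- delta

def test_delta_basic_values():
    assert delta([0.5, 0.5], [0.5, 0.5]) == 0.0
    assert delta([1.0, 0.0], [0.0, 1.0]) == 1.0
    assert delta([0.9, 0.1], [0.1, 0.9]) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        delta([0.5, 0.5], [0.3, 0.3, 0.4])


@pytest.mark.parametrize("seed", range(5))
def test_delta_symmetry_and_bounds(seed, rng):
    r = np.random.default_rng(seed)
    pA = r.dirichlet([1, 1, 1])
    pB = r.dirichlet([1, 1, 1])
    d = delta(pA, pB)
    assert d == pytest.approx(delta(pB, pA))
    assert 0.0 <= d <= 1.0


def test_rank_markers_is_permutation_and_sorted(fixture_cohort):
    ft = allele_frequencies(fixture_cohort.table)
    df = rank_markers(ft)
    assert sorted(df["marker_id"]) == sorted(
        l.marker_id for l in ft.panel
    )
    md = df["max_delta"].to_numpy()
    assert (md[:-1] >= md[1:] - 1e-12).all()
    pair_cols = [c for c in df.columns if c.startswith("delta:")]
    assert (
        df[pair_cols].max(axis=1).to_numpy()
        == pytest.approx(md)
    )


def test_rank_markers_identical_groups_all_zero():
    t = table_from_genotypes(
        {"A": [[(1, 2)], [(1, 1)]], "B": [[(1, 2)], [(1, 1)]]}
    )
    df = rank_markers(allele_frequencies(t))
    assert (df["max_delta"] == 0).all()


# ----------------------------------------------------------------------- Fst

def wc_theta_oracle(geno_a, geno_b):
    """Raw-ANOVA Weir–Cockerham theta from per-copy 0/1 indicators."""
    pops = [geno_a, geno_b]
    alleles = sorted({a for g in pops for pair in g for a in pair})
    r = 2
    n = [len(g) for g in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for al in alleles:
        y = [[[1.0 if a == al else 0.0 for a in pair] for pair in g]
             for g in pops]
        ybar_ij = {
            (i, j): sum(y[i][j]) / 2 for i in range(r) for j in range(n[i])
        }
        ybar_i = [
            sum(ybar_ij[(i, j)] for j in range(n[i])) / n[i] for i in range(r)
        ]
        ybar = sum(n[i] * ybar_i[i] for i in range(r)) / sum(n)
        ssg = sum(
            (y[i][j][k] - ybar_ij[(i, j)]) ** 2
            for i in range(r) for j in range(n[i]) for k in range(2)
        )
        ssi = 2 * sum(
            (ybar_ij[(i, j)] - ybar_i[i]) ** 2
            for i in range(r) for j in range(n[i])
        )
        ssp = 2 * sum(n[i] * (ybar_i[i] - ybar) ** 2 for i in range(r))
        msg = ssg / sum(n)
        msi = ssi / sum(x - 1 for x in n)
        msp = ssp / (r - 1)
        s_g = msg
        s_i = (msi - msg) / 2
        s_p = (msp - msi) / (2 * nc)
        num += s_p
        den += s_p + s_i + s_g
    return num / den


@pytest.mark.parametrize("seed", range(4))
def test_fst_matches_anova_oracle(seed):
    r = np.random.default_rng(seed)
    ga = [tuple(r.integers(1, 4, 2)) for _ in range(12)]
    gb = [tuple(r.integers(1, 3, 2)) for _ in range(9)]
    panel = [LocusDef("L1", (1, 2, 3))]
    t = table_from_genotypes(
        {"A": [[g] for g in ga], "B": [[g] for g in gb]}, panel=panel
    )
    res = pairwise_fst(t, "A", "B")
    assert res.theta == pytest.approx(wc_theta_oracle(ga, gb), abs=1e-12)


def test_fst_fixed_difference_is_one():
    t = table_from_genotypes(
        {"A": [[(1, 1)]] * 4, "B": [[(2, 2)]] * 4}
    )
    res = pairwise_fst(t, "A", "B")
    assert res.per_locus.iloc[0] == pytest.approx(1.0)


def test_fst_null_near_zero():
    ft = make_panel_frequencies(46, [0.5] * 46, K=2, seed=3)
    ft.freqs[1] = ft.freqs[0]  # identical groups: true theta 0
    cohort = simulate_cohort(
        SimConfig(
            ft,
            [SimBlock(n=100, label="G1", group="G1"),
             SimBlock(n=100, label="G2", group="G2")],
            seed=21,
        )
    )
    res = pairwise_fst(cohort.table, "G1", "G2")
    assert abs(res.theta) < 0.02


def test_fst_symmetry_and_label_invariance():
    r = np.random.default_rng(8)
    ga = [tuple(r.integers(1, 3, 2)) for _ in range(10)]
    gb = [tuple(r.integers(1, 3, 2)) for _ in range(10)]
    t = table_from_genotypes({"A": [[g] for g in ga], "B": [[g] for g in gb]})
    fwd = pairwise_fst(t, "A", "B").theta
    rev = pairwise_fst(t, "B", "A").theta
    assert fwd == pytest.approx(rev, abs=1e-14)
    swap = {1: 2, 2: 1}
    ga2 = [(swap[a], swap[b]) for a, b in ga]
    gb2 = [(swap[a], swap[b]) for a, b in gb]
    t2 = table_from_genotypes(
        {"A": [[g] for g in ga2], "B": [[g] for g in gb2]}
    )
    assert pairwise_fst(t2, "A", "B").theta == pytest.approx(fwd, abs=1e-14)


def test_fst_monomorphic_locus_excluded_not_nan():
    t = table_from_genotypes(
        {"A": [[(1, 1), (1, 2)]] * 3, "B": [[(1, 1), (2, 2)]] * 3}
    )
    res = pairwise_fst(t, "A", "B")
    assert np.isnan(res.per_locus.iloc[0])  # monomorphic across both
    assert np.isfinite(res.theta)


# ----------------------------------------------------------------------- HWE

def hwe_oracle(n11, n12, n22):
    """Exact-rational enumeration of the conditional heterozygote law."""
    n = n11 + n12 + n22
    n1, n2 = 2 * n11 + n12, 2 * n22 + n12
    def weight(h):
        a, b = (n1 - h) // 2, (n2 - h) // 2
        return Fraction(factorial(n) * 2**h,
                        factorial(a) * factorial(h) * factorial(b))
    hs = range(n1 % 2, min(n1, n2) + 1, 2)
    probs = {h: weight(h) for h in hs}
    tot = sum(probs.values())
    obs = probs[n12]
    return float(sum(p for p in probs.values() if p <= obs) / tot)


def test_hwe_exact_equals_oracle_full_sweep_n_le_20():
    for n in range(1, 21):
        for n11 in range(n + 1):
            for n12 in range(n - n11 + 1):
                n22 = n - n11 - n12
                if 2 * n11 + n12 == 0 or 2 * n22 + n12 == 0:
                    continue
                p = _biallelic_exact_p(n12, 2 * n11 + n12, 2 * n22 + n12)
                assert p == pytest.approx(
                    hwe_oracle(n11, n12, n22), abs=1e-10
                ), (n11, n12, n22)


def test_hwe_single_heterozygote_is_one():
    assert hwe_exact({(1, 2): 1}) == 1.0


def test_hwe_all_missing_flagged():
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(hwe_exact({}))


def test_hwe_monte_carlo_matches_exact_on_collapsed_triallelic():
    # counts involving three alleles where one is absent from het classes
    # small enough to cross-check against a biallelic margin: use a
    # genuinely triallelic table and verify MC stability across seeds
    counts = {(1, 1): 6, (1, 2): 8, (2, 2): 4, (1, 3): 2, (3, 3): 1}
    p1 = hwe_exact(counts, n_perm=40_000, seed=1)
    p2 = hwe_exact(counts, n_perm=40_000, seed=2)
    assert 0 < p1 <= 1
    assert p1 == pytest.approx(p2, abs=0.02)


def test_hwe_scan_has_row_per_group_locus(main4):
    df = hwe_scan(main4, n_perm=2_000, seed=0)
    assert len(df) == 4 * 46
    assert df["p_value"].dropna().between(0, 1).all()


# ------------------------------------------------------------------------ LD

def two_locus_table(n, pA, pB, seed, group="G"):
    ft = make_panel_frequencies(2, [0.0, 0.0], K=2, seed=seed)
    ft.freqs[0, 0] = [pA, 1 - pA, 0]
    ft.freqs[0, 1] = [pB, 1 - pB, 0]
    cohort = simulate_cohort(
        SimConfig(ft, [SimBlock(n=n, label=group, group="G1")], seed=seed)
    )
    return cohort.table


def test_ld_duplicate_locus_minimal_p():
    r = np.random.default_rng(4)
    genos = [[(a, b), (a, b)] for a, b in r.integers(1, 3, (40, 2))]
    t = table_from_genotypes({"G": genos})
    n_perm = 200
    p = ld_test(t, "G", "L1", "L2", n_perm=n_perm, seed=0)
    assert p == pytest.approx(1 / (n_perm + 1))


def test_ld_monomorphic_locus_returns_one():
    genos = [[(1, 1), (1, 2)], [(1, 1), (2, 2)], [(1, 1), (1, 1)],
             [(1, 1), (1, 2)], [(1, 1), (2, 2)]]
    t = table_from_genotypes({"G": genos})
    with pytest.warns(UserWarning, match="monomorphic"):
        assert ld_test(t, "G", "L1", "L2", n_perm=100, seed=0) == 1.0


def test_ld_type_one_error_rate_under_independence():
    """Independently simulated locus pairs give uniform-ish p-values."""
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        t = two_locus_table(200, 0.4, 0.6, seed=1000 + rep)
        p = ld_test(t, "G", "SIM-1", "SIM-2", n_perm=199, seed=rep)
        hits += p < 0.05
    assert 0.02 <= hits / n_rep <= 0.09
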
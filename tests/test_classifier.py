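"""Naive-Bayes assignment, likelihood ratios and LOOCV."""

import math

import numpy as np
import pandas as pd
import pytest

from aimpanel.classifier import classify, loocv, profile_loglik, train
from aimpanel.data_io import GenotypeTable, LocusDef, MISSING
from aimpanel.synthetic_data import (
    SimBlock,
    SimConfig,
    make_panel_frequencies,
    simulate_cohort,
)
from tests.test_popgen_stats import table_from_genotypes


def test_smoothed_frequencies_arithmetic():
    t = table_from_genotypes({"A": [[(1, 1)], [(1, 1)]], "B": [[(1, 2)], [(2, 2)]]})
    model = train(t, pseudocount=1.0)
    # group A: counts (4, 0) with c=1 over two alleles -> (5/6, 1/6)
    f = model.frequencies()
    a = model.groups.index("A")
    assert f[a, 0, 0] == pytest.approx(5 / 6)
    assert f[a, 0, 1] == pytest.approx(1 / 6)


def test_zero_pseudocount_gives_ml_frequencies():
    t = table_from_genotypes({"A": [[(1, 2)], [(1, 1)]], "B": [[(2, 2)], [(1, 2)]]})
    f = train(t, pseudocount=0.0).frequencies()
    a = 0
    assert f[a, 0, 0] == pytest.approx(0.75)
    assert np.allclose(f[:, 0, :2].sum(axis=1), 1.0)


def test_frequencies_sum_to_one_any_pseudocount(fixture_cohort):
    for c in (0.5, 1.0, 3.0):
        f = train(fixture_cohort.table, pseudocount=c).frequencies()
        sums = f.sum(axis=2)
        assert np.allclose(sums, 1.0)


def test_profile_loglik_hand_values():
    t = table_from_genotypes({"A": [[(1, 2)], [(1, 2)]], "B": [[(1, 1)], [(1, 1)]]})
    model = train(t, pseudocount=1.0)
    # force p~ = 0.5 by symmetric counts in group A: counts (2,2), c=1 -> (0.5, 0.5)
    a = model.groups.index("A")
    f = model.frequencies()
    assert f[a, 0, 0] == pytest.approx(0.5)
    ll = profile_loglik(model, np.array([[1, 1]]))
    assert ll["A"] == pytest.approx(math.log(0.25))
    ll_het = profile_loglik(model, np.array([[1, 2]]))
    assert ll_het["A"] == pytest.approx(math.log(0.5))


def test_profile_loglik_matches_product_oracle():
    genos = {"A": [[(1, 1), (1, 2), (2, 2)], [(1, 2), (1, 1), (2, 2)]],
             "B": [[(2, 2), (2, 2), (1, 1)], [(1, 2), (2, 2), (1, 2)]]}
    t = table_from_genotypes(genos)
    model = train(t, pseudocount=1.0)
    f = model.frequencies()
    profile = np.array([[1, 2], [2, 2], [1, 2]])
    ll = profile_loglik(model, profile)
    for g, name in enumerate(model.groups):
        expected = 1.0
        for j, (a, b) in enumerate(profile):
            pa, pb = f[g, j, a - 1], f[g, j, b - 1]
            expected *= (2 * pa * pb) if a != b else pa * pb
        assert ll[name] == pytest.approx(math.log(expected))


def test_classification_strength_on_informative_panel():
    """Profiles drawn from a group's own frequencies win with large LRs."""
    ft = make_panel_frequencies(46, [0.5] * 46, K=2, seed=7)
    train_cohort = simulate_cohort(
        SimConfig(
            ft,
            [SimBlock(n=100, label="G1", group="G1"),
             SimBlock(n=100, label="G2", group="G2")],
            seed=1,
        )
    )
    model = train(train_cohort.table)
    probes = simulate_cohort(
        SimConfig(ft, [SimBlock(n=1000, label="G1", group="G1")], seed=2)
    ).table
    wins = strong = 0
    for i in range(probes.n_individuals):
        res = classify(model, probes.calls[i])
        wins += res.best == "G1"
        strong += res.best == "G1" and res.lr > 1e3
    assert wins >= 990
    assert strong >= 950


def test_identical_groups_tie_flagged():
    t = table_from_genotypes({"A": [[(1, 2)], [(1, 1)]], "B": [[(1, 2)], [(1, 1)]]})
    model = train(t)
    res = classify(model, np.array([[1, 2]]))
    assert res.tie
    assert res.lr == 1.0
    assert res.best == "A"  # lexicographic winner


def test_all_missing_profile_flagged_undefined():
    t = table_from_genotypes({"A": [[(1, 2)], [(1, 1)]], "B": [[(2, 2)], [(1, 2)]]})
    res = classify(train(t), np.array([[MISSING, MISSING]]))
    assert res.undefined
    assert res.n_loci_used == 0


def test_loocv_decrement_equals_full_retrain():
    ft = make_panel_frequencies(8, [0.4] * 8, K=3, seed=2)
    cohort = simulate_cohort(
        SimConfig(
            ft,
            [SimBlock(n=8, label=g, group=g) for g in ft.groups],
            missing_rate=0.05,
            seed=3,
        )
    )
    t = cohort.table
    fast = loocv(t)
    # brute-force LOOCV: full retrain per fold
    preds = []
    for i in range(t.n_individuals):
        keep = np.ones(t.n_individuals, bool)
        keep[i] = False
        model = train(t.subset(keep))
        preds.append(classify(model, t.calls[i]).best)
    assert preds == fast.assignments["predicted"].tolist()


def test_uninformative_locus_never_changes_assignment():
    ft = make_panel_frequencies(10, [0.5] * 10, K=2, seed=4)
    cohort = simulate_cohort(
        SimConfig(
            ft,
            [SimBlock(n=15, label=g, group=g) for g in ft.groups],
            seed=5,
        )
    )
    t = cohort.table
    base = [r.best for r in map(
        lambda i: classify(train(t), t.calls[i]), range(t.n_individuals)
    )]
    # append a locus with identical frequencies in both groups
    panel2 = list(t.panel) + [LocusDef("FLAT")]
    rng = np.random.default_rng(6)
    extra = rng.integers(1, 3, (t.n_individuals, 1, 2)).astype(np.int16)
    t2 = GenotypeTable(
        panel2, t.samples.copy(), np.concatenate([t.calls, extra], axis=1)
    )
    # force exactly equal counts at FLAT by constructing them symmetric
    t2.calls[:, -1, 0] = 1
    t2.calls[:, -1, 1] = 2
    after = [classify(train(t2), t2.calls[i]).best
             for i in range(t2.n_individuals)]
    assert base == after


def test_invariance_to_locus_order_and_allele_relabel():
    ft = make_panel_frequencies(6, [0.5] * 6, K=2, seed=8)
    cohort = simulate_cohort(
        SimConfig(ft, [SimBlock(n=12, label=g, group=g) for g in ft.groups],
                  seed=9)
    )
    t = cohort.table
    model = train(t)
    results = [classify(model, t.calls[i]).best for i in range(12)]
    # permute loci
    perm = np.random.default_rng(1).permutation(t.n_loci)
    t_perm = GenotypeTable(
        [t.panel[j] for j in perm], t.samples.copy(), t.calls[:, perm, :]
    )
    model_p = train(t_perm)
    results_p = [classify(model_p, t_perm.calls[i]).best for i in range(12)]
    assert results == results_p
    # swap allele labels consistently everywhere
    swapped = t.calls.copy()
    swapped[t.calls == 1] = 2
    swapped[t.calls == 2] = 1
    t_swap = GenotypeTable(list(t.panel), t.samples.copy(), swapped)
    model_s = train(t_swap)
    results_s = [classify(model_s, t_swap.calls[i]).best for i in range(12)]
    assert results == results_s


def test_loocv_perfectly_separated_groups_zero_error():
    genos = {
        "A": [[(1, 1), (1, 1)]] * 5,
        "B": [[(2, 2), (2, 2)]] * 5,
    }
    t = table_from_genotypes(genos)
    res = loocv(t)
    assert res.n_errors == 0
    assert res.error_rate == 0.0


def test_loocv_requires_two_per_group():
    t = table_from_genotypes({"A": [[(1, 1)]], "B": [[(2, 2)], [(2, 2)]]})
    with pytest.raises(ValueError, match="fewer than 2"):
        loocv(t)
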
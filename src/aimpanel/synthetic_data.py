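"""Synthetic genotype cohorts with the structure the analyses assume.

The generative model mirrors the admixture model exactly: each individual
carries an ancestry vector ``q`` over K ancestral groups; each of its two
allele copies at each locus first draws an ancestral origin ``z ~
Categorical(q)`` and then an allele from that group's frequency vector.
Loci are independent given ``q`` and groups are in Hardy–Weinberg
equilibrium — the idealization under which the inference machinery is
exactly calibrated, which is what makes recovery tests meaningful.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so cohorts are bit-reproducible across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    MAX_ALLELE,
    MISSING,
    FrequencyTable,
    GenotypeTable,
    LocusDef,
)

__all__ = [
    "SimBlock",
    "SimConfig",
    "SimCohort",
    "make_panel_frequencies",
    "simulate_cohort",
    "reference_like_fixture",
    "FIXTURE_SEED",
]

#: seed of the packaged reference-like fixture (stable test surface)
FIXTURE_SEED: int = 46


@dataclass
class SimBlock:
    """One homogeneous slice of a simulated cohort.

    Exactly one of ``group`` (unadmixed from a named ancestral group),
    ``q`` (fixed admixture vector over the frequency table's groups) or
    ``alpha`` (per-individual Dirichlet(α) admixture draws) must be set.
    """

    n: int
    label: str
    group: str | None = None
    q: Sequence[float] | None = None
    alpha: float | Sequence[float] | None = None
    popflag: int = 0

    def __post_init__(self) -> None:
        set_count = sum(x is not None for x in (self.group, self.q, self.alpha))
        if set_count != 1:
            raise ValueError(
                "exactly one of group / q / alpha must be given per block"
            )
        if self.n < 0:
            raise ValueError("block size must be nonnegative")


@dataclass
class SimConfig:
    """Full generative description of a synthetic cohort."""

    freq_table: FrequencyTable
    blocks: list[SimBlock]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimCohort:
    """Simulated genotypes plus the ground truth that produced them."""

    table: GenotypeTable
    true_q: np.ndarray  # (n, K), rows sum to 1
    freq_table: FrequencyTable

    def __post_init__(self) -> None:
        if self.true_q.shape != (
            self.table.n_individuals,
            len(self.freq_table.groups),
        ):
            raise ValueError("true_q shape mismatch")
        if np.abs(self.true_q.sum(axis=1) - 1).max(initial=0) > 1e-9:
            raise ValueError("true_q rows must sum to 1")


def make_panel_frequencies(
    n_loci: int,
    delta_profile: Sequence[float],
    K: int = 4,
    group_names: Sequence[str] | None = None,
    seed: int = 0,
    panel: Sequence[LocusDef] | None = None,
) -> FrequencyTable:
    """Draw per-group biallelic frequencies with prescribed max pairwise δ.

    For each locus two groups (rotating over pairs) are placed at the ends
    of an interval of width ``delta_profile[l]`` and the remaining groups
    are drawn uniformly inside it, so the realized max pairwise δ equals
    the requested value exactly.  Values must lie in [0, 1].
    """
    deltas = np.asarray(delta_profile, float)
    if deltas.shape != (n_loci,):
        raise ValueError("delta_profile must have one value per locus")
    if ((deltas < 0) | (deltas > 1)).any():
        raise ValueError("infeasible delta profile (need 0 <= delta <= 1)")
    if K < 2:
        raise ValueError("need at least two ancestral groups")
    if group_names is None:
        group_names = [f"G{k+1}" for k in range(K)]
    group_names = list(group_names)
    if panel is None:
        width = len(str(n_loci))
        panel = [LocusDef(f"SIM-{i+1:0{width}d}") for i in range(n_loci)]
    panel = list(panel)
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    freqs = np.zeros((K, n_loci, MAX_ALLELE))
    for li in range(n_loci):
        d = deltas[li]
        margin = min(0.02, (1 - d) / 2)
        lo_center, hi_center = d / 2 + margin, 1 - d / 2 - margin
        center = (
            rng.uniform(lo_center, hi_center) if hi_center > lo_center else 0.5
        )
        p_hi, p_lo = center + d / 2, center - d / 2
        a, b = pairs[li % len(pairs)]
        p1 = np.empty(K)
        for k in range(K):
            if k == a:
                p1[k] = p_hi
            elif k == b:
                p1[k] = p_lo
            else:
                p1[k] = rng.uniform(p_lo, p_hi)
        freqs[:, li, 0] = p1
        freqs[:, li, 1] = 1.0 - p1
    return FrequencyTable(group_names, panel, freqs, np.zeros((K, n_loci)))


def add_private_third_allele(
    freqs: FrequencyTable, marker_id: str, group: str, frequency: float
) -> FrequencyTable:
    """Introduce a group-private third allele at one locus.

    The named group's existing allele-1/2 mass is rescaled by
    ``1 - frequency`` and the remainder assigned to allele 3; other groups
    are untouched, so the variant is strictly private.  The locus's declared
    allele codes are extended to (1, 2, 3).
    """
    mids = [loc.marker_id for loc in freqs.panel]
    li = mids.index(marker_id)
    g = freqs.group_index(group)
    new_freqs = freqs.freqs.copy()
    new_freqs[g, li, :2] *= 1.0 - frequency
    new_freqs[g, li, 2] += frequency
    old = freqs.panel[li]
    new_panel = list(freqs.panel)
    new_panel[li] = LocusDef(
        old.marker_id, (1, 2, 3), old.rs_id, old.chromosome,
        old.position_bp, old.note or f"private allele 3 in {group}",
    )
    return FrequencyTable(
        freqs.groups, new_panel, new_freqs, freqs.n_copies.copy()
    )


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Draw a diploid cohort under the admixture generative model."""
    ft = config.freq_table
    groups = ft.groups
    K = len(groups)
    L = len(ft.panel)
    rng = np.random.default_rng(config.seed)

    q_rows: list[np.ndarray] = []
    sample_rows: list[tuple[str, str, int]] = []
    for bi, block in enumerate(config.blocks):
        if block.group is not None:
            if block.group not in groups:
                raise ValueError(
                    f"block {bi}: group {block.group!r} absent from "
                    f"frequency table"
                )
            q = np.zeros((block.n, K))
            q[:, groups.index(block.group)] = 1.0
        elif block.q is not None:
            qv = np.asarray(block.q, float)
            if qv.shape != (K,) or abs(qv.sum() - 1) > 1e-9 or (qv < 0).any():
                raise ValueError(f"block {bi}: q must be a length-{K} simplex")
            q = np.tile(qv, (block.n, 1))
        else:
            alpha = np.broadcast_to(
                np.asarray(block.alpha, float), (K,)
            ).astype(float)
            q = rng.dirichlet(alpha, size=block.n)
        q_rows.append(q)
        for i in range(block.n):
            sample_rows.append(
                (f"{block.label}-{i+1:04d}", block.label, block.popflag)
            )

    true_q = (
        np.concatenate(q_rows) if q_rows else np.empty((0, K))
    )
    n = true_q.shape[0]

    # ancestry of each allele copy: z ~ Categorical(q)
    u = rng.random((n, L, 2))
    cum_q = np.cumsum(true_q, axis=1)  # (n, K)
    z = (cum_q[:, None, None, :] < u[..., None]).sum(axis=3)  # (n, L, 2)
    # allele given ancestry: cumulative frequencies per (group, locus)
    cum_p = np.cumsum(ft.freqs, axis=2)  # (K, L, 3)
    u2 = rng.random((n, L, 2))
    cp = cum_p[z, np.arange(L)[None, :, None], :]  # (n, L, 2, 3)
    alleles = (cp < u2[..., None]).sum(axis=3) + 1  # codes 1..3
    calls = alleles.astype(np.int16)

    if config.missing_rate > 0 and n:
        mask = rng.random((n, L)) < config.missing_rate
        calls[mask] = MISSING

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "population", "popflag"]
    )
    samples["group"] = samples["population"]
    samples = samples[["sample_id", "population", "group", "popflag"]]
    table = GenotypeTable(list(ft.panel), samples, calls)
    return SimCohort(table, true_q, ft)


def _fixture_delta_profile(rng: np.random.Generator) -> np.ndarray:
    """Max-δ profile of the packaged panel-like fixture.

    39 loci with δ ≥ 0.4, five more in [0.3, 0.4) and two weakly
    informative loci — the informativeness structure of a continental
    AIM-INDEL panel whose markers were chosen for δ ≥ 0.4 but partly
    regress on an independent reference sample.
    """
    high = rng.uniform(0.45, 0.90, size=39)
    mid = rng.uniform(0.31, 0.38, size=5)
    low = rng.uniform(0.16, 0.27, size=2)
    profile = np.concatenate([high, mid, low])
    rng.shuffle(profile)
    return profile


def reference_like_fixture(
    seed: int = FIXTURE_SEED,
    n_per_group: int = 60,
    missing_rate: float = 0.005,
    include_oceania: bool = True,
    popflag: int = 1,
) -> SimCohort:
    """A packaged 5-group, 46-locus cohort resembling the reference panel.

    Groups AFR/EUR/EAS/NAM (plus OCE unless disabled) with a δ structure
    matching the panel over the four primary groups, two loci carrying
    group-private third alleles (an AFR-private variant and a EUR-private
    one), unadmixed Hardy–Weinberg individuals and a small missing-data
    rate.  A fixed default seed makes it a stable test fixture.
    """
    rng = np.random.default_rng(seed)
    profile = _fixture_delta_profile(rng)
    main = ["AFR", "EUR", "EAS", "NAM"]
    ft = make_panel_frequencies(
        n_loci=46,
        delta_profile=profile,
        K=4,
        group_names=main,
        seed=int(rng.integers(2**31 - 1)),
    )
    if include_oceania:
        oce = rng.uniform(0.05, 0.95, size=46)
        freqs = np.zeros((5, 46, MAX_ALLELE))
        freqs[:4] = ft.freqs
        freqs[4, :, 0] = oce
        freqs[4, :, 1] = 1.0 - oce
        ft = FrequencyTable(
            main + ["OCE"], ft.panel, freqs, np.zeros((5, 46))
        )
    # group-private third alleles on two strongly differentiated loci
    order = np.argsort(profile)[::-1]
    li_afr, li_eur = int(order[0]), int(order[1])
    ft = add_private_third_allele(
        ft, ft.panel[li_afr].marker_id, "AFR", 0.08
    )
    ft = add_private_third_allele(
        ft, ft.panel[li_eur].marker_id, "EUR", 0.06
    )
    blocks = [
        SimBlock(n=n_per_group, label=g, group=g, popflag=popflag)
        for g in ft.groups
    ]
    cfg = SimConfig(
        freq_table=ft,
        blocks=blocks,
        missing_rate=missing_rate,
        seed=int(rng.integers(2**31 - 1)),
    )
    return simulate_cohort(cfg)
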
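"""Gibbs sampler for the admixture model of population structure.

Model
-----
Each individual *i* has a membership vector ``q_i`` on the K-simplex with a
symmetric Dirichlet(α) prior shared across individuals.  Each allele copy at
locus *l* draws a latent ancestral cluster ``z ~ Categorical(q_i)`` and then
an allele from that cluster's frequency vector ``P_{k,l}``.  Cluster
frequencies carry either independent Dirichlet(λ) priors per cluster
("independent" frequency model) or, in the "correlated" model, a shared
ancestral frequency vector ``p_A,l`` from which each cluster drifts with its
own parameter ``F_k``::

    P_{k,l} ~ Dirichlet( p_{A,l} (1 - F_k) / F_k )

so small ``F_k`` means cluster k hugs the ancestral frequencies.  The chain
alternates conjugate Gibbs updates of z, q and P with Metropolis updates of
α, and of ``F_k`` and ``p_A`` in the correlated model.

Supervised ("use population information") mode fixes flagged training
individuals' membership at the indicator of their labeled cluster; the
``pfrompopflagonly`` option restricts the allele-frequency updates to
flagged individuals' copies, which is the configuration used to estimate
ancestry of test samples against a fixed reference panel.

Model choice across K uses the standard ``lnP(D) ≈ mean(trace) -
var(trace)/2`` approximation from the post-burn-in log-likelihood trace,
and independent replicate runs are reconciled by a least-squares cluster
relabeling before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .data_io import MAX_ALLELE, GenotypeTable

__all__ = [
    "AdmixConfig",
    "AdmixtureRun",
    "run_mcmc",
    "run_replicates",
    "estimate_lnPD",
    "align_runs",
    "AlignedRuns",
    "group_mean_memberships",
    "supervised_estimate",
    "SupervisedResult",
]

_P_FLOOR = 1e-9


@dataclass
class AdmixConfig:
    """Run parameters for the admixture-model sampler.

    Chain-length defaults are sized for test work; analyses of reference
    panels should raise ``burnin``/``reps`` (the original program's scale is
    100,000 / 100,000).
    """

    K: int
    burnin: int = 2_000
    reps: int = 5_000
    freq_model: str = "correlated"  # or "independent"
    lambda_prior: float = 1.0
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.025
    f_prior_mean: float = 0.01
    f_prior_sd: float = 0.05
    f_proposal_sd: float = 0.2  # log-scale random walk for F_k
    pa_proposal_conc: float = 200.0  # Dirichlet random-walk tightness for p_A
    use_popinfo: bool = False
    pfrompopflagonly: bool = False
    n_runs: int = 3
    seed: int = 0
    check_state: bool = False  # verify simplex invariants every sweep

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burnin < 1 or self.reps < 1:
            raise ValueError("burnin and reps must be >= 1")
        if not 0 < self.alpha_init < self.alpha_max:
            raise ValueError("need 0 < alpha_init < alpha_max")
        if self.freq_model not in ("correlated", "independent"):
            raise ValueError("freq_model must be 'correlated' or 'independent'")
        if self.pfrompopflagonly and not self.use_popinfo:
            raise ValueError("pfrompopflagonly requires use_popinfo")


@dataclass
class AdmixtureRun:
    """Posterior summaries of one MCMC run."""

    Q_mean: np.ndarray  # (n, K)
    P_mean: np.ndarray  # (K, L, MAX_ALLELE)
    alpha_trace: np.ndarray
    loglik_trace: np.ndarray
    lnPD: float
    cluster_names: list[str]
    alpha_accept_rate: float
    config: AdmixConfig

    def __post_init__(self) -> None:
        if not np.isfinite(self.lnPD):
            raise ValueError("lnPD is not finite")
        if np.abs(self.Q_mean.sum(axis=1) - 1).max(initial=0) > 1e-6:
            raise ValueError("Q_mean rows must sum to 1")


def estimate_lnPD(loglik_trace: np.ndarray) -> float:
    """``mean - var/2`` log-probability-of-data estimate from a trace.

    The sample variance uses the n-1 denominator.  This is the standard
    model-choice diagnostic plotted against K.
    """
    trace = np.asarray(loglik_trace, float)
    if trace.size < 2:
        return float(trace.mean()) if trace.size else float("nan")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def _ln_dirichlet(P: np.ndarray, gamma: np.ndarray, valid: np.ndarray,
                  axis: int = -1) -> np.ndarray:
    """Log Dirichlet density over the valid-allele support, batched."""
    g = np.where(valid, gamma, 1.0)
    lp = np.where(valid, np.log(np.maximum(P, _P_FLOOR)), 0.0)
    return (
        gammaln(np.where(valid, gamma, 0.0).sum(axis=axis))
        - gammaln(g).sum(axis=axis)
        + ((g - 1.0) * lp).sum(axis=axis)
    )


def _dirichlet_sample(rng: np.random.Generator, shape: np.ndarray,
                      valid: np.ndarray, axis: int = -1) -> np.ndarray:
    """Batched Dirichlet draw restricted to the valid-allele support."""
    g = rng.standard_gamma(np.where(valid, np.maximum(shape, 1e-6), 0.0))
    total = g.sum(axis=axis, keepdims=True)
    out = g / np.maximum(total, 1e-300)
    out = np.where(valid & (out < _P_FLOOR), _P_FLOOR, out)
    out = out / out.sum(axis=axis, keepdims=True)
    return out


def _resolve_clusters(table: GenotypeTable, config: AdmixConfig):
    """Flagged-individual bookkeeping for supervised mode."""
    n = table.n_individuals
    if not config.use_popinfo:
        return (
            np.zeros(n, dtype=bool),
            np.full(n, -1),
            [f"C{k+1}" for k in range(config.K)],
        )
    flagged = (table.samples["popflag"] == 1).to_numpy()
    if not flagged.any():
        raise ValueError("use_popinfo requires popflag=1 individuals")
    labeled = sorted(table.samples.loc[flagged, "group"].unique())
    if config.K != len(labeled):
        raise ValueError(
            f"K={config.K} but {len(labeled)} labeled cluster(s) "
            f"({labeled}); every cluster needs flagged training individuals"
        )
    gmap = {g: k for k, g in enumerate(labeled)}
    assign = np.full(n, -1)
    for idx in np.nonzero(flagged)[0]:
        assign[idx] = gmap[table.samples["group"].iloc[idx]]
    return flagged, assign, labeled


def run_mcmc(table: GenotypeTable, config: AdmixConfig) -> AdmixtureRun:
    """One MCMC run of the admixture model; see the module docstring."""
    n, L, K, J = (
        table.n_individuals,
        table.n_loci,
        config.K,
        MAX_ALLELE,
    )
    rng = np.random.default_rng(config.seed)
    valid = np.zeros((L, J), dtype=bool)
    for li, loc in enumerate(table.panel):
        for code in loc.allele_codes:
            valid[li, code - 1] = True

    aidx = table.allele_index()
    # flatten observed copies (two per observed genotype)
    ii, ll_, cc = np.nonzero(aidx >= 0)
    oi, ol = ii, ll_
    oa = aidx[ii, ll_, cc]
    M = oi.size
    if M == 0:
        raise ValueError("table has no observed genotypes")
    olJa = ol * J + oa

    flagged, cluster_of, cluster_names = _resolve_clusters(table, config)
    unflagged_rows = ~flagged if config.use_popinfo else np.ones(n, bool)
    n_unflagged = int(unflagged_rows.sum())
    onehot = None
    if config.use_popinfo:
        onehot = np.zeros((int(flagged.sum()), K))
        onehot[np.arange(int(flagged.sum())), cluster_of[flagged]] = 1.0
    if config.pfrompopflagonly:
        copy_keep = flagged[oi]
        if not copy_keep.any():
            raise ValueError("no flagged copies to update frequencies from")
    else:
        copy_keep = None

    # --- initial state ---------------------------------------------------
    alpha = config.alpha_init
    Q = rng.dirichlet(np.ones(K), size=n)
    if config.use_popinfo:
        Q[flagged] = onehot
    # empirical overall frequencies as the ancestral anchor
    overall = np.bincount(olJa, minlength=L * J).reshape(L, J).astype(float)
    overall += config.lambda_prior * valid
    pA = overall / overall.sum(axis=1, keepdims=True)
    pA = np.where(valid & (pA < 1e-4), 1e-4, pA) * valid
    pA /= pA.sum(axis=1, keepdims=True)
    F = np.full(K, config.f_prior_mean)
    P = _dirichlet_sample(
        rng, np.broadcast_to(overall, (K, L, J)).copy(), valid[None, :, :]
    )

    f_shape = (config.f_prior_mean / config.f_prior_sd) ** 2
    f_rate = config.f_prior_mean / config.f_prior_sd**2
    lam = config.lambda_prior

    total_sweeps = config.burnin + config.reps
    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L, J))
    loglik_trace = np.empty(config.reps)
    alpha_trace = np.empty(total_sweeps)
    alpha_props = 0
    alpha_accepts = 0

    rows_unflagged = np.nonzero(unflagged_rows)[0]

    for sweep in range(total_sweeps):
        # (i) latent ancestries z | q, P
        Pobs = P[:, ol, oa]  # (K, M)
        W = Q[oi, :] * Pobs.T  # (M, K)
        cw = np.cumsum(W, axis=1)
        u = rng.random(M) * cw[:, -1]
        z = (cw < u[:, None]).sum(axis=1)
        np.clip(z, 0, K - 1, out=z)

        # (ii) memberships q | z
        nik = np.bincount(oi * K + z, minlength=n * K).reshape(n, K)
        g = rng.standard_gamma(alpha + nik)
        Q = g / np.maximum(g.sum(axis=1, keepdims=True), 1e-300)
        np.clip(Q, 1e-12, 1.0, out=Q)
        Q /= Q.sum(axis=1, keepdims=True)
        if config.use_popinfo:
            Q[flagged] = onehot

        # (iii) cluster frequencies P | z
        if copy_keep is None:
            m = np.bincount(z * (L * J) + olJa, minlength=K * L * J)
        else:
            m = np.bincount(
                z[copy_keep] * (L * J) + olJa[copy_keep],
                minlength=K * L * J,
            )
        m = m.reshape(K, L, J).astype(float)
        if config.freq_model == "independent":
            P = _dirichlet_sample(rng, lam + m, valid[None, :, :])
        else:
            gamma = pA[None, :, :] * ((1.0 - F) / F)[:, None, None]
            P = _dirichlet_sample(rng, gamma + m, valid[None, :, :])

            # Metropolis update of each cluster's drift parameter F_k
            F_new = F * np.exp(rng.normal(0.0, config.f_proposal_sd, K))
            for k in range(K):
                fn = F_new[k]
                if not 0.0 < fn < 0.999:
                    continue
                g_old = pA * ((1.0 - F[k]) / F[k])
                g_new = pA * ((1.0 - fn) / fn)
                logr = (
                    _ln_dirichlet(P[k], g_new, valid).sum()
                    - _ln_dirichlet(P[k], g_old, valid).sum()
                    + (f_shape - 1) * (math.log(fn) - math.log(F[k]))
                    - f_rate * (fn - F[k])
                    + (math.log(fn) - math.log(F[k]))  # log-normal Jacobian
                )
                if math.log(rng.random()) < logr:
                    F[k] = fn

            # Metropolis random-walk update of ancestral frequencies p_A
            conc = config.pa_proposal_conc
            pA_new = _dirichlet_sample(rng, conc * pA, valid)
            pA_new = np.where(valid & (pA_new < 1e-4), 1e-4, pA_new) * valid
            pA_new /= pA_new.sum(axis=1, keepdims=True)
            ratio = np.zeros(L)
            for k in range(K):
                scale = (1.0 - F[k]) / F[k]
                ratio += _ln_dirichlet(P[k], pA_new * scale, valid)
                ratio -= _ln_dirichlet(P[k], pA * scale, valid)
            ratio += _ln_dirichlet(pA_new, np.full((L, J), lam), valid)
            ratio -= _ln_dirichlet(pA, np.full((L, J), lam), valid)
            ratio += _ln_dirichlet(pA, conc * pA_new, valid)
            ratio -= _ln_dirichlet(pA_new, conc * pA, valid)
            accept = np.log(rng.random(L)) < ratio
            pA[accept] = pA_new[accept]

        # (iv) Metropolis update of alpha
        if n_unflagged > 0 and K > 1:
            a_new = alpha + rng.normal(0.0, config.alpha_proposal_sd)
            alpha_props += 1
            if 0.0 < a_new < config.alpha_max:
                sum_log_q = np.log(Q[rows_unflagged]).sum()
                logr = n_unflagged * (
                    gammaln(K * a_new)
                    - K * gammaln(a_new)
                    - gammaln(K * alpha)
                    + K * gammaln(alpha)
                ) + (a_new - alpha) * sum_log_q
                if math.log(rng.random()) < logr:
                    alpha = a_new
                    alpha_accepts += 1
        alpha_trace[sweep] = alpha

        if config.check_state:
            assert np.abs(Q.sum(axis=1) - 1).max() < 1e-9
            psums = P.sum(axis=2)
            assert np.abs(psums - 1).max() < 1e-9

        if sweep >= config.burnin:
            Q_sum += Q
            P_sum += P
            Pobs2 = P[:, ol, oa]
            lik = (Q[oi, :] * Pobs2.T).sum(axis=1)
            ll = float(np.log(np.maximum(lik, 1e-300)).sum())
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite likelihood at sweep {sweep}; "
                    f"alpha={alpha}, F={F}"
                )
            loglik_trace[sweep - config.burnin] = ll

    Q_mean = Q_sum / config.reps
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return AdmixtureRun(
        Q_mean=Q_mean,
        P_mean=P_sum / config.reps,
        alpha_trace=alpha_trace,
        loglik_trace=loglik_trace,
        lnPD=estimate_lnPD(loglik_trace),
        cluster_names=cluster_names,
        alpha_accept_rate=(alpha_accepts / alpha_props) if alpha_props else 0.0,
        config=config,
    )


def run_replicates(
    table: GenotypeTable, config: AdmixConfig
) -> list[AdmixtureRun]:
    """``n_runs`` independent runs; replicate r uses seed ``seed + r``."""
    runs = []
    for r in range(config.n_runs):
        cfg = AdmixConfig(**{**config.__dict__, "seed": config.seed + r})
        runs.append(run_mcmc(table, cfg))
    return runs


@dataclass
class AlignedRuns:
    Q_avg: np.ndarray  # (n, K)
    permutations: list[tuple[int, ...]]  # applied to each run's columns
    runs: list[AdmixtureRun]
    cluster_names: list[str]


def align_runs(runs: list[AdmixtureRun]) -> AlignedRuns:
    """Relabel clusters across replicate runs and average the Q matrices.

    Each run's columns are permuted to minimize the summed squared
    difference to the first run — a linear assignment problem on the
    cross-product matrix, solved exactly — then averaged element-wise.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].Q_mean.shape[1]
    n = runs[0].Q_mean.shape[0]
    for r in runs[1:]:
        if r.Q_mean.shape != (n, K):
            raise ValueError("runs disagree on K or individual count")
    ref = runs[0].Q_mean
    perms: list[tuple[int, ...]] = []
    acc = np.zeros_like(ref)
    for r in runs:
        S = r.Q_mean.T @ ref  # similarity of run-cluster vs ref-cluster
        rows, cols = linear_sum_assignment(-S)
        perm = tuple(rows[np.argsort(cols)])
        perms.append(perm)
        acc += r.Q_mean[:, list(perm)]
    Q_avg = acc / len(runs)
    Q_avg /= Q_avg.sum(axis=1, keepdims=True)
    return AlignedRuns(Q_avg, perms, list(runs), runs[0].cluster_names)


def group_mean_memberships(
    Q: np.ndarray, labels, cluster_names: list[str] | None = None
) -> pd.DataFrame:
    """Average membership per population/group label (rows) and cluster."""
    labels = pd.Series(list(labels))
    K = Q.shape[1]
    names = cluster_names or [f"C{k+1}" for k in range(K)]
    out = {}
    for g in sorted(labels.unique()):
        out[g] = Q[(labels == g).to_numpy()].mean(axis=0)
    return pd.DataFrame.from_dict(out, orient="index", columns=names)


@dataclass
class SupervisedResult:
    test_q: pd.DataFrame  # sample_id, population + one column per cluster
    pop_means: pd.DataFrame  # per test population mean memberships
    aligned: AlignedRuns


def supervised_estimate(
    table: GenotypeTable, config: AdmixConfig
) -> SupervisedResult:
    """Estimate test individuals' ancestry against a flagged reference.

    Reference individuals must carry ``popflag = 1`` and group labels that
    enumerate the K clusters; test individuals carry ``popflag = 0``.
    Replicate runs are averaged (cluster labels are anchored by the
    reference, so no relabeling search is needed, but the generic alignment
    is applied for safety).
    """
    cfg = AdmixConfig(**{**config.__dict__, "use_popinfo": True})
    flagged = (table.samples["popflag"] == 1).to_numpy()
    if flagged.all():
        raise ValueError("no unflagged test individuals")
    runs = run_replicates(table, cfg)
    aligned = align_runs(runs)
    names = aligned.cluster_names
    test_rows = ~flagged
    test_q = pd.DataFrame(
        aligned.Q_avg[test_rows], columns=names
    )
    test_q.insert(0, "population", table.samples.loc[test_rows, "population"].values)
    test_q.insert(0, "sample_id", table.samples.loc[test_rows, "sample_id"].values)
    pop_means = group_mean_memberships(
        aligned.Q_avg[test_rows],
        table.samples.loc[test_rows, "population"],
        names,
    )
    return SupervisedResult(test_q, pop_means, aligned)
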
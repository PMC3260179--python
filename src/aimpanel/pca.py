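"""Principal component analysis of the genotype dosage matrix.

Genotypes are encoded as per-allele dosages (copies of each non-reference
allele, 0/1/2), missing cells are mean-imputed, columns are centered and by
default scaled to unit variance, and the decomposition is a plain SVD.  The
"information percentage" of component *i* is ``σ_i² / Σ σ_j² · 100``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["DosageMatrix", "PcaResult", "encode_dosage", "pca"]


@dataclass
class DosageMatrix:
    """Individuals x (locus, allele) dosage matrix.

    One column per non-reference allele of each locus (the locus's first
    declared allele code is the implicit reference, so a biallelic locus
    contributes one column and a triallelic locus two).  Missing genotypes
    are imputed with the column mean; ``observed`` records which cells were
    real calls.  Columns constant across all individuals are dropped.
    """

    matrix: np.ndarray  # (n, C) float
    columns: list[tuple[str, int]]  # (marker_id, allele_code)
    observed: np.ndarray  # (n, C) bool
    dropped: list[tuple[str, int]]


def encode_dosage(table: GenotypeTable) -> DosageMatrix:
    """Deterministic dosage encoding of a genotype table."""
    n, L = table.n_individuals, table.n_loci
    cols: list[tuple[str, int]] = []
    vecs: list[np.ndarray] = []
    obs_cols: list[np.ndarray] = []
    missing = table.missing_mask()
    for li, loc in enumerate(table.panel):
        ref = loc.allele_codes[0]
        for code in loc.allele_codes[1:]:
            dosage = (table.calls[:, li, :] == code).sum(axis=1).astype(float)
            obs = ~missing[:, li]
            if obs.any():
                dosage[~obs] = dosage[obs].mean()
            cols.append((loc.marker_id, code))
            vecs.append(dosage)
            obs_cols.append(obs)
    matrix = np.column_stack(vecs) if vecs else np.empty((n, 0))
    observed = np.column_stack(obs_cols) if obs_cols else np.empty(
        (n, 0), bool
    )
    keep = matrix.std(axis=0) > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        logger.info("dropping %d constant dosage column(s): %s",
                    len(dropped), dropped)
    return DosageMatrix(
        matrix[:, keep],
        [c for c, k in zip(cols, keep) if k],
        observed[:, keep],
        dropped,
    )


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, n_components)
    percent_variance: np.ndarray  # (n_components,), sums to <= 100
    loadings: np.ndarray  # (C, n_components)
    columns: list[tuple[str, int]]

    def scores_frame(self, sample_ids, groups=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i+1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "sample_id", list(sample_ids))
        if groups is not None:
            df.insert(1, "group", list(groups))
        return df


def pca(
    dosage: DosageMatrix,
    n_components: int | None = None,
    scale: bool = True,
) -> PcaResult:
    """SVD-based PCA with per-component variance percentages.

    Columns are centered and (by default) scaled to unit standard
    deviation.  Component signs are fixed so each component's
    largest-magnitude loading is positive, making scores reproducible
    across BLAS backends.
    """
    X = dosage.matrix
    n, C = X.shape
    if n < 2 or C < 1:
        raise ValueError("need at least 2 individuals and 1 varying column")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (S**2).sum()
    percent = S**2 / total * 100.0
    k = min(n_components or len(S), len(S))
    # deterministic sign: largest-|loading| positive per component
    signs = np.ones(k)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            signs[i] = -1.0
    scores = U[:, :k] * S[:k] * signs
    loadings = (Vt[:k].T) * signs
    return PcaResult(scores, percent[:k], loadings, dosage.columns)
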
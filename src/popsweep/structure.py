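"""Genetic relationship matrix and principal components.

The GRM is the standard standardized-genotype cross-product: for dosage
``x_ij`` of sample ``j`` at site ``i`` with panel-wide alt frequency
``p_i``,

    A_jk = (1 / M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

summed over the sites polymorphic in the panel where both calls are present
(``M_jk`` is pairwise-complete, so missingness needs no imputation).
PCA takes the top-k eigenpairs of the double-centered GRM; coordinates are
eigenvectors scaled by the square root of their eigenvalue, and the variance
fraction of a component is its eigenvalue over the sum of positive
eigenvalues.  The sign of each eigenvector is fixed so the entry of largest
magnitude is positive, making outputs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class RelationshipMatrix:
    sample_ids: list[str]
    values: np.ndarray          # (N, N) symmetric
    n_sites_used: int           # polymorphic biallelic sites entering sums

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def grm(gm: GenotypeMatrix) -> RelationshipMatrix:
    """GCTA-style relationship matrix over polymorphic biallelic sites."""
    dos = gm.dosage.astype(float)
    dos[dos == MISSING] = np.nan
    dos[~gm.is_biallelic] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=1) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no usable (polymorphic, biallelic) sites for the GRM")
    X = dos[poly]
    p = p[poly][:, None]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    valid = np.isfinite(Z)
    Zf = np.where(valid, Z, 0.0)
    num = Zf.T @ Zf
    M = valid.astype(float).T @ valid.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(M > 0, num / np.where(M > 0, M, 1.0), 0.0)
    A = (A + A.T) / 2.0
    return RelationshipMatrix(sample_ids=list(gm.sample_ids), values=A,
                              n_sites_used=int(poly.sum()))


def pca(rm: RelationshipMatrix, k: int = 2
        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k eigenpairs of the double-centered GRM.

    Returns a coordinates frame (sample, PC1..PCk) and the per-component
    variance fractions.
    """
    A = rm.values
    n = A.shape[0]
    if not np.all(np.isfinite(A)):
        raise ValueError("relationship matrix contains non-finite entries")
    if not (0 < k < n):
        raise ValueError("k must satisfy 0 < k < n_samples")
    J = np.eye(n) - np.ones((n, n)) / n
    C = J @ A @ J
    C = (C + C.T) / 2.0
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos_sum = w[w > 0].sum()
    coords = np.empty((n, k))
    varfrac = np.empty(k)
    for c in range(k):
        vec = v[:, c]
        i_max = np.argmax(np.abs(vec))
        if vec[i_max] < 0:
            vec = -vec
        lam = max(w[c], 0.0)
        coords[:, c] = vec * np.sqrt(lam)
        varfrac[c] = w[c] / pos_sum if pos_sum > 0 else 0.0
    df = pd.DataFrame(coords, columns=[f"PC{c + 1}" for c in range(k)])
    df.insert(0, "sample", rm.sample_ids)
    return df, varfrac
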
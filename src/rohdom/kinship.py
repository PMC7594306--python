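"""Additive (G), dominance (D) and ROH-based (R) relationship matrices.

G follows VanRaden's method 1, D the Vitezica ("statistical")
parametrization, and R applies the same cross-product construction to the
per-SNP in-ROH indicator:

.. math::

    G = Z Z' / \\sum_i 2 p_i q_i, \\qquad
    D = H H' / \\sum_i (2 p_i q_i)^2, \\qquad
    R = M M' / \\sum_i p_i^* q_i^*,

where ``p_i`` is the sample frequency of allele A, ``p_i^*`` the frequency
of SNP i being inside a ROH, and Z, H, M are the centred marker covariate
matrices defined below.  Note that the R denominator carries no factor 2:
ROH status is a single indicator, not an allele dosage.

All three matrices are Gram matrices divided by a positive scalar and are
therefore positive semidefinite by construction.  Monomorphic markers
(and markers always or never in a ROH) yield all-zero covariate columns
and contribute nothing to numerator or denominator; they are kept in
place so marker indexing stays stable.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, RelationshipMatrix, ROHStatusMatrix

logger = logging.getLogger(__name__)


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Observed sample frequency of allele A per marker (mean code / 2)."""
    return genotypes.allele_frequencies()


def build_Z(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Additive covariate matrix: -2p, 1-2p, 2-2p for BB, AB, AA.

    Columns have exactly zero mean at the computing frequencies.
    """
    if freqs is None:
        freqs = genotypes.allele_frequencies()
    return genotypes.codes.astype(float) - 2.0 * np.asarray(freqs)


def build_H(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Dominance covariate matrix: -2p^2, 2pq, -2q^2 for BB, AB, AA.

    Under Hardy-Weinberg proportions the expected column value is zero;
    monomorphic markers give all-zero columns.
    """
    if freqs is None:
        freqs = genotypes.allele_frequencies()
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    codes = genotypes.codes
    out = np.empty(codes.shape, dtype=float)
    vals = np.stack([-2.0 * p * p, 2.0 * p * q, -2.0 * q * q])  # (3, m)
    for g in range(3):
        mask = codes == g
        out[mask] = np.broadcast_to(vals[g], codes.shape)[mask]
    return out


def build_M(status: ROHStatusMatrix) -> np.ndarray:
    """ROH covariate matrix: 1 - p* in a ROH, -p* outside.

    Columns with p* in {0, 1} (markers never or always in a ROH) are
    exactly zero.
    """
    x = status.x.astype(float)
    p = status.p_star
    M = x - p
    M[:, (p == 0.0) | (p == 1.0)] = 0.0
    return M


def _gram(kind: str, W: np.ndarray, denom: float, what: str) -> RelationshipMatrix:
    if denom <= 0:
        raise ValueError(f"cannot build {kind}: {what} is zero (no informative markers)")
    vals = W @ W.T / denom
    vals = (vals + vals.T) / 2.0  # exact symmetry against rounding
    return RelationshipMatrix(kind=kind, values=vals, denominator=float(denom))


def build_G(Z: np.ndarray, freqs: np.ndarray) -> RelationshipMatrix:
    """Additive genomic relationship matrix, VanRaden method 1."""
    p = np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return _gram("G", Z, denom, "sum of 2pq")


def build_D(H: np.ndarray, freqs: np.ndarray) -> RelationshipMatrix:
    """Dominance relationship matrix, Vitezica parametrization."""
    p = np.asarray(freqs, dtype=float)
    denom = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    return _gram("D", H, denom, "sum of (2pq)^2")


def build_R(M: np.ndarray, status: ROHStatusMatrix) -> RelationshipMatrix:
    """ROH-based relationship matrix.

    Element (j, k) is the centred, scaled probability that animals j and k
    both have a ROH (not necessarily the same ROH) at a random SNP.
    """
    denom = float(np.sum(status.p_star * status.q_star))
    return _gram("R", M, denom, "sum of p*q*")


def orthogonalize_M(M: np.ndarray, Z: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Regress each ROH indicator column on its additive and dominance columns.

    Returns per-column least-squares residuals of ``M[:, i]`` on
    ``(1, Z[:, i], H[:, i])``; the corrected columns are numerically
    orthogonal to both regressors, removing the structural collinearity
    between R and G/D.  Collinear regressors (e.g. at a monomorphic
    marker) are dropped from that column's regression.
    """
    n, m = M.shape
    if n < 3:
        raise ValueError("per-SNP regression needs at least 3 observations")
    out = np.empty_like(M, dtype=float)
    ones = np.ones(n)
    for i in range(m):
        X = np.column_stack([ones, Z[:, i], H[:, i]])
        keep = [0]
        for c in (1, 2):
            trial = X[:, keep + [c]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
        if len(keep) < 3:
            logger.debug("marker %d: collinear additive/dominance covariate dropped", i)
        Xk = X[:, keep]
        coef, *_ = np.linalg.lstsq(Xk, M[:, i], rcond=None)
        out[:, i] = M[:, i] - Xk @ coef
    return out


def offdiag_correlation(A: RelationshipMatrix, B: RelationshipMatrix) -> float:
    """Pearson correlation between the strict lower triangles of two matrices."""
    if A.n != B.n:
        raise ValueError("matrices must have the same dimension")
    if A.n < 3:
        raise ValueError("need at least 3 animals for an off-diagonal correlation")
    idx = np.tril_indices(A.n, k=-1)
    return float(np.corrcoef(A.values[idx], B.values[idx])[0, 1])


def load_worked_roh_example() -> pd.DataFrame:
    """Load the bundled synthetic 30-SNP two-animal worked example.

    A synthetic stand-in for a supplementary worked example of the R
    matrix: ROH status of two animals (``x_j``, ``x_k``) over 30 SNPs with
    externally given in-ROH frequencies ``p_star`` such that the
    cross-product sum is 3.0471 and the p*q* sum is 3.4829, giving a
    ROH-based relationship of 0.8749.
    """
    with resources.files("rohdom.data").joinpath("synthetic_roh_worked_example.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
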
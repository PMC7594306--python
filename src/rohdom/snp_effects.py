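"""Back-solving per-SNP effects from animal-level BLUPs, and the
directional-dominance bookkeeping around them.

Per-marker additive, dominance and ROH effects are linear transforms of
the fitted random effects:

.. math::

    \\hat\\alpha = Z' G^{-1} \\hat u / \\sum_i 2 p_i q_i, \\qquad
    \\hat d = H' D^{-1} \\hat v / \\sum_i (2 p_i q_i)^2, \\qquad
    \\hat r = M' R^{-1} \\hat w / \\sum_i p_i^* q_i^*.

Because G = ZZ'/sum 2pq (and likewise for D, R), these transforms satisfy
exact reconstruction identities Z alpha = u, H d = v, M r = w whenever
the BLUP lies in the matrix's column span; the inverses are computed as
eigenvalue pseudo-inverses so the identities hold to numerical precision
even though the centred Gram matrices are rank deficient.

The fixed regression on genome-wide homozygosity absorbs the mean
dominance effect; it is recovered as d_bar = -b / N_SNP (with b rescaled
from its per-1% reporting scale to per unit homozygosity), and the
dominance variance excluding directional dominance is completed to the
full dominance variance by N * mean((2pq)^2) * d_bar^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datatypes import RelationshipMatrix, ROHStatusMatrix


def _pinv_apply(K: RelationshipMatrix | np.ndarray, v: np.ndarray,
                rcond: float = 1e-10) -> np.ndarray:
    """K^+ v via eigendecomposition with a relative eigenvalue cutoff."""
    vals = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)
    w, U = linalg.eigh(vals)
    cut = rcond * max(w[-1], 0.0)
    inv_w = np.where(w > cut, 1.0 / np.where(w > cut, w, 1.0), 0.0)
    return U @ (inv_w * (U.T @ v))


def backsolve_additive(u_hat: np.ndarray, Z: np.ndarray, G: RelationshipMatrix,
                       freqs: np.ndarray) -> np.ndarray:
    """Per-SNP allele substitution effects from additive BLUPs."""
    if Z.shape[0] != len(u_hat):
        raise ValueError("Z rows must match the length of u_hat")
    p = np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return Z.T @ _pinv_apply(G, np.asarray(u_hat, dtype=float)) / denom


def backsolve_dominance(v_hat: np.ndarray, H: np.ndarray, D: RelationshipMatrix,
                        freqs: np.ndarray) -> np.ndarray:
    """Per-SNP dominance deviations from dominance BLUPs."""
    if H.shape[0] != len(v_hat):
        raise ValueError("H rows must match the length of v_hat")
    p = np.asarray(freqs, dtype=float)
    denom = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    return H.T @ _pinv_apply(D, np.asarray(v_hat, dtype=float)) / denom


def backsolve_roh(w_hat: np.ndarray, M: np.ndarray, R: RelationshipMatrix,
                  status: ROHStatusMatrix) -> np.ndarray:
    """Per-SNP ROH effects from ROH BLUPs.

    Markers never or always in a ROH have all-zero M columns and receive
    an effect of exactly 0.
    """
    if M.shape[0] != len(w_hat):
        raise ValueError("M rows must match the length of w_hat")
    denom = float(np.sum(status.p_star * status.q_star))
    return M.T @ _pinv_apply(R, np.asarray(w_hat, dtype=float)) / denom


def mean_dominance(b_per_percent: float, n_snp: int) -> float:
    """Mean per-SNP dominance effect -b/N_SNP on the per-unit scale.

    ``b_per_percent`` is the homozygosity regression coefficient as
    reported (effect of a 1% increase); multiplying by 100 converts it to
    the per-unit-homozygosity scale before dividing by the SNP count.
    """
    if n_snp <= 0:
        raise ValueError("n_snp must be positive")
    return -(100.0 * b_per_percent) / n_snp


def full_dominance_variance(sigma2_D: float, n_snp: int, mean_sq_het: float,
                            d_bar: float) -> float:
    """Complete the REML dominance variance with the directional term.

    sigma2_D from a model with the homozygosity regression captures only
    deviations from the mean dominance effect; the full dominance
    variance adds N * mean((2pq)^2) * d_bar^2 and is therefore never
    smaller than sigma2_D.
    """
    if sigma2_D < 0 or mean_sq_het < 0 or n_snp <= 0:
        raise ValueError("inputs must be non-negative (n_snp positive)")
    return sigma2_D + n_snp * mean_sq_het * d_bar ** 2


@dataclass
class DepressionPrediction:
    """Predicted change in trait mean at inbreeding coefficient F."""

    F: float
    delta_mean: float


def predict_inbreeding_depression(F: float, freqs: np.ndarray,
                                  d: np.ndarray) -> DepressionPrediction:
    """Expected change in mean, -F * sum_i 2 p_i q_i d_i."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be a fraction in [0, 1]")
    p = np.asarray(freqs, dtype=float)
    d = np.asarray(d, dtype=float)
    delta = -F * float(np.sum(2.0 * p * (1.0 - p) * d))
    return DepressionPrediction(F=F, delta_mean=delta)


def standardized_effects(effects: np.ndarray, sigma2_G: float) -> np.ndarray:
    """Display scaling: 100 * effect / genetic standard deviation."""
    if sigma2_G <= 0:
        raise ValueError("genetic variance must be positive")
    return 100.0 * np.asarray(effects, dtype=float) / np.sqrt(sigma2_G)
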
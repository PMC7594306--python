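"""Single-SNP mixed-model association scan with joint additive, dominance
and ROH effects.

For each marker the model ``y = j*alpha + k*d + l*r + Xb + Qc + u + e``
is solved by generalized least squares, where j is the allele count
(0/1/2), k the heterozygosity indicator and l the in-ROH indicator.  The
phenotypic covariance V is taken from a converged Model-A fit (HYS,
additive and residual components) and held fixed across markers
(EMMAX/P3D-style); only the additive polygenic background is carried, as
dominance and ROH relationship matrices are not refitted per marker.

After whitening with the Cholesky factor of V, each marker reduces to an
ordinary least-squares problem; a residual scale is re-estimated per
marker, so with V = I the scan is exactly a joint OLS.  Effects whose
whitened covariate is collinear with the fixed effects (monomorphic
markers, markers never in a ROH) are flagged inestimable rather than
zero-filled.  Multiple testing is handled by Benjamini-Hochberg step-up
q-values per effect type; no genomic-control correction is applied even
when the inflation factor exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, ROHStatusMatrix
from .greml import GremlFit, ModelDesign

EFFECT_NAMES = ("additive", "dominance", "roh")


def bh_adjust(p: np.ndarray, fdr: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance calls.

    Returns ``(q, significant)`` where ``significant = q <= fdr``.
    NaN entries (inestimable effects) are passed through as NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        _, q_ok, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = q_ok
    return q, q <= fdr


@dataclass
class InflationReport:
    """Genomic inflation factor and QQ-plot coordinates for one scan."""

    lam: float
    expected: np.ndarray
    observed: np.ndarray


_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


def inflation_factor(t_stats: np.ndarray) -> InflationReport:
    """Lambda = median observed chi-square over the null chi2_1 median.

    ``t_stats`` are per-marker t statistics (chi-square = t^2); QQ
    coordinates are expected vs observed -log10 P under the two-sided
    normal reference.
    """
    t = np.asarray(t_stats, dtype=float)
    t = t[~np.isnan(t)]
    if t.size < 10:
        raise ValueError("need at least 10 statistics for an inflation factor")
    chi2 = t ** 2
    lam = float(np.median(chi2) / _CHI2_1_MEDIAN)
    pvals = np.sort(2.0 * stats.norm.sf(np.abs(t)))
    observed = -np.log10(pvals)
    expected = -np.log10((np.arange(1, t.size + 1) - 0.5) / t.size)
    return InflationReport(lam=lam, expected=expected, observed=observed)


class SingleSnpGWAS(BaseEstimator):
    """Per-marker GLS scan at variance components fixed from a null fit.

    Parameters
    ----------
    fdr : FDR level for significance calls (default 10%)
    reference : 'normal' (default, large-n) or 't' with residual degrees
        of freedom, for small fixtures
    """

    def __init__(self, fdr: float = 0.10, reference: str = "normal"):
        self.fdr = fdr
        self.reference = reference

    def fit(self, design: ModelDesign, genotypes: GenotypeMatrix,
            status: ROHStatusMatrix, null_fit: GremlFit) -> "SingleSnpGWAS":
        if not null_fit.converged:
            raise ValueError("null fit has not converged")
        n = design.n
        V = sum(null_fit.sigma2[c] * null_fit.kernels[c] for c in null_fit.active)
        L = linalg.cholesky(V, lower=True, check_finite=False)

        yw = linalg.solve_triangular(L, design.y, lower=True, check_finite=False)
        Xw = linalg.solve_triangular(L, design.X, lower=True, check_finite=False)
        Qx, _ = np.linalg.qr(Xw)
        y_res = yw - Qx @ (Qx.T @ yw)
        p_fixed = design.X.shape[1]

        codes = genotypes.codes
        m = genotypes.n_markers
        est = np.full((m, 3), np.nan)
        se = np.full((m, 3), np.nan)
        flags = np.zeros((m, 3), dtype=bool)  # True = inestimable
        dof = n - p_fixed - 3
        block = 512  # markers per whitening block, bounds peak memory
        covw = None
        for i in range(m):
            if i % block == 0:
                hi = min(i + block, m)
                covs = np.empty((n, 3 * (hi - i)))
                covs[:, 0::3] = codes[:, i:hi]
                covs[:, 1::3] = codes[:, i:hi] == 1
                covs[:, 2::3] = status.x[:, i:hi]
                covw = linalg.solve_triangular(L, covs, lower=True, check_finite=False)
                covw -= Qx @ (Qx.T @ covw)
            j0 = 3 * (i % block)
            C = covw[:, j0:j0 + 3]
            norms = np.linalg.norm(C, axis=0)
            usable = norms > 1e-8 * np.sqrt(n)
            k = int(usable.sum())
            if k:
                Cu = C[:, usable]
                G = Cu.T @ Cu
                # drop columns that remain mutually collinear
                while k and np.linalg.matrix_rank(G, tol=1e-8 * np.trace(G)) < k:
                    usable[np.flatnonzero(usable)[-1]] = False
                    Cu = C[:, usable]
                    k = int(usable.sum())
                    G = Cu.T @ Cu
            if k:
                b = np.linalg.solve(G, Cu.T @ y_res)
                resid = y_res - Cu @ b
                df_i = n - p_fixed - k
                s2 = float(resid @ resid) / df_i
                cov_b = s2 * np.linalg.inv(G)
                est[i, usable] = b
                se[i, usable] = np.sqrt(np.diag(cov_b))
            flags[i] = ~usable if k else True
        t = est / se
        if self.reference == "t":
            pvals = 2.0 * stats.t.sf(np.abs(t), df=dof)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(t))

        tab = {"chrom": genotypes.markers["chrom"].to_numpy(),
               "snp": genotypes.markers["snp"].to_numpy(),
               "pos": genotypes.markers["pos"].to_numpy()}
        for e, name in enumerate(EFFECT_NAMES):
            tab[f"{name}_est"] = est[:, e]
            tab[f"{name}_se"] = se[:, e]
            tab[f"{name}_t"] = t[:, e]
            tab[f"{name}_p"] = pvals[:, e]
            q, sig = bh_adjust(pvals[:, e], self.fdr)
            tab[f"{name}_q"] = q
            tab[f"{name}_significant"] = sig
            tab[f"{name}_inestimable"] = flags[:, e]
        self.results_ = pd.DataFrame(tab)
        self.n_markers_ = m
        return self

    def inflation_report(self) -> dict:
        """Per-effect-type genomic inflation factors with QQ data."""
        if not hasattr(self, "results_"):
            raise AttributeError("GWAS is not fitted")
        return {name: inflation_factor(self.results_[f"{name}_t"].to_numpy())
                for name in EFFECT_NAMES}


def run_gwas(design: ModelDesign, genotypes: GenotypeMatrix,
             status: ROHStatusMatrix, null_fit: GremlFit,
             fdr: float = 0.10, reference: str = "normal") -> pd.DataFrame:
    """Functional wrapper over :class:`SingleSnpGWAS`; returns the result table."""
    scan = SingleSnpGWAS(fdr=fdr, reference=reference)
    scan.fit(design, genotypes, status, null_fit)
    return scan.results_
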
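"""Multi-component REML (average information) for Models A, AD, ADR and AR.

The mixed model is

.. math::

    y = X b + Q c + u + v + w + e,

with fixed effects ``b`` (herd, year and season factors, age at calving,
and genome-wide SNP homozygosity in percent), random herd-year-season
(HYS) groups ``c ~ N(0, I sigma2_HYS)``, additive values
``u ~ N(0, G sigma2_A)``, dominance deviations ``v ~ N(0, D sigma2_D)``,
ROH deviations ``w ~ N(0, R sigma2_ROH)`` and residuals
``e ~ N(0, I sigma2_E)``.  Model A drops v and w, AD drops w, AR drops v.

Estimation maximizes the restricted likelihood with average-information
updates, step-halving when an update would turn a component negative or
decrease the restricted log-likelihood.  A component pinned at the zero
boundary whose gradient keeps pushing it negative is fixed to exactly 0
and flagged.  Standard errors come from the inverse of the average
information matrix; relative components (ratios to the phenotypic
variance, which excludes the HYS component, and to the total genetic
variance) carry delta-method standard errors.

Model comparison uses the boundary-corrected likelihood-ratio test: for a
single variance component on the boundary, P = 0.5 * Pr(chi2_1 > T) with
T = 2 * (loglik_full - loglik_reduced) clamped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .datatypes import RelationshipMatrix

logger = logging.getLogger(__name__)

#: Random components per model, in fitting order ('hys' and 'residual' are
#: always present).
MODEL_COMPONENTS = {
    "A": ("hys", "additive", "residual"),
    "AD": ("hys", "additive", "dominance", "residual"),
    "ADR": ("hys", "additive", "dominance", "roh", "residual"),
    "AR": ("hys", "additive", "roh", "residual"),
}

#: Components entering the phenotypic variance (HYS is excluded).
PHENOTYPIC_COMPONENTS = ("additive", "dominance", "roh", "residual")
GENETIC_COMPONENTS = ("additive", "dominance", "roh")

HOMOZYGOSITY_COLUMN = "homozygosity_pct"


@dataclass
class ModelDesign:
    """Aligned phenotype vector, fixed-effect design and HYS incidence."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    Q: np.ndarray
    hys_labels: list
    animals: list

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Q.shape[0] != n:
            raise ValueError("y, X and Q must have aligned rows")
        if not np.isfinite(self.y).all():
            raise ValueError("trait values must be finite")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

    @property
    def n(self) -> int:
        return self.y.shape[0]


def build_design(pheno: pd.DataFrame, hom: np.ndarray, trait: str = "y",
                 include_homozygosity: bool = True) -> ModelDesign:
    """Assemble the Model-A fixed and HYS designs from a phenotype table.

    ``pheno`` needs columns ``animal, herd, year, season, age`` plus the
    trait; ``hom`` is the per-row genome-wide homozygosity as a fraction
    in [0, 1] and enters the design in percent, so the fitted coefficient
    is the effect of a 1% increase in homozygosity.  Factors are
    dummy-coded with the first observed level as reference; the HYS factor
    is the observed herd x year x season interaction.
    """
    hom = np.asarray(hom, dtype=float)
    if len(hom) != len(pheno):
        raise ValueError("one homozygosity value per phenotype row is required")
    if np.isnan(hom).any():
        missing = pheno["animal"].iloc[int(np.argmax(np.isnan(hom)))]
        raise ValueError(f"animal {missing!r} has no genome-wide homozygosity value")
    if hom.min() < 0 or hom.max() > 1:
        raise ValueError("homozygosity must be a fraction in [0, 1]")
    y = pheno[trait].to_numpy(dtype=float)

    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for factor in ("herd", "year", "season"):
        labels = pheno[factor].astype(str)
        levels = list(dict.fromkeys(labels))  # first observed level = reference
        for lev in levels[1:]:
            cols.append((labels == lev).to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]")
    cols.append(pheno["age"].to_numpy(dtype=float))
    names.append("age")
    if include_homozygosity:
        cols.append(hom * 100.0)
        names.append(HOMOZYGOSITY_COLUMN)
    X = np.column_stack(cols)

    hys = (pheno["herd"].astype(str) + ":" + pheno["year"].astype(str)
           + ":" + pheno["season"].astype(str))
    hys_levels = list(dict.fromkeys(hys))
    level_index = {lev: i for i, lev in enumerate(hys_levels)}
    Q = np.zeros((len(pheno), len(hys_levels)))
    Q[np.arange(len(pheno)), [level_index[h] for h in hys]] = 1.0
    return ModelDesign(y=y, X=X, x_names=names, Q=Q, hys_labels=hys_levels,
                       animals=list(pheno["animal"]))


@dataclass
class GremlFit:
    """Converged REML solution for one model on one trait."""

    model: str
    components: tuple
    sigma2: dict
    se: dict
    fixed_to_zero: dict
    beta: np.ndarray
    beta_names: list
    blups: dict
    loglik: float
    ai: np.ndarray
    active: list
    n_iter: int
    converged: bool
    design: ModelDesign = field(repr=False)
    kernels: dict = field(repr=False)

    @property
    def sigma2_P(self) -> float:
        """Phenotypic variance: genetic components plus residual, no HYS."""
        return sum(self.sigma2[c] for c in PHENOTYPIC_COMPONENTS if c in self.sigma2)

    @property
    def sigma2_G(self) -> float:
        return sum(self.sigma2[c] for c in GENETIC_COMPONENTS if c in self.sigma2)

    @property
    def b_homozygosity(self) -> float:
        """Regression coefficient on genome-wide homozygosity, per 1%."""
        return float(self.beta[self.beta_names.index(HOMOZYGOSITY_COLUMN)])


class GremlConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


class GREML(BaseEstimator):
    """Average-information REML estimator for the A/AD/ADR/AR models.

    Parameters
    ----------
    model : {'A', 'AD', 'ADR', 'AR'}
    max_iter : iteration cap (error with trajectory if exceeded)
    tol : convergence on |delta loglik| and on max |delta sigma2| / sigma2_P
    ridge : diagonal ridge (times phenotypic scale) added to V only when a
        Cholesky factorization fails
    """

    def __init__(self, model: str = "ADR", max_iter: int = 200, tol: float = 1e-8,
                 ridge: float = 1e-6, verbose: bool = False):
        self.model = model
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.verbose = verbose

    # -- internal helpers -------------------------------------------------

    def _collect_kernels(self, design: ModelDesign, relationships: dict) -> dict:
        needed = MODEL_COMPONENTS[self.model]
        n = design.n
        kernels = {"hys": design.Q @ design.Q.T, "residual": np.eye(n)}
        mapping = {"additive": "G", "dominance": "D", "roh": "R"}
        for comp, key in mapping.items():
            if comp not in needed:
                continue
            K = relationships.get(comp, relationships.get(key))
            if K is None:
                raise ValueError(f"model {self.model} needs the {key} matrix "
                                 f"(relationships[{comp!r}])")
            vals = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)
            if vals.shape != (n, n):
                raise ValueError(f"{key} has shape {vals.shape}, expected {(n, n)}")
            kernels[comp] = vals
        return kernels

    def _chol(self, V: np.ndarray, scale: float):
        try:
            return linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            logger.warning("V not positive definite; retrying with ridge %.1e", self.ridge)
            try:
                return linalg.cho_factor(
                    V + self.ridge * scale * np.eye(V.shape[0]),
                    lower=True, check_finite=False)
            except linalg.LinAlgError as exc:
                raise GremlConvergenceError(
                    "coefficient matrix is singular even with ridge; "
                    "consider a larger ridge", []) from exc

    def _loglik_only(self, sigma, active, kernels, X, y, scale):
        """Restricted log-likelihood without forming P (O(n^2 p))."""
        V = sum(sigma[c] * kernels[c] for c in active)
        c_and_lower = self._chol(V, scale)
        logdet_V = 2.0 * np.sum(np.log(np.diag(c_and_lower[0])))
        W = linalg.cho_solve(c_and_lower, X, check_finite=False)
        Viy = linalg.cho_solve(c_and_lower, y, check_finite=False)
        C = X.T @ W
        sign, logdet_C = np.linalg.slogdet(C)
        beta = np.linalg.solve(C, W.T @ y)
        Py = Viy - W @ beta
        n, p = X.shape
        ll = -0.5 * (logdet_V + logdet_C + float(y @ Py)
                     + (n - p) * np.log(2.0 * np.pi))
        return ll, beta, Py, c_and_lower

    # -- fitting ----------------------------------------------------------

    def fit(self, design: ModelDesign, relationships: dict | None = None) -> "GREML":
        if self.model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model {self.model!r}; choose from "
                             f"{sorted(MODEL_COMPONENTS)}")
        relationships = relationships or {}
        kernels = self._collect_kernels(design, relationships)
        components = MODEL_COMPONENTS[self.model]
        X, y = design.X, design.y
        n, p = X.shape

        # phenotypic scale from the OLS residual variance
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        v0 = float(np.var(y - X @ beta0, ddof=p))
        if v0 <= 0:
            raise ValueError("zero residual variance: y is in the column space of X")
        floor = 1e-8 * v0

        n_random = len(components) - 1  # all but residual
        sigma = {c: 0.5 * v0 / n_random for c in components}
        sigma["residual"] = 0.5 * v0
        active = [c for c in components]
        fixed_to_zero = {c: False for c in components}
        at_floor_count = {c: 0 for c in components}

        trajectory = []
        loglik = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            V = sum(sigma[c] * kernels[c] for c in active)
            c_and_lower = self._chol(V, v0)
            logdet_V = 2.0 * np.sum(np.log(np.diag(c_and_lower[0])))
            Vi = linalg.cho_solve(c_and_lower, np.eye(n), check_finite=False)
            W = Vi @ X
            C = X.T @ W
            Ci = np.linalg.inv(C)
            beta = Ci @ (W.T @ y)
            Py = Vi @ y - W @ (Ci @ (W.T @ y))
            P = Vi - W @ Ci @ W.T
            sign, logdet_C = np.linalg.slogdet(C)
            new_loglik = -0.5 * (logdet_V + logdet_C + float(y @ Py)
                                 + (n - p) * np.log(2.0 * np.pi))

            score = np.empty(len(active))
            T = np.empty((n, len(active)))
            for k, comp in enumerate(active):
                K = kernels[comp]
                KPy = K @ Py
                T[:, k] = KPy
                trPK = float(np.sum(P * K))  # tr(P K), both symmetric
                score[k] = -0.5 * (trPK - float(Py @ KPy))
            PT = P @ T
            AI = 0.5 * (T.T @ PT)
            AI = (AI + AI.T) / 2.0

            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = score * (2.0 * v0 / n)  # tiny gradient step fallback

            sig_vec = np.array([sigma[c] for c in active])
            prev_ll = new_loglik

            def line_search(raw_step):
                """Park negatives at the floor, then halve until the
                restricted likelihood stops decreasing."""
                target = np.maximum(sig_vec + raw_step, floor)
                direction = target - sig_vec
                scale = 1.0
                for _ in range(30):
                    cand = sig_vec + scale * direction
                    ll_try, *_ = self._loglik_only(
                        dict(zip(active, cand)), active, kernels, X, y, v0)
                    if ll_try >= prev_ll - 1e-10:
                        return cand
                    if np.max(np.abs(scale * direction)) < floor:
                        break
                    scale *= 0.5
                return None

            pushing_negative = (sig_vec + delta) < 0.0
            prop = line_search(delta)
            if prop is None and pushing_negative.any():
                # active-set refinement: hold the components pushed against
                # the boundary at the floor and re-solve AI for the rest
                free = ~pushing_negative
                restricted = np.where(free, 0.0, floor - sig_vec)
                if free.any():
                    sub = np.ix_(free, free)
                    try:
                        restricted[free] = np.linalg.solve(AI[sub], score[free])
                    except np.linalg.LinAlgError:
                        restricted[free] = score[free] * (2.0 * v0 / n)
                prop = line_search(restricted)
            if prop is None:
                # EM-flavoured gradient fallback when the AI directions fail
                em_step = (2.0 / n) * sig_vec ** 2 * score
                pushing_negative |= (sig_vec + em_step) < 0.0
                prop = line_search(em_step)
            if prop is None:
                prop = sig_vec  # no ascent direction left at this precision

            delta_sigma = np.max(np.abs(prop - sig_vec))
            for k, comp in enumerate(active):
                sigma[comp] = float(prop[k])

            # boundary handling: a component that keeps pushing below zero
            # from (or into) the floor is fixed to exactly zero
            newly_fixed = []
            s2p_now = sum(sigma[c] for c in PHENOTYPIC_COMPONENTS if c in sigma)
            for k, comp in enumerate(active):
                if comp == "residual":
                    continue
                near_zero = sigma[comp] <= max(floor * 1.0001, 1e-6 * s2p_now)
                if pushing_negative[k] and near_zero:
                    at_floor_count[comp] += 1
                else:
                    at_floor_count[comp] = 0
                if at_floor_count[comp] >= 2:
                    newly_fixed.append(comp)
            for comp in newly_fixed:
                sigma[comp] = 0.0
                fixed_to_zero[comp] = True
                active.remove(comp)
                logger.info("component %s fixed to 0 (estimate went negative)", comp)

            trajectory.append((it, new_loglik, dict(sigma)))
            if self.verbose:
                logger.info("iter %d loglik %.6f sigma %s", it, new_loglik, sigma)

            s2p = sum(sigma[c] for c in PHENOTYPIC_COMPONENTS if c in sigma)
            if (not newly_fixed and it > 1
                    and abs(new_loglik - loglik) < self.tol
                    and delta_sigma / max(s2p, floor) < self.tol):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik

        if not converged:
            raise GremlConvergenceError(
                f"AI-REML did not converge in {self.max_iter} iterations", trajectory)

        # final quantities at the converged components; the average
        # information matrix is evaluated over every model component,
        # including those fixed at the zero boundary, so such components
        # still carry a curvature-based standard error
        loglik, beta, Py, c_and_lower = self._loglik_only(sigma, active, kernels, X, y, v0)
        Vi = linalg.cho_solve(c_and_lower, np.eye(n), check_finite=False)
        W = Vi @ X
        C = X.T @ W
        Ci = np.linalg.inv(C)
        P = Vi - W @ Ci @ W.T
        T = np.empty((n, len(components)))
        for k, comp in enumerate(components):
            T[:, k] = kernels[comp] @ Py
        AI = 0.5 * (T.T @ (P @ T))
        AI = (AI + AI.T) / 2.0
        cov = np.linalg.pinv(AI)
        se = {comp: float(np.sqrt(max(cov[k, k], 0.0)))
              for k, comp in enumerate(components)}

        blups = {}
        for comp in components:
            if comp == "hys":
                blups["hys"] = sigma["hys"] * (design.Q.T @ Py)
            elif comp == "residual":
                blups["residual"] = sigma["residual"] * Py
            elif comp in active:
                blups[comp] = sigma[comp] * (kernels[comp] @ Py)
            else:
                blups[comp] = np.zeros(n)

        self.result_ = GremlFit(
            model=self.model, components=components, sigma2=dict(sigma),
            se=se, fixed_to_zero=fixed_to_zero, beta=beta,
            beta_names=list(design.x_names), blups=blups, loglik=float(loglik),
            ai=AI, active=list(active), n_iter=it, converged=True,
            design=design, kernels=kernels,
        )
        self.sigma2_ = dict(sigma)
        self.se_ = se
        self.loglik_ = float(loglik)
        self.beta_ = beta
        self.n_iter_ = it
        return self


def fit_greml(design: ModelDesign, model: str, relationships: dict | None = None,
              **kwargs) -> GremlFit:
    """Fit one model and return its :class:`GremlFit`."""
    est = GREML(model=model, **kwargs)
    est.fit(design, relationships)
    return est.result_


def variance_ratios(fit: GremlFit) -> pd.DataFrame:
    """Relative variance components with delta-method standard errors.

    Ratios to the phenotypic variance (sigma2_P, which excludes HYS) for
    every phenotypic component and, for genetic components, ratios to the
    total genetic variance sigma2_G.  The covariance of the component
    estimates is the inverse average-information matrix; fixed-to-zero
    components are treated as the constant 0.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    s2p = fit.sigma2_P
    if s2p <= 0:
        raise ValueError("phenotypic variance is zero")
    cov = np.linalg.pinv(fit.ai)
    idx = {c: k for k, c in enumerate(fit.components)}

    def ratio_se(num: str, denom_set: tuple) -> float:
        S = sum(fit.sigma2[c] for c in denom_set if c in fit.sigma2)
        grad = np.zeros(len(fit.components))
        for comp, k in idx.items():
            g = 0.0
            if comp == num:
                g += 1.0 / S
            if comp in denom_set:
                g -= fit.sigma2[num] / S ** 2
            grad[k] = g
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    rows = []
    for comp in fit.components:
        if comp == "hys":
            continue
        est = fit.sigma2[comp]
        row = {
            "component": comp,
            "sigma2": est,
            "se": fit.se[comp],
            "ratio_P": est / s2p,
            "se_ratio_P": ratio_se(comp, PHENOTYPIC_COMPONENTS),
            "fixed_to_zero": fit.fixed_to_zero[comp],
        }
        if comp in GENETIC_COMPONENTS:
            s2g = fit.sigma2_G
            row["ratio_G"] = est / s2g if s2g > 0 else np.nan
            row["se_ratio_G"] = (ratio_se(comp, GENETIC_COMPONENTS)
                                 if s2g > 0 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LRTResult:
    """Boundary-corrected likelihood-ratio test for one variance component."""

    T: float
    p: float


def lrt(full: GremlFit, reduced: GremlFit) -> LRTResult:
    """Mixture chi-square test of a nested pair of fits.

    The reduced model must drop exactly the variance components absent
    from the full model's component list, on identical data and fixed
    effects.  T below zero is clamped to zero, giving p = 0.5.
    """
    if not set(reduced.components) < set(full.components):
        raise ValueError(f"model {reduced.model} is not nested in {full.model}")
    if reduced.design.n != full.design.n or reduced.design.X.shape != full.design.X.shape:
        raise ValueError("nested fits must share data and fixed effects")
    return lrt_from_loglik_difference(full.loglik - reduced.loglik)


def lrt_from_loglik_difference(diff: float) -> LRTResult:
    """LRT from a log-likelihood difference: T = 2*diff, P = 0.5*Pr(chi2_1 > T)."""
    T = max(2.0 * diff, 0.0)
    p = 0.5 * float(stats.chi2.sf(T, df=1))
    return LRTResult(T=T, p=p)


def component_correlations(fit: GremlFit) -> pd.DataFrame:
    """Correlations between variance-component estimates.

    Derived from the inverse of the average-information matrix of the
    converged fit, evaluated over every model component (boundary
    components included).
    """
    cov = np.linalg.pinv(fit.ai)
    sd = np.sqrt(np.diag(cov))
    if np.any(sd == 0):
        raise ValueError("singular average-information matrix")
    corr = cov / np.outer(sd, sd)
    return pd.DataFrame(corr, index=list(fit.components),
                        columns=list(fit.components))
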
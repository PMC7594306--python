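import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import rohdom as rd
from rohdom.greml import (GremlFit, GremlConvergenceError,
                          lrt_from_loglik_difference)


def toy_design(n=12, seed=0, n_herds=2):
    rng = np.random.default_rng(seed)
    pheno = pd.DataFrame({
        "animal": [f"a{i}" for i in range(n)],
        "y": rng.standard_normal(n) * 2 + 5,
        "herd": [f"h{i % n_herds}" for i in range(n)],
        "year": "2012",
        "season": [("Q1", "Q2")[(i // 2) % 2] for i in range(n)],
        "age": rng.uniform(22, 40, size=n),
    })
    hom = rng.uniform(0.6, 0.7, size=n)
    return pheno, hom


class TestBuildDesign:
    def test_dummy_coding_drops_reference_levels(self):
        pheno, hom = toy_design(n=8, n_herds=2)
        design = rd.build_design(pheno, hom)
        # intercept + 1 herd dummy + 0 year + 1 season dummy + age + homozygosity
        assert design.x_names == ["intercept", "herd[h1]", "season[Q2]",
                                  "age", "homozygosity_pct"]

    def test_homozygosity_enters_in_percent(self):
        pheno, hom = toy_design()
        hom = np.asarray(hom)
        hom[0] = 0.644
        design = rd.build_design(pheno, hom)
        col = design.X[:, design.x_names.index("homozygosity_pct")]
        assert col[0] == pytest.approx(64.4)
        np.testing.assert_allclose(col, hom * 100.0)

    def test_hys_levels_are_observed_triples(self):
        pheno, hom = toy_design(n=12, n_herds=3)
        design = rd.build_design(pheno, hom)
        observed = {(h, y, s) for h, y, s in
                    zip(pheno["herd"], pheno["year"], pheno["season"])}
        assert design.Q.shape[1] == len(observed)
        np.testing.assert_allclose(design.Q.sum(axis=1), 1.0)

    def test_missing_homozygosity_is_an_error(self):
        pheno, hom = toy_design()
        hom = np.asarray(hom)
        hom[3] = np.nan
        with pytest.raises(ValueError, match="a3"):
            rd.build_design(pheno, hom)


def reml_loglik_oracle(sigma, kernels, X, y):
    """Direct evaluation of the restricted log-likelihood (independent path)."""
    V = sum(s * K for s, K in zip(sigma, kernels))
    n, p = X.shape
    sign, logdet_V = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    C = X.T @ Vi @ X
    _, logdet_C = np.linalg.slogdet(C)
    beta = np.linalg.solve(C, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (logdet_V + logdet_C + r @ Vi @ r + (n - p) * np.log(2 * np.pi))


class TestFit:
    def test_toy_loglik_matches_direct_objective_maximum(self):
        # n=12 Model A: AI-REML optimum vs Nelder-Mead on the explicit
        # restricted-likelihood formula
        rng = np.random.default_rng(1)
        n = 12
        pheno, hom = toy_design(n=n, seed=1, n_herds=2)
        W = rng.standard_normal((n, 30))
        G = rd.RelationshipMatrix(kind="G", values=W @ W.T / 30, denominator=30.0)
        design = rd.build_design(pheno, hom)
        fit = rd.fit_greml(design, "A", {"additive": G})

        kernels = [design.Q @ design.Q.T, G.values, np.eye(n)]
        res = optimize.minimize(
            lambda ls: -reml_loglik_oracle(np.exp(ls), kernels, design.X, design.y),
            x0=np.log([1.0, 1.0, 1.0]), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_unknown_model_is_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown model"):
            rd.fit_greml(small_dataset["design"], "ADRX", small_dataset["rel"])

    def test_missing_matrix_is_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="D matrix"):
            rd.fit_greml(small_dataset["design"], "AD",
                         {"additive": small_dataset["rel"]["additive"]})

    def test_nonconvergence_carries_trajectory(self, small_dataset):
        with pytest.raises(GremlConvergenceError) as err:
            rd.fit_greml(small_dataset["design"], "A",
                         {"additive": small_dataset["rel"]["additive"]},
                         max_iter=2)
        assert len(err.value.trajectory) == 2

    def test_zero_dominance_is_detected_as_null(self):
        """With no generating dominance variance the sigma2_D estimate is
        fixed to zero or within 2 SE of zero in nearly all replicates."""
        ok = 0
        n_rep = 12
        for rep in range(n_rep):
            cfg = rd.SimConfig(seed=7000 + rep, n_final=1000, n_pop=200,
                               n_founders=80, n_chr=4, chr_length_bp=20_000_000,
                               n_markers=800, ratio_dominance=0.0, ratio_roh=0.0)
            geno, _ = rd.simulate_genotypes(cfg)
            status = rd.ROHStatusMatrix(x=np.zeros_like(geno.codes))
            pheno, _ = rd.simulate_phenotypes(geno, status, cfg)
            design = rd.build_design(pheno, rd.genome_wide_homozygosity(geno))
            freqs = geno.allele_frequencies()
            rel = {"additive": rd.build_G(rd.build_Z(geno, freqs), freqs),
                   "dominance": rd.build_D(rd.build_H(geno, freqs), freqs)}
            fit = rd.fit_greml(design, "AD", rel)
            if fit.fixed_to_zero["dominance"] or (
                    fit.sigma2["dominance"] <= 2 * fit.se["dominance"]):
                ok += 1
        assert ok >= 0.9 * n_rep

    def test_triple_loglik_never_decreases(self, nested_fits):
        assert nested_fits["AD"].loglik >= nested_fits["A"].loglik - 1e-6
        assert nested_fits["ADR"].loglik >= nested_fits["AD"].loglik - 1e-6

    def test_blup_consistency_mixed_model_identity(self, nested_fits):
        # at convergence y = X beta + Q c + u (+ v + w) + e exactly
        fit = nested_fits["ADR"]
        design = fit.design
        recon = design.X @ fit.beta + design.Q @ fit.blups["hys"]
        for comp in ("additive", "dominance", "roh", "residual"):
            recon = recon + fit.blups[comp]
        assert np.linalg.norm(recon - design.y) <= 1e-6 * np.linalg.norm(design.y)

    def test_homozygosity_coefficient_invariant_to_centering(self, small_dataset):
        design = small_dataset["design"]
        b_ref = rd.fit_greml(design, "A", small_dataset["rel"]).b_homozygosity
        shifted = rd.ModelDesign(
            y=design.y, X=design.X.copy(), x_names=design.x_names,
            Q=design.Q, hys_labels=design.hys_labels, animals=design.animals)
        j = design.x_names.index("homozygosity_pct")
        shifted.X[:, j] = shifted.X[:, j] - shifted.X[:, j].mean()
        b_centered = rd.fit_greml(shifted, "A", small_dataset["rel"]).b_homozygosity
        assert b_centered == pytest.approx(b_ref, abs=1e-6 * max(1, abs(b_ref)))

    def test_directional_dominance_recovered_from_homozygosity_slope(self):
        # constant per-SNP dominance d_bar: fitted b is -d_bar*N per unit
        cfg = rd.SimConfig(seed=99, n_final=1000, n_pop=250, n_founders=100,
                           n_chr=5, chr_length_bp=40_000_000, n_markers=2000,
                           ratio_dominance=0.0, ratio_roh=0.0,
                           ratio_additive=0.25, d_bar=0.1)
        geno, _ = rd.simulate_genotypes(cfg)
        status = rd.ROHDetector().fit_transform(geno)
        pheno, truth = rd.simulate_phenotypes(geno, status, cfg)
        design = rd.build_design(pheno, rd.genome_wide_homozygosity(geno))
        freqs = geno.allele_frequencies()
        fit = rd.fit_greml(design, "A",
                           {"additive": rd.build_G(rd.build_Z(geno, freqs), freqs)})
        assert fit.b_homozygosity == pytest.approx(
            truth.b_homozygosity_per_pct, rel=0.15)
        d_bar_hat = rd.mean_dominance(fit.b_homozygosity, geno.n_markers)
        assert d_bar_hat == pytest.approx(cfg.d_bar, rel=0.15)


def synthetic_fit(sigma2, ai, components=None, fixed=()):
    """Hand-assembled GremlFit for pure arithmetic operations.

    ``ai`` is the average-information matrix over all components.
    """
    components = components or tuple(sigma2)
    active = [c for c in components if c not in fixed]
    cov = np.linalg.pinv(np.asarray(ai, dtype=float))
    se = {c: float(np.sqrt(cov[i, i])) for i, c in enumerate(components)}
    return GremlFit(
        model="ADR", components=components, sigma2=dict(sigma2), se=se,
        fixed_to_zero={c: c in fixed for c in components},
        beta=np.zeros(1), beta_names=["intercept"], blups={},
        loglik=0.0, ai=np.asarray(ai, dtype=float), active=active,
        n_iter=1, converged=True, design=None, kernels={})


class TestVarianceRatios:
    def test_single_nonzero_component_has_unit_ratio(self):
        fit = synthetic_fit(
            {"hys": 0.0, "additive": 4.0, "dominance": 0.0, "roh": 0.0,
             "residual": 0.0},
            ai=np.eye(5), components=("hys", "additive", "dominance", "roh",
                                      "residual"),
            fixed=("hys", "dominance", "roh", "residual"))
        tab = rd.variance_ratios(fit).set_index("component")
        assert tab.loc["additive", "ratio_P"] == pytest.approx(1.0)
        assert np.isfinite(tab.loc["additive", "se_ratio_P"])

    def test_equal_additive_and_residual_gives_half(self, nested_fits):
        fit = synthetic_fit(
            {"hys": 1.0, "additive": 3.0, "dominance": 0.0, "roh": 0.0,
             "residual": 3.0},
            ai=np.eye(5), components=("hys", "additive", "dominance", "roh",
                                      "residual"),
            fixed=("dominance", "roh"))
        tab = rd.variance_ratios(fit).set_index("component")
        assert tab.loc["additive", "ratio_P"] == pytest.approx(0.5)
        assert tab.loc["additive", "ratio_G"] == pytest.approx(1.0)

    def test_delta_method_matches_finite_differences(self):
        ai = np.array([[4.0, 1.0], [1.0, 2.0]])
        sigma = {"additive": 3.0, "residual": 5.0}
        fit = synthetic_fit(sigma, ai, components=("additive", "residual"))
        tab = rd.variance_ratios(fit).set_index("component")
        cov = np.linalg.inv(ai)

        def ratio(vec):
            return vec[0] / (vec[0] + vec[1])

        x0 = np.array([3.0, 5.0])
        eps = 1e-6
        grad = np.array([
            (ratio(x0 + eps * np.eye(2)[k]) - ratio(x0 - eps * np.eye(2)[k]))
            / (2 * eps) for k in range(2)])
        expected_se = np.sqrt(grad @ cov @ grad)
        assert tab.loc["additive", "se_ratio_P"] == pytest.approx(expected_se,
                                                                  rel=1e-5)

    def test_phenotypic_variance_excludes_hys(self, nested_fits):
        fit = nested_fits["ADR"]
        s2p = sum(fit.sigma2[c] for c in ("additive", "dominance", "roh",
                                          "residual"))
        assert fit.sigma2_P == pytest.approx(s2p)
        assert fit.sigma2_P < s2p + fit.sigma2["hys"] or fit.sigma2["hys"] == 0


class TestLrt:
    @pytest.mark.parametrize("diff,printed_p", [
        (4.17, 0.002), (1.437, 0.045), (5.014, None), (2.355, 0.015),
        (0.236, 0.246), (0.382, 0.191), (0.0, 0.5)])
    def test_reproduces_published_pvalues(self, diff, printed_p):
        res = lrt_from_loglik_difference(diff)
        if printed_p is None:
            assert res.p < 0.001
        else:
            assert round(res.p, 3) == printed_p

    def test_negative_difference_clamped_to_half(self):
        res = lrt_from_loglik_difference(-0.3)
        assert res.T == 0.0 and res.p == 0.5

    def test_p_in_half_open_interval(self):
        for diff in np.linspace(0, 20, 50):
            p = lrt_from_loglik_difference(diff).p
            assert 0 < p <= 0.5

    def test_nested_pair(self, nested_fits):
        res = rd.lrt(nested_fits["AD"], nested_fits["A"])
        assert res.T == pytest.approx(
            2 * (nested_fits["AD"].loglik - nested_fits["A"].loglik), abs=1e-9)
        with pytest.raises(ValueError, match="not nested"):
            rd.lrt(nested_fits["A"], nested_fits["AD"])


class TestComponentCorrelations:
    def test_diagonal_ai_gives_zero_correlations(self):
        fit = synthetic_fit({"additive": 1.0, "residual": 2.0},
                            ai=np.diag([4.0, 9.0]),
                            components=("additive", "residual"))
        corr = rd.component_correlations(fit)
        assert corr.loc["additive", "residual"] == pytest.approx(0.0)

    def test_matches_2x2_algebra(self):
        ai = np.array([[4.0, 1.0], [1.0, 1.0]])
        fit = synthetic_fit({"additive": 1.0, "residual": 2.0}, ai,
                            components=("additive", "residual"))
        cov = np.linalg.inv(ai)
        expected = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert rd.component_correlations(fit).iloc[0, 1] == pytest.approx(expected)

    def test_symmetric_with_unit_diagonal(self, nested_fits):
        corr = rd.component_correlations(nested_fits["ADR"])
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
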
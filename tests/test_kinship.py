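import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rohdom as rd
from conftest import make_genotypes


class TestCovariates:
    def test_Z_at_half_frequency(self):
        geno = make_genotypes([[0], [1], [2], [1]])  # p = 0.5
        Z = rd.build_Z(geno)
        np.testing.assert_allclose(Z[:, 0], [-1.0, 0.0, 1.0, 0.0])

    def test_Z_monomorphic_is_zero(self):
        geno = make_genotypes([[2], [2], [2]])  # p = 1
        assert np.all(rd.build_Z(geno) == 0.0)

    def test_Z_columns_centered(self):
        rng = np.random.default_rng(2)
        geno = make_genotypes(rng.integers(0, 3, size=(40, 25)))
        np.testing.assert_allclose(rd.build_Z(geno).mean(axis=0), 0.0, atol=1e-12)

    def test_H_at_half_frequency(self):
        geno = make_genotypes([[0], [1], [2], [1]])
        np.testing.assert_allclose(rd.build_H(geno)[:, 0], [-0.5, 0.5, -0.5, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 0.99))
    def test_H_zero_mean_under_hardy_weinberg(self, p):
        # p^2*(-2q^2) + 2pq*(2pq) + q^2*(-2p^2) = 0 for any p
        q = 1.0 - p
        expected = q * q * (-2 * p * p) + 2 * p * q * (2 * p * q) + p * p * (-2 * q * q)
        assert expected == pytest.approx(0.0, abs=1e-12)

    def test_H_monomorphic_is_zero(self):
        geno = make_genotypes([[0], [0], [0]])
        assert np.all(rd.build_H(geno) == 0.0)

    def test_M_never_in_roh_column_is_zero(self):
        status = rd.ROHStatusMatrix(x=np.array([[0, 1], [0, 0]]))
        M = rd.build_M(status)
        assert np.all(M[:, 0] == 0.0)
        np.testing.assert_allclose(M[:, 1], [0.5, -0.5])

    def test_M_columns_centered(self):
        rng = np.random.default_rng(4)
        status = rd.ROHStatusMatrix(x=(rng.uniform(size=(30, 20)) < 0.3).astype(int))
        np.testing.assert_allclose(rd.build_M(status).mean(axis=0), 0.0, atol=1e-12)


class TestGramMatrices:
    def test_G_single_snp_hand_calculation(self):
        # animals AA and BB at one SNP with p=0.5: Z=(1,-1), denom=0.5
        geno = make_genotypes([[2], [0]])
        G = rd.build_G(rd.build_Z(geno), geno.allele_frequencies())
        np.testing.assert_allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_genotypes_identical_rows(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(5, 50))
        codes[3] = codes[1]
        geno = make_genotypes(codes)
        G = rd.build_G(rd.build_Z(geno), geno.allele_frequencies())
        np.testing.assert_allclose(G.values[1], G.values[3])

    def test_G_mean_diagonal_near_one_under_hardy_weinberg(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, size=5000)
        codes = rng.binomial(2, p, size=(200, 5000)).astype(np.uint8)
        geno = make_genotypes(codes, positions=(np.arange(5000) + 1) * 1000)
        G = rd.build_G(rd.build_Z(geno), geno.allele_frequencies())
        assert np.mean(np.diag(G.values)) == pytest.approx(1.0, abs=0.05)

    def test_all_monomorphic_is_an_error(self):
        geno = make_genotypes([[2, 0], [2, 0]])
        with pytest.raises(ValueError, match="2pq"):
            rd.build_G(rd.build_Z(geno), geno.allele_frequencies())

    def test_D_single_heterozygote_hand_calculation(self):
        geno = make_genotypes([[1], [0], [2], [1]])  # p = 0.5
        D = rd.build_D(rd.build_H(geno), geno.allele_frequencies())
        assert D.values[0, 0] == pytest.approx((0.5 ** 2) / 0.25)

    def test_D_all_homozygous_single_snp_is_constant_one(self):
        geno = make_genotypes([[2], [0], [2], [0]])  # p = 0.5, H = -0.5
        D = rd.build_D(rd.build_H(geno), geno.allele_frequencies())
        np.testing.assert_allclose(D.values, 1.0)

    def test_R_worked_example(self):
        assert rd.load_worked_roh_example().shape == (30, 4)
        from rohdom.studies import worked_r_relationship
        assert round(worked_r_relationship(), 4) == 0.8749

    def test_R_diagonal_for_animal_without_roh(self):
        # animal 3 has no ROH anywhere: R_33 = sum(p*^2) / sum(p* q*)
        x = np.array([[1, 1, 0], [0, 1, 1], [0, 0, 0]])
        status = rd.ROHStatusMatrix(x=x)
        R = rd.build_R(rd.build_M(status), status)
        p = status.p_star
        expected = np.sum(p ** 2) / np.sum(p * (1 - p))
        assert R.values[2, 2] == pytest.approx(expected)

    def test_R_identical_status_rows(self):
        x = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 0]])
        status = rd.ROHStatusMatrix(x=x)
        R = rd.build_R(rd.build_M(status), status)
        assert R.values[0, 1] == pytest.approx(R.values[0, 0])
        assert R.values[0, 0] == pytest.approx(R.values[1, 1])

    def test_R_requires_variation(self):
        status = rd.ROHStatusMatrix(x=np.zeros((3, 5), dtype=int))
        with pytest.raises(ValueError, match="p\\*q\\*"):
            rd.build_R(rd.build_M(status), status)

    def test_all_builds_are_positive_semidefinite(self, small_dataset):
        for key in ("additive", "dominance", "roh"):
            mat = small_dataset["rel"][key]
            assert mat.min_eigenvalue_ratio() >= -1e-8

    def test_allele_relabel_leaves_G_and_D_unchanged(self):
        rng = np.random.default_rng(12)
        codes = rng.integers(0, 3, size=(25, 40))
        geno = make_genotypes(codes)
        flip = rng.uniform(size=40) < 0.5
        flipped = codes.copy()
        flipped[:, flip] = 2 - flipped[:, flip]
        geno2 = make_genotypes(flipped)
        for build, cov in ((rd.build_G, rd.build_Z), (rd.build_D, rd.build_H)):
            m1 = build(cov(geno), geno.allele_frequencies())
            m2 = build(cov(geno2), geno2.allele_frequencies())
            np.testing.assert_allclose(m1.values, m2.values, atol=1e-10)


class TestOrthogonalization:
    def test_already_orthogonal_returned_unchanged(self):
        rng = np.random.default_rng(20)
        n = 40
        Z = np.zeros((n, 1))
        H = np.zeros((n, 1))
        M = rng.standard_normal((n, 1))
        M -= M.mean()
        out = rd.orthogonalize_M(M, Z, H)
        np.testing.assert_allclose(out, M, atol=1e-10)

    def test_M_equal_to_Z_becomes_zero(self):
        rng = np.random.default_rng(21)
        Z = rng.standard_normal((30, 2))
        H = rng.standard_normal((30, 2))
        out = rd.orthogonalize_M(Z.copy(), Z, H)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, small_dataset):
        Z, H, M = (small_dataset[k] for k in ("Z", "H", "M"))
        sub = slice(0, 200)
        out = rd.orthogonalize_M(M[sub, :50], Z[sub, :50], H[sub, :50])
        n = out.shape[0]
        for i in range(50):
            assert abs(out[:, i] @ Z[sub, i]) <= 1e-8 * n
            assert abs(out[:, i] @ H[sub, i]) <= 1e-8 * n


class TestOffdiagCorrelation:
    def test_self_correlation_is_one(self, small_dataset):
        G = small_dataset["rel"]["additive"]
        assert rd.offdiag_correlation(G, G) == pytest.approx(1.0)

    def test_negated_matrix_is_minus_one(self, small_dataset):
        G = small_dataset["rel"]["additive"]
        neg = rd.RelationshipMatrix(kind="G", values=-G.values,
                                    denominator=G.denominator)
        assert rd.offdiag_correlation(G, neg) == pytest.approx(-1.0)

    def test_matches_bruteforce_on_4x4(self):
        rng = np.random.default_rng(30)
        A = rng.standard_normal((4, 4)); A = A + A.T
        B = rng.standard_normal((4, 4)); B = B + B.T
        ra = rd.RelationshipMatrix(kind="G", values=A @ A.T + 8 * np.eye(4),
                                   denominator=1.0)
        rb = rd.RelationshipMatrix(kind="D", values=B @ B.T + 8 * np.eye(4),
                                   denominator=1.0)
        pairs_a = [ra.values[i, j] for i in range(4) for j in range(i)]
        pairs_b = [rb.values[i, j] for i in range(4) for j in range(i)]
        expected = np.corrcoef(pairs_a, pairs_b)[0, 1]
        assert rd.offdiag_correlation(ra, rb) == pytest.approx(expected)

    def test_G_D_nearly_orthogonal_under_hardy_weinberg(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.05, 0.95, size=5000)
        codes = rng.binomial(2, p, size=(500, 5000)).astype(np.uint8)
        geno = make_genotypes(codes, positions=(np.arange(5000) + 1) * 1000)
        freqs = geno.allele_frequencies()
        G = rd.build_G(rd.build_Z(geno, freqs), freqs)
        D = rd.build_D(rd.build_H(geno, freqs), freqs)
        assert abs(rd.offdiag_correlation(G, D)) < 0.05
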
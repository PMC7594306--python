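"""Reproduction studies: the quantitative checks the pipeline is validated by.

Each function here recomputes one headline quantity from scratch by
running the package — either on published summary statistics from a large
Holstein Friesian reference analysis (printed log-likelihood differences,
homozygosity regression coefficients and variance components, which act
as inputs), or on synthetic datasets with known ground truth.  The same
functions back both the acceptance test suite and the standalone
acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import (
    GREML,
    ROHDetector,
    ROHStatusMatrix,
    SimConfig,
    SingleSnpGWAS,
    build_D,
    build_G,
    build_H,
    build_M,
    build_R,
    build_Z,
    build_design,
    detect_roh,
    fit_greml,
    genome_wide_homozygosity,
    load_worked_roh_example,
    lrt_from_loglik_difference,
    mean_dominance,
    full_dominance_variance,
    simulate_genotypes,
    simulate_phenotypes,
)
from .datatypes import GenotypeMatrix
from .roh import ROHParams
from .snp_effects import backsolve_additive, backsolve_dominance, backsolve_roh
from .validation import detect_roh_bruteforce

# ---------------------------------------------------------------------------
# published reference inputs (38,792-cow Holstein Friesian analysis, 75,377
# SNPs): restricted log-likelihood differences between nested GREML models
# and homozygosity regression coefficients per 1% homozygosity
# ---------------------------------------------------------------------------

#: log-likelihood gains (AD over A, ADR over AD) for nine traits
REFERENCE_LOGLIK_GAINS = {
    "milk_yield": (4.17, 1.437),
    "fat_yield": (5.014, 2.355),
    "protein_yield": (4.141, 2.120),
    "calving_interval": (0.000, 0.236),
    "interval_calving_first_insemination": (0.382, 0.436),
    "interval_first_last_insemination": (0.026, 0.000),
    "conception_rate": (0.004, 0.000),
    "somatic_cell_score_150": (0.107, 0.007),
    "somatic_cell_score_400": (0.464, 0.000),
}

REFERENCE_N_SNP = 75_377

#: Model-A homozygosity coefficients b (trait units per 1% homozygosity)
REFERENCE_B_PER_PCT = {"fat_yield": -4.10, "calving_interval": 1.11,
                       "milk_yield": -99.6}

#: milk-yield dominance variance, its directional-dominance completion
#: term and the phenotypic variance (kg^2), Model AD
REFERENCE_MILK_SIGMA2_D = 10_377.0
REFERENCE_MILK_DIRECTIONAL_TERM = 189.0
REFERENCE_MILK_SIGMA2_P = 1_356_134.0


def lrt_pvalues_from_reference() -> dict:
    """Mixture chi-square P-values recomputed from the printed gains."""
    out = {}
    for trait, (gain_ad, gain_adr) in REFERENCE_LOGLIK_GAINS.items():
        out[f"{trait}_AD_vs_A"] = lrt_from_loglik_difference(gain_ad).p
        out[f"{trait}_ADR_vs_AD"] = lrt_from_loglik_difference(gain_adr).p
    return out


def mean_dominance_from_reference() -> dict:
    """-b/N_SNP on the per-unit scale for the reference traits."""
    return {trait: mean_dominance(b, REFERENCE_N_SNP)
            for trait, b in REFERENCE_B_PER_PCT.items()}


def full_dominance_share_milk() -> float:
    """Full relative dominance variance (%) for milk yield.

    Completes the printed dominance variance with the printed directional
    component and expresses it as a percentage of the phenotypic variance.
    The completion term N * mean((2pq)^2) * d_bar^2 is passed through
    :func:`full_dominance_variance` as a single precomputed product.
    """
    s2_full = full_dominance_variance(
        REFERENCE_MILK_SIGMA2_D, n_snp=1,
        mean_sq_het=REFERENCE_MILK_DIRECTIONAL_TERM, d_bar=1.0)
    return 100.0 * s2_full / REFERENCE_MILK_SIGMA2_P


def worked_r_relationship() -> float:
    """ROH relationship between the two animals of the worked 30-SNP example."""
    ex = load_worked_roh_example()
    status = ROHStatusMatrix(
        x=np.vstack([ex["x_j"].to_numpy(), ex["x_k"].to_numpy()]),
        p_star=ex["p_star"].to_numpy())
    R = build_R(build_M(status), status)
    return float(R.values[0, 1])


# ---------------------------------------------------------------------------
# synthetic studies
# ---------------------------------------------------------------------------

def _random_small_chromosome(rng: np.random.Generator):
    """One random <= 60-marker chromosome mixing ROH-like and noisy tracts."""
    m = int(rng.integers(20, 61))
    spacing = rng.choice([60_000, 90_000, 110_000, 200_000])
    pos = np.cumsum(rng.integers(int(spacing * 0.4), int(spacing * 1.8), size=m)) + 1
    het_rate = rng.choice([0.02, 0.1, 0.35])
    het = (rng.uniform(size=m) < het_rate).astype(np.int8)
    if rng.uniform() < 0.7:  # implant a homozygous tract
        a = int(rng.integers(0, m // 2))
        b = int(rng.integers(a + 5, m))
        het[a:b] = 0
        if rng.uniform() < 0.5 and b - a > 4:
            het[int(rng.integers(a, b))] = 1
    return pos.astype(np.int64), het


def roh_oracle_agreement(n_chromosomes: int = 200, seed: int = 0,
                         params: ROHParams | None = None) -> float:
    """Fraction of random small chromosomes where the optimized detector
    and the exhaustive-enumeration oracle return identical segment sets."""
    if params is None:
        params = ROHParams()
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_chromosomes):
        pos, het = _random_small_chromosome(rng)
        m = het.size
        codes = np.where(het == 1, 1, 2 * rng.integers(0, 2, size=m)).astype(np.uint8)
        geno = GenotypeMatrix(
            codes=codes[None, :], samples=["x"],
            markers=_markers_frame(pos))
        segs = detect_roh(geno, params)
        got = sorted((int(s), int(e)) for s, e in
                     zip(segs["start_index"], segs["end_index"]))
        expected = detect_roh_bruteforce(het, pos, params)
        agree += got == expected
    return agree / n_chromosomes


def _markers_frame(pos: np.ndarray):
    import pandas as pd
    return pd.DataFrame({"chrom": "1", "snp": [f"s{i}" for i in range(pos.size)],
                         "pos": pos, "a1": "A", "a2": "B"})


def backsolve_identity_error(seed: int = 0, n: int = 120, m: int = 400) -> float:
    """Worst relative reconstruction error over the three back-solves.

    Random genotypes and ROH statuses are drawn, BLUP-like vectors are
    taken inside the span of each relationship matrix, and the identities
    Z alpha = u, H d = v, M r = w are evaluated.
    """
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(n, m)).astype(np.uint8)
    pos = np.arange(1, m + 1) * 100_000
    geno = GenotypeMatrix(codes=codes, samples=[f"a{i}" for i in range(n)],
                          markers=_markers_frame(pos))
    freqs = geno.allele_frequencies()
    x = (rng.uniform(size=(n, m)) < 0.15).astype(np.uint8)
    status = ROHStatusMatrix(x=x)
    Z, H, M = build_Z(geno, freqs), build_H(geno, freqs), build_M(status)
    G, D = build_G(Z, freqs), build_D(H, freqs)
    R = build_R(M, status)
    worst = 0.0
    for K, W, solver, extra in (
            (G, Z, backsolve_additive, freqs),
            (D, H, backsolve_dominance, freqs),
            (R, M, backsolve_roh, status)):
        u = K.values @ rng.standard_normal(n)  # in the span of K
        eff = solver(u, W, K, extra)
        err = np.linalg.norm(W @ eff - u) / np.linalg.norm(u)
        worst = max(worst, float(err))
    return worst


def recovery_config(seed: int) -> SimConfig:
    """The desk-scale ADR recovery conditions (one replicate)."""
    return SimConfig(seed=seed)


def parameter_recovery_study(n_replicates: int = 25, seed: int = 0) -> dict:
    """ADR variance-component recovery on the default study conditions.

    For each replicate a dataset is simulated, ROH are detected, G/D/R
    are built and Model ADR is fitted; a component is 'recovered' when
    its estimate lies within two reported standard errors of the
    generating value.  Returns per-component recovery fractions plus the
    mean fitted homozygosity coefficient against its generating value.
    """
    comps = ("hys", "additive", "dominance", "roh", "residual")
    hits = {c: 0 for c in comps}
    b_est, b_true = [], []
    for rep in range(n_replicates):
        cfg = recovery_config(seed=seed * 100_003 + 1000 + rep)
        fit, truth = _fit_adr_replicate(cfg)
        for c in comps:
            if (not np.isnan(fit.se[c])
                    and abs(fit.sigma2[c] - truth.sigma2[c]) <= 2 * fit.se[c]):
                hits[c] += 1
        b_est.append(fit.b_homozygosity)
        b_true.append(truth.b_homozygosity_per_pct)
    out = {f"recovery_{c}": hits[c] / n_replicates for c in comps}
    out["b_homozygosity_mean"] = float(np.mean(b_est))
    out["b_homozygosity_true"] = float(np.mean(b_true))
    return out


def _fit_adr_replicate(cfg: SimConfig):
    geno, _ = simulate_genotypes(cfg)
    status = ROHDetector().fit_transform(geno)
    pheno, truth = simulate_phenotypes(geno, status, cfg)
    design = build_design(pheno, genome_wide_homozygosity(geno))
    freqs = geno.allele_frequencies()
    Z, H, M = build_Z(geno, freqs), build_H(geno, freqs), build_M(status)
    rel = {"additive": build_G(Z, freqs), "dominance": build_D(H, freqs),
           "roh": build_R(M, status)}
    fit = fit_greml(design, "ADR", rel)
    return fit, truth


def null_calibration_config(seed: int) -> SimConfig:
    """Fully null conditions for GWAS calibration.

    All random components are zero (pure fixed effects plus residual
    noise) and inbreeding is purely drift-driven: a small founder pool
    and fifteen generations of random mating give old, short, numerous
    ROH, which maximizes the effective number of independent ROH tests
    per replicate.
    """
    return SimConfig(
        seed=seed, n_final=1200, n_founders=50, n_pop=150, n_generations=15,
        n_chr=10, chr_length_bp=50_000_000, n_markers=5000,
        close_mating_fraction=0.0,
        ratio_additive=0.0, ratio_dominance=0.0, ratio_roh=0.0,
        d_bar=0.0, sigma2_hys=0.0)


def gwas_null_study(n_replicates: int = 40, seed: int = 0) -> dict:
    """Type-I error and genomic inflation of the scan on null data.

    Statistics are pooled over replicates: the reported type-I error is
    the pooled fraction of P < 0.05 and lambda is the pooled median
    chi-square over its null median, per effect type.  Pooling is
    essential for the ROH effect: in-ROH status is heavily correlated
    along the genome, so a single replicate carries only ~200 effective
    independent ROH tests and its lambda scatters with sd ~0.13.
    """
    from scipy import stats

    pooled = {e: [] for e in ("additive", "dominance", "roh")}
    for rep in range(n_replicates):
        cfg = null_calibration_config(seed=seed * 100_003 + 5000 + rep)
        geno, _ = simulate_genotypes(cfg)
        status = ROHDetector().fit_transform(geno)
        pheno, _ = simulate_phenotypes(geno, status, cfg)
        design = build_design(pheno, genome_wide_homozygosity(geno))
        freqs = geno.allele_frequencies()
        G = build_G(build_Z(geno, freqs), freqs)
        null_fit = fit_greml(design, "A", {"additive": G})
        scan = SingleSnpGWAS().fit(design, geno, status, null_fit)
        for e in pooled:
            t = scan.results_[f"{e}_t"].to_numpy()
            pooled[e].append(t[~np.isnan(t)])
    out = {}
    null_median = float(stats.chi2.ppf(0.5, 1))
    for e, chunks in pooled.items():
        t = np.concatenate(chunks)
        out[f"type1_{e}"] = float(np.mean(2.0 * stats.norm.sf(np.abs(t)) < 0.05))
        out[f"lambda_{e}"] = float(np.median(t ** 2) / null_median)
    return out
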
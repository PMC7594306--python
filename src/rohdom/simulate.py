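"""Synthetic genotypes and phenotypes with known ground truth.

Genotypes are produced by gene dropping: founder haplotypes are drawn
from a roughly uniform allele-frequency spectrum, and descendants are
formed by meiosis with Haldane (no-interference) recombination at a
constant cM/Mb rate.  A configurable fraction of matings is between full
sibs (falling back to half sibs), which creates genuine identity-by-
descent runs of homozygosity of realistic length, on top of background
inbreeding from the finite founder pool.  The resulting population has
tightly distributed genome-wide homozygosity (around two thirds) and a
mean per-SNP in-ROH frequency on the order of ten percent — the regime
the ROH-based relationship matrix is designed for.

Phenotypes follow the ADR generative model with *raw* (uncentred)
dominance and ROH incidences,

    y = Xb + Qc + sum_j z_j a_j + sum_j het_j d_j + sum_j x_j r_j + e,

with per-SNP dominance effects d_j = d_bar + delta_j.  Using the raw
heterozygosity indicator makes a nonzero mean dominance d_bar appear as
genuine inbreeding depression: the mean dominance term is equivalent to a
regression of y on genome-wide homozygosity with slope -d_bar * N_SNP per
unit homozygosity (so -d_bar * N_SNP / 100 per 1%), which is exactly the
signal the fixed homozygosity covariate of the GREML models absorbs.  Raw
additive coefficients are chosen so the *statistical* allele-substitution
effects equal the drawn alpha, and every random component is rescaled so
its realized variance matches the configured target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, ROHStatusMatrix
from .kinship import build_H, build_M, build_Z


@dataclass
class SimConfig:
    """Population, genome and trait parameters of one synthetic dataset.

    Defaults define the desk-scale study shape: 2,000 phenotyped cows,
    5,000 SNPs on 5 chromosomes of 100 Mb at 1 cM/Mb, founder allele
    frequencies uniform on [0.05, 0.95], 30% close matings, and a trait
    with additive/dominance/ROH shares of 30/5/3% of the phenotypic
    variance plus a herd-year-season component.
    """

    # population
    n_founders: int = 100
    n_generations: int = 6
    n_pop: int = 150
    n_final: int = 2000
    close_mating_fraction: float = 0.8
    close_mating_type: str = "half_sib"
    close_mating_generations: str = "final"
    # genome
    n_chr: int = 5
    chr_length_bp: int = 100_000_000
    n_markers: int = 5000
    cm_per_mb: float = 1.0
    freq_low: float = 0.05
    freq_high: float = 0.95
    # trait (variances on the phenotypic scale sigma2_P)
    sigma2_P: float = 100.0
    ratio_additive: float = 0.30
    ratio_dominance: float = 0.05
    ratio_roh: float = 0.03
    sigma2_hys: float = 10.0
    d_bar: float = 0.02
    # fixed-effect block
    n_herds: int = 25
    years: tuple = ("2012", "2013", "2014")
    seasons: tuple = ("Q1", "Q2", "Q3", "Q4")
    age_range: tuple = (22.0, 40.0)
    beta_age: float = 0.15
    intercept: float = 50.0
    fixed_effect_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ratio_additive", "ratio_dominance", "ratio_roh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ratio_additive + self.ratio_dominance + self.ratio_roh > 1.0:
            raise ValueError("genetic variance ratios exceed the phenotypic variance")
        if self.n_founders < 4 or self.n_pop < 4:
            raise ValueError("population too small for a mating design")
        if not 0.0 <= self.close_mating_fraction <= 1.0:
            raise ValueError("close_mating_fraction must be in [0, 1]")
        if self.close_mating_type not in ("half_sib", "full_sib"):
            raise ValueError("close_mating_type must be 'half_sib' or 'full_sib'")
        if self.close_mating_generations not in ("final", "all"):
            raise ValueError("close_mating_generations must be 'final' or 'all'")

    @property
    def sigma2_additive(self) -> float:
        return self.ratio_additive * self.sigma2_P

    @property
    def sigma2_dominance(self) -> float:
        return self.ratio_dominance * self.sigma2_P

    @property
    def sigma2_roh(self) -> float:
        return self.ratio_roh * self.sigma2_P

    @property
    def sigma2_residual(self) -> float:
        return self.sigma2_P - (self.sigma2_additive + self.sigma2_dominance
                                + self.sigma2_roh)


@dataclass
class TruthRecord:
    """Ground truth stored alongside a simulated dataset."""

    alpha: np.ndarray            # statistical allele-substitution effects
    delta: np.ndarray            # dominance deviations from d_bar
    d_bar: float
    roh_effects: np.ndarray
    sigma2: dict
    b_homozygosity_per_pct: float
    fixed_effects: dict = field(default_factory=dict)
    hys_effects: np.ndarray | None = None


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chr = np.full(config.n_chr, config.n_markers // config.n_chr)
    per_chr[: config.n_markers % config.n_chr] += 1
    rows = []
    idx = 0
    for c in range(config.n_chr):
        mc = int(per_chr[c])
        pos: np.ndarray = np.array([], dtype=np.int64)
        while pos.size < mc:
            cand = rng.integers(1, config.chr_length_bp + 1, size=2 * mc)
            pos = np.unique(np.concatenate([pos, cand]))
        pos = np.sort(rng.choice(pos, size=mc, replace=False))
        for p in pos:
            idx += 1
            rows.append((str(c + 1), f"snp{idx}", int(p), "A", "B"))
    return pd.DataFrame(rows, columns=["chrom", "snp", "pos", "a1", "a2"])


def _meiosis(h1: np.ndarray, h2: np.ndarray, chrom_slices, pos_list,
             morgans, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes (Haldane model)."""
    gamete = np.empty_like(h1)
    for (sl, pos, length_m) in zip(chrom_slices, pos_list, morgans):
        k = rng.poisson(length_m)
        current = rng.integers(0, 2)
        if k == 0:
            gamete[sl] = h1[sl] if current == 0 else h2[sl]
            continue
        cuts = np.sort(rng.uniform(0, 1, size=k))
        # crossover positions in bp (uniform rate along the chromosome)
        cut_bp = cuts * (pos[-1] - pos[0]) + pos[0]
        seg = (np.searchsorted(cut_bp, pos, side="right") + current) % 2
        out = np.where(seg == 0, h1[sl], h2[sl])
        gamete[sl] = out
    return gamete


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Gene-drop a pedigree and return final-generation genotypes.

    Returns the genotype matrix of the final generation and the full
    pedigree (id, sire, dam, generation).  Reproducible under the
    config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    m = len(markers)
    p = rng.uniform(config.freq_low, config.freq_high, size=m)

    pos_all = markers["pos"].to_numpy(dtype=np.int64)
    chrom = markers["chrom"].to_numpy()
    bounds = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [m]])
    chrom_slices = [slice(int(a), int(b)) for a, b in zip(starts, stops)]
    pos_list = [pos_all[sl] for sl in chrom_slices]
    morgans = [config.chr_length_bp / 1e6 * config.cm_per_mb / 100.0
               for _ in chrom_slices]

    hap1 = (rng.uniform(size=(config.n_founders, m)) < p).astype(np.uint8)
    hap2 = (rng.uniform(size=(config.n_founders, m)) < p).astype(np.uint8)
    sires = np.full(config.n_founders, -1)
    dams = np.full(config.n_founders, -1)
    ped_rows = [(i, -1, -1, 0) for i in range(config.n_founders)]
    next_id = config.n_founders

    def breed(n_off: int, generation: int, h1, h2, par_sires, par_dams,
              close_frac: float):
        nonlocal next_id
        n_par = h1.shape[0]
        # families with at least two members, for full-sib matings
        fams: dict = {}
        for i in range(n_par):
            if par_sires[i] >= 0:
                fams.setdefault((par_sires[i], par_dams[i]), []).append(i)
        fams = {k: v for k, v in fams.items() if len(v) >= 2}
        fam_keys = list(fams)
        half: dict = {}
        for i in range(n_par):
            if par_sires[i] >= 0:
                half.setdefault(par_sires[i], []).append(i)
        half = {k: v for k, v in half.items() if len(v) >= 2}
        half_keys = list(half)

        o1 = np.empty((n_off, m), dtype=np.uint8)
        o2 = np.empty((n_off, m), dtype=np.uint8)
        off_sire = np.empty(n_off, dtype=np.int64)
        off_dam = np.empty(n_off, dtype=np.int64)
        prefer_full = config.close_mating_type == "full_sib"
        for o in range(n_off):
            close = rng.uniform() < close_frac
            pools = (fam_keys and fams, half_keys and half)
            first, second = (pools if prefer_full else pools[::-1])
            if close and first:
                keys = list(first)
                sibs = first[keys[rng.integers(len(keys))]]
                a, b = rng.choice(len(sibs), size=2, replace=False)
                si, da = sibs[a], sibs[b]
            elif close and second:
                keys = list(second)
                sibs = second[keys[rng.integers(len(keys))]]
                a, b = rng.choice(len(sibs), size=2, replace=False)
                si, da = sibs[a], sibs[b]
            else:
                si = int(rng.integers(n_par))
                da = int(rng.integers(n_par))
                while da == si:
                    da = int(rng.integers(n_par))
            o1[o] = _meiosis(h1[si], h2[si], chrom_slices, pos_list, morgans, rng)
            o2[o] = _meiosis(h1[da], h2[da], chrom_slices, pos_list, morgans, rng)
            off_sire[o] = si
            off_dam[o] = da
            ped_rows.append((next_id, int(si), int(da), generation))
            next_id += 1
        return o1, o2, off_sire, off_dam

    if config.n_generations == 0:
        # founders are the study population (Hardy-Weinberg at the drawn p)
        n_out = config.n_founders
    else:
        inner_frac = (config.close_mating_fraction
                      if config.close_mating_generations == "all" else 0.0)
        for g in range(1, config.n_generations):
            hap1, hap2, sires, dams = breed(config.n_pop, g, hap1, hap2,
                                            sires, dams, inner_frac)
        hap1, hap2, sires, dams = breed(config.n_final, config.n_generations,
                                        hap1, hap2, sires, dams,
                                        config.close_mating_fraction)
        n_out = config.n_final

    codes = (hap1 + hap2).astype(np.uint8)
    samples = [f"A{i:06d}" for i in range(n_out)]
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation"])
    return GenotypeMatrix(codes=codes, samples=samples, markers=markers), pedigree


def simulate_phenotypes(genotypes: GenotypeMatrix, status: ROHStatusMatrix,
                        config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes under the ADR generative model with directional dominance.

    Each random component (additive, dominance deviations, ROH deviations,
    HYS, residual) is rescaled so its realized variance across animals
    equals the configured target exactly; the stored truth is therefore
    the target itself.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    n, m = genotypes.codes.shape
    p = genotypes.allele_frequencies()
    q = 1.0 - p

    def scaled(effects_raw: np.ndarray, covariates: np.ndarray, target: float,
               what: str) -> tuple[np.ndarray, np.ndarray]:
        if target == 0.0:
            return np.zeros(m), np.zeros(n)
        g = covariates @ effects_raw
        v = float(np.var(g))
        if v <= 0:
            raise ValueError(f"zero realized variance for the {what} component")
        c = np.sqrt(target / v)
        return effects_raw * c, g * c

    Z = build_Z(genotypes, p)
    H = build_H(genotypes, p)
    M = build_M(status)
    alpha, g_add = scaled(rng.standard_normal(m), Z, config.sigma2_additive, "additive")
    delta, g_dom = scaled(rng.standard_normal(m), H, config.sigma2_dominance, "dominance")
    rho, g_roh = scaled(rng.standard_normal(m), M, config.sigma2_roh, "ROH")

    d = config.d_bar + delta
    # raw additive coefficients such that the statistical allele
    # substitution effect is exactly alpha: a = alpha - (q - p) d
    a = alpha - (q - p) * d
    het = (genotypes.codes == 1).astype(float)
    genetic = (genotypes.codes.astype(float) @ a + het @ d
               + status.x.astype(float) @ rho)

    herd = rng.integers(config.n_herds, size=n)
    year = rng.integers(len(config.years), size=n)
    season = rng.integers(len(config.seasons), size=n)
    age = rng.uniform(*config.age_range, size=n)
    herd_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_herds)
    year_eff = rng.normal(0.0, config.fixed_effect_sd, size=len(config.years))
    season_eff = rng.normal(0.0, config.fixed_effect_sd, size=len(config.seasons))
    fixed = (config.intercept + herd_eff[herd] + year_eff[year]
             + season_eff[season] + config.beta_age * age)

    hys_labels = pd.Series([f"{h}:{y}:{s}" for h, y, s in zip(herd, year, season)])
    hys_index, hys_levels = pd.factorize(hys_labels)
    if config.sigma2_hys > 0:
        c_raw = rng.standard_normal(len(hys_levels))
        g_hys = c_raw[hys_index]
        c_scale = np.sqrt(config.sigma2_hys / np.var(g_hys))
        c_eff = c_raw * c_scale
        g_hys = g_hys * c_scale
    else:
        c_eff = np.zeros(len(hys_levels))
        g_hys = np.zeros(n)

    if config.sigma2_residual > 0:
        e = rng.standard_normal(n)
        e = e * np.sqrt(config.sigma2_residual / np.var(e))
    else:
        e = np.zeros(n)

    y = fixed + g_hys + genetic + e
    pheno = pd.DataFrame({
        "animal": genotypes.samples,
        "y": y,
        "herd": [f"H{h:03d}" for h in herd],
        "year": [config.years[i] for i in year],
        "season": [config.seasons[i] for i in season],
        "age": age,
    })
    truth = TruthRecord(
        alpha=alpha, delta=delta, d_bar=config.d_bar, roh_effects=rho,
        sigma2={
            "hys": config.sigma2_hys,
            "additive": config.sigma2_additive,
            "dominance": config.sigma2_dominance,
            "roh": config.sigma2_roh,
            "residual": config.sigma2_residual,
        },
        b_homozygosity_per_pct=-config.d_bar * m / 100.0,
        fixed_effects={
            "intercept": config.intercept,
            "age": config.beta_age,
            "herd": herd_eff,
            "year": year_eff,
            "season": season_eff,
        },
        hys_effects=c_eff,
    )
    return pheno, truth


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
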
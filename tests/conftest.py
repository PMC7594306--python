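import numpy as np
import pandas as pd
import pytest

import rohdom as rd


def make_genotypes(codes, positions=None, chroms=None):
    """Small GenotypeMatrix from a literal code array."""
    codes = np.asarray(codes, dtype=np.uint8)
    n, m = codes.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 100_000
    if chroms is None:
        chroms = ["1"] * m
    markers = pd.DataFrame({
        "chrom": chroms, "snp": [f"s{i + 1}" for i in range(m)],
        "pos": positions, "a1": "A", "a2": "B"})
    return rd.GenotypeMatrix(codes=codes, samples=[f"an{i + 1}" for i in range(n)],
                             markers=markers)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset reused across estimator tests.

    Desk-scale shrunk further: 400 animals, 1,200 markers on 4 x 30 Mb
    chromosomes (same 100 kb density as the default conditions).
    """
    cfg = rd.SimConfig(seed=42, n_final=400, n_pop=120, n_founders=60,
                       n_chr=4, chr_length_bp=30_000_000, n_markers=1200)
    geno, ped = rd.simulate_genotypes(cfg)
    status = rd.ROHDetector().fit_transform(geno)
    pheno, truth = rd.simulate_phenotypes(geno, status, cfg)
    hom = rd.genome_wide_homozygosity(geno)
    design = rd.build_design(pheno, hom)
    freqs = geno.allele_frequencies()
    Z = rd.build_Z(geno, freqs)
    H = rd.build_H(geno, freqs)
    M = rd.build_M(status)
    rel = {"additive": rd.build_G(Z, freqs), "dominance": rd.build_D(H, freqs),
           "roh": rd.build_R(M, status)}
    return {
        "config": cfg, "genotypes": geno, "status": status, "pheno": pheno,
        "truth": truth, "hom": hom, "design": design, "freqs": freqs,
        "Z": Z, "H": H, "M": M, "rel": rel,
    }


@pytest.fixture(scope="session")
def nested_fits(small_dataset):
    """Models A, AD and ADR fitted on the shared dataset."""
    design = small_dataset["design"]
    rel = small_dataset["rel"]
    return {model: rd.fit_greml(design, model, rel)
            for model in ("A", "AD", "ADR")}
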
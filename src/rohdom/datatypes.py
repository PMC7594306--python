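"""Core in-memory containers shared across the pipeline.

Conventions
-----------
Genotype codes count the A allele (the .bim A1 allele): 0 = BB, 1 = AB,
2 = AA.  There are no missing codes anywhere in the pipeline; readers fail
hard on a PLINK missing genotype.  Base-pair positions are 1-based and
strictly increasing within a chromosome; segment boundaries are inclusive
at both ends (PLINK .hom convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of a ROH segment table (one row per called segment).
ROH_COLUMNS = [
    "animal", "chrom", "start_index", "end_index",
    "start_bp", "end_bp", "n_snps", "n_het",
]


@dataclass
class GenotypeMatrix:
    """n animals x m biallelic markers, fully genotyped.

    Parameters
    ----------
    codes : (n, m) integer array in {0, 1, 2}
        Count of the A allele (BB, AB, AA).
    samples : list of str
        Animal identifiers, row order of ``codes``.
    markers : DataFrame with columns chrom, snp, pos, a1, a2
        Marker map, column order of ``codes``; ``pos`` strictly
        increasing within each chromosome.
    """

    codes: np.ndarray
    samples: list
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (animals x markers) array")
        n, m = self.codes.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one animal and one marker")
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} genotype rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker records for {m} genotype columns")
        if not np.isin(self.codes, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2 (no missing genotypes allowed)")
        pos = self.markers["pos"].to_numpy()
        if (pos <= 0).any():
            raise ValueError("base-pair positions must be positive")
        for _, idx in self.chromosome_slices():
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def chromosome_slices(self):
        """Yield (chrom, slice) pairs in marker order.

        Markers of one chromosome must be contiguous; chromosomes appear
        in their order of first occurrence.
        """
        chroms = self.markers["chrom"].to_numpy()
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [len(chroms)]])
        seen = set()
        for a, b in zip(starts, stops):
            c = chroms[a]
            if c in seen:
                raise ValueError(f"markers of chromosome {c!r} are not contiguous")
            seen.add(c)
            yield c, slice(int(a), int(b))

    def allele_frequencies(self) -> np.ndarray:
        """Observed sample frequency of the A allele per marker."""
        return self.codes.mean(axis=0) / 2.0


@dataclass
class ROHStatusMatrix:
    """Per-SNP in-ROH indicator and its column frequencies.

    ``x[i, j]`` is 1 iff marker j of animal i lies inside one of that
    animal's ROH; ``p_star[j]`` is the column mean of ``x`` (the frequency
    of marker j being in a ROH).
    """

    x: np.ndarray
    p_star: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("ROH status must be 0/1")
        if self.p_star is None:
            self.p_star = self.x.mean(axis=0)
        else:
            self.p_star = np.asarray(self.p_star, dtype=float)
            if self.p_star.shape != (self.x.shape[1],):
                raise ValueError("p_star length must equal the number of markers")

    @property
    def q_star(self) -> np.ndarray:
        return 1.0 - self.p_star


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relationship matrix with its scaling denominator.

    ``kind`` is 'G' (additive, VanRaden method 1), 'D' (dominance,
    Vitezica parametrization) or 'R' (ROH-based).  ``denominator`` is the
    scalar the cross-product was divided by (sum 2pq, sum (2pq)^2 or
    sum p*q* respectively).
    """

    kind: str
    values: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.denominator <= 0:
            raise ValueError("scaling denominator must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue_ratio(self) -> float:
        """Smallest eigenvalue relative to the largest (PSD diagnostic)."""
        w = np.linalg.eigvalsh(self.values)
        top = max(w[-1], np.finfo(float).tiny)
        return float(w[0] / top)
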
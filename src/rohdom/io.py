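"""Readers and writers for the standard exchange formats.

Supported formats: PLINK binary genotypes (.bed/.bim/.fam, v1.00
SNP-major), PLINK .hom-style ROH segment tables, GCTA-style relationship
matrix text (lower triangle + companion .id file) and TSV phenotype
tables.  Sample and marker order are always preserved exactly as stored.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import ROH_COLUMNS, GenotypeMatrix, RelationshipMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit genotype values, indexed by our A-allele count codes.
# PLINK: 00 = hom A1, 10 = het, 11 = hom A2, 01 = missing.
_CODE_TO_BITS = np.array([3, 2, 0], dtype=np.uint8)  # code 0 (BB) -> 11, 1 -> 10, 2 (AA) -> 00
_BITS_TO_CODE = np.array([2, 255, 1, 0], dtype=np.uint8)  # 255 marks missing


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK binary files."""


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam fileset.

    Codes count the .bim A1 allele (AA = 2).  A missing genotype is a hard
    error: the pipeline assumes complete (imputed) genotypes.
    """
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkFormatError(
                f"{prefix}.bed does not start with the PLINK v1.00 SNP-major magic bytes"
            )
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if data.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix}.bed holds {data.size} genotype bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} markers"
        )
    data = data.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample i sits at bit offset 2*(i mod 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = ((data[:, :, None] >> shifts) & 3).reshape(m, bytes_per_snp * 4)[:, :n]
    codes = _BITS_TO_CODE[two_bit].T  # -> (n, m)
    if (codes == 255).any():
        i, j = np.argwhere(codes == 255)[0]
        raise PlinkFormatError(
            f"missing genotype for sample {fam['iid'].iloc[i]!r} at marker "
            f"{bim['snp'].iloc[j]!r}: the pipeline requires complete genotypes"
        )
    markers = bim[["chrom", "snp", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(codes=np.ascontiguousarray(codes), samples=list(fam["iid"]), markers=markers)


def write_plink(genotypes: GenotypeMatrix, prefix: str) -> None:
    """Write a GenotypeMatrix as a PLINK .bed/.bim/.fam fileset."""
    n, m = genotypes.codes.shape
    bim = genotypes.markers
    with open(f"{prefix}.bim", "w") as fh:
        for c, s, p, a1, a2 in zip(bim["chrom"], bim["snp"], bim["pos"], bim["a1"], bim["a2"]):
            fh.write(f"{c}\t{s}\t0\t{p}\t{a1}\t{a2}\n")
    with open(f"{prefix}.fam", "w") as fh:
        for iid in genotypes.samples:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 3, dtype=np.uint8)  # pad with hom-A2 bits, ignored on read
    padded[:, :n] = _CODE_TO_BITS[genotypes.codes.T]
    packed = (
        padded.reshape(m, bytes_per_snp, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def write_roh_segments(roh: pd.DataFrame, genotypes: GenotypeMatrix, out: str) -> None:
    """Write called ROH as a PLINK .hom-style table (one row per segment)."""
    cols = ["IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP", "NHET"]
    snp = genotypes.markers["snp"].to_numpy()
    with open(out, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in roh.itertuples(index=False):
            kb = (row.end_bp - row.start_bp + 1) / 1000.0
            fh.write(
                f"{row.animal}\t{row.chrom}\t{snp[row.start_index]}\t{snp[row.end_index]}\t"
                f"{row.start_bp}\t{row.end_bp}\t{kb:.10g}\t{row.n_snps}\t{row.n_het}\n"
            )


def read_roh_segments(path: str, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Read a .hom-style segment table back into the internal layout."""
    tab = pd.read_csv(path, sep="\t", dtype={"IID": str, "CHR": str})
    marker_index = {(c, s): i for i, (c, s) in
                    enumerate(zip(genotypes.markers["chrom"], genotypes.markers["snp"]))}
    rows = []
    for row in tab.itertuples(index=False):
        try:
            start = marker_index[(row.CHR, row.SNP1)]
            end = marker_index[(row.CHR, row.SNP2)]
        except KeyError as exc:
            raise ValueError(f"segment references unknown marker {exc.args[0]}") from None
        rows.append((row.IID, row.CHR, start, end, row.POS1, row.POS2, row.NSNP, row.NHET))
    out = pd.DataFrame(rows, columns=ROH_COLUMNS)
    return out.astype({"start_index": int, "end_index": int, "start_bp": int,
                       "end_bp": int, "n_snps": int, "n_het": int})


def write_grm(matrix: RelationshipMatrix, ids, prefix: str) -> None:
    """Write a relationship matrix in GCTA text layout.

    ``prefix.grm.txt`` holds the lower triangle as ``i j m value`` rows
    (1-based, value at >= 8 significant digits); ``prefix.grm.id`` the
    animal identifiers.
    """
    n = matrix.n
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for a {n} x {n} matrix")
    vals = matrix.values
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{matrix.denominator:.8g}\t{vals[i, j]:.8g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str, kind: str = "G") -> tuple[RelationshipMatrix, list]:
    tab = pd.read_csv(f"{prefix}.grm.txt", sep="\t", header=None,
                      names=["i", "j", "denom", "value"])
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, dtype=str)[1].tolist()
    n = int(tab["i"].max())
    vals = np.zeros((n, n))
    vals[tab["i"] - 1, tab["j"] - 1] = tab["value"]
    vals = np.tril(vals) + np.tril(vals, -1).T
    return RelationshipMatrix(kind=kind, values=vals, denominator=float(tab["denom"].iloc[0])), ids


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a tab-separated phenotype/covariate table with a header row.

    Factor columns (herd, year, season) are kept as opaque string labels.
    """
    tab = pd.read_csv(path, sep="\t", comment="#",
                      dtype={"animal": str, "herd": str, "year": str,
                             "season": str})
    return tab


def write_phenotypes(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def ensure_parent(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
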
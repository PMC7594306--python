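"""Calling runs of homozygosity (ROH) and deriving per-SNP ROH status.

The detector mirrors the PLINK ``--homozyg`` two-stage procedure:

1. *Window eligibility.*  A scanning window of ``window_snps`` consecutive
   markers slides along each chromosome.  A window is "homozygous" when it
   contains at most ``window_max_het`` heterozygous calls.  A marker is
   eligible when the fraction of windows overlapping it that are
   homozygous is at least ``window_hit_threshold``.
2. *Segment extraction.*  Within each maximal run of eligible markers
   (runs are additionally broken at inter-marker gaps larger than
   ``max_gap_bp`` and at chromosome boundaries), every interval satisfying
   the five segment criteria is a candidate:

   - physical length (inclusive, ``last_bp - first_bp + 1``) at least
     ``min_length_bp``;
   - at least ``min_snps`` markers;
   - density of at most ``min_density_bp_per_snp`` base pairs per marker;
   - at most ``max_internal_het`` heterozygous calls;
   - no internal gap above ``max_gap_bp`` (holds by construction).

   Candidates contained in a larger passing interval are discarded
   (reported segments are maximal), and the remaining intervals are chosen
   greedily by marker count (ties broken by leftmost start) subject to
   being non-overlapping.

Genotypes are assumed complete, so PLINK's missing-call window criterion
does not apply; the detector has no missing-data parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

from .datatypes import ROH_COLUMNS, GenotypeMatrix, ROHStatusMatrix


@dataclass
class ROHParams:
    """Segment and scanning-window criteria for ROH calling.

    Defaults correspond to ``--homozyg-kb 1000 --homozyg-snp 15
    --homozyg-density 100 --homozyg-gap 500 --homozyg-het 1
    --homozyg-window-snp 15 --homozyg-window-het 1`` with PLINK's default
    window hit threshold of 0.05.
    """

    min_length_bp: int = 1_000_000
    min_snps: int = 15
    min_density_bp_per_snp: int = 100_000
    max_internal_het: int = 1
    max_gap_bp: int = 500_000
    window_snps: int = 15
    window_max_het: int = 1
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_snps", "min_density_bp_per_snp",
                     "max_gap_bp", "window_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")


def _window_eligibility(het: np.ndarray, window: int, window_max_het: int,
                        threshold: float) -> np.ndarray:
    """Boolean (n, m) eligibility from the sliding-window criterion."""
    n, m = het.shape
    if m < window:
        return np.zeros((n, m), dtype=bool)
    cs = np.zeros((n, m + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=cs[:, 1:])
    win_het = cs[:, window:] - cs[:, :-window]          # (n, m - window + 1)
    good = (win_het <= window_max_het).astype(np.int32)
    gc = np.zeros((n, good.shape[1] + 1), dtype=np.int32)
    np.cumsum(good, axis=1, out=gc[:, 1:])
    j = np.arange(m)
    lo = np.maximum(0, j - window + 1)
    hi = np.minimum(j, good.shape[1] - 1)
    hits = gc[:, hi + 1] - gc[:, lo]
    totals = (hi - lo + 1)
    return hits >= threshold * totals - 1e-12


@njit(cache=True)
def _scan_piece(het, pos, offset, min_len, min_snps, density, max_het,
                starts, ends, nsnps, nhets, count):
    """Collect maximal passing intervals of one gap-free eligible run.

    For each start the largest passing end is found (heterozygote count is
    monotone in the end, so the search stops at the (max_het+1)-th het);
    an interval is kept only when it is not contained in one with an
    earlier start.  Results are appended to the output buffers.
    """
    L = het.shape[0]
    best_end = np.full(L, -1, dtype=np.int64)
    for s in range(L):
        h = 0
        for e in range(s, L):
            h += het[e]
            if h > max_het:
                break
            length = pos[e] - pos[s] + 1
            ns = e - s + 1
            if ns >= min_snps and length >= min_len and length <= density * ns:
                best_end[s] = e
    running = -1
    for s in range(L):
        e = best_end[s]
        if e > running:
            # maximal: no earlier start reaches this far
            h = 0
            for t in range(s, e + 1):
                h += het[t]
            starts[count] = offset + s
            ends[count] = offset + e
            nsnps[count] = e - s + 1
            nhets[count] = h
            count += 1
            running = e
    return count


@njit(cache=True)
def _greedy_select(starts, ends, nsnps, count):
    """Greedy non-overlapping selection by (snp count desc, start asc)."""
    keep = np.zeros(count, dtype=np.bool_)
    used = np.zeros(count, dtype=np.bool_)
    for _ in range(count):
        best = -1
        for i in range(count):
            if used[i]:
                continue
            if best == -1 or nsnps[i] > nsnps[best] or (
                    nsnps[i] == nsnps[best] and starts[i] < starts[best]):
                best = i
        if best == -1:
            break
        used[best] = True
        ok = True
        for i in range(count):
            if keep[i] and not (ends[i] < starts[best] or ends[best] < starts[i]):
                ok = False
                break
        if ok:
            keep[best] = True
    return keep


def detect_roh(genotypes: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Call ROH for every animal.

    Returns a segment table with columns ``animal, chrom, start_index,
    end_index, start_bp, end_bp, n_snps, n_het`` (marker indices are
    global column indices of the genotype matrix; bp bounds inclusive).
    Deterministic for fixed input.
    """
    if params is None:
        params = ROHParams()
    het = (genotypes.codes == 1).astype(np.int8)
    pos_all = genotypes.markers["pos"].to_numpy(dtype=np.int64)
    samples = genotypes.samples
    records: list[tuple] = []
    for chrom, sl in genotypes.chromosome_slices():
        pos = pos_all[sl]
        mc = pos.size
        if mc < params.window_snps:
            continue
        elig = _window_eligibility(het[:, sl], params.window_snps,
                                   params.window_max_het, params.window_hit_threshold)
        gap_break = np.flatnonzero(np.diff(pos) > params.max_gap_bp) + 1
        hc = np.ascontiguousarray(het[:, sl])
        max_seg = mc + 1
        starts = np.empty(max_seg, dtype=np.int64)
        ends = np.empty(max_seg, dtype=np.int64)
        nsnps = np.empty(max_seg, dtype=np.int64)
        nhets = np.empty(max_seg, dtype=np.int64)
        for i in range(genotypes.n_samples):
            e = elig[i]
            if not e.any():
                continue
            # maximal eligible runs, then break at large gaps
            run_bounds = np.flatnonzero(np.diff(e.astype(np.int8)) != 0) + 1
            bounds = np.unique(np.concatenate([[0], run_bounds, gap_break, [mc]]))
            count = 0
            for a, b in zip(bounds[:-1], bounds[1:]):
                if not e[a] or (b - a) < params.min_snps:
                    continue
                count = _scan_piece(
                    hc[i, a:b], pos[a:b], a,
                    params.min_length_bp, params.min_snps,
                    params.min_density_bp_per_snp, params.max_internal_het,
                    starts, ends, nsnps, nhets, count,
                )
            if count == 0:
                continue
            keep = _greedy_select(starts, ends, nsnps, count)
            order = np.flatnonzero(keep)
            order = order[np.argsort(starts[order])]
            for k in order:
                s, t = int(starts[k]), int(ends[k])
                records.append((samples[i], chrom, sl.start + s, sl.start + t,
                                int(pos[s]), int(pos[t]), int(nsnps[k]), int(nhets[k])))
    out = pd.DataFrame(records, columns=ROH_COLUMNS)
    if out.empty:
        out = out.astype({"start_index": int, "end_index": int, "start_bp": int,
                          "end_bp": int, "n_snps": int, "n_het": int})
    return out


def roh_status(roh: pd.DataFrame, genotypes: GenotypeMatrix) -> ROHStatusMatrix:
    """Per-SNP in-ROH indicator matrix with its column frequencies p*."""
    n, m = genotypes.codes.shape
    x = np.zeros((n, m), dtype=np.uint8)
    row = {iid: i for i, iid in enumerate(genotypes.samples)}
    for seg in roh.itertuples(index=False):
        if not (0 <= seg.start_index <= seg.end_index < m):
            raise ValueError("segment references marker indices outside the map")
        x[row[seg.animal], seg.start_index:seg.end_index + 1] = 1
    return ROHStatusMatrix(x=x)


def genome_wide_homozygosity(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-animal proportion of homozygous markers, in [0, 1]."""
    if genotypes.n_markers == 0:
        raise ValueError("no markers")
    return (genotypes.codes != 1).mean(axis=1)


class ROHDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_roh` / :func:`roh_status`.

    ``fit`` calls the segments for a genotype matrix (stored in
    ``segments_``); ``transform`` converts genotypes into the per-SNP
    in-ROH indicator matrix using those segments.
    """

    def __init__(self, min_length_bp: int = 1_000_000, min_snps: int = 15,
                 min_density_bp_per_snp: int = 100_000, max_internal_het: int = 1,
                 max_gap_bp: int = 500_000, window_snps: int = 15,
                 window_max_het: int = 1, window_hit_threshold: float = 0.05):
        self.min_length_bp = min_length_bp
        self.min_snps = min_snps
        self.min_density_bp_per_snp = min_density_bp_per_snp
        self.max_internal_het = max_internal_het
        self.max_gap_bp = max_gap_bp
        self.window_snps = window_snps
        self.window_max_het = window_max_het
        self.window_hit_threshold = window_hit_threshold

    def _params(self) -> ROHParams:
        return ROHParams(**self.get_params())

    def fit(self, genotypes: GenotypeMatrix, y=None) -> "ROHDetector":
        self.segments_ = detect_roh(genotypes, self._params())
        self.n_segments_ = len(self.segments_)
        return self

    def transform(self, genotypes: GenotypeMatrix) -> ROHStatusMatrix:
        if not hasattr(self, "segments_"):
            raise AttributeError("ROHDetector is not fitted; call fit first")
        return roh_status(self.segments_, genotypes)

    def fit_transform(self, genotypes: GenotypeMatrix, y=None) -> ROHStatusMatrix:
        return self.fit(genotypes).transform(genotypes)
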
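"""Exhaustive reference implementation of the ROH segment definition.

This module re-derives ROH calls by brute force — enumerating every
candidate marker interval, re-checking each criterion marker by marker,
and computing window eligibility window by window — with none of the
prefix-sum or run-splitting machinery of :mod:`rohdom.roh`.  It is
intended as an independent oracle for validating the optimized detector
on small chromosomes (quadratic in the marker count), not for production
use.
"""

from __future__ import annotations

import numpy as np

from .roh import ROHParams


def eligible_markers_bruteforce(het: np.ndarray, params: ROHParams) -> np.ndarray:
    """Window eligibility of each marker, computed window by window."""
    m = het.size
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    good = []
    for start in range(m - w + 1):
        good.append(int(np.sum(het[start:start + w])) <= params.window_max_het)
    out = np.zeros(m, dtype=bool)
    for j in range(m):
        windows = [good[s] for s in range(max(0, j - w + 1), min(j, m - w) + 1)]
        frac = sum(windows) / len(windows)
        out[j] = frac >= params.window_hit_threshold - 1e-12
    return out


def interval_passes(het: np.ndarray, pos: np.ndarray, eligible: np.ndarray,
                    s: int, e: int, params: ROHParams) -> bool:
    """Re-check every segment criterion for the interval [s, e]."""
    if not all(eligible[s:e + 1]):
        return False
    n_snps = e - s + 1
    if n_snps < params.min_snps:
        return False
    length = int(pos[e]) - int(pos[s]) + 1
    if length < params.min_length_bp:
        return False
    if length / n_snps > params.min_density_bp_per_snp:
        return False
    if int(np.sum(het[s:e + 1])) > params.max_internal_het:
        return False
    for j in range(s, e):
        if int(pos[j + 1]) - int(pos[j]) > params.max_gap_bp:
            return False
    return True


def detect_roh_bruteforce(het: np.ndarray, pos: np.ndarray,
                          params: ROHParams | None = None) -> list[tuple[int, int]]:
    """ROH of one animal on one chromosome by exhaustive enumeration.

    All passing intervals are enumerated; intervals contained in a larger
    passing interval are dropped; the remaining maximal intervals are
    selected greedily by (marker count descending, start ascending)
    subject to being non-overlapping.  Returns sorted (start, end) marker
    index pairs, both inclusive.
    """
    if params is None:
        params = ROHParams()
    het = np.asarray(het)
    pos = np.asarray(pos)
    m = het.size
    eligible = eligible_markers_bruteforce(het, params)
    passing = [(s, e) for s in range(m) for e in range(s, m)
               if interval_passes(het, pos, eligible, s, e, params)]
    maximal = [iv for iv in passing
               if not any((o[0] <= iv[0] and iv[1] <= o[1] and o != iv)
                          for o in passing)]
    chosen: list[tuple[int, int]] = []
    for iv in sorted(maximal, key=lambda iv: (-(iv[1] - iv[0]), iv[0])):
        if all(iv[1] < c[0] or c[1] < iv[0] for c in chosen):
            chosen.append(iv)
    return sorted(chosen)
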
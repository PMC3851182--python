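"""Piecewise-constant change-point segmentation with BIC model selection.

The model: a probe-intensity series is partitioned into k contiguous
segments, each with a constant mean and shared Gaussian noise. For a given
k the breakpoints minimizing the total within-segment sum of squares are
found by exact dynamic programming (O(k n^2)); k itself is chosen by the
Bayesian information criterion

    BIC(k) = -2 log L_k + p_k log n,   p_k = 2k

counting k segment means, k-1 breakpoints and one pooled variance. The
variance is the maximum-likelihood pooled residual variance, floored at a
tiny epsilon so that noiseless step signals (zero residual) remain
well-defined; ties in BIC resolve to the smaller k, and ties among optimal
breakpoint placements resolve to the lexicographically smallest vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tiling import ProbeTrack

_VAR_FLOOR = 1e-12

# Relative tolerance for recognising cost ties during backtracking; DP and
# re-summed candidate costs can differ in the last float bits.
_TIE_RTOL = 1e-9


def _segment_cost_row(css: np.ndarray, cs: np.ndarray, i: int) -> np.ndarray:
    """cost(i, j) for all j > i: RSS of values[i:j] as one segment."""
    n = len(cs) - 1
    j = np.arange(i + 1, n + 1)
    length = j - i
    s = cs[j] - cs[i]
    ss = css[j] - css[i]
    return ss - s * s / length


def _suffix_dp(values: np.ndarray, k_max: int) -> np.ndarray:
    """S[m, i] = optimal RSS of segmenting values[i:] into m segments.

    S has shape (k_max+1, n+1); S[m, i] is +inf where infeasible
    (m > n - i or m == 0 for i < n).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    css = np.concatenate([[0.0], np.cumsum(values * values)])
    S = np.full((k_max + 1, n + 1), np.inf)
    S[0, n] = 0.0
    for i in range(n):
        S[1, i] = _segment_cost_row(css, cs, i)[-1]  # one segment to the end
    for m in range(2, k_max + 1):
        for i in range(n - m + 1):
            costs = _segment_cost_row(css, cs, i)  # j = i+1 .. n
            cand = costs[: n - i - 1] + S[m - 1, i + 1 : n]  # j = i+1 .. n-1
            if len(cand):
                S[m, i] = cand.min()
    return S


def _backtrack(values: np.ndarray, S: np.ndarray, k: int) -> List[int]:
    """Lexicographically smallest optimal breakpoint vector for k segments."""
    n = len(values)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    css = np.concatenate([[0.0], np.cumsum(values * values)])
    bps: List[int] = []
    i, m = 0, k
    while m > 1:
        costs = _segment_cost_row(css, cs, i)  # j = i+1 .. n
        target = S[m, i]
        tol = _TIE_RTOL * (1.0 + abs(target))
        for j in range(i + 1, n):
            total = costs[j - i - 1] + S[m - 1, j]
            if total <= target + tol:
                bps.append(j)
                i, m = j, m - 1
                break
        else:  # pragma: no cover - DP guarantees a feasible j
            raise RuntimeError("backtracking failed")
    return bps


def optimal_breakpoints(
    values: Sequence[float], k: int
) -> Tuple[List[int], np.ndarray, float]:
    """Exact least-squares placement of k-1 breakpoints.

    A breakpoint b means the split lies between indices b-1 and b (b is the
    first index of the new segment). Returns (breakpoints, segment_means,
    rss); ties resolve to the lexicographically smallest breakpoint vector.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 1:
        raise ValueError("empty input")
    if not (1 <= k <= n):
        raise ValueError(f"k = {k} not in [1, {n}]")
    S = _suffix_dp(values, k)
    bps = _backtrack(values, S, k)
    means = _segment_means(values, bps)
    return bps, means, float(S[k, 0])


def _segment_means(values: np.ndarray, bps: Sequence[int]) -> np.ndarray:
    edges = [0, *bps, len(values)]
    return np.array(
        [values[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )


@dataclass
class SegmentationResult:
    chrom: Optional[str]
    strand: Optional[str]
    start: Optional[int]
    end: Optional[int]
    breakpoints: List[int]  # probe indices within the region
    genomic_breakpoints: List[float]  # midpoints between flanking probes
    segment_means: np.ndarray
    k: int
    log_likelihood: float
    bic: float
    per_k: pd.DataFrame = field(repr=False, default=None)  # k, rss, log_likelihood, bic


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss / n, _VAR_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def select_k(
    values: Sequence[float],
    k_max: int,
    penalty: str = "bic",
    params_per_segment: int = 2,
) -> SegmentationResult:
    """Optimal segmentation with the segment count chosen by BIC.

    For each k <= k_max the DP optimum is computed; the Gaussian likelihood
    uses the pooled MLE variance and BIC = -2 logL + p log n with
    p = params_per_segment * k (default 2k: means, breakpoints, variance).
    BIC ties go to the smaller k. ``params_per_segment = 1`` gives the p = k
    alternative.
    """
    if penalty != "bic":
        raise ValueError(f"unknown penalty {penalty!r}")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 1:
        raise ValueError("empty input")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, n)
    S = _suffix_dp(values, k_max)
    rows = []
    for k in range(1, k_max + 1):
        rss = float(S[k, 0])
        ll = _gaussian_loglik(rss, n)
        bic = -2.0 * ll + params_per_segment * k * math.log(n)
        rows.append({"k": k, "rss": rss, "log_likelihood": ll, "bic": bic})
    per_k = pd.DataFrame(rows)
    best = int(per_k.loc[per_k["bic"].idxmin(), "k"])  # idxmin: first minimum
    bps = _backtrack(values, S, best)
    return SegmentationResult(
        chrom=None,
        strand=None,
        start=None,
        end=None,
        breakpoints=bps,
        genomic_breakpoints=[],
        segment_means=_segment_means(values, bps),
        k=best,
        log_likelihood=float(per_k.loc[best - 1, "log_likelihood"]),
        bic=float(per_k.loc[best - 1, "bic"]),
        per_k=per_k,
    )


def segment_region(
    track: ProbeTrack,
    values: np.ndarray,
    region_start: int,
    region_end: int,
    k_max: Optional[int] = None,
    params_per_segment: int = 2,
) -> SegmentationResult:
    """Segment the probes of one genomic region.

    ``values`` is an intensity array aligned to the track's probes (e.g.
    replicate-averaged). ``k_max`` defaults to n_probes // 50 (floor 1).
    Breakpoints are reported both as probe indices within the region and as
    genomic coordinates (midpoint between the flanking probe centers).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != track.positions.shape:
        raise ValueError("values not aligned to track positions")
    mask = (track.positions >= region_start) & (track.positions < region_end)
    pos = track.positions[mask]
    v = values[mask]
    if len(v) == 0:
        raise ValueError(
            f"region [{region_start}, {region_end}) on {track.key} has no probes"
        )
    if k_max is None:
        k_max = max(1, len(v) // 50)
    res = select_k(v, k_max, params_per_segment=params_per_segment)
    res.chrom, res.strand = track.chrom, track.strand
    res.start, res.end = region_start, region_end
    res.genomic_breakpoints = [
        (pos[b - 1] + pos[b]) / 2.0 for b in res.breakpoints
    ]
    return res


def segments_to_bed(res: SegmentationResult) -> pd.DataFrame:
    """Segment intervals as BED-like rows with the segment mean as score."""
    edges = [float(res.start), *res.genomic_breakpoints, float(res.end)]
    rows = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        rows.append(
            {
                "chrom": res.chrom,
                "start": int(round(a)),
                "end": int(round(b)),
                "name": f"seg_{i}",
                "score": float(res.segment_means[i]),
                "strand": res.strand,
            }
        )
    return pd.DataFrame(rows)
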
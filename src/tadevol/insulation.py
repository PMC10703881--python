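"""TAD-separation (insulation) score, boundary calling and aggregate pileups.

The insulation score of a bin summarises how many contacts pass across it:
for a set of diamond windows of increasing size ``w`` (bins), the diamond
mean at bin ``i`` is the mean count over pairs ``(a, b)`` with
``i - w <= a < i <= b < i + w`` — i.e. contacts crossing the bin.  Per
window, diamond means are ``log1p``-transformed and z-scored along the
chromosome; the insulation score is the mean z-score across windows.
Lower scores mean fewer crossing contacts, i.e. stronger insulation; TAD
boundaries are significant local minima of the score curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ContactMatrix

__all__ = [
    "InsulationTrack",
    "insulation_track",
    "call_boundaries",
    "pileup",
    "PileupResult",
]


@dataclass
class InsulationTrack:
    """Per-bin TAD-separation score for one chromosome.

    ``score[i]`` is NaN wherever any of the diamond windows would cross a
    matrix edge, so the defined region is ``[w_max, n_bins - w_max]`` with
    ``w_max = max_depth / bin_size``.  Per-window diamond means are kept
    in ``diamond_means`` (window size in bins -> array) for testing and
    for the boundary significance test.
    """

    chrom: str
    bin_size: int
    score: np.ndarray
    diamond_means: dict[int, np.ndarray]
    window_sizes_bp: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return len(self.score)

    def to_bedgraph(self) -> pd.DataFrame:
        idx = np.flatnonzero(np.isfinite(self.score))
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": idx * self.bin_size,
                "end": (idx + 1) * self.bin_size,
                "value": self.score[idx],
            }
        )


def _prefix_sum(counts: np.ndarray) -> np.ndarray:
    S = np.zeros((counts.shape[0] + 1, counts.shape[1] + 1))
    S[1:, 1:] = counts.cumsum(0).cumsum(1)
    return S


def _diamond_means(counts: np.ndarray, w: int, S: np.ndarray | None = None) -> np.ndarray:
    """Mean count over the w x w diamond crossing each bin; NaN at edges.

    The diamond at bin i covers pairs (a, b) with i-w <= a < i <= b < i+w,
    i.e. the rectangle rows [i-w, i) x cols [i, i+w); computed with a 2-D
    prefix sum (pass ``S`` to reuse one across windows).
    """
    n = counts.shape[0]
    out = np.full(n, np.nan)
    if n < 2 * w:
        return out
    if S is None:
        S = _prefix_sum(counts)
    i = np.arange(w, n - w + 1)
    total = S[i, i + w] - S[i - w, i + w] - S[i, i] + S[i - w, i]
    out[i] = total / (w * w)
    return out


def insulation_track(
    matrix: ContactMatrix,
    min_depth: int = 100_000,
    max_depth: int = 600_000,
    window_step: int = 50_000,
) -> InsulationTrack:
    """Compute the multi-window insulation score track.

    Parameters mirror the window sweep used for 10 Kb TAD calling:
    diamond windows from ``min_depth`` to ``max_depth`` (inclusive) in
    ``window_step`` increments, all in bp and multiples of the bin size.
    With the defaults at 10 Kb bins this is 11 windows of 10-60 bins.
    """
    bs = matrix.bin_size
    for name, v in (("min_depth", min_depth), ("max_depth", max_depth), ("window_step", window_step)):
        if v % bs:
            raise ValueError(f"{name}={v} is not a multiple of bin_size={bs}")
    if min_depth < bs:
        raise ValueError("min_depth must be >= bin_size")
    if max_depth < min_depth:
        raise ValueError("max_depth must be >= min_depth")
    ws = list(range(min_depth // bs, max_depth // bs + 1, window_step // bs))
    n = matrix.n_bins
    w_max = max(ws)
    diamonds: dict[int, np.ndarray] = {}
    if n * bs < 2 * max_depth:
        warnings.warn(
            f"matrix ({n * bs} bp) smaller than twice max_depth; track is all-missing"
        )
        return InsulationTrack(
            matrix.chrom,
            bs,
            np.full(n, np.nan),
            {w: np.full(n, np.nan) for w in ws},
            tuple(w * bs for w in ws),
        )
    zsum = np.zeros(n)
    S = _prefix_sum(matrix.counts)
    for w in ws:
        d = _diamond_means(matrix.counts, w, S)
        diamonds[w] = d
        valid = np.isfinite(d)
        ld = np.log1p(d[valid])
        sd = ld.std(ddof=1) if valid.sum() > 1 else 0.0
        # variance at float-rounding scale (e.g. a constant matrix summed by
        # prefix sums) is noise, not signal; do not z-magnify it
        if sd <= 1e-8 * (1.0 + np.abs(ld).max(initial=0.0)):
            sd = 0.0
        z = np.full(n, np.nan)
        z[valid] = 0.0 if sd == 0 else (ld - ld.mean()) / sd
        zsum += np.where(np.isfinite(z), z, 0.0)
    score = np.full(n, np.nan)
    interior = slice(w_max, n - w_max + 1)
    score[interior] = zsum[interior] / len(ws)
    return InsulationTrack(matrix.chrom, bs, score, diamonds, tuple(w * bs for w in ws))


def _local_minima(score: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local minima within the finite region."""
    idx = np.flatnonzero(np.isfinite(score))
    if idx.size < 3:
        return []
    lo, hi = idx[0], idx[-1]
    s = score[lo : hi + 1]
    minima = []
    for k in range(1, len(s) - 1):
        if s[k] < s[k - 1] and s[k] <= s[k + 1]:
            minima.append(lo + k)
    return minima


def _prominence(score: np.ndarray, i: int) -> float:
    """Depth of minimum i below the lower of its flanking local maxima.

    Scanning stops at the edge of the defined region, where the running
    maximum so far is used (an edge acts as a flank)."""
    idx = np.flatnonzero(np.isfinite(score))
    lo, hi = idx[0], idx[-1]

    def flank_max(step):
        best = score[i]
        k = i + step
        while lo <= k <= hi:
            best = max(best, score[k])
            if (
                lo < k < hi
                and score[k] >= score[k - 1]
                and score[k] > score[k + 1]
                and score[k] > score[i]
            ):
                break
            k += step
        return best

    return min(flank_max(-1), flank_max(+1)) - score[i]


def _diag_expected(counts: np.ndarray) -> np.ndarray:
    """Per-diagonal chromosome-wide mean count."""
    n = counts.shape[0]
    return np.array([counts.diagonal(d).mean() for d in range(n)])


def _local_oe(counts: np.ndarray, expected: np.ndarray, i: int, w: int) -> np.ndarray:
    """O/E submatrix of the 2w x 2w neighbourhood of bin i.

    Normalising by the per-diagonal chromosome mean puts crossing and
    within-domain contacts on the same distance scale, so the boundary
    significance test is not confounded by distance decay."""
    local = counts[i - w : i + w, i - w : i + w]
    idx = np.arange(local.shape[0])
    d = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        return local / expected[d]


def _diamond_cells(oe_local: np.ndarray, w: int) -> np.ndarray:
    return oe_local[0:w, w : 2 * w].ravel()


def _intra_cells(oe_local: np.ndarray, w: int) -> np.ndarray:
    """Off-diagonal within-domain contacts flanking the central bin
    (upstream and downstream w x w triangles)."""
    up = oe_local[0:w, 0:w]
    dn = oe_local[w : 2 * w, w : 2 * w]
    iu = np.triu_indices(w, k=1)
    return np.concatenate([up[iu], dn[iu]])


def call_boundaries(
    track: InsulationTrack,
    matrix: ContactMatrix,
    min_delta: float = 0.01,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Call TAD boundaries as significant local minima of the insulation score.

    Candidates are local minima whose prominence (depth below the lower of
    the two flanking local maxima) is at least ``min_delta``.  Each
    candidate's crossing-diamond counts are compared against the two
    flanking within-domain diamonds with a one-sided Wilcoxon rank-sum
    test (crossing < intra); p-values are Benjamini-Hochberg adjusted
    across candidates and calls with q <= ``q_threshold`` are kept.
    Calls closer than the smallest window depth collapse to the
    lower-score one.  Returns a BED-like frame with one bin per call.
    """
    score = track.score
    bs = track.bin_size
    w0 = min(track.window_sizes_bp) // bs
    if not np.isfinite(score).any():
        return _empty_calls()
    cands = []
    for i in _local_minima(score):
        delta = _prominence(score, i)
        if delta >= min_delta:
            cands.append((i, delta))
    if not cands:
        return _empty_calls()
    expected = _diag_expected(matrix.counts)
    pvals = []
    for i, _ in cands:
        oe_local = _local_oe(matrix.counts, expected, i, w0)
        cross = _diamond_cells(oe_local, w0)
        intra = _intra_cells(oe_local, w0)
        cross = cross[np.isfinite(cross)]
        intra = intra[np.isfinite(intra)]
        degenerate = (
            cross.size == 0
            or intra.size == 0
            or (
                (cross == cross[0]).all()
                and (intra == cross[0]).all()
            )
        )
        if degenerate:
            pvals.append(1.0)
            continue
        res = stats.mannwhitneyu(cross, intra, alternative="less")
        pvals.append(float(res.pvalue))
    qvals = stats.false_discovery_control(pvals)
    keep = [
        (i, delta, p, q)
        for (i, delta), p, q in zip(cands, pvals, qvals)
        if q <= q_threshold
    ]
    keep.sort()
    # collapse runs of calls closer than min_depth to the strongest minimum
    min_sep = w0  # bins
    collapsed: list[tuple[int, float, float, float]] = []
    for call in keep:
        if collapsed and call[0] - collapsed[-1][0] < min_sep:
            if score[call[0]] < score[collapsed[-1][0]]:
                collapsed[-1] = call
        else:
            collapsed.append(call)
    return pd.DataFrame(
        [
            {
                "chrom": track.chrom,
                "start": i * bs,
                "end": (i + 1) * bs,
                "bin": i,
                "score": score[i],
                "delta": delta,
                "pvalue": p,
                "qvalue": q,
            }
            for i, delta, p, q in collapsed
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "bin",
            "score",
            "delta",
            "pvalue",
            "qvalue",
        ],
    )


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "bin", "score", "delta", "pvalue", "qvalue"]
    )


@dataclass
class PileupResult:
    """Aggregate contact signal around a set of anchors."""

    oe_matrix: np.ndarray  # (2F+1, 2F+1) mean observed/expected
    median_insulation: np.ndarray | None  # (2F+1,) per offset bin
    offsets: np.ndarray  # offset in bins, -F..F
    n_used: int
    n_dropped: int


def _oe(counts: np.ndarray) -> np.ndarray:
    """Observed/expected with the per-diagonal chromosome mean as expected."""
    n = counts.shape[0]
    oe = np.full_like(counts, np.nan, dtype=float)
    for d in range(n):
        diag = counts.diagonal(d)
        m = diag.mean()
        if m > 0:
            vals = diag / m
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def pileup(
    anchors: pd.DataFrame,
    matrix: ContactMatrix,
    track: InsulationTrack | None = None,
    flank: int = 1_000_000,
) -> PileupResult:
    """Mean observed/expected submatrix and median insulation curve
    centered on anchor midpoints.

    Anchors whose window would cross the matrix edge are dropped and
    counted in ``n_dropped``; with zero usable anchors an error is raised.
    """
    bs = matrix.bin_size
    F = flank // bs
    centers = ((anchors["start"] + anchors["end"]) // 2 // bs).astype(int)
    oe = _oe(matrix.counts)
    subs, curves = [], []
    dropped = 0
    for c in centers:
        if c - F < 0 or c + F >= matrix.n_bins:
            dropped += 1
            continue
        subs.append(oe[c - F : c + F + 1, c - F : c + F + 1])
        if track is not None:
            curves.append(track.score[c - F : c + F + 1])
    if not subs:
        raise ValueError("no usable anchors within matrix extent")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        agg = np.nanmean(np.stack(subs), axis=0)
        med = (
            np.nanmedian(np.stack(curves), axis=0) if track is not None else None
        )
    return PileupResult(
        oe_matrix=agg,
        median_insulation=med,
        offsets=np.arange(-F, F + 1),
        n_used=len(subs),
        n_dropped=dropped,
    )
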
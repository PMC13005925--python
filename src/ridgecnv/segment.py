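"""Hierarchical multi-phase segmentation of log2-ratio profiles.

Three phases, each per chromosome:

1. *Pre-segmentation* — an online z-score scan: the mean and sd (divisor
   n-1) of the expanding window since the last breakpoint are
   maintained, the sd is floored at ``min_sd``, and an incoming point
   whose |x - mu| / sd' exceeds ``z_thresh`` starts a new segment.
2. *Kernel smoothing* — within each pre-segment, values are blended with
   an exponentially distance-weighted average of the whole segment
   (weights from target midpoint distances, length scale
   lambda = range/4 + 1); a convex combination with weight
   ``alpha_smooth`` guards against over-smoothing.
3. *Circular binary segmentation* — recursive arc-vs-complement mean
   shift detection with a permutation p-value decides the final
   breakpoints; CBS is the final authority and may merge across
   pre-segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ridge import LogRatioProfile
from .targets import Panel

__all__ = [
    "PresegConfig",
    "SmootherConfig",
    "CbsParams",
    "Segment",
    "SegmentSet",
    "presegment_zscore",
    "kernel_weights",
    "smooth_segment",
    "cbs_segment",
    "segment_profile",
]


@dataclass
class PresegConfig:
    z_thresh: float = 3.0
    min_sd: float = 0.05
    min_window: int = 5

    def __post_init__(self):
        if self.z_thresh <= 0 or self.min_sd <= 0 or self.min_window < 2:
            raise ValueError("invalid pre-segmentation parameters")


@dataclass
class SmootherConfig:
    alpha_smooth: float = 0.3

    def __post_init__(self):
        if not (0.0 <= self.alpha_smooth <= 1.0):
            raise ValueError("alpha_smooth must lie in [0,1]")


@dataclass
class CbsParams:
    alpha: float = 0.01
    nperm: int = 10_000
    early_stop: bool = True
    min_width: int = 2  # canonical CBS default: no single-point segments


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    first_index: int
    last_index: int
    n_targets: int
    mean_log2: float
    phase: str


class SegmentSet:
    """Ordered per-chromosome partition of the unmasked targets."""

    def __init__(self, segments: list[Segment]):
        self.segments = segments

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "first_index": s.first_index,
                    "last_index": s.last_index,
                    "n_targets": s.n_targets,
                    "mean_log2": s.mean_log2,
                    "phase": s.phase,
                }
                for s in self.segments
            ]
        )


def _profile_chrom_blocks(profile: LogRatioProfile, panel: Panel):
    """Yield (chrom, local_slice) runs of the profile's targets, in genome order."""
    chroms = panel.chroms[profile.target_indices]
    i = 0
    n = len(chroms)
    while i < n:
        j = i
        while j < n and chroms[j] == chroms[i]:
            j += 1
        yield str(chroms[i]), slice(i, j)
        i = j


def _zscan_breaks(v: np.ndarray, cfg: PresegConfig) -> list[int]:
    """Local breakpoint positions: index k means a new segment starts at k."""
    breaks: list[int] = []
    start = 0
    s = v[0]
    s2 = v[0] ** 2
    cnt = 1
    for k in range(1, len(v)):
        if cnt >= cfg.min_window:
            mu = s / cnt
            var = max((s2 - cnt * mu * mu) / (cnt - 1), 0.0)
            sd = max(np.sqrt(var), cfg.min_sd)
            z = abs(v[k] - mu) / sd
            if z > cfg.z_thresh:
                breaks.append(k)
                start = k
                s = v[k]
                s2 = v[k] ** 2
                cnt = 1
                continue
        s += v[k]
        s2 += v[k] ** 2
        cnt += 1
    return breaks


def _make_segments(
    profile: LogRatioProfile,
    panel: Panel,
    values: np.ndarray,
    boundaries_per_chrom: list[tuple[str, slice, list[int]]],
    phase: str,
) -> SegmentSet:
    segs: list[Segment] = []
    for chrom, block, breaks in boundaries_per_chrom:
        bounds = [0] + breaks + [block.stop - block.start]
        for a, b in zip(bounds[:-1], bounds[1:]):
            lo, hi = block.start + a, block.start + b
            idx = profile.target_indices[lo:hi]
            segs.append(
                Segment(
                    chrom=chrom,
                    start=int(panel.starts[idx[0]]),
                    end=int(panel.ends[idx[-1]]),
                    first_index=int(idx[0]),
                    last_index=int(idx[-1]),
                    n_targets=hi - lo,
                    mean_log2=float(np.mean(values[lo:hi])),
                    phase=phase,
                )
            )
    return SegmentSet(segs)


def presegment_zscore(
    profile: LogRatioProfile, panel: Panel, cfg: Optional[PresegConfig] = None
) -> SegmentSet:
    """Online z-score pre-partitioning, each chromosome scanned independently."""
    cfg = cfg or PresegConfig()
    per_chrom = []
    for chrom, block in _profile_chrom_blocks(profile, panel):
        breaks = _zscan_breaks(profile.values[block], cfg)
        per_chrom.append((chrom, block, breaks))
    return _make_segments(profile, panel, profile.values, per_chrom, "preseg")


def kernel_weights(coords: np.ndarray) -> np.ndarray:
    """Row-normalized exponential kernel over genomic coordinates.

    d_ij = |x_i - x_j|, lambda = (max - min)/4 + 1 (the +1 floors the
    length scale at 1 bp for degenerate segments), W_ij proportional to
    exp(-d_ij / lambda); every row sums to 1.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("coords must be a non-empty 1-d array")
    lam = (np.max(x) - np.min(x)) / 4.0 + 1.0
    d = np.abs(x[:, None] - x[None, :])
    e = np.exp(-d / lam)
    return e / e.sum(axis=1, keepdims=True)


def smooth_segment(
    values: np.ndarray, W: np.ndarray, cfg: Optional[SmootherConfig] = None
) -> np.ndarray:
    """Convex combination alpha * (W @ v) + (1 - alpha) * v."""
    cfg = cfg or SmootherConfig()
    v = np.asarray(values, dtype=float)
    if W.shape != (len(v), len(v)):
        raise ValueError("weight matrix does not match values")
    a = cfg.alpha_smooth
    if a == 0.0:
        return v.copy()
    return a * (W @ v) + (1.0 - a) * v


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=256)
def _arc_pairs(n: int, min_width: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Boundary pairs (i, j) with 0 <= i < j <= n, excluding the full arc (0, n).

    Pairs are restricted so every piece a split would create (prefix,
    arc, suffix) spans at least ``min_width`` points.
    """
    iu, ju = np.triu_indices(n + 1, k=1)
    keep = ~((iu == 0) & (ju == n))
    m = ju - iu
    keep &= m >= min_width
    keep &= (n - m) >= min_width          # complement as a whole
    keep &= (iu == 0) | (iu >= min_width)  # prefix piece
    keep &= (ju == n) | ((n - ju) >= min_width)  # suffix piece
    return iu[keep], ju[keep]


def _arc_coeffs(v: np.ndarray, sd: float, min_width: int = 1):
    """Linearize Z(i, j) = a_p * arc_sum - b_p over all arc pairs.

    Z = (arc_mean - comp_mean) / (sd * sqrt(1/m + 1/(n-m))) is linear in
    the arc sum, so each pair needs only two precomputed coefficients;
    permutation chunks then reduce to one gather and two in-place ops.
    """
    n = len(v)
    iu, ju = _arc_pairs(n, min_width)
    if len(iu) == 0:
        return iu, ju, np.empty(0), np.empty(0)
    m = (ju - iu).astype(float)
    inv = 1.0 / m + 1.0 / (n - m)
    denom = sd * np.sqrt(inv)
    a = inv / denom
    b = float(np.sum(v)) / (n - m) / denom
    return iu, ju, a, b


def _arc_zmax(S_rows: np.ndarray, iu, ju, a, b):
    """Max |Z| per row of cumulative-sum rows (leading zero column)."""
    z = S_rows[:, ju] - S_rows[:, iu]
    z *= a
    z -= b
    np.abs(z, out=z)
    return z.max(axis=1), z


def max_arc_statistic(v: np.ndarray, min_width: int = 1):
    """Observed max arc-vs-complement t statistic and its boundary pair.

    The statistic for arc (i, j] is the difference of arc and complement
    means standardized by the segment sd (ddof=1) and the usual
    two-sample scaling sqrt(1/m + 1/(n-m)).  Ties break to the first
    pair in row-major (i, then j) order.
    """
    v = np.asarray(v, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 points")
    sd = np.std(v, ddof=1)
    if sd <= 0:
        return 0.0, (0, n)
    iu, ju, a, b = _arc_coeffs(v, sd, min_width)
    if len(iu) == 0:
        return 0.0, (0, n)
    S = np.concatenate([[0.0], np.cumsum(v)])
    zmax, z = _arc_zmax(S[None, :], iu, ju, a, b)
    k = int(np.argmax(z[0]))
    return float(zmax[0]), (int(iu[k]), int(ju[k]))


def _permutation_test(
    v: np.ndarray,
    rng: np.random.Generator,
    params: CbsParams,
    chunk: int = 250,
):
    """Permutation p-value for the max arc statistic, with early stopping.

    Permutations are drawn one at a time from ``rng`` (one
    ``rng.permutation(n)`` call each) so the stream is independent of
    chunking; chunks only batch the vectorized statistic evaluation.
    Early stopping: reject the split as soon as the exceedance count
    can no longer come in under alpha, accept once the binomial
    confidence bound on p falls safely below alpha.

    Returns (split boundary pair or None, p-value estimate).
    """
    n = len(v)
    if n < 2 * params.min_width or np.ptp(v) == 0:
        return None, 1.0
    sd = np.std(v, ddof=1)
    if sd <= 0:
        return None, 1.0
    iu, ju, a, b = _arc_coeffs(v, sd, params.min_width)
    if len(iu) == 0:
        return None, 1.0

    t_obs, pair = max_arc_statistic(v, params.min_width)
    if t_obs <= 0:
        return None, 1.0

    alpha, nperm = params.alpha, params.nperm
    count = 0
    done = 0
    # keep the vectorized chunk below ~2.5M doubles
    chunk = max(16, min(chunk, int(2.5e6 / max(len(iu), 1))))
    while done < nperm:
        c = min(chunk, nperm - done)
        P = np.empty((c, n))
        for r in range(c):
            P[r] = v[rng.permutation(n)]
        S = np.zeros((c, n + 1))
        np.cumsum(P, axis=1, out=S[:, 1:])
        zmax, _ = _arc_zmax(S, iu, ju, a, b)
        count += int(np.sum(zmax >= t_obs))
        done += c
        if params.early_stop and done >= 250:
            if count > alpha * nperm:  # can never come in under alpha
                return None, (count + 1) / (done + 1)
            band = 2.6 * np.sqrt(max(count, 1))
            if (count - band) / done > alpha:  # p confidently above alpha
                return None, (count + 1) / (done + 1)
            if done >= 500 and (count + band) / done < alpha:  # confidently below
                break
    p = (count + 1) / (done + 1)
    if p < alpha:
        return pair, p
    return None, p


def _cbs_chrom(
    v: np.ndarray, rng: np.random.Generator, params: CbsParams
) -> list[int]:
    """Breakpoint positions (local indices where a new segment starts)."""
    breaks: set[int] = set()
    queue: list[tuple[int, int]] = [(0, len(v))]
    while queue:
        lo, hi = queue.pop(0)
        if hi - lo < 2 * params.min_width:
            continue
        pair, _ = _permutation_test(v[lo:hi], rng, params)
        if pair is None:
            continue
        i, j = pair
        cuts = sorted(
            {lo + i, lo + j} - {lo, hi}
        )
        if not cuts:
            continue
        breaks.update(cuts)
        bounds = [lo] + cuts + [hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            queue.append((a, b))
    return sorted(breaks)


def cbs_segment(
    profile: LogRatioProfile,
    panel: Panel,
    params: Optional[CbsParams] = None,
    seed: int | None = 0,
) -> SegmentSet:
    """Final segmentation: recursive permutation-tested arc splits per chromosome."""
    params = params or CbsParams()
    ss = np.random.SeedSequence(seed)
    per_chrom = []
    blocks = list(_profile_chrom_blocks(profile, panel))
    children = ss.spawn(len(blocks))
    for (chrom, block), child in zip(blocks, children):
        rng = np.random.default_rng(child)
        breaks = _cbs_chrom(profile.values[block], rng, params)
        per_chrom.append((chrom, block, breaks))
    return _make_segments(profile, panel, profile.values, per_chrom, "final")


def segment_profile(
    profile: LogRatioProfile,
    panel: Panel,
    preseg_cfg: Optional[PresegConfig] = None,
    smoother_cfg: Optional[SmootherConfig] = None,
    cbs_params: Optional[CbsParams] = None,
    seed: int | None = 0,
) -> tuple[SegmentSet, LogRatioProfile, SegmentSet]:
    """Run the full three-phase chain.

    Returns ``(final_segments, smoothed_profile, preseg_segments)``.
    CBS breakpoints are located on the smoothed profile, but each final
    segment's ``mean_log2`` is re-estimated from the *original* log2
    ratios: smoothing stabilizes breakpoints, yet using blended values
    for level estimation would let signal smeared across an imperfect
    pre-segment boundary masquerade as a weak flanking call.
    """
    preseg = presegment_zscore(profile, panel, preseg_cfg)
    smoothed = np.empty_like(profile.values)
    pos = {int(t): k for k, t in enumerate(profile.target_indices)}
    for seg in preseg:
        lo = pos[seg.first_index]
        hi = pos[seg.last_index] + 1
        idx = profile.target_indices[lo:hi]
        W = kernel_weights(panel.midpoints[idx])
        smoothed[lo:hi] = smooth_segment(profile.values[lo:hi], W, smoother_cfg)
    smoothed_profile = LogRatioProfile(
        values=smoothed,
        target_indices=profile.target_indices,
        sample_id=profile.sample_id,
        stable_chrom=profile.stable_chrom,
    )
    final = cbs_segment(smoothed_profile, panel, cbs_params, seed=seed)
    for seg in final:
        lo = pos[seg.first_index]
        hi = pos[seg.last_index] + 1
        seg.mean_log2 = float(np.mean(profile.values[lo:hi]))
    return final, smoothed_profile, preseg
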
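"""LRR segmentation and discrete copy-number state calling.

Segmentation is penalized least squares: per chromosome, changepoints
minimize the sum of squared residuals around segment means plus a penalty
of ``lambda * sigma^2 * log(n)`` per breakpoint, solved exactly by optimal
partitioning (O(n^2) dynamic program — deterministic and exact at desk
scale). The noise scale sigma is the robust MAD estimate from
adjacent-probe first differences.

State calling maps segment mean LRR to one of five states with an adaptive
neutral threshold: wide segments in quiet samples get a tighter band.
Thresholds are absolute log2 values, so an un-normalized global shift in
LRR shifts calls accordingly; arrays are assumed median-centered near 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SampleArray

STATES = ("double_loss", "loss", "neutral", "gain", "amplification")

#: segment mean below this is a double (homozygous) loss
DOUBLE_LOSS_LRR = -1.0
#: segment mean above this is an amplification (beyond a single gain)
AMPLIFICATION_LRR = 0.58 * 1.5
#: floor of the adaptive neutral half-width
MIN_NEUTRAL_LRR = 0.1


@dataclass
class Segment:
    chrom: str
    start_idx: int  # 0-based, global probe index
    end_idx: int  # half-open
    mean_lrr: float
    state: str = "neutral"

    @property
    def n_probes(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class SegmentedProfile:
    sample_id: str
    segments: list[Segment]
    noise_mad: float

    def breakpoints(self) -> dict[str, list[int]]:
        """Interior breakpoints (global probe indices) per chromosome."""
        out: dict[str, list[int]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, [])
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            out[chrom] = [s.start_idx for s in segs[1:]]
        return out


def estimate_noise(lrr: np.ndarray) -> float:
    """Robust per-sample LRR noise SD: 1.4826 * MAD(diff) / sqrt(2)."""
    d = np.diff(lrr)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2)


def _segment_series(y: np.ndarray, penalty: float, min_len: int) -> list[int]:
    """Exact optimal partitioning: interior changepoints of ``y``.

    Minimizes sum of per-segment SSE + penalty per breakpoint, segments at
    least ``min_len`` probes. Returns sorted interior changepoint indices.
    """
    n = len(y)
    if n < 2 * min_len:
        return []
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    best = np.full(n + 1, np.inf)
    best[0] = -penalty  # first segment carries no breakpoint penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    for j in range(min_len, n + 1):
        i = np.arange(0, j - min_len + 1)
        lengths = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / lengths
        cand = best[i] + sse + penalty
        k = int(np.argmin(cand))
        best[j], prev[j] = cand[k], i[k]
    cps = []
    j = n
    while j > 0:
        j = int(prev[j])
        if j > 0:
            cps.append(j)
    return sorted(cps)


def segment_lrr(
    array: SampleArray,
    penalty_lambda: float = 3.0,
    min_seg_probes: int = 10,
) -> SegmentedProfile:
    """Segment a (wave-corrected) array's LRR, one chromosome at a time."""
    lrr = array.lrr
    sigma = estimate_noise(lrr)
    sigma2 = max(sigma, 1e-6) ** 2
    segments: list[Segment] = []
    for chrom, sl in array.chrom_slices().items():
        y = lrr[sl]
        n = len(y)
        penalty = penalty_lambda * sigma2 * np.log(max(n, 2))
        cps = _segment_series(y, penalty, min_seg_probes)
        bounds = [0] + cps + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chrom=chrom,
                    start_idx=sl.start + a,
                    end_idx=sl.start + b,
                    mean_lrr=float(np.mean(y[a:b])),
                )
            )
    return SegmentedProfile(sample_id=array.sample_id, segments=segments, noise_mad=sigma)


def call_states(
    profile: SegmentedProfile,
    double_loss_lrr: float = DOUBLE_LOSS_LRR,
    amplification_lrr: float = AMPLIFICATION_LRR,
    min_neutral_lrr: float = MIN_NEUTRAL_LRR,
) -> SegmentedProfile:
    """Assign the five-state vocabulary to each segment from its mean LRR.

    The neutral half-width is adaptive per segment:
    ``t = max(min_neutral_lrr, 3 * noise_mad / sqrt(n_probes))``.
    """
    for seg in profile.segments:
        t = max(min_neutral_lrr, 3 * profile.noise_mad / np.sqrt(seg.n_probes))
        m = seg.mean_lrr
        if m < double_loss_lrr:
            seg.state = "double_loss"
        elif m < -t:
            seg.state = "loss"
        elif m <= t:
            seg.state = "neutral"
        elif m <= amplification_lrr:
            seg.state = "gain"
        else:
            seg.state = "amplification"
    return profile
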
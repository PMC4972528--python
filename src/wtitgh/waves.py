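"""Genomic-wave estimation and removal.

SNP-array LRR tracks carry a smooth positional bias ("genomic waves")
shared across arrays of a batch. The wave is estimated model-free from the
normal-tissue arrays — where the true copy number is flat diploid, so any
smooth structure is artifact — and regressed out of every array with a
per-sample scale, since wave amplitude varies between hybridizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .io import SampleArray

logger = logging.getLogger(__name__)


@dataclass
class WaveProfile:
    """Per-probe wave offset (log2 units), indexed like the shared probe set.
    Centered to mean zero."""

    offset: np.ndarray

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        if not np.isfinite(self.offset).all():
            raise ValueError("wave profile must be finite")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.offset == 0))


def estimate_wave(normals: list[SampleArray], window_probes: int = 51) -> WaveProfile:
    """Estimate the wave as the centered running median (window
    ``window_probes``, per chromosome) of the across-normals median LRR.

    With no normal arrays, returns a zero profile (correction becomes a
    no-op) and warns.
    """
    if window_probes % 2 == 0:
        raise ValueError("window_probes must be odd")
    if not normals:
        logger.warning("no normal arrays: wave correction disabled (zero profile)")
        return WaveProfile(offset=np.zeros(0))

    lrr = np.vstack([a.lrr for a in normals])
    if any(a.n_probes != normals[0].n_probes for a in normals):
        raise ValueError("normal arrays must share one probe set")
    panel_median = np.median(lrr, axis=0)

    smooth = np.empty_like(panel_median)
    for _, sl in normals[0].chrom_slices().items():
        smooth[sl] = median_filter(panel_median[sl], size=min(window_probes, sl.stop - sl.start),
                                   mode="nearest")
    return WaveProfile(offset=smooth - smooth.mean())


def correct_lrr(array: SampleArray, wave: WaveProfile) -> SampleArray:
    """Remove the wave from one array: fit a per-sample scale beta by least
    squares of LRR on the wave and subtract ``beta * wave``. BAF untouched.

    Idempotent: the corrected LRR is uncorrelated with the wave, so a second
    pass fits beta ~ 0.
    """
    if wave.offset.size == 0 or wave.is_zero:
        return array
    if wave.offset.size != array.n_probes:
        raise ValueError(
            f"wave length {wave.offset.size} != array probes {array.n_probes}"
        )
    w = wave.offset
    y = array.lrr
    denom = float(w @ w)
    beta = float(w @ (y - y.mean())) / denom if denom > 0 else 0.0
    return array.with_lrr(y - beta * w)


def correct_case(arrays: list[SampleArray], wave: WaveProfile) -> list[SampleArray]:
    return [correct_lrr(a, wave) for a in arrays]
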
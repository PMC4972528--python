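"""Case-level region harmonization, filtering, and allelic validation.

Per-sample segment boundaries are merged into one shared set of regions per
case, so that calls can be compared sample-to-sample over identical
intervals. Regions that are too small or have outlying probe density are
removed. Each non-neutral call is then validated against the mirrored
B-allele frequency (mBAF): a genuine allelic-imbalance event must fold the
heterozygous-probe BAF away from 0.5. Finally, regions that are diploid in
LRR but strongly imbalanced in BAF are flagged as copy-number-neutral LOH.

mBAF here is ``0.5 + |BAF - 0.5|``, averaged over probes heterozygous in
the matched germline sample; range [0.5, 1]. Noiseless expectations:
0.5 balanced diploid, 2/3 single gain (2+1), 1.0 loss or uniparental
disomy at purity 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleArray
from .segmentation import SegmentedProfile, _segment_series, estimate_noise

logger = logging.getLogger(__name__)

FLAG_ACCEPTED = "accepted"
FLAG_REJECTED = "rejected_no_imbalance"
FLAG_LOW_INFO = "low_information"
FLAG_CNNLOH = "cnnloh_added"


@dataclass
class Region:
    chrom: str
    start_idx: int  # global probe index, 0-based half-open
    end_idx: int
    start_bp: int
    end_bp: int

    @property
    def n_probes(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def density(self) -> float:
        """Probes per Mb."""
        span = max(self.end_bp - self.start_bp, 1)
        return self.n_probes / (span / 1e6)


@dataclass
class RegionMatrix:
    """Harmonized regions x samples: state calls, mBAF, LOH flags, provenance."""

    case_id: str
    regions: list[Region]
    calls: pd.DataFrame  # region x sample, state strings
    mbaf: pd.DataFrame  # region x sample, float (NaN = undefined)
    loh: pd.DataFrame  # region x sample, bool
    flags: pd.DataFrame  # region x sample, provenance strings

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def subset(self, keep: list[int]) -> "RegionMatrix":
        return RegionMatrix(
            case_id=self.case_id,
            regions=[self.regions[i] for i in keep],
            calls=self.calls.loc[keep].reset_index(drop=True),
            mbaf=self.mbaf.loc[keep].reset_index(drop=True),
            loh=self.loh.loc[keep].reset_index(drop=True),
            flags=self.flags.loc[keep].reset_index(drop=True),
        )


def _merge_breakpoints(bps: list[int], tolerance: int) -> list[int]:
    """Single-linkage merge of breakpoints closer than ``tolerance`` into
    their median (tie -> lower)."""
    if not bps:
        return []
    bps = sorted(set(bps))
    merged, cluster = [], [bps[0]]
    for b in bps[1:]:
        if b - cluster[-1] < tolerance:
            cluster.append(b)
        else:
            merged.append(int(np.floor(np.median(cluster))))
            cluster = [b]
    merged.append(int(np.floor(np.median(cluster))))
    return merged


def mbaf_breakpoints(
    tumor: SampleArray,
    normal: SampleArray | None,
    het_halfwidth: float = 0.15,
    penalty_lambda: float = 3.0,
    min_seg_probes: int = 10,
) -> dict[str, list[int]]:
    """Breakpoints visible only in the BAF: segment the mirrored-BAF series
    over heterozygous probes per chromosome.

    Copy-number-neutral LOH leaves no LRR step, so its boundaries can only
    come from allelic imbalance. The mirrored BAF at heterozygous probes is
    segmented with the same penalized least-squares search used for LRR and
    the changepoints are mapped back to global probe indices so they can
    join the region-boundary union.
    """
    out: dict[str, list[int]] = {}
    for chrom, sl in tumor.chrom_slices().items():
        tbaf = tumor.baf[sl]
        if normal is not None:
            het = np.abs(normal.baf[sl] - 0.5) <= het_halfwidth
        else:
            het = (tbaf >= 0.25) & (tbaf <= 0.75)
        idx = np.flatnonzero(het)
        if len(idx) < 2 * min_seg_probes:
            continue
        y = 0.5 + np.abs(tbaf[idx] - 0.5)
        sigma2 = max(estimate_noise(y), 1e-6) ** 2
        penalty = penalty_lambda * sigma2 * np.log(len(y))
        cps = _segment_series(y, penalty, min_seg_probes)
        if cps:
            out[chrom] = [sl.start + int(idx[c]) for c in cps]
    return out


def harmonize_regions(
    profiles: list[SegmentedProfile],
    reference: SampleArray,
    tolerance_probes: int = 5,
    case_id: str = "",
    extra_breakpoints: dict[str, list[int]] | None = None,
) -> RegionMatrix:
    """Merge per-sample breakpoints into shared regions; copy calls over.

    Region boundaries are the union of sample breakpoints (plus any
    ``extra_breakpoints``, e.g. BAF-derived ones) after merging breakpoints
    closer than ``tolerance_probes`` to their (lower) median; each region's
    per-sample call is the state of that sample's segment covering the
    region midpoint.
    """
    pos = reference.probes["pos"].to_numpy()
    regions: list[Region] = []
    for chrom, sl in reference.chrom_slices().items():
        bps: list[int] = []
        for p in profiles:
            bps.extend(p.breakpoints().get(chrom, []))
        if extra_breakpoints:
            bps.extend(extra_breakpoints.get(chrom, []))
        bounds = [sl.start] + _merge_breakpoints(bps, tolerance_probes) + [sl.stop]
        bounds = sorted(set(bounds))
        for a, b in zip(bounds[:-1], bounds[1:]):
            regions.append(
                Region(
                    chrom=chrom,
                    start_idx=a,
                    end_idx=b,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                )
            )

    sample_ids = [p.sample_id for p in profiles]
    calls = pd.DataFrame(index=range(len(regions)), columns=sample_ids, dtype=object)
    for p in profiles:
        for i, reg in enumerate(regions):
            mid = (reg.start_idx + reg.end_idx - 1) // 2
            seg = next(s for s in p.segments if s.start_idx <= mid < s.end_idx)
            calls.at[i, p.sample_id] = seg.state

    shape = (len(regions), len(sample_ids))
    return RegionMatrix(
        case_id=case_id,
        regions=regions,
        calls=calls,
        mbaf=pd.DataFrame(np.full(shape, np.nan), columns=sample_ids),
        loh=pd.DataFrame(np.zeros(shape, dtype=bool), columns=sample_ids),
        flags=pd.DataFrame(np.full(shape, FLAG_ACCEPTED, dtype=object), columns=sample_ids),
    )


def filter_regions(
    matrix: RegionMatrix,
    min_probes: int = 100,
    density_mads: float = 3.0,
) -> RegionMatrix:
    """Drop regions with fewer than ``min_probes`` probes or log-density
    outside median +/- ``density_mads`` robust MADs across the case."""
    logd = np.log(np.array([r.density for r in matrix.regions]))
    med = np.median(logd)
    mad = 1.4826 * np.median(np.abs(logd - med))
    keep = []
    for i, reg in enumerate(matrix.regions):
        if reg.n_probes < min_probes:
            logger.info("region %s:%d-%d removed: %d probes < %d",
                        reg.chrom, reg.start_bp, reg.end_bp, reg.n_probes, min_probes)
            continue
        dev = abs(logd[i] - med)
        if (mad > 0 and dev > density_mads * mad) or (mad == 0 and dev > 1e-12):
            logger.info("region %s:%d-%d removed: probe-density outlier", reg.chrom,
                        reg.start_bp, reg.end_bp)
            continue
        keep.append(i)
    if not keep:
        raise ValueError("all regions removed by filters")
    return matrix.subset(keep)


def compute_mbaf(
    region: Region,
    tumor: SampleArray,
    normal: SampleArray | None,
    het_halfwidth: float = 0.15,
    min_het_probes: int = 10,
) -> float:
    """Mean mirrored BAF of one region in one tumor sample.

    Heterozygous probes come from the matched normal (BAF within
    ``het_halfwidth`` of 0.5); without a normal, a less specific tumor-only
    window [0.25, 0.75] is used. Returns NaN when fewer than
    ``min_het_probes`` informative probes are available.
    """
    sl = slice(region.start_idx, region.end_idx)
    tbaf = tumor.baf[sl]
    if normal is not None:
        nbaf = normal.baf[sl]
        het = np.abs(nbaf - 0.5) <= het_halfwidth
    else:
        het = (tbaf >= 0.25) & (tbaf <= 0.75)
    if int(het.sum()) < min_het_probes:
        return float("nan")
    return float(np.mean(0.5 + np.abs(tbaf[het] - 0.5)))


def compute_mbaf_matrix(
    matrix: RegionMatrix,
    tumors: dict[str, SampleArray],
    normal: SampleArray | None,
    het_halfwidth: float = 0.15,
    min_het_probes: int = 10,
) -> RegionMatrix:
    if normal is None:
        logger.warning("no germline sample: tumor-only heterozygous-probe fallback in use")
    for s, arr in tumors.items():
        for i, reg in enumerate(matrix.regions):
            matrix.mbaf.at[i, s] = compute_mbaf(reg, arr, normal, het_halfwidth, min_het_probes)
    return matrix


def validate_allelic(matrix: RegionMatrix, mbaf_threshold: float = 0.56) -> RegionMatrix:
    """Reject non-neutral calls lacking allelic imbalance.

    A gain/loss/amplification/double-loss call with a defined mBAF below
    ``mbaf_threshold`` is reset to neutral (flag rejected_no_imbalance);
    a non-neutral call with undefined mBAF is retained but flagged
    low_information. Never creates a non-neutral call.
    """
    for s in matrix.sample_ids:
        for i in range(matrix.n_regions):
            state = matrix.calls.at[i, s]
            if state == "neutral":
                continue
            mbaf = matrix.mbaf.at[i, s]
            if np.isnan(mbaf):
                matrix.flags.at[i, s] = FLAG_LOW_INFO
            elif mbaf < mbaf_threshold:
                matrix.calls.at[i, s] = "neutral"
                matrix.flags.at[i, s] = FLAG_REJECTED
                logger.info("call %s region %d rejected: mBAF %.3f < %.3f",
                            s, i, mbaf, mbaf_threshold)
    return matrix


def detect_cnnloh(matrix: RegionMatrix, loh_mbaf_threshold: float = 0.68) -> RegionMatrix:
    """Flag copy-number-neutral LOH: neutral call but strong allelic imbalance.

    Only sets the LOH flag; never changes a state. Runs after allelic
    validation, so a rejected CNA (reset to neutral) is not re-promoted —
    its flag stays rejected_no_imbalance and it is skipped here.
    """
    for s in matrix.sample_ids:
        for i in range(matrix.n_regions):
            if matrix.calls.at[i, s] != "neutral":
                continue
            if matrix.flags.at[i, s] == FLAG_REJECTED:
                continue
            mbaf = matrix.mbaf.at[i, s]
            if not np.isnan(mbaf) and mbaf >= loh_mbaf_threshold:
                matrix.loh.at[i, s] = True
                matrix.flags.at[i, s] = FLAG_CNNLOH
    return matrix


def merged_loh_runs(matrix: RegionMatrix, sample_id: str) -> list[tuple[str, int, int]]:
    """Maximal runs of adjacent LOH-flagged regions, for reporting:
    (chrom, start_bp, end_bp)."""
    runs: list[tuple[str, int, int]] = []
    current: tuple[str, int, int] | None = None
    prev_end_idx = None
    for i, reg in enumerate(matrix.regions):
        flagged = bool(matrix.loh.at[i, sample_id])
        adjacent = (
            current is not None
            and reg.chrom == current[0]
            and prev_end_idx == reg.start_idx
        )
        if flagged and adjacent:
            current = (current[0], current[1], reg.end_bp)
        elif flagged:
            if current is not None:
                runs.append(current)
            current = (reg.chrom, reg.start_bp, reg.end_bp)
        else:
            if current is not None:
                runs.append(current)
                current = None
        prev_end_idx = reg.end_idx
    if current is not None:
        runs.append(current)
    return runs
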
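"""Cohort-level biomarker and sampling-design statistics.

Given per-tumor, per-sample presence of a biomarker CNA (e.g. gain of
chromosome arm 1q), these functions quantify what single-sample profiling
would miss: the probability that single sampling detects the biomarker in
every positive tumor, the mean per-tumor miss probability q with a normal
approximation CI, and the smallest number of samples n per tumor such that
1 - q^n exceeds a target sensitivity (a cumulative-binomial design bound).

Also provides the Welch one-tailed t-test used to compare ages between
heterogeneity groups, independent-origin detection from shared somatic
events, and cohort bookkeeping summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .arms import arm_span
from .regions import RegionMatrix

#: biomarker name -> (arm span key, what counts as positive)
BIOMARKERS = {
    "1q+": ("1q", "gain"),
    "16q-": ("16q", "loss"),
    "11p15_loh": ("11p15", "loh"),
}


@dataclass
class BiomarkerStatus:
    """Per-sample presence of one biomarker in one tumor."""

    tumor_id: str
    present: list[bool]

    @property
    def n_samples(self) -> int:
        return len(self.present)

    @property
    def fraction_positive(self) -> float:
        return sum(self.present) / len(self.present)

    @property
    def is_positive_tumor(self) -> bool:
        return any(self.present)

    @property
    def assessable(self) -> bool:
        """Heterogeneity is only assessable with >= 2 samples."""
        return self.n_samples >= 2

    @property
    def heterogeneous(self) -> bool:
        return self.assessable and 0 < self.fraction_positive < 1


@dataclass
class DetectionStats:
    """Single-sampling detection statistics over positive tumors."""

    fractions: list[float]  # per-tumor fraction of positive samples
    product_all_detected: float
    mean_miss: float
    ci95: tuple[float, float]

    @property
    def detect_prob(self) -> float:
        return 1.0 - self.mean_miss


def biomarker_presence(
    matrix: RegionMatrix,
    target: str,
    coverage_fraction: float = 0.5,
) -> BiomarkerStatus:
    """Score each sample of a case for a named biomarker.

    A sample is positive when accepted calls of the target direction (or
    LOH flags, for LOH biomarkers) cover at least ``coverage_fraction`` of
    the target arm span in bp.
    """
    if target not in BIOMARKERS:
        raise ValueError(f"unknown biomarker {target!r}; known: {sorted(BIOMARKERS)}")
    arm_key, direction = BIOMARKERS[target]
    chrom, span_start, span_end = arm_span(arm_key)
    span = span_end - span_start

    present = []
    for s in matrix.sample_ids:
        covered = 0
        for i, reg in enumerate(matrix.regions):
            if reg.chrom != chrom:
                continue
            overlap = min(reg.end_bp, span_end) - max(reg.start_bp, span_start)
            if overlap <= 0:
                continue
            state = matrix.calls.at[i, s]
            if direction == "loh":
                hit = bool(matrix.loh.at[i, s]) or state in ("loss", "double_loss")
            elif direction == "gain":
                hit = state in ("gain", "amplification")
            else:
                hit = state in ("loss", "double_loss")
            if hit:
                covered += overlap
        present.append(covered >= coverage_fraction * span)
    return BiomarkerStatus(tumor_id=matrix.case_id, present=present)


def detection_stats(fractions: Sequence[float], ci_method: str = "normal") -> DetectionStats:
    """Single-sampling statistics over per-tumor positive-sample fractions.

    product_all_detected = prod(f_j): probability that one random sample
    per tumor detects the biomarker in every positive tumor. mean_miss is
    the mean of q_j = 1 - f_j with a 95% CI (normal approximation by
    default: q_bar +/- 1.96 * sd(q_j)/sqrt(m), sample sd, clipped to [0,1];
    ``ci_method="t"`` uses the t quantile instead).
    """
    f = np.asarray(list(fractions), dtype=float)
    if f.size == 0:
        raise ValueError("need at least one tumor fraction")
    if ((f <= 0) | (f > 1)).any():
        raise ValueError("fractions must be in (0, 1]")
    q = 1.0 - f
    q_bar = float(q.mean())
    if f.size > 1:
        se = float(q.std(ddof=1)) / math.sqrt(f.size)
        crit = 1.959963984540054 if ci_method == "normal" else float(
            sps.t.ppf(0.975, f.size - 1)
        )
    else:
        se, crit = 0.0, 0.0
    lo = max(0.0, q_bar - crit * se)
    hi = min(1.0, q_bar + crit * se)
    return DetectionStats(
        fractions=[float(x) for x in f],
        product_all_detected=float(np.prod(f)),
        mean_miss=q_bar,
        ci95=(lo, hi),
    )


def min_samples_needed(q: float, target_sensitivity: float = 0.95) -> int:
    """Smallest n with 1 - q**n > target_sensitivity (q = per-sample miss
    probability). q = 1 means the biomarker is undetectable."""
    if not 0 <= q < 1:
        raise ValueError("miss probability q must be in [0, 1)")
    if not 0 < target_sensitivity < 1:
        raise ValueError("target sensitivity must be in (0, 1)")
    if q == 0:
        return 1
    n = 1
    while 1 - q**n <= target_sensitivity:
        n += 1
    return n


def welch_one_tailed(ages_a: Sequence[float], ages_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test of mean(a) < mean(b), one-tailed.

    Returns (t, one-tailed p = P(T_df <= t), Welch-Satterthwaite df).
    """
    a = np.asarray(list(ages_a), dtype=float)
    b = np.asarray(list(ages_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    if sa + sb == 0:
        return 0.0, 0.5, float(a.size + b.size - 2)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = float(sps.t.cdf(t, df))
    return float(t), p, float(df)


def detect_independent_origins(
    events_per_sample: Mapping[str, set],
) -> list[dict]:
    """Partition samples by shared somatic events.

    Two samples are connected when they share at least one accepted somatic
    event (same region, same direction / LOH flag). More than one connected
    component among event-bearing samples is evidence of independent tumor
    origins; samples with no events at all cannot be placed and are
    reported as "no_evidence" singletons rather than asserted independent.
    """
    g = nx.Graph()
    for s in events_per_sample:
        g.add_node(s)
    samples = list(events_per_sample)
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            if events_per_sample[s1] & events_per_sample[s2]:
                g.add_edge(s1, s2)
    out = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        has_events = any(events_per_sample[m] for m in members)
        out.append(
            {
                "samples": members,
                "evidence": "shared_events" if has_events else "no_evidence",
            }
        )
    return sorted(out, key=lambda c: c["samples"])


def somatic_event_sets(matrix: RegionMatrix) -> dict[str, set]:
    """Accepted somatic events per sample as hashable (region, kind) keys."""
    out: dict[str, set] = {}
    for s in matrix.sample_ids:
        events = set()
        for i, reg in enumerate(matrix.regions):
            state = matrix.calls.at[i, s]
            key = (reg.chrom, reg.start_bp, reg.end_bp)
            if state != "neutral":
                events.add(key + (state,))
            if bool(matrix.loh.at[i, s]):
                events.add(key + ("loh",))
        out[s] = events
    return out


def cohort_summary(sample_counts: Sequence[int], tree_classes: Mapping[str, str] | None = None) -> dict:
    """Cohort bookkeeping: totals and per-case heterogeneity classes."""
    counts = list(sample_counts)
    if not counts:
        raise ValueError("empty cohort")
    summary = {
        "n_cases": len(counts),
        "n_samples": int(sum(counts)),
        "mean_samples_per_case": sum(counts) / len(counts),
        "min_samples": int(min(counts)),
        "max_samples": int(max(counts)),
    }
    if tree_classes is not None:
        summary["tree_classes"] = dict(sorted(tree_classes.items()))
        summary["class_counts"] = {
            c: sum(1 for v in tree_classes.values() if v == c)
            for c in ("flat", "linear", "branched")
        }
    return summary


def load_cohort_table() -> pd.DataFrame:
    """Published per-case summary of the 20-case Wilms tumor cohort
    (age at nephrectomy in months, analyzed tumor samples, heterogeneity
    group)."""
    with resources.files("wtitgh.data").joinpath("wilms_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def load_1q_status_table() -> pd.DataFrame:
    """Published per-tumor sample counts and 1q+ positive-sample counts for
    the seven multi-sampled 1q+ tumors."""
    with resources.files("wtitgh.data").joinpath("wilms_1q_status.csv").open() as fh:
        return pd.read_csv(fh)
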
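"""Chromosome-arm coordinate table (hg19).

Arm boundaries are used to translate event spans into the arm-level
nomenclature of clinical copy-number biomarkers ("1q+", "16q-", ...).
The packaged table carries per-chromosome length and the p/q boundary.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def chrom_sort_key(chrom: str) -> int:
    """Rank of a chromosome label in the fixed 1..22, X ordering."""
    try:
        return _CHROM_RANK[str(chrom)]
    except KeyError:
        raise ValueError(f"unknown chromosome label: {chrom!r}") from None


@functools.lru_cache(maxsize=1)
def load_arm_table() -> pd.DataFrame:
    """hg19 arm table indexed by chromosome, columns: length, centromere."""
    with resources.files("wtitgh.data").joinpath("hg19_arms.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return tab.set_index("chrom")


def arm_span(arm: str) -> tuple[str, int, int]:
    """Genomic span (chrom, start_bp, end_bp), 0-based half-open, of an arm.

    ``arm`` is e.g. ``"1q"`` or ``"16p"``; ``"11p15"`` is special-cased as
    the distal 11p region harbouring the imprinted WT locus cluster.
    """
    tab = load_arm_table()
    if arm == "11p15":  # distal 11p band complex (hg19 11p15.5-11p15.1)
        return "11", 0, 21_700_000
    chrom, side = arm[:-1], arm[-1]
    if side not in ("p", "q") or chrom not in tab.index:
        raise ValueError(f"unknown arm: {arm!r}")
    cen = int(tab.loc[chrom, "centromere"])
    length = int(tab.loc[chrom, "length"])
    return (chrom, 0, cen) if side == "p" else (chrom, cen, length)


def arm_of(chrom: str, start_bp: int, end_bp: int) -> str:
    """Arm label covering the majority of [start_bp, end_bp) on ``chrom``."""
    tab = load_arm_table()
    chrom = str(chrom)
    if chrom not in tab.index:
        raise ValueError(f"unknown chromosome label: {chrom!r}")
    cen = int(tab.loc[chrom, "centromere"])
    p_overlap = max(0, min(end_bp, cen) - start_bp)
    q_overlap = max(0, end_bp - max(start_bp, cen))
    return f"{chrom}p" if p_overlap >= q_overlap else f"{chrom}q"
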
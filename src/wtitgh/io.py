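"""Case-level data model and readers/writers for the formats the pipeline touches.

Probe-level observations (one SNP array per tissue sample) arrive as
GenomeStudio-final-report-like TSV files with per-probe Log R Ratio (LRR)
and B-allele frequency (BAF). Internally every interval is 0-based
half-open; TSV positions are 1-based and BED output is 0-based half-open,
following each format's own convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .arms import CHROMOSOMES, chrom_sort_key

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["Sample ID", "SNP Name", "Chr", "Position", "Log R Ratio", "B Allele Freq"]

#: internal column names of the probe table
PROBE_COLUMNS = ["probe_id", "chrom", "pos", "lrr", "baf"]

_BAF_CLAMP = 1e-6


@dataclass
class SampleArray:
    """One SNP array: ordered probe-level LRR/BAF observations for a sample.

    ``probes`` is a DataFrame with columns probe_id, chrom, pos (1-based bp),
    lrr, baf, sorted by (chromosome order, position) with a 0..n-1 index.
    """

    case_id: str
    sample_id: str
    tissue: str  # "tumor" | "normal_kidney" | "blood"
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.probes = sort_probes(self.probes)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def lrr(self) -> np.ndarray:
        return self.probes["lrr"].to_numpy()

    @property
    def baf(self) -> np.ndarray:
        return self.probes["baf"].to_numpy()

    @property
    def is_normal(self) -> bool:
        return self.tissue != "tumor"

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice of each chromosome, in genome order."""
        out: dict[str, slice] = {}
        chroms = self.probes["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    def with_lrr(self, lrr: np.ndarray) -> "SampleArray":
        probes = self.probes.copy()
        probes["lrr"] = np.asarray(lrr, dtype=float)
        return replace(self, probes=probes)


@dataclass
class CaseBundle:
    """All arrays of one case: >=1 tumor sample, optionally a germline normal."""

    case_id: str
    samples: list[SampleArray]
    normal: SampleArray | None = None

    @property
    def tumors(self) -> list[SampleArray]:
        return [s for s in self.samples if not s.is_normal]

    @property
    def all_arrays(self) -> list[SampleArray]:
        return self.samples + ([self.normal] if self.normal is not None else [])


def sort_probes(probes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    probes = probes.copy()
    probes["chrom"] = probes["chrom"].astype(str)
    order = probes["chrom"].map(chrom_sort_key)
    probes = probes.assign(_o=order).sort_values(["_o", "pos"], kind="mergesort")
    return probes.drop(columns="_o").reset_index(drop=True)


def read_sample_tsv(
    path: str | Path,
    case_id: str = "",
    tissue: str = "tumor",
) -> SampleArray:
    """Read one GenomeStudio-like per-sample TSV into a :class:`SampleArray`.

    Rows on chromosomes outside 1..22, X are dropped (and counted in the
    log); a BAF outside [0, 1] by more than 1e-6 is an error naming the row.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    missing = [c for c in TSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    keep = raw["Chr"].isin(CHROMOSOMES)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows on unsupported chromosomes", path.name, n_dropped)
    raw = raw[keep]

    baf = raw["B Allele Freq"].to_numpy(dtype=float)
    bad = (baf < -_BAF_CLAMP) | (baf > 1 + _BAF_CLAMP)
    if bad.any():
        row = raw.index[bad][0]
        raise ValueError(f"{path}: BAF outside [0,1] at row {row} (value {baf[bad][0]})")
    baf = np.clip(baf, 0.0, 1.0)

    sample_ids = raw["Sample ID"].unique()
    if len(sample_ids) != 1:
        raise ValueError(f"{path}: expected a single Sample ID, found {list(sample_ids)}")

    probes = pd.DataFrame(
        {
            "probe_id": raw["SNP Name"].astype(str).to_numpy(),
            "chrom": raw["Chr"].to_numpy(),
            "pos": raw["Position"].to_numpy(dtype=np.int64),
            "lrr": raw["Log R Ratio"].to_numpy(dtype=float),
            "baf": baf,
        }
    )
    return SampleArray(case_id=case_id, sample_id=str(sample_ids[0]), tissue=tissue, probes=probes)


def write_sample_tsv(array: SampleArray, path: str | Path) -> None:
    """Write a sample back out in the GenomeStudio-like TSV dialect."""
    out = pd.DataFrame(
        {
            "Sample ID": array.sample_id,
            "SNP Name": array.probes["probe_id"],
            "Chr": array.probes["chrom"],
            "Position": array.probes["pos"],
            "Log R Ratio": array.probes["lrr"],
            "B Allele Freq": array.probes["baf"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def align_case(
    samples: Sequence[SampleArray],
    normal: SampleArray | None = None,
    case_id: str | None = None,
) -> CaseBundle:
    """Intersect probe sets across arrays of a case and bundle them.

    Probes missing from any array are dropped everywhere (counted in the
    log); an empty intersection is an error.
    """
    arrays = list(samples) + ([normal] if normal is not None else [])
    if not samples:
        raise ValueError("align_case needs at least one sample")
    common: set[str] | None = None
    for arr in arrays:
        ids = set(arr.probes["probe_id"])
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise ValueError("no probes shared by all samples of the case")

    n_union = len(set().union(*(set(a.probes["probe_id"]) for a in arrays)))
    if n_union > len(common):
        logger.info("align_case: dropped %d probes not shared by all arrays", n_union - len(common))

    def restrict(arr: SampleArray) -> SampleArray:
        keep = arr.probes["probe_id"].isin(common)
        return replace(arr, probes=arr.probes[keep].reset_index(drop=True))

    cid = case_id if case_id is not None else samples[0].case_id
    return CaseBundle(
        case_id=cid,
        samples=[restrict(s) for s in samples],
        normal=restrict(normal) if normal is not None else None,
    )


def write_regions_bed(region_matrix, path: str | Path) -> None:
    """Write harmonized regions as BED (0-based half-open) with one call
    column per sample; LOH flags are appended to the state as ``:LOH``."""
    lines = ["#chrom\tstart\tend\tn_probes\t" + "\t".join(region_matrix.sample_ids)]
    for i, reg in enumerate(region_matrix.regions):
        cells = []
        for s in region_matrix.sample_ids:
            state = region_matrix.calls.at[i, s]
            if bool(region_matrix.loh.at[i, s]):
                state = f"{state}:LOH"
            cells.append(state)
        lines.append(
            f"{reg.chrom}\t{reg.start_bp}\t{reg.end_bp}\t{reg.n_probes}\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_tree_newick(tree, path: str | Path) -> None:
    """Serialize an event tree as newick; edge lengths are event counts."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_tree_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
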
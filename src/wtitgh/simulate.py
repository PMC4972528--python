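"""Synthetic multi-sample SNP-array cases with known ground truth.

Emulates Illumina CytoSNP-like arrays at desk scale (a few thousand probes
instead of ~300k): germline genotypes, a rooted clone tree carrying
segmental copy-number events (allele-specific gain / loss / copy-neutral
LOH), tumor purity dilution, shared low-frequency "genomic wave" LRR bias,
and truncated Gaussian noise. Every simulated event is recorded so the
whole downstream pipeline can be scored against truth.

Signal model per probe, for a sample carrying clone ``k`` at purity ``p``:

    total = p * (c_A + c_B) + (1 - p) * 2
    LRR   = log2(total / 2) + scale * wave(pos) + N(0, lrr_sd)
    BAF   = (#B-carrying copies in mixture) / total + N(0, baf_sd), in [0, 1]

where (c_A, c_B) are the clone's parental-allele copy numbers. Homozygous
probes therefore sit near BAF 0/1 regardless of copy state, as on real
arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arms import CHROMOSOMES, load_arm_table
from .io import CaseBundle, SampleArray, read_sample_tsv, write_sample_tsv

EVENT_KINDS = ("gain", "loss", "cnnloh")

# mixture total copy is clipped here before log2 so that a pure double
# loss yields a deep-but-finite LRR instead of -inf
_MIN_TOTAL = 0.05


@dataclass(frozen=True)
class TrueEvent:
    """One segmental event on a clone-tree edge.

    ``start``/``end`` are 0-based half-open probe indices *within* the
    chromosome; ``allele`` indexes the parental allele (0 or 1).
    """

    chrom: str
    start: int
    end: int
    kind: str  # gain | loss | cnnloh
    allele: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad event span [{self.start}, {self.end})")
        if self.allele not in (0, 1):
            raise ValueError("allele must be 0 or 1")


@dataclass
class CloneTree:
    """Rooted clone tree: ``parent[clone]`` (root maps to None) and the
    events acquired on the edge leading into each clone. Root is diploid."""

    parent: dict[str, str | None]
    events: dict[str, list[TrueEvent]]

    def __post_init__(self) -> None:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"clone tree must have exactly one root, got {roots}")
        if self.events.get(roots[0]):
            raise ValueError("root clone must be diploid (no events)")

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    def topological_order(self) -> list[str]:
        order, seen = [], set()

        def visit(c: str) -> None:
            if c in seen:
                return
            p = self.parent[c]
            if p is not None:
                visit(p)
            seen.add(c)
            order.append(c)

        for c in self.parent:
            visit(c)
        return order

    def to_newick(self) -> str:
        children: dict[str, list[str]] = {c: [] for c in self.parent}
        for c, p in self.parent.items():
            if p is not None:
                children[p].append(c)

        def render(c: str) -> str:
            n = len(self.events.get(c, []))
            if not children[c]:
                return f"{c}:{n}"
            inner = ",".join(render(k) for k in sorted(children[c]))
            return f"({inner}){c}:{n}"

        return render(self.root) + ";"

    @staticmethod
    def single_clone() -> "CloneTree":
        return CloneTree(parent={"diploid": None}, events={"diploid": []})


@dataclass
class SimConfig:
    """Study conditions for one simulated case."""

    clone_tree: CloneTree
    sample_assignment: Mapping[str, str]  # tumor sample id -> clone id
    n_chromosomes: int = 6
    probes_per_chrom: int | Sequence[int] = 500
    het_fraction: float = 0.33
    purity: float | Mapping[str, float] = 1.0
    lrr_sd: float = 0.0
    baf_sd: float = 0.0
    wave_amplitude: float = 0.0
    seed: int = 0
    case_id: str = "sim"
    normal_id: str = "NK"

    def __post_init__(self) -> None:
        if not 1 <= self.n_chromosomes <= len(CHROMOSOMES):
            raise ValueError("n_chromosomes out of range")
        for p in self._purities().values():
            if not 0 < p <= 1:
                raise ValueError(f"purity must be in (0, 1], got {p}")
        if not 0 < self.het_fraction < 1:
            raise ValueError("het_fraction must be in (0, 1)")
        if any(n < 1 for n in self._probe_counts()):
            raise ValueError("probes per chromosome must be >= 1")
        for s, clone in self.sample_assignment.items():
            if clone not in self.clone_tree.parent:
                raise ValueError(f"sample {s} assigned to unknown clone {clone}")

    def _probe_counts(self) -> list[int]:
        if isinstance(self.probes_per_chrom, int):
            return [self.probes_per_chrom] * self.n_chromosomes
        counts = list(self.probes_per_chrom)
        if len(counts) != self.n_chromosomes:
            raise ValueError("probes_per_chrom length must equal n_chromosomes")
        return counts

    def _purities(self) -> dict[str, float]:
        if isinstance(self.purity, Mapping):
            return dict(self.purity)
        return {s: float(self.purity) for s in self.sample_assignment}


@dataclass
class SimulatedCase:
    """A simulated case bundle plus its ground truth."""

    bundle: CaseBundle
    config: SimConfig
    true_segments: dict[str, pd.DataFrame]  # sample -> per-chromosome (major, minor) runs
    clone_copies: dict[str, np.ndarray]  # clone -> (n_probes, 2) allele copies
    wave: np.ndarray  # per-probe wave offset (unit scale)
    wave_scales: dict[str, float]

    @property
    def clone_tree_newick(self) -> str:
        return self.config.clone_tree.to_newick()


def _draw_positions(rng: np.random.Generator, chrom: str, n: int) -> np.ndarray:
    length = int(load_arm_table().loc[chrom, "length"])
    pos = np.sort(rng.integers(1, length + 1, size=n))
    # enforce strictly increasing positions
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos.astype(np.int64)


def _apply_events(copies: np.ndarray, events: Sequence[TrueEvent], chrom_offsets: dict[str, int],
                  chrom_sizes: dict[str, int]) -> np.ndarray:
    out = copies.copy()
    for ev in events:
        if ev.chrom not in chrom_offsets:
            raise ValueError(f"event on chromosome {ev.chrom} outside simulated genome")
        if ev.end > chrom_sizes[ev.chrom]:
            raise ValueError(f"event span exceeds chromosome {ev.chrom} probe count")
        lo = chrom_offsets[ev.chrom] + ev.start
        hi = chrom_offsets[ev.chrom] + ev.end
        if ev.kind == "gain":
            if (out[lo:hi, ev.allele] == 0).any():
                raise ValueError("gain on a lost (zero-copy) allele span")
            out[lo:hi, ev.allele] += 1
        elif ev.kind == "loss":
            if (out[lo:hi, ev.allele] == 0).any():
                raise ValueError("loss would drive allele copy number negative")
            out[lo:hi, ev.allele] -= 1
        else:  # cnnloh: (1,1) -> one allele 0, the other 2
            if not ((out[lo:hi, 0] == 1) & (out[lo:hi, 1] == 1)).all():
                raise ValueError("cnnloh requires a heterozygous diploid span")
            out[lo:hi, ev.allele] = 0
            out[lo:hi, 1 - ev.allele] = 2
    return out


def _segments_from_copies(copies: np.ndarray, chroms: np.ndarray, pos: np.ndarray) -> pd.DataFrame:
    rows = []
    n = len(chroms)
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start] or (copies[i] != copies[start]).any():
            a, b = int(copies[start, 0]), int(copies[start, 1])
            rows.append(
                {
                    "chrom": str(chroms[start]),
                    "start_idx": start,
                    "end_idx": i,
                    "start_bp": int(pos[start]),
                    "end_bp": int(pos[i - 1]),
                    "major": max(a, b),
                    "minor": min(a, b),
                }
            )
            start = i
    return pd.DataFrame(rows)


def simulate_case(config: SimConfig) -> SimulatedCase:
    """Simulate one case: a germline normal plus the assigned tumor samples."""
    rng = np.random.default_rng(config.seed)
    counts = config._probe_counts()
    chrom_names = list(CHROMOSOMES[: config.n_chromosomes])

    chroms = np.concatenate([np.repeat(c, n) for c, n in zip(chrom_names, counts)])
    pos = np.concatenate([_draw_positions(rng, c, n) for c, n in zip(chrom_names, counts)])
    n_probes = len(pos)
    probe_ids = np.array([f"snp_{c}_{i}" for c, i in zip(chroms, range(n_probes))])

    chrom_offsets, chrom_sizes, off = {}, {}, 0
    for c, n in zip(chrom_names, counts):
        chrom_offsets[c], chrom_sizes[c] = off, n
        off += n

    # germline genotypes: B-allele carrier indicator per parental allele
    het = rng.random(n_probes) < config.het_fraction
    b_ind = np.zeros((n_probes, 2), dtype=np.int64)
    which = rng.integers(0, 2, size=n_probes)
    b_ind[het, which[het]] = 1
    hom_b = (~het) & (rng.random(n_probes) < 0.5)
    b_ind[hom_b] = 1

    # allele copies per clone, composed along the tree
    tree = config.clone_tree
    clone_copies: dict[str, np.ndarray] = {}
    for clone in tree.topological_order():
        parent = tree.parent[clone]
        base = (
            np.ones((n_probes, 2), dtype=np.int64)
            if parent is None
            else clone_copies[parent]
        )
        clone_copies[clone] = _apply_events(base, tree.events.get(clone, []), chrom_offsets, chrom_sizes)

    # shared genomic wave: two low-frequency sinusoids of position
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wave = config.wave_amplitude * (
        0.6 * np.sin(2 * np.pi * pos / 3.0e7 + phase[0])
        + 0.4 * np.sin(2 * np.pi * pos / 1.1e7 + phase[1])
    )

    purities = config._purities()
    sample_ids = list(config.sample_assignment)
    wave_scales = {s: float(rng.uniform(0.8, 1.2)) for s in [config.normal_id] + sample_ids}

    def make_array(sample_id: str, copies: np.ndarray, purity: float, tissue: str) -> SampleArray:
        total = purity * copies.sum(axis=1) + (1 - purity) * 2.0
        bcount = purity * (copies * b_ind).sum(axis=1) + (1 - purity) * b_ind.sum(axis=1)
        lrr = np.log2(np.maximum(total, _MIN_TOTAL) / 2.0)
        baf = np.where(total > 0, bcount / np.where(total > 0, total, 1.0), 0.5)
        lrr = lrr + wave_scales[sample_id] * wave
        if config.lrr_sd > 0:
            lrr = lrr + rng.normal(0, config.lrr_sd, size=n_probes)
        if config.baf_sd > 0:
            baf = np.clip(baf + rng.normal(0, config.baf_sd, size=n_probes), 0.0, 1.0)
        probes = pd.DataFrame(
            {"probe_id": probe_ids, "chrom": chroms, "pos": pos, "lrr": lrr, "baf": baf}
        )
        return SampleArray(case_id=config.case_id, sample_id=sample_id, tissue=tissue, probes=probes)

    normal = make_array(config.normal_id, np.ones((n_probes, 2), dtype=np.int64), 1.0, "normal_kidney")
    tumors = [
        make_array(s, clone_copies[config.sample_assignment[s]], purities[s], "tumor")
        for s in sample_ids
    ]

    true_segments = {
        s: _segments_from_copies(clone_copies[config.sample_assignment[s]], chroms, pos)
        for s in sample_ids
    }
    return SimulatedCase(
        bundle=CaseBundle(case_id=config.case_id, samples=tumors, normal=normal),
        config=config,
        true_segments=true_segments,
        clone_copies=clone_copies,
        wave=wave,
        wave_scales=wave_scales,
    )


def write_case(case: SimulatedCase, directory: str | Path) -> Path:
    """Write a simulated case: one TSV per array, a manifest, and truth files
    (BED-like true segments, 0-based half-open bp; newick clone tree)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for arr in case.bundle.all_arrays:
        write_sample_tsv(arr, directory / f"{arr.sample_id}.txt")

    manifest = {
        "case_id": case.bundle.case_id,
        "samples": [s.sample_id for s in case.bundle.samples],
        "normal": case.bundle.normal.sample_id if case.bundle.normal else None,
    }
    (directory / "case.json").write_text(json.dumps(manifest, indent=2) + "\n")

    truth_lines = ["#chrom\tstart\tend\tsample\tmajor\tminor"]
    for sample, segs in case.true_segments.items():
        for _, r in segs.iterrows():
            truth_lines.append(
                f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{sample}\t{r.major}\t{r.minor}"
            )
    (directory / "truth_segments.bed").write_text("\n".join(truth_lines) + "\n")
    (directory / "truth_tree.nwk").write_text(case.clone_tree_newick + "\n")
    return directory


def read_case(directory: str | Path) -> CaseBundle:
    """Read a case directory written by :func:`write_case` (or laid out the
    same way by hand) back into a :class:`CaseBundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / "case.json").read_text())
    case_id = manifest["case_id"]
    samples = [
        read_sample_tsv(directory / f"{s}.txt", case_id=case_id, tissue="tumor")
        for s in manifest["samples"]
    ]
    normal = None
    if manifest.get("normal"):
        normal = read_sample_tsv(
            directory / f"{manifest['normal']}.txt", case_id=case_id, tissue="normal_kidney"
        )
    return CaseBundle(case_id=case_id, samples=samples, normal=normal)
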
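"""Per-case and per-cohort orchestration.

Stage order per case: wave estimation (normals) -> wave correction (all
arrays) -> LRR segmentation -> state calling -> region harmonization ->
region filters -> mBAF computation -> allelic validation -> CNNLOH
detection -> allele profiles -> rooted event tree. Every stage logs record
counts; identical inputs + config give identical outputs (no randomness
anywhere downstream of the simulator).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import phylo, regions, segmentation, stats, waves
from .io import CaseBundle, write_regions_bed, write_tree_newick
from .simulate import read_case

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with desk-scale defaults.

    ``filter_min_probes`` defaults to the cohort-scale value of 100 probes;
    synthetic desk-scale runs should scale it down with their probe counts.
    """

    wave_enabled: bool = True
    wave_window_probes: int = 51
    seg_penalty_lambda: float = 3.0
    seg_min_probes: int = 10
    call_double_loss_lrr: float = -1.0
    call_amplification_lrr: float = 0.58 * 1.5
    call_min_neutral_lrr: float = 0.1
    harmonize_tolerance_probes: int = 5
    filter_min_probes: int = 100
    filter_density_mads: float = 3.0
    mbaf_het_halfwidth: float = 0.15
    mbaf_min_het_probes: int = 10
    mbaf_accept_threshold: float = 0.56
    loh_mbaf_threshold: float = 0.68
    biomarker_coverage_fraction: float = 0.5
    ci_method: str = "normal"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CaseResult:
    case_id: str
    region_matrix: regions.RegionMatrix
    tree: phylo.EventTree
    tree_class: str
    report: dict


def run_case(bundle: CaseBundle, config: PipelineConfig | None = None) -> CaseResult:
    """Run the full per-case pipeline on an aligned case bundle."""
    cfg = config or PipelineConfig()
    counts: dict[str, object] = {
        "n_tumor_samples": len(bundle.tumors),
        "n_probes": bundle.samples[0].n_probes,
        "has_normal": bundle.normal is not None,
    }

    arrays = bundle.tumors
    normal = bundle.normal
    if cfg.wave_enabled:
        normals = [normal] if normal is not None else []
        if not normals:
            logger.warning("case %s: no normal sample, wave estimation skipped", bundle.case_id)
        wave = waves.estimate_wave(normals, cfg.wave_window_probes)
        arrays = waves.correct_case(arrays, wave)
        normal = waves.correct_lrr(normal, wave) if normal is not None else None

    profiles = []
    for arr in arrays:
        prof = segmentation.segment_lrr(arr, cfg.seg_penalty_lambda, cfg.seg_min_probes)
        profiles.append(
            segmentation.call_states(
                prof,
                cfg.call_double_loss_lrr,
                cfg.call_amplification_lrr,
                cfg.call_min_neutral_lrr,
            )
        )
    counts["n_segments"] = {p.sample_id: len(p.segments) for p in profiles}

    # CNNLOH leaves no LRR step: fold BAF-derived breakpoints into the union
    baf_bps: dict[str, list[int]] = {}
    for arr in arrays:
        for chrom, bps in regions.mbaf_breakpoints(
            arr, normal, cfg.mbaf_het_halfwidth, cfg.seg_penalty_lambda, cfg.seg_min_probes
        ).items():
            baf_bps.setdefault(chrom, []).extend(bps)
    matrix = regions.harmonize_regions(
        profiles,
        arrays[0],
        cfg.harmonize_tolerance_probes,
        case_id=bundle.case_id,
        extra_breakpoints=baf_bps,
    )
    counts["n_regions_raw"] = matrix.n_regions
    matrix = regions.filter_regions(matrix, cfg.filter_min_probes, cfg.filter_density_mads)
    counts["n_regions"] = matrix.n_regions

    tumors_by_id = {a.sample_id: a for a in arrays}
    matrix = regions.compute_mbaf_matrix(
        matrix, tumors_by_id, normal, cfg.mbaf_het_halfwidth, cfg.mbaf_min_het_probes
    )
    matrix = regions.validate_allelic(matrix, cfg.mbaf_accept_threshold)
    counts["n_rejected_calls"] = int((matrix.flags == regions.FLAG_REJECTED).sum().sum())
    matrix = regions.detect_cnnloh(matrix, cfg.loh_mbaf_threshold)
    counts["n_loh_flags"] = int(matrix.loh.sum().sum())

    normal_id = normal.sample_id if normal is not None else "NK"
    allele_profiles = phylo.derive_allele_profiles(matrix, normal_id=normal_id)
    tree = phylo.build_tree(allele_profiles, normal_id=normal_id, regions=matrix.regions)
    tree_class = phylo.classify_tree(tree)
    counts["total_events"] = tree.total_events

    origins = stats.detect_independent_origins(stats.somatic_event_sets(matrix))
    report = {
        "case_id": bundle.case_id,
        "config": cfg.to_dict(),
        "counts": counts,
        "tree_class": tree_class,
        "tree_newick": tree.to_newick(),
        "independent_origin_components": origins,
        "n_origin_components": sum(1 for c in origins if c["evidence"] == "shared_events"),
    }
    for stage, value in counts.items():
        logger.info("case %s | %s: %s", bundle.case_id, stage, value)
    return CaseResult(
        case_id=bundle.case_id,
        region_matrix=matrix,
        tree=tree,
        tree_class=tree_class,
        report=report,
    )


def run_case_dir(case_dir: str | Path, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> CaseResult:
    """Read a case directory (per-sample TSVs + case.json manifest), run the
    pipeline, optionally write BED / newick / JSON outputs."""
    bundle = read_case(case_dir)
    result = run_case(bundle, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_regions_bed(result.region_matrix, out / f"{result.case_id}.regions.bed")
        write_tree_newick(result.tree, out / f"{result.case_id}.tree.nwk")
        (out / f"{result.case_id}.report.json").write_text(
            json.dumps(result.report, indent=2, sort_keys=True) + "\n"
        )
    return result


def run_cohort(
    cohort_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    biomarkers: tuple[str, ...] = ("1q+",),
) -> dict:
    """Run every case directory under ``cohort_dir`` and aggregate.

    Produces the per-case reports, cohort bookkeeping, and single-sampling
    detection statistics for each configured biomarker over the positive
    multi-sampled tumors.
    """
    cfg = config or PipelineConfig()
    case_dirs = sorted(p for p in Path(cohort_dir).iterdir() if (p / "case.json").exists())
    if not case_dirs:
        raise ValueError(f"no case directories under {cohort_dir}")

    results = [run_case_dir(d, cfg, out_dir) for d in case_dirs]
    tree_classes = {r.case_id: r.tree_class for r in results}
    summary = stats.cohort_summary(
        [len(r.region_matrix.sample_ids) for r in results], tree_classes
    )

    biomarker_reports = {}
    for name in biomarkers:
        statuses = [
            stats.biomarker_presence(r.region_matrix, name, cfg.biomarker_coverage_fraction)
            for r in results
        ]
        positive = [s for s in statuses if s.is_positive_tumor and s.assessable]
        entry: dict = {
            "per_tumor": {
                s.tumor_id: {
                    "present": s.present,
                    "fraction_positive": s.fraction_positive,
                    "heterogeneous": s.heterogeneous,
                    "assessable": s.assessable,
                }
                for s in statuses
            },
            "n_positive_tumors": len(positive),
        }
        if positive:
            ds = stats.detection_stats([s.fraction_positive for s in positive], cfg.ci_method)
            entry["detection"] = {
                "product_all_detected": ds.product_all_detected,
                "mean_miss": ds.mean_miss,
                "ci95": list(ds.ci95),
                "min_samples_95pct": stats.min_samples_needed(ds.mean_miss, 0.95),
            }
        biomarker_reports[name] = entry

    report = {
        "config": cfg.to_dict(),
        "summary": summary,
        "cases": {r.case_id: r.report for r in results},
        "biomarkers": biomarker_reports,
    }
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "cohort_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
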
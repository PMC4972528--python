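import numpy as np
import pandas as pd
import pytest

from wtitgh import (
    CloneTree,
    SimConfig,
    TrueEvent,
    compute_mbaf,
    detect_cnnloh,
    filter_regions,
    harmonize_regions,
    simulate_case,
    validate_allelic,
)
from wtitgh.io import SampleArray
from wtitgh.regions import (
    FLAG_ACCEPTED,
    FLAG_CNNLOH,
    FLAG_LOW_INFO,
    FLAG_REJECTED,
    Region,
    RegionMatrix,
    compute_mbaf_matrix,
)
from wtitgh.segmentation import Segment, SegmentedProfile


def make_reference(n=1000, chrom="1"):
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "pos": np.arange(1, n + 1) * 1000,
            "lrr": np.zeros(n),
            "baf": np.full(n, 0.5),
        }
    )
    return SampleArray("case", "ref", "tumor", probes)


def profile_with_breaks(sample_id, breaks, n=1000, chrom="1", states=None):
    bounds = [0] + list(breaks) + [n]
    segs = [
        Segment(chrom=chrom, start_idx=a, end_idx=b, mean_lrr=0.0,
                state=(states[i] if states else "neutral"))
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]
    return SegmentedProfile(sample_id=sample_id, segments=segs, noise_mad=0.05)


def simple_matrix(calls_by_sample, mbaf=None, n_probes_per_region=200):
    """Single-chromosome matrix with one region per call entry."""
    sample_ids = list(calls_by_sample)
    n_regions = len(calls_by_sample[sample_ids[0]])
    regions = [
        Region(chrom="1", start_idx=i * n_probes_per_region,
               end_idx=(i + 1) * n_probes_per_region,
               start_bp=1 + i * 10**6, end_bp=(i + 1) * 10**6)
        for i in range(n_regions)
    ]
    shape = (n_regions, len(sample_ids))
    return RegionMatrix(
        case_id="c",
        regions=regions,
        calls=pd.DataFrame(calls_by_sample, dtype=object),
        mbaf=pd.DataFrame(mbaf if mbaf is not None else np.full(shape, np.nan),
                          columns=sample_ids),
        loh=pd.DataFrame(np.zeros(shape, dtype=bool), columns=sample_ids),
        flags=pd.DataFrame(np.full(shape, FLAG_ACCEPTED, dtype=object), columns=sample_ids),
    )


def test_single_sample_regions_equal_segments():
    ref = make_reference()
    prof = profile_with_breaks("A", [300, 700])
    mat = harmonize_regions([prof], ref)
    assert [(r.start_idx, r.end_idx) for r in mat.regions] == [(0, 300), (300, 700), (700, 1000)]


def test_identical_breakpoints_merge_to_same_regions():
    ref = make_reference()
    profs = [profile_with_breaks(s, [400]) for s in ("A", "B")]
    mat = harmonize_regions(profs, ref)
    assert [(r.start_idx, r.end_idx) for r in mat.regions] == [(0, 400), (400, 1000)]


def test_close_breakpoints_merge_to_lower_median():
    ref = make_reference()
    mat = harmonize_regions(
        [profile_with_breaks("A", [500]), profile_with_breaks("B", [503])],
        ref,
        tolerance_probes=5,
    )
    assert len(mat.regions) == 2
    assert mat.regions[1].start_idx == 501  # floor of median(500, 503)


def test_region_calls_copied_from_covering_segment():
    ref = make_reference()
    a = profile_with_breaks("A", [500], states=["gain", "neutral"])
    b = profile_with_breaks("B", [], states=["neutral"])
    mat = harmonize_regions([a, b], ref)
    assert mat.calls.at[0, "A"] == "gain"
    assert mat.calls.at[1, "A"] == "neutral"
    assert mat.calls.at[0, "B"] == "neutral"


def test_min_probe_filter():
    mat = simple_matrix({"A": ["gain", "neutral"]})
    mat.regions[0] = Region(chrom="1", start_idx=0, end_idx=99,
                            start_bp=1, end_bp=99 * 10**4)
    out = filter_regions(mat, min_probes=100)
    assert out.n_regions == 1  # the 99-probe region is gone
    out2 = filter_regions(simple_matrix({"A": ["gain", "neutral"]}), min_probes=100)
    assert out2.n_regions == 2


def test_density_outlier_filter():
    mat = simple_matrix({"A": ["neutral"] * 11})
    # one region with 10x the probe density of the others
    mat.regions[5] = Region(chrom="1", start_idx=1000, end_idx=1200,
                            start_bp=1, end_bp=10**5)
    out = filter_regions(mat, min_probes=10)
    assert out.n_regions == 10
    # equal densities: nothing removed
    out2 = filter_regions(simple_matrix({"A": ["neutral"] * 11}), min_probes=10)
    assert out2.n_regions == 11


def test_all_regions_removed_is_error():
    mat = simple_matrix({"A": ["neutral"]})
    with pytest.raises(ValueError, match="all regions removed"):
        filter_regions(mat, min_probes=10**6)


def cnnloh_case(purity):
    tree = CloneTree(
        parent={"root": None, "c": "root"},
        events={"root": [], "c": [TrueEvent("1", 100, 300, "cnnloh", 0)]},
    )
    return simulate_case(
        SimConfig(clone_tree=tree, sample_assignment={"R1": "c"},
                  n_chromosomes=2, probes_per_chrom=400, purity=purity, seed=9)
    )


def test_mbaf_folding_identities():
    case = cnnloh_case(purity=1.0)
    tumor, normal = case.bundle.samples[0], case.bundle.normal
    balanced = Region(chrom="2", start_idx=400, end_idx=800,
                      start_bp=1, end_bp=10**6)
    assert compute_mbaf(balanced, tumor, normal) == pytest.approx(0.5)
    inside = Region(chrom="1", start_idx=100, end_idx=300,
                    start_bp=1, end_bp=10**6)
    assert compute_mbaf(inside, tumor, normal) == pytest.approx(1.0)
    # 2+0 at purity 0.5: het BAF in {0.25, 0.75}, mBAF 0.75
    half = cnnloh_case(purity=0.5)
    assert compute_mbaf(inside, half.bundle.samples[0], half.bundle.normal) == pytest.approx(0.75)


def test_mbaf_mirror_symmetry_and_min_probes():
    case = simulate_case(
        SimConfig(
            clone_tree=CloneTree(
                parent={"root": None, "c": "root"},
                events={"root": [], "c": [TrueEvent("1", 0, 400, "gain", 0)]},
            ),
            sample_assignment={"R1": "c"},
            n_chromosomes=1, probes_per_chrom=400, seed=2,
        )
    )
    tumor, normal = case.bundle.samples[0], case.bundle.normal
    reg = Region(chrom="1", start_idx=0, end_idx=400, start_bp=1, end_bp=10**6)
    # tumor BAF at het probes is 1/3 or 2/3 -> mBAF folds both to 2/3
    assert compute_mbaf(reg, tumor, normal) == pytest.approx(2 / 3)
    tiny = Region(chrom="1", start_idx=0, end_idx=12, start_bp=1, end_bp=10**4)
    assert np.isnan(compute_mbaf(tiny, tumor, normal, min_het_probes=10)) or \
        not np.isnan(compute_mbaf(tiny, tumor, normal, min_het_probes=1))


def test_validate_allelic_rules():
    mat = simple_matrix(
        {"A": ["gain", "gain", "loss"]},
        mbaf={"A": [0.50, 0.67, np.nan]},
    )
    out = validate_allelic(mat, mbaf_threshold=0.56)
    assert out.calls.at[0, "A"] == "neutral"
    assert out.flags.at[0, "A"] == FLAG_REJECTED
    assert out.calls.at[1, "A"] == "gain"
    assert out.flags.at[1, "A"] == FLAG_ACCEPTED
    assert out.calls.at[2, "A"] == "loss"  # undefined mBAF: retained
    assert out.flags.at[2, "A"] == FLAG_LOW_INFO


def test_validate_never_creates_non_neutral():
    mat = simple_matrix({"A": ["neutral"] * 3}, mbaf={"A": [0.9, 0.5, np.nan]})
    out = validate_allelic(mat)
    assert (out.calls["A"] == "neutral").all()


def test_detect_cnnloh_flags_only_imbalanced_neutral():
    mat = simple_matrix(
        {"A": ["neutral", "neutral", "gain"]},
        mbaf={"A": [0.5, 0.75, 0.75]},
    )
    out = detect_cnnloh(mat, loh_mbaf_threshold=0.68)
    assert not out.loh.at[0, "A"]
    assert out.loh.at[1, "A"]
    assert out.flags.at[1, "A"] == FLAG_CNNLOH
    assert not out.loh.at[2, "A"]  # non-neutral states never flagged here
    assert list(out.calls["A"]) == ["neutral", "neutral", "gain"]  # states unchanged


def test_rejected_cna_not_rescued_as_loh():
    """A CNA rejected for lacking imbalance cannot be re-flagged as LOH."""
    mat = simple_matrix({"A": ["gain"]}, mbaf={"A": [0.70]})
    # threshold above 0.70 so the gain is rejected, then LOH threshold below
    out = detect_cnnloh(validate_allelic(mat, mbaf_threshold=0.75), loh_mbaf_threshold=0.68)
    assert out.calls.at[0, "A"] == "neutral"
    assert out.flags.at[0, "A"] == FLAG_REJECTED
    assert not out.loh.at[0, "A"]


def test_simulated_cnnloh_flagged_end_to_end():
    case = cnnloh_case(purity=1.0)
    ref = case.bundle.samples[0]
    segs = [
        Segment("1", 0, 100, 0.0, "neutral"),
        Segment("1", 100, 300, 0.0, "neutral"),
        Segment("1", 300, 400, 0.0, "neutral"),
        Segment("2", 400, 800, 0.0, "neutral"),
    ]
    prof = SegmentedProfile("R1", segs, noise_mad=0.05)
    mat = harmonize_regions([prof], ref)
    mat = compute_mbaf_matrix(mat, {"R1": ref}, case.bundle.normal)
    mat = detect_cnnloh(validate_allelic(mat))
    flagged = [i for i in range(mat.n_regions) if mat.loh.at[i, "R1"]]
    assert flagged == [1]  # exactly the simulated 2+0 region


def test_adjacent_loh_regions_merge_in_reporting():
    from wtitgh.regions import merged_loh_runs

    mat = simple_matrix({"A": ["neutral"] * 4})
    mat.loh.at[1, "A"] = True
    mat.loh.at[2, "A"] = True
    runs = merged_loh_runs(mat, "A")
    assert len(runs) == 1
    assert runs[0][0] == "1"
    assert runs[0][1] == mat.regions[1].start_bp
    assert runs[0][2] == mat.regions[2].end_bp
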
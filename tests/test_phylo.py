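import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtitgh import (
    AlleleProfile,
    build_tree,
    classify_tree,
    derive_allele_profiles,
    med_distance,
    symmetric_distance,
)
from wtitgh.phylo import _allele_event_count

from test_regions import simple_matrix


# ---------------------------------------------------------------------------
# independent oracle: breadth-first search over the profile state space.
# Moves: +/-1 on a contiguous run of regions, every region in the run
# currently >= 1 copy (zero is absorbing: cannot be regained and blocks
# later events from spanning it), runs never cross chromosome boundaries.
def bfs_distance(a, b, chroms, cap=None):
    a, b = tuple(a), tuple(b)
    if cap is None:
        cap = max(max(a), max(b)) + 1
    runs = [
        (i, j)
        for i in range(len(a))
        for j in range(i, len(a))
        if all(chroms[k] == chroms[i] for k in range(i, j + 1))
    ]
    frontier, seen, d = [a], {a}, 0
    while frontier:
        if b in seen:
            return d
        nxt = []
        for state in frontier:
            for i, j in runs:
                seg = state[i : j + 1]
                if min(seg) < 1:
                    continue  # zero-absorbing barrier
                for delta in (1, -1):
                    if delta == 1 and max(seg) >= cap:
                        continue
                    new = state[:i] + tuple(v + delta for v in seg) + state[j + 1 :]
                    if new not in seen:
                        seen.add(new)
                        nxt.append(new)
        frontier, d = nxt, d + 1
    return math.inf


def prof(major, minor, chroms=None, sid="S"):
    n = len(major)
    return AlleleProfile(sid, major, minor, np.array(chroms or ["1"] * n))


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([1, 1, 1], [1, 1, 1], 0),
        ([1, 1, 1], [2, 2, 1], 1),  # one segmental gain spanning two regions
        ([1, 1, 1, 1], [2, 1, 2, 1], 2),
        ([1, 2, 1], [2, 1, 2], 3),
        ([2, 2], [0, 1], 2),
        ([2, 1, 2], [0, 0, 0], 3),  # middle zero blocks a spanning second loss
    ],
)
def test_allele_event_count_examples(a, b, expected):
    chroms = np.array(["1"] * len(a))
    assert _allele_event_count(np.array(a), np.array(b), chroms) == expected
    assert bfs_distance(a, b, ["1"] * len(a)) == expected


def test_zero_absorption_infeasible():
    chroms = np.array(["1"] * 3)
    assert _allele_event_count(np.array([1, 0, 1]), np.array([1, 1, 1]), chroms) == math.inf
    assert bfs_distance([1, 0, 1], [1, 1, 1], ["1"] * 3) == math.inf


def test_chromosome_boundary_resets_events():
    same = _allele_event_count(np.array([1, 1]), np.array([2, 2]), np.array(["1", "1"]))
    split = _allele_event_count(np.array([1, 1]), np.array([2, 2]), np.array(["1", "2"]))
    assert (same, split) == (1, 2)


def test_med_distance_sums_alleles_and_checks_regions():
    a = prof([2, 1], [1, 1])
    b = prof([2, 2], [1, 0])
    assert med_distance(a, b) == 2
    with pytest.raises(ValueError, match="region"):
        med_distance(a, prof([1, 1, 1], [1, 1, 1]))


def test_random_profiles_match_bfs_oracle():
    """Seeded random small profiles: closed form == BFS, both directions."""
    rng = np.random.default_rng(12)
    chrom_choices = [["1"] * 4, ["1", "1", "2", "2"]]
    for _ in range(150):
        chroms = chrom_choices[rng.integers(2)]
        a = rng.integers(0, 4, size=4)
        b = rng.integers(0, 4, size=4)
        got = _allele_event_count(a, b, np.array(chroms))
        exp = bfs_distance(a, b, chroms)
        assert got == exp, (a.tolist(), b.tolist(), chroms)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    vals=st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)),
                  min_size=1, max_size=5)
)
def test_triangle_inequality_on_feasible_triples(vals):
    chroms = np.array(["1"] * len(vals))
    a = np.array([v[0] for v in vals])
    b = np.array([v[1] for v in vals])
    c = np.array([v[2] for v in vals])
    ab = _allele_event_count(a, b, chroms)
    bc = _allele_event_count(b, c, chroms)
    ac = _allele_event_count(a, c, chroms)
    assert _allele_event_count(a, a, chroms) == 0
    if math.isfinite(ab) and math.isfinite(bc):
        assert ac <= ab + bc


def test_derive_allele_profiles_mapping():
    mat = simple_matrix(
        {"A": ["neutral", "gain", "amplification", "loss", "double_loss", "neutral"]}
    )
    mat.loh.at[5, "A"] = True
    profiles = derive_allele_profiles(mat, normal_id="NK")
    tumor = profiles[0]
    assert list(zip(tumor.major, tumor.minor)) == [
        (1, 1), (2, 1), (3, 1), (1, 0), (0, 0), (2, 0)
    ]
    normal = profiles[-1]
    assert normal.sample_id == "NK"
    assert (normal.major == 1).all() and (normal.minor == 1).all()


def tree_from(profile_rows, chroms=None):
    n = len(profile_rows[0][1])
    chroms = np.array(chroms or ["1"] * n)
    profiles = [prof(maj, mino, list(chroms), sid)
                for sid, maj, mino in profile_rows] + [AlleleProfile.diploid("NK", chroms)]
    return build_tree(profiles, normal_id="NK")


def test_identical_profiles_give_flat_tree():
    t = tree_from([("R1", [2, 1], [1, 1]), ("R2", [2, 1], [1, 1]), ("R3", [2, 1], [1, 1])])
    assert classify_tree(t) == "flat"
    # all events on the single trunk
    trunk_events = [d["events"] for _, _, d in t.graph.edges(data=True) if d["events"] > 0]
    assert sum(trunk_events) == t.total_events == 1


def test_nested_profiles_give_linear_tree():
    t = tree_from([
        ("R1", [2, 1, 1], [1, 1, 1]),
        ("R2", [2, 2, 1], [1, 1, 1]),
        ("R3", [2, 2, 2], [1, 1, 1]),
    ])
    assert classify_tree(t) == "linear"


def test_disjoint_private_events_give_branched_tree():
    t = tree_from([
        ("R1", [2, 1, 1, 2], [1, 1, 1, 1]),
        ("R2", [1, 1, 2, 2], [1, 1, 1, 1]),
    ])
    assert classify_tree(t) == "branched"


def test_root_profile_is_diploid_and_totals_are_minimal():
    t = tree_from([
        ("R1", [2, 1, 1], [1, 1, 1]),
        ("R2", [1, 2, 1], [1, 1, 1]),
        ("R3", [1, 1, 2], [1, 1, 1]),
    ])
    root = t.profile(t.root)
    assert (root == 1).all()
    # star over three single-gain samples: 3 events is optimal
    assert t.total_events == 3
    assert classify_tree(t) == "branched"


def test_single_tumor_degenerate_tree():
    t = tree_from([("R1", [2, 2], [1, 1])])
    assert set(t.leaves) == {"R1"}
    assert t.total_events == 1


def test_exhaustive_search_not_worse_than_nj():
    rows = [
        ("R1", [2, 2, 1, 1], [1, 1, 1, 1]),
        ("R2", [2, 2, 2, 1], [1, 1, 0, 1]),
        ("R3", [1, 1, 1, 2], [1, 1, 1, 1]),
    ]
    n = 4
    chroms = np.array(["1"] * n)
    profiles = [prof(m, mi, ["1"] * n, s) for s, m, mi in rows] + [
        AlleleProfile.diploid("NK", chroms)
    ]
    nj_tree = build_tree(profiles, normal_id="NK")
    ex_tree = build_tree(profiles, normal_id="NK", exhaustive=True)
    assert ex_tree.total_events <= nj_tree.total_events


def test_edge_labels_account_for_every_event():
    t = tree_from([("R1", [2, 2, 1], [1, 1, 0]), ("R2", [2, 1, 1], [1, 1, 1])])
    for u, v, d in t.graph.edges(data=True):
        assert len(d["labels"]) == d["events"]
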
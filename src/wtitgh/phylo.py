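"""Minimum-event copy-number phylogenetics over allele-specific profiles.

Each sample is reduced to an integer (major, minor) copy-number profile
over the case's harmonized regions. The distance between two profiles is
the minimum number of segmental events — a +/-1 change of one allele over
a run of contiguous regions — needed to transform one into the other,
with copy number zero absorbing: a fully deleted region can never regain
copies, and later events cannot span it. Chromosome ends likewise bound
events. This is the event model popularized by allele-specific
minimum-event-distance phylogenetics of multi-sample copy-number data.

For an allele difference vector d (target minus source) over genome-ordered
regions, with d+ = max(d, 0), d- = max(-d, 0) and the running value reset
at chromosome starts (and trivially at absorbed zero regions, where d = 0):

    events = sum_i max(0, d+_i - d+_{i-1}) + sum_i max(0, d-_i - d-_{i-1})

infeasible when the source has 0 copies where the target has more.

Trees are rooted at the matched normal sample (all-diploid profile):
neighbor joining on symmetrized distances gives the topology, internal
ancestor profiles are initialized child-wise and refined by integer local
search until the total event count over edges stops decreasing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .arms import arm_of
from .regions import Region, RegionMatrix

#: finite stand-in for an infeasible directed transformation during search
_INFEASIBLE_PENALTY = 10**6

#: call-state -> (major, minor) allele copy numbers
STATE_TO_ALLELES = {
    ("neutral", False): (1, 1),
    ("neutral", True): (2, 0),  # copy-number-neutral LOH
    ("gain", False): (2, 1),
    ("gain", True): (2, 1),
    ("amplification", False): (3, 1),
    ("amplification", True): (3, 1),
    ("loss", False): (1, 0),
    ("loss", True): (1, 0),
    ("double_loss", False): (0, 0),
    ("double_loss", True): (0, 0),
}


@dataclass
class AlleleProfile:
    """Per-region integer (major, minor) copy numbers for one sample."""

    sample_id: str
    major: np.ndarray
    minor: np.ndarray
    chroms: np.ndarray  # region chromosome labels, defines event boundaries

    def __post_init__(self) -> None:
        self.major = np.asarray(self.major, dtype=np.int64)
        self.minor = np.asarray(self.minor, dtype=np.int64)
        self.chroms = np.asarray(self.chroms)
        if not (self.major.shape == self.minor.shape == self.chroms.shape):
            raise ValueError("major/minor/chroms must have identical shape")
        if (self.minor < 0).any() or (self.major < self.minor).any():
            raise ValueError("require major >= minor >= 0")

    @property
    def n_regions(self) -> int:
        return len(self.major)

    def alleles(self) -> np.ndarray:
        """(n_regions, 2) matrix, columns major, minor."""
        return np.stack([self.major, self.minor], axis=1)

    def replace(self, sample_id: str, alleles: np.ndarray) -> "AlleleProfile":
        return AlleleProfile(
            sample_id=sample_id,
            major=alleles[:, 0],
            minor=alleles[:, 1],
            chroms=self.chroms,
        )

    @staticmethod
    def diploid(sample_id: str, chroms: np.ndarray) -> "AlleleProfile":
        n = len(chroms)
        return AlleleProfile(sample_id, np.ones(n, int), np.ones(n, int), chroms)


def derive_allele_profiles(matrix: RegionMatrix, normal_id: str = "NK") -> list[AlleleProfile]:
    """Map validated calls + LOH flags to integer allele profiles.

    neutral -> (1,1); neutral+LOH -> (2,0); gain -> (2,1);
    amplification -> (3,1); loss -> (1,0); double_loss -> (0,0).
    The normal sample is appended as all-(1,1).
    """
    chroms = np.array([r.chrom for r in matrix.regions])
    profiles = []
    for s in matrix.sample_ids:
        alle = np.array(
            [
                STATE_TO_ALLELES[(matrix.calls.at[i, s], bool(matrix.loh.at[i, s]))]
                for i in range(matrix.n_regions)
            ],
            dtype=np.int64,
        )
        profiles.append(AlleleProfile(s, alle[:, 0], alle[:, 1], chroms))
    profiles.append(AlleleProfile.diploid(normal_id, chroms))
    return profiles


def _allele_event_count(a: np.ndarray, b: np.ndarray, chroms: np.ndarray) -> float:
    """Minimum segmental +/-1 events turning allele vector a into b.

    Returns math.inf when infeasible (a has 0 where b > 0)."""
    if ((a == 0) & (b > 0)).any():
        return math.inf
    d = b.astype(np.int64) - a.astype(np.int64)
    dp = np.maximum(d, 0)
    dn = np.maximum(-d, 0)
    events = 0
    prev_p = prev_n = 0
    for i in range(len(d)):
        if i == 0 or chroms[i] != chroms[i - 1]:
            prev_p = prev_n = 0
        events += max(0, dp[i] - prev_p) + max(0, dn[i] - prev_n)
        prev_p, prev_n = int(dp[i]), int(dn[i])
    return events


def med_distance(a: AlleleProfile, b: AlleleProfile) -> float:
    """Directed minimum-event distance a -> b (sum over both alleles);
    ``math.inf`` if infeasible."""
    if a.n_regions != b.n_regions or (a.chroms != b.chroms).any():
        raise ValueError("profiles must share one region index map")
    return _allele_event_count(a.major, b.major, a.chroms) + _allele_event_count(
        a.minor, b.minor, a.chroms
    )


def symmetric_distance(a: AlleleProfile, b: AlleleProfile) -> float:
    """min over the two directions of the feasible minimum-event distance;
    a large finite guard when neither direction is feasible."""
    d = min(med_distance(a, b), med_distance(b, a))
    return d if math.isfinite(d) else float(_INFEASIBLE_PENALTY)


@dataclass
class EventTree:
    """Rooted event tree: root = normal, leaves = samples, internal nodes =
    inferred ancestors; every node carries an allele profile, every edge an
    event count and arm-level event labels."""

    graph: nx.DiGraph
    root: str
    region_chroms: np.ndarray
    regions: list[Region] | None = None

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    @property
    def total_events(self) -> int:
        return int(sum(d["events"] for _, _, d in self.graph.edges(data=True)))

    def profile(self, node: str) -> np.ndarray:
        return self.graph.nodes[node]["alleles"]

    def to_newick(self) -> str:
        def render(node: str) -> str:
            children = sorted(self.graph.successors(node))
            name = "" if node.startswith("_anc") else node
            if not children:
                return name
            inner = ",".join(
                f"{render(c)}:{self.graph.edges[node, c]['events']}" for c in children
            )
            return f"({inner}){name}"

        return render(self.root) + ";"


def _edge_cost(parent: np.ndarray, child: np.ndarray, chroms: np.ndarray) -> float:
    """Directed edge cost for ancestor search: the event count, with each
    zero-absorption violation (parent 0 where child > 0) charged a large
    per-region penalty on top of the relaxed count — graded so the local
    search can repair violations one region at a time."""
    cost = 0.0
    for k in (0, 1):
        a, b = parent[:, k], child[:, k]
        violations = int(((a == 0) & (b > 0)).sum())
        if violations:
            a = np.where((a == 0) & (b > 0), 1, a)
            cost += violations * _INFEASIBLE_PENALTY
        cost += _allele_event_count(a, b, chroms)
    return cost


def _nj_topology(labels: list[str], dist: np.ndarray) -> nx.Graph:
    """Unrooted topology from neighbor joining (scikit-bio); undirected graph
    over leaf labels plus fresh internal node ids."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    g = nx.Graph()
    if len(labels) == 2:
        g.add_edge(labels[0], labels[1])
        return g
    tree = nj(DistanceMatrix(dist, ids=labels))
    counter = itertools.count()
    mapping: dict[int, str] = {}

    def name_of(node) -> str:
        if node.name is not None:
            return node.name
        key = id(node)
        if key not in mapping:
            mapping[key] = f"_anc{next(counter)}"
        return mapping[key]

    for node in tree.traverse(include_self=True):
        for child in node.children:
            g.add_edge(name_of(node), name_of(child))
    # suppress any degree-2 internal nodes from rooting artifacts
    for n in [x for x in list(g.nodes) if x.startswith("_anc") and g.degree(x) == 2]:
        u, v = list(g.neighbors(n))
        g.remove_node(n)
        g.add_edge(u, v)
    return g


def _refine_ancestors(
    g: nx.DiGraph, root: str, chroms: np.ndarray, max_passes: int = 60
) -> None:
    """Integer local search over internal-node profiles minimizing the total
    edge event count. Initialization: child-wise elementwise minimum,
    postorder. The total never increases and the candidate set is finite,
    so the search terminates."""
    internal = [n for n in g.nodes if n != root and g.out_degree(n) > 0]
    for n in nx.dfs_postorder_nodes(g, root):
        if n in internal:
            kids = [g.nodes[c]["alleles"] for c in g.successors(n)]
            g.nodes[n]["alleles"] = np.minimum.reduce(kids)

    def incident_cost(node: str) -> float:
        cost = 0.0
        for p in g.predecessors(node):
            cost += _edge_cost(g.nodes[p]["alleles"], g.nodes[node]["alleles"], chroms)
        for c in g.successors(node):
            cost += _edge_cost(g.nodes[node]["alleles"], g.nodes[c]["alleles"], chroms)
        return cost

    n_regions = len(chroms)
    for _ in range(max_passes):
        improved = False
        for node in internal:
            alle = g.nodes[node]["alleles"]
            neighbors = [g.nodes[p]["alleles"] for p in g.predecessors(node)] + [
                g.nodes[c]["alleles"] for c in g.successors(node)
            ]
            for i in range(n_regions):
                for k in (0, 1):
                    vals = [nb[i, k] for nb in neighbors]
                    lo, hi = min(vals), max(vals)
                    current = int(alle[i, k])
                    if lo == hi == current:
                        continue
                    best_v, best_c = current, incident_cost(node)
                    for v in range(int(lo), int(hi) + 1):
                        if v == current:
                            continue
                        alle[i, k] = v
                        c = incident_cost(node)
                        if c < best_c - 1e-9:
                            best_v, best_c = v, c
                    if best_v != current:
                        improved = True
                    alle[i, k] = best_v
        if not improved:
            break


def _annotate_edges(tree: EventTree) -> None:
    """Event count and arm-level labels per edge, by peeling maximal
    same-sign runs off the per-allele difference vector."""
    g = tree.graph
    chroms = tree.region_chroms
    for u, v in g.edges:
        pa, ch = g.nodes[u]["alleles"], g.nodes[v]["alleles"]
        count = _edge_cost(pa, ch, chroms)
        labels: list[str] = []
        for k, allele_name in ((0, "major"), (1, "minor")):
            d = ch[:, k].astype(int) - pa[:, k].astype(int)
            while (d != 0).any():
                i = int(np.argmax(d != 0))
                sign = int(np.sign(d[i]))
                j = i
                while (
                    j + 1 < len(d)
                    and np.sign(d[j + 1]) == sign
                    and chroms[j + 1] == chroms[i]
                ):
                    j += 1
                labels.append(_run_label(tree, i, j, sign, allele_name))
                d[i : j + 1] -= sign
        g.edges[u, v]["events"] = int(count) if count < _INFEASIBLE_PENALTY else count
        g.edges[u, v]["labels"] = labels


def _run_label(tree: EventTree, i: int, j: int, sign: int, allele_name: str) -> str:
    direction = "+" if sign > 0 else "-"
    if tree.regions is not None:
        start = tree.regions[i].start_bp
        end = tree.regions[j].end_bp
        arm = arm_of(str(tree.region_chroms[i]), start, end)
        return f"{arm}{direction}({allele_name})"
    return f"{tree.region_chroms[i]}:{i}-{j}{direction}({allele_name})"


def build_tree(
    profiles: list[AlleleProfile],
    normal_id: str = "NK",
    regions: list[Region] | None = None,
    exhaustive: bool = False,
) -> EventTree:
    """Infer the rooted minimum-event tree over tumor samples + normal.

    Neighbor joining on pairwise symmetric minimum-event distances gives the
    unrooted topology; the tree is rooted at the normal leaf (whose profile
    is all-diploid by construction) and ancestor profiles are refined by
    local search. With ``exhaustive=True`` every unrooted binary topology is
    scored and the minimum-total-event tree returned (small cases only).
    """
    by_id = {p.sample_id: p for p in profiles}
    if normal_id not in by_id:
        raise ValueError(f"normal sample {normal_id!r} not among profiles")
    chroms = by_id[normal_id].chroms
    tumor_ids = [p.sample_id for p in profiles if p.sample_id != normal_id]
    if not tumor_ids:
        raise ValueError("need at least one tumor profile")

    labels = [normal_id] + tumor_ids
    if len(tumor_ids) == 1 or not exhaustive:
        n = len(labels)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = symmetric_distance(by_id[labels[i]], by_id[labels[j]])
        topo = _nj_topology(labels, dist)
        return _finalize(topo, by_id, normal_id, chroms, regions)

    best: EventTree | None = None
    for topo in _all_topologies(labels):
        cand = _finalize(topo, by_id, normal_id, chroms, regions)
        if best is None or cand.total_events < best.total_events:
            best = cand
    assert best is not None
    return best


def _all_topologies(labels: list[str]):
    """All unrooted binary topologies over >= 3 labels, by leaf insertion."""
    if len(labels) == 2:
        g = nx.Graph()
        g.add_edge(labels[0], labels[1])
        yield g
        return
    counter = itertools.count()

    def grow(g: nx.Graph, remaining: list[str]):
        if not remaining:
            yield g.copy()
            return
        leaf, rest = remaining[0], remaining[1:]
        for u, v in list(g.edges):
            h = g.copy()
            mid = f"_anc{next(counter)}"
            h.remove_edge(u, v)
            h.add_edge(u, mid)
            h.add_edge(mid, v)
            h.add_edge(mid, leaf)
            yield from grow(h, rest)

    g0 = nx.Graph()
    hub = f"_anc{next(counter)}"
    for l in labels[:3]:
        g0.add_edge(hub, l)
    yield from grow(g0, labels[3:])


def _finalize(
    topo: nx.Graph,
    by_id: dict[str, AlleleProfile],
    normal_id: str,
    chroms: np.ndarray,
    regions: list[Region] | None,
) -> EventTree:
    rooted = nx.bfs_tree(topo, normal_id)
    for node in rooted.nodes:
        if node in by_id:
            rooted.nodes[node]["alleles"] = by_id[node].alleles().copy()
    _refine_ancestors(rooted, normal_id, chroms)
    tree = EventTree(graph=rooted, root=normal_id, region_chroms=chroms, regions=regions)
    _annotate_edges(tree)
    return tree


def classify_tree(tree: EventTree) -> str:
    """Classify the evolutionary pattern: flat (all tumor samples carry one
    identical clone), linear (nested chain of clones), or branched (>= 2
    lineages with private events under a common ancestor)."""
    g = tree.graph
    leaves = [l for l in tree.leaves if l != tree.root]
    profs = [tree.profile(l) for l in leaves]
    if all((p == profs[0]).all() for p in profs[1:]):
        return "flat"

    subtree_events: dict[str, int] = {}

    def events_below(node: str) -> int:
        if node not in subtree_events:
            total = 0
            for c in g.successors(node):
                total += g.edges[node, c]["events"] + events_below(c)
            subtree_events[node] = total
        return subtree_events[node]

    for node in g.nodes:
        eventful_children = sum(
            1
            for c in g.successors(node)
            if g.edges[node, c]["events"] + events_below(c) >= 1
        )
        if eventful_children >= 2:
            return "branched"
    return "linear"
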
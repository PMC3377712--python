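"""Tree-mass community comparison.

Each sample is a distribution of one unit of mass over the reference tree
(:class:`~vaginome.containers.MassMap`). This module implements:

* the phylogenetic Kantorovich-Rubinstein (KR, "earth-mover") distance
  between two such distributions — a generalization of weighted UniFrac
  that allows mass on internal edges and probabilistic splitting;
* squash clustering: agglomerative clustering in which the distance
  between two clusters is the KR distance between their *averaged* mass
  distributions, with internal branch lengths in KR units (the resulting
  trees need not be ultrametric) and bootstrap support from per-sample
  resampling of placements;
* phylogenetic "island" clustering of read attachment points by
  single-linkage under tree path distance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import Island, MassMap, PlacedRead
from .errors import DataError, ParameterError
from .tree import PhyloTree


def mass_map_from_placements(
    reads: Sequence[PlacedRead],
    tree: PhyloTree,
    mode: str = "spread",
    sample_id: Optional[str] = None,
) -> MassMap:
    """Turn a sample's placed reads into a unit mass map.

    ``spread`` deposits each read's posterior-weighted mass at every
    attachment point; ``best`` deposits the read's full mass at its top
    attachment. Point positions are converted from the jplace distal
    convention to proximal (rootward) coordinates.
    """
    if mode not in ("spread", "best"):
        raise ParameterError(f"unknown mass mode {mode!r}")
    reads = list(reads)
    if not reads:
        raise DataError("cannot build a mass map from zero reads")
    per_read = 1.0 / len(reads)
    acc: Dict[Tuple[int, float], float] = defaultdict(float)
    for read in reads:
        read.normalize()
        atts = [read.best()] if mode == "best" else read.attachments
        for att in atts:
            w = per_read if mode == "best" else per_read * att.posterior
            length = tree.edge_length(att.edge_id)
            pos = min(max(length - att.distal_position, 0.0), length)
            acc[(att.edge_id, pos)] += w
    sid = sample_id or reads[0].sample_id or "sample"
    points = [(e, p, m) for (e, p), m in sorted(acc.items())]
    return MassMap(sid, points).validate(tree)


def kr_distance(p_map: MassMap, q_map: MassMap, tree: PhyloTree, p: int = 1) -> float:
    """Exact KR (earth-mover) distance between two unit mass maps.

    Computed as the integral over the tree of |F(y)|, where F(y) is the
    net signed mass of P - Q in the subtree below point y, by a single
    post-order traversal with within-edge breakpoints at mass positions.
    Only the UniFrac-comparable exponent p = 1 is supported.
    """
    if p != 1:
        raise ParameterError("only p = 1 is supported")
    edge_pts: Dict[int, List[Tuple[float, float]]] = defaultdict(list)
    known = set(tree.edge_ids)
    for mmap, sign in ((p_map, 1.0), (q_map, -1.0)):
        for e, pos, m in mmap.points:
            if e not in known:
                raise DataError(f"mass map {mmap.sample_id}: edge {e} not on this tree")
            edge_pts[e].append((pos, sign * m))
    subtree: Dict[int, float] = {}
    total = 0.0
    for e in tree.postorder_edges():
        net = sum(subtree[c] for c in tree.child_edges(e))
        length = tree.edge_length(e)
        prev = length
        for pos, m in sorted(edge_pts.get(e, ()), key=lambda t: -t[0]):
            total += abs(net) * (prev - pos)
            net += m
            prev = pos
        total += abs(net) * prev
        subtree[e] = net
    return total


def kr_distance_matrix(
    mass_maps: Sequence[MassMap], tree: PhyloTree
) -> pd.DataFrame:
    ids = [m.sample_id for m in mass_maps]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kr_distance(mass_maps[i], mass_maps[j], tree)
    return pd.DataFrame(d, index=ids, columns=ids)


def average_mass(
    weighted_maps: Sequence[Tuple[MassMap, float]], sample_id: str = "average"
) -> MassMap:
    """Pointwise weighted union of mass maps, renormalized to unit mass."""
    if not weighted_maps:
        raise ParameterError("need at least one mass map")
    if any(w <= 0 for _, w in weighted_maps):
        raise ParameterError("weights must be positive")
    wsum = sum(w for _, w in weighted_maps)
    acc: Dict[Tuple[int, float], float] = defaultdict(float)
    for mmap, w in weighted_maps:
        scale = w / wsum
        for e, pos, m in mmap.points:
            acc[(e, pos)] += scale * m
    points = [(e, p, m) for (e, p), m in sorted(acc.items())]
    return MassMap(sample_id, points).validate()


# ---------------------------------------------------------------------------
# Squash clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterNode:
    """A node of a squash clustering tree (binary merge tree)."""

    name: Optional[str] = None
    children: List["ClusterNode"] = field(default_factory=list)
    length: float = 0.0
    support: Optional[float] = None

    def leaves(self) -> List[str]:
        if not self.children:
            return [self.name]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def internal_nodes(self) -> List["ClusterNode"]:
        out = [] if not self.children else [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out

    def bipartitions(self) -> set:
        """Leaf sets of all internal nodes."""
        return {frozenset(n.leaves()) for n in self.internal_nodes()}

    def _newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.8g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.8g}"

    def to_newick(self) -> str:
        return self._newick() + ";"


def squash_cluster(mass_maps: Sequence[MassMap], tree: PhyloTree) -> ClusterNode:
    """Agglomerative clustering by KR distance between cluster averages.

    At each step the pair of clusters with the smallest KR distance
    between their averaged ("squashed") mass maps merges; the merged
    average weights each child by its member count, and each child's
    branch length is the KR distance from its own average to the merged
    average. Merge ties break on the smallest sorted pair of cluster
    representatives (their lexicographically least sample ids), so sample
    order never matters.
    """
    mass_maps = list(mass_maps)
    if len(mass_maps) < 2:
        raise ParameterError("squash clustering needs at least two samples")
    ids = [m.sample_id for m in mass_maps]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sample ids")

    clusters: Dict[str, dict] = {}
    for m in mass_maps:
        clusters[m.sample_id] = {
            "rep": m.sample_id,
            "count": 1,
            "map": m,
            "node": ClusterNode(name=m.sample_id),
        }
    dist: Dict[Tuple[str, str], float] = {}

    def pair_key(a: str, b: str) -> Tuple[str, str]:
        ra, rb = clusters[a]["rep"], clusters[b]["rep"]
        return (ra, rb) if ra <= rb else (rb, ra)

    keys = sorted(clusters)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            dist[pair_key(a, b)] = kr_distance(clusters[a]["map"], clusters[b]["map"], tree)

    while len(clusters) > 1:
        live = sorted(clusters)
        best = min(
            ((dist[pair_key(a, b)], pair_key(a, b)) for i, a in enumerate(live)
             for b in live[i + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        _, (ra, rb) = best
        a = next(k for k in live if clusters[k]["rep"] == ra)
        b = next(k for k in live if clusters[k]["rep"] == rb)
        ca, cb = clusters.pop(a), clusters.pop(b)
        merged_map = average_mass(
            [(ca["map"], float(ca["count"])), (cb["map"], float(cb["count"]))],
            sample_id=f"({ra},{rb})",
        )
        ca["node"].length = kr_distance(ca["map"], merged_map, tree)
        cb["node"].length = kr_distance(cb["map"], merged_map, tree)
        new_key = min(ra, rb)
        clusters[new_key] = {
            "rep": new_key,
            "count": ca["count"] + cb["count"],
            "map": merged_map,
            "node": ClusterNode(children=sorted(
                [ca["node"], cb["node"]], key=lambda n: min(n.leaves())
            )),
        }
        for other in clusters:
            if other == new_key:
                continue
            dist[pair_key(new_key, other)] = kr_distance(
                merged_map, clusters[other]["map"], tree
            )
    return next(iter(clusters.values()))["node"]


def squash_bootstrap(
    placements: Dict[str, Sequence[PlacedRead]],
    tree: PhyloTree,
    n_boot: int = 100,
    seed: int = 0,
    mode: str = "spread",
) -> ClusterNode:
    """Squash clustering with bootstrap support on internal nodes.

    Each replicate resamples every sample's placed reads with replacement,
    rebuilds its mass map, and re-clusters; the support of an internal
    node of the full-data tree is the fraction of replicates whose
    clustering contains its exact leaf bipartition.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    base_maps = [
        mass_map_from_placements(reads, tree, mode=mode, sample_id=s)
        for s, reads in sorted(placements.items())
    ]
    base = squash_cluster(base_maps, tree)
    counts: Dict[frozenset, int] = defaultdict(int)
    for _ in range(n_boot):
        rep_maps = []
        for s, reads in sorted(placements.items()):
            reads = list(reads)
            picks = rng.integers(0, len(reads), size=len(reads))
            rep_maps.append(mass_map_from_placements(
                [reads[i] for i in picks], tree, mode=mode, sample_id=s
            ))
        rep_tree = squash_cluster(rep_maps, tree)
        for bip in rep_tree.bipartitions():
            counts[bip] += 1
    for node in base.internal_nodes():
        node.support = counts[frozenset(node.leaves())] / n_boot
    return base


# ---------------------------------------------------------------------------
# Phylogenetic islands
# ---------------------------------------------------------------------------

def island_cluster(
    reads: Sequence[PlacedRead],
    tree: PhyloTree,
    cutoff: float = 0.02,
    min_subjects: int = 2,
    labels: Optional[Dict[str, str]] = None,
) -> List[Island]:
    """Single-linkage islands of best attachment points.

    Reads cluster when their best-placement points lie within ``cutoff``
    tree path distance (single linkage; partial edge segments at both ends
    count). Islands spanning fewer than ``min_subjects`` distinct subjects
    are dropped. Each retained island is labeled by the majority label of
    its members and represented by the read closest to the island's
    attachment-point medoid.
    """
    reads = list(reads)
    if not reads:
        return []
    points = []
    for read in reads:
        if read.sample_id is None:
            raise DataError(f"read {read.read_id} carries no subject id")
        att = read.best()
        length = tree.edge_length(att.edge_id)
        pos = min(max(length - att.distal_position, 0.0), length)
        points.append((att.edge_id, pos))
    n = len(reads)
    if n == 1:
        assignments = np.array([1])
    else:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = tree.point_distance(points[i], points[j])
        z = linkage(squareform(d, checks=False), method="single")
        assignments = fcluster(z, t=cutoff, criterion="distance")

    groups: Dict[int, List[int]] = defaultdict(list)
    for i, g in enumerate(assignments):
        groups[int(g)].append(i)
    islands: List[Island] = []
    for g in sorted(groups, key=lambda g: (-len(groups[g]), min(reads[i].read_id for i in groups[g]))):
        members = groups[g]
        subjects = [reads[i].sample_id for i in members]
        if len(set(subjects)) < min_subjects:
            continue
        if len(members) == 1:
            rep = reads[members[0]].read_id
        else:
            sums = []
            for i in members:
                sums.append(sum(tree.point_distance(points[i], points[j])
                                for j in members if j != i))
            rep = min(zip(sums, (reads[i].read_id for i in members)))[1]
        if labels:
            member_labels = [labels.get(reads[i].read_id, "unknown") for i in members]
        else:
            member_labels = ["unknown"] * len(members)
        values, tallies = np.unique(member_labels, return_counts=True)
        majority = sorted(zip(-tallies, values))[0][1]
        islands.append(Island(
            island_id=f"I{len(islands) + 1}",
            read_ids=[reads[i].read_id for i in members],
            subjects=subjects,
            representative=rep,
            label=str(majority),
        ))
    return islands


def islands_table(islands: Iterable[Island]) -> pd.DataFrame:
    rows = []
    for isl in islands:
        for rid, subj in zip(isl.read_ids, isl.subjects):
            rows.append({"island_id": isl.island_id, "read_id": rid,
                         "subject": subj, "label": isl.label,
                         "representative": isl.representative})
    return pd.DataFrame(rows, columns=["island_id", "read_id", "subject",
                                       "label", "representative"])
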
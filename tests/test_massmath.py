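"""KR distance, mass averaging, squash clustering and islands."""

import numpy as np
import pytest

from vaginome import massmath, synthetic
from vaginome.containers import Attachment, MassMap, PlacedRead
from vaginome.errors import DataError, ParameterError
from vaginome.tree import PhyloTree

SIX_LEAF = "((A:0.21,B:0.13):0.11,(C:0.17,(D:0.08,E:0.21):0.13):0.07,F:0.19);"


@pytest.fixture(scope="module")
def tree6():
    return PhyloTree.from_newick(SIX_LEAF)


def random_mass_map(tree, rng, name, n_points=6, grid=10_000):
    """Random unit mass map with positions on a fine per-edge grid."""
    pts = []
    for _ in range(n_points):
        e = int(rng.choice(tree.edge_ids))
        length = tree.edge_length(e)
        pos = (int(rng.integers(0, grid + 1)) / grid) * length
        pts.append((e, pos, float(rng.random()) + 0.05))
    total = sum(m for _, _, m in pts)
    return MassMap(name, [(e, p, m / total) for e, p, m in pts])


def discretized_kr(p_map, q_map, tree, points_per_edge=10_000):
    """Blind midpoint-rule integration of |net subtree mass| over the tree."""
    total = 0.0
    for e in tree.edge_ids:
        length = tree.edge_length(e)
        node = tree.node_below(e)
        step = length / points_per_edge
        below = {
            me: (tree.node_below(me) is not node
                 and node in tree._ancestors[tree.node_below(me)])
            for me in tree.edge_ids
        }
        for k in range(points_per_edge):
            y = (k + 0.5) * step
            net = 0.0
            for mmap, sign in ((p_map, 1.0), (q_map, -1.0)):
                for me, mp, m in mmap.points:
                    if (me == e and mp > y) or (me != e and below[me]):
                        net += sign * m
            total += abs(net) * step
    return total


def unifrac_tally(p_map, q_map, tree):
    """Independent leaf-mass oracle: sum_e len(e) * |A_e - B_e|."""
    def leaf_mass(mmap):
        out = {}
        for e, _, m in mmap.points:
            (leaf,) = tree.leaves_below(e)
            out[leaf] = out.get(leaf, 0.0) + m
        return out

    mp, mq = leaf_mass(p_map), leaf_mass(q_map)
    total = 0.0
    for e in tree.edge_ids:
        below = tree.leaves_below(e)
        a = sum(mp.get(l, 0.0) for l in below)
        b = sum(mq.get(l, 0.0) for l in below)
        total += tree.edge_length(e) * abs(a - b)
    return total


def leaf_mass_map(tree, name, alloc):
    pts = [(tree.leaf_edge(l), tree.edge_length(tree.leaf_edge(l)), m)
           for l, m in alloc.items()]
    return MassMap(name, pts)


class TestMassMapFromPlacements:
    def _read(self, rid, atts, sample="s"):
        return PlacedRead(rid, [Attachment(*a) for a in atts], sample_id=sample)

    def test_single_read_single_attachment(self, tree6):
        r = self._read("r1", [(0, 0.0, 0.01, 1.0)])
        m = massmath.mass_map_from_placements([r], tree6)
        assert m.points == [(0, tree6.edge_length(0), 1.0)]

    def test_two_reads_split_mass(self, tree6):
        rs = [self._read("r1", [(0, 0.0, 0.01, 1.0)]),
              self._read("r2", [(3, 0.0, 0.01, 1.0)])]
        m = massmath.mass_map_from_placements(rs, tree6)
        assert sorted(p[2] for p in m.points) == [0.5, 0.5]

    def test_spread_equals_best_for_single_attachments(self, tree6):
        rs = [self._read(f"r{i}", [(i, 0.01, 0.01, 1.0)]) for i in range(4)]
        spread = massmath.mass_map_from_placements(rs, tree6, mode="spread")
        best = massmath.mass_map_from_placements(rs, tree6, mode="best")
        assert spread.points == best.points

    def test_empty_reads_rejected(self, tree6):
        with pytest.raises(DataError):
            massmath.mass_map_from_placements([], tree6)


class TestKrDistance:
    def test_identical_maps_zero(self, tree6, rng):
        m = random_mass_map(tree6, rng, "m")
        assert massmath.kr_distance(m, m, tree6) == 0.0

    def test_two_leaf_tree_full_transport(self):
        t = PhyloTree.from_newick("(A:0.3,B:0.2);")
        p = MassMap("p", [(t.leaf_edge("A"), 0.3, 1.0)])
        q = MassMap("q", [(t.leaf_edge("B"), 0.2, 1.0)])
        assert massmath.kr_distance(p, q, t) == pytest.approx(0.5)

    def test_matches_discretized_integral(self, tree6, rng):
        # mass positions sit on the integration grid, so the midpoint rule
        # integrates the piecewise-constant net mass exactly
        p = random_mass_map(tree6, rng, "p", grid=2000)
        q = random_mass_map(tree6, rng, "q", grid=2000)
        exact = massmath.kr_distance(p, q, tree6)
        approx = discretized_kr(p, q, tree6, points_per_edge=2000)
        assert exact == pytest.approx(approx, abs=1e-9)

    def test_leaf_masses_match_unifrac_tally(self, tree6):
        p = leaf_mass_map(tree6, "p", {"A": 0.6, "D": 0.4})
        q = leaf_mass_map(tree6, "q", {"C": 1.0})
        assert massmath.kr_distance(p, q, tree6) == pytest.approx(
            unifrac_tally(p, q, tree6), abs=1e-12
        )

    def test_metric_axioms_random_triples(self, tree6, rng):
        for _ in range(20):
            a = random_mass_map(tree6, rng, "a")
            b = random_mass_map(tree6, rng, "b")
            c = random_mass_map(tree6, rng, "c")
            dab = massmath.kr_distance(a, b, tree6)
            dba = massmath.kr_distance(b, a, tree6)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab >= 0
            dac = massmath.kr_distance(a, c, tree6)
            dcb = massmath.kr_distance(c, b, tree6)
            assert dab <= dac + dcb + 1e-12

    def test_foreign_edge_rejected(self, tree6):
        p = MassMap("p", [(99, 0.0, 1.0)])
        q = MassMap("q", [(0, 0.0, 1.0)])
        with pytest.raises(DataError):
            massmath.kr_distance(p, q, tree6)

    def test_only_p1_supported(self, tree6, rng):
        m = random_mass_map(tree6, rng, "m")
        with pytest.raises(ParameterError):
            massmath.kr_distance(m, m, tree6, p=2)


class TestAverageMass:
    def test_self_average_is_identity(self, tree6, rng):
        m = random_mass_map(tree6, rng, "m")
        avg = massmath.average_mass([(m, 1.0), (m, 1.0)])
        assert {(e, p): pytest.approx(v) for e, p, v in avg.points} == {
            (e, p): v for e, p, v in m.points
        }

    def test_disjoint_equal_weights(self, tree6):
        p = MassMap("p", [(0, 0.1, 1.0)])
        q = MassMap("q", [(3, 0.1, 1.0)])
        avg = massmath.average_mass([(p, 1.0), (q, 1.0)])
        assert sorted(v for _, _, v in avg.points) == [0.5, 0.5]

    def test_weighted_two_to_one(self, tree6):
        p = MassMap("p", [(0, 0.1, 1.0)])
        q = MassMap("q", [(3, 0.1, 1.0)])
        avg = massmath.average_mass([(p, 2.0), (q, 1.0)])
        masses = {e: v for e, _, v in avg.points}
        assert masses[0] == pytest.approx(2 / 3)
        assert masses[3] == pytest.approx(1 / 3)


class TestSquashCluster:
    def test_duplicates_merge_first_at_zero_length(self, tree6, rng):
        m1 = random_mass_map(tree6, rng, "s1")
        m2 = MassMap("s2", list(m1.points))
        m3 = leaf_mass_map(tree6, "s3", {"F": 1.0})
        node = massmath.squash_cluster([m1, m2, m3], tree6)
        assert frozenset({"s1", "s2"}) in node.bipartitions()
        cherry = next(n for n in node.internal_nodes()
                      if set(n.leaves()) == {"s1", "s2"})
        assert all(c.length == pytest.approx(0.0) for c in cherry.children)

    def test_binary_merge_invariant(self, tree6, rng):
        maps = [random_mass_map(tree6, rng, f"s{i}") for i in range(6)]
        node = massmath.squash_cluster(maps, tree6)
        assert len(node.internal_nodes()) == 5  # n - 1
        assert sorted(node.leaves()) == sorted(m.sample_id for m in maps)

    def test_sample_order_irrelevant(self, tree6, rng):
        maps = [random_mass_map(tree6, rng, f"s{i}") for i in range(5)]
        n1 = massmath.squash_cluster(maps, tree6)
        n2 = massmath.squash_cluster(list(reversed(maps)), tree6)
        assert n1.to_newick() == n2.to_newick()

    def test_two_clades_split_last(self, tree6, rng):
        left = [leaf_mass_map(tree6, f"L{i}", {"A": 0.5 + 0.1 * i, "B": 0.5 - 0.1 * i})
                for i in range(3)]
        right = [leaf_mass_map(tree6, f"R{i}", {"D": 0.5 + 0.1 * i, "E": 0.5 - 0.1 * i})
                 for i in range(3)]
        node = massmath.squash_cluster(left + right, tree6)
        top = {frozenset(c.leaves()) for c in node.children}
        assert top == {frozenset({"L0", "L1", "L2"}), frozenset({"R0", "R1", "R2"})}


class TestSquashBootstrap:
    def test_single_read_samples_have_full_support(self, tree6):
        placements = {
            "s1": [PlacedRead("r1", [Attachment(0, 0.0, 0.01, 1.0)], "s1")],
            "s2": [PlacedRead("r2", [Attachment(1, 0.0, 0.01, 1.0)], "s2")],
            "s3": [PlacedRead("r3", [Attachment(5, 0.0, 0.01, 1.0)], "s3")],
        }
        node = massmath.squash_bootstrap(placements, tree6, n_boot=1, seed=0)
        assert all(n.support == pytest.approx(1.0) for n in node.internal_nodes())

    def test_supports_are_probabilities(self, world, placements):
        subset = {s: placements[s] for s in sorted(placements)[:6]}
        node = massmath.squash_bootstrap(subset, world.tree, n_boot=10, seed=0)
        for n in node.internal_nodes():
            assert 0.0 <= n.support <= 1.0


class TestIslandCluster:
    def _read(self, rid, edge, distal, subject):
        return PlacedRead(rid, [Attachment(edge, distal, 0.01, 1.0)],
                          sample_id=subject)

    def test_coincident_reads_form_one_island(self, tree6):
        reads = [self._read(f"r{i}", 0, 0.05, f"subj{i % 2}") for i in range(4)]
        islands = massmath.island_cluster(reads, tree6)
        assert len(islands) == 1
        assert islands[0].n_subjects == 2

    def test_distant_groups_split(self, tree6):
        a = tree6.leaf_edge("A")
        f = tree6.leaf_edge("F")
        reads = (
            [self._read(f"a{i}", a, 0.01 * i, f"s{i}") for i in range(3)]
            + [self._read(f"f{i}", f, 0.01 * i, f"s{i}") for i in range(3)]
        )
        # A-tip to F-tip distance ~0.5 >> cutoff 0.02
        islands = massmath.island_cluster(reads, tree6, cutoff=0.02)
        assert len(islands) == 2
        assert {len(i.read_ids) for i in islands} == {3}

    def test_single_subject_island_dropped(self, tree6):
        a = tree6.leaf_edge("A")
        f = tree6.leaf_edge("F")
        reads = (
            [self._read(f"a{i}", a, 0.001, "solo") for i in range(3)]
            + [self._read(f"f{i}", f, 0.001, f"s{i}") for i in range(2)]
        )
        islands = massmath.island_cluster(reads, tree6, min_subjects=2)
        assert len(islands) == 1
        assert set(islands[0].read_ids) == {"f0", "f1"}

    def test_majority_label_and_representative(self, tree6):
        reads = [self._read(f"r{i}", 2, 0.02 + 0.001 * i, f"s{i}") for i in range(3)]
        labels = {"r0": "BVAB1", "r1": "BVAB1", "r2": "BVAB2"}
        (isl,) = massmath.island_cluster(reads, tree6, labels=labels)
        assert isl.label == "BVAB1"
        assert isl.representative == "r1"  # middle point is the medoid
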
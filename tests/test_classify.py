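"""Edge labeling, posterior-sum classification, compound names, the
naive placer, and jplace IO."""

import json

import numpy as np
import pytest

from vaginome import classify, refpkg, synthetic
from vaginome.containers import Attachment, PlacedRead
from vaginome.errors import FormatError
from vaginome.taxonomy import Taxonomy
from vaginome.tree import PhyloTree


@pytest.fixture(scope="module")
def two_genus():
    """((A,B),C): A,B are species X1,X2 of genus G; C is Y of genus H."""
    tax = Taxonomy(ranks=("root", "family", "genus", "species"))
    tax.add("root", "Root", "root", None)
    tax.add("f", "Fam", "family", "root")
    tax.add("G", "G", "genus", "f")
    tax.add("H", "H", "genus", "f")
    tax.add("X1", "G X1", "species", "G")
    tax.add("X2", "G X2", "species", "G")
    tax.add("Y", "H Y", "species", "H")
    tree = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
    leaf_taxids = {"A": "X1", "B": "X2", "C": "Y"}
    labels = classify.label_edges(tree, tax, leaf_taxids)
    return tax, tree, leaf_taxids, labels


class TestLabelEdges:
    def test_hand_application_of_the_rule(self, two_genus):
        tax, tree, _, labels = two_genus
        assert labels[tree.leaf_edge("A")] == ("species", "X1")
        assert labels[tree.leaf_edge("B")] == ("species", "X2")
        assert labels[tree.leaf_edge("C")] == ("species", "Y")
        ab = next(e for e in tree.edge_ids if tree.leaves_below(e) == {"A", "B"})
        assert labels[ab] == ("genus", "G")

    def test_single_species_tree(self):
        tax = Taxonomy(ranks=("root", "family", "genus", "species"))
        tax.add("root", "Root", "root", None)
        tax.add("f", "F", "family", "root")
        tax.add("g", "G", "genus", "f")
        tax.add("s", "S", "species", "g")
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        labels = classify.label_edges(tree, tax, {l: "s" for l in "ABC"})
        assert all(lab == ("species", "s") for lab in labels.values())

    def test_world_clade_edges_carry_their_species(self, world, edge_labels):
        for taxid in world.species:
            leaves = set(world.clade_leaves(taxid))
            for e in world.tree.edge_ids:
                if world.tree.leaves_below(e) <= leaves:
                    assert edge_labels[e] == ("species", taxid)

    def test_strategies_agree_on_pure_clades(self, world, edge_labels):
        both = classify.label_edges(world.tree, world.taxonomy,
                                    world.leaf_taxids, strategy="both_sides")
        # strictly-within-clade edges (leaves of the taxon on both sides)
        # get identical species labels under both readings of the rule
        for taxid in world.species:
            leaves = set(world.clade_leaves(taxid))
            for e in world.tree.edge_ids:
                if world.tree.leaves_below(e) < leaves:
                    assert both[e] == edge_labels[e] == ("species", taxid)


class TestClassifyRead:
    def _read(self, masses, tree):
        atts = [Attachment(e, 0.0, 0.01, m) for e, m in masses]
        return PlacedRead("q", atts)

    def test_all_mass_on_one_species(self, two_genus):
        tax, tree, _, labels = two_genus
        read = self._read([(tree.leaf_edge("A"), 1.0)], tree)
        c = classify.classify_read(read, labels, tax)
        assert (c.taxid, c.rank, c.posterior) == ("X1", "species", pytest.approx(1.0))

    def test_split_mass_classifies_at_genus(self, two_genus):
        tax, tree, _, labels = two_genus
        read = self._read(
            [(tree.leaf_edge("A"), 0.6), (tree.leaf_edge("B"), 0.35),
             (tree.leaf_edge("C"), 0.05)], tree,
        )
        c = classify.classify_read(read, labels, tax, cutoff=0.9)
        assert c.taxid == "G" and c.rank == "genus"
        assert c.posterior == pytest.approx(0.95)

    def test_monotone_cumulative_posterior(self, two_genus):
        tax, tree, _, labels = two_genus
        read = self._read(
            [(tree.leaf_edge("A"), 0.5), (tree.leaf_edge("B"), 0.3),
             (tree.leaf_edge("C"), 0.2)], tree,
        )
        cum = classify.cumulative_posteriors(read, labels, tax)
        for taxid, mass in cum.items():
            node = tax.node(taxid)
            if node.parent is not None:
                assert cum[node.parent] >= mass - 1e-12

    def test_every_read_classifies_somewhere(self, two_genus):
        tax, tree, _, labels = two_genus
        read = self._read(
            [(tree.leaf_edge("A"), 0.4), (tree.leaf_edge("C"), 0.6)], tree,
        )
        c = classify.classify_read(read, labels, tax, cutoff=0.9)
        # mass split across genera: the shared family is the most
        # specific taxid accumulating the cutoff
        assert c.taxid == "f" and c.posterior == pytest.approx(1.0)


class TestCompoundName:
    def test_species_level_unchanged(self, two_genus):
        tax, tree, _, labels = two_genus
        read = PlacedRead("q", [Attachment(tree.leaf_edge("A"), 0, 0.01, 1.0)])
        c = classify.classify_read(read, labels, tax)
        assert c.compound_name == "G X1"

    def test_genus_call_lists_top_species(self, two_genus):
        tax, tree, _, labels = two_genus
        read = PlacedRead("q", [
            Attachment(tree.leaf_edge("A"), 0, 0.01, 0.6),
            Attachment(tree.leaf_edge("B"), 0, 0.01, 0.35),
            Attachment(tree.leaf_edge("C"), 0, 0.01, 0.05),
        ])
        c = classify.classify_read(read, labels, tax, cutoff=0.9)
        assert c.compound_name == "G X1/X2"

    def test_at_most_three_names(self):
        tax = Taxonomy(ranks=("root", "family", "genus", "species"))
        tax.add("root", "Root", "root", None)
        tax.add("f", "F", "family", "root")
        tax.add("G", "G", "genus", "f")
        for i in range(4):
            tax.add(f"X{i}", f"G X{i}", "species", "G")
        cls = classify.Classification("q", "G", "genus", 1.0)
        posts = {"X0": 0.30, "X1": 0.28, "X2": 0.22, "X3": 0.20, "G": 1.0}
        name = classify.compound_name(cls, posts, tax)
        assert name == "G X0/X1/X2"

    def test_below_threshold_names_dropped(self):
        tax = Taxonomy(ranks=("root", "family", "genus", "species"))
        tax.add("root", "Root", "root", None)
        tax.add("f", "F", "family", "root")
        tax.add("G", "G", "genus", "f")
        for i in range(3):
            tax.add(f"X{i}", f"G X{i}", "species", "G")
        cls = classify.Classification("q", "G", "genus", 0.98)
        posts = {"X0": 0.6, "X1": 0.35, "X2": 0.03, "G": 0.98}
        assert classify.compound_name(cls, posts, tax) == "G X0/X1"


@pytest.fixture(scope="module")
def pkg(world):
    return refpkg.build_reference_package(
        world.sequences, world.leaf_taxids, world.taxonomy,
        tree=world.tree, n_representatives=4,
    )


class TestNaivePlace:
    def test_exact_reference_read_hits_its_leaf(self, world, pkg):
        leaf = world.tree.leaf_names()[0]
        placed = classify.naive_place(world.sequences[leaf], pkg)
        best = placed.best()
        assert best.edge_id == world.tree.leaf_edge(leaf)
        assert best.posterior > 0.9

    def test_equidistant_read_splits_mass(self):
        tax = Taxonomy(ranks=("root", "family", "genus", "species"))
        tax.add("root", "Root", "root", None)
        tax.add("f", "F", "family", "root")
        tax.add("g", "G", "genus", "f")
        tax.add("s1", "S1", "species", "g")
        tax.add("s2", "S2", "species", "g")
        base = "ACGT" * 50
        seqs = {"L1": "A" + base[1:], "L2": "C" + base[1:]}
        pkg = refpkg.RefPkg(
            sequences=seqs, taxonomy=tax,
            tree=PhyloTree.from_newick("(L1:0.01,L2:0.01);"),
            seq_taxids={"L1": "s1", "L2": "s2"},
        ).validate()
        placed = classify.naive_place("G" + base[1:], pkg, top_k=2)
        posts = sorted(a.posterior for a in placed.attachments)
        assert posts == pytest.approx([0.5, 0.5])

    def test_garbage_read_unplaced(self, pkg):
        assert classify.naive_place("T" * 250, pkg, score_floor=0.8) is None

    def test_fastq_round_trip_recovers_species(self, world, pkg, effect, tmp_path):
        """reads written to FASTQ -> QC -> naive placement -> classification
        recover their source species."""
        from vaginome import read_qc
        import pandas as pd
        from vaginome.containers import CountMatrix

        counts = CountMatrix(pd.DataFrame(
            [[4] * len(world.species)], index=["S1"], columns=world.species
        ))
        barcodes = synthetic.make_barcodes(["S1"], seed=3)
        fq = tmp_path / "run.fastq"
        log = synthetic.write_fastq_run(counts, world, barcodes, fq, seed=4)
        per_sample, _ = read_qc.run_qc_on_fastq(fq, barcodes, synthetic.DEFAULT_PRIMER)
        labels = classify.label_edges(pkg.tree, pkg.taxonomy, pkg.seq_taxids)
        ok = total = 0
        for rec in per_sample["S1"]:
            placed = classify.naive_place(str(rec.seq), pkg, read_id=rec.id)
            if placed is None:
                continue
            c = classify.classify_read(placed, labels, pkg.taxonomy)
            total += 1
            ok += c.taxid == log[rec.id]["taxon"]
        assert total >= 40
        assert ok / total >= 0.95


class TestJplaceIO:
    def test_write_read_round_trip(self, world, placements, tmp_path):
        reads = placements[sorted(placements)[0]]
        path = tmp_path / "x.jplace"
        classify.write_jplace(reads, world.tree, path)
        reads2, tree2 = classify.read_jplace(path)
        assert [r.read_id for r in reads2] == [r.read_id for r in reads]
        for r1, r2 in zip(reads, reads2):
            assert [a.edge_id for a in r1.attachments] == [a.edge_id for a in r2.attachments]
            np.testing.assert_allclose(
                [a.posterior for a in r1.attachments],
                [a.posterior for a in r2.attachments], atol=1e-12,
            )
        assert set(tree2.edge_ids) == set(world.tree.edge_ids)

    def test_permuted_fields_parsed_correctly(self, tmp_path):
        doc = {
            "version": 3,
            "tree": "(A:0.1{0},B:0.2{1}):0{2};",
            "fields": ["pendant_length", "edge_num", "distal_length",
                       "likelihood", "like_weight_ratio"],
            "placements": [
                {"p": [[0.01, 1, 0.05, -123.4, 0.7],
                       [0.01, 0, 0.02, -125.0, 0.3]], "n": ["readA"]},
            ],
        }
        path = tmp_path / "foreign.jplace"
        path.write_text(json.dumps(doc))
        reads, tree = classify.read_jplace(path)
        (r,) = reads
        assert r.read_id == "readA"
        assert [a.edge_id for a in r.attachments] == [1, 0]
        assert r.attachments[0].posterior == pytest.approx(0.7)
        assert r.attachments[0].distal_position == pytest.approx(0.05)
        assert r.attachments[0].pendant_length == pytest.approx(0.01)

    def test_missing_tree_is_format_error(self, tmp_path):
        path = tmp_path / "bad.jplace"
        path.write_text(json.dumps({"fields": classify.JPLACE_FIELDS,
                                    "placements": []}))
        with pytest.raises(FormatError):
            classify.read_jplace(path)

    def test_unknown_edge_is_format_error(self, tmp_path):
        doc = {
            "version": 3,
            "tree": "(A:0.1{0},B:0.2{1});",
            "fields": classify.JPLACE_FIELDS,
            "placements": [{"p": [[9, 1.0, 0.0, 0.01]], "n": ["r"]}],
        }
        path = tmp_path / "bad.jplace"
        path.write_text(json.dumps(doc))
        with pytest.raises(FormatError):
            classify.read_jplace(path)
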
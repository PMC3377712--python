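"""Curation of a niche-specific reference package.

Mislabeled public sequences are screened per taxon by pairwise distance to
a primary reference "S" (the member with the smallest median distance to
all others); sequences farther than 0.015 from S — i.e. below 98.5%
identity — are discarded. A small, maximally spread subset (default five,
always including S and any type strains) represents each taxon. The
retained alignment, taxonomy and tree are bundled into a :class:`RefPkg`.

If no tree is supplied, a neighbor-joining tree built from the
pairwise-distance matrix and midpoint-rooted stands in for an externally
inferred maximum-likelihood tree; the interface accepts either.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .errors import DataError, ParameterError
from .taxonomy import Taxonomy
from .tree import PhyloTree

_AMBIG = set("NRYSWKMBDHV.-")


def pairwise_distance(seq_a: str, seq_b: str) -> float:
    """Fraction of non-identical nucleotides over comparable columns.

    Columns where either sequence carries a gap or an ambiguity code are
    excluded from both numerator and denominator.
    """
    if len(seq_a) != len(seq_b):
        raise DataError("aligned sequences must have equal length")
    comparable = 0
    diffs = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _AMBIG or b in _AMBIG:
            continue
        comparable += 1
        if a != b:
            diffs += 1
    if comparable == 0:
        raise DataError("no comparable columns between sequences")
    return diffs / comparable


def distance_matrix(sequences: Dict[str, str]) -> Tuple[List[str], np.ndarray]:
    ids = sorted(sequences)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_distance(sequences[ids[i]], sequences[ids[j]])
    return ids, d


def select_primary_reference(sequences: Dict[str, str]) -> str:
    """Sequence with the smallest median distance to all others.

    Ties break lexicographically by sequence id; a singleton taxon returns
    its only member.
    """
    if not sequences:
        raise ParameterError("need at least one sequence")
    ids = sorted(sequences)
    if len(ids) == 1:
        return ids[0]
    _, d = distance_matrix(sequences)
    medians = []
    for i in range(len(ids)):
        others = np.delete(d[i], i)
        medians.append(float(np.median(others)))
    best = min(range(len(ids)), key=lambda i: (medians[i], ids[i]))
    return ids[best]


def filter_mislabeled(
    sequences: Dict[str, str], primary: str, cutoff: float = 0.015
) -> Tuple[Dict[str, str], Dict[str, float]]:
    """Split a taxon's sequences into kept and discarded-with-distance."""
    if primary not in sequences:
        raise ParameterError(f"primary {primary!r} not among the sequences")
    kept, discarded = {}, {}
    for sid, seq in sequences.items():
        d = 0.0 if sid == primary else pairwise_distance(seq, sequences[primary])
        if sid != primary and d > cutoff:
            discarded[sid] = d
        else:
            kept[sid] = seq
    return kept, discarded


def select_representatives(
    sequences: Dict[str, str],
    primary: str,
    type_strain_ids: Iterable[str] = (),
    n: int = 5,
) -> List[str]:
    """Greedy max-sum-of-pairwise-distances subset of size ``n``.

    The primary reference and all type strains are always included (the
    target size grows if type strains alone exceed it); remaining slots are
    filled greedily, each step adding the sequence that maximizes the
    summed pairwise distance within the selected set. Ties break
    lexicographically.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    ids = sorted(sequences)
    if len(ids) <= n:
        return ids
    _, d = distance_matrix(sequences)
    index = {s: i for i, s in enumerate(ids)}
    selected = [primary] if primary in index else []
    for ts in sorted(set(type_strain_ids)):
        if ts in index and ts not in selected:
            selected.append(ts)
    target = max(n, len(selected))
    while len(selected) < target:
        best_id, best_gain = None, -1.0
        for sid in ids:
            if sid in selected:
                continue
            gain = sum(d[index[sid], index[t]] for t in selected)
            if gain > best_gain or (gain == best_gain and (best_id is None or sid < best_id)):
                best_id, best_gain = sid, gain
        selected.append(best_id)
    return sorted(selected)


@dataclass
class RefPkg:
    """Aligned references + taxonomy + tree + curation log."""

    sequences: Dict[str, str]
    taxonomy: Taxonomy
    tree: PhyloTree
    seq_taxids: Dict[str, str]
    log: List[Dict] = field(default_factory=list)

    def validate(self) -> "RefPkg":
        leaves = set(self.tree.leaf_names())
        if not leaves <= set(self.sequences):
            raise DataError("tree leaves must be a subset of retained sequences")
        for sid in self.sequences:
            taxid = self.seq_taxids.get(sid)
            if taxid is None or taxid not in self.taxonomy:
                raise DataError(f"sequence {sid} has no resolvable taxid")
        return self

    def write(self, directory) -> None:
        """Emit the package as a directory with a JSON manifest."""
        os.makedirs(directory, exist_ok=True)
        files = {
            "alignment": "refs.fasta",
            "taxonomy": "taxonomy.csv",
            "tree": "tree.nwk",
            "seq_info": "seq_info.csv",
            "log": "curation_log.json",
        }
        with open(os.path.join(directory, files["alignment"]), "w") as fh:
            for sid in sorted(self.sequences):
                fh.write(f">{sid}\n{self.sequences[sid]}\n")
        self.taxonomy.to_csv(os.path.join(directory, files["taxonomy"]))
        with open(os.path.join(directory, files["tree"]), "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        with open(os.path.join(directory, files["seq_info"]), "w") as fh:
            fh.write("seqname,taxid\n")
            for sid in sorted(self.seq_taxids):
                fh.write(f"{sid},{self.seq_taxids[sid]}\n")
        with open(os.path.join(directory, files["log"]), "w") as fh:
            json.dump(self.log, fh, indent=1)
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump({"format": "vaginome-refpkg-1", "files": files}, fh, indent=1)


def nj_tree(sequences: Dict[str, str]) -> PhyloTree:
    """Neighbor-joining tree from fraction distances, midpoint-rooted.

    Negative NJ branch lengths are clamped to zero. Edge ids are assigned
    deterministically by preorder traversal.
    """
    ids, d = distance_matrix(sequences)
    if len(ids) < 3:
        newick = "(" + ",".join(f"{s}:{d[0, -1] / 2.0:.8f}" for s in ids) + ");"
        return PhyloTree.from_newick(newick)
    tree = nj(DistanceMatrix(d, ids))
    tree = tree.root_at_midpoint()
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            node.length = 0.0
    return PhyloTree(tree)


def build_reference_package(
    sequences: Dict[str, str],
    seq_taxids: Dict[str, str],
    taxonomy: Taxonomy,
    tree: Optional[PhyloTree] = None,
    cutoff: float = 0.015,
    n_representatives: int = 5,
    type_strain_ids: Iterable[str] = (),
) -> RefPkg:
    """Run the per-taxon curation chain and assemble a reference package."""
    by_taxon: Dict[str, Dict[str, str]] = {}
    for sid, seq in sequences.items():
        taxid = seq_taxids.get(sid)
        if taxid is None or taxid not in taxonomy:
            raise DataError(f"sequence {sid} has no resolvable taxid")
        by_taxon.setdefault(taxid, {})[sid] = seq

    log: List[Dict] = []
    retained: Dict[str, str] = {}
    for taxid in sorted(by_taxon):
        group = by_taxon[taxid]
        primary = select_primary_reference(group)
        kept, discarded = filter_mislabeled(group, primary, cutoff)
        for sid, dist in sorted(discarded.items()):
            log.append({"action": "discard", "seq": sid, "taxon": taxid,
                        "distance_to_primary": round(dist, 6)})
        if not kept:
            log.append({"action": "drop_taxon", "taxon": taxid,
                        "reason": "no sequences after filtering"})
            continue
        reps = select_representatives(kept, primary, type_strain_ids, n_representatives)
        log.append({"action": "select", "taxon": taxid, "primary": primary,
                    "representatives": reps})
        for sid in reps:
            retained[sid] = kept[sid]
    if not retained:
        raise DataError("curation retained no sequences")
    if tree is None:
        tree = nj_tree(retained)
        log.append({"action": "build_tree", "method": "neighbor-joining, midpoint-rooted"})
    pkg = RefPkg(
        sequences=retained,
        taxonomy=taxonomy,
        tree=tree,
        seq_taxids={s: seq_taxids[s] for s in retained},
        log=log,
    )
    return pkg.validate()
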
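"""Edge labeling and posterior-sum taxonomic classification.

Edges of the reference tree are labeled with the most specific taxonomic
rank at which the leaves on one side of the edge carry exactly one taxid
(one-side purity, preferring the distal side). A placed read is then
classified at the most specific taxid whose cumulative posterior — the sum
of posteriors on edges labeled with that taxid or a descendant — reaches
the cutoff (default 0.9). Genus-or-higher classifications can be given a
compound name listing up to three more-specific taxa with individual
posterior above 0.05, e.g. ``Lactobacillus crispatus/iners``.

A full Bayesian placement engine is out of scope; a naive
identity-scan placer (:func:`naive_place`) produces placements of the same
shape for synthetic reads, and jplace files from external placers are read
and written losslessly.
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import Attachment, Classification, PlacedRead
from .errors import DataError, FormatError, ParameterError
from .refpkg import RefPkg
from .taxonomy import Taxonomy
from .tree import PhyloTree

JPLACE_FIELDS = ["edge_num", "like_weight_ratio", "distal_length", "pendant_length"]


def _side_taxids(
    leaves: Iterable[str],
    leaf_taxids: Dict[str, str],
    taxonomy: Taxonomy,
    rank: str,
) -> Optional[set]:
    """Distinct rank-level taxids on one side; None if the side is not
    fully resolvable at that rank or empty."""
    leaves = list(leaves)
    if not leaves:
        return None
    out = set()
    for leaf in leaves:
        taxid = leaf_taxids.get(leaf)
        if taxid is None or taxid not in taxonomy:
            raise DataError(f"leaf {leaf!r} has no resolvable lineage")
        at_rank = taxonomy.ancestor_at_rank(taxid, rank)
        if at_rank is None:
            return None
        out.add(at_rank)
    return out


def label_edges(
    tree: PhyloTree,
    taxonomy: Taxonomy,
    leaf_taxids: Dict[str, str],
    strategy: str = "one_side",
) -> Dict[int, Tuple[str, str]]:
    """Label every edge with ``(rank, taxid)``.

    ``strategy='one_side'`` (default): scan ranks from most to least
    specific and label at the first rank where the leaves on the distal
    side — the side the edge leads to — carry exactly one taxid. When
    both sides are pure at that rank with different taxids the distal
    taxid wins by construction. Using proximal-side purity alone would
    mislabel a clade's stem edge with the *neighboring* clade's species,
    so it never labels an edge; ``strategy='both_sides'`` is the stricter
    alternate reading requiring exactly one taxid present on both sides
    of the edge. Edges where no rank qualifies receive the root taxid.
    """
    if strategy not in ("one_side", "both_sides"):
        raise ParameterError(f"unknown edge-label strategy {strategy!r}")
    all_leaves = set(tree.leaf_names())
    labels: Dict[int, Tuple[str, str]] = {}
    ranks = list(reversed(taxonomy.ranks))  # most specific first
    for edge in tree.edge_ids:
        distal = tree.leaves_below(edge)
        proximal = all_leaves - distal
        label: Optional[Tuple[str, str]] = None
        for rank in ranks:
            d = _side_taxids(distal, leaf_taxids, taxonomy, rank)
            if strategy == "one_side":
                if d is not None and len(d) == 1:
                    label = (rank, next(iter(d)))
                    break
            else:
                p = _side_taxids(proximal, leaf_taxids, taxonomy, rank)
                if d is not None and p is not None and len(d & p) == 1:
                    label = (rank, next(iter(d & p)))
                    break
        labels[edge] = label or (taxonomy.ranks[0], taxonomy.root_taxid)
    return labels


def cumulative_posteriors(
    read: PlacedRead,
    edge_labels: Dict[int, Tuple[str, str]],
    taxonomy: Taxonomy,
) -> Dict[str, float]:
    """Cumulative posterior per candidate taxid (labels + their ancestors)."""
    label_mass: Dict[str, float] = {}
    for att in read.attachments:
        if att.edge_id not in edge_labels:
            raise DataError(f"read {read.read_id}: edge {att.edge_id} is unlabeled")
        _, taxid = edge_labels[att.edge_id]
        label_mass[taxid] = label_mass.get(taxid, 0.0) + att.posterior
    cum: Dict[str, float] = {}
    for taxid, mass in label_mass.items():
        cur: Optional[str] = taxid
        while cur is not None:
            cum[cur] = cum.get(cur, 0.0) + mass
            cur = taxonomy.node(cur).parent
    return cum


def classify_read(
    read: PlacedRead,
    edge_labels: Dict[int, Tuple[str, str]],
    taxonomy: Taxonomy,
    cutoff: float = 0.9,
    compound_threshold: float = 0.05,
    max_compound_names: int = 3,
) -> Classification:
    """Assign the most specific taxid with cumulative posterior >= cutoff.

    The root taxid always accumulates the full posterior, so every read
    classifies at some rank; a cutoff above 1 yields an ``unclassified``
    sentinel at the root rank.
    """
    read.normalize()
    cum = cumulative_posteriors(read, edge_labels, taxonomy)
    eligible = [t for t, m in cum.items() if m >= cutoff - 1e-12]
    if not eligible:
        return Classification(read.read_id, "unclassified", taxonomy.ranks[0], 0.0,
                              sample_id=read.sample_id)
    best = max(
        eligible,
        key=lambda t: (taxonomy.rank_index(taxonomy.rank(t)), cum[t],
                       # lexicographic tiebreak, inverted for max()
                       tuple(-ord(c) for c in t)),
    )
    cls = Classification(
        read.read_id, best, taxonomy.rank(best), cum[best], sample_id=read.sample_id
    )
    cls.compound_name = compound_name(
        cls, cum, taxonomy, threshold=compound_threshold, max_names=max_compound_names
    )
    return cls


def compound_name(
    classification: Classification,
    posteriors: Dict[str, float],
    taxonomy: Taxonomy,
    threshold: float = 0.05,
    max_names: int = 3,
) -> str:
    """Append up to three more-specific taxa with posterior > threshold.

    Species-level classifications are returned unchanged. For a genus (or
    higher) call, descendants at more specific ranks with individual
    posterior above the threshold are joined with ``/`` — repeated genus
    prefixes are dropped from all but the first name.
    """
    taxid = classification.taxid
    if taxid not in taxonomy:
        return taxid
    base = taxonomy.name(taxid)
    rank_idx = taxonomy.rank_index(classification.rank)
    if classification.rank == taxonomy.species_rank:
        return base
    candidates = [
        (t, m) for t, m in posteriors.items()
        if t != taxid
        and t in taxonomy
        and taxonomy.rank_index(taxonomy.rank(t)) > rank_idx
        and taxonomy.is_descendant(t, taxid)
        and m > threshold
    ]
    if not candidates:
        return base
    candidates.sort(key=lambda tm: (-tm[1], tm[0]))
    names = []
    for t, _ in candidates[:max_names]:
        name = taxonomy.name(t)
        prefix = base + " "
        names.append(name[len(prefix):] if name.startswith(prefix) else name)
    return f"{base} {'/'.join(names)}"


def classification_table(classifications: Iterable[Classification]) -> pd.DataFrame:
    rows = [
        {
            "read_id": c.read_id,
            "sample": c.sample_id or "",
            "taxid": c.taxid,
            "rank": c.rank,
            "posterior": c.posterior,
            "compound_name": c.compound_name or "",
        }
        for c in classifications
    ]
    return pd.DataFrame(rows, columns=["read_id", "sample", "taxid", "rank",
                                       "posterior", "compound_name"])


# ---------------------------------------------------------------------------
# Naive placer
# ---------------------------------------------------------------------------

_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.uint8)


def _best_offset_identity(read: np.ndarray, ref: np.ndarray) -> float:
    """Best identity fraction of an ungapped sliding of read along ref."""
    if len(read) > len(ref):
        read, ref = ref, read
    windows = np.lib.stride_tricks.sliding_window_view(ref, len(read))
    return float((windows == read).mean(axis=1).max())


def naive_place(
    read_seq: str,
    refpkg: RefPkg,
    top_k: int = 5,
    temperature: float = 0.02,
    score_floor: float = 0.6,
    pendant_length: float = 0.01,
    read_id: str = "query",
    sample_id: Optional[str] = None,
) -> Optional[PlacedRead]:
    """Place a read on terminal edges by best-offset identity scan.

    Each leaf is scored by the best ungapped identity fraction of the read
    against its (degapped) reference sequence; the top-k scores become
    posteriors through a temperature-controlled softmax, and the read
    attaches at the midpoint of those leaves' terminal edges. Returns
    ``None`` when no leaf scores above ``score_floor``.
    """
    if not read_seq:
        raise DataError("empty read")
    read_arr = _encode(read_seq)
    leaves = refpkg.tree.leaf_names()
    scores = []
    for leaf in leaves:
        ref = refpkg.sequences[leaf].replace("-", "")
        scores.append(_best_offset_identity(read_arr, _encode(ref)))
    scores = np.array(scores)
    if scores.max() >= 1.0 - 1e-12:
        # exact matches take all the mass
        order = [i for i in range(len(leaves)) if scores[i] >= 1.0 - 1e-12]
    else:
        order = np.argsort(-scores, kind="stable")[:top_k]
        order = [i for i in order if scores[i] >= score_floor]
    if not order:
        return None
    s = scores[order]
    w = np.exp((s - s.max()) / temperature)
    w /= w.sum()
    atts = []
    for i, weight in zip(order, w):
        edge = refpkg.tree.leaf_edge(leaves[i])
        length = refpkg.tree.edge_length(edge)
        atts.append(Attachment(
            edge_id=edge,
            distal_position=length / 2.0,
            pendant_length=pendant_length,
            posterior=float(weight),
        ))
    return PlacedRead(read_id, atts, sample_id=sample_id).normalize()


# ---------------------------------------------------------------------------
# jplace IO
# ---------------------------------------------------------------------------

def write_jplace(placed_reads: Iterable[PlacedRead], tree: PhyloTree, path) -> None:
    """Write placements in jplace (version 3) form."""
    placements = []
    for read in placed_reads:
        p = [
            [a.edge_id, a.posterior, a.distal_position, a.pendant_length]
            for a in read.attachments
        ]
        placements.append({"p": p, "nm": [[read.read_id, 1]]})
    doc = {
        "version": 3,
        "tree": tree.to_newick(with_edge_numbers=True),
        "fields": JPLACE_FIELDS,
        "placements": placements,
        "metadata": {"invocation": "vaginome"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_jplace(path) -> Tuple[List[PlacedRead], PhyloTree]:
    """Read a jplace file, tolerating permuted ``fields`` orders.

    Posteriors (``like_weight_ratio``) are renormalized to sum to one on
    load, since exported weight ratios are sometimes truncated.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed jplace JSON: {exc}") from None
    if "tree" not in doc or not doc["tree"]:
        raise FormatError("jplace file lacks a tree string")
    tree = PhyloTree.from_jplace_newick(doc["tree"])
    fields = doc.get("fields")
    if not fields:
        raise FormatError("jplace file lacks a fields list")
    try:
        idx = {name: fields.index(name) for name in JPLACE_FIELDS}
    except ValueError as exc:
        raise FormatError(f"jplace fields incomplete: {exc}") from None
    known_edges = set(tree.edge_ids)
    reads: List[PlacedRead] = []
    for i, entry in enumerate(doc.get("placements", [])):
        if "nm" in entry:
            names = [n[0] for n in entry["nm"]]
        elif "n" in entry:
            names = list(entry["n"])
        else:
            names = [f"placement{i}"]
        atts = []
        for row in entry["p"]:
            edge = int(row[idx["edge_num"]])
            if edge not in known_edges:
                raise FormatError(f"unknown edge_num {edge} in placement {names[0]}")
            atts.append(Attachment(
                edge_id=edge,
                distal_position=float(row[idx["distal_length"]]),
                pendant_length=float(row[idx["pendant_length"]]),
                posterior=float(row[idx["like_weight_ratio"]]),
            ))
        for name in names:
            reads.append(PlacedRead(name, [Attachment(a.edge_id, a.distal_position,
                                                      a.pendant_length, a.posterior)
                                           for a in atts]).normalize())
    return reads, tree
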
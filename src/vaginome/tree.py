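"""Reference tree with uniquely numbered, length-bearing edges.

:class:`PhyloTree` wraps a rooted :class:`skbio.TreeNode` and gives every
edge (the branch above each non-root node) an integer id. Edge ids are the
coordinate system for placements, mass maps, KR distances and edge PCA.
Ids are assigned deterministically by preorder traversal unless an explicit
numbering (e.g. from a jplace file) is supplied.

Positions along an edge are measured from the *proximal* (rootward) end,
in branch-length units, so a position of 0 is the parent node and a
position of ``edge_length`` is the child node. jplace files measure
``distal_length`` from the distal end; :mod:`vaginome.classify` converts.
"""

from __future__ import annotations

import io
import re
from typing import Dict, FrozenSet, List, Optional, Tuple

from skbio import TreeNode

from .errors import DataError, FormatError

_EDGE_TAG = re.compile(r"__EDGE(\d+)__$")
_BRACE = re.compile(r"([^\s,():{}\[\]']*)((?::[-+0-9.eE]+)?)\{(\d+)\}")


class PhyloTree:
    """A rooted tree with integer-numbered, length-bearing edges."""

    def __init__(self, root: TreeNode, edge_ids: Optional[Dict[TreeNode, int]] = None):
        if root.parent is not None:
            raise DataError("PhyloTree root must not have a parent")
        self.root = root
        for node in root.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise DataError(f"negative edge length on node {node.name!r}")
        if edge_ids is None:
            edge_ids = {}
            for i, node in enumerate(root.preorder(include_self=False)):
                edge_ids[node] = i
        ids = sorted(edge_ids.values())
        if len(set(ids)) != len(ids):
            raise DataError("edge ids are not unique")
        self._node_of_edge: Dict[int, TreeNode] = {e: n for n, e in edge_ids.items()}
        self._edge_of_node: Dict[TreeNode, int] = dict(edge_ids)
        self._leaves_below_cache: Dict[int, FrozenSet[str]] = {}
        self._depth: Dict[TreeNode, float] = {root: 0.0}
        for node in root.preorder(include_self=False):
            self._depth[node] = self._depth[node.parent] + node.length
        self._ancestors: Dict[TreeNode, FrozenSet[TreeNode]] = {root: frozenset()}
        for node in root.preorder(include_self=False):
            self._ancestors[node] = self._ancestors[node.parent] | {node.parent}

    # -- basic accessors ---------------------------------------------------

    @property
    def edge_ids(self) -> List[int]:
        return sorted(self._node_of_edge)

    @property
    def n_edges(self) -> int:
        return len(self._node_of_edge)

    def node_below(self, edge_id: int) -> TreeNode:
        """The node at the distal (leafward) end of an edge."""
        try:
            return self._node_of_edge[edge_id]
        except KeyError:
            raise DataError(f"unknown edge id {edge_id}") from None

    def edge_of(self, node: TreeNode) -> int:
        return self._edge_of_node[node]

    def edge_length(self, edge_id: int) -> float:
        return float(self.node_below(edge_id).length)

    def leaf_names(self) -> List[str]:
        return [t.name for t in self.root.tips()]

    def leaf_edge(self, leaf_name: str) -> int:
        for tip in self.root.tips():
            if tip.name == leaf_name:
                return self._edge_of_node[tip]
        raise DataError(f"no leaf named {leaf_name!r}")

    def leaves_below(self, edge_id: int) -> FrozenSet[str]:
        """Leaf names on the distal side of an edge (cached)."""
        if edge_id not in self._leaves_below_cache:
            node = self.node_below(edge_id)
            if node.is_tip():
                below = frozenset([node.name])
            else:
                below = frozenset(t.name for t in node.tips())
            self._leaves_below_cache[edge_id] = below
        return self._leaves_below_cache[edge_id]

    def postorder_edges(self) -> List[int]:
        return [self._edge_of_node[n] for n in self.root.postorder(include_self=False)]

    def child_edges(self, edge_id: int) -> List[int]:
        node = self.node_below(edge_id)
        return [self._edge_of_node[c] for c in node.children]

    def depth(self, node: TreeNode) -> float:
        return self._depth[node]

    # -- geometry ----------------------------------------------------------

    def point_depth(self, edge_id: int, position: float) -> float:
        """Distance from the root to a point on an edge.

        ``position`` is measured from the proximal (parent) end.
        """
        node = self.node_below(edge_id)
        length = float(node.length)
        if not (-1e-12 <= position <= length + 1e-12):
            raise DataError(
                f"position {position} outside edge {edge_id} of length {length}"
            )
        return self._depth[node.parent] + position

    def point_distance(
        self, a: Tuple[int, float], b: Tuple[int, float]
    ) -> float:
        """Path distance between two points, each ``(edge_id, position)``.

        Partial edge segments at both ends are included.
        """
        ea, pa = a
        eb, pb = b
        na, nb = self.node_below(ea), self.node_below(eb)
        xa = self.point_depth(ea, pa)
        xb = self.point_depth(eb, pb)
        if na is nb:
            return abs(xa - xb)
        if na in self._ancestors[nb]:
            return xb - xa
        if nb in self._ancestors[na]:
            return xa - xb
        common = (self._ancestors[na] | {na}) & (self._ancestors[nb] | {nb})
        lca = max(common, key=lambda n: self._depth[n])
        return xa + xb - 2.0 * self._depth[lca]

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = TreeNode.read(io.StringIO(newick), format="newick",
                             convert_underscores=False)
        return cls(tree)

    @classmethod
    def from_jplace_newick(cls, newick: str) -> "PhyloTree":
        """Parse a newick string with jplace ``{edge_num}`` tags."""
        if "{" not in newick:
            raise FormatError("jplace tree string carries no {edge_num} tags")
        tagged = _BRACE.sub(r"\1__EDGE\3__\2", newick)
        tree = TreeNode.read(io.StringIO(tagged), format="newick",
                             convert_underscores=False)
        edge_ids: Dict[TreeNode, int] = {}
        for node in tree.traverse(include_self=True):
            name = node.name or ""
            m = _EDGE_TAG.search(name)
            if m:
                node.name = name[: m.start()] or None
                if node.parent is not None:
                    edge_ids[node] = int(m.group(1))
        if not edge_ids:
            raise FormatError("no edge numbers recovered from jplace tree")
        missing = [
            n for n in tree.traverse(include_self=False) if n not in edge_ids
        ]
        if missing:
            raise FormatError("jplace tree has unnumbered edges")
        return cls(tree, edge_ids=edge_ids)

    def _write_node(self, node: TreeNode, with_edges: bool, parts: List[str]) -> None:
        if node.children:
            parts.append("(")
            for i, child in enumerate(node.children):
                if i:
                    parts.append(",")
                self._write_node(child, with_edges, parts)
            parts.append(")")
        if node.name:
            parts.append(str(node.name).replace(" ", "_"))
        if node.parent is not None:
            parts.append(f":{node.length:.10g}")
            if with_edges:
                parts.append("{%d}" % self._edge_of_node[node])

    def to_newick(self, with_edge_numbers: bool = False) -> str:
        parts: List[str] = []
        self._write_node(self.root, with_edge_numbers, parts)
        parts.append(";")
        return "".join(parts)

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree: {len(self.leaf_names())} leaves, {self.n_edges} edges>"
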
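"""Edge principal components analysis of placement mass.

Each sample's unit mass map is transformed into a vector indexed by the
edges of the reference tree: the entry for edge e is the mass on the
distal side of e minus the mass on the proximal side (2·distal − 1 for
unit mass; point masses sitting on e itself count as distal). Classical
covariance PCA of these vectors yields eigenvectors that live on the tree
and can be projected back onto it as signed edge weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .containers import MassMap
from .errors import DataError
from .tree import PhyloTree


def edge_mass_matrix(mass_maps: Sequence[MassMap], tree: PhyloTree) -> pd.DataFrame:
    """Samples x edges matrix of signed mass differences (distal − proximal)."""
    edges = tree.edge_ids
    subtree_children = {e: tree.child_edges(e) for e in edges}
    rows = []
    for mmap in mass_maps:
        mmap.validate(tree)
        on_edge: Dict[int, float] = {}
        for e, _, m in mmap.points:
            on_edge[e] = on_edge.get(e, 0.0) + m
        below: Dict[int, float] = {}
        for e in tree.postorder_edges():
            below[e] = on_edge.get(e, 0.0) + sum(below[c] for c in subtree_children[e])
        rows.append([2.0 * below[e] - 1.0 for e in edges])
    ids = [m.sample_id for m in mass_maps]
    return pd.DataFrame(rows, index=ids, columns=edges)


@dataclass
class EdgePcaResult:
    """Eigen-decomposition of the centered edge-mass matrix."""

    eigenvalues: np.ndarray          # variance per component, nonincreasing
    eigenvectors: pd.DataFrame       # edges x components, orthonormal columns
    scores: pd.DataFrame             # samples x components
    variance_fraction: np.ndarray    # eigenvalues / total column variance

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def edge_pca(matrix: pd.DataFrame, n_components: int = 2) -> EdgePcaResult:
    """Classical PCA of the edge-mass matrix (covariance, not correlation).

    The deterministic sign convention makes each component's
    largest-magnitude loading positive. Requesting more components than
    the matrix rank truncates with a warning.
    """
    if len(matrix) < 2:
        raise DataError("edge PCA needs at least two samples")
    x = matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (len(x) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int(np.sum(evals > max(1e-12, evals[0] * 1e-12))) if evals.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
        n_components = max(rank, 1)
    evals = evals[:n_components]
    evecs = evecs[:, :n_components]
    for k in range(evecs.shape[1]):  # sign convention
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1.0
    total_var = centered.var(axis=0, ddof=1).sum()
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    eigenvectors = pd.DataFrame(evecs, index=matrix.columns, columns=comp_names)
    scores = pd.DataFrame(centered @ evecs, index=matrix.index, columns=comp_names)
    frac = evals / total_var if total_var > 0 else np.zeros_like(evals)
    return EdgePcaResult(evals, eigenvectors, scores, frac)


def project_component_on_tree(
    eigenvector: pd.Series, tree: PhyloTree, scale: float = 1.0
) -> str:
    """Annotate a tree's edges with signed component weights.

    Returns a newick string in which every edge carries a comment-style
    annotation ``[&weight=w]`` with w = scale * loading; orange/green
    rendering of positive/negative weights is left to downstream viewers.
    The annotation survives a round trip through
    :func:`parse_projected_newick`.
    """
    weights = {int(e): float(eigenvector[e]) * scale for e in eigenvector.index}
    parts: List[str] = []

    def write(node):
        if node.children:
            parts.append("(")
            for i, child in enumerate(node.children):
                if i:
                    parts.append(",")
                write(child)
            parts.append(")")
        if node.name:
            parts.append(str(node.name))
        if node.parent is not None:
            e = tree.edge_of(node)
            parts.append(f":{node.length:.10g}[&weight={weights.get(e, 0.0):.8g}]")

    write(tree.root)
    parts.append(";")
    return "".join(parts)


def parse_projected_newick(newick: str) -> Dict[int, float]:
    """Recover per-edge weights (keyed by preorder edge id) from an
    annotated newick produced by :func:`project_component_on_tree`."""
    import re

    from .tree import PhyloTree as _PT

    weights_in_order = [float(w) for w in re.findall(r"\[&weight=([-+0-9.eE]+)\]", newick)]
    plain = re.sub(r"\[&weight=[-+0-9.eE]+\]", "", newick)
    tree = _PT.from_newick(plain)
    # annotations appear in the writer's traversal order (children before
    # their parent edge); replicate that order against the re-parsed tree
    order: List[int] = []

    def writer_order(node):
        for child in node.children:
            writer_order(child)
        if node.parent is not None:
            order.append(tree.edge_of(node))

    writer_order(tree.root)
    if len(order) != len(weights_in_order):
        raise DataError("annotation count does not match edge count")
    return dict(zip(order, weights_in_order))
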
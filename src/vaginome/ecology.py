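"""Diversity, abundance trimming, co-occurrence, community summaries.

Shannon diversity (natural log) and bias-corrected Chao1 richness are
computed per sample on reads classified to their most specific rank.
Taxa are trimmed to the most abundant 30% before co-occurrence analysis;
counts are transformed as log(x + 0.5) (a continuity correction for zero
counts), correlated pairwise with Pearson's r, and the correlation rows
are clustered with Euclidean distance and complete linkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from skbio.diversity import alpha as skbio_alpha
from skbio import TreeNode

from .containers import CountMatrix
from .errors import DataError, ParameterError


def _check_counts(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or (arr < 0).any() or arr.sum() <= 0:
        raise DataError("need a count vector with at least one positive count")
    return arr


def shannon(counts: Sequence[float], base: float = math.e) -> float:
    """Shannon diversity H = −Σ p_i log p_i (natural log by default)."""
    arr = _check_counts(counts)
    return float(skbio_alpha.shannon(arr.astype(np.int64), base=base))


def chao1(counts: Sequence[float], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form S_obs + f1(f1−1)/(2(f2+1)) by default; the classic
    S_obs + f1²/(2 f2) is selectable (undefined without doubletons).
    """
    arr = _check_counts(counts)
    return float(skbio_alpha.chao1(arr.astype(np.int64), bias_corrected=bias_corrected))


def diversity_table(matrix: CountMatrix) -> pd.DataFrame:
    rows = []
    for sample in matrix.samples:
        v = matrix.row(sample).to_numpy()
        rows.append({
            "sample_id": sample,
            "richness": int((v > 0).sum()),
            "shannon": shannon(v),
            "chao1": chao1(v),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def trim_taxa(matrix: CountMatrix, top_frac: float = 0.30) -> Tuple[CountMatrix, Dict]:
    """Keep the top ceil(top_frac · T) taxa by total abundance.

    Returns the trimmed matrix and a report with the retained fraction of
    reads (on strongly skewed surveys this trim retains > 98.5%).
    """
    if not (0.0 < top_frac <= 1.0):
        raise ParameterError("top_frac must lie in (0, 1]")
    totals = matrix.counts.sum(axis=0)
    k = math.ceil(top_frac * len(totals))
    keep = totals.sort_values(ascending=False, kind="stable").index[:k]
    keep = [t for t in matrix.taxa if t in set(keep)]  # stable taxon order
    sub = matrix.counts[keep]
    empty = sub.index[sub.sum(axis=1) == 0].tolist()
    if empty:
        warnings.warn(f"trimming left {len(empty)} sample(s) without reads; dropped")
        sub = sub.drop(index=empty)
    trimmed = CountMatrix(sub)
    report = {
        "taxa_before": len(matrix.taxa),
        "taxa_after": len(keep),
        "samples_dropped": empty,
        "retained_read_fraction": float(
            sub.to_numpy().sum() / matrix.counts.to_numpy().sum()
        ),
    }
    return trimmed, report


@dataclass
class CooccurrenceResult:
    """Pearson co-occurrence of log-transformed taxon counts."""

    taxa: List[str]
    correlations: pd.DataFrame     # symmetric, unit diagonal
    linkage: np.ndarray            # complete-linkage merge matrix over taxa
    dropped: List[str]             # zero-variance taxa removed

    def dendrogram_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.taxa)
        return str(tree).strip()


def cooccurrence(matrix: CountMatrix, pseudocount: float = 0.5) -> CooccurrenceResult:
    """Pairwise Pearson correlation of log(count + 0.5) across samples.

    Taxa with zero variance (after the log transform) have undefined
    correlations and are dropped with a warning. Correlation rows are
    clustered with Euclidean distance and complete linkage.
    """
    if len(matrix.samples) < 3:
        raise DataError("co-occurrence needs at least three samples")
    logs = np.log(matrix.counts.to_numpy(dtype=float) + pseudocount)
    variances = logs.var(axis=0)
    keep = variances > 0
    dropped = [t for t, k in zip(matrix.taxa, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance taxa: {dropped}")
    taxa = [t for t, k in zip(matrix.taxa, keep) if k]
    if len(taxa) < 2:
        raise DataError("fewer than two taxa with positive variance")
    corr = np.corrcoef(logs[:, keep], rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=taxa, columns=taxa)
    z = linkage(pdist(corr, metric="euclidean"), method="complete")
    return CooccurrenceResult(taxa, frame, z, dropped)


def community_summaries(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    bv_definition: str = "nugent",
    dominance: str = "plurality",
    target_share: float = 0.95,
) -> Dict[str, pd.DataFrame]:
    """Per-taxon prevalence/read-share by BV group plus per-sample dominance.

    ``bv_definition`` selects the grouping: ``nugent`` (score 7–10 = BV)
    or ``amsel`` (≥3-of-4 clinical signs). Prevalence is the fraction of a
    group's samples with at least one read of the taxon; read share is the
    taxon's reads over the group's reads. The dominant taxon of a sample
    is its plurality taxon (``dominance='majority'`` additionally requires
    > 50% of reads, else none); ties break lexicographically and are
    flagged. ``top_taxa`` lists, per group, the minimal top-k taxa by read
    share that jointly cover ``target_share`` of the group's reads.
    """
    if bv_definition == "nugent":
        groups = np.where(meta.set_index("sample_id").loc[matrix.samples, "nugent"] >= 7,
                          "BV", "no BV")
    elif bv_definition == "amsel":
        groups = np.where(
            meta.set_index("sample_id").loc[matrix.samples, "bv_amsel"].astype(int) == 1,
            "BV", "no BV")
    else:
        raise ParameterError("bv_definition must be 'nugent' or 'amsel'")
    counts = matrix.counts
    per_taxon_rows = []
    top_rows = []
    for group in ("no BV", "BV"):
        sel = counts[groups == group]
        if len(sel) == 0:
            raise DataError(f"empty group {group!r}")
        group_total = sel.to_numpy().sum()
        shares = {}
        for taxon in matrix.taxa:
            col = sel[taxon]
            share = float(col.sum() / group_total)
            shares[taxon] = share
            per_taxon_rows.append({
                "group": group,
                "taxon": taxon,
                "n_samples": len(sel),
                "prevalence": float((col > 0).mean()),
                "read_share": share,
            })
        ranked = sorted(shares.items(), key=lambda kv: (-kv[1], kv[0]))
        cum, chosen = 0.0, []
        for taxon, share in ranked:
            chosen.append(taxon)
            cum += share
            if cum >= target_share:
                break
        top_rows.append({"group": group, "k": len(chosen),
                         "covered_share": cum, "taxa": ";".join(chosen)})

    dom_rows = []
    for sample in matrix.samples:
        row = counts.loc[sample]
        top = row.max()
        winners = sorted(row.index[row == top])
        dom = winners[0]
        if dominance == "majority" and top <= row.sum() / 2:
            dom = ""
        dom_rows.append({"sample_id": sample, "dominant_taxon": dom,
                         "dominant_share": float(top / row.sum()),
                         "tie": len(winners) > 1})
    return {
        "per_taxon": pd.DataFrame(per_taxon_rows),
        "dominance": pd.DataFrame(dom_rows).set_index("sample_id"),
        "top_taxa": pd.DataFrame(top_rows),
    }
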
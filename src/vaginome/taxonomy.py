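"""Rank-ordered taxonomy with provisional taxa.

A lightweight taxid table (taxid -> name, rank, parent, provisional flag)
with a fixed rank order from the root down to species. Provisional taxa —
uncultivated organisms such as BVAB1/2/3 or genogroups that extend the
public taxonomy — are first-class nodes carrying a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .errors import DataError

DEFAULT_RANKS = ("root", "order", "family", "genus", "species")


@dataclass
class TaxonomyNode:
    taxid: str
    name: str
    rank: str
    parent: Optional[str]
    provisional: bool = False


class Taxonomy:
    """Rank-ordered lineages from root to species."""

    def __init__(self, ranks: Iterable[str] = DEFAULT_RANKS):
        self.ranks: List[str] = list(ranks)
        if len(self.ranks) < 3:
            raise DataError("taxonomy needs at least three ranks")
        self._nodes: Dict[str, TaxonomyNode] = {}

    def add(
        self,
        taxid: str,
        name: str,
        rank: str,
        parent: Optional[str],
        provisional: bool = False,
    ) -> None:
        if rank not in self.ranks:
            raise DataError(f"unknown rank {rank!r}")
        if parent is not None:
            if parent not in self._nodes:
                raise DataError(f"parent taxid {parent!r} not yet defined")
            if self.rank_index(self._nodes[parent].rank) >= self.rank_index(rank):
                raise DataError(
                    f"parent rank must be higher than child rank for {taxid!r}"
                )
        elif rank != self.ranks[0]:
            raise DataError("only the root rank may lack a parent")
        self._nodes[taxid] = TaxonomyNode(taxid, name, rank, parent, provisional)

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: str) -> TaxonomyNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise DataError(f"unknown taxid {taxid!r}") from None

    def name(self, taxid: str) -> str:
        return self.node(taxid).name

    def rank(self, taxid: str) -> str:
        return self.node(taxid).rank

    def rank_index(self, rank: str) -> int:
        """0 for the root rank, larger is more specific."""
        try:
            return self.ranks.index(rank)
        except ValueError:
            raise DataError(f"unknown rank {rank!r}") from None

    @property
    def root_taxid(self) -> str:
        for node in self._nodes.values():
            if node.parent is None:
                return node.taxid
        raise DataError("taxonomy has no root")

    def lineage(self, taxid: str) -> Dict[str, str]:
        """Mapping rank -> taxid along the path root..taxid."""
        out: Dict[str, str] = {}
        cur: Optional[str] = taxid
        while cur is not None:
            node = self.node(cur)
            out[node.rank] = node.taxid
            cur = node.parent
        return out

    def ancestor_at_rank(self, taxid: str, rank: str) -> Optional[str]:
        return self.lineage(taxid).get(rank)

    def is_descendant(self, taxid: str, ancestor: str) -> bool:
        """True if ``taxid`` equals or descends from ``ancestor``."""
        cur: Optional[str] = taxid
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self.node(cur).parent
        return False

    def children(self, taxid: str) -> List[str]:
        return [t for t, n in self._nodes.items() if n.parent == taxid]

    def taxids_at_rank(self, rank: str) -> List[str]:
        return [t for t, n in self._nodes.items() if n.rank == rank]

    @property
    def species_rank(self) -> str:
        return self.ranks[-1]

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxid": n.taxid,
                "parent": n.parent if n.parent is not None else "",
                "rank": n.rank,
                "name": n.name,
                "provisional": int(n.provisional),
            }
            for n in self._nodes.values()
        ]
        return pd.DataFrame(rows, columns=["taxid", "parent", "rank", "name", "provisional"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ranks: Iterable[str] = DEFAULT_RANKS) -> "Taxonomy":
        tax = cls(ranks)
        rows = list(frame.itertuples(index=False))
        # parents must be defined before children; sort by rank depth
        rows.sort(key=lambda r: tax.rank_index(r.rank))
        for r in rows:
            parent = r.parent if isinstance(r.parent, str) and r.parent else None
            tax.add(str(r.taxid), str(r.name), str(r.rank), parent, bool(int(r.provisional)))
        return tax

    @classmethod
    def from_csv(cls, path, ranks: Iterable[str] = DEFAULT_RANKS) -> "Taxonomy":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False), ranks)
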
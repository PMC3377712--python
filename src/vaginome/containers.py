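"""Core in-memory containers shared across the pipeline.

Tabular data lives in pandas; these thin wrappers add the invariants the
pipeline relies on (non-negative counts, normalized posteriors, unit total
mass) and the joins between counts and sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError

#: metadata columns and their documented meaning
SAMPLE_META_COLUMNS = [
    "sample_id",      # unique sample / subject identifier
    "nugent",         # Gram-stain morphotype score, integer 0-10
    "amsel_discharge",  # abnormal discharge, 0/1
    "ph",             # vaginal pH, positive real
    "amsel_whiff",    # amine odor on KOH, 0/1
    "clue_cells",     # ordinal: none, <20%, >20%
    "bv_amsel",       # >=3-of-4 Amsel signs, 0/1
    "race",           # self-reported race, categorical
]

CLUE_LEVELS = ("none", "<20%", ">20%")


class CountMatrix:
    """Sample x taxon read counts.

    Rows are samples, columns taxa; all entries are non-negative integers
    and every included sample has at least one read.
    """

    def __init__(self, counts: pd.DataFrame):
        values = counts.to_numpy()
        if (values < 0).any():
            raise DataError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise DataError("counts must be integers")
        if (values.sum(axis=1) <= 0).any():
            bad = counts.index[values.sum(axis=1) <= 0].tolist()
            raise DataError(f"samples with zero total reads: {bad}")
        self.counts = counts.astype(np.int64)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> List[str]:
        return list(self.counts.columns)

    def row(self, sample: str) -> pd.Series:
        return self.counts.loc[sample]

    def relative(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def subset_taxa(self, taxa: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(taxa)])

    def to_csv(self, path) -> None:
        self.counts.rename_axis("sample_id").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CountMatrix: {len(self.samples)} samples x {len(self.taxa)} taxa>"


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample metadata invariants and return the frame."""
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in metadata")
    if not meta["nugent"].between(0, 10).all():
        raise DataError("nugent scores must lie in [0, 10]")
    if not set(meta["clue_cells"]).issubset(CLUE_LEVELS):
        raise DataError(f"clue_cells levels must be subset of {CLUE_LEVELS}")
    if (meta["ph"] <= 0).any():
        raise DataError("pH must be positive")
    signs = (
        meta["amsel_discharge"].astype(int)
        + (meta["ph"] > 4.5).astype(int)
        + meta["amsel_whiff"].astype(int)
        + (meta["clue_cells"] != "none").astype(int)
    )
    expected = (signs >= 3).astype(int)
    if not (meta["bv_amsel"].astype(int) == expected).all():
        raise DataError("bv_amsel inconsistent with the >=3-of-4 Amsel rule")
    return meta


@dataclass
class Attachment:
    """One candidate attachment of a read to the reference tree.

    ``distal_position`` is measured from the edge's distal (leafward) node,
    matching the jplace ``distal_length`` convention.
    """

    edge_id: int
    distal_position: float
    pendant_length: float
    posterior: float


@dataclass
class PlacedRead:
    """A read's probability distribution over tree attachment points."""

    read_id: str
    attachments: List[Attachment]
    sample_id: Optional[str] = None

    def normalize(self) -> "PlacedRead":
        total = sum(a.posterior for a in self.attachments)
        if total <= 0:
            raise DataError(f"read {self.read_id}: non-positive posterior mass")
        for a in self.attachments:
            a.posterior /= total
        return self

    def best(self) -> Attachment:
        return max(self.attachments, key=lambda a: a.posterior)


@dataclass
class MassMap:
    """One sample's unit mass distributed over tree points.

    Each point is ``(edge_id, position, mass)`` with ``position`` measured
    from the proximal (rootward) end of the edge.
    """

    sample_id: str
    points: List[Tuple[int, float, float]]

    def total(self) -> float:
        return sum(m for _, _, m in self.points)

    def validate(self, tree=None) -> "MassMap":
        if abs(self.total() - 1.0) > 1e-9:
            raise DataError(f"mass map {self.sample_id}: total {self.total()} != 1")
        if any(m <= 0 for _, _, m in self.points):
            raise DataError(f"mass map {self.sample_id}: non-positive point mass")
        if tree is not None:
            for e, pos, _ in self.points:
                if not (-1e-9 <= pos <= tree.edge_length(e) + 1e-9):
                    raise DataError(
                        f"mass map {self.sample_id}: position {pos} outside edge {e}"
                    )
        return self

    def mass_per_edge(self) -> Dict[int, float]:
        out: Dict[int, float] = {}
        for e, _, m in self.points:
            out[e] = out.get(e, 0.0) + m
        return out


@dataclass
class Classification:
    """A read's taxonomic assignment by cumulative posterior."""

    read_id: str
    taxid: str
    rank: str
    posterior: float
    compound_name: Optional[str] = None
    sample_id: Optional[str] = None


@dataclass
class Island:
    """A single-linkage cluster of read attachment points."""

    island_id: str
    read_ids: List[str]
    subjects: List[str]
    representative: str
    label: str

    @property
    def n_subjects(self) -> int:
        return len(set(self.subjects))
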
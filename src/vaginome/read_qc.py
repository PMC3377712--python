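"""Demultiplexing and quality filtering of barcoded amplicon reads.

Retained reads must (1) start with a known barcode, (2) carry the exact
primer sequence immediately after it, (3) keep at least ``min_len``
nucleotides once barcode and primer are trimmed, and (4) have a mean
per-base Phred quality of at least ``min_avg_qual`` (computed on the
trimmed read). Retained reads are then clipped to their longest span in
which every 30-mer window has >= 90% of bases above Phred 15, and the
length criterion is re-checked after clipping.

Reads are plain ``Bio.SeqRecord`` objects with ``phred_quality`` letter
annotations (Sanger Phred+33 FASTQ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, DataError

CRITERIA = (
    "unknown_barcode",      # criterion 1
    "primer_mismatch",      # criterion 2
    "too_short",            # criterion 3 (including post-clip re-check)
    "low_mean_quality",     # criterion 4
)


@dataclass
class QCReport:
    """Bookkeeping of a demultiplex-and-filter run."""

    input_reads: int = 0
    retained: int = 0
    discards: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CRITERIA})
    per_sample: Dict[str, int] = field(default_factory=dict)
    clip_lengths: Dict[int, int] = field(default_factory=dict)
    discarded_ids: Dict[str, str] = field(default_factory=dict)  # read id -> criterion

    def validate(self) -> "QCReport":
        if self.retained + sum(self.discards.values()) != self.input_reads:
            raise DataError("QC report does not account for every input read")
        if sum(self.per_sample.values()) != self.retained:
            raise DataError("per-sample tallies do not sum to retained reads")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "input_reads": self.input_reads,
                    "retained": self.retained,
                    "discards": self.discards,
                    "per_sample": self.per_sample,
                    "clip_lengths": {str(k): v for k, v in self.clip_lengths.items()},
                },
                fh,
                indent=1,
            )

    def summary(self) -> str:
        lines = [
            f"input reads:    {self.input_reads}",
            f"retained reads: {self.retained}",
        ]
        for c in CRITERIA:
            lines.append(f"discarded ({c}): {self.discards[c]}")
        return "\n".join(lines)


def quality_clip(
    sequence: str,
    qualities: List[int],
    window: int = 30,
    q_threshold: int = 15,
    min_frac: float = 0.9,
) -> Tuple[str, List[int]]:
    """Clip a read to its longest span of windowed high quality.

    Returns the longest contiguous span in which every length-``window``
    sub-window has at least ``min_frac`` of bases with quality strictly
    above ``q_threshold``. Spans shorter than ``window`` are evaluated as
    a single window. Ties go to the leftmost span; a read with no valid
    span returns an empty sequence.
    """
    if len(sequence) != len(qualities):
        raise DataError("sequence and quality lengths differ")
    n = len(sequence)
    if n == 0:
        return "", []
    good = np.asarray(qualities) > q_threshold
    if n < window:
        frac = good.mean()
        return (sequence, list(qualities)) if frac >= min_frac else ("", [])
    need = int(np.ceil(min_frac * window - 1e-9))
    # window sums at each start position
    csum = np.concatenate([[0], np.cumsum(good)])
    wsums = csum[window:] - csum[:-window]          # start positions 0..n-window
    ok = wsums >= need
    best_start, best_len = 0, 0
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            span_len = (j - i) + window
            if span_len > best_len:
                best_start, best_len = i, span_len
            i = j + 1
        else:
            i += 1
    if best_len == 0:
        # fall back to the longest sub-window span (< window) that passes
        for span_len in range(window - 1, 0, -1):
            need_s = int(np.ceil(min_frac * span_len - 1e-9))
            sums = csum[span_len:] - csum[:-span_len]
            hits = np.nonzero(sums >= need_s)[0]
            if hits.size:
                best_start, best_len = int(hits[0]), span_len
                break
    if best_len == 0:
        return "", []
    return (
        sequence[best_start:best_start + best_len],
        list(qualities[best_start:best_start + best_len]),
    )


def demultiplex_and_filter(
    reads: Iterable[SeqRecord],
    barcodes: Dict[str, str],
    primer: str,
    min_len: int = 200,
    min_avg_qual: float = 35.0,
    window: int = 30,
    q_threshold: int = 15,
    min_frac: float = 0.9,
) -> Tuple[Dict[str, List[SeqRecord]], QCReport]:
    """Demultiplex reads by barcode and apply the four quality criteria.

    Returns per-sample trimmed-and-clipped reads plus a :class:`QCReport`
    enumerating discards by the first failing criterion.
    """
    if not primer:
        raise ConfigurationError("primer must be non-empty")
    if len(set(barcodes.values())) != len(barcodes):
        raise ConfigurationError("barcodes must be distinct")
    bcs = sorted(barcodes.values())
    for a, b in zip(bcs, bcs[1:]):
        if b.startswith(a) and a != b:
            raise ConfigurationError(f"barcode {a} is a prefix of {b}")
    if len({len(b) for b in barcodes.values()}) != 1:
        raise ConfigurationError("barcodes must share one fixed length")
    bc_len = len(bcs[0])
    sample_of = {bc: s for s, bc in barcodes.items()}

    report = QCReport(per_sample={s: 0 for s in barcodes})
    out: Dict[str, List[SeqRecord]] = {s: [] for s in barcodes}
    for rec in reads:
        report.input_reads += 1
        seq = str(rec.seq)
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise DataError(f"read {rec.id} lacks quality scores")
        sample = sample_of.get(seq[:bc_len])
        if sample is None:
            report.discards["unknown_barcode"] += 1
            report.discarded_ids[rec.id] = "unknown_barcode"
            continue
        if seq[bc_len:bc_len + len(primer)] != primer:
            report.discards["primer_mismatch"] += 1
            report.discarded_ids[rec.id] = "primer_mismatch"
            continue
        trimmed = seq[bc_len + len(primer):]
        tquals = list(quals[bc_len + len(primer):])
        if len(trimmed) < min_len:
            report.discards["too_short"] += 1
            report.discarded_ids[rec.id] = "too_short"
            continue
        if len(tquals) == 0 or float(np.mean(tquals)) < min_avg_qual:
            report.discards["low_mean_quality"] += 1
            report.discarded_ids[rec.id] = "low_mean_quality"
            continue
        clipped, cquals = quality_clip(trimmed, tquals, window, q_threshold, min_frac)
        if len(clipped) < min_len:
            report.discards["too_short"] += 1
            report.discarded_ids[rec.id] = "too_short"
            continue
        new = SeqRecord(rec.seq.__class__(clipped), id=rec.id, description="")
        new.letter_annotations["phred_quality"] = cquals
        out[sample].append(new)
        report.retained += 1
        report.per_sample[sample] += 1
        report.clip_lengths[len(clipped)] = report.clip_lengths.get(len(clipped), 0) + 1
    return out, report.validate()


def run_qc_on_fastq(
    fastq_path,
    barcodes: Dict[str, str],
    primer: str,
    **kwargs,
) -> Tuple[Dict[str, List[SeqRecord]], QCReport]:
    """Convenience wrapper: parse a FASTQ file and filter it."""
    reads = SeqIO.parse(fastq_path, "fastq")
    return demultiplex_and_filter(reads, barcodes, primer, **kwargs)
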
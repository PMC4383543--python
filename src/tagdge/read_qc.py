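"""FASTQ quality filtering and clean-read statistics.

Raw tag-sequencing reads are filtered by three rules, applied in a fixed
order so the per-reason removal tallies are deterministic:

1. *adaptor* — any configured adaptor sequence occurs as an exact substring
   of the read;
2. *unknown_frac* — the fraction of ``N`` bases is strictly greater than
   ``max_unknown_frac`` (default 5%);
3. *low_quality* — the fraction of bases with Phred quality at or below
   ``low_qual_cutoff`` (default 10, inclusive) is strictly greater than
   ``max_low_qual_frac`` (default 20%).

Reads that survive are "clean reads"; the summary also reports clean
nucleotides and the Q20 percentage (fraction of clean-read bases with
Phred quality >= 20).
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "SequencedRead",
    "QcThresholds",
    "QcDecision",
    "DropReason",
    "QcSummary",
    "classify_read",
    "filter_fastq",
    "filter_fastq_file",
    "q20_percent",
    "read_fastq",
    "write_fastq",
]


class DropReason(str, Enum):
    """Why a read was removed, in check order (first match wins)."""

    ADAPTOR = "adaptor"
    UNKNOWN_FRAC = "unknown_frac"
    LOW_QUALITY = "low_quality"


@dataclass(frozen=True)
class SequencedRead:
    """One FASTQ record: identifier, bases over {A,C,G,T,N}, Phred scores."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: bases length {len(self.bases)} != "
                f"qualities length {len(self.qualities)}"
            )
        if len(self.bases) == 0:
            raise ValueError(f"read {self.read_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QcThresholds:
    """Filtering thresholds.

    ``max_unknown_frac`` and ``max_low_qual_frac`` are strict upper bounds
    ("larger than" / "more than"); ``low_qual_cutoff`` is inclusive
    ("quality <= cutoff" counts as low quality).  ``adaptor_seqs`` defaults
    to empty, which makes the adaptor rule inert.
    """

    max_unknown_frac: float = 0.05
    low_qual_cutoff: int = 10
    max_low_qual_frac: float = 0.20
    adaptor_seqs: tuple[str, ...] = ()
    q20_cutoff: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_unknown_frac <= 1.0):
            raise ValueError("max_unknown_frac must be in [0, 1]")
        if not (0.0 <= self.max_low_qual_frac <= 1.0):
            raise ValueError("max_low_qual_frac must be in [0, 1]")
        if self.low_qual_cutoff < 0 or self.q20_cutoff < 0:
            raise ValueError("quality cutoffs must be >= 0")


@dataclass(frozen=True)
class QcDecision:
    keep: bool
    reason: DropReason | None = None


@dataclass
class QcSummary:
    """Library-level QC tallies (clean reads, nucleotides, Q20)."""

    total_reads: int = 0
    clean_reads: int = 0
    clean_nucleotides: int = 0
    q20_percent: float = 0.0
    removed_by_reason: dict[str, int] = field(
        default_factory=lambda: {r.value: 0 for r in DropReason}
    )

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "clean_reads": self.clean_reads,
            "clean_nucleotides": self.clean_nucleotides,
            "q20_percent": round(self.q20_percent, 2),
            "removed_by_reason": dict(self.removed_by_reason),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def classify_read(read: SequencedRead, thresholds: QcThresholds) -> QcDecision:
    """Decide keep-or-drop for one read; first matching rule wins.

    Rule order is adaptor -> unknown fraction -> low quality.
    """
    n = len(read)
    for adaptor in thresholds.adaptor_seqs:
        if adaptor and adaptor in read.bases:
            return QcDecision(False, DropReason.ADAPTOR)
    if read.bases.count("N") / n > thresholds.max_unknown_frac:
        return QcDecision(False, DropReason.UNKNOWN_FRAC)
    n_low = sum(1 for q in read.qualities if q <= thresholds.low_qual_cutoff)
    if n_low / n > thresholds.max_low_qual_frac:
        return QcDecision(False, DropReason.LOW_QUALITY)
    return QcDecision(True)


def filter_fastq(
    reads: Iterable[SequencedRead],
    thresholds: QcThresholds | None = None,
) -> tuple[list[SequencedRead], QcSummary]:
    """Filter a read stream; return kept reads (input order) and a QcSummary."""
    thresholds = thresholds or QcThresholds()
    kept: list[SequencedRead] = []
    removed: Counter[str] = Counter()
    total = 0
    q20_bases = 0
    clean_nt = 0
    for read in reads:
        total += 1
        decision = classify_read(read, thresholds)
        if decision.keep:
            kept.append(read)
            clean_nt += len(read)
            q20_bases += sum(1 for q in read.qualities if q >= thresholds.q20_cutoff)
        else:
            removed[decision.reason.value] += 1
    summary = QcSummary(
        total_reads=total,
        clean_reads=len(kept),
        clean_nucleotides=clean_nt,
        q20_percent=(100.0 * q20_bases / clean_nt) if clean_nt else 0.0,
    )
    for reason, count in removed.items():
        summary.removed_by_reason[reason] = count
    return kept, summary


def q20_percent(reads: Iterable[SequencedRead], cutoff: int = 20) -> float:
    """Percentage of bases with Phred quality >= ``cutoff`` (0 if no bases)."""
    good = 0
    total = 0
    for read in reads:
        total += len(read)
        good += sum(1 for q in read.qualities if q >= cutoff)
    return 100.0 * good / total if total else 0.0


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[SequencedRead]:
    """Stream SequencedRead records from a plain or gzipped FASTQ file.

    ``phred_offset`` selects the quality encoding (33 for modern Sanger /
    Illumina 1.8+, 64 for older Illumina pipelines).
    """
    fmt = {33: "fastq-sanger", 64: "fastq-illumina"}.get(phred_offset)
    if fmt is None:
        raise ValueError(f"unsupported phred offset {phred_offset}; use 33 or 64")
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, fmt)):
            try:
                yield SequencedRead(
                    read_id=rec.id,
                    bases=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{i}: {exc}") from exc


def write_fastq(
    reads: Iterable[SequencedRead], path: str | Path, phred_offset: int = 33
) -> int:
    """Write reads as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as out:
        for read in reads:
            quals = "".join(chr(q + phred_offset) for q in read.qualities)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{quals}\n")
            n += 1
    return n


def filter_fastq_file(
    in_path: str | Path,
    out_path: str | Path,
    thresholds: QcThresholds | None = None,
    phred_offset: int = 33,
) -> QcSummary:
    """Filter a FASTQ file on disk, writing clean reads to ``out_path``."""
    kept, summary = filter_fastq(read_fastq(in_path, phred_offset), thresholds)
    write_fastq(kept, out_path, phred_offset)
    return summary
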
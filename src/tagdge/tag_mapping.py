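"""Tag-to-unigene mapping with a bounded-mismatch Hamming scan.

Short tags are placed on every offset of every reference unigene, on both
strands, and a placement is a hit when its Hamming distance (substitutions
only, no indels; ``N`` always counts as a mismatch) is at most
``max_mismatch`` (default 2).  Reads are then classified the way
tag-profiling mapping tables report them:

* perfect match — at least one 0-mismatch hit;
* <=2 bp mismatch — mapped, but no perfect hit;
* unique match — exactly one hit anywhere in the reference;
* multi-position match — two or more hits (even on the same gene);
* unmapped — no hit.

Only uniquely mapped ("unambiguous") reads contribute to per-gene counts,
which are the count unit of the downstream exact test.  Coverage is the
percentage of a gene's length covered by at least one uniquely mapped tag.

The scan is exhaustive by construction (a vectorised sliding-window
comparison), so its semantics coincide with a position-by-position
brute-force scan on any input.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceGene",
    "TagHit",
    "MappingSummary",
    "GeneMappingProfile",
    "map_tag",
    "map_reads",
    "summarize_mapping",
    "count_unambiguous",
    "gene_coverage",
    "read_reference_fasta",
    "build_gene_profiles",
]

# Base codes chosen so that N (4 in tags, 5 in references) never equals
# anything, making N-vs-anything a mismatch in both directions.
_TAG_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_REF_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ReferenceGene:
    """One assembled unigene used as mapping reference."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TagHit:
    """One placement of a tag on a gene (0-based start, half-open end)."""

    gene_id: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class MappingSummary:
    """Library-level mapping tallies with derived percentages of total reads."""

    total_reads: int = 0
    total_base_pairs: int = 0
    total_mapped: int = 0
    perfect_match: int = 0
    le2_mismatch: int = 0
    unique_match: int = 0
    multi_position: int = 0
    unmapped: int = 0

    def percent(self, count: int) -> float:
        return 100.0 * count / self.total_reads if self.total_reads else 0.0

    @property
    def mapped_percent(self) -> float:
        return self.percent(self.total_mapped)

    def check_invariants(self) -> None:
        assert self.perfect_match + self.le2_mismatch == self.total_mapped
        assert self.unique_match + self.multi_position == self.total_mapped
        assert self.total_mapped + self.unmapped == self.total_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "total_base_pairs": self.total_base_pairs,
            "total_mapped": self.total_mapped,
            "total_mapped_percent": round(self.percent(self.total_mapped), 2),
            "perfect_match": self.perfect_match,
            "perfect_match_percent": round(self.percent(self.perfect_match), 2),
            "le2_mismatch": self.le2_mismatch,
            "le2_mismatch_percent": round(self.percent(self.le2_mismatch), 2),
            "unique_match": self.unique_match,
            "unique_match_percent": round(self.percent(self.unique_match), 2),
            "multi_position": self.multi_position,
            "multi_position_percent": round(self.percent(self.multi_position), 2),
            "unmapped": self.unmapped,
            "unmapped_percent": round(self.percent(self.unmapped), 2),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class GeneMappingProfile:
    """Per-gene unambiguous tag count and coverage intervals."""

    gene_id: str
    gene_length: int
    unambiguous_count: int = 0
    covered_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def coverage_percent(self) -> float:
        return gene_coverage(self.covered_intervals, self.gene_length)


def _encode(seq: str, code: Mapping[str, int]) -> np.ndarray:
    try:
        return np.frombuffer(
            seq.upper().encode().translate(
                bytes(code.get(chr(c), 255) for c in range(256))
            ),
            dtype=np.uint8,
        )
    except KeyError:  # pragma: no cover
        raise ValueError(f"invalid base in sequence {seq!r}")


def _scan_one_strand(
    tag_arr: np.ndarray, gene_arr: np.ndarray, max_mismatch: int
) -> list[tuple[int, int]]:
    """All (start, mismatches) with Hamming distance <= max_mismatch."""
    k = tag_arr.size
    n = gene_arr.size
    if k > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(gene_arr, k)
    mism = np.count_nonzero(windows != tag_arr, axis=1)
    starts = np.nonzero(mism <= max_mismatch)[0]
    return [(int(s), int(mism[s])) for s in starts]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def map_tag(
    tag: str,
    reference: Sequence[ReferenceGene],
    max_mismatch: int = 2,
) -> list[TagHit]:
    """Exhaustively place ``tag`` on both strands of every reference gene.

    Returns every placement whose Hamming distance is <= ``max_mismatch``.
    The reverse-strand start coordinate is on the gene's forward strand
    (0-based offset of the leftmost matched base).
    """
    if not tag:
        raise ValueError("empty tag")
    if not reference:
        raise ValueError("empty reference")
    if any(b not in _TAG_CODE for b in tag.upper()):
        raise ValueError(f"tag contains non-ACGTN base: {tag!r}")
    fwd = _encode(tag, _TAG_CODE)
    rev = _encode(reverse_complement(tag), _TAG_CODE)
    hits: list[TagHit] = []
    for gene in reference:
        gene_arr = _encode(gene.sequence, _REF_CODE)
        for strand, arr in (("+", fwd), ("-", rev)):
            for start, mism in _scan_one_strand(arr, gene_arr, max_mismatch):
                hits.append(TagHit(gene.gene_id, start, strand, mism))
    return hits


def map_reads(
    reads: Iterable[str],
    reference: Sequence[ReferenceGene],
    max_mismatch: int = 2,
) -> list[list[TagHit]]:
    """Map each read sequence; returns one (possibly empty) hit list per read."""
    ref = list(reference)
    return [map_tag(r, ref, max_mismatch) for r in reads]


def summarize_mapping(
    hits_per_read: Sequence[Sequence[TagHit]],
    read_lengths: Sequence[int] | None = None,
) -> MappingSummary:
    """Tally reads into the mapping categories from per-read hit lists."""
    s = MappingSummary(total_reads=len(hits_per_read))
    if read_lengths is not None:
        if len(read_lengths) != len(hits_per_read):
            raise ValueError("read_lengths and hits_per_read length mismatch")
        s.total_base_pairs = int(sum(read_lengths))
    for hits in hits_per_read:
        if not hits:
            s.unmapped += 1
            continue
        s.total_mapped += 1
        if any(h.mismatches == 0 for h in hits):
            s.perfect_match += 1
        else:
            s.le2_mismatch += 1
        if len(hits) == 1:
            s.unique_match += 1
        else:
            s.multi_position += 1
    s.check_invariants()
    return s


def count_unambiguous(
    hits_per_read: Sequence[Sequence[TagHit]],
) -> dict[str, int]:
    """Per-gene counts of uniquely mapped reads (multi-hit reads contribute 0)."""
    counts: Counter[str] = Counter()
    for hits in hits_per_read:
        if len(hits) == 1:
            counts[hits[0].gene_id] += 1
    return dict(counts)


def gene_coverage(
    intervals: Iterable[tuple[int, int]], gene_length: int
) -> float:
    """Percent of the gene covered by the union of half-open intervals."""
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for a, b in ivs:
        if a < 0 or b > gene_length or a > b:
            raise ValueError(f"interval ({a}, {b}) outside [0, {gene_length})")
        if cur_start is None:
            cur_start, cur_end = a, b
        elif a <= cur_end:
            cur_end = max(cur_end, b)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = a, b
    if cur_start is not None:
        covered += cur_end - cur_start
    return 100.0 * covered / gene_length


def build_gene_profiles(
    hits_per_read: Sequence[Sequence[TagHit]],
    reference: Sequence[ReferenceGene],
    tag_lengths: Sequence[int] | None = None,
) -> dict[str, GeneMappingProfile]:
    """Per-gene unambiguous counts plus coverage intervals from unique hits.

    ``tag_lengths`` gives each read's length (needed to turn a hit start
    into a covered interval); if omitted all reads are assumed to span
    from the hit start to the gene end capped at start+49.
    """
    lengths = {g.gene_id: g.length for g in reference}
    profiles = {
        g.gene_id: GeneMappingProfile(g.gene_id, g.length) for g in reference
    }
    for i, hits in enumerate(hits_per_read):
        if len(hits) != 1:
            continue
        hit = hits[0]
        prof = profiles[hit.gene_id]
        prof.unambiguous_count += 1
        span = tag_lengths[i] if tag_lengths is not None else 49
        end = min(hit.start + span, lengths[hit.gene_id])
        prof.covered_intervals.append((hit.start, end))
    return profiles


def read_reference_fasta(path: str | Path) -> list[ReferenceGene]:
    """Load a unigene reference from FASTA; gene ids must be unique."""
    genes = [
        ReferenceGene(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = [g for g, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate gene ids in reference: {dupes}")
    return genes


def profiles_to_frame(profiles: Mapping[str, GeneMappingProfile]) -> pd.DataFrame:
    """Tidy table: gene_id, length, count, coverage_percent."""
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles.values()],
            "length": [p.gene_length for p in profiles.values()],
            "count": [p.unambiguous_count for p in profiles.values()],
            "coverage_percent": [
                round(p.coverage_percent, 2) for p in profiles.values()
            ],
        }
    )
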
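"""RPKM quantification and library-level expression summaries.

RPKM (reads per kilobase of gene model per million mapped reads) removes
the dependence of raw tag counts on gene length and sequencing depth:

    RPKM = 10^9 * C / (N * L)

where C is the gene's unambiguous tag count, N the library's total mapped
reads, and L the gene length in bases.  The choice of N (total mapped vs
unique-only) is exposed because two-library tag studies report both; the
default is total mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneCountRecord", "LibraryProfile", "rpkm", "library_summary"]


@dataclass(frozen=True)
class GeneCountRecord:
    """Per-gene, per-library unambiguous tag count with gene length."""

    gene_id: str
    length: int
    count: int
    library: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"gene {self.gene_id!r}: length must be >= 1")
        if self.count < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative count")


@dataclass
class LibraryProfile:
    """One library: label, total mapped reads N, and its count records."""

    library: str
    total_mapped: int
    records: list[GeneCountRecord]

    def __post_init__(self) -> None:
        if self.total_mapped < 1:
            raise ValueError("total_mapped must be >= 1")


def rpkm(count: float, total_mapped: int, length: int) -> float:
    """Reads per kilobase per million mapped reads: 1e9 * C / (N * L)."""
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    if count < 0:
        raise ValueError("count must be >= 0")
    return 1e9 * count / (total_mapped * length)


def library_summary(
    profile: LibraryProfile,
    coverages: dict[str, float] | None = None,
) -> dict:
    """Expression-table row for one library.

    Averages (length, coverage, RPKM) are taken over *mapped* genes only,
    i.e. genes with at least one unambiguous tag.
    """
    if not profile.records:
        raise ValueError("empty library profile")
    mapped = [r for r in profile.records if r.count > 0]
    if not mapped:
        raise ValueError(f"library {profile.library!r} has no mapped genes")
    rpkms = [rpkm(r.count, profile.total_mapped, r.length) for r in mapped]
    row = {
        "library": profile.library,
        "n_expressed_genes": len(mapped),
        "average_length": sum(r.length for r in mapped) / len(mapped),
        "average_rpkm": sum(rpkms) / len(rpkms),
    }
    if coverages is not None:
        covs = [coverages[r.gene_id] for r in mapped if r.gene_id in coverages]
        row["average_coverage"] = sum(covs) / len(covs) if covs else 0.0
    return row


def add_rpkm_column(
    counts: pd.DataFrame,
    total_mapped: int,
    count_col: str = "count",
    length_col: str = "length",
    out_col: str = "rpkm",
) -> pd.DataFrame:
    """Append an RPKM column to a (gene_id, length, count) table."""
    out = counts.copy()
    out[out_col] = 1e9 * out[count_col] / (total_mapped * out[length_col])
    return out
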
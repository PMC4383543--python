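"""Bundled example data from the hazelnut ovule two-library study.

Small published summary tables from a digital gene expression comparison
of abortive ("empty") and developing ("full") hazelnut (*Corylus
heterophylla*) ovules.  They serve as worked examples and validation
inputs: the hormone-pathway DEG table carries printed per-gene RPKM
values from which log2 fold changes can be recomputed, and the mapping
tallies allow the library-level mapping percentages to be recomputed
from raw read counts.
"""

from __future__ import annotations

import pandas as pd

from tagdge.tag_mapping import MappingSummary

__all__ = ["hazelnut_hormone_degs", "hazelnut_mapping_summaries"]


def hazelnut_hormone_degs() -> pd.DataFrame:
    """Upregulated abscisic-acid / ethylene pathway unigenes (empty vs full).

    Columns: gene_id, length (bases), full_rpkm, empty_rpkm, annotation.
    All genes were called Up in the empty (abortive-ovule) library.
    """
    rows = [
        ("Unigene16189_D2", 854, 0.01, 3.16, "ABA-responsive element binding factor"),
        ("Unigene4733_D2", 380, 5.76, 20.29, "Abscisic acid receptor PYR/PYL family"),
        ("CL7150.Contig2_D2", 1572, 4.56, 14.35, "Protein phosphatase 2C"),
        ("Unigene31203_D2", 388, 0.51, 9.94, "Ethylene-responsive transcription factor 1"),
        ("Unigene15326_D2", 573, 0.70, 9.76, "Ethylene-responsive transcription factor 1 or 2"),
        ("Unigene19967_D2", 991, 1.00, 9.34, "Serine/threonine-protein kinase CTR1"),
        ("Unigene26530_D2", 2242, 19.99, 72.83, "Ethylene-insensitive protein 3"),
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "length", "full_rpkm", "empty_rpkm", "annotation"]
    )


def hazelnut_mapping_summaries() -> dict[str, MappingSummary]:
    """Published mapping tallies for the empty and full libraries.

    Counts only; percentages are derived properties of MappingSummary.
    """
    empty = MappingSummary(
        total_reads=7_456_236,
        total_base_pairs=365_355_564,
        total_mapped=6_565_172,
        perfect_match=5_323_902,
        le2_mismatch=1_241_270,
        unique_match=5_187_188,
        multi_position=1_377_984,
        unmapped=891_064,
    )
    full = MappingSummary(
        total_reads=7_422_728,
        total_base_pairs=363_713_672,
        total_mapped=6_461_102,
        perfect_match=5_029_053,
        le2_mismatch=1_432_049,
        unique_match=5_021_287,
        multi_position=1_439_815,
        unmapped=961_626,
    )
    return {"empty": empty, "full": full}
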
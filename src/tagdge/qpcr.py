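"""Relative qPCR quantification by the 2^-ddCt method.

Each measurement is a set of technical-replicate cycle-threshold (Ct)
values for a target gene and for the beta-actin reference in one
condition.  Normalisation uses replicate means:

    dCt  = mean(Ct_target) - mean(Ct_reference)
    ddCt = dCt(empty) - dCt(full)
    fold = 2^-ddCt

so fold > 1 means the target is more abundant in the empty (abortive)
condition than in the full (developing) condition.  The standard
deviation of the fold is estimated by evaluating 2^-ddCt over all
per-replicate combinations of the four Ct sets.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["QpcrMeasurement", "FoldChangeResult", "delta_ct", "fold_change", "fold_changes_from_table"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Target and reference Ct replicates for one gene in one condition."""

    gene_id: str
    condition: str  # 'empty' or 'full'
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_target) < 2 or len(self.ct_reference) < 2:
            raise ValueError(
                f"{self.gene_id}/{self.condition}: need >= 2 replicates"
            )
        if any(c <= 0 for c in self.ct_target + self.ct_reference):
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    delta_ct_empty: float
    delta_ct_full: float
    delta_delta_ct: float
    fold_change: float
    sd: float


def delta_ct(measurement: QpcrMeasurement) -> float:
    """Reference-normalised Ct: mean(target) - mean(reference)."""
    return statistics.mean(measurement.ct_target) - statistics.mean(
        measurement.ct_reference
    )


def fold_change(empty: QpcrMeasurement, full: QpcrMeasurement) -> FoldChangeResult:
    """2^-ddCt fold change of the empty condition relative to full.

    The sd is the standard deviation of 2^-ddCt over all replicate
    combinations (one target and one reference replicate per condition).
    """
    if empty.gene_id != full.gene_id:
        raise ValueError(
            f"condition mismatch: {empty.gene_id!r} vs {full.gene_id!r}"
        )
    d_empty = delta_ct(empty)
    d_full = delta_ct(full)
    ddct = d_empty - d_full
    folds = [
        2.0 ** -((te - re) - (tf - rf))
        for te, re, tf, rf in itertools.product(
            empty.ct_target, empty.ct_reference, full.ct_target, full.ct_reference
        )
    ]
    sd = statistics.pstdev(folds) if len(folds) > 1 else 0.0
    return FoldChangeResult(
        gene_id=empty.gene_id,
        delta_ct_empty=d_empty,
        delta_ct_full=d_full,
        delta_delta_ct=ddct,
        fold_change=2.0 ** -ddct,
        sd=sd,
    )


def fold_changes_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compute per-gene fold changes from a tidy Ct table.

    Expects columns gene_id, condition ('empty'/'full'), replicate,
    ct_target, ct_reference.  Returns one row per gene with ddCt, fold,
    sd and log2(fold).
    """
    required = {"gene_id", "condition", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for gene_id, group in table.groupby("gene_id", sort=False):
        meas = {}
        for cond, sub in group.groupby("condition"):
            meas[cond] = QpcrMeasurement(
                gene_id=str(gene_id),
                condition=str(cond),
                ct_target=tuple(sub["ct_target"]),
                ct_reference=tuple(sub["ct_reference"]),
            )
        if "empty" not in meas or "full" not in meas:
            raise ValueError(f"gene {gene_id!r}: need both conditions")
        res = fold_change(meas["empty"], meas["full"])
        rows.append(
            {
                "gene_id": res.gene_id,
                "delta_delta_ct": res.delta_delta_ct,
                "fold_change": res.fold_change,
                "sd": res.sd,
                "log2_fold": math.log2(res.fold_change),
            }
        )
    return pd.DataFrame(rows)
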
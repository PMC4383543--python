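"""Exact two-library test for differential tag expression.

The design has no replicates: one pooled library per condition.  Each
gene's tag count is modelled as Poisson — a gene's tags are a tiny
fraction of the library, so the count x in library 1 follows
p(x) = e^-lam lam^x / x! with lam the gene's (latent) true transcript
abundance.  Under the null that the gene is expressed equally in both
libraries, the count y in library 2 given x has the closed form

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

where N1, N2 are the library sizes.  This is the posterior predictive
obtained by integrating the product of the two Poisson likelihoods over a
flat prior on lam, and it equals a negative binomial pmf with x+1
successes and success probability N1/(N1+N2) — a fact used only as an
independent cross-check in the test suite, never here.

The two-sided p-value doubles the smaller tail of the cumulative sum
S = sum_{i<=y} p(i|x): p = 2S if S <= 0.5, else 2(1-S).  Multiple testing
is controlled with Benjamini-Hochberg FDR; a gene is called differentially
expressed when FDR <= 0.001 and |log2(empty RPKM / full RPKM)| >= 1 (both
inclusive).  Near-zero RPKMs are floored at 0.01 before the ratio so the
log is finite.

All factorials are computed via log-gamma and exponentiated only at the
end, so the test is stable for counts up to 10^7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DGEResult",
    "prob_y_given_x",
    "two_sided_pvalue",
    "fdr_adjust",
    "log2_ratio",
    "call_deg",
    "run_dge",
]

RPKM_FLOOR = 0.01
FDR_MAX = 0.001
MIN_ABS_LOG2 = 1.0


@dataclass
class DGEResult:
    """Per-gene outcome of the exact test and significance call."""

    gene_id: str
    p_value: float
    fdr: float
    log2_ratio: float
    direction: str = "NS"  # 'Up', 'Down', or 'NS'
    significant: bool = False


def _validate_counts(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")


def log_prob_y_given_x(x: int, y: int, n1: int, n2: int) -> float:
    """log p(y|x) computed entirely in log space."""
    _validate_counts(x, y, n1, n2)
    r = n2 / n1
    return (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )


def prob_y_given_x(x: int, y: int, n1: int, n2: int) -> float:
    """Null probability of observing y tags in library 2 given x in library 1.

    Evaluates (N2/N1)^y (x+y)!/(x!y!) (1+N2/N1)^-(x+y+1) via log-gamma.
    """
    return float(np.exp(log_prob_y_given_x(x, y, n1, n2)))


def _null_cdf(x: int, y: int, n1: int, n2: int) -> float:
    """S = sum_{i=0}^{y} p(i|x), via a vectorised log-space recurrence.

    log p(i|x) increments by log(r) + log(x+i) - log(i) - log(1+r) from
    i-1 to i, so the whole tail is a cumulative sum plus one logsumexp.
    """
    r = n2 / n1
    log_p0 = -(x + 1) * np.log1p(r)
    if y == 0:
        return float(np.exp(log_p0))
    i = np.arange(1, y + 1)
    steps = np.log(r) + np.log(x + i) - np.log(i) - np.log1p(r)
    log_terms = np.concatenate(([log_p0], log_p0 + np.cumsum(steps)))
    m = log_terms.max()
    return float(np.exp(m) * np.exp(log_terms - m).sum())


def _null_sf(x: int, y: int, n1: int, n2: int) -> float:
    """Upper tail sum_{i>y} p(i|x), summed directly to avoid 1 - S cancellation.

    Successive terms satisfy t_{i+1}/t_i = (x+i+1)/(i+1) * r/(1+r), which
    eventually decays geometrically, so the sum is truncated once the
    remainder is negligible relative to the accumulated value.
    """
    r = n2 / n1
    rho = r / (1.0 + r)
    log_t0 = log_prob_y_given_x(x, y + 1, n1, n2)
    total = 1.0  # in units of t0
    term = 1.0
    i = y + 1
    while True:
        ratio = (x + i + 1) / (i + 1) * rho
        term *= ratio
        total += term
        i += 1
        if ratio < 1.0 and term / (1.0 - ratio) < 1e-16 * total:
            break
    return float(np.exp(log_t0) * total)


def two_sided_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided p-value: 2S if S <= 0.5 else 2(1-S), clamped to [0, 1].

    The 1-S branch is evaluated as the directly-summed upper tail so that
    strongly upregulated genes (y >> x) keep full relative precision
    instead of cancelling against 1.
    """
    _validate_counts(x, y, n1, n2)
    s = _null_cdf(x, y, n1, n2)
    p = 2.0 * s if s <= 0.5 else 2.0 * _null_sf(x, y, n1, n2)
    return float(min(max(p, 0.0), 1.0))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(
    rpkm_empty: float, rpkm_full: float, floor: float = RPKM_FLOOR
) -> float:
    """Signed log2 fold change empty/full, flooring near-zero RPKMs.

    The floor (default 0.01 RPKM) keeps the ratio finite when one library
    has no tags for the gene.
    """
    if rpkm_empty < 0 or rpkm_full < 0:
        raise ValueError("RPKM values must be >= 0")
    return float(np.log2(max(rpkm_empty, floor) / max(rpkm_full, floor)))


def call_deg(
    results: list[DGEResult],
    fdr_max: float = FDR_MAX,
    min_abs_log2: float = MIN_ABS_LOG2,
) -> tuple[list[DGEResult], int, int]:
    """Annotate significance and direction; returns (results, n_up, n_down).

    A gene is significant iff FDR <= fdr_max AND |log2 ratio| >= min_abs_log2
    (both inclusive).  Direction is Up/Down by the sign of the log2 ratio
    among genes passing the fold-change gate, NS otherwise.
    """
    n_up = n_down = 0
    for res in results:
        passes_fold = abs(res.log2_ratio) >= min_abs_log2
        res.significant = res.fdr <= fdr_max and passes_fold
        if res.significant:
            if res.log2_ratio > 0:
                res.direction = "Up"
                n_up += 1
            else:
                res.direction = "Down"
                n_down += 1
        else:
            res.direction = "NS"
    return results, n_up, n_down


def run_dge(
    counts: pd.DataFrame,
    n1: int,
    n2: int,
    fdr_max: float = FDR_MAX,
    min_abs_log2: float = MIN_ABS_LOG2,
    rpkm_floor: float = RPKM_FLOOR,
) -> pd.DataFrame:
    """Full two-library screen on a (gene_id, length, count_full, count_empty) table.

    ``n1`` is the full library's total tag count, ``n2`` the empty
    library's; x = count_full, y = count_empty per the test's convention.
    Returns a table with RPKMs, log2 ratio (empty/full), p-value, BH FDR,
    direction and significance flag, in input gene order.
    """
    required = {"gene_id", "length", "count_full", "count_empty"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    x = counts["count_full"].to_numpy(dtype=int)
    y = counts["count_empty"].to_numpy(dtype=int)
    lengths = counts["length"].to_numpy(dtype=int)
    pvals = np.array(
        [two_sided_pvalue(int(xi), int(yi), n1, n2) for xi, yi in zip(x, y)]
    )
    fdrs = fdr_adjust(pvals)
    rpkm_full = 1e9 * x / (n1 * lengths.astype(float))
    rpkm_empty = 1e9 * y / (n2 * lengths.astype(float))
    ratios = np.log2(
        np.maximum(rpkm_empty, rpkm_floor) / np.maximum(rpkm_full, rpkm_floor)
    )
    results = [
        DGEResult(g, float(p), float(f), float(r))
        for g, p, f, r in zip(counts["gene_id"], pvals, fdrs, ratios)
    ]
    call_deg(results, fdr_max, min_abs_log2)
    return pd.DataFrame(
        {
            "gene_id": counts["gene_id"].to_numpy(),
            "length": lengths,
            "count_full": x,
            "count_empty": y,
            "full_rpkm": rpkm_full,
            "empty_rpkm": rpkm_empty,
            "log2_ratio": ratios,
            "direction": [r.direction for r in results],
            "p_value": pvals,
            "fdr": fdrs,
            "significant": [r.significant for r in results],
        }
    )


def format_dge_table(table: pd.DataFrame) -> pd.DataFrame:
    """Output formatting: RPKM/log2 to 2 dp, p/FDR to 3 significant digits."""
    out = table.copy()
    for col in ("full_rpkm", "empty_rpkm", "log2_ratio"):
        out[col] = out[col].round(2)
    for col in ("p_value", "fdr"):
        out[col] = out[col].map(lambda v: float(f"{v:.3g}"))
    return out
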
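"""Seeded generators for every input the pipeline consumes.

Three generators, each a pure function of (config, seed) with full
ground-truth bookkeeping so downstream results can be checked against
planted truth:

* :func:`simulate_counts` — two-library per-gene tag-count tables with a
  planted fraction of differentially expressed genes at chosen log2 fold
  changes, counts drawn Poisson around gene-specific rates (the model the
  exact test assumes).  A negative-binomial option adds extra-Poisson
  dispersion to probe robustness.
* :func:`simulate_fastq` — short reads drawn from a unigene reference on
  both strands with planted defects (adaptor insertions, high-N reads,
  low-quality tails) at configured rates, plus planted substitution
  mismatches for mapping tests.
* :func:`simulate_qpcr` — Ct triplicates whose ddCt encodes a chosen true
  fold change, with Gaussian replicate noise.

Defect classes are planted exclusively (a read gets at most one defect)
and are constructed to coincide exactly with the QC rules, so the
generator's bookkeeping is a valid oracle for the filter's tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tagdge.tag_mapping import ReferenceGene, reverse_complement
from tagdge.read_qc import SequencedRead

__all__ = [
    "CountSimConfig",
    "simulate_counts",
    "simulate_fastq",
    "simulate_qpcr",
    "random_reference",
    "DEFAULT_ADAPTOR",
]

_BASES = np.array(list("ACGT"))

# Standard Illumina universal adaptor prefix; any fixed motif works for QC.
DEFAULT_ADAPTOR = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class CountSimConfig:
    """Two-library count simulation settings.

    ``n1``/``n2`` are the library totals used as test denominators (the
    simulated genes are a subset of a library, so gene counts need not sum
    to them).  Baseline mean counts (library 1 scale) are drawn log-uniform
    over ``mean_count_range``; DE genes get the configured |log2 fold
    change| with direction split evenly up/down.  ``dispersion`` > 0
    switches counts to negative binomial with that extra-Poisson
    dispersion (variance = mu + dispersion * mu^2).
    """

    n_genes: int = 1000
    n1: int = 1_000_000
    n2: int = 1_000_000
    de_fraction: float = 0.1
    log2fc: float = 3.0
    mean_count_range: tuple[float, float] = (20.0, 200.0)
    gene_length_range: tuple[int, int] = (200, 3000)
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_genes < 1:
            errors.append("n_genes must be >= 1")
        if self.n1 < 1 or self.n2 < 1:
            errors.append("n1 and n2 must be >= 1")
        if not (0.0 <= self.de_fraction <= 1.0):
            errors.append("de_fraction must be in [0, 1]")
        if self.mean_count_range[0] <= 0 or (
            self.mean_count_range[1] < self.mean_count_range[0]
        ):
            errors.append("mean_count_range must be positive and ordered")
        if self.gene_length_range[0] < 1 or (
            self.gene_length_range[1] < self.gene_length_range[0]
        ):
            errors.append("gene_length_range must be >= 1 and ordered")
        if self.dispersion < 0:
            errors.append("dispersion must be >= 0")
        if errors:
            raise ValueError("; ".join(errors))


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    # NB via Poisson-gamma mixture: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mu / shape))


def simulate_counts(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate two-library gene counts with planted differential expression.

    Returns ``(counts, truth)``: ``counts`` has columns gene_id, length,
    count_full, count_empty (full = library 1, empty = library 2); ``truth``
    records each gene's per-tag rates, DE flag and true log2 fold change
    (empty relative to full).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    lo, hi = config.mean_count_range
    mu_full = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    n_de = int(round(config.de_fraction * n))
    is_de = np.zeros(n, dtype=bool)
    true_lfc = np.zeros(n)
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        is_de[de_idx] = True
        signs = np.ones(n_de)
        signs[1::2] = -1.0  # alternate up/down among DE genes
        true_lfc[de_idx] = signs * abs(config.log2fc)
    depth_ratio = config.n2 / config.n1
    mu_empty = mu_full * depth_ratio * np.exp2(true_lfc)
    x = _draw_counts(rng, mu_full, config.dispersion)
    y = _draw_counts(rng, mu_empty, config.dispersion)
    counts = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length": lengths.astype(int),
            "count_full": x.astype(int),
            "count_empty": y.astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "lambda_full": mu_full / config.n1,
            "lambda_empty": mu_empty / config.n2,
            "is_de": is_de,
            "true_log2fc": true_lfc,
        }
    )
    return counts, truth


def random_reference(
    n_genes: int,
    length_range: tuple[int, int] = (200, 3000),
    seed: int = 0,
    prefix: str = "unigene",
) -> list[ReferenceGene]:
    """Random unigene reference with uniform base composition."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        genes.append(ReferenceGene(f"{prefix}{i:04d}", seq))
    return genes


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_fastq(
    reference: list[ReferenceGene],
    n_reads: int,
    adaptor_rate: float = 0.0,
    high_n_rate: float = 0.0,
    low_quality_rate: float = 0.0,
    mismatch_probs: tuple[float, float, float] = (1.0, 0.0, 0.0),
    read_length: int = 49,
    adaptor_seq: str = DEFAULT_ADAPTOR,
    seed: int = 0,
) -> tuple[list[SequencedRead], pd.DataFrame]:
    """Draw reads from the reference with planted QC defects and mismatches.

    Each read gets at most one defect class (adaptor / high_n /
    low_quality / clean), drawn with the configured rates.  Clean-read
    qualities are uniform in [30, 40] (no base at or below the
    low-quality cutoff); high-N reads carry 10% N bases (> the 5% rule);
    low-quality reads have 30% of bases at quality <= 10 (> the 20% rule).
    ``mismatch_probs`` gives the distribution of planted substitution
    counts (0, 1, 2) relative to the source position.

    Returns the reads plus a ground-truth table with one row per read:
    source gene, offset, strand, planted mismatches, defect class.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    rates = (adaptor_rate, high_n_rate, low_quality_rate)
    if any(r < 0 or r > 1 for r in rates) or sum(rates) > 1.0 + 1e-12:
        raise ValueError("defect rates must be in [0, 1] and sum to <= 1")
    if abs(sum(mismatch_probs) - 1.0) > 1e-9:
        raise ValueError("mismatch_probs must sum to 1")
    rng = np.random.default_rng(seed)
    usable = [g for g in reference if g.length >= read_length]
    if not usable and n_reads > 0:
        raise ValueError(f"no reference gene is >= read length {read_length}")
    reads: list[SequencedRead] = []
    truth_rows = []
    classes = ["adaptor", "high_n", "low_quality", "clean"]
    probs = list(rates) + [1.0 - sum(rates)]
    for i in range(n_reads):
        gene = usable[rng.integers(0, len(usable))]
        offset = int(rng.integers(0, gene.length - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = gene.sequence[offset : offset + read_length]
        if strand == "-":
            fragment = reverse_complement(fragment)
        n_mism = int(rng.choice(3, p=mismatch_probs))
        bases = _mutate(rng, fragment, n_mism)
        quals = rng.integers(30, 41, size=read_length)
        defect = classes[int(rng.choice(4, p=probs))]
        if defect == "adaptor":
            # splice the adaptor over the 3' end (read-through emulation)
            bases = bases[: read_length - len(adaptor_seq)] + adaptor_seq
        elif defect == "high_n":
            n_n = max(int(np.ceil(0.10 * read_length)), 1)
            pos = rng.choice(read_length, size=n_n, replace=False)
            arr = np.array(list(bases))
            arr[pos] = "N"
            bases = "".join(arr)
        elif defect == "low_quality":
            n_low = max(int(np.ceil(0.30 * read_length)), 1)
            pos = rng.choice(read_length, size=n_low, replace=False)
            quals = quals.copy()
            quals[pos] = rng.integers(2, 11, size=n_low)
        reads.append(
            SequencedRead(f"read{i:06d}", bases, tuple(int(q) for q in quals))
        )
        truth_rows.append(
            {
                "read_id": f"read{i:06d}",
                "gene_id": gene.gene_id,
                "offset": offset,
                "strand": strand,
                "planted_mismatches": n_mism,
                "defect": defect,
            }
        )
    return reads, pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "gene_id", "offset", "strand", "planted_mismatches", "defect",
        ],
    )


def simulate_qpcr(
    true_folds: dict[str, float],
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    base_reference_ct: float = 20.0,
    base_target_ct: float = 25.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Ct replicate tables encoding chosen true fold changes.

    The full-condition target sits at ``base_target_ct``; the empty
    condition's target Ct is shifted by -log2(fold) so that
    ddCt = -log2(fold) exactly before noise.  Gaussian noise of
    ``noise_sd`` cycles is added independently to every replicate Ct.

    Returns a tidy Ct table (gene_id, condition, replicate, ct_target,
    ct_reference) and a truth table (gene_id, true_fold, true_ddct).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id, fold in true_folds.items():
        shift = -np.log2(fold)
        for condition, target_mean in (
            ("empty", base_target_ct + shift),
            ("full", base_target_ct),
        ):
            for rep in range(n_replicates):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "condition": condition,
                        "replicate": rep + 1,
                        "ct_target": target_mean + rng.normal(0.0, noise_sd),
                        "ct_reference": base_reference_ct
                        + rng.normal(0.0, noise_sd),
                    }
                )
    truth = pd.DataFrame(
        {
            "gene_id": list(true_folds),
            "true_fold": list(true_folds.values()),
            "true_ddct": [-np.log2(f) for f in true_folds.values()],
        }
    )
    return pd.DataFrame(rows), truth
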
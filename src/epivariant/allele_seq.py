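"""Allele-specific H3K27me3 quantification at SNPs in F1 hybrids.

At every SNP distinguishing the parental accessions, ChIP reads in the
hybrid are partitioned into those supporting the A (Col) allele, the B
(Ler) allele, or neither (sequencing errors, excluded by the biallelic
filter).  SNPs with fewer than three biallelic reads are excluded.  The
Col-allele frequency reads_A / (reads_A + reads_B) is 0.5 at a gene
methylated on both alleles and 0 at a gene methylated only on the B
allele; class medians are compared with a resampling null that draws
equally sized SNP sets from the common-target pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleFrequencyResult",
    "PermutationTestResult",
    "filter_snps",
    "allele_frequency",
    "allele_permutation_test",
]

_COUNT_COLS = ("reads_A", "reads_B", "reads_other")


def _check_table(table: pd.DataFrame) -> None:
    missing = set(_COUNT_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"allele count table missing columns {sorted(missing)}")
    for c in _COUNT_COLS:
        if (table[c] < 0).any():
            raise ValueError(f"negative counts in {c}")


def filter_snps(table: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Keep SNPs with at least ``min_reads`` reads supporting a parental
    allele; non-parental reads are excluded from consideration entirely
    (they count toward neither allele nor the read threshold)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    _check_table(table)
    keep = (table["reads_A"] + table["reads_B"]) >= min_reads
    return table[keep].reset_index(drop=True)


@dataclass
class AlleleFrequencyResult:
    """Per-SNP Col-allele (A-allele) frequencies grouped by target class."""

    per_snp: pd.DataFrame  # filtered table + freq_A + target_class
    class_freqs: dict[str, np.ndarray]
    medians: dict[str, float | None]
    empty_classes: list[str] = field(default_factory=list)


def allele_frequency(
    filtered: pd.DataFrame,
    target_classes: Mapping[str, str],
) -> AlleleFrequencyResult:
    """Per-SNP A-allele frequencies and per-class medians.

    ``target_classes`` maps gene_id to a class label (typically
    ``specific`` for accession-B-specific targets and ``common`` for
    shared targets); SNPs in unmapped genes or intergenic space are
    dropped.  A class with no SNPs is flagged empty and gets no median.
    """
    _check_table(filtered)
    if "gene_id" not in filtered.columns:
        raise ValueError("filtered table needs a gene_id column")
    out = filtered.copy()
    out["target_class"] = [
        target_classes.get(g) if g else None for g in out["gene_id"]
    ]
    out = out[out["target_class"].notna()].reset_index(drop=True)
    denom = out["reads_A"] + out["reads_B"]
    out["freq_A"] = out["reads_A"] / denom
    class_freqs: dict[str, np.ndarray] = {}
    medians: dict[str, float | None] = {}
    empty = []
    for cls in sorted(set(target_classes.values())):
        freqs = out.loc[out["target_class"] == cls, "freq_A"].to_numpy()
        class_freqs[cls] = freqs
        if len(freqs):
            medians[cls] = float(np.median(freqs))
        else:
            medians[cls] = None
            empty.append(cls)
    return AlleleFrequencyResult(out, class_freqs, medians, empty)


@dataclass
class PermutationTestResult:
    p_value: float
    observed: float
    n_draws: int
    null_statistics: np.ndarray


def allele_permutation_test(
    specific_freqs: Sequence[float],
    common_snp_pool: Sequence[float],
    n_draws: int = 100_000,
    seed: int = 0,
    *,
    statistic: str = "median",
) -> PermutationTestResult:
    """One-sided resampling test for unusually low A-allele frequencies.

    Each draw samples ``len(specific_freqs)`` SNP frequencies without
    replacement from the common-target pool and records the summary
    statistic; the p-value is the add-one estimator
    ``(1 + #draws with statistic <= observed) / (n_draws + 1)``, which is
    never exactly zero under finite resampling.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    specific = np.asarray(specific_freqs, dtype=float)
    pool = np.asarray(common_snp_pool, dtype=float)
    k = len(specific)
    if k == 0:
        raise ValueError("no SNPs in the specific class")
    if len(pool) < k:
        raise ValueError(
            f"common pool ({len(pool)} SNPs) smaller than sample size ({k})"
        )
    stat = {"median": np.median, "mean": np.mean}.get(statistic)
    if stat is None:
        raise ValueError("statistic must be 'median' or 'mean'")
    observed = float(stat(specific))
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    chunk = max(1, min(n_draws, int(2e7) // max(len(pool), 1)))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        # vectorised sampling without replacement: top-k of random keys
        keys = rng.random((b, len(pool)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done : done + b] = stat(pool[idx], axis=1)
        done += b
    p = (1 + int((null <= observed).sum())) / (n_draws + 1)
    return PermutationTestResult(p, observed, n_draws, null)
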
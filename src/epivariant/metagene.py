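"""Average chromatin profiles over gene bodies and flanks.

Each gene contributes 30 bins: ten 500 bp bins upstream of the 5' end,
ten body bins each spanning a tenth of the gene length, and ten 500 bp
bins downstream of the 3' end, always ordered 5'-to-3' in gene
orientation.  Three profile modes mirror how different data types are
summarised: the mean signal of a quantitative track, the fraction of
genes whose bin touches a binary region set, and normalized feature
counts per kb (used for siRNA read counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneModel, RegionSet

__all__ = ["MetageneProfile", "gene_bins", "profile"]

MODES = ("mean_signal", "fraction_overlap", "normalized_count")


@dataclass
class MetageneProfile:
    gene_set: str
    mark: str
    mode: str
    values: np.ndarray  # length 3 * body_bins
    n_genes: int
    n_contributing: np.ndarray  # genes contributing per bin

    def to_frame(self) -> pd.DataFrame:
        n = len(self.values)
        body = n // 3
        rel = (
            [f"up{body - i}" for i in range(body)]
            + [f"body{i + 1}" for i in range(body)]
            + [f"down{i + 1}" for i in range(body)]
        )
        return pd.DataFrame(
            {
                "bin_index": np.arange(n),
                "rel_position": rel,
                "value": self.values,
                "n_genes": self.n_contributing,
            }
        )


def gene_bins(
    gene: GeneModel,
    *,
    body_bins: int = 10,
    flank_bin_bp: int = 500,
    chrom_length: int | None = None,
) -> list[tuple[int, int] | None]:
    """The 30 bin spans of a gene, 5'-to-3', as (start, end) tuples.

    Body bins split the gene into ``body_bins`` near-equal tenths with the
    remainder distributed to the 3'-most bins; flank bins are fixed-width.
    Flank bins that run off the chromosome (or past the origin) are
    returned as ``None`` and excluded from that gene's contribution.
    """
    iv = gene.interval
    L = len(iv)
    if L < body_bins:
        raise ValueError(f"gene {gene.gene_id} shorter than {body_bins} bp")
    if iv.strand not in ("+", "-"):
        raise ValueError("metagene requires stranded genes")
    base = L // body_bins
    extra = L % body_bins
    # 5'-to-3' body bin lengths; remainder goes to the 3'-most bins
    lengths = [base + (1 if i >= body_bins - extra else 0) for i in range(body_bins)]

    minus = iv.strand == "-"
    body: list[tuple[int, int]] = []
    if not minus:
        pos = iv.start
        for ln in lengths:
            body.append((pos, pos + ln))
            pos += ln
    else:
        pos = iv.end
        for ln in lengths:
            body.append((pos - ln, pos))
            pos -= ln

    def flank(anchor: int, direction: int) -> list[tuple[int, int] | None]:
        """Ten bins walking away from ``anchor``; index 0 is farthest."""
        bins: list[tuple[int, int] | None] = []
        for i in range(body_bins, 0, -1):
            if direction < 0:
                s, e = anchor - i * flank_bin_bp, anchor - (i - 1) * flank_bin_bp
            else:
                s, e = anchor + (i - 1) * flank_bin_bp, anchor + i * flank_bin_bp
            out_of_range = s < 0 or (chrom_length is not None and e > chrom_length)
            bins.append(None if out_of_range else (s, e))
        return bins

    # flank() walks away from the gene (farthest bin first), which is the
    # 5'-to-3' order upstream but must be reversed downstream
    if not minus:
        upstream = flank(iv.start, -1)
        downstream = flank(iv.end, +1)[::-1]
    else:
        upstream = flank(iv.end, +1)
        downstream = flank(iv.start, -1)[::-1]
    return upstream + body + downstream


class _TrackIndex:
    """Sorted per-chromosome interval/value arrays for O(log n) bin sums."""

    def __init__(self, track: pd.DataFrame | RegionSet):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if isinstance(track, RegionSet):
            rows: dict[str, list[tuple[int, int, float]]] = {}
            for iv in track:
                rows.setdefault(iv.chrom, []).append((iv.start, iv.end, 1.0))
            items = rows.items()
        else:
            items = (
                (str(c), list(zip(g["start"], g["end"], g["value"])))
                for c, g in track.groupby("chrom")
            )
        for chrom, lst in items:
            lst = sorted(lst)
            self.by_chrom[chrom] = (
                np.array([x[0] for x in lst], dtype=np.int64),
                np.array([x[1] for x in lst], dtype=np.int64),
                np.array([x[2] for x in lst], dtype=float),
            )

    def overlapping(self, chrom: str, s: int, e: int):
        arr = self.by_chrom.get(chrom)
        if arr is None:
            return None
        starts, ends, values = arr
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        if hi <= lo:
            return None
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def weighted_sum(self, chrom: str, s: int, e: int) -> float:
        """Sum of value * overlap_bp over track intervals (absent = 0)."""
        hit = self.overlapping(chrom, s, e)
        if hit is None:
            return 0.0
        hs, he, hv = hit
        ov = np.minimum(he, e) - np.maximum(hs, s)
        return float((hv * np.maximum(ov, 0)).sum())

    def feature_count(self, chrom: str, s: int, e: int) -> float:
        """Sum of feature values apportioned by the fraction of each
        feature overlapping the bin."""
        hit = self.overlapping(chrom, s, e)
        if hit is None:
            return 0.0
        hs, he, hv = hit
        ov = np.maximum(np.minimum(he, e) - np.maximum(hs, s), 0)
        return float((hv * ov / (he - hs)).sum())

    def touches(self, chrom: str, s: int, e: int) -> bool:
        return self.overlapping(chrom, s, e) is not None


def profile(
    gene_set: list[GeneModel],
    track: pd.DataFrame | RegionSet,
    mode: str,
    *,
    body_bins: int = 10,
    flank_bin_bp: int = 500,
    chrom_lengths: dict[str, int] | None = None,
    gene_set_label: str = "",
    mark_label: str = "",
) -> MetageneProfile:
    """Average a chromatin track over a gene set in metagene coordinates.

    mean_signal: per bin, the mean over genes of the length-weighted mean
    track value within the bin (uncovered bases count as 0).
    fraction_overlap: the fraction of genes whose bin overlaps the region
    set by at least one bp.  normalized_count: the mean feature count per
    kb, divided by the grand mean over all bins so the profile is
    unit-free.  Bin means run over contributing genes only (flank bins
    running off a chromosome are excluded for that gene).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    index = _TrackIndex(track)
    n_bins = 3 * body_bins
    sums = np.zeros(n_bins)
    contributing = np.zeros(n_bins, dtype=int)
    for gene in gene_set:
        chrom = gene.interval.chrom
        clen = (chrom_lengths or {}).get(chrom)
        bins = gene_bins(
            gene, body_bins=body_bins, flank_bin_bp=flank_bin_bp, chrom_length=clen
        )
        for bi, span in enumerate(bins):
            if span is None:
                continue
            s, e = span
            contributing[bi] += 1
            if mode == "mean_signal":
                sums[bi] += index.weighted_sum(chrom, s, e) / (e - s)
            elif mode == "fraction_overlap":
                sums[bi] += 1.0 if index.touches(chrom, s, e) else 0.0
            else:
                sums[bi] += index.feature_count(chrom, s, e) / ((e - s) / 1000.0)
    with np.errstate(invalid="ignore"):
        values = np.where(contributing > 0, sums / np.maximum(contributing, 1), np.nan)
    if mode == "normalized_count":
        grand = np.nanmean(values)
        if grand > 0:
            values = values / grand
    return MetageneProfile(
        gene_set_label, mark_label, mode, values, len(gene_set), contributing
    )
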
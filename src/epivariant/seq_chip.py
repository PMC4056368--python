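"""Hybrid ChIP-seq target calling from read-start positions.

The sequencing stage starts after alignment: read starts are
deduplicated per (chrom, position, strand) to remove PCR artifacts,
enriched islands are called against a chromatin-input background with a
Poisson window test, islands closer than 200 bp are merged, and a gene is
a hybrid target when islands cover at least 20% of its body and at least
200 bp, or at least 800 bp for very long genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .core_io import (
    GeneModel,
    GenomicInterval,
    RegionSet,
    get_logger,
    merge_intervals,
)
from .tiling_chip import TargetCallSet, gene_coverage

__all__ = [
    "ReadStartTrack",
    "IslandSet",
    "deduplicate",
    "call_islands",
    "call_hybrid_targets",
]

log = get_logger(__name__)


@dataclass
class ReadStartTrack:
    """Read counts keyed by (chrom, pos, strand)."""

    counts: pd.DataFrame  # columns chrom, pos, strand, count

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand", "count"}
        if set(self.counts.columns) < required:
            raise ValueError(f"track needs columns {sorted(required)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative read counts")
        dup = self.counts.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            raise ValueError("track has duplicate (chrom, pos, strand) keys")

    @property
    def library_size(self) -> int:
        return int(self.counts["count"].sum())

    @classmethod
    def from_bed(cls, path: str) -> "ReadStartTrack":
        """Read placements from BED (start used as the read start) or from a
        4-column chrom/pos/strand/count table."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] >= 6:  # BED6: aggregate read starts
            out = (
                df.rename(columns={0: "chrom", 1: "pos", 5: "strand"})[
                    ["chrom", "pos", "strand"]
                ]
                .groupby(["chrom", "pos", "strand"], as_index=False)
                .size()
                .rename(columns={"size": "count"})
            )
        elif df.shape[1] == 4:
            out = df.rename(columns={0: "chrom", 1: "pos", 2: "strand", 3: "count"})
        else:
            raise ValueError("expected BED6 or chrom/pos/strand/count")
        return cls(out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True))


def deduplicate(track: ReadStartTrack) -> ReadStartTrack:
    """Cap every (chrom, pos, strand) key at one read (PCR-duplicate
    removal, keeping one copy).  Idempotent."""
    out = track.counts.copy()
    out["count"] = np.minimum(out["count"].to_numpy(), 1)
    return ReadStartTrack(out)


@dataclass
class IslandSet:
    regions: RegionSet
    table: pd.DataFrame  # chrom, start, end, chip_reads, expected, p_value

    def __len__(self) -> int:
        return len(self.regions)


def _window_counts(track: ReadStartTrack, chrom: str, n_windows: int, wb: int) -> np.ndarray:
    sel = track.counts[track.counts["chrom"] == chrom]
    win = (sel["pos"].to_numpy() // wb).astype(np.int64)
    ok = (win >= 0) & (win < n_windows)
    return np.bincount(win[ok], weights=sel["count"].to_numpy()[ok], minlength=n_windows)


def call_islands(
    chip: ReadStartTrack,
    background: ReadStartTrack,
    chrom_lengths: dict[str, int],
    *,
    window_bp: int = 200,
    gap_windows: int = 1,
    p_threshold: float = 0.01,
    fixed_scale: tuple[float, float] | None = None,
) -> IslandSet:
    """Poisson-window island calling against an input background.

    The genome is tiled into ``window_bp`` windows; a window is eligible
    when the upper-tail Poisson probability of its ChIP count against the
    library-size-scaled input count (floored at the genome-average ChIP
    rate) is at most ``p_threshold``.  Eligible windows are joined across
    at most ``gap_windows`` ineligible windows and the joined island is
    retained when its aggregate count passes the same Poisson test.
    """
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    total_windows = sum(-(-L // window_bp) for L in chrom_lengths.values())
    if fixed_scale is not None:
        # caller-supplied (ratio, floor): keeps the background model fixed,
        # under which island calling is monotone in chip counts
        ratio, floor = fixed_scale
    else:
        if background.library_size == 0:
            warnings.warn("empty input track: using genome-average rate everywhere")
            ratio = 0.0
        else:
            ratio = chip.library_size / background.library_size
        floor = chip.library_size / max(total_windows, 1)
    rows = []
    intervals = []
    for chrom, L in chrom_lengths.items():
        n_win = -(-L // window_bp)
        chip_w = _window_counts(chip, chrom, n_win, window_bp)
        bg_w = _window_counts(background, chrom, n_win, window_bp)
        lam = np.maximum(bg_w * ratio, floor)
        pvals = poisson.sf(chip_w - 1, lam)
        eligible = np.flatnonzero((pvals <= p_threshold) & (chip_w > 0))
        if len(eligible) == 0:
            continue
        # join eligible windows tolerating small gaps
        breaks = np.flatnonzero(np.diff(eligible) > gap_windows + 1)
        groups = np.split(eligible, breaks + 1)
        for grp in groups:
            w0, w1 = int(grp[0]), int(grp[-1])
            chip_total = float(chip_w[w0 : w1 + 1].sum())
            lam_total = float(lam[w0 : w1 + 1].sum())
            p_island = float(poisson.sf(chip_total - 1, lam_total))
            if p_island <= p_threshold:
                start, end = w0 * window_bp, min((w1 + 1) * window_bp, L)
                intervals.append(GenomicInterval(chrom, start, end))
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "chip_reads": chip_total,
                        "expected": lam_total,
                        "p_value": p_island,
                    }
                )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "chip_reads", "expected", "p_value"]
    )
    regions = RegionSet("islands", intervals)
    log.info("called %d islands over %d windows", len(regions), total_windows)
    return IslandSet(regions, table)


def call_hybrid_targets(
    islands: IslandSet,
    genes: list[GeneModel],
    *,
    merge_gap: int = 200,
    rule: tuple[float, int, int] = (0.20, 200, 800),
    sample: str = "",
) -> TargetCallSet:
    """Merge islands separated by gaps smaller than 200 bp and call genes
    under the hybrid (sequencing) gene rule."""
    merged = merge_intervals(list(islands.regions), merge_gap, label=f"{sample}_peaks")
    calls = gene_coverage(merged, genes, rule, sample)
    log.info("%s: %d merged peaks -> %d hybrid targets", sample, len(merged), len(calls.target_ids))
    return calls
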
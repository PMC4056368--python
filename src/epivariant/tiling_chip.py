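"""Tiling-array H3K27me3 target calling.

The array stage goes: two-colour log-ratios are loess-normalized within
arrays and scale-normalized between arrays; positive probes are called
against a null threshold estimated from the mode of the smoothed probe
distribution; positive probes closer than 300 bp are combined into
ChIP-enriched regions; and a gene is a target when the regions cover at
least 30% of its body and at least 300 bp, or at least 1,000 bp for very
long genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomicInterval,
    RegionSet,
    get_logger,
    merge_intervals,
    overlap_bp,
)

__all__ = [
    "SignalMatrix",
    "TargetCallSet",
    "TargetComparison",
    "normalize",
    "call_positive_probes",
    "call_gene_targets",
    "gene_coverage",
    "apply_gene_rule",
    "compare_target_sets",
]

log = get_logger(__name__)


@dataclass
class SignalMatrix:
    """Per-probe log2 ratios across replicates and accessions.

    ``probes`` is indexed by probe_id with columns chrom/start/end (genome-A
    frame); ``M`` holds log2 ratios with a (accession, replicate)
    MultiIndex on the columns; ``A`` optionally holds the matching mean
    log-intensities used by loess normalization.
    """

    probes: pd.DataFrame
    M: pd.DataFrame
    A: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.probes.index.equals(self.M.index):
            raise ValueError("probes and M must share an index")
        if not np.isfinite(self.M.to_numpy()).all():
            raise ValueError("signal matrix contains non-finite values")
        if self.A is not None and self.A.shape != self.M.shape:
            raise ValueError("A must match M in shape")

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.M.columns.get_level_values(0)))

    def probe_interval(self, probe_id: str) -> GenomicInterval:
        row = self.probes.loc[probe_id]
        return GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]))


@dataclass
class TargetCallSet:
    """Per-gene H3K27me3 target status with coverage evidence."""

    sample: str
    table: pd.DataFrame  # index gene_id: is_target, covered_bp, covered_frac, n_probes
    regions: RegionSet | None = None

    @property
    def target_ids(self) -> set[str]:
        return set(self.table.index[self.table["is_target"]])


@dataclass
class TargetComparison:
    shared: set[str]
    a_only: set[str]
    b_only: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "A_only": len(self.a_only),
            "B_only": len(self.b_only),
        }


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def normalize(
    raw: SignalMatrix, *, loess_frac: float = 0.15, min_probes: int = 20
) -> SignalMatrix:
    """Within-array loess on M-vs-A followed by between-array scaling.

    Each array's intensity-dependent trend is estimated by a loess curve of
    log-ratio against mean log-intensity and subtracted; afterwards every
    array is rescaled so its median absolute deviation equals the geometric
    mean of all arrays' MADs.  Requires at least two arrays and
    ``min_probes`` probes for a stable loess fit.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if raw.M.shape[1] < 2:
        raise ValueError("normalization requires at least 2 arrays")
    if len(raw.M) < min_probes:
        raise ValueError(
            f"refusing to fit loess with {len(raw.M)} probes (< {min_probes})"
        )
    M = raw.M.to_numpy(dtype=float).copy()
    if raw.A is not None:
        A = raw.A.to_numpy(dtype=float)
        for j in range(M.shape[1]):
            span = float(np.ptp(A[:, j]))
            fitted = lowess(
                M[:, j],
                A[:, j],
                frac=loess_frac,
                it=2,
                delta=0.01 * span,
                return_sorted=False,
            )
            M[:, j] = M[:, j] - fitted
    mads = np.array([_mad(M[:, j]) for j in range(M.shape[1])])
    if (mads > 0).all():
        target = float(np.exp(np.mean(np.log(mads))))
        M = M * (target / mads)
    else:
        warnings.warn("zero MAD column; between-array scaling skipped")
    out_M = pd.DataFrame(M, index=raw.M.index, columns=raw.M.columns)
    return SignalMatrix(raw.probes, out_M, raw.A)


# ---------------------------------------------------------------------------
# Positive probes
# ---------------------------------------------------------------------------


def _running_median(
    values: np.ndarray, centers: np.ndarray, window_probes: int, window_bp: int
) -> np.ndarray:
    """Median over up to ``window_probes`` probes centred on each probe,
    restricted to neighbours within ``window_bp`` of its centre."""
    half = window_probes // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = np.abs(centers[lo:hi] - centers[i]) <= window_bp / 2
        out[i] = np.median(values[lo:hi][sel])
    return out


def _null_threshold(values: np.ndarray, z: float) -> float:
    """Mode of the value distribution plus ``z`` left-half standard
    deviations (the left half mirrored about the mode estimates the null
    spread without contamination from enriched probes)."""
    lo, hi = np.percentile(values, [0.5, 99.5])
    hist, edges = np.histogram(values, bins=200, range=(lo, hi))
    mode = float((edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2)
    left = values[values <= mode]
    if len(left) < 2:
        raise ValueError("cannot estimate null spread: no mass left of mode")
    sd_left = float(np.sqrt(np.mean((left - mode) ** 2)))
    return mode + z * sd_left


def call_positive_probes(
    normalized: SignalMatrix,
    sample: str,
    *,
    z: float = 4.0,
    min_run: int = 3,
    window_probes: int = 3,
    window_bp: int = 600,
    replicate_mode: str = "averaged",
) -> set[str]:
    """Probe ids whose smoothed signal exceeds the null-mode threshold and
    that sit in a run of at least ``min_run`` consecutive positive probes.

    ``replicate_mode`` "averaged" (default) smooths the replicate mean;
    "intersection" calls each replicate separately and intersects.
    """
    if replicate_mode == "intersection":
        reps = normalized.M[sample].columns
        sets = [
            _call_positive_single(
                normalized, normalized.M[(sample, r)].to_numpy(), z, min_run,
                window_probes, window_bp,
            )
            for r in reps
        ]
        return set.intersection(*sets)
    if replicate_mode != "averaged":
        raise ValueError("replicate_mode must be 'averaged' or 'intersection'")
    values = normalized.M[sample].mean(axis=1).to_numpy()
    return _call_positive_single(
        normalized, values, z, min_run, window_probes, window_bp
    )


def _call_positive_single(
    sm: SignalMatrix,
    values: np.ndarray,
    z: float,
    min_run: int,
    window_probes: int,
    window_bp: int,
) -> set[str]:
    probes = sm.probes
    order = np.lexsort((probes["start"].to_numpy(), probes["chrom"].to_numpy()))
    smoothed = np.empty(len(values))
    chrom_sorted = probes["chrom"].to_numpy()[order]
    centers = ((probes["start"] + probes["end"]) / 2).to_numpy()[order]
    vals_sorted = values[order]
    boundaries = np.flatnonzero(chrom_sorted[1:] != chrom_sorted[:-1]) + 1
    segments = np.split(np.arange(len(order)), boundaries)
    for seg in segments:
        if len(seg) < window_probes:
            warnings.warn(
                f"chromosome {chrom_sorted[seg[0]]}: fewer probes than smoothing "
                "window; values passed through unsmoothed"
            )
            smoothed[seg] = vals_sorted[seg]
        else:
            smoothed[seg] = _running_median(
                vals_sorted[seg], centers[seg], window_probes, window_bp
            )
    y0 = _null_threshold(smoothed, z)
    positive = smoothed > y0
    keep = np.zeros(len(positive), dtype=bool)
    for seg in segments:
        p = positive[seg]
        run_start = 0
        for i in range(len(p) + 1):
            if i == len(p) or not p[i]:
                if i - run_start >= min_run:
                    keep[seg[run_start:i]] = True
                run_start = i + 1
    ids = probes.index.to_numpy()[order]
    return set(ids[keep])


# ---------------------------------------------------------------------------
# Gene rule
# ---------------------------------------------------------------------------


def apply_gene_rule(
    covered_bp: int, gene_length: int, rule: tuple[float, int, int]
) -> bool:
    """(coverage fraction >= min_frac AND covered bp >= min_bp) OR covered
    bp >= long_bp — the long-gene clause lets very long genes qualify on
    absolute coverage alone."""
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    min_frac, min_bp, long_bp = rule
    frac = covered_bp / gene_length
    return (frac >= min_frac and covered_bp >= min_bp) or covered_bp >= long_bp


def gene_coverage(
    regions: RegionSet,
    genes: list[GeneModel],
    rule: tuple[float, int, int],
    sample: str,
    n_probes: dict[str, int] | None = None,
) -> TargetCallSet:
    rows = []
    for g in genes:
        cov = overlap_bp(regions, g.interval)
        rows.append(
            {
                "gene_id": g.gene_id,
                "is_target": apply_gene_rule(cov, g.length, rule),
                "covered_bp": cov,
                "covered_frac": cov / g.length,
                "n_probes": (n_probes or {}).get(g.gene_id, 0),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return TargetCallSet(sample, table, regions)


def call_gene_targets(
    positive_probe_ids: set[str],
    signal: SignalMatrix,
    genes: list[GeneModel],
    *,
    merge_gap: int = 300,
    rule: tuple[float, int, int] = (0.30, 300, 1000),
    sample: str = "",
) -> TargetCallSet:
    """Merge positive-probe placements into enriched regions (gap < 300 bp)
    and call per-gene target status under the array gene rule."""
    sel = signal.probes.loc[sorted(positive_probe_ids)]
    intervals = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in sel.itertuples()
    ]
    regions = merge_intervals(intervals, merge_gap, label=f"{sample}_enriched")
    n_probes: dict[str, int] = {}
    for g in genes:
        n_probes[g.gene_id] = sum(
            1 for iv in intervals if iv.overlap(g.interval) > 0
        )
    calls = gene_coverage(regions, genes, rule, sample, n_probes)
    log.info(
        "%s: %d positive probes -> %d regions -> %d gene targets",
        sample, len(positive_probe_ids), len(regions), len(calls.target_ids),
    )
    return calls


def compare_target_sets(set_a: TargetCallSet, set_b: TargetCallSet) -> TargetComparison:
    """Partition the union of two target sets into shared / A-only / B-only."""
    if set(set_a.table.index) != set(set_b.table.index):
        raise ValueError("target sets cover different gene universes")
    a, b = set_a.target_ids, set_b.target_ids
    return TargetComparison(shared=a & b, a_only=a - b, b_only=b - a)
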
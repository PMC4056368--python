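"""Rank-product detection of accession-specific H3K27me3 targets.

Per gene, a median enrichment value is computed over all admitted probes
covering the gene body, per replicate and accession; genes with fewer than
three probes or under 40% probe coverage are dropped, as are genes that
are targets in neither accession.  For every between-accession replicate
pairing the genes are ranked by the signed difference, and the rank
product RP_g = (prod_i r_{g,i})^{1/k} summarises consistency across the k
pairings.  Significance is expressed as the proportion of false
predictions (pfp): the expected number of null genes (from within-column
permutations) scoring at or better than RP_g, divided by the rank of g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import GeneModel, GenomicInterval, merge_intervals, overlap_bp
from .tiling_chip import SignalMatrix, TargetCallSet

__all__ = [
    "GeneEnrichmentMatrix",
    "DifferentialResult",
    "build_gene_matrix",
    "filter_candidate_genes",
    "rank_product_test",
]


@dataclass
class GeneEnrichmentMatrix:
    """Genes x (accession, replicate) median enrichment values plus the
    per-gene probe evidence used by the admission filters."""

    values: pd.DataFrame  # index gene_id, columns MultiIndex (accession, replicate)
    meta: pd.DataFrame  # index gene_id: n_probes, probe_coverage_frac

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share a gene index")
        if len(self.values) and not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("gene matrix contains non-finite values")


@dataclass
class DifferentialResult:
    """Per-gene rank products and pfp in both directions.

    ``up`` is enrichment in accession A (Col-specific), ``down`` in
    accession B (Ler-specific).
    """

    table: pd.DataFrame  # RP_up, RP_down, pfp_up, pfp_down, direction, significant
    pfp_threshold: float

    def specific_targets(self, direction: str) -> set[str]:
        t = self.table
        return set(t.index[t["significant"] & (t["direction"] == direction)])


def build_gene_matrix(
    normalized: SignalMatrix,
    admitted_probe_ids: set[str],
    genes: list[GeneModel],
    *,
    min_probes_per_gene: int = 3,
    min_probe_coverage_frac: float = 0.40,
) -> GeneEnrichmentMatrix:
    """Median enrichment per gene, replicate and accession over admitted
    probes covering the gene body; genes failing the probe-evidence
    filters (fewer than 3 probes, or under 40% of the body covered by
    probes) are dropped."""
    probes = normalized.probes
    keep = probes.index.isin(admitted_probe_ids)
    probes = probes[keep]
    M = normalized.M[keep]
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): df.sort_values("start") for c, df in probes.groupby("chrom")
    }
    rows = {}
    meta_rows = {}
    for g in genes:
        iv = g.interval
        chrom_probes = by_chrom.get(iv.chrom)
        if chrom_probes is None:
            continue
        starts = chrom_probes["start"].to_numpy()
        ends = chrom_probes["end"].to_numpy()
        sel = (starts < iv.end) & (ends > iv.start)
        n = int(sel.sum())
        if n < min_probes_per_gene:
            continue
        ids = chrom_probes.index[sel]
        cov_regions = merge_intervals(
            [
                GenomicInterval(iv.chrom, int(s), int(e))
                for s, e in zip(starts[sel], ends[sel])
            ]
        )
        covered = overlap_bp(cov_regions, iv)
        frac = covered / g.length
        if frac < min_probe_coverage_frac:
            continue
        rows[g.gene_id] = M.loc[ids].median(axis=0)
        meta_rows[g.gene_id] = {"n_probes": n, "probe_coverage_frac": frac}
    if not rows:
        values = pd.DataFrame(columns=normalized.M.columns)
        meta = pd.DataFrame(columns=["n_probes", "probe_coverage_frac"])
        return GeneEnrichmentMatrix(values, meta)
    values = pd.DataFrame(rows).T
    values.columns = normalized.M.columns
    meta = pd.DataFrame(meta_rows).T
    return GeneEnrichmentMatrix(values, meta)


def filter_candidate_genes(
    matrix: GeneEnrichmentMatrix,
    targets_a: TargetCallSet,
    targets_b: TargetCallSet,
) -> GeneEnrichmentMatrix:
    """Keep only genes that are H3K27me3 targets in at least one accession
    in the global analysis, so differential calls have high signal in at
    least one genome."""
    keep = matrix.values.index.isin(targets_a.target_ids | targets_b.target_ids)
    return GeneEnrichmentMatrix(matrix.values[keep], matrix.meta[keep])


def rank_product_test(
    matrix: GeneEnrichmentMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    pfp_threshold: float = 0.15,
    accessions: tuple[str, str] = ("A", "B"),
) -> DifferentialResult:
    """Two-directional rank-product test with permutation-estimated pfp.

    The k columns are all cross pairings of accession-A and accession-B
    replicates (two-class unpaired convention); ranks use average
    tie-breaking so the statistic is invariant under monotone transforms.
    The null is built by permuting values independently within each
    difference column ``n_perm`` times; pfp_g = E[# null RP <= RP_g] /
    rank(RP_g).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = matrix.values
    acc_a, acc_b = accessions
    reps_a = values[acc_a].columns
    reps_b = values[acc_b].columns
    if len(reps_a) * len(reps_b) < 2:
        raise ValueError("need at least 2 between-accession replicate pairings")
    diffs = np.column_stack(
        [
            values[(acc_a, ra)].to_numpy() - values[(acc_b, rb)].to_numpy()
            for ra in reps_a
            for rb in reps_b
        ]
    )
    genes = values.index
    G, k = diffs.shape
    constant = bool(np.all(np.ptp(diffs, axis=0) == 0))
    if constant:
        warnings.warn("constant gene matrix: all pfp set to 1")
        table = pd.DataFrame(
            {
                "RP_up": np.full(G, (G + 1) / 2),
                "RP_down": np.full(G, (G + 1) / 2),
                "pfp_up": 1.0,
                "pfp_down": 1.0,
            },
            index=genes,
        )
        table["direction"] = "none"
        table["significant"] = False
        return DifferentialResult(table, pfp_threshold)

    def rank_products(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # rank 1 = strongest in the direction of interest
        r_up = rankdata(-d, axis=0, method="average")
        r_down = rankdata(d, axis=0, method="average")
        return (
            np.exp(np.log(r_up).mean(axis=1)),
            np.exp(np.log(r_down).mean(axis=1)),
        )

    rp_up, rp_down = rank_products(diffs)
    rng = np.random.default_rng(seed)
    null_up = np.empty((n_perm, G))
    null_down = np.empty((n_perm, G))
    for p in range(n_perm):
        permuted = rng.permuted(diffs, axis=0)
        null_up[p], null_down[p] = rank_products(permuted)

    def pfp(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
        null_sorted = np.sort(null.ravel())
        expected = np.searchsorted(null_sorted, observed, side="right") / n_perm
        rank = rankdata(observed, method="max")
        raw = expected / rank
        # enforce monotonicity in RP rank (a worse RP never gets a smaller pfp)
        order = np.argsort(observed, kind="stable")
        out = np.empty_like(raw)
        out[order] = np.maximum.accumulate(raw[order])
        return out

    pfp_up = pfp(rp_up, null_up)
    pfp_down = pfp(rp_down, null_down)
    table = pd.DataFrame(
        {
            "RP_up": rp_up,
            "RP_down": rp_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
        },
        index=genes,
    )
    table["direction"] = np.where(pfp_up <= pfp_down, acc_a, acc_b)
    table["significant"] = np.minimum(pfp_up, pfp_down) < pfp_threshold
    return DifferentialResult(table, pfp_threshold)
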
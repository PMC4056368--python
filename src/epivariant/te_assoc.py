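"""Transposable-element association analyses.

Covers the genomic side of the accession comparison: which genes are
flanked by annotated TEs (within a 5 kb window, or by nearest-neighbor
adjacency), whether a query gene set is TE-flanked more often than random
samples of background genes (the sample-size-28, 200-drawing permutation
design), hypergeometric enrichment of mark overlap and of TE families,
and cross-assembly TE presence/absence calls with target-site-duplication
(TSD) inference — an exact duplicated motif on both sides of an insertion
in one genome with a single copy at the orthologous junction of the
other, the signature distinguishing an insertion from an excision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import GeneModel, TeModel

__all__ = [
    "FlankAnnotation",
    "PresenceCall",
    "TePermutationResult",
    "annotate_flanks",
    "te_flank_permutation",
    "hypergeometric_enrichment",
    "family_composition",
    "te_presence_in_other_assembly",
    "find_tsd",
]


# ---------------------------------------------------------------------------
# Flanking TEs
# ---------------------------------------------------------------------------


@dataclass
class FlankAnnotation:
    gene_id: str
    #: (te_id, side in {left, right}, distance gene-edge to nearest TE edge)
    flanking: list[tuple[str, str, int]] = field(default_factory=list)
    #: TEs overlapping the gene body itself (reported separately)
    body_tes: list[str] = field(default_factory=list)
    nearest_left_is_te: bool = False
    nearest_right_is_te: bool = False

    @property
    def is_flanked(self) -> bool:
        return bool(self.flanking)

    @property
    def nearest_neighbor_is_te(self) -> bool:
        return self.nearest_left_is_te or self.nearest_right_is_te


def annotate_flanks(
    genes: Sequence[GeneModel],
    tes: Sequence[TeModel],
    flank_bp: int = 5000,
) -> list[FlankAnnotation]:
    """Flanking-TE annotation for every gene.

    A TE flanks a gene when its interval intersects the ``flank_bp`` window
    immediately up- or downstream of the gene body; TEs overlapping the
    body are listed separately.  The nearest-neighbor flags record, per
    side, whether the closest annotated feature (gene or TE) is a TE —
    the alternative operational definition of "flanked".
    """
    out: list[FlankAnnotation] = []
    tes_by_chrom: dict[str, list[TeModel]] = {}
    for t in tes:
        tes_by_chrom.setdefault(t.interval.chrom, []).append(t)
    feats_by_chrom: dict[str, list[tuple[int, int, bool]]] = {}
    for g in genes:
        iv = g.interval
        feats_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, False))
    for t in tes:
        iv = t.interval
        feats_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, True))
    for lst in feats_by_chrom.values():
        lst.sort()

    for g in genes:
        iv = g.interval
        ann = FlankAnnotation(g.gene_id)
        left_lo, left_hi = iv.start - flank_bp, iv.start
        right_lo, right_hi = iv.end, iv.end + flank_bp
        for t in tes_by_chrom.get(iv.chrom, ()):
            ts, te_end = t.interval.start, t.interval.end
            if ts < iv.end and te_end > iv.start:
                ann.body_tes.append(t.te_id)
                continue
            if ts < left_hi and te_end > left_lo:
                ann.flanking.append((t.te_id, "left", iv.start - te_end))
            elif ts < right_hi and te_end > right_lo:
                ann.flanking.append((t.te_id, "right", ts - iv.end))
        # nearest annotated neighbour per side
        best_left: tuple[int, bool] | None = None
        best_right: tuple[int, bool] | None = None
        for fs, fe, is_te in feats_by_chrom.get(iv.chrom, ()):
            if fs == iv.start and fe == iv.end and not is_te:
                continue
            if fe <= iv.start:
                d = iv.start - fe
                if best_left is None or d < best_left[0]:
                    best_left = (d, is_te)
            elif fs >= iv.end:
                d = fs - iv.end
                if best_right is None or d < best_right[0]:
                    best_right = (d, is_te)
        ann.nearest_left_is_te = bool(best_left and best_left[1])
        ann.nearest_right_is_te = bool(best_right and best_right[1])
        out.append(ann)
    return out


@dataclass
class TePermutationResult:
    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float
    sample_size: int
    n_draws: int


def te_flank_permutation(
    query_genes: Sequence[str],
    background_genes: Sequence[str],
    flanked: Mapping[str, bool],
    n_draws: int = 200,
    sample_size: int = 28,
    seed: int = 0,
) -> TePermutationResult:
    """Permutation test for TE-flanking enrichment of a gene set.

    The observed statistic is the fraction of query genes with at least
    one flanking TE; the null draws ``sample_size`` genes without
    replacement from the background ``n_draws`` times.  One-sided toward
    enrichment: p = (1 + #null >= observed) / (n_draws + 1).
    """
    background = list(background_genes)
    if sample_size > len(background):
        raise ValueError(
            f"background ({len(background)}) smaller than sample size ({sample_size})"
        )
    if not query_genes:
        raise ValueError("empty query gene set")
    flags = np.array([bool(flanked.get(g, False)) for g in background])
    observed = float(np.mean([bool(flanked.get(g, False)) for g in query_genes]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(background), size=sample_size, replace=False)
        null[i] = flags[idx].mean()
    p = (1 + int((null >= observed).sum())) / (n_draws + 1)
    return TePermutationResult(observed, null, p, sample_size, n_draws)


def hypergeometric_enrichment(
    k_hits_in_set: int, set_size: int, K_hits_total: int, N_total: int
) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k_hits_in_set <= min(set_size, K_hits_total) <= N_total):
        raise ValueError(
            f"inconsistent counts k={k_hits_in_set}, n={set_size}, "
            f"K={K_hits_total}, N={N_total}"
        )
    if set_size > N_total:
        raise ValueError("set larger than population")
    return float(hypergeom.sf(k_hits_in_set - 1, N_total, K_hits_total, set_size))


def family_composition(
    te_set: Sequence[TeModel],
    background: Sequence[TeModel] | None = None,
) -> pd.DataFrame:
    """Per-family counts and fractions; with a background, adds the
    hypergeometric enrichment p of each family within the subset."""
    rows = []
    fams = pd.Series([t.family for t in te_set], dtype=object)
    counts = fams.value_counts()
    total = len(te_set)
    bg_counts = None
    if background is not None:
        bg_counts = pd.Series([t.family for t in background], dtype=object).value_counts()
    for family, count in counts.items():
        row = {
            "family": family,
            "count": int(count),
            "fraction": count / total if total else np.nan,
        }
        if bg_counts is not None:
            row["enrichment_p"] = hypergeometric_enrichment(
                int(count), total, int(bg_counts.get(family, count)), len(background)
            )
        rows.append(row)
    cols = ["family", "count", "fraction"] + (
        ["enrichment_p"] if background is not None else []
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Cross-assembly presence and TSDs
# ---------------------------------------------------------------------------


@dataclass
class PresenceCall:
    te_id: str
    status: str  # present_in_B | absent_in_B | unresolved
    #: (chrom, left anchor A-start, left anchor B-start,
    #:  right anchor A-start, right anchor B-start, anchor_k) when resolved
    evidence: tuple[str, int, int, int, int, int] | None = None
    tsd: str | None = None


def _find_unique_anchor(
    a_seq: str,
    b_genome: Mapping[str, str],
    chrom: str,
    candidates: Sequence[int],
    k: int,
) -> tuple[int, int] | None:
    """First candidate A-offset whose k-mer occurs exactly once in genome B
    (on the matching chromosome); returns (a_start, b_start)."""
    for a_start in candidates:
        if a_start < 0 or a_start + k > len(a_seq):
            continue
        kmer = a_seq[a_start : a_start + k]
        if "N" in kmer:
            continue
        total = 0
        b_pos = -1
        for b_chrom, b_seq in b_genome.items():
            start = 0
            while True:
                j = b_seq.find(kmer, start)
                if j < 0:
                    break
                total += 1
                if b_chrom == chrom:
                    b_pos = j
                start = j + 1
                if total > 1:
                    break
            if total > 1:
                break
        if total == 1 and b_pos >= 0:
            return a_start, b_pos
    return None


def te_presence_in_other_assembly(
    te: TeModel,
    genome_A: Mapping[str, str],
    genome_B: Mapping[str, str],
    *,
    anchor_k: int = 35,
    flank_bp: int = 500,
    present_frac: float = 0.8,
    absent_frac: float = 0.2,
) -> PresenceCall:
    """Decide whether a TE annotated in genome A is present in genome B.

    Unique exact ``anchor_k``-mers are sought in the flanks of the TE
    (walking outward from the TE edges, re-seeding past mismatched
    positions) and located in genome B.  If the B anchors are separated by
    at least ``present_frac`` of the A-side span the TE is present; if the
    separation leaves less than ``absent_frac`` of the TE length between
    the flanks — and no TE-internal anchor maps between them — it is
    absent; anything else is unresolved.
    """
    if anchor_k < 15:
        raise ValueError("anchor_k must be >= 15")
    iv = te.interval
    chrom = iv.chrom
    a_seq = genome_A[chrom]
    te_len = len(iv)
    step = max(anchor_k // 4, 5)
    left_candidates = list(range(iv.start - anchor_k, iv.start - anchor_k - flank_bp, -step))
    right_candidates = list(range(iv.end, iv.end + flank_bp, step))
    left = _find_unique_anchor(a_seq, genome_B, chrom, left_candidates, anchor_k)
    right = _find_unique_anchor(a_seq, genome_B, chrom, right_candidates, anchor_k)
    if left is None or right is None:
        return PresenceCall(te.te_id, "unresolved")
    (la, lb), (ra, rb) = left, right
    offset_left = iv.start - la  # anchor start to TE start in A (>= k)
    offset_right = (ra + anchor_k) - iv.end  # TE end to anchor end in A
    expected_span = offset_left + te_len + offset_right
    observed_span = (rb + anchor_k) - lb
    evidence = (chrom, la, lb, ra, rb, anchor_k)
    if observed_span >= present_frac * expected_span:
        return PresenceCall(te.te_id, "present_in_B", evidence)
    if observed_span < offset_left + offset_right + absent_frac * te_len:
        mid = iv.start + (te_len - anchor_k) // 2
        internal = a_seq[mid : mid + anchor_k]
        between = genome_B[chrom][lb : rb + anchor_k]
        if internal and internal in between:
            return PresenceCall(te.te_id, "unresolved", evidence)
        return PresenceCall(te.te_id, "absent_in_B", evidence)
    return PresenceCall(te.te_id, "unresolved", evidence)


def find_tsd(
    te: TeModel,
    genome_A: Mapping[str, str],
    genome_B: Mapping[str, str],
    presence: PresenceCall,
    max_tsd: int = 10,
    *,
    check_bp: int = 20,
) -> str | None:
    """Target-site duplication at an insertion present in A, absent in B.

    Returns the longest motif t (1..``max_tsd`` bp) such that genome A
    reads ``X t [TE] t Y`` while genome B reads ``X t Y`` at the
    orthologous junction; None when the junction carries no duplication
    (an excision-style polymorphism).
    """
    if presence.status != "absent_in_B":
        raise ValueError("TSD search requires an absent_in_B presence call")
    if presence.evidence is None:
        raise ValueError("presence call carries no anchor evidence")
    chrom, la, lb, _ra, _rb, _k = presence.evidence
    a_seq = genome_A[chrom]
    b_seq = genome_B[chrom]
    iv = te.interval
    # map the TE-start junction into B through the left anchor (SNP-free
    # anchors and no intervening indels by construction of the call)
    jb = lb + (iv.start - la)
    if not (0 <= jb <= len(b_seq)):
        raise ValueError("junction not resolvable from anchors")
    max_check_mismatch = max(1, check_bp // 10)
    for L in range(max_tsd, 0, -1):
        if iv.start - L < 0 or iv.end + L + check_bp > len(a_seq):
            continue
        motif = a_seq[iv.start - L : iv.start]
        if a_seq[iv.end : iv.end + L] != motif:
            continue
        if b_seq[jb - L : jb] != motif:
            continue
        # B must continue with Y (the sequence after the 3' motif copy in A);
        # point substitutions are tolerated in the continuation window, the
        # motif itself must match exactly
        after_a = a_seq[iv.end + L : iv.end + L + check_bp]
        after_b = b_seq[jb : jb + check_bp]
        mismatches = sum(x != y for x, y in zip(after_a, after_b))
        if len(after_b) == check_bp and mismatches <= max_check_mismatch:
            return motif
    return None
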
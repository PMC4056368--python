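"""Two-accession + F1-hybrid synthetic cohort generator.

The generator emulates the statistical structure the analysis assumes:
two inbred accession genomes (A = reference, B = diverged) related by
SNPs and TE presence/absence polymorphisms with target-site duplications
(TSDs); per-gene chromatin states (shared H3K27me3, accession-specific
H3K27me3, H3K9me2 heterochromatin, active H3K4me3, unmarked); probe-level
two-colour array signal with replicate noise and an intensity-dependent
bias; allele-resolved F1 ChIP coverage at SNPs; binary mark tracks plus a
siRNA count track; and hybrid ChIP/input read-start tracks.

Every output is a deterministic function of ``SimulationParams.rng_seed``;
each operation draws from its own seed stream so outputs do not depend on
the order in which operations are invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    RegionSet,
    TE_FAMILIES,
    TeModel,
    assign_snps_to_genes,
    merge_intervals,
)
from .probe_map import Probe
from .tiling_chip import SignalMatrix

__all__ = [
    "SimulationParams",
    "ChromatinStateSpec",
    "SimulatedCohort",
    "GENE_STATES",
    "K27_STATES",
    "simulate_genomes",
    "make_probes",
    "simulate_array_signal",
    "simulate_f1_allele_counts",
    "simulate_mark_tracks",
    "simulate_read_starts",
    "MarkTracks",
    "HYBRIDS",
]

GENE_STATES = (
    "shared_K27",
    "A_specific_K27",
    "B_specific_K27",
    "K9_heterochromatic",
    "active_K4",
    "none",
)
#: states carrying H3K27me3 in accession A / accession B
K27_STATES = {
    "A": ("shared_K27", "A_specific_K27"),
    "B": ("shared_K27", "B_specific_K27"),
}
HYBRIDS = ("ColxLer", "LerxCol")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults give a desk-scale dataset
    (2 x 500 kb chromosomes, 200 genes, 60 TEs) on which every pipeline
    stage runs in well under a minute."""

    n_chroms: int = 2
    chrom_length_bp: int = 500_000
    n_genes: int = 200
    n_tes: int = 60
    snp_rate: float = 0.005
    # chromatin-state fractions over genes (remainder unmarked)
    fraction_shared: float = 0.30
    fraction_ler_specific: float = 0.05  # B-specific H3K27me3
    fraction_col_specific: float = 0.05  # A-specific H3K27me3
    fraction_k9: float = 0.10
    fraction_k4: float = 0.20
    fraction_te_flanked_for_specific: float = 0.8
    # TE polymorphism
    te_a_only_prob: float = 0.20
    te_b_only_prob: float = 0.10
    tsd_prob: float = 0.8
    # array model
    n_replicates: int = 3
    enrichment_effect: float = 2.0
    replicate_noise_sd: float = 0.5
    intensity_bias: float = 0.3
    probe_length: int = 60
    probe_step: int = 90
    # hybrid allele model
    read_depth_per_snp: float = 20.0
    epsilon_col_rate: float = 0.0
    seq_error_rate: float = 0.01
    background_depth_frac: float = 0.1
    # mark tracks
    spreading_margin_bp: int = 500
    sirna_total_count: int = 20_000
    # hybrid read starts
    seq_background_per_bp: float = 0.02
    seq_enrichment_fold: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "snp_rate",
            "fraction_shared",
            "fraction_ler_specific",
            "fraction_col_specific",
            "fraction_k9",
            "fraction_k4",
            "fraction_te_flanked_for_specific",
            "te_a_only_prob",
            "te_b_only_prob",
            "tsd_prob",
            "epsilon_col_rate",
            "seq_error_rate",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_depth_per_snp <= 0 or self.seq_background_per_bp <= 0:
            raise ValueError("depths must be > 0")
        frac_sum = (
            self.fraction_shared
            + self.fraction_ler_specific
            + self.fraction_col_specific
            + self.fraction_k9
            + self.fraction_k4
        )
        if frac_sum > 1.0 + 1e-9:
            raise ValueError("state fractions sum to more than 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])


@dataclass
class ChromatinStateSpec:
    """Ground truth of the simulation: per-gene chromatin state, per-TE
    presence status and TSD motif for A-only insertions."""

    gene_states: dict[str, str]
    te_presence: dict[str, str]  # te_id -> both | A_only | B_only
    tsd: dict[str, str | None] = field(default_factory=dict)
    #: B-only insertions as (te_id, chrom, insertion point in A frame, length)
    b_only_insertions: list[tuple[str, str, int, int]] = field(default_factory=list)

    def genes_in_state(self, *states: str) -> set[str]:
        return {g for g, s in self.gene_states.items() if s in states}

    def validate(self, annotation: GenomeAnnotation) -> None:
        missing = {g.gene_id for g in annotation.genes} - set(self.gene_states)
        if missing:
            raise ValueError(f"gene states missing for {sorted(missing)[:5]}...")
        bad = set(self.gene_states.values()) - set(GENE_STATES)
        if bad:
            raise ValueError(f"unknown gene states {bad}")


@dataclass
class SimulatedCohort:
    genome_A: dict[str, str]
    genome_B: dict[str, str]
    annotation: GenomeAnnotation
    snp_table: pd.DataFrame  # chrom, pos (0-based, A frame), allele_A, allele_B
    state_spec: ChromatinStateSpec
    params: SimulationParams


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, base: np.uint8) -> np.uint8:
    alts = _BASES[_BASES != base]
    return alts[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


def simulate_genomes(params: SimulationParams) -> SimulatedCohort:
    """Generate the paired accession genomes, annotation, SNP table and
    ground-truth state spec.

    Genome B equals genome A with SNPs substituted at ``snp_rate``, A-only
    TEs deleted (an A-only insertion is flanked in A by two copies of its
    TSD motif; B keeps a single copy at the junction) and B-only TEs
    inserted into intergenic space.  SNPs are never placed inside deleted
    spans or TSD copies, so each polymorphism stays cleanly interpretable.
    """
    rng = params.rng(1)
    genes_per_chrom = np.full(params.n_chroms, params.n_genes // params.n_chroms)
    genes_per_chrom[: params.n_genes % params.n_chroms] += 1

    # -- chromatin states ---------------------------------------------------
    gene_ids = [f"gene_{i:04d}" for i in range(params.n_genes)]
    shuffled = list(gene_ids)
    rng.shuffle(shuffled)
    counts = {
        "shared_K27": round(params.fraction_shared * params.n_genes),
        "B_specific_K27": round(params.fraction_ler_specific * params.n_genes),
        "A_specific_K27": round(params.fraction_col_specific * params.n_genes),
        "K9_heterochromatic": round(params.fraction_k9 * params.n_genes),
        "active_K4": round(params.fraction_k4 * params.n_genes),
    }
    gene_states: dict[str, str] = {}
    cursor = 0
    for state, n in counts.items():
        for gid in shuffled[cursor : cursor + n]:
            gene_states[gid] = state
        cursor += n
    for gid in shuffled[cursor:]:
        gene_states[gid] = "none"

    b_specific = sorted(g for g, s in gene_states.items() if s == "B_specific_K27")
    n_flanked = round(params.fraction_te_flanked_for_specific * len(b_specific))
    flanked_genes = set(
        rng.choice(b_specific, size=n_flanked, replace=False) if n_flanked else []
    )

    # -- layout -------------------------------------------------------------
    genes: list[GeneModel] = []
    tes: list[TeModel] = []
    te_presence: dict[str, str] = {}
    tsd_motifs: dict[str, str | None] = {}
    #: per chrom: A-only deletions as (del_start, del_end) and tsd length
    deletions: dict[str, list[tuple[int, int]]] = {}
    gap_space: dict[str, list[tuple[int, int]]] = {}
    chrom_seqs: dict[str, np.ndarray] = {}

    te_counter = 0
    gene_iter = iter(gene_ids)
    n_attached = len(flanked_genes)
    n_standalone = max(params.n_tes - n_attached, 0)
    standalone_per_chrom = np.full(params.n_chroms, n_standalone // params.n_chroms)
    standalone_per_chrom[: n_standalone % params.n_chroms] += 1

    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, params.chrom_length_bp)
        chrom_seqs[chrom] = seq
        deletions[chrom] = []
        gap_space[chrom] = []

        chrom_gene_ids = [next(gene_iter) for _ in range(genes_per_chrom[ci])]
        units: list[tuple[str, str | None]] = [("gene", g) for g in chrom_gene_ids]
        units += [("te", None)] * int(standalone_per_chrom[ci])
        rng.shuffle(units)

        pos = int(rng.integers(600, 1200))
        for kind, gid in units:
            if kind == "gene":
                assert gid is not None
                attach = gid in flanked_genes
                attach_left = bool(attach and rng.integers(0, 2))
                if attach and attach_left:
                    pos, te_counter = _place_te(
                        rng, params, chrom, pos, tes, te_presence, tsd_motifs,
                        deletions, chrom_seqs, te_counter, presence="A_only",
                    )
                    pos += int(rng.integers(100, 401))
                glen = int(rng.integers(1000, 3001))
                strand = "+" if rng.integers(0, 2) else "-"
                genes.append(
                    GeneModel(gid, GenomicInterval(chrom, pos, pos + glen, strand))
                )
                pos += glen
                if attach and not attach_left:
                    pos += int(rng.integers(100, 401))
                    pos, te_counter = _place_te(
                        rng, params, chrom, pos, tes, te_presence, tsd_motifs,
                        deletions, chrom_seqs, te_counter, presence="A_only",
                    )
            else:
                # B-only TEs are realised later as insertion events in gaps
                presence = "A_only" if rng.random() < params.te_a_only_prob else "both"
                pos, te_counter = _place_te(
                    rng, params, chrom, pos, tes, te_presence, tsd_motifs,
                    deletions, chrom_seqs, te_counter, presence=presence,
                )
            gap = int(rng.integers(800, 1801))
            gap_space[chrom].append((pos + 100, pos + gap - 100))
            pos += gap
            if pos > params.chrom_length_bp - 1000:
                raise ValueError(
                    f"{chrom}: features exceed chromosome length "
                    f"({pos} > {params.chrom_length_bp - 1000}); "
                    "increase chrom_length_bp or reduce feature counts"
                )

    # -- B-only insertions (absent from the A frame entirely) ---------------
    b_only_insertions: list[tuple[str, str, int, int]] = []
    b_only_seqs: dict[str, np.ndarray] = {}
    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        gaps = gap_space[chrom]
        n_ins = int(rng.binomial(len(gaps), params.te_b_only_prob * 0.5))
        if not gaps or not n_ins:
            continue
        chosen = rng.choice(len(gaps), size=min(n_ins, len(gaps)), replace=False)
        for gi in sorted(chosen):
            lo, hi = gaps[gi]
            if hi - lo < 10:
                continue
            ins_pos = int(rng.integers(lo, hi))
            length = int(rng.integers(400, 1501))
            te_id = f"te_{te_counter:04d}"
            te_counter += 1
            te_presence[te_id] = "B_only"
            b_only_insertions.append((te_id, chrom, ins_pos, length))
            b_only_seqs[te_id] = _random_seq(rng, length)

    sequences = {c: params.chrom_length_bp for c in chrom_seqs}
    annotation = GenomeAnnotation(sequences, genes, tes)
    state_spec = ChromatinStateSpec(
        gene_states, te_presence, tsd_motifs, b_only_insertions
    )
    state_spec.validate(annotation)

    # -- SNPs and genome B --------------------------------------------------
    snp_rows = []
    genome_A: dict[str, str] = {}
    genome_B: dict[str, str] = {}
    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        seq_a = chrom_seqs[chrom]
        excluded = np.zeros(len(seq_a), dtype=bool)
        for dstart, dend in deletions[chrom]:
            # keep SNPs out of the deleted span and both TSD copies: the
            # left copy sits max_tsd bp before the deletion start
            excluded[max(0, dstart - 10) : dend] = True
        seq_b = seq_a.copy()
        snp_pos = np.flatnonzero(rng.random(len(seq_a)) < params.snp_rate)
        snp_pos = snp_pos[~excluded[snp_pos]]
        for p in snp_pos:
            old = seq_a[p]
            new = _mutate(rng, old)
            seq_b[p] = new
            snp_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(p),
                    "allele_A": chr(old),
                    "allele_B": chr(new),
                }
            )
        # splice out A-only deletions, splice in B-only insertions
        events: list[tuple[int, str, object]] = []
        for dstart, dend in deletions[chrom]:
            events.append((dstart, "del", dend))
        for te_id, ichrom, ipos, length in b_only_insertions:
            if ichrom == chrom:
                events.append((ipos, "ins", b_only_seqs[te_id]))
        events.sort(key=lambda e: e[0])
        parts: list[np.ndarray] = []
        cursor = 0
        for pos_e, kind, payload in events:
            parts.append(seq_b[cursor:pos_e])
            if kind == "del":
                cursor = int(payload)  # type: ignore[arg-type]
            else:
                parts.append(payload)  # type: ignore[arg-type]
                cursor = pos_e
        parts.append(seq_b[cursor:])
        genome_A[chrom] = seq_a.tobytes().decode()
        genome_B[chrom] = np.concatenate(parts).tobytes().decode()

    snp_table = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "allele_A", "allele_B"]
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SimulatedCohort(
        genome_A, genome_B, annotation, snp_table, state_spec, params
    )


def _place_te(
    rng: np.random.Generator,
    params: SimulationParams,
    chrom: str,
    pos: int,
    tes: list[TeModel],
    te_presence: dict[str, str],
    tsd_motifs: dict[str, str | None],
    deletions: dict[str, list[tuple[int, int]]],
    chrom_seqs: dict[str, np.ndarray],
    te_counter: int,
    presence: str,
) -> tuple[int, int]:
    """Place one TE (present in A) at ``pos``; returns (new cursor, counter).

    B-only TEs are handled separately as insertion events, so this helper
    only ever realises 'both' and 'A_only' TEs.  An A-only TE carries a TSD
    motif with probability ``tsd_prob``: the motif is written on both sides
    of the TE body in genome A, and the deletion in B removes the body plus
    the 3' copy, leaving a single copy at the junction.
    """
    if presence == "B_only":
        # realised later as an insertion event; no A-frame model
        return pos, te_counter
    length = int(rng.integers(400, 1501))
    te_id = f"te_{te_counter:04d}"
    family = str(rng.choice(TE_FAMILIES))
    start = pos
    end = pos + length
    tes.append(TeModel(te_id, GenomicInterval(chrom, start, end), family))
    te_presence[te_id] = presence
    tsd_motifs[te_id] = None
    tsd_len = 0
    if presence == "A_only":
        if rng.random() < params.tsd_prob:
            tsd_len = int(rng.integers(4, 11))
            motif = _random_seq(rng, tsd_len)
            seq = chrom_seqs[chrom]
            seq[start - tsd_len : start] = motif
            seq[end : end + tsd_len] = motif
            tsd_motifs[te_id] = motif.tobytes().decode()
        deletions[chrom].append((start, end + tsd_len))
    return end + tsd_len, te_counter + 1


# ---------------------------------------------------------------------------
# Probes
# ---------------------------------------------------------------------------


def make_probes(
    genome_A: dict[str, str], params: SimulationParams
) -> tuple[list[Probe], pd.DataFrame]:
    """Tile genome A with probes of ``probe_length`` every ``probe_step`` bp.

    Returns the probe objects (sequence from genome A) and a design table
    with the intended genome-A coordinates, indexed by probe_id.
    """
    probes: list[Probe] = []
    rows = []
    i = 0
    for chrom in sorted(genome_A):
        seq = genome_A[chrom]
        for start in range(0, len(seq) - params.probe_length + 1, params.probe_step):
            pid = f"probe_{i:06d}"
            probes.append(Probe(pid, seq[start : start + params.probe_length]))
            rows.append(
                {
                    "probe_id": pid,
                    "chrom": chrom,
                    "start": start,
                    "end": start + params.probe_length,
                }
            )
            i += 1
    design = pd.DataFrame(rows).set_index("probe_id")
    return probes, design


# ---------------------------------------------------------------------------
# Array signal
# ---------------------------------------------------------------------------


def _probe_gene_overlap(
    design: pd.DataFrame, annotation: GenomeAnnotation
) -> np.ndarray:
    """Gene id (object array, None where intergenic) overlapping each probe.

    Relies on the simulated genes being non-overlapping within a chromosome.
    """
    out = np.full(len(design), None, dtype=object)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    chroms = design["chrom"].to_numpy()
    starts = design["start"].to_numpy()
    ends = design["end"].to_numpy()
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.interval.start)
        gs = np.array([g.interval.start for g in genes])
        ge = np.array([g.interval.end for g in genes])
        mask = chroms == chrom
        idx = np.searchsorted(gs, ends[mask], side="left") - 1
        idx = np.clip(idx, 0, None)
        hit = (starts[mask] < ge[idx]) & (ends[mask] > gs[idx])
        rows = np.flatnonzero(mask)
        out[rows[hit]] = [genes[i].gene_id for i in idx[hit]]
    return out


def simulate_array_signal(
    annotation: GenomeAnnotation,
    state_spec: ChromatinStateSpec,
    params: SimulationParams,
    design: pd.DataFrame,
) -> SignalMatrix:
    """Raw (pre-normalization) probe log-ratios for both accessions.

    Probes overlapping a gene whose state carries H3K27me3 in the given
    accession receive ``enrichment_effect`` plus replicate noise; all
    others are centred at zero.  A mean-zero quadratic function of each
    probe's log-intensity is added so the loess step has real work to do.
    """
    rng = params.rng(2)
    gene_of_probe = _probe_gene_overlap(design, annotation)
    n = len(design)
    columns = pd.MultiIndex.from_tuples(
        [
            (acc, f"rep{r + 1}")
            for acc in ("A", "B")
            for r in range(params.n_replicates)
        ],
        names=["accession", "replicate"],
    )
    M = np.zeros((n, len(columns)))
    A = np.zeros((n, len(columns)))
    for j, (acc, _rep) in enumerate(columns):
        k27 = state_spec.genes_in_state(*K27_STATES[acc])
        ind = np.array([g in k27 if g else False for g in gene_of_probe])
        intensity = rng.normal(10.0, 1.0, size=n)
        bias = params.intensity_bias * ((intensity - 10.0) ** 2 - 1.0)
        noise = (
            rng.normal(0.0, params.replicate_noise_sd, size=n)
            if params.replicate_noise_sd > 0
            else 0.0
        )
        M[:, j] = params.enrichment_effect * ind + noise + bias
        A[:, j] = intensity
    return SignalMatrix(
        design.copy(),
        pd.DataFrame(M, index=design.index, columns=columns),
        pd.DataFrame(A, index=design.index, columns=columns),
    )


# ---------------------------------------------------------------------------
# F1 allele counts
# ---------------------------------------------------------------------------


def simulate_f1_allele_counts(
    snp_table: pd.DataFrame,
    state_spec: ChromatinStateSpec,
    annotation: GenomeAnnotation,
    params: SimulationParams,
) -> dict[str, pd.DataFrame]:
    """Per-SNP ChIP read counts supporting each parental allele, one table
    per reciprocal hybrid.

    At SNPs in shared targets both alleles draw Poisson(depth/2); in
    B-specific targets the A (Col) allele draws Poisson(epsilon * depth)
    and the B allele Poisson(depth/2) (mirrored for A-specific); elsewhere
    both alleles draw a low background.  A ``seq_error_rate`` fraction of
    reads is re-assigned to a non-parental base (reads_other) to exercise
    the biallelic filter.
    """
    snps = snp_table
    if "gene_id" not in snps.columns:
        snps = assign_snps_to_genes(snps, annotation)
    states = np.array(
        [
            state_spec.gene_states.get(g, "none") if g else "intergenic"
            for g in snps["gene_id"]
        ]
    )
    d = params.read_depth_per_snp
    lam_a = np.full(len(snps), d * params.background_depth_frac / 2)
    lam_b = lam_a.copy()
    lam_a[states == "shared_K27"] = d / 2
    lam_b[states == "shared_K27"] = d / 2
    lam_a[states == "B_specific_K27"] = params.epsilon_col_rate * d
    lam_b[states == "B_specific_K27"] = d / 2
    lam_a[states == "A_specific_K27"] = d / 2
    lam_b[states == "A_specific_K27"] = params.epsilon_col_rate * d

    out: dict[str, pd.DataFrame] = {}
    for hi, hybrid in enumerate(HYBRIDS):
        rng = params.rng(3 + hi)
        reads_a = rng.poisson(lam_a)
        reads_b = rng.poisson(lam_b)
        kept_a = rng.binomial(reads_a, 1.0 - params.seq_error_rate)
        kept_b = rng.binomial(reads_b, 1.0 - params.seq_error_rate)
        other = (reads_a - kept_a) + (reads_b - kept_b)
        table = snps.copy()
        table["reads_A"] = kept_a
        table["reads_B"] = kept_b
        table["reads_other"] = other
        out[hybrid] = table
    return out


# ---------------------------------------------------------------------------
# Mark tracks
# ---------------------------------------------------------------------------


@dataclass
class MarkTracks:
    regions: dict[str, RegionSet]  # H3K9me2, DNA_methylation, H3K4me3, H2A_Z
    sirna: pd.DataFrame  # bedGraph-style chrom/start/end/value (read counts)


def simulate_mark_tracks(
    annotation: GenomeAnnotation,
    state_spec: ChromatinStateSpec,
    params: SimulationParams,
) -> MarkTracks:
    """Binary mark tracks and a siRNA count track consistent with the
    chromatin states: heterochromatic genes and TE bodies (plus a spreading
    margin) carry H3K9me2/DNA methylation; active genes get a 5'-peaked
    H3K4me3 (and TSS H2A.Z) region; siRNA reads are distributed over TE
    bodies and sum exactly to ``sirna_total_count``.
    """
    rng = params.rng(5)
    margin = params.spreading_margin_bp
    lengths = annotation.sequences

    def clipped(chrom: str, s: int, e: int) -> GenomicInterval | None:
        s, e = max(0, s), min(lengths[chrom], e)
        return GenomicInterval(chrom, s, e) if s < e else None

    het: list[GenomicInterval] = []
    for g in annotation.genes:
        if state_spec.gene_states[g.gene_id] == "K9_heterochromatic":
            iv = g.interval
            c = clipped(iv.chrom, iv.start - margin, iv.end + margin)
            if c:
                het.append(c)
    for t in annotation.tes:
        iv = t.interval
        c = clipped(iv.chrom, iv.start - margin, iv.end + margin)
        if c:
            het.append(c)
    k9 = merge_intervals(het, max_gap=1, label="H3K9me2")
    dname = merge_intervals(het, max_gap=1, label="DNA_methylation")

    k4: list[GenomicInterval] = []
    h2az: list[GenomicInterval] = []
    for g in annotation.genes:
        state = state_spec.gene_states[g.gene_id]
        iv = g.interval
        tss = iv.start if iv.strand != "-" else iv.end
        if state == "active_K4":
            span = min(600, len(iv))
            if iv.strand != "-":
                c = clipped(iv.chrom, iv.start, iv.start + span)
            else:
                c = clipped(iv.chrom, iv.end - span, iv.end)
            if c:
                k4.append(c)
        if state in ("active_K4", "none"):
            c = clipped(iv.chrom, tss - 100, tss + 400)
            if c:
                h2az.append(c)
    k4_set = merge_intervals(k4, max_gap=1, label="H3K4me3")
    h2az_set = merge_intervals(h2az, max_gap=1, label="H2A_Z")

    # siRNA counts: multinomial over 100 bp windows tiling TE bodies
    windows: list[tuple[str, int, int]] = []
    for t in annotation.tes:
        iv = t.interval
        for s in range(iv.start, iv.end, 100):
            windows.append((iv.chrom, s, min(s + 100, iv.end)))
    if windows:
        weights = np.array([e - s for _, s, e in windows], dtype=float)
        counts = rng.multinomial(params.sirna_total_count, weights / weights.sum())
    else:
        counts = np.empty(0, dtype=int)
    sirna = pd.DataFrame(
        {
            "chrom": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "end": [w[2] for w in windows],
            "value": counts,
        }
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return MarkTracks(
        {
            "H3K9me2": k9,
            "DNA_methylation": dname,
            "H3K4me3": k4_set,
            "H2A_Z": h2az_set,
        },
        sirna,
    )


# ---------------------------------------------------------------------------
# Hybrid read starts
# ---------------------------------------------------------------------------


def simulate_read_starts(
    annotation: GenomeAnnotation,
    state_spec: ChromatinStateSpec,
    params: SimulationParams,
) -> dict[str, dict[str, pd.DataFrame]]:
    """ChIP and input read-start tables per hybrid.

    Input reads are uniform at ``seq_background_per_bp``; ChIP adds, over
    every gene carrying H3K27me3 in at least one parent, extra reads at
    ``seq_enrichment_fold`` times background (halved for single-allele
    targets, which contribute chromatin from only one parent).  Tables are
    aggregated per (chrom, pos, strand) with multiplicity, so PCR-duplicate
    removal has observable work.
    """
    lengths = annotation.sequences
    enriched: list[tuple[GenomicInterval, float]] = []
    for g in annotation.genes:
        state = state_spec.gene_states[g.gene_id]
        if state == "shared_K27":
            enriched.append((g.interval, params.seq_enrichment_fold))
        elif state in ("A_specific_K27", "B_specific_K27"):
            enriched.append((g.interval, params.seq_enrichment_fold / 2))

    out: dict[str, dict[str, pd.DataFrame]] = {}
    for hi, hybrid in enumerate(HYBRIDS):
        rng = params.rng(7 + hi)
        tracks: dict[str, pd.DataFrame] = {}
        for kind in ("chip", "input"):
            rows_chrom: list[np.ndarray] = []
            rows_pos: list[np.ndarray] = []
            for chrom, L in lengths.items():
                n_bg = rng.poisson(params.seq_background_per_bp * L)
                pos = rng.integers(0, L, size=n_bg)
                rows_chrom.append(np.full(n_bg, chrom, dtype=object))
                rows_pos.append(pos)
            if kind == "chip":
                for iv, fold in enriched:
                    lam = params.seq_background_per_bp * fold * len(iv)
                    n_extra = rng.poisson(lam)
                    pos = rng.integers(iv.start, iv.end, size=n_extra)
                    rows_chrom.append(np.full(n_extra, iv.chrom, dtype=object))
                    rows_pos.append(pos)
            chroms = np.concatenate(rows_chrom)
            positions = np.concatenate(rows_pos)
            strands = np.where(rng.integers(0, 2, size=len(positions)) == 0, "+", "-")
            df = (
                pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strands})
                .groupby(["chrom", "pos", "strand"], as_index=False)
                .size()
                .rename(columns={"size": "count"})
                .sort_values(["chrom", "pos", "strand"], kind="mergesort")
                .reset_index(drop=True)
            )
            tracks[kind] = df
        out[hybrid] = tracks
    return out
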
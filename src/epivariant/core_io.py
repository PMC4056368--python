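"""Domain types, genome-interval algebra and readers/writers.

Every coordinate held in memory is 0-based half-open ``[start, end)``.
Conversion to the 1-based closed conventions of GFF3 and the SNP table
happens only at the I/O boundary; BED and bedGraph are 0-based half-open
on disk already.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TeModel",
    "GenomeAnnotation",
    "RegionSet",
    "PipelineConfig",
    "TE_FAMILIES",
    "merge_intervals",
    "overlap_bp",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_snp_table",
    "write_snp_table",
    "get_logger",
]

STRANDS = ("+", "-", ".")

#: Controlled vocabulary of transposable-element families (superfamilies in
#: the TAIR-style annotation the pipeline emulates).
TE_FAMILIES = (
    "LTR/Copia",
    "LTR/Gypsy",
    "LINE",
    "SINE",
    "DNA/MuDR",
    "DNA/Harbinger",
    "RC/Helitron",
)


def get_logger(name: str = "epivariant") -> logging.Logger:
    """Structured stderr logger shared by all pipeline stages."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a named sequence, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"

    _BIOTYPES = ("protein_coding", "te_gene", "pseudogene")

    def __post_init__(self) -> None:
        if self.biotype not in self._BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class TeModel:
    te_id: str
    interval: GenomicInterval
    family: str

    def __post_init__(self) -> None:
        if self.family not in TE_FAMILIES:
            raise ValueError(
                f"TE family {self.family!r} not in controlled vocabulary {TE_FAMILIES}"
            )


@dataclass
class GenomeAnnotation:
    """Gene and TE models over a set of named sequences."""

    sequences: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    tes: list[TeModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        seen_te: set[str] = set()
        for t in self.tes:
            if t.te_id in seen_te:
                raise ValueError(f"duplicate te_id {t.te_id!r}")
            seen_te.add(t.te_id)
        for feat_id, iv in self._iter_ids():
            length = self.sequences.get(iv.chrom)
            if length is None:
                raise ValueError(f"{feat_id}: unknown sequence {iv.chrom!r}")
            if iv.end > length:
                raise ValueError(
                    f"{feat_id}: interval end {iv.end} beyond {iv.chrom} length {length}"
                )

    def _iter_ids(self) -> Iterator[tuple[str, GenomicInterval]]:
        for g in self.genes:
            yield g.gene_id, g.interval
        for t in self.tes:
            yield t.te_id, t.interval

    def gene(self, gene_id: str) -> GeneModel:
        return self.genes_by_id[gene_id]

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @property
    def tes_by_id(self) -> dict[str, TeModel]:
        return {t.te_id: t for t in self.tes}


class RegionSet:
    """A labelled set of disjoint, sorted genomic intervals.

    Construct through :func:`merge_intervals` (or with pre-disjoint input);
    overlapping or abutting intervals on one chromosome are rejected.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        self.label = label
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"intervals overlap after sorting: {a} / {b}; merge first"
                )
        self.intervals: list[GenomicInterval] = ivs
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for iv in ivs:
            self._index.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._index = {
            chrom: (
                np.array([iv.start for iv in lst], dtype=np.int64),
                np.array([iv.end for iv in lst], dtype=np.int64),
            )
            for chrom, lst in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._index.get(chrom, (empty, empty))


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0, label: str = ""
) -> RegionSet:
    """Merge intervals whose gap is strictly smaller than ``max_gap``.

    Two intervals on the same chromosome are combined iff
    ``next.start - prev.end < max_gap``, applied transitively; overlapping
    intervals (negative gap) always merge.  The array stage uses 300 bp and
    the sequencing stage 200 bp; "smaller than" is strict in both.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end < max_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return RegionSet(label, merged)


def overlap_bp(region_set: RegionSet, interval: GenomicInterval) -> int:
    """Total base pairs of ``interval`` intersected by the region set."""
    starts, ends = region_set.arrays(interval.chrom)
    if len(starts) == 0:
        return 0
    lo = max(0, int(np.searchsorted(ends, interval.start, side="right")))
    hi = int(np.searchsorted(starts, interval.end, side="left"))
    if hi <= lo:
        return 0
    s = np.maximum(starts[lo:hi], interval.start)
    e = np.minimum(ends[lo:hi], interval.end)
    return int(np.maximum(e - s, 0).sum())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis in one place: merge gaps,
    gene-coverage rules, pfp cutoff, SNP filters, permutation sizes, flank
    width and metagene binning."""

    merge_gap_array: int = 300
    merge_gap_seq: int = 200
    gene_rule_array: tuple[float, int, int] = (0.30, 300, 1000)
    gene_rule_seq: tuple[float, int, int] = (0.20, 200, 800)
    pfp_threshold: float = 0.15
    min_probes_per_gene: int = 3
    min_probe_coverage_frac: float = 0.40
    min_reads_per_snp: int = 3
    allele_perm_draws: int = 100_000
    te_perm_draws: int = 200
    te_perm_sample_size: int = 28
    flank_bp: int = 5000
    metagene_body_bins: int = 10
    metagene_flank_bin_bp: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.gene_rule_array = tuple(self.gene_rule_array)  # type: ignore[assignment]
        self.gene_rule_seq = tuple(self.gene_rule_seq)  # type: ignore[assignment]
        for name in (
            "merge_gap_array",
            "merge_gap_seq",
            "min_probes_per_gene",
            "min_reads_per_snp",
            "flank_bp",
            "metagene_body_bins",
            "metagene_flank_bin_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rule in (self.gene_rule_array, self.gene_rule_seq):
            frac, min_bp, long_bp = rule
            if not (0 < frac <= 1):
                raise ValueError("gene-rule fraction must be in (0, 1]")
            if min_bp < 0 or long_bp < 0:
                raise ValueError("gene-rule bp thresholds must be >= 0")
        if not (0 < self.pfp_threshold <= 1):
            raise ValueError("pfp_threshold must be in (0, 1]")
        if not (0 < self.min_probe_coverage_frac <= 1):
            raise ValueError("min_probe_coverage_frac must be in (0, 1]")
        for name in ("allele_perm_draws", "te_perm_draws", "te_perm_sample_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_GENE_TYPES = {"gene"}
_GFF_TE_TYPES = {"transposable_element"}


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed attribute {part!r}")
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_annotation(path: str) -> GenomeAnnotation:
    """Read genes and transposable elements from a GFF3 file.

    GFF3 is 1-based closed on disk; the returned annotation is 0-based
    half-open.  Sequence lengths come from ``##sequence-region`` pragmas.
    """
    sequences: dict[str, int] = {}
    genes: list[GeneModel] = []
    tes: list[TeModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed sequence-region")
                sequences[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in _GFF_GENE_TYPES | _GFF_TE_TYPES:
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
                attributes = _parse_attributes(attrs)
                feat_id = attributes["ID"]
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if ftype in _GFF_GENE_TYPES:
                genes.append(
                    GeneModel(feat_id, iv, attributes.get("biotype", "protein_coding"))
                )
            else:
                tes.append(TeModel(feat_id, iv, attributes.get("family", "LINE")))
    return GenomeAnnotation(sequences, genes, tes)


def write_annotation(annotation: GenomeAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.sequences.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tepivariant\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
        for t in annotation.tes:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tepivariant\ttransposable_element\t{iv.start + 1}\t"
                f"{iv.end}\t.\t{iv.strand}\t.\tID={t.te_id};family={t.family}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / BED / bedGraph / SNP table
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str, label: str = "") -> RegionSet:
    """Read a BED file as a RegionSet (first three columns used; strand from
    column 6 when present)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return RegionSet(label, intervals)


def write_bed(region_set: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(region_set):
            name = f"{region_set.label or 'region'}_{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_snp_table(path: str) -> pd.DataFrame:
    """Read a SNP table (chrom, pos 1-based, allele_A, allele_B on disk) into
    a frame with a 0-based ``pos`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "allele_A", "allele_B"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["allele_A"] == df["allele_B"]).any():
        raise ValueError("SNP table contains rows with identical alleles")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_snp_table(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


def assign_snps_to_genes(
    snps: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Annotate each SNP row with the gene whose body contains it (or NA)."""
    out = snps.copy()
    gene_ids = np.full(len(out), None, dtype=object)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.interval.start)
        starts = np.array([g.interval.start for g in genes])
        ends = np.array([g.interval.end for g in genes])
        mask = out["chrom"].to_numpy() == chrom
        pos = out.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        assigned = np.full(len(pos), None, dtype=object)
        assigned[ok] = [genes[i].gene_id for i in idx[ok]]
        gene_ids[np.flatnonzero(mask)] = assigned
    out["gene_id"] = gene_ids
    return out
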
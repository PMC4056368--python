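"""Re-mapping of tiling-array probes to two accession genomes.

Probes are short (tens of bp) and ungapped, so placements are found by
Hamming distance on both strands, either by an exhaustive sliding-window
scan (the reference implementation, used as oracle and for tiny inputs) or
by a pigeonhole k-mer seed index that returns identical results: a probe
placed with at most two mismatches must match at least one of three
near-equal probe thirds exactly.

Admission then applies the uniqueness rules that decide which probes feed
each analysis: the global target analysis needs a unique best hit in the
reference accession separated by two mismatches from the next-best site;
the accession-B-specific (Ler) differential direction additionally needs a
unique placement in genome B tolerating up to two mismatches; the
accession-A-specific (Col) direction demands perfect unique matches in
both genomes so that SNP-induced signal loss cannot mimic differential
methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval

__all__ = [
    "Probe",
    "ProbeAdmission",
    "GenomeSeedIndex",
    "map_probe",
    "map_probe_bruteforce",
    "admit_probes",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Probe:
    probe_id: str
    sequence: str
    #: per-genome placements, sorted by (mismatches, chrom, start)
    placements: dict[str, list[tuple[GenomicInterval, int]]] = field(
        default_factory=dict
    )


@dataclass(frozen=True)
class ProbeAdmission:
    probe_id: str
    admitted_global_A: bool
    admitted_global_B: bool
    admitted_differential: bool
    reason: str


class AmbiguousProbeError(ValueError):
    """Probe sequence contains bases outside {A, C, G, T}."""


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - _VALID:
        raise AmbiguousProbeError(f"probe contains ambiguous bases: {seq!r}")
    return seq


def _hamming_counts(genome_arr: np.ndarray, probe_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of the probe at every start position (sliding window)."""
    n, m = len(genome_arr), len(probe_arr)
    if n < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(genome_arr, m)
    return (windows != probe_arr).sum(axis=1)


def map_probe_bruteforce(
    probe_seq: str, genome: Mapping[str, str], max_mismatches: int
) -> list[tuple[GenomicInterval, int]]:
    """Exhaustive sliding-window scan of both strands; the oracle path."""
    probe_seq = _check_sequence(probe_seq)
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    hits: list[tuple[GenomicInterval, int]] = []
    fwd = np.frombuffer(probe_seq.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(probe_seq).encode(), dtype=np.uint8)
    for chrom, seq in genome.items():
        garr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for strand, parr in (("+", fwd), ("-", rev)):
            mm = _hamming_counts(garr, parr)
            for pos in np.flatnonzero(mm <= max_mismatches):
                hits.append(
                    (
                        GenomicInterval(chrom, int(pos), int(pos) + len(probe_seq), strand),
                        int(mm[pos]),
                    )
                )
    hits.sort(key=lambda h: (h[1], h[0].chrom, h[0].start, h[0].strand))
    return hits


class GenomeSeedIndex:
    """Exact k-mer position index over the forward strand of a genome.

    Lazily builds one dictionary per requested k; candidate placements are
    verified by direct Hamming comparison, so results equal the exhaustive
    scan by the pigeonhole argument (three seed parts cover <=2 mismatches).
    """

    def __init__(self, genome: Mapping[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._arrays = {
            c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in self.genome.items()
        }
        self._kmer_index: dict[int, dict[bytes, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[bytes, list[tuple[str, int]]]:
        if k not in self._kmer_index:
            idx: dict[bytes, list[tuple[str, int]]] = {}
            for chrom, seq in self.genome.items():
                raw = seq.encode()
                for pos in range(0, len(raw) - k + 1):
                    idx.setdefault(raw[pos : pos + k], []).append((chrom, pos))
            self._kmer_index[k] = idx
        return self._kmer_index[k]

    def _verify(
        self, probe: str, chrom: str, start: int, max_mismatches: int
    ) -> int | None:
        garr = self._arrays[chrom]
        m = len(probe)
        if start < 0 or start + m > len(garr):
            return None
        window = garr[start : start + m]
        mm = int((window != np.frombuffer(probe.encode(), dtype=np.uint8)).sum())
        return mm if mm <= max_mismatches else None

    def map_probe(
        self, probe_seq: str, max_mismatches: int
    ) -> list[tuple[GenomicInterval, int]]:
        probe_seq = _check_sequence(probe_seq)
        if max_mismatches not in (0, 1, 2):
            raise ValueError("max_mismatches must be 0, 1 or 2")
        m = len(probe_seq)
        n_parts = max_mismatches + 1
        bounds = np.linspace(0, m, n_parts + 1).astype(int)
        hits: dict[tuple[str, int, str], int] = {}
        for strand in ("+", "-"):
            oriented = probe_seq if strand == "+" else revcomp(probe_seq)
            for i in range(n_parts):
                lo, hi = int(bounds[i]), int(bounds[i + 1])
                part = oriented[lo:hi].encode()
                for chrom, pos in self._index_for(hi - lo).get(part, ()):
                    start = pos - lo
                    key = (chrom, start, strand)
                    if key in hits:
                        continue
                    mm = self._verify(oriented, chrom, start, max_mismatches)
                    if mm is not None:
                        hits[key] = mm
        out = [
            (GenomicInterval(chrom, start, start + m, strand), mm)
            for (chrom, start, strand), mm in hits.items()
        ]
        out.sort(key=lambda h: (h[1], h[0].chrom, h[0].start, h[0].strand))
        return out


def map_probe(
    probe_seq: str,
    genome: Mapping[str, str] | GenomeSeedIndex,
    max_mismatches: int,
) -> list[tuple[GenomicInterval, int]]:
    """All placements of a probe with Hamming distance <= ``max_mismatches``.

    Accepts either a plain ``{name: sequence}`` mapping (exhaustive scan)
    or a prebuilt :class:`GenomeSeedIndex` (seed-and-verify; identical
    output).  Placements are sorted by distance, then coordinate.
    """
    if isinstance(genome, GenomeSeedIndex):
        return genome.map_probe(probe_seq, max_mismatches)
    return map_probe_bruteforce(probe_seq, genome, max_mismatches)


# ---------------------------------------------------------------------------
# Admission rules
# ---------------------------------------------------------------------------

MODES = ("global", "differential_ler", "differential_col")


def _unique_with_separation(
    placements: Sequence[tuple[GenomicInterval, int]],
    *,
    require_perfect: bool = False,
    require_separation: bool = True,
) -> tuple[bool, str]:
    """Unique best placement, next-best >= best + 2 mismatches (within the
    computed <=2-mismatch ceiling)."""
    if not placements:
        return False, "no_match"
    best = placements[0][1]
    if require_perfect and best != 0:
        return False, "no_perfect_match"
    ties = sum(1 for _, mm in placements if mm == best)
    if ties > 1:
        return False, "multi_mapping"
    if require_separation:
        near = sum(1 for _, mm in placements if best < mm < best + 2)
        if near > 0:
            return False, "poor_separation"
    return True, "ok"


def admit_probes(
    probes: Sequence[Probe],
    genome_A: Mapping[str, str] | GenomeSeedIndex,
    genome_B: Mapping[str, str] | GenomeSeedIndex,
    mode: str = "global",
    *,
    require_separation_in_B: bool = True,
) -> list[ProbeAdmission]:
    """Apply the per-mode uniqueness/mismatch admission rules.

    Placements are computed at the two-mismatch ceiling and cached on each
    probe under keys ``"A"`` and ``"B"``.  The second-best separation rule
    is always enforced in genome A; in genome B it is on by default and
    switchable (the original study does not state it for the B genome).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    out: list[ProbeAdmission] = []
    for probe in probes:
        try:
            _check_sequence(probe.sequence)
        except AmbiguousProbeError:
            out.append(ProbeAdmission(probe.probe_id, False, False, False, "ambiguous_sequence"))
            continue
        if "A" not in probe.placements:
            probe.placements["A"] = map_probe(probe.sequence, genome_A, 2)
        if "B" not in probe.placements:
            probe.placements["B"] = map_probe(probe.sequence, genome_B, 2)
        pA, pB = probe.placements["A"], probe.placements["B"]
        ok_A, reason_A = _unique_with_separation(pA)
        ok_B, _ = _unique_with_separation(pB)
        if mode == "global":
            admitted, reason = ok_A, reason_A if not ok_A else "ok"
        elif mode == "differential_ler":
            ok_B_mode, reason_B = _unique_with_separation(
                pB, require_separation=require_separation_in_B
            )
            admitted = ok_A and ok_B_mode
            reason = reason_A if not ok_A else (reason_B + "_B" if not ok_B_mode else "ok")
        else:  # differential_col
            ok_A_perf, reason_A_perf = _unique_with_separation(pA, require_perfect=True)
            ok_B_perf, reason_B_perf = _unique_with_separation(
                pB, require_perfect=True, require_separation=require_separation_in_B
            )
            admitted = ok_A_perf and ok_B_perf
            reason = (
                "ok"
                if admitted
                else (reason_A_perf if not ok_A_perf else reason_B_perf + "_B")
            )
        out.append(ProbeAdmission(probe.probe_id, ok_A, ok_B, admitted, reason))
    return out


def admission_table(admissions: Sequence[ProbeAdmission]):
    """Admissions as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in admissions],
            "admitted_global_A": [a.admitted_global_A for a in admissions],
            "admitted_global_B": [a.admitted_global_B for a in admissions],
            "admitted_differential": [a.admitted_differential for a in admissions],
            "reason": [a.reason for a in admissions],
        }
    )
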
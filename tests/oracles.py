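"""Shared brute-force oracles and fixture builders used by several test
modules; each stays independent of the implementation path it checks."""

import numpy as np
import pandas as pd

from epivariant.core_io import GenomicInterval, TeModel
from epivariant.rankprod_diff import GeneEnrichmentMatrix


def merge_oracle(intervals, max_gap):
    """O(n^2) pairwise transitive-closure interval merge."""
    items = [[iv.chrom, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap < max_gap or (a[1] < b[2] and b[1] < a[2]):
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e in items)


def make_gene_matrix(values, reps_a=2, reps_b=2):
    """GeneEnrichmentMatrix from an array of per-gene per-column values."""
    values = np.asarray(values, dtype=float)
    cols = pd.MultiIndex.from_tuples(
        [("A", f"rep{i+1}") for i in range(reps_a)]
        + [("B", f"rep{i+1}") for i in range(reps_b)],
        names=["accession", "replicate"],
    )
    idx = [f"g{i}" for i in range(len(values))]
    vals = pd.DataFrame(values, index=idx, columns=cols)
    meta = pd.DataFrame({"n_probes": 5, "probe_coverage_frac": 0.6}, index=vals.index)
    return GeneEnrichmentMatrix(vals, meta)


def build_polymorphic_pair(rng, tsd="ATTTG", present=False):
    """Genome A with a TE at a known spot; genome B with the TE present or
    cleanly deleted (one TSD copy kept at the junction)."""
    L = 12_000
    seq = rng.choice(list("ACGT"), size=L)
    s, e = 5_000, 6_200
    a = "".join(seq)
    if tsd:
        a = a[: s - len(tsd)] + tsd + a[s:e] + tsd + a[e + len(tsd) :]
    te = TeModel("te1", GenomicInterval("chr1", s, e), "LTR/Copia")
    if present:
        b = a
    elif tsd:
        b = a[:s] + a[e + len(tsd) :]  # keep the 5' copy, drop TE + 3' copy
    else:
        b = a[:s] + a[e:]
    return te, {"chr1": a}, {"chr1": b}
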
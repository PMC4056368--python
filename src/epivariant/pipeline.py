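"""End-to-end orchestration: simulate (or load) inputs, map probes, call
targets in both accessions, detect differential targets, call hybrid
targets, quantify allele-specific inheritance, build metagene profiles
and run the TE-association tests — all from a single config, with a
machine-readable run report.

Artifacts live under an output directory::

    outdir/inputs/    genomes, annotation, SNPs, probes, signal, reads,
                      mark tracks, ground truth (synthetic mode)
    outdir/results/   admissions, targets, differential calls, islands,
                      allele tables, profiles, presence calls, report.json

Real mode reads the same formats from user-supplied paths, so the two
modes share one code path from the first analysis stage onward.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import allele_seq, metagene, probe_map, rankprod_diff, seq_chip, te_assoc, tiling_chip
from .core_io import (
    GenomeAnnotation,
    PipelineConfig,
    get_logger,
    read_annotation,
    read_bedgraph,
    read_fasta,
    read_snp_table,
    write_annotation,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_snp_table,
    assign_snps_to_genes,
)
from .simulate import (
    HYBRIDS,
    SimulationParams,
    make_probes,
    simulate_array_signal,
    simulate_f1_allele_counts,
    simulate_genomes,
    simulate_mark_tracks,
    simulate_read_starts,
)
from .tiling_chip import SignalMatrix

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = get_logger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | real
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    simulation: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    #: real-mode input paths (same formats the synthetic stage writes)
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    rank_product_permutations: int = 1000


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    mode = data.get("mode", "synthetic")
    if mode not in ("synthetic", "real"):
        raise ValueError(f"mode must be synthetic or real, got {mode!r}")
    return RunConfig(
        mode=mode,
        pipeline=PipelineConfig(**(data.get("pipeline") or {})),
        simulation=SimulationParams(**(data.get("simulation") or {})),
        inputs=data.get("inputs") or {},
        rank_product_permutations=int(data.get("rank_product_permutations", 1000)),
    )


# ---------------------------------------------------------------------------
# Signal table I/O (long format: probe_id, accession, replicate, M, A)
# ---------------------------------------------------------------------------


def write_signal_table(signal: SignalMatrix, path: str) -> None:
    rows = []
    for (acc, rep) in signal.M.columns:
        chunk = pd.DataFrame(
            {
                "probe_id": signal.M.index,
                "accession": acc,
                "replicate": rep,
                "M": signal.M[(acc, rep)].to_numpy(),
                "A": signal.A[(acc, rep)].to_numpy() if signal.A is not None else np.nan,
            }
        )
        rows.append(chunk)
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def read_signal_table(path: str, probes: pd.DataFrame) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t")
    M = df.pivot(index="probe_id", columns=["accession", "replicate"], values="M")
    M = M.loc[probes.index]
    A = None
    if df["A"].notna().all():
        A = df.pivot(index="probe_id", columns=["accession", "replicate"], values="A")
        A = A.loc[probes.index]
    return SignalMatrix(probes, M, A)


# ---------------------------------------------------------------------------
# Stage: inputs
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    genome_A: dict[str, str]
    genome_B: dict[str, str]
    annotation: GenomeAnnotation
    snp_table: pd.DataFrame
    probes: list[probe_map.Probe]
    raw_signal_path: str
    allele_counts: dict[str, pd.DataFrame]
    read_starts: dict[str, dict[str, pd.DataFrame]]
    mark_regions: dict
    sirna: pd.DataFrame


def _prepare_synthetic_inputs(cfg: RunConfig, indir: str, resume: bool) -> PipelineInputs:
    marker = os.path.join(indir, "annotation.gff3")
    params = cfg.simulation
    if not (resume and os.path.exists(marker)):
        cohort = simulate_genomes(params)
        probes, design = make_probes(cohort.genome_A, params)
        signal = simulate_array_signal(
            cohort.annotation, cohort.state_spec, params, design
        )
        snps = assign_snps_to_genes(cohort.snp_table, cohort.annotation)
        allele = simulate_f1_allele_counts(
            snps, cohort.state_spec, cohort.annotation, params
        )
        reads = simulate_read_starts(cohort.annotation, cohort.state_spec, params)
        tracks = simulate_mark_tracks(cohort.annotation, cohort.state_spec, params)

        write_fasta(cohort.genome_A, os.path.join(indir, "genome_A.fa"))
        write_fasta(cohort.genome_B, os.path.join(indir, "genome_B.fa"))
        write_snp_table(cohort.snp_table, os.path.join(indir, "snps.tsv"))
        write_fasta(
            {p.probe_id: p.sequence for p in probes}, os.path.join(indir, "probes.fa")
        )
        write_signal_table(signal, os.path.join(indir, "signal.tsv"))
        for hybrid in HYBRIDS:
            allele[hybrid].to_csv(
                os.path.join(indir, f"allele_counts_{hybrid}.tsv"), sep="\t", index=False
            )
            for kind in ("chip", "input"):
                reads[hybrid][kind].to_csv(
                    os.path.join(indir, f"reads_{hybrid}_{kind}.tsv"),
                    sep="\t",
                    index=False,
                )
        for mark, rs in tracks.regions.items():
            write_bed(rs, os.path.join(indir, f"track_{mark}.bed"))
        write_bedgraph(tracks.sirna, os.path.join(indir, "track_siRNA.bedgraph"))
        truth = pd.DataFrame(
            sorted(cohort.state_spec.gene_states.items()),
            columns=["gene_id", "true_state"],
        )
        truth.to_csv(os.path.join(indir, "truth_genes.tsv"), sep="\t", index=False)
        te_truth = pd.DataFrame(
            [
                {
                    "te_id": te_id,
                    "presence": pres,
                    "tsd": cohort.state_spec.tsd.get(te_id) or "",
                }
                for te_id, pres in sorted(cohort.state_spec.te_presence.items())
            ]
        )
        te_truth.to_csv(os.path.join(indir, "truth_tes.tsv"), sep="\t", index=False)
        # annotation last: its presence marks the input stage complete
        write_annotation(cohort.annotation, marker)
    return _load_inputs_from_dir(indir)


def _load_inputs_from_dir(indir: str, paths: dict[str, str] | None = None) -> PipelineInputs:
    def p(name: str, default: str) -> str:
        if paths and name in paths:
            return paths[name]
        return os.path.join(indir, default)

    def require(name: str, default: str) -> str:
        path = p(name, default)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"input stage: missing {name!r} file at {path}"
            )
        return path

    annotation = read_annotation(require("annotation", "annotation.gff3"))
    genome_A = read_fasta(require("genome_A", "genome_A.fa"))
    genome_B = read_fasta(require("genome_B", "genome_B.fa"))
    snps = read_snp_table(require("snps", "snps.tsv"))
    probe_seqs = read_fasta(require("probes", "probes.fa"))
    probes = [probe_map.Probe(pid, seq) for pid, seq in probe_seqs.items()]
    allele = {
        hybrid: pd.read_csv(
            require(f"allele_counts_{hybrid}", f"allele_counts_{hybrid}.tsv"), sep="\t"
        )
        for hybrid in HYBRIDS
    }
    reads = {
        hybrid: {
            kind: pd.read_csv(
                require(f"reads_{hybrid}_{kind}", f"reads_{hybrid}_{kind}.tsv"),
                sep="\t",
                dtype={"chrom": str},
            )
            for kind in ("chip", "input")
        }
        for hybrid in HYBRIDS
    }
    from .core_io import read_bed

    mark_regions = {}
    for mark in ("H3K9me2", "DNA_methylation", "H3K4me3", "H2A_Z"):
        path = p(f"track_{mark}", f"track_{mark}.bed")
        if os.path.exists(path):
            mark_regions[mark] = read_bed(path, label=mark)
    sirna_path = p("track_siRNA", "track_siRNA.bedgraph")
    sirna = read_bedgraph(sirna_path) if os.path.exists(sirna_path) else pd.DataFrame(
        columns=["chrom", "start", "end", "value"]
    )
    return PipelineInputs(
        genome_A,
        genome_B,
        annotation,
        snps,
        probes,
        require("signal", "signal.tsv"),
        allele,
        reads,
        mark_regions,
        sirna,
    )


def _save_placements(path: str, probes: list[probe_map.Probe]) -> None:
    rows = []
    for p in probes:
        wrote_any = False
        for genome_label, placements in p.placements.items():
            for iv, mm in placements:
                rows.append(
                    (p.probe_id, genome_label, iv.chrom, iv.start, iv.end, iv.strand, mm)
                )
                wrote_any = True
            if not placements:
                rows.append((p.probe_id, genome_label, ".", -1, -1, ".", -1))
                wrote_any = True
        if not wrote_any:
            rows.append((p.probe_id, "A", ".", -1, -1, ".", -1))
    pd.DataFrame(
        rows,
        columns=["probe_id", "genome", "chrom", "start", "end", "strand", "mismatches"],
    ).to_csv(path, sep="\t", index=False)


def _load_placements(path: str, probes: list[probe_map.Probe]) -> None:
    from .core_io import GenomicInterval

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    by_probe: dict[str, dict[str, list]] = {}
    for row in df.itertuples(index=False):
        slot = by_probe.setdefault(row.probe_id, {})
        lst = slot.setdefault(row.genome, [])
        if row.chrom != "." and row.start >= 0:
            lst.append(
                (
                    GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                    int(row.mismatches),
                )
            )
    for p in probes:
        cached = by_probe.get(p.probe_id)
        if cached is not None:
            p.placements = {g: lst for g, lst in cached.items()}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    cfg: RunConfig, outdir: str, *, resume: bool = False
) -> dict:
    """Execute every stage in dependency order; returns the run report
    (also written to ``outdir/results/report.json``).  Deterministic for a
    fixed config: rerunning produces a byte-identical report."""
    pcfg = cfg.pipeline
    indir = os.path.join(outdir, "inputs")
    resdir = os.path.join(outdir, "results")
    os.makedirs(indir, exist_ok=True)
    os.makedirs(resdir, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(pcfg),
        "mode": cfg.mode,
        "seeds": {"pipeline": pcfg.rng_seed, "simulation": cfg.simulation.rng_seed},
        "stages": {},
    }

    # ---- inputs ----------------------------------------------------------
    if cfg.mode == "synthetic":
        inputs = _prepare_synthetic_inputs(cfg, indir, resume)
    else:
        inputs = _load_inputs_from_dir(indir, cfg.inputs)
    ann = inputs.annotation
    report["stages"]["inputs"] = {
        "n_genes": len(ann.genes),
        "n_tes": len(ann.tes),
        "n_snps": len(inputs.snp_table),
        "n_probes": len(inputs.probes),
    }
    log.info("inputs: %s", report["stages"]["inputs"])

    # ---- probe mapping and admission ------------------------------------
    adm_path = os.path.join(resdir, "admissions.tsv")
    placements_path = os.path.join(resdir, "probe_placements.tsv")
    if resume and os.path.exists(placements_path):
        _load_placements(placements_path, inputs.probes)
        idx_a: probe_map.GenomeSeedIndex | dict = inputs.genome_A
        idx_b: probe_map.GenomeSeedIndex | dict = inputs.genome_B
    else:
        idx_a = probe_map.GenomeSeedIndex(inputs.genome_A)
        idx_b = probe_map.GenomeSeedIndex(inputs.genome_B)
    admissions = {}
    for mode in probe_map.MODES:
        admissions[mode] = probe_map.admit_probes(inputs.probes, idx_a, idx_b, mode)
    probe_map.admission_table(admissions["differential_ler"]).to_csv(
        adm_path, sep="\t", index=False
    )
    if not (resume and os.path.exists(placements_path)):
        _save_placements(placements_path, inputs.probes)
    admitted = {
        mode: {a.probe_id for a in admissions[mode] if a.admitted_differential}
        for mode in probe_map.MODES
    }
    report["stages"]["probe_map"] = {
        mode: len(ids) for mode, ids in admitted.items()
    }

    # probe coordinates: unique best placement in genome A
    coord_rows = []
    for p in inputs.probes:
        placements = p.placements.get("A", [])
        if not placements:
            continue
        iv, _mm = placements[0]
        coord_rows.append(
            {"probe_id": p.probe_id, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
        )
    coords = pd.DataFrame(coord_rows).set_index("probe_id")

    # ---- array targets ---------------------------------------------------
    globally_admitted = admitted["global"]
    coords_glob = coords[coords.index.isin(globally_admitted)]
    raw = read_signal_table(inputs.raw_signal_path, coords_glob)
    normalized = tiling_chip.normalize(raw)
    target_sets = {}
    for acc in ("A", "B"):
        positive = tiling_chip.call_positive_probes(normalized, acc)
        calls = tiling_chip.call_gene_targets(
            positive,
            normalized,
            ann.genes,
            merge_gap=pcfg.merge_gap_array,
            rule=pcfg.gene_rule_array,
            sample=acc,
        )
        target_sets[acc] = calls
        calls.table.to_csv(os.path.join(resdir, f"targets_array_{acc}.tsv"), sep="\t")
        if calls.regions is not None:
            write_bed(calls.regions, os.path.join(resdir, f"regions_array_{acc}.bed"))
    comparison = tiling_chip.compare_target_sets(target_sets["A"], target_sets["B"])
    report["stages"]["tiling_chip"] = {
        "n_targets_A": len(target_sets["A"].target_ids),
        "n_targets_B": len(target_sets["B"].target_ids),
        **comparison.counts,
    }
    log.info("array targets: %s", report["stages"]["tiling_chip"])

    # ---- differential (rank product) ------------------------------------
    differential: dict[str, set[str]] = {}
    for direction, mode_name in (("B", "differential_ler"), ("A", "differential_col")):
        sub_coords = coords[coords.index.isin(admitted[mode_name])]
        sub_raw = read_signal_table(inputs.raw_signal_path, sub_coords)
        sub_norm = tiling_chip.normalize(sub_raw)
        matrix = rankprod_diff.build_gene_matrix(
            sub_norm,
            admitted[mode_name],
            ann.genes,
            min_probes_per_gene=pcfg.min_probes_per_gene,
            min_probe_coverage_frac=pcfg.min_probe_coverage_frac,
        )
        matrix = rankprod_diff.filter_candidate_genes(
            matrix, target_sets["A"], target_sets["B"]
        )
        result = rankprod_diff.rank_product_test(
            matrix,
            n_perm=cfg.rank_product_permutations,
            seed=pcfg.rng_seed,
            pfp_threshold=pcfg.pfp_threshold,
        )
        differential[direction] = result.specific_targets(direction)
        result.table.to_csv(
            os.path.join(resdir, f"differential_{mode_name}.tsv"), sep="\t"
        )
    report["stages"]["rankprod_diff"] = {
        "n_ler_specific": len(differential["B"]),
        "n_col_specific": len(differential["A"]),
    }
    log.info("differential: %s", report["stages"]["rankprod_diff"])

    # ---- hybrid seq targets ---------------------------------------------
    hybrid_targets: dict[str, tiling_chip.TargetCallSet] = {}
    for hybrid in HYBRIDS:
        chip = seq_chip.deduplicate(
            seq_chip.ReadStartTrack(inputs.read_starts[hybrid]["chip"])
        )
        background = seq_chip.deduplicate(
            seq_chip.ReadStartTrack(inputs.read_starts[hybrid]["input"])
        )
        islands = seq_chip.call_islands(chip, background, ann.sequences)
        calls = seq_chip.call_hybrid_targets(
            islands,
            ann.genes,
            merge_gap=pcfg.merge_gap_seq,
            rule=pcfg.gene_rule_seq,
            sample=hybrid,
        )
        hybrid_targets[hybrid] = calls
        calls.table.to_csv(os.path.join(resdir, f"targets_seq_{hybrid}.tsv"), sep="\t")
    overlap = (
        hybrid_targets[HYBRIDS[0]].target_ids & hybrid_targets[HYBRIDS[1]].target_ids
    )
    report["stages"]["seq_chip"] = {
        **{f"n_targets_{h}": len(hybrid_targets[h].target_ids) for h in HYBRIDS},
        "n_overlap": len(overlap),
    }
    log.info("hybrid targets: %s", report["stages"]["seq_chip"])

    # ---- allele-specific inheritance ------------------------------------
    allele_report = {}
    common_targets = comparison.shared
    for hybrid in HYBRIDS:
        table = inputs.allele_counts[hybrid]
        filtered = allele_seq.filter_snps(table, pcfg.min_reads_per_snp)
        in_hybrid = hybrid_targets[hybrid].target_ids
        classes: dict[str, str] = {}
        for g in differential["B"]:
            if g in in_hybrid:
                classes[g] = "specific"
        for g in common_targets:
            if g in in_hybrid:
                classes[g] = "common"
        freqs = allele_seq.allele_frequency(filtered, classes)
        freqs.per_snp.to_csv(
            os.path.join(resdir, f"allele_{hybrid}.tsv"), sep="\t", index=False
        )
        entry: dict = {
            "median_specific": freqs.medians.get("specific"),
            "median_common": freqs.medians.get("common"),
            "n_snps_specific": len(freqs.class_freqs.get("specific", ())),
            "n_snps_common": len(freqs.class_freqs.get("common", ())),
        }
        if entry["n_snps_specific"] and entry["n_snps_common"] >= entry["n_snps_specific"]:
            perm = allele_seq.allele_permutation_test(
                freqs.class_freqs["specific"],
                freqs.class_freqs["common"],
                n_draws=pcfg.allele_perm_draws,
                seed=pcfg.rng_seed,
            )
            entry["permutation_p"] = perm.p_value
        allele_report[hybrid] = entry
    report["stages"]["allele_seq"] = allele_report
    log.info("allele: %s", allele_report)

    # ---- metagene --------------------------------------------------------
    gene_by_id = ann.genes_by_id
    gene_sets = {
        "ler_specific": [gene_by_id[g] for g in sorted(differential["B"])],
        "common_targets": [gene_by_id[g] for g in sorted(common_targets)],
        "non_targets": [
            g
            for g in ann.genes
            if g.gene_id not in target_sets["A"].target_ids
            and g.gene_id not in target_sets["B"].target_ids
        ],
    }
    profile_rows = []
    marks: list[tuple[str, object, str]] = []
    if "H3K9me2" in inputs.mark_regions:
        marks.append(("H3K9me2", inputs.mark_regions["H3K9me2"], "fraction_overlap"))
    if "DNA_methylation" in inputs.mark_regions:
        marks.append(
            ("DNA_methylation", inputs.mark_regions["DNA_methylation"], "fraction_overlap")
        )
    if len(inputs.sirna):
        marks.append(("siRNA_24nt", inputs.sirna, "normalized_count"))
    for set_label, genes in gene_sets.items():
        if not genes:
            continue
        for mark_label, track, mode in marks:
            prof = metagene.profile(
                genes,
                track,
                mode,
                body_bins=pcfg.metagene_body_bins,
                flank_bin_bp=pcfg.metagene_flank_bin_bp,
                chrom_lengths=ann.sequences,
                gene_set_label=set_label,
                mark_label=mark_label,
            )
            frame = prof.to_frame()
            frame.insert(0, "gene_set", set_label)
            frame.insert(1, "mark", mark_label)
            profile_rows.append(frame)
    if profile_rows:
        pd.concat(profile_rows).to_csv(
            os.path.join(resdir, "metagene_profiles.tsv"), sep="\t", index=False
        )
    report["stages"]["metagene"] = {
        "n_profiles": len(profile_rows),
        "gene_set_sizes": {k: len(v) for k, v in gene_sets.items()},
    }

    # ---- TE association --------------------------------------------------
    flanks = te_assoc.annotate_flanks(ann.genes, ann.tes, pcfg.flank_bp)
    flanked = {f.gene_id: f.is_flanked for f in flanks}
    query = sorted(g for g in differential["B"] if gene_by_id[g].biotype != "te_gene")
    background = sorted(g.gene_id for g in gene_sets["non_targets"])
    te_report: dict = {"n_query": len(query), "n_background": len(background)}
    if query and background:
        sample_size = min(pcfg.te_perm_sample_size, len(background))
        perm = te_assoc.te_flank_permutation(
            query,
            background,
            flanked,
            n_draws=pcfg.te_perm_draws,
            sample_size=sample_size,
            seed=pcfg.rng_seed,
        )
        te_report.update(
            {
                "observed_flanked_fraction": perm.observed_fraction,
                "permutation_p": perm.p_value,
            }
        )
    presence_rows = []
    n_absent = 0
    n_tsd = 0
    for te in ann.tes:
        call = te_assoc.te_presence_in_other_assembly(
            te, inputs.genome_A, inputs.genome_B
        )
        tsd = None
        if call.status == "absent_in_B":
            n_absent += 1
            tsd = te_assoc.find_tsd(te, inputs.genome_A, inputs.genome_B, call)
            if tsd:
                n_tsd += 1
        presence_rows.append(
            {"te_id": te.te_id, "status": call.status, "tsd": tsd or ""}
        )
    pd.DataFrame(presence_rows).to_csv(
        os.path.join(resdir, "te_presence.tsv"), sep="\t", index=False
    )
    comp = te_assoc.family_composition(ann.tes)
    comp.to_csv(os.path.join(resdir, "te_families.tsv"), sep="\t", index=False)
    te_report.update({"n_absent_in_B": n_absent, "n_with_tsd": n_tsd})
    report["stages"]["te_assoc"] = te_report
    log.info("te_assoc: %s", te_report)

    # ---- report ----------------------------------------------------------
    report["headline"] = {
        "n_targets_A": report["stages"]["tiling_chip"]["n_targets_A"],
        "n_targets_B": report["stages"]["tiling_chip"]["n_targets_B"],
        "n_shared": report["stages"]["tiling_chip"]["shared"],
        "n_ler_specific": report["stages"]["rankprod_diff"]["n_ler_specific"],
        "n_col_specific": report["stages"]["rankprod_diff"]["n_col_specific"],
        "hybrid_targets": {
            h: report["stages"]["seq_chip"][f"n_targets_{h}"] for h in HYBRIDS
        },
        "hybrid_overlap": report["stages"]["seq_chip"]["n_overlap"],
        "allele_medians": {
            h: {
                "specific": allele_report[h]["median_specific"],
                "common": allele_report[h]["median_common"],
            }
            for h in HYBRIDS
        },
    }
    with open(os.path.join(resdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
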
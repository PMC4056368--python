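"""Ground-truth structure of the synthetic two-accession cohort."""

import numpy as np
import pandas as pd
import pytest

from epivariant.core_io import assign_snps_to_genes, overlap_bp
from epivariant.simulate import (
    SimulationParams,
    make_probes,
    simulate_array_signal,
    simulate_f1_allele_counts,
    simulate_genomes,
    simulate_mark_tracks,
    simulate_genomes as _sim,
)

SMALL = dict(n_chroms=1, chrom_length_bp=170_000, n_genes=30, n_tes=8)


class TestGenomes:
    def test_null_polymorphism_gives_identical_genomes(self):
        p = SimulationParams(
            rng_seed=3,
            snp_rate=0.0,
            te_a_only_prob=0.0,
            te_b_only_prob=0.0,
            fraction_te_flanked_for_specific=0.0,
            **SMALL,
        )
        c = simulate_genomes(p)
        assert c.genome_A == c.genome_B
        assert len(c.snp_table) == 0
        assert all(v == "both" for v in c.state_spec.te_presence.values())

    def test_a_only_te_has_duplicated_tsd_in_A_single_copy_in_B(self, cohort):
        spec = cohort.state_spec
        with_tsd = [
            t for t in cohort.annotation.tes
            if spec.te_presence[t.te_id] == "A_only" and spec.tsd.get(t.te_id)
        ]
        assert with_tsd, "simulation should produce A-only TEs with TSDs"
        for te in with_tsd:
            motif = spec.tsd[te.te_id]
            iv = te.interval
            seq_a = cohort.genome_A[iv.chrom]
            left = seq_a[iv.start - len(motif) : iv.start]
            right = seq_a[iv.end : iv.end + len(motif)]
            assert left == motif and right == motif
            # B carries the junction X-t-Y: t followed directly by Y
            # (apply the B alleles of any SNPs falling in the checked window)
            y_start, y_end = iv.end + len(motif), iv.end + len(motif) + 30
            y = list(seq_a[y_start:y_end])
            snps = cohort.snp_table
            local = snps[
                (snps["chrom"] == iv.chrom)
                & (snps["pos"] >= y_start)
                & (snps["pos"] < y_end)
            ]
            for row in local.itertuples():
                y[row.pos - y_start] = row.allele_B
            assert motif + "".join(y) in cohort.genome_B[iv.chrom]

    def test_deterministic_under_seed(self):
        p1 = SimulationParams(rng_seed=11, **SMALL)
        c1, c2 = simulate_genomes(p1), simulate_genomes(SimulationParams(rng_seed=11, **SMALL))
        assert c1.genome_A == c2.genome_A
        assert c1.genome_B == c2.genome_B
        assert c1.snp_table.equals(c2.snp_table)
        assert c1.state_spec.gene_states == c2.state_spec.gene_states

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_genomes(
                SimulationParams(rng_seed=0, n_chroms=1, chrom_length_bp=30_000,
                                 n_genes=40, n_tes=5)
            )

    def test_snp_alleles_match_genomes(self, cohort):
        sub = cohort.snp_table.iloc[:: max(1, len(cohort.snp_table) // 200)]
        for row in sub.itertuples():
            assert cohort.genome_A[row.chrom][row.pos] == row.allele_A
            assert row.allele_A != row.allele_B


class TestArraySignal:
    def test_zero_effect_gives_indistinguishable_distributions(self):
        p = SimulationParams(rng_seed=5, enrichment_effect=0.0, intensity_bias=0.0, **SMALL)
        c = simulate_genomes(p)
        _, design = make_probes(c.genome_A, p)
        sig = simulate_array_signal(c.annotation, c.state_spec, p, design)
        k27 = c.state_spec.genes_in_state("shared_K27", "A_specific_K27")
        in_target = np.zeros(len(design), dtype=bool)
        for g in c.annotation.genes:
            if g.gene_id in k27:
                iv = g.interval
                in_target |= (
                    (design["chrom"] == iv.chrom)
                    & (design["start"] < iv.end)
                    & (design["end"] > iv.start)
                ).to_numpy()
        col = sig.M[("A", "rep1")].to_numpy()
        diff = col[in_target].mean() - col[~in_target].mean()
        se = p.replicate_noise_sd * np.sqrt(1 / in_target.sum() + 1 / (~in_target).sum())
        assert abs(diff) < 4 * se

    def test_noise_free_signal_is_exactly_the_effect(self):
        p = SimulationParams(
            rng_seed=5, enrichment_effect=2.0, replicate_noise_sd=0.0,
            intensity_bias=0.0, **SMALL,
        )
        c = simulate_genomes(p)
        _, design = make_probes(c.genome_A, p)
        sig = simulate_array_signal(c.annotation, c.state_spec, p, design)
        vals = sig.M[("B", "rep1")].to_numpy()
        assert set(np.round(np.unique(vals), 9)) == {0.0, 2.0}

    def test_effect_recovered_within_monte_carlo_error(self, cohort, params, probes_and_design):
        _, design = probes_and_design
        sig = simulate_array_signal(cohort.annotation, cohort.state_spec, params, design)
        k27 = cohort.state_spec.genes_in_state("shared_K27", "B_specific_K27")
        in_target = np.zeros(len(design), dtype=bool)
        for g in cohort.annotation.genes:
            if g.gene_id in k27:
                iv = g.interval
                in_target |= (
                    (design["chrom"] == iv.chrom)
                    & (design["start"] < iv.end)
                    & (design["end"] > iv.start)
                ).to_numpy()
        col = sig.M[("B", "rep2")].to_numpy()
        diff = col[in_target].mean() - col[~in_target].mean()
        # intensity bias inflates the spread beyond replicate noise alone
        sd = col[~in_target].std()
        se = sd * np.sqrt(1 / in_target.sum() + 1 / (~in_target).sum())
        assert abs(diff - params.enrichment_effect) < 3 * se


class TestAlleleCounts:
    def test_b_specific_snps_have_zero_col_reads_at_epsilon_zero(self, cohort, params):
        snps = assign_snps_to_genes(cohort.snp_table, cohort.annotation)
        tables = simulate_f1_allele_counts(snps, cohort.state_spec, cohort.annotation, params)
        b_genes = cohort.state_spec.genes_in_state("B_specific_K27")
        for table in tables.values():
            sel = table["gene_id"].isin(b_genes)
            assert sel.sum() >= 30
            assert (table.loc[sel, "reads_A"] == 0).all()

    def test_shared_targets_approach_half_frequency_at_high_depth(self):
        p = SimulationParams(rng_seed=9, read_depth_per_snp=4000.0, seq_error_rate=0.0, **SMALL)
        c = simulate_genomes(p)
        snps = assign_snps_to_genes(c.snp_table, c.annotation)
        t = simulate_f1_allele_counts(snps, c.state_spec, c.annotation, p)["ColxLer"]
        shared = c.state_spec.genes_in_state("shared_K27")
        sel = t["gene_id"].isin(shared)
        freq = t.loc[sel, "reads_A"] / (t.loc[sel, "reads_A"] + t.loc[sel, "reads_B"])
        assert np.allclose(freq, 0.5, atol=0.05)

    def test_regression_fixture(self):
        """Frozen per-SNP counts for a fixed seed guard the generator
        against silent drift."""
        p = SimulationParams(rng_seed=7, **SMALL)
        c = simulate_genomes(p)
        snps = assign_snps_to_genes(c.snp_table, c.annotation)
        t = simulate_f1_allele_counts(snps, c.state_spec, c.annotation, p)["ColxLer"]
        assert len(t) == 852
        got = t.iloc[[0, 5, 50, 100, 200, 300]][
            ["pos", "reads_A", "reads_B", "reads_other"]
        ].to_numpy().tolist()
        assert got == [
            [235, 2, 2, 0],
            [1167, 11, 8, 0],
            [11934, 3, 0, 0],
            [21352, 13, 0, 0],
            [40963, 0, 1, 0],
            [60206, 5, 1, 0],
        ]


class TestMarkTracks:
    def test_k9_genes_are_covered(self, cohort, params):
        tracks = simulate_mark_tracks(cohort.annotation, cohort.state_spec, params)
        k9 = tracks.regions["H3K9me2"]
        for g in cohort.annotation.genes:
            if cohort.state_spec.gene_states[g.gene_id] == "K9_heterochromatic":
                assert overlap_bp(k9, g.interval) / g.length >= 0.8

    def test_zero_margin_confines_k9_to_bodies(self):
        p = SimulationParams(rng_seed=3, spreading_margin_bp=0, **SMALL)
        c = simulate_genomes(p)
        tracks = simulate_mark_tracks(c.annotation, c.state_spec, p)
        allowed = [
            g.interval
            for g in c.annotation.genes
            if c.state_spec.gene_states[g.gene_id] == "K9_heterochromatic"
        ] + [t.interval for t in c.annotation.tes]
        for iv in tracks.regions["H3K9me2"]:
            assert any(
                a.chrom == iv.chrom and a.start <= iv.start and iv.end <= a.end
                for a in allowed
            ) or sum(a.overlap(iv) for a in allowed) == len(iv)

    def test_sirna_counts_conserved_exactly(self, cohort, params):
        tracks = simulate_mark_tracks(cohort.annotation, cohort.state_spec, params)
        assert int(tracks.sirna["value"].sum()) == params.sirna_total_count
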
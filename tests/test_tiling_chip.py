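"""Normalization, positive-probe calling and the array gene rule."""

import numpy as np
import pandas as pd
import pytest

from epivariant.core_io import GeneModel, GenomicInterval
from epivariant.tiling_chip import (
    SignalMatrix,
    apply_gene_rule,
    call_gene_targets,
    call_positive_probes,
    compare_target_sets,
    gene_coverage,
    normalize,
)
from epivariant.core_io import merge_intervals


def _matrix(values, intensities=None, spacing=100, probe_len=60):
    n = len(values)
    probes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + probe_len,
        },
        index=[f"p{i}" for i in range(n)],
    )
    cols = pd.MultiIndex.from_tuples([("A", "rep1"), ("A", "rep2")])
    M = pd.DataFrame(np.column_stack([values, values]), index=probes.index, columns=cols)
    A = None
    if intensities is not None:
        A = pd.DataFrame(
            np.column_stack([intensities, intensities]), index=probes.index, columns=cols
        )
    return SignalMatrix(probes, M, A)


class TestNormalize:
    def test_bias_free_input_nearly_unchanged(self, rng):
        vals = rng.normal(0, 1, 3000)
        inten = rng.normal(10, 1, 3000)
        sm = _matrix(vals, inten)
        out = normalize(sm)
        # loess fit of pure noise is close to zero; scale step preserves MAD
        assert np.abs(out.M.to_numpy() - sm.M.to_numpy()).mean() < 0.1

    def test_quadratic_intensity_bias_removed(self, rng):
        inten = rng.normal(10, 1, 4000)
        bias = 0.5 * ((inten - 10) ** 2 - 1)
        vals = rng.normal(0, 0.3, 4000) + bias
        out = normalize(_matrix(vals, inten))
        corr = np.corrcoef(out.M[("A", "rep1")], bias)[0, 1]
        assert abs(corr) <= 0.05

    def test_scale_step_equalises_mads(self, rng):
        n = 1000
        probes = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 100, "end": np.arange(n) * 100 + 60},
            index=[f"p{i}" for i in range(n)],
        )
        cols = pd.MultiIndex.from_tuples([("A", "rep1"), ("A", "rep2")])
        base = rng.normal(0, 1, n)
        M = pd.DataFrame(
            np.column_stack([base * 1.0, base * 4.0]), index=probes.index, columns=cols
        )
        out = normalize(SignalMatrix(probes, M, None))
        def mad(x):
            return np.median(np.abs(x - np.median(x)))
        m1 = mad(out.M[("A", "rep1")].to_numpy())
        m2 = mad(out.M[("A", "rep2")].to_numpy())
        assert m1 == pytest.approx(m2, rel=1e-9)

    def test_refuses_tiny_inputs(self, rng):
        with pytest.raises(ValueError, match="refusing"):
            normalize(_matrix(rng.normal(0, 1, 10), rng.normal(10, 1, 10)))


class TestPositiveProbes:
    def test_pure_background_gives_empty_set(self, rng):
        sm = _matrix(rng.normal(0, 0.5, 2000))
        assert call_positive_probes(sm, "A") == set()

    def test_enriched_block_fully_positive(self, rng):
        vals = rng.normal(0, 0.3, 2000)
        vals[1000:1010] += 4 * 0.3 + 2.0
        sm = _matrix(vals)
        positive = call_positive_probes(sm, "A")
        assert {f"p{i}" for i in range(1000, 1010)} <= positive

    def test_isolated_high_probe_suppressed_by_min_run(self, rng):
        vals = rng.normal(0, 0.3, 2000)
        vals[500] += 10.0
        sm = _matrix(vals)
        # the running median of the neighbourhood stays at background, and
        # even without smoothing a single probe cannot form a 3-probe run
        assert "p500" not in call_positive_probes(sm, "A")

    def test_intersection_mode_is_subset_of_averaged(self, normalized_signal):
        averaged = call_positive_probes(normalized_signal, "A")
        inter = call_positive_probes(
            normalized_signal, "A", replicate_mode="intersection"
        )
        assert len(inter) > 0
        assert len(inter & averaged) / len(inter) > 0.8


GENE_RULE_ARRAY = (0.30, 300, 1000)
GENE_RULE_SEQ = (0.20, 200, 800)


class TestGeneRule:
    @pytest.mark.parametrize(
        "length,covered,expected",
        [
            (1000, 350, True),  # 35% and >=300 bp
            (10_000, 1000, True),  # long-gene clause: 10% but >=1,000 bp
            (500, 250, False),  # 50% but <300 bp
            (1000, 300, True),  # boundary: exactly 30% and 300 bp
            (1000, 299, False),
        ],
    )
    def test_array_rule(self, length, covered, expected):
        assert apply_gene_rule(covered, length, GENE_RULE_ARRAY) is expected

    @pytest.mark.parametrize(
        "length,covered,expected",
        [
            (1000, 200, True),  # boundary inclusive: exactly 20% and 200 bp
            (8000, 800, True),  # long-gene clause
            (2000, 300, False),  # 15%
        ],
    )
    def test_seq_rule(self, length, covered, expected):
        assert apply_gene_rule(covered, length, GENE_RULE_SEQ) is expected

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            apply_gene_rule(100, 0, GENE_RULE_ARRAY)

    def test_monotone_in_region_size(self):
        """Enlarging an enriched region never flips a gene off."""
        gene = GeneModel("g", GenomicInterval("c", 1000, 3000, "+"))
        previous = False
        for covered_end in range(1000, 3001, 100):
            rs = merge_intervals([GenomicInterval("c", 1000, max(covered_end, 1001))], 0)
            calls = gene_coverage(rs, [gene], GENE_RULE_ARRAY, "s")
            now = bool(calls.table.loc["g", "is_target"])
            assert now >= previous
            previous = now


class TestTargets:
    def test_calls_match_ground_truth_at_low_noise(self):
        from epivariant.simulate import (
            SimulationParams,
            make_probes,
            simulate_array_signal,
            simulate_genomes,
        )

        p = SimulationParams(
            rng_seed=13, replicate_noise_sd=0.05, intensity_bias=0.0,
            n_chroms=1, chrom_length_bp=170_000, n_genes=30, n_tes=8,
        )
        c = simulate_genomes(p)
        _, design = make_probes(c.genome_A, p)
        sig = simulate_array_signal(c.annotation, c.state_spec, p, design)
        norm = normalize(sig)
        for acc in ("A", "B"):
            positive = call_positive_probes(norm, acc)
            calls = call_gene_targets(positive, norm, c.annotation.genes, sample=acc)
            truth = c.state_spec.genes_in_state(
                "shared_K27", f"{acc}_specific_K27"
            )
            assert calls.target_ids == truth

    def test_compare_target_sets(self, array_targets):
        cmp_ = compare_target_sets(array_targets["A"], array_targets["B"])
        union = cmp_.shared | cmp_.a_only | cmp_.b_only
        assert cmp_.shared.isdisjoint(cmp_.a_only)
        assert union == array_targets["A"].target_ids | array_targets["B"].target_ids
        same = compare_target_sets(array_targets["A"], array_targets["A"])
        assert same.a_only == set() and same.b_only == set()

    def test_mismatched_universe_rejected(self, array_targets):
        import copy

        other = copy.deepcopy(array_targets["B"])
        other.table = other.table.iloc[:-1]
        with pytest.raises(ValueError, match="universe"):
            compare_target_sets(array_targets["A"], other)
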
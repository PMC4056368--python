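"""Flanking-TE statistics, presence/absence calls and TSD inference."""

import itertools
from math import comb

import numpy as np
import pytest

from epivariant.core_io import GeneModel, GenomicInterval, TeModel
from epivariant.te_assoc import (
    annotate_flanks,
    family_composition,
    find_tsd,
    hypergeometric_enrichment,
    te_flank_permutation,
    te_presence_in_other_assembly,
)


def _gene(gid, start, end, chrom="chr1"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, "+"))


def _te(tid, start, end, family="LINE", chrom="chr1"):
    return TeModel(tid, GenomicInterval(chrom, start, end), family)


class TestAnnotateFlanks:
    def test_window_rule(self):
        genes = [_gene("g1", 10_000, 12_000)]
        tes = [_te("near", 9_700, 9_900), _te("far", 18_100, 18_500)]
        (ann,) = annotate_flanks(genes, tes, flank_bp=5000)
        assert [(t, s, d) for t, s, d in ann.flanking] == [("near", "left", 100)]

    def test_body_te_reported_separately(self):
        genes = [_gene("g1", 10_000, 12_000)]
        tes = [_te("in", 10_500, 11_000)]
        (ann,) = annotate_flanks(genes, tes)
        assert ann.body_tes == ["in"] and ann.flanking == []

    def test_nearest_neighbor_flags(self):
        genes = [_gene("g1", 10_000, 12_000), _gene("g2", 13_000, 14_000)]
        tes = [_te("t1", 9_000, 9_500)]
        anns = {a.gene_id: a for a in annotate_flanks(genes, tes)}
        assert anns["g1"].nearest_left_is_te
        assert not anns["g1"].nearest_right_is_te  # g2 is closer than any TE
        assert not anns["g2"].nearest_left_is_te  # g1 sits between

    def test_matches_double_loop_oracle(self, rng):
        genes, tes = [], []
        for i in range(40):
            s = int(rng.integers(0, 200_000))
            genes.append(_gene(f"g{i}", s, s + int(rng.integers(500, 3000))))
        for i in range(30):
            s = int(rng.integers(0, 200_000))
            tes.append(_te(f"t{i}", s, s + int(rng.integers(100, 1500))))
        flank_bp = 5000
        anns = {a.gene_id: a for a in annotate_flanks(genes, tes, flank_bp)}
        for g in genes:
            iv = g.interval
            expected = set()
            for t in tes:
                ts, te_ = t.interval.start, t.interval.end
                if ts < iv.end and te_ > iv.start:
                    continue  # body overlap
                if (ts < iv.start and te_ > iv.start - flank_bp) or (
                    te_ > iv.end and ts < iv.end + flank_bp
                ):
                    expected.add(t.te_id)
            got = {t for t, _, _ in anns[g.gene_id].flanking}
            assert got == expected


class TestFlankPermutation:
    def test_fully_flanked_background_gives_p_one(self):
        genes = [f"g{i}" for i in range(40)]
        flanked = {g: True for g in genes}
        res = te_flank_permutation(genes[:10], genes, flanked, 200, 28, seed=0)
        assert res.observed_fraction == 1.0
        assert res.p_value == 1.0

    def test_observation_above_all_draws_hits_bound(self):
        background = [f"g{i}" for i in range(100)]
        flanked = {g: False for g in background}
        query = ["q1", "q2"]
        flanked.update({q: True for q in query})
        res = te_flank_permutation(query, background, flanked, 200, 28, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_matches_exhaustive_enumeration_on_tiny_background(self, rng):
        background = [f"g{i}" for i in range(8)]
        flanked = {g: i % 2 == 0 for i, g in enumerate(background)}
        query = ["g0", "g1", "g3"]
        observed = np.mean([flanked[q] for q in query])
        exact = np.mean(
            [
                np.mean([flanked[g] for g in combo]) >= observed
                for combo in itertools.combinations(background, 3)
            ]
        )
        res = te_flank_permutation(query, background, flanked, 5000, 3, seed=4)
        # sampled (1 + #null >= obs) / (n + 1) converges to the enumeration
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_small_background_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            te_flank_permutation(["q"], ["g1", "g2"], {}, 200, 28)


class TestHypergeometric:
    def test_zero_hits_is_certain(self):
        assert hypergeometric_enrichment(0, 5, 10, 100) == pytest.approx(1.0)

    def test_hand_enumerated_case(self):
        # N=4, K=2, n=2: P(X >= 2) = C(2,2)C(2,0)/C(4,2) = 1/6
        assert hypergeometric_enrichment(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_matches_summation_oracle_on_random_instances(self, rng):
        for _ in range(100):
            N = int(rng.integers(2, 20))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            oracle = sum(
                comb(K, x) * comb(N - K, n - x) / comb(N, n)
                for x in range(k, min(n, K) + 1)
            )
            assert hypergeometric_enrichment(k, n, K, N) == pytest.approx(oracle)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 3, 10, 100)


class TestFamilyComposition:
    def test_single_family(self):
        tes = [_te(f"t{i}", i * 1000, i * 1000 + 100, "LTR/Copia") for i in range(5)]
        comp = family_composition(tes)
        assert comp["fraction"].tolist() == [1.0]

    def test_empty_subset(self):
        comp = family_composition([])
        assert len(comp) == 0

    def test_skewed_subset_enrichment(self):
        background = [
            _te(f"t{i}", i * 1000, i * 1000 + 100, "LTR/Copia" if i < 10 else "LINE")
            for i in range(40)
        ]
        subset = background[:8] + background[-2:]
        comp = family_composition(subset, background).set_index("family")
        # 8 of 10 Copia in a subset of 10 from 10/40 Copia total
        oracle = sum(
            comb(10, x) * comb(30, 10 - x) / comb(40, 10) for x in range(8, 11)
        )
        assert comp.loc["LTR/Copia", "enrichment_p"] == pytest.approx(oracle)


from oracles import build_polymorphic_pair as _build_polymorphic_pair


class TestPresenceAndTsd:
    def test_deleted_te_called_absent(self, rng):
        te, ga, gb = _build_polymorphic_pair(rng)
        call = te_presence_in_other_assembly(te, ga, gb)
        assert call.status == "absent_in_B"

    def test_unchanged_te_called_present(self, rng):
        te, ga, gb = _build_polymorphic_pair(rng, present=True)
        call = te_presence_in_other_assembly(te, ga, gb)
        assert call.status == "present_in_B"

    def test_presence_robust_to_one_percent_flank_snps(self, rng):
        te, ga, gb = _build_polymorphic_pair(rng)
        b = list(gb["chr1"])
        n_mut = len(b) // 100
        for pos in rng.choice(len(b), size=n_mut, replace=False):
            b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
        call = te_presence_in_other_assembly(te, ga, {"chr1": "".join(b)})
        assert call.status == "absent_in_B"

    def test_tsd_recovered_exactly(self, rng):
        te, ga, gb = _build_polymorphic_pair(rng, tsd="ATACCT")
        call = te_presence_in_other_assembly(te, ga, gb)
        assert find_tsd(te, ga, gb, call) == "ATACCT"

    def test_clean_excision_gives_no_tsd(self, rng):
        te, ga, gb = _build_polymorphic_pair(rng, tsd="")
        call = te_presence_in_other_assembly(te, ga, gb)
        assert call.status == "absent_in_B"
        assert find_tsd(te, ga, gb, call) is None

    def test_tsd_requires_absent_call(self, rng):
        te, ga, gb = _build_polymorphic_pair(rng, present=True)
        call = te_presence_in_other_assembly(te, ga, gb)
        with pytest.raises(ValueError, match="absent_in_B"):
            find_tsd(te, ga, gb, call)

    def test_all_motif_lengths_against_bruteforce_junction_oracle(self, rng):
        """Exhaustive scan over motif lengths 1..10 agrees with direct
        junction comparison for constructed insertions."""
        for L in range(1, 11):
            motif = "".join(rng.choice(list("ACGT"), size=L))
            te, ga, gb = _build_polymorphic_pair(rng, tsd=motif)
            call = te_presence_in_other_assembly(te, ga, gb)
            assert call.status == "absent_in_B"
            got = find_tsd(te, ga, gb, call)
            # brute-force oracle: longest t with A = X t TE t Y and B = X t Y
            a, b = ga["chr1"], gb["chr1"]
            s, e = te.interval.start, te.interval.end
            oracle = None
            for cand in range(10, 0, -1):
                t = a[s - cand : s]
                if a[e : e + cand] == t and (a[: s] + a[e + cand :]) == b:
                    oracle = t
                    break
            assert got == oracle
            # the constructed motif may extend by coincidental context matches,
            # so compare to the oracle rather than the seed motif; the oracle
            # must at least end with the planted motif
            assert oracle is not None and (motif in (a[s - len(oracle): s]))
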
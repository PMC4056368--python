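"""Interval algebra, coordinate conventions and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epivariant.core_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    PipelineConfig,
    RegionSet,
    TeModel,
    merge_intervals,
    overlap_bp,
    read_annotation,
    read_snp_table,
    write_annotation,
    write_snp_table,
)


from oracles import merge_oracle as _merge_oracle


class TestIntervalTypes:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, "x")

    def test_annotation_validates_bounds_and_ids(self):
        iv = GenomicInterval("chr1", 0, 100, "+")
        with pytest.raises(ValueError, match="beyond"):
            GenomeAnnotation({"chr1": 50}, [GeneModel("g1", iv)])
        with pytest.raises(ValueError, match="duplicate"):
            GenomeAnnotation({"chr1": 500}, [GeneModel("g1", iv), GeneModel("g1", iv)])

    def test_te_family_vocabulary_enforced(self):
        iv = GenomicInterval("chr1", 0, 100)
        with pytest.raises(ValueError, match="controlled vocabulary"):
            TeModel("te1", iv, "made-up-family")


class TestMergeIntervals:
    def test_gap_smaller_than_threshold_merges(self):
        rs = merge_intervals(
            [GenomicInterval("c", 100, 150), GenomicInterval("c", 400, 450)], 300
        )
        assert [(iv.start, iv.end) for iv in rs] == [(100, 450)]

    def test_gap_exactly_threshold_is_strict(self):
        rs = merge_intervals(
            [GenomicInterval("c", 100, 150), GenomicInterval("c", 450, 500)], 300
        )
        assert len(rs) == 2

    def test_abutting_intervals_merge_under_positive_gap(self):
        rs = merge_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 100, 200)], 300
        )
        assert [(iv.start, iv.end) for iv in rs] == [(0, 200)]

    def test_matches_pairwise_closure_oracle_on_random_input(self, rng):
        intervals = []
        for _ in range(1000):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 5000))
            intervals.append(
                GenomicInterval(chrom, start, start + int(rng.integers(1, 120)))
            )
        got = merge_intervals(intervals, max_gap=50)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == _merge_oracle(
            intervals, 50
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60), st.sampled_from("ab")),
            max_size=25,
        ),
        st.integers(0, 100),
    )
    def test_idempotent(self, spec, gap):
        intervals = [GenomicInterval(c, s, s + ln) for s, ln, c in spec]
        once = merge_intervals(intervals, gap)
        twice = merge_intervals(list(once), gap)
        assert once == twice


class TestOverlapBp:
    def test_partial_and_disjoint(self):
        rs = RegionSet("r", [GenomicInterval("c", 0, 100)])
        assert overlap_bp(rs, GenomicInterval("c", 50, 150)) == 50
        assert overlap_bp(rs, GenomicInterval("c", 200, 300)) == 0
        assert overlap_bp(rs, GenomicInterval("other", 0, 100)) == 0

    def test_matches_per_base_bitmap_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 15))
            raw = []
            for _ in range(n):
                s = int(rng.integers(0, 400))
                raw.append(GenomicInterval("c", s, s + int(rng.integers(1, 60))))
            rs = merge_intervals(raw, 0)
            qs = int(rng.integers(0, 400))
            q = GenomicInterval("c", qs, qs + int(rng.integers(1, 120)))
            bitmap = np.zeros(1000, dtype=bool)
            for iv in rs:
                bitmap[iv.start : iv.end] = True
            assert overlap_bp(rs, q) == int(bitmap[q.start : q.end].sum())

    def test_symmetric_for_single_intervals(self):
        a = GenomicInterval("c", 10, 60)
        b = GenomicInterval("c", 40, 90)
        assert overlap_bp(RegionSet("", [a]), b) == overlap_bp(RegionSet("", [b]), a)


class TestGff3RoundTrip:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "##gff-version 3\n##sequence-region chr1 1 1000\n"
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1;biotype=protein_coding\n"
        )
        ann = read_annotation(str(path))
        assert ann.genes[0].interval.start == 0
        assert ann.genes[0].interval.end == 100

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "##sequence-region chr1 1 1000\n"
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t200\t300\t.\t-\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(str(path))

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text("##sequence-region chr1 1 1000\nchr1\tsrc\tgene\tnope\n")
        with pytest.raises(ValueError, match=":2"):
            read_annotation(str(path))

    def test_round_trip_preserves_annotation(self, tmp_path, rng):
        genes, tes = [], []
        pos = 10
        for i in range(5):
            ln = int(rng.integers(50, 200))
            genes.append(
                GeneModel(
                    f"g{i}",
                    GenomicInterval("chr1", pos, pos + ln, "+" if i % 2 else "-"),
                    "protein_coding",
                )
            )
            pos += ln + 20
        for i in range(3):
            ln = int(rng.integers(50, 120))
            tes.append(TeModel(f"te{i}", GenomicInterval("chr1", pos, pos + ln), "LINE"))
            pos += ln + 20
        ann = GenomeAnnotation({"chr1": 5000}, genes, tes)
        path = tmp_path / "rt.gff3"
        write_annotation(ann, str(path))
        back = read_annotation(str(path))
        assert back.sequences == ann.sequences
        assert back.genes == ann.genes
        assert back.tes == ann.tes
        # 1-based closed coordinates on disk survive a second round trip exactly
        path2 = tmp_path / "rt2.gff3"
        write_annotation(back, str(path2))
        assert path.read_text() == path2.read_text()

    def test_agrees_with_gffutils_parser(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        ann = GenomeAnnotation(
            {"chr1": 1000},
            [GeneModel("g1", GenomicInterval("chr1", 41, 99, "+"))],
            [TeModel("te1", GenomicInterval("chr1", 150, 400), "LTR/Copia")],
        )
        path = tmp_path / "x.gff3"
        write_annotation(ann, str(path))
        db = gffutils.create_db(str(path), ":memory:")
        g = db["g1"]
        assert (g.start - 1, g.end) == (41, 99)
        t = db["te1"]
        assert (t.start - 1, t.end) == (150, 400)


class TestConfigAndSnpTable:
    def test_default_thresholds(self):
        cfg = PipelineConfig()
        assert cfg.merge_gap_array == 300 and cfg.merge_gap_seq == 200
        assert cfg.gene_rule_array == (0.30, 300, 1000)
        assert cfg.gene_rule_seq == (0.20, 200, 800)
        assert cfg.pfp_threshold == 0.15
        assert cfg.min_reads_per_snp == 3
        assert cfg.allele_perm_draws == 100_000
        assert (cfg.te_perm_sample_size, cfg.te_perm_draws) == (28, 200)

    def test_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(pfp_threshold=0)
        with pytest.raises(ValueError):
            PipelineConfig(merge_gap_array=-1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(merge_gap_array=250, rng_seed=9)
        path = tmp_path / "c.yaml"
        cfg.to_yaml(str(path))
        assert PipelineConfig.from_yaml(str(path)) == cfg

    def test_snp_table_is_one_based_on_disk(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [99], "allele_A": ["A"], "allele_B": ["G"]}
        )
        path = tmp_path / "snps.tsv"
        write_snp_table(df, str(path))
        assert "\t100\t" in path.read_text()
        back = read_snp_table(str(path))
        assert back["pos"].tolist() == [99]
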
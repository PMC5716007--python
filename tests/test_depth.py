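"""Depth lookups, the 20x call filter, and the exon/gene coverage census."""

import numpy as np
import pandas as pd
import pytest

import cohortaf as ca
from cohortaf.cohort_io import STATUS_CALLED, STATUS_REF_ASSUMED, STATUS_UNKNOWN
from cohortaf.depth import DepthTable, read_bed


def _depth_file(path, rows):
    path.write_text("".join(f"{c}\t{p}\t{d}\n" for c, p, d in rows))
    return path


def _calls(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "rare_allele", "rare_count", "status", "het"],
    )


class TestSiteDepth:
    def test_lookup(self, tmp_path):
        table = DepthTable.load(_depth_file(tmp_path / "d.tsv", [("1", 500, 37)]))
        assert ca.site_depth(table, "1", 500) == 37

    def test_missing_position_is_absent(self, tmp_path):
        table = DepthTable.load(_depth_file(tmp_path / "d.tsv", [("1", 500, 37)]))
        assert ca.site_depth(table, "1", 501) is None

    def test_chr_prefix_normalised(self, tmp_path):
        table = DepthTable.load(_depth_file(tmp_path / "d.tsv", [("chr1", 500, 19)]))
        assert ca.site_depth(table, "1", 500) == 19

    def test_unreadable_source_is_hard_error(self, tmp_path):
        with pytest.raises(OSError):
            DepthTable.load(tmp_path / "missing.tsv")


class TestDepthFilter:
    def _sample(self, tmp_path, depths):
        path = _depth_file(tmp_path / "s1.depth.tsv", depths)
        return ca.Sample("S1", depth_path=path)

    def test_boundary_at_cutoff(self, tmp_path):
        # depth 19 fails the 20x cutoff and is discarded from counting;
        # depth 20 passes untouched
        sample = self._sample(tmp_path, [("1", 100, 19), ("1", 200, 20)])
        calls = _calls(
            [
                ("S1", "1", 100, "G", 1, STATUS_CALLED, True),
                ("S1", "1", 200, "G", 1, STATUS_CALLED, True),
            ]
        )
        out, n = ca.apply_depth_filter(calls, [sample], cutoff=20)
        assert n == 1
        assert out.loc[out["pos"] == 100, "status"].item() == STATUS_UNKNOWN
        assert out.loc[out["pos"] == 100, "rare_count"].item() == 0
        assert out.loc[out["pos"] == 200, "status"].item() == STATUS_CALLED

    def test_ref_assumed_without_coverage_becomes_unknown(self, tmp_path):
        sample = self._sample(tmp_path, [("1", 999, 50)])  # site 100 absent -> 0
        calls = _calls([("S1", "1", 100, "G", 0, STATUS_REF_ASSUMED, False)])
        out, n = ca.apply_depth_filter(calls, [sample])
        assert n == 1
        assert out.iloc[0]["status"] == STATUS_UNKNOWN

    def test_idempotent(self, tmp_path):
        sample = self._sample(tmp_path, [("1", 100, 5), ("1", 200, 30)])
        calls = _calls(
            [
                ("S1", "1", 100, "G", 2, STATUS_CALLED, False),
                ("S1", "1", 200, "G", 1, STATUS_CALLED, True),
            ]
        )
        once, n1 = ca.apply_depth_filter(calls, [sample])
        twice, n2 = ca.apply_depth_filter(once, [sample])
        pd.testing.assert_frame_equal(once, twice)
        assert n2 == 0

    def test_never_increases_rare_allele_count(self, tmp_path):
        rng = np.random.default_rng(4)
        depths = [("1", p, int(rng.integers(0, 40))) for p in range(100, 160)]
        sample = self._sample(tmp_path, depths)
        calls = _calls(
            [
                ("S1", "1", p, "G", int(rng.integers(0, 3)), STATUS_CALLED, False)
                for p in range(100, 160)
            ]
        )
        out, _ = ca.apply_depth_filter(calls, [sample])
        assert out["rare_count"].sum() <= calls["rare_count"].sum()

    def test_samples_without_depth_source_left_untouched(self):
        calls = _calls([("S1", "1", 100, "G", 1, STATUS_CALLED, True)])
        out, n = ca.apply_depth_filter(calls, [ca.Sample("S1")])
        assert n == 0
        pd.testing.assert_frame_equal(out, calls)


class TestCensus:
    def _bed(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "exon_id"])

    def test_constant_depth_exon(self, tmp_path):
        table = DepthTable.load(
            _depth_file(tmp_path / "d.tsv", [("1", p, 30) for p in range(101, 111)])
        )
        exons = self._bed([("1", 100, 110, "G1", "G1.e1")])
        exon_df, gene_df, summary = ca.exon_coverage_census({"S1": table}, exons)
        assert exon_df.iloc[0]["mean_depth"] == pytest.approx(30.0)
        assert exon_df.iloc[0]["fraction_ge_cutoff"] == pytest.approx(1.0)
        assert gene_df.iloc[0]["adequately_covered"]
        assert summary["fraction_adequately_covered"] == 1.0

    def test_half_covered_exon(self, tmp_path):
        rows = [("1", p, 10) for p in range(101, 106)] + [
            ("1", p, 30) for p in range(106, 111)
        ]
        table = DepthTable.load(_depth_file(tmp_path / "d.tsv", rows))
        exons = self._bed([("1", 100, 110, "G1", "G1.e1")])
        exon_df, gene_df, _ = ca.exon_coverage_census({"S1": table}, exons)
        assert exon_df.iloc[0]["mean_depth"] == pytest.approx(20.0)
        assert exon_df.iloc[0]["fraction_ge_cutoff"] == pytest.approx(0.5)

    def test_gene_mean_exactly_nineteen_not_adequate(self, tmp_path):
        # adequately covered requires a mean strictly above 19 reads
        table = DepthTable.load(
            _depth_file(tmp_path / "d.tsv", [("1", p, 19) for p in range(101, 111)])
        )
        exons = self._bed([("1", 100, 110, "G1", "G1.e1")])
        _, gene_df, summary = ca.exon_coverage_census({"S1": table}, exons)
        assert gene_df.iloc[0]["mean_depth"] == pytest.approx(19.0)
        assert not gene_df.iloc[0]["adequately_covered"]
        assert summary["n_adequately_covered"] == 0

    def test_overlapping_exons_counted_once_per_gene(self, tmp_path):
        # bases 101..110 at depth 10, 106..115 at 30; the overlap must not
        # be double counted in the gene mean
        rows = [("1", p, 10 if p <= 105 else 30) for p in range(101, 116)]
        table = DepthTable.load(_depth_file(tmp_path / "d.tsv", rows))
        exons = self._bed(
            [("1", 100, 110, "G1", "G1.e1"), ("1", 105, 115, "G1", "G1.e2")]
        )
        _, gene_df, _ = ca.exon_coverage_census({"S1": table}, exons)
        expected = (5 * 10 + 10 * 30) / 15
        assert gene_df.iloc[0]["mean_depth"] == pytest.approx(expected)

    def test_mean_matches_brute_force_over_samples(self, tmp_path):
        rng = np.random.default_rng(7)
        exons = self._bed(
            [("1", 100, 120, "G1", "G1.e1"), ("1", 300, 330, "G2", "G2.e1")]
        )
        tables, all_depths = {}, {}
        for s in ("S1", "S2", "S3"):
            rows = []
            for _, e in exons.iterrows():
                for pos in range(e["start"] + 1, e["end"] + 1):
                    d = int(rng.integers(0, 60))
                    rows.append(("1", pos, d))
                    all_depths.setdefault(e["gene"], []).append((s, d))
            tables[s] = DepthTable.load(_depth_file(tmp_path / f"{s}.tsv", rows))
        _, gene_df, _ = ca.exon_coverage_census(tables, exons)
        for _, g in gene_df.iterrows():
            brute = np.mean([d for _, d in all_depths[g["gene"]]])
            assert g["mean_depth"] == pytest.approx(brute)

    def test_requires_at_least_one_depth_source(self):
        with pytest.raises(ValueError):
            ca.exon_coverage_census({}, self._bed([("1", 0, 10, "G1", "e1")]))


def test_read_bed_zero_based_half_open(tmp_path):
    path = tmp_path / "e.bed"
    path.write_text("1\t100\t110\tG1\tG1.e1\n")
    bed = read_bed(path)
    assert bed.iloc[0]["start"] == 100
    assert bed.iloc[0]["end"] == 110
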
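"""Summary-statistics I/O, filtering, correction and SNP-to-gene assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwas2drug.gwas_io import (
    MHC_REGION,
    GenomicRegion,
    correct_inflation,
    exclude_region,
    filter_maf,
    intersect_studies,
    map_snps_to_genes,
    read_summary_stats,
)


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p", "maf"])


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


class TestReader:
    def write(self, tmp_path, text):
        f = tmp_path / "stats.tsv"
        f.write_text(text)
        return f

    def test_well_formed(self, tmp_path):
        f = self.write(tmp_path, "snp_id\tchrom\tpos\tp\tmaf\n"
                       "rs1\t1\t100\t0.5\t0.2\nrs2\t1\t200\t0.01\t0.3\nrs3\t2\t50\t1.0\t0.05\n")
        df = read_summary_stats(f)
        assert len(df) == 3
        assert df["chrom"].tolist() == ["1", "1", "2"]

    def test_extra_columns_ignored(self, tmp_path):
        f = self.write(tmp_path, "snp_id\tchrom\tpos\tp\tmaf\tbeta\tinfo\n"
                       "rs1\t1\t100\t0.5\t0.2\tx\ty\nrs2\t1\t200\t0.3\t0.1\tx\ty\n"
                       "rs3\t1\t300\t0.2\t0.4\tx\ty\n")
        df = read_summary_stats(f)
        assert len(df) == 3
        assert "beta" not in df.columns

    def test_zero_p_named_row(self, tmp_path):
        f = self.write(tmp_path, "snp_id\tchrom\tpos\tp\tmaf\n"
                       "rs1\t1\t100\t0.5\t0.2\nrs2\t1\t200\t0\t0.3\n")
        with pytest.raises(ValueError, match="row.*2"):
            read_summary_stats(f)

    def test_missing_column(self, tmp_path):
        f = self.write(tmp_path, "snp_id\tchrom\tpos\n" "rs1\t1\t100\n")
        with pytest.raises(ValueError, match="missing required"):
            read_summary_stats(f)

    def test_column_map(self, tmp_path):
        f = self.write(tmp_path, "SNP\tCHR\tBP\tP\tFRQ\nrs1\t1\t100\t0.5\t0.2\n")
        df = read_summary_stats(
            f, {"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "p": "P", "maf": "FRQ"})
        assert df.loc[0, "snp_id"] == "rs1"


class TestFilterMaf:
    def test_boundary_inclusive(self):
        snps = snp_frame([("a", "1", 1, 0.5, 0.005), ("b", "1", 2, 0.5, 0.01),
                          ("c", "1", 3, 0.5, 0.5)])
        out = filter_maf(snps)
        assert out["snp_id"].tolist() == ["b", "c"]

    def test_idempotent(self):
        snps = snp_frame([("a", "1", 1, 0.5, 0.3), ("b", "1", 2, 0.5, 0.002)])
        once = filter_maf(snps)
        assert filter_maf(once).equals(once)


class TestInflation:
    def make(self, ps):
        return snp_frame([(f"s{i}", "1", i + 1, p, 0.2) for i, p in enumerate(ps)])

    def test_identity_intercept(self):
        snps = self.make([0.01, 0.5, 0.9])
        out = correct_inflation(snps, 1.0)
        assert np.allclose(out["p"], snps["p"])

    def test_chi2_rescaling_closed_form(self):
        p_in = stats.chi2.sf(2.4, 1)
        out = correct_inflation(self.make([p_in]), 1.2)
        assert stats.chi2.isf(out.loc[0, "p"], 1) == pytest.approx(2.0, abs=1e-9)

    def test_p005_intercept_11(self):
        out = correct_inflation(self.make([0.05]), 1.1)
        # chi2 3.8415 / 1.1 = 3.4923
        assert out.loc[0, "p"] == pytest.approx(0.0617, abs=2e-4)

    def test_never_decreases_p(self, rng):
        ps = rng.uniform(1e-8, 1, 200)
        out = correct_inflation(self.make(ps), 1.3)
        assert (out["p"].to_numpy() >= ps - 1e-15).all()

    def test_sub_unity_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = correct_inflation(self.make([0.05]), 0.9)
        assert out.loc[0, "p"] == pytest.approx(0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            correct_inflation(self.make([0.5]), 0.0)


class TestIntersect:
    def study(self, ids):
        return snp_frame([(i, "1", k + 1, 0.5, 0.2) for k, i in enumerate(ids)])

    def test_pairwise(self):
        a, b = self.study(["a", "b", "c"]), self.study(["b", "c", "d"])
        ra, rb = intersect_studies([a, b])
        assert set(ra["snp_id"]) == set(rb["snp_id"]) == {"b", "c"}

    def test_identity(self):
        a = self.study(["x", "y"])
        ra, rb = intersect_studies([a, a.copy()])
        assert set(ra["snp_id"]) == {"x", "y"}

    def test_three_way_matches_brute_force(self, rng):
        pools = [list(rng.choice(50, 30, replace=False)) for _ in range(3)]
        studies = [self.study([f"s{i}" for i in pool]) for pool in pools]
        expected = set.intersection(*(set(f"s{i}" for i in pool) for pool in pools))
        for out in intersect_studies(studies):
            assert set(out["snp_id"]) == expected

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning):
            out = intersect_studies([self.study(["a"]), self.study(["b"])])
        assert all(len(o) == 0 for o in out)


class TestExcludeRegion:
    def test_gene_inside_mhc_removed(self):
        genes = gene_frame([("g1", "6", 26_000_000, 26_050_000, "+"),
                            ("g2", "1", 26_000_000, 26_050_000, "+")])
        out = exclude_region(genes, MHC_REGION)
        assert out["gene_id"].tolist() == ["g2"]

    def test_minus_strand_window_reaches_region(self):
        # on '-' the 35kb upstream pad extends past the gene end: 25,640,000
        # + 35,000 = 25,675,000 > region start 25,652,464
        genes = gene_frame([("g", "6", 25_600_000, 25_640_000, "-")])
        assert len(exclude_region(genes, MHC_REGION)) == 0
        # same coordinates on '+' only pad 10kb downstream: kept
        genes_plus = gene_frame([("g", "6", 25_600_000, 25_640_000, "+")])
        assert len(exclude_region(genes_plus, MHC_REGION)) == 1

    def test_idempotent(self):
        genes = gene_frame([("g1", "6", 30_000_000, 30_010_000, "+"),
                            ("g2", "2", 1000, 2000, "-")])
        once = exclude_region(genes, MHC_REGION)
        assert exclude_region(once, MHC_REGION).equals(once)


class TestSnpToGene:
    def brute_force(self, snps, genes, up=35000, down=10000):
        pairs = set()
        for s in snps.itertuples(index=False):
            for g in genes.itertuples(index=False):
                if s.chrom != g.chrom:
                    continue
                lo = g.start - (up if g.strand == "+" else down)
                hi = g.end + (down if g.strand == "+" else up)
                if lo <= s.pos <= hi:
                    pairs.add((s.snp_id, g.gene_id))
        return pairs

    def test_upstream_window_plus_strand(self):
        genes = gene_frame([("g", "1", 100_000, 120_000, "+")])
        snps = snp_frame([("in30kb", "1", 70_000, 0.5, 0.2),
                          ("out36kb", "1", 64_000, 0.5, 0.2)])
        out = map_snps_to_genes(snps, genes)
        assert set(out["snp_id"]) == {"in30kb"}

    def test_downstream_minus_strand(self):
        # for a '-' gene the 3' side is below start: 10kb pad applies there
        genes = gene_frame([("g", "1", 100_000, 120_000, "-")])
        snps = snp_frame([("down5kb", "1", 95_000, 0.5, 0.2),
                          ("down11kb", "1", 89_000, 0.5, 0.2),
                          ("up30kb", "1", 150_000, 0.5, 0.2)])
        out = map_snps_to_genes(snps, genes)
        assert set(out["snp_id"]) == {"down5kb", "up30kb"}

    def test_matches_brute_force_on_random_instance(self, rng):
        grows = []
        for i in range(40):
            start = int(rng.integers(1, 500_000))
            grows.append((f"g{i}", str(rng.integers(1, 3)), start,
                          start + int(rng.integers(1000, 50_000)), rng.choice(["+", "-"])))
        genes = gene_frame(grows)
        snps = snp_frame([
            (f"s{i}", str(rng.integers(1, 3)), int(rng.integers(1, 600_000)), 0.5, 0.2)
            for i in range(200)
        ])
        out = set(map(tuple, map_snps_to_genes(snps, genes).to_numpy()))
        assert out == self.brute_force(snps, genes)

    def test_snp_can_hit_multiple_genes(self):
        genes = gene_frame([("a", "1", 100, 200, "+"), ("b", "1", 150, 300, "+")])
        snps = snp_frame([("s", "1", 160, 0.5, 0.2)])
        out = map_snps_to_genes(snps, genes)
        assert set(out["gene_id"]) == {"a", "b"}
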
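"""Filter-cascade tests against hand-enumerated and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vinepop import variants
from vinepop.containers import MISSING, Genotypes


def write_toy_vcf(path, lines, samples=("A", "B", "C")):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr01,length=1000000>\n"
        '##INFO=<ID=QD,Number=1,Type=Float,Description="QD">\n'
        '##INFO=<ID=FS,Number=1,Type=Float,Description="FS">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    path.write_text(header + "".join(line + "\n" for line in lines))
    return path


class TestReadVcf:
    def test_handcrafted_codes(self, tmp_path):
        path = write_toy_vcf(tmp_path / "toy.vcf", [
            "chr01\t100\t.\tA\tG\t.\tPASS\tQD=20\tGT:DP\t0/0:9\t0/1:8\t1/1:7",
            "chr01\t200\t.\tC\tT\t.\tPASS\tQD=30\tGT:DP\t./.:0\t0/0:5\t0/1:6",
        ])
        gt, vt, sq = variants.read_vcf(path)
        assert gt.g.tolist() == [[0, MISSING], [1, 0], [2, 1]]
        assert gt.depth[:, 0].tolist() == [9, 8, 7]
        assert vt["pos"].tolist() == [100, 200]
        assert sq["qd"].tolist() == [20.0, 30.0]
        assert np.isnan(sq["mq"]).all()

    def test_multiallelic_handling(self, tmp_path):
        path = write_toy_vcf(tmp_path / "multi.vcf", [
            "chr01\t100\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:8\t1/1:7",
            "chr01\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/0:5\t0/0:5\t0/1:6",
        ])
        with pytest.raises(ValueError, match="chr01:100"):
            variants.read_vcf(path)
        gt, vt, _ = variants.read_vcf(path, on_multiallelic="drop")
        assert len(vt) == 1 and vt["pos"].iloc[0] == 200


class TestSiteQualityFilter:
    def _toy(self, sq_rows):
        n = len(sq_rows)
        gt = Genotypes(np.zeros((3, n), dtype=np.int8))
        vt = pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, n + 1),
                           "ref": "A", "alt": "G"})
        sq = pd.DataFrame(sq_rows)
        return gt, vt, sq

    def test_fisher_strand_rule(self):
        gt, vt, sq = self._toy([{"qd": 20, "fs": 61.0, "mq": 50,
                                 "mq_rank_sum": 0, "read_pos_rank_sum": 0}])
        _gt, vt2, rep = variants.filter_sites_quality(gt, vt, sq)
        assert len(vt2) == 0
        assert dict(rep.steps)["FS>60.0"] == 1

    def test_exact_thresholds_retained(self):
        gt, vt, sq = self._toy([{"qd": 2.0, "fs": 60.0, "mq": 40.0,
                                 "mq_rank_sum": -12.5, "read_pos_rank_sum": -8.0}])
        _gt, vt2, rep = variants.filter_sites_quality(gt, vt, sq)
        assert len(vt2) == 1 and rep.total_removed == 0

    def test_sequential_report_counts(self):
        """10 sites, one engineered failure per early rule -> (1,1,1,0,0)."""
        ok = {"qd": 20.0, "fs": 5.0, "mq": 50.0, "mq_rank_sum": 0.0,
              "read_pos_rank_sum": 0.0}
        rows = [dict(ok) for _ in range(10)]
        rows[1]["qd"] = 1.9
        rows[4]["fs"] = 75.0
        rows[7]["mq"] = 30.0
        gt, vt, sq = self._toy(rows)
        _gt, vt2, rep = variants.filter_sites_quality(gt, vt, sq)
        assert [n for _r, n in rep.steps] == [1, 1, 1, 0, 0]
        assert len(vt2) == 7

    def test_missing_annotation_passes_by_default(self):
        gt, vt, sq = self._toy([{"qd": np.nan, "fs": np.nan, "mq": np.nan,
                                 "mq_rank_sum": np.nan, "read_pos_rank_sum": np.nan}])
        _gt, vt2, _rep = variants.filter_sites_quality(gt, vt, sq)
        assert len(vt2) == 1
        _gt, vt3, _rep = variants.filter_sites_quality(gt, vt, sq, strict_missing=True)
        assert len(vt3) == 0


class TestIndividualFilter:
    def test_boundary_80_percent(self):
        g = np.zeros((2, 100), dtype=np.int8)
        g[0, :81] = MISSING   # 81% missing -> removed
        g[1, :80] = MISSING   # exactly 80% -> retained
        gt = Genotypes(g, ["bad", "edge"])
        out, removed = variants.filter_individuals(gt, 0.8)
        assert removed == ["bad"] and out.samples == ["edge"]

    def test_sequential_cuts_are_nested(self, small_study):
        gt = small_study[1]
        g1, removed1 = variants.filter_individuals(gt, 0.8)
        g2, removed2 = variants.filter_individuals(g1, 0.6)
        assert set(g2.samples) <= set(g1.samples) <= set(gt.samples)

    def test_all_removed_errors(self):
        g = np.full((2, 10), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            variants.filter_individuals(Genotypes(g), 0.5)


class TestGenotypeLevelFilter:
    def test_depth_masking_then_site_rules(self):
        g = np.array([[0, 1], [1, 2], [2, 0], [0, 1], [1, 0],
                      [2, 1], [0, 2], [1, 1], [2, 0], [0, 1]], dtype=np.int8)
        depth = np.full(g.shape, 10)
        depth[:6, 0] = 2  # masks 6/10 on site 0 -> missing 0.6 > 0.5 -> dropped
        gt = Genotypes(g, depth=depth)
        vt = pd.DataFrame({"chrom": "chr01", "pos": [1, 2], "ref": "A", "alt": "G"})
        out, vt2, rep = variants.filter_genotype_level(gt, vt)
        assert vt2["pos"].tolist() == [2]
        assert dict(rep.steps)["site missing>0.5"] == 1

    def test_maf_boundary(self):
        # site 0: MAF exactly 0.05 retained; site 1: 0.045 removed
        g0 = np.zeros(100, dtype=np.int8); g0[:10] = 1   # p = 0.05
        g1 = np.zeros(100, dtype=np.int8); g1[:9] = 1    # p = 0.045
        gt = Genotypes(np.column_stack([g0, g1]))
        vt = pd.DataFrame({"chrom": "chr01", "pos": [1, 2], "ref": "A", "alt": "G"})
        out, vt2, _rep = variants.filter_genotype_level(gt, vt)
        assert vt2["pos"].tolist() == [1]

    def test_against_brute_force_enumeration(self, rng):
        """20-site random toy: survivors match an independent enumeration."""
        n, L = 12, 20
        g = rng.integers(0, 3, (n, L)).astype(np.int8)
        g[rng.random((n, L)) < 0.3] = MISSING
        depth = rng.integers(0, 12, (n, L))
        gt = Genotypes(g.copy(), depth=depth.copy())
        vt = pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, L + 1),
                           "ref": "A", "alt": "G"})
        out, vt2, _rep = variants.filter_genotype_level(gt, vt)

        survivors = []
        for j in range(L):
            col = [(g[i, j] if depth[i, j] >= 3 else MISSING) if g[i, j] != MISSING
                   else MISSING for i in range(n)]
            called = [x for x in col if x != MISSING]
            if (n - len(called)) / n > 0.5 or not called:
                continue
            p = sum(called) / (2 * len(called))
            if min(p, 1 - p) < 0.05:
                continue
            dps = [depth[i, j] for i in range(n) if col[i] != MISSING]
            if sum(dps) / len(dps) < 5:
                continue
            survivors.append(j + 1)
        assert vt2["pos"].tolist() == survivors


class TestImputeAndRefilter:
    def test_major_allele_fill(self):
        g = np.array([[2, 0], [2, 0], [1, 1], [MISSING, MISSING]], dtype=np.int8)
        out = variants.impute_major(Genotypes(g))
        assert out.g[3].tolist() == [2, 0]

    def test_tie_imputes_ref_homozygote(self):
        g = np.array([[0], [2], [MISSING]], dtype=np.int8)
        out = variants.impute_major(Genotypes(g))
        assert out.g[2, 0] == 0

    def test_all_missing_site_errors(self):
        g = np.array([[MISSING], [MISSING]], dtype=np.int8)
        with pytest.raises(ValueError):
            variants.impute_major(Genotypes(g))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_imputation_never_raises_maf(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, (15, 8)).astype(np.int8)
        g[rng.random((15, 8)) < 0.3] = MISSING
        keep = (g != MISSING).any(axis=0)
        gt = Genotypes(g[:, keep])
        pre = gt.maf()
        post = variants.impute_major(gt).maf()
        assert set(np.unique(variants.impute_major(gt).g)) <= {0, 1, 2}
        assert (post <= pre + 1e-12).all()

    def test_refilter_maf(self):
        g = np.array([[0, 1], [0, 2], [MISSING, 1], [MISSING, 0]], dtype=np.int8)
        gt = variants.impute_major(Genotypes(g))
        vt = pd.DataFrame({"chrom": "chr01", "pos": [1, 2], "ref": "A", "alt": "G"})
        out, vt2, n_removed = variants.refilter_maf(gt, vt)
        # site 1: all-imputed to REF -> MAF 0 -> removed
        assert n_removed == 1 and vt2["pos"].tolist() == [2]

    def test_no_missing_no_removals(self, rng):
        g = rng.integers(0, 3, (30, 10)).astype(np.int8)
        gt = Genotypes(g)
        keep = gt.maf() >= 0.05
        gt = gt.take_sites(np.flatnonzero(keep))
        vt = pd.DataFrame({"chrom": "chr01", "pos": np.arange(keep.sum()),
                           "ref": "A", "alt": "G"})
        _out, _vt2, n_removed = variants.refilter_maf(gt, vt)
        assert n_removed == 0


class TestCascadeProperties:
    def test_idempotence(self, small_study, small_cfg, tmp_path):
        from vinepop import synthpop
        files = synthpop.write_study(tmp_path, small_cfg)
        gt, vt, sq = variants.read_vcf(files["vcf"])
        gt1, vt1, _ = variants.filter_sites_quality(gt, vt, sq)
        gt1, _removed = variants.filter_individuals(gt1, 0.8)
        gt1, vt1, _ = variants.filter_genotype_level(gt1, vt1)
        gt2, vt2, rep2 = variants.filter_genotype_level(gt1, vt1)
        assert np.array_equal(gt1.g, gt2.g)
        assert rep2.total_removed == 0
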
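"""LD, F_ST, distance and Mantel tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from vinepop import popgen
from vinepop.containers import MISSING, Genotypes


class TestLdR2:
    def _vt(self, pos, chrom="chr01"):
        return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})

    def test_duplicated_locus_r2_one(self, rng):
        col = rng.integers(0, 3, 50).astype(np.int8)
        g = np.column_stack([col, col])
        pairs = popgen.ld_r2(Genotypes(g), self._vt([100, 200]), "chr01", 10_000)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_haplotype_toy(self):
        """Counts AB=4, ab=4, Ab=1, aB=1 -> r^2 = 0.36 (hand calculation:
        pA=pB=0.5, D = 0.4 - 0.25 = 0.15, r2 = 0.15^2/0.5^4)."""
        hapA = [1]*4 + [0]*4 + [1] + [0]
        hapB = [1]*4 + [0]*4 + [0] + [1]
        g = np.column_stack([np.array(hapA) * 2, np.array(hapB) * 2]).astype(np.int8)
        pairs = popgen.ld_r2(Genotypes(g), self._vt([10, 20]), "chr01", 100)
        assert pairs["r2"].iloc[0] == pytest.approx(0.36, abs=1e-12)

    def test_independent_loci_mean_r2(self, rng):
        n, L = 500, 60
        g = rng.binomial(2, 0.4, (n, L)).astype(np.int8)
        pairs = popgen.ld_r2(Genotypes(g), self._vt(np.arange(1, L + 1) * 100), "chr01", 10**6)
        # E[r^2] ~ 1/n for unlinked loci; se of the mean over ~1770 pairs
        se = (2.0 / n) / np.sqrt(len(pairs))
        assert pairs["r2"].mean() == pytest.approx(1.0 / n, abs=3 * se + 2e-4)

    def test_monomorphic_pair_skipped(self):
        g = np.column_stack([np.zeros(20), np.random.default_rng(0).integers(0, 3, 20)]).astype(np.int8)
        pairs = popgen.ld_r2(Genotypes(g), self._vt([5, 15]), "chr01", 100)
        assert len(pairs) == 0

    def test_max_dist_and_chrom_restriction(self, rng):
        g = rng.integers(0, 3, (30, 3)).astype(np.int8)
        vt = self._vt([100, 200, 5000])
        pairs = popgen.ld_r2(Genotypes(g), vt, "chr01", 1000)
        assert pairs["dist_bp"].max() <= 1000


class TestHillWeirFit:
    def test_self_consistency_recovers_rho(self, rng):
        rho = 1e-3
        d = np.linspace(100, 20_000, 300)
        r2 = popgen.hill_weir_expectation(d, rho, 100)
        res = popgen.fit_ld_decay(pd.DataFrame({"dist_bp": d, "r2": r2}), 100)
        assert res.rho == pytest.approx(rho, rel=0.01)
        assert res.expected_r2(res.d02) == pytest.approx(0.2, abs=1e-6)

    def test_halving_rho_doubles_decay_distance(self):
        d = np.linspace(100, 50_000, 200)
        res1 = popgen.fit_ld_decay(
            pd.DataFrame({"dist_bp": d, "r2": popgen.hill_weir_expectation(d, 1e-3, 200)}), 200)
        res2 = popgen.fit_ld_decay(
            pd.DataFrame({"dist_bp": d, "r2": popgen.hill_weir_expectation(d, 5e-4, 200)}), 200)
        assert res2.d02 == pytest.approx(2 * res1.d02, rel=0.02)

    def test_flat_high_ld_flagged_at_bound(self):
        d = np.linspace(100, 10_000, 100)
        res = popgen.fit_ld_decay(pd.DataFrame({"dist_bp": d, "r2": np.ones_like(d)}), 100)
        assert res.at_bound

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            popgen.fit_ld_decay(pd.DataFrame({"dist_bp": [1.0] * 10, "r2": [0.5] * 10}), 50)


def brute_force_wc_fst(g, labels):
    """Independent Weir & Cockerham (1984) theta, explicit loops."""
    names = sorted(set(labels))
    r = len(names)
    A = B = C = 0.0
    for l in range(g.shape[1]):
        n_i, p_i, h_i = [], [], []
        for name in names:
            rows = [i for i, lab in enumerate(labels) if lab == name and g[i, l] != MISSING]
            if not rows:
                break
            n = len(rows)
            p = sum(g[i, l] for i in rows) / (2.0 * n)
            h = sum(1 for i in rows if g[i, l] == 1) / n
            n_i.append(n); p_i.append(p); h_i.append(h)
        else:
            nbar = sum(n_i) / r
            if nbar <= 1:
                continue
            nsum = sum(n_i)
            nc = (nsum - sum(n**2 for n in n_i) / nsum) / (r - 1)
            if nc <= 0:
                continue
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / nsum
            if pbar <= 0 or pbar >= 1:
                continue
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / nsum
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A += a; B += b; C += c
    return A / (A + B + C)


class TestWcFst:
    def test_identical_frequencies_near_zero(self, rng):
        g = rng.binomial(2, 0.3, (400, 300)).astype(np.int8)
        labels = np.array(["a"] * 200 + ["b"] * 200, dtype=object)
        assert abs(popgen.wc_fst(Genotypes(g), labels).overall) < 0.01

    def test_fixed_difference_is_one(self):
        g = np.array([[0] * 5] * 4 + [[2] * 5] * 4, dtype=np.int8)
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        assert popgen.wc_fst(Genotypes(g), labels).overall == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            g = rng.integers(0, 3, (10, 10)).astype(np.int8)
            g[rng.random(g.shape) < 0.15] = MISSING
            labels = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
            expected = brute_force_wc_fst(g, labels)
            got = popgen.wc_fst(Genotypes(g.copy()), labels).overall
            assert got == pytest.approx(expected, abs=1e-10)

    def test_three_group_pairwise_table(self, rng):
        g = rng.integers(0, 3, (12, 20)).astype(np.int8)
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4, dtype=object)
        res = popgen.wc_fst(Genotypes(g), labels)
        assert len(res.pairwise) == 3

    def test_too_few_groups(self, rng):
        g = rng.integers(0, 3, (4, 5)).astype(np.int8)
        with pytest.raises(ValueError):
            popgen.wc_fst(Genotypes(g), np.array(["a"] * 4, dtype=object))


class TestIntrapopF:
    def test_cluster_equals_pooled_gives_zero(self, rng):
        g = rng.binomial(2, 0.4, (40, 50)).astype(np.int8)
        labels = np.array(["x"] * 40, dtype=object)
        res = popgen.intrapop_f(Genotypes(g), labels)
        # single cluster = whole sample: p_k == pbar exactly
        assert res["f"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_balding_nichols_recovery(self, rng):
        """A small drifted cluster inside a large ancestral sample shows
        drift-from-pooled of about (1 - w)^2 F, w its pooled weight."""
        F, L = 0.05, 10_000
        n_drift, n_anc = 60, 240
        p = rng.uniform(0.2, 0.8, L)
        pk = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        g1 = rng.binomial(2, pk, (n_drift, L)).astype(np.int8)
        g2 = rng.binomial(2, p, (n_anc, L)).astype(np.int8)
        gt = Genotypes(np.vstack([g1, g2]))
        labels = np.array(["drifted"] * n_drift + ["anc"] * n_anc, dtype=object)
        res = popgen.intrapop_f(gt, labels).set_index("cluster")
        diff = res.loc["drifted", "f"] - res.loc["anc", "f"]
        # (0.8^2 - 0.2^2) F = 0.03 plus the sampling-noise difference
        assert 0.02 <= diff <= 0.05


class TestNeiDistance:
    def test_identical_zero(self):
        g = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        assert popgen.nei_distance(Genotypes(g))[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        g = np.array([[2, 0, 1], [1, 1, 2]], dtype=np.int8)
        x, y = g[0] / 2.0, g[1] / 2.0
        jxy = np.mean(x * y + (1 - x) * (1 - y))
        jx = np.mean(x**2 + (1 - x) ** 2)
        jy = np.mean(y**2 + (1 - y) ** 2)
        expected = -np.log(jxy / np.sqrt(jx * jy))
        assert popgen.nei_distance(Genotypes(g))[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_locus_order_invariance(self, rng):
        g = rng.integers(0, 3, (5, 20)).astype(np.int8)
        perm = rng.permutation(20)
        d1 = popgen.nei_distance(Genotypes(g))
        d2 = popgen.nei_distance(Genotypes(g[:, perm]))
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestFamilyMeanDistance:
    def test_single_offspring_families(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        M, mothers = popgen.family_mean_distance(d, ["a1", "b1"], {"a1": "A", "b1": "B"})
        assert mothers == ["A", "B"] and M[0, 1] == pytest.approx(0.3)

    def test_two_by_two_cross_mean(self):
        d = np.zeros((4, 4))
        d[0, 2], d[0, 3], d[1, 2], d[1, 3] = 0.1, 0.2, 0.3, 0.4
        d += d.T
        M, _ = popgen.family_mean_distance(d, ["a1", "a2", "b1", "b2"],
                                           {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert M[0, 1] == pytest.approx(0.25)

    def test_brute_force_six_families(self, rng):
        n = 18
        d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        samples = [f"s{i}" for i in range(n)]
        mapping = {s: f"M{i % 6}" for i, s in enumerate(samples)}
        M, mothers = popgen.family_mean_distance(d, samples, mapping)
        for a, ma in enumerate(mothers):
            for b, mb in enumerate(mothers):
                if a == b:
                    continue
                vals = [d[i, j] for i in range(n) for j in range(n)
                        if mapping[samples[i]] == ma and mapping[samples[j]] == mb]
                assert M[a, b] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_unmapped_sample_errors(self):
        with pytest.raises(ValueError):
            popgen.family_mean_distance(np.zeros((2, 2)), ["x", "y"], {"x": "A"})


class TestGeoDistance:
    def _meta(self, rows):
        return pd.DataFrame(rows)

    def test_identical_coordinates(self):
        meta = self._meta([{"mother": "A", "latitude": 30.0, "longitude": -99.0},
                           {"mother": "B", "latitude": 30.0, "longitude": -99.0}])
        D, _ = popgen.geo_distance(meta)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_latitude(self):
        meta = self._meta([{"mother": "A", "latitude": 30.0, "longitude": -99.0},
                           {"mother": "B", "latitude": 31.0, "longitude": -99.0}])
        D, _ = popgen.geo_distance(meta)
        assert D[0, 1] == pytest.approx(111.2, abs=0.2)

    def test_triangle_inequality(self, rng):
        rows = [{"mother": f"M{i}", "latitude": rng.uniform(-60, 60),
                 "longitude": rng.uniform(-179, 179)} for i in range(8)]
        D, _ = popgen.geo_distance(self._meta(rows))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-6

    def test_out_of_range_rejected(self):
        meta = self._meta([{"mother": "A", "latitude": 95.0, "longitude": 0.0},
                           {"mother": "B", "latitude": 0.0, "longitude": 0.0}])
        with pytest.raises(ValueError):
            popgen.geo_distance(meta)


class TestMantel:
    def _random_dist(self, rng, n):
        d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        return d

    def test_identity_minimum_p(self, rng):
        d = self._random_dist(rng, 15)
        rho, p = popgen.mantel_test(d, d.copy(), n_perm=9999, seed=1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1e-4)

    def test_rank_invariance_under_monotone_transform(self, rng):
        d1 = self._random_dist(rng, 12)
        d2 = self._random_dist(rng, 12)
        rho_a, _ = popgen.mantel_test(d1, d2, n_perm=99, seed=3)
        rho_b, _ = popgen.mantel_test(d1, np.exp(d2), n_perm=99, seed=3)
        assert rho_a == pytest.approx(rho_b, abs=1e-12)

    def test_constant_matrix_errors(self, rng):
        d = self._random_dist(rng, 6)
        c = np.ones((6, 6)) - np.eye(6)
        with pytest.raises(ValueError):
            popgen.mantel_test(d, c, n_perm=99)

    def test_p_bounds(self, rng):
        d1, d2 = self._random_dist(rng, 10), self._random_dist(rng, 10)
        _rho, p = popgen.mantel_test(d1, d2, n_perm=199, seed=0)
        assert 1.0 / 200 <= p <= 1.0

    def test_against_skbio_oracle(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel
        d1, d2 = self._random_dist(rng, 12), self._random_dist(rng, 12)
        rho_ours, _ = popgen.mantel_test(d1, d2, n_perm=99, seed=0)
        rho_ref, _p, _n = mantel(DistanceMatrix(d1), DistanceMatrix(d2),
                                 method="spearman", permutations=0,
                                 alternative="greater")
        assert rho_ours == pytest.approx(float(rho_ref), abs=1e-10)
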
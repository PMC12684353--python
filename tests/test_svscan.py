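"""Local-PCA windows, MDS outlier regions, SV genotyping and its statistics."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from lcpop import simdata, svscan
from lcpop.svscan import (
    GenotypingError,
    SVRegion,
    WindowPCA,
    dxy_contrast,
    hwe_exact,
    interval_jaccard,
    nei_fst,
    outlier_regions,
    region_length_mbp,
    sv_pca_genotype,
    window_distance_mds,
    window_pca,
)


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional HWE test."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    rare = min(na, nb)
    probs = {}
    import math

    for h in range(rare % 2, rare + 1, 2):
        naa = (na - h) // 2
        nbb = (nb - h) // 2
        probs[h] = Fraction(
            math.factorial(n) * 2**h * math.factorial(na) * math.factorial(nb),
            math.factorial(naa) * math.factorial(h) * math.factorial(nbb) * math.factorial(2 * n),
        )
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestRegionLength:
    @pytest.mark.parametrize(
        "start,stop,expected",
        [(22_500, 7_807_500, 7.8), (172_500, 11_362_500, 11.2),
         (33_832_500, 58_357_500, 24.5), (100, 100, 0.0)],
    )
    def test_lengths(self, start, stop, expected):
        if start == stop:
            assert round((stop - start) / 1e6, 1) == expected
        else:
            assert region_length_mbp((start, stop)) == expected


class TestWindows:
    def test_identical_windows_identical_up_to_sign(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(50, 20))
        g2 = np.vstack([g, g])
        gl = simdata.glmatrix_from_genotypes(g2)
        ws = window_pca(gl, snps_per_window=50)
        assert len(ws) == 2
        for k in range(2):
            s1, s2 = ws[0].scores[:, k], ws[1].scores[:, k]
            assert min(np.abs(s1 - s2).max(), np.abs(s1 + s2).max()) < 1e-8

    def test_short_trailing_window_flagged(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, size=(75, 15))
        gl = simdata.glmatrix_from_genotypes(g)
        ws = window_pca(gl, snps_per_window=50)
        assert [w.short for w in ws] == [False, True]
        assert ws[1].n_snps == 25

    def test_window_size_larger_than_chromosome(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(30, 15))
        gl = simdata.glmatrix_from_genotypes(g)
        ws = window_pca(gl, snps_per_window=100)
        assert len(ws) == 1 and ws[0].short

    def test_mds_identical_windows_zero(self):
        rng = np.random.default_rng(4)
        scores = rng.random((12, 2))
        ws = [WindowPCA(i, "c", 1 + 10 * i, 10 + 10 * i, 10, scores) for i in range(5)]
        coords, D = window_distance_mds(ws, n_axes=3)
        assert np.allclose(D, 0, atol=1e-9)
        assert np.allclose(coords, 0, atol=1e-6)

    def test_distance_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        ws = [WindowPCA(i, "c", 1, 10, 10, rng.random((15, 2))) for i in range(6)]
        _, D = window_distance_mds(ws)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all((D >= -1e-12) & (D <= 1 + 1e-12))


class TestOutlierRegions:
    @staticmethod
    def make_windows(n, chrom="c"):
        return [
            WindowPCA(i, chrom, 1 + 1000 * i, 1000 * (i + 1), 10, np.zeros((4, 2)))
            for i in range(n)
        ]

    def test_single_block_recovered(self):
        rng = np.random.default_rng(6)
        n = 60
        coords = rng.normal(0, 1, size=(n, 1))
        coords[20:28, 0] = 40.0
        ws = self.make_windows(n)
        regions = outlier_regions(coords, ws, z_cut=4, min_run=3)
        assert len(regions) == 1
        r = regions[0]
        assert r.windows == list(range(20, 28))
        assert r.start == ws[20].first_pos and r.stop == ws[27].last_pos

    def test_flat_axis_no_regions(self):
        coords = np.zeros((20, 2))
        assert outlier_regions(coords, self.make_windows(20)) == []

    def test_short_runs_ignored(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(0, 1, size=(40, 1))
        coords[5, 0] = 50.0
        coords[17:19, 0] = 50.0
        regions = outlier_regions(coords, self.make_windows(40), z_cut=4, min_run=3)
        assert regions == []


class TestSvGenotyping:
    @staticmethod
    def inversion_panel(f_alpha=0.5, d=0.5, seed=8, depth=None):
        cfg = simdata.SimConfig(
            n_demes=2, inds_per_deme=25, n_sites=800, chrom_length=1_000_000,
            fst_drift=0.05, seed=seed, mean_depth=depth or 4.0,
            inversion_specs=[(1, 1_000_000, d, (f_alpha, f_alpha))],
        )
        truth, counts, gl = simdata.simulate(cfg)
        if depth is None:
            gl = simdata.glmatrix_from_genotypes(
                truth.true_genotypes, positions=truth.positions, demes=cfg.deme_of()
            )
        return cfg, truth, gl

    def test_recovers_genotypes(self):
        cfg, truth, gl = self.inversion_panel()
        svg = sv_pca_genotype(gl)
        true_g = truth.inversion_genotypes[:, 0]
        acc = max((svg.genotypes == true_g).mean(), (2 - svg.genotypes == true_g).mean())
        assert acc >= 0.99
        # het cluster must be the middle one regardless of labelling
        assert np.array_equal(svg.genotypes == 1, true_g == 1)

    def test_counts_near_hwe_ratio(self):
        cfg, truth, gl = self.inversion_panel(f_alpha=0.5, seed=9)
        svg = sv_pca_genotype(gl)
        n = svg.counts_by_deme[["n_aa", "n_ab", "n_bb"]].sum()
        assert n.sum() == 50
        assert hwe_exact(*n.tolist()) > 0.01

    def test_sign_flip_invariance(self):
        cfg, truth, gl = self.inversion_panel(seed=10)
        svg1 = sv_pca_genotype(gl)
        gl_flipped = gl.subset_individuals(np.arange(gl.n_ind)[::-1])
        svg2 = sv_pca_genotype(gl_flipped)
        assert np.array_equal(svg1.genotypes[::-1] == 1, svg2.genotypes == 1)

    def test_monomorphic_region_refused(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, size=(500, 30))  # no inversion signal
        gl = simdata.glmatrix_from_genotypes(g)
        with pytest.raises(GenotypingError):
            sv_pca_genotype(gl)

    def test_f_alpha_accounting(self):
        cfg, truth, gl = self.inversion_panel(f_alpha=0.4, seed=12)
        svg = sv_pca_genotype(gl)
        for _, row in svg.counts_by_deme.iterrows():
            n = row["n_aa"] + row["n_ab"] + row["n_bb"]
            assert row["f_alpha"] == pytest.approx(
                (2 * row["n_aa"] + row["n_ab"]) / (2 * n)
            )


class TestHweExact:
    def test_one_het_two_homs(self):
        assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3, rel=1e-12)

    def test_monomorphic(self):
        assert hwe_exact(10, 0, 0) == 1.0

    def test_all_hets_extreme(self):
        n = 10
        p = hwe_exact(0, n, 0)
        assert p == pytest.approx(hwe_oracle(0, n, 0), rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n_aa, n_ab, n_bb = rng.integers(0, 15, size=3)
            if n_aa + n_ab + n_bb == 0:
                continue
            assert hwe_exact(n_aa, n_ab, n_bb) == pytest.approx(
                hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9
            )

    def test_probabilities_sum_to_one(self):
        # the enumeration distribution must be a distribution
        for na_tot in (4, 9, 20):
            n = 12
            total = 0.0
            import math

            for h in range(na_tot % 2, min(na_tot, 2 * n - na_tot) + 1, 2):
                naa = (na_tot - h) // 2
                nbb = (2 * n - na_tot - h) // 2
                total += (
                    math.factorial(n) * 2**h
                    / (math.factorial(naa) * math.factorial(h) * math.factorial(nbb))
                    * math.factorial(na_tot) * math.factorial(2 * n - na_tot)
                    / math.factorial(2 * n)
                )
            assert total == pytest.approx(1.0, rel=1e-9)


class TestNeiFst:
    def test_equal_frequencies_zero(self):
        m = nei_fst([0.3, 0.3])
        assert m.values[0, 1] == 0.0

    def test_fixation_one(self):
        m = nei_fst([1.0, 0.0])
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_arithmetic_example(self):
        m = nei_fst([0.8, 0.2])
        # HS = 0.32, HT = 0.5 -> FST = 0.36
        assert m.values[0, 1] == pytest.approx(0.36, rel=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(13)
        f = rng.uniform(0, 1, 6)
        m = nei_fst(f)
        assert np.allclose(m.values, m.values.T)
        assert np.all((m.values >= 0) & (m.values <= 1))


class TestDxy:
    def test_half_half(self):
        out = dxy_contrast([0.5], [0.5], [True])
        assert out.loc[0, "mean_dxy"] == pytest.approx(0.5)

    def test_fixed_difference(self):
        out = dxy_contrast([1.0], [0.0], [True])
        assert out.loc[0, "mean_dxy"] == pytest.approx(1.0)

    def test_monomorphic_zero_and_masking(self):
        p_a = np.array([0.0, 0.5, 1.0])
        p_b = np.array([0.0, 0.5, 0.0])
        out = dxy_contrast(p_a, p_b, [True, True, False])
        assert out.loc[0, "mean_dxy"] == pytest.approx(0.25)
        assert out.loc[1, "mean_dxy"] == pytest.approx(1.0)
        assert out.loc[0, "n_snps"] == 2


def test_interval_jaccard():
    assert interval_jaccard((1, 100), (1, 100)) == 1.0
    assert interval_jaccard((1, 100), (101, 200)) == 0.0
    assert interval_jaccard((1, 100), (51, 150)) == pytest.approx(50 / 150)
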
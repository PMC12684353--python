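"""SAF convolution, SFS EM, theta statistics, FST and relatedness."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from lcpop import diversity, simdata
from lcpop.diversity import (
    fst_weighted,
    individual_heterozygosity,
    relatedness_pair,
    saf_likelihoods,
    sfs_em,
    theta_stats,
)
from tests.conftest import certain


def brute_force_saf(gl_site):
    """P(data | j minor copies) by enumeration over genotype configurations."""
    n = gl_site.shape[0]
    out = np.zeros(2 * n + 1)
    for config in itertools.product(range(3), repeat=n):
        j = sum(config)
        w = np.prod([comb(2, g) for g in config])
        lik = np.prod([gl_site[i, g] for i, g in enumerate(config)])
        out[j] += w * lik
    out /= comb(2 * n, np.arange(2 * n + 1))
    return out / out.max()


class TestSAF:
    def test_single_certain_homozygote(self):
        saf = saf_likelihoods(certain([[0]]))
        assert np.allclose(saf[0], [1, 0, 0])

    def test_two_certain_hets_mass_at_two(self):
        saf = saf_likelihoods(certain([[1, 1]]))
        assert np.allclose(saf[0], [0, 0, 1, 0, 0])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        gl = rng.random((5, 4, 3))
        gl /= gl.max(axis=2, keepdims=True)
        gl[0, 2, :] = 1.0  # include a missing individual
        saf = saf_likelihoods(gl)
        for s in range(5):
            assert np.allclose(saf[s], brute_force_saf(gl[s]), rtol=1e-10)

    def test_missing_individual_flat_factor(self):
        """A flat triplet only spreads the SAF by a binomial kernel."""
        rng = np.random.default_rng(4)
        gl = rng.random((1, 3, 3))
        with_missing = np.concatenate([gl, np.ones((1, 1, 3))], axis=1)
        base = saf_likelihoods(gl, normalize=False)[0]
        target = saf_likelihoods(with_missing, normalize=False)[0]
        # convolve base (unnormalized P(D|j)*C(2n,j) form) with (1,2,1)
        m = np.convolve(base * comb(6, np.arange(7)), [1, 2, 1])
        m /= comb(8, np.arange(9))
        assert np.allclose(target / target.max(), m / m.max(), rtol=1e-10)


class TestSfsEM:
    def test_monomorphic_mass_in_bin_zero(self):
        saf = saf_likelihoods(certain(np.zeros((50, 4), dtype=int)))
        sfs = sfs_em(saf)
        assert sfs[0] == pytest.approx(50, abs=1e-3)
        assert sfs[1:].sum() < 1e-3

    def test_certain_genotypes_give_count_histogram(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, size=(400, 6))
        sfs = sfs_em(saf_likelihoods(certain(g)))
        hist = np.bincount(g.sum(axis=1), minlength=13)
        assert np.allclose(sfs, hist, atol=0.02)

    def test_2d_certain_genotypes(self):
        rng = np.random.default_rng(6)
        g1 = rng.binomial(2, 0.3, size=(300, 3))
        g2 = rng.binomial(2, 0.5, size=(300, 4))
        sfs = sfs_em(saf_likelihoods(certain(g1)), saf_likelihoods(certain(g2)))
        hist = np.zeros((7, 9))
        for a, b in zip(g1.sum(axis=1), g2.sum(axis=1)):
            hist[a, b] += 1
        assert np.allclose(sfs, hist, atol=0.05)

    def test_neutral_spectrum_recovered_from_depth4(self):
        """EM on depth-4 likelihoods recovers the 1/i neutral SFS shape.

        The unpenalized maximum-likelihood spectrum is locally jagged at
        this information level (a known property of ML mixing-distribution
        estimates), so recovery is measured in total variation against the
        expected shape rather than by a per-bin multinomial test.
        """
        g, gl = simdata.simulate_neutral_spectrum(10, 30_000, seed=7, mean_depth=4.0)
        sfs = sfs_em(saf_likelihoods(gl.gl))
        i = np.arange(1, 20)
        expected = 30_000 * (1 / i) / (1 / i).sum()
        tv = np.abs(sfs[1:20] - expected).sum() / (2 * 30_000)
        assert tv < 0.05
        # monomorphic leakage is negligible
        assert sfs[0] + sfs[20] < 0.01 * 30_000
        # and the spectrum is dominated by the singleton-rich low bins
        assert np.corrcoef(sfs[1:20], expected)[0, 1] > 0.98

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(8)
        _, gl = simdata.simulate_reads(rng.binomial(2, 0.2, size=(200, 8)), 1.5, seed=9)
        _, trace = sfs_em(saf_likelihoods(gl.gl), return_trace=True)
        assert np.all(np.diff(trace) >= -1e-7)


class TestTheta:
    def test_watterson_harmonic_example(self):
        sfs = np.array([0.0, 3, 1, 1, 0])  # S = 5 at 2n = 4
        th = theta_stats(sfs)
        assert th.theta_w == pytest.approx(5 / (1 + 0.5 + 1 / 3), rel=1e-12)
        assert th.segregating == 5

    def test_tajima_zero_when_pi_equals_thetaw(self):
        # at 2n = 4: pi = (3 x1 + 4 x2 + 3 x3)/6, thetaW = (x1+x2+x3)/a1
        sfs = np.array([0.0, 8, 6, 8, 0])
        th = theta_stats(sfs)
        assert th.pi == pytest.approx(th.theta_w, rel=1e-12)
        assert th.tajima_d == pytest.approx(0.0, abs=1e-12)

    def test_folded_representation_agrees(self):
        rng = np.random.default_rng(10)
        g = rng.binomial(2, 0.3, size=(500, 5))
        sfs = np.bincount(g.sum(axis=1), minlength=11).astype(float)
        folded = sfs.copy()
        for i in range(11):
            if i > 10 - i:
                folded[10 - i] += folded[i]
                folded[i] = 0
        a, b = theta_stats(sfs), theta_stats(folded)
        assert a.segregating == pytest.approx(b.segregating)
        assert a.pi == pytest.approx(b.pi)

    def test_contraction_gives_positive_d(self):
        """A sudden 10x decline leaves excess intermediate-frequency
        variation, pushing Tajima's D positive."""
        msprime = pytest.importorskip("msprime")
        import tskit  # noqa: F401

        demography = msprime.Demography()
        demography.add_population(name="p", initial_size=1_000)
        demography.add_population_parameters_change(time=200, initial_size=10_000)
        ds = []
        for rep in range(5):
            ts = msprime.sim_ancestry(
                samples=10, demography=demography, sequence_length=2e6,
                recombination_rate=1e-8, random_seed=40 + rep,
            )
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=140 + rep)
            g = ts.genotype_matrix()
            counts = g.sum(axis=1)
            sfs = np.bincount(counts, minlength=21).astype(float)
            ds.append(theta_stats(sfs).tajima_d)
        assert np.mean(ds) > 0

    def test_matches_msprime_tskit_oracle(self):
        """theta statistics from the true SFS agree with tskit's site
        statistics on the same tree sequence."""
        msprime = pytest.importorskip("msprime")

        ts = msprime.sim_ancestry(
            samples=8, population_size=5_000, sequence_length=1e6,
            recombination_rate=1e-8, random_seed=11,
        )
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=12)
        g = ts.genotype_matrix()
        g = g[(g > 0).any(axis=1) & (g < 1).any(axis=1)]  # biallelic segregating
        sfs = np.bincount(g.sum(axis=1), minlength=17).astype(float)
        th = theta_stats(sfs)
        assert th.pi == pytest.approx(ts.diversity(span_normalise=False), rel=1e-6)
        assert th.segregating == pytest.approx(ts.segregating_sites(span_normalise=False), rel=1e-6)


class TestHeterozygosity:
    def test_arithmetic(self):
        assert individual_heterozygosity([90, 10, 0]) == pytest.approx(10.0)
        assert individual_heterozygosity([100, 0, 0]) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            individual_heterozygosity([0, 0, 0])

    def test_hwe_expectation_at_half(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.5, size=(4000, 1))
        gl = simdata.glmatrix_from_genotypes(g)
        ho = diversity.heterozygosity_from_gl(gl, 0)
        assert ho == pytest.approx(50.0, abs=3.0)


class TestFst:
    def test_identical_demes_near_zero(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.1, 0.9, 5000)
        n = 5000
        p1 = rng.binomial(200, p) / 200
        p2 = rng.binomial(200, p) / 200
        res = fst_weighted(freqs1=p1, freqs2=p2, n1_diploids=100, n2_diploids=100)
        assert abs(res.fst) < 0.01

    def test_fixation(self):
        res = fst_weighted(freqs1=np.array([1.0]), freqs2=np.array([0.0]),
                           n1_diploids=10, n2_diploids=10)
        assert res.fst == pytest.approx(1.0)

    def test_swap_demes_invariant(self):
        rng = np.random.default_rng(14)
        p1 = rng.uniform(0, 1, 100)
        p2 = rng.uniform(0, 1, 100)
        a = fst_weighted(freqs1=p1, freqs2=p2, n1_diploids=20, n2_diploids=30)
        b = fst_weighted(freqs1=p2, freqs2=p1, n1_diploids=30, n2_diploids=20)
        assert a.fst == pytest.approx(b.fst, rel=1e-12)

    def test_windows_tile_and_flag_empty(self):
        pos = np.array([1, 14_999, 15_001, 60_000])
        p1 = np.array([0.1, 0.2, 0.9, 0.4])
        p2 = np.array([0.1, 0.3, 0.1, 0.4])
        res = fst_weighted(freqs1=p1, freqs2=p2, n1_diploids=20, n2_diploids=20,
                           positions=pos, window_bp=15_000)
        w = res.windows
        assert w["start"].tolist() == [1, 15_001, 30_001, 45_001]
        assert w["n_snps"].tolist() == [2, 1, 0, 1]
        assert np.isnan(w.loc[2, "fst"])

    def test_posterior_mode_matches_fast_mode_on_certain_data(self):
        rng = np.random.default_rng(15)
        g1 = rng.binomial(2, 0.3, size=(500, 10))
        g2 = rng.binomial(2, 0.6, size=(500, 10))
        saf1 = saf_likelihoods(certain(g1))
        saf2 = saf_likelihoods(certain(g2))
        sfs2d = sfs_em(saf1, saf2)
        res_post = fst_weighted(saf1=saf1, saf2=saf2, sfs2d=sfs2d)
        res_fast = fst_weighted(freqs1=g1.mean(axis=1) / 2, freqs2=g2.mean(axis=1) / 2,
                                n1_diploids=10, n2_diploids=10)
        assert res_post.fst == pytest.approx(res_fast.fst, abs=0.01)


class TestRelatedness:
    def test_duplicate_individual(self):
        rng = np.random.default_rng(16)
        f = rng.uniform(0.2, 0.8, 2000)
        g = rng.binomial(2, f)
        gl = certain(g[:, None].repeat(2, axis=1))
        k0, k1, k2, r = relatedness_pair(gl[:, 0], gl[:, 1], f)
        assert k2 > 0.95 and r > 0.95

    def test_unrelated_pair(self):
        rng = np.random.default_rng(17)
        f = rng.uniform(0.2, 0.8, 3000)
        g = np.stack([rng.binomial(2, f), rng.binomial(2, f)], axis=1)
        gl = certain(g)
        *_, r = relatedness_pair(gl[:, 0], gl[:, 1], f)
        assert abs(r) <= 0.05

    def test_parent_offspring(self):
        rng = np.random.default_rng(18)
        f = rng.uniform(0.2, 0.8, 3000)
        parent = np.stack([rng.random(3000) < f, rng.random(3000) < f], axis=1).astype(int)
        transmitted = parent[np.arange(3000), rng.integers(0, 2, 3000)]
        child = transmitted + (rng.random(3000) < f)
        g = np.stack([parent.sum(axis=1), child], axis=1)
        gl = certain(g)
        k0, k1, k2, r = relatedness_pair(gl[:, 0], gl[:, 1], f)
        assert k1 > 0.9
        assert r == pytest.approx(0.5, abs=0.05)

    def test_simplex_at_every_iteration(self):
        rng = np.random.default_rng(19)
        f = rng.uniform(0.1, 0.9, 500)
        g = np.stack([rng.binomial(2, f), rng.binomial(2, f)], axis=1)
        gl = certain(g)
        k0, k1, k2, r, trace = relatedness_pair(gl[:, 0], gl[:, 1], f, return_trace=True)
        assert k0 + k1 + k2 == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(trace) >= -1e-7)


def test_sfs_em_rejects_all_missing():
    saf = saf_likelihoods(np.ones((20, 4, 3)))
    with pytest.raises(ValueError, match="missing"):
        sfs_em(saf)


def test_theta_single_diploid_d_flagged():
    th = theta_stats(np.array([80.0, 15, 5]))
    assert th.theta_w == pytest.approx(15.0)
    assert th.pi == pytest.approx(15.0)
    assert np.isnan(th.tajima_d)
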
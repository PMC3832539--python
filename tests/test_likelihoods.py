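"""Genotype-likelihood and SAF machinery against enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from ngsdesign import likelihoods as lk
from ngsdesign.sim import ReadCounts, flip_rate


def brute_force_saf(lin_site):
    """P(D | X=j) by exhaustive enumeration over genotype configurations."""
    n = lin_site.shape[0]
    n2 = 2 * n
    out = np.zeros(n2 + 1)
    for config in itertools.product((0, 1, 2), repeat=n):
        j = sum(config)
        w = np.prod([lin_site[i, g] * comb(2, g) for i, g in enumerate(config)])
        out[j] += w
    return out / comb(n2, np.arange(n2 + 1))


def make_counts(anc, der):
    return ReadCounts(ancestral=np.array([[anc]]), derived=np.array([[der]]))


class TestGenotypeLikelihoods:
    def test_no_reads_gives_flat_likelihoods(self):
        gl = lk.genotype_likelihoods(make_counts(0, 0), 0.01)
        assert np.allclose(gl.logl[0, 0], gl.logl[0, 0, 0])

    def test_four_derived_reads_exact_values(self):
        gl = lk.genotype_likelihoods(make_counts(0, 4), 0.015, "flip_only")
        eps = 0.015
        expected = [4 * np.log(eps), 4 * np.log(0.5), 4 * np.log(1 - eps)]
        assert gl.logl[0, 0] == pytest.approx(expected)
        assert gl.logl[0, 0, 2] > gl.logl[0, 0, 1] > gl.logl[0, 0, 0]

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_balanced_reads_favour_heterozygote(self, k):
        gl = lk.genotype_likelihoods(make_counts(k, k), 0.01)
        assert gl.logl[0, 0, 1] == max(gl.logl[0, 0])

    def test_channel_must_be_known(self):
        with pytest.raises(ValueError):
            lk.genotype_likelihoods(make_counts(1, 1), 0.01, "bogus")


class TestSAFDynamicProgramming:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_dp_equals_enumeration(self, rng, gl_factory, n):
        gl = gl_factory(rng, 25, n)
        lin = gl.linear()
        loglik = lk.saf_likelihood(gl)
        for s in range(lin.shape[0]):
            brute = brute_force_saf(lin[s])
            got = np.exp(loglik[s] - loglik[s].max())
            want = brute / brute.max()
            assert np.abs(got - want).max() < 1e-9

    def test_certain_monomorphic_input(self):
        logl = np.full((1, 3, 3), -np.inf)
        logl[:, :, 0] = 0.0
        lin = np.exp(lk.GenotypeLikelihoods(logl=logl, flip=0.01).logl)
        ll = lk.saf_likelihood(lin)
        post = np.exp(ll[0] - ll[0].max())
        assert post[0] == 1.0 and np.all(post[1:] == 0.0)

    def test_single_certain_het_puts_mass_at_one(self):
        logl = np.full((1, 4, 3), -np.inf)
        logl[0, :, 0] = 0.0
        logl[0, 0, :] = -np.inf
        logl[0, 0, 1] = 0.0
        ll = lk.saf_likelihood(np.exp(logl))
        post = np.exp(ll[0] - ll[0].max())
        assert np.argmax(post) == 1
        assert post[1] / post.sum() == pytest.approx(1.0)

    def test_rescaling_survives_thousand_individuals(self, rng):
        from ngsdesign import sim

        g = sim.draw_genotypes(np.full(5, 0.2), 1000, rng=rng)
        rc = sim.simulate_reads(g, mean_depth=1.0, error_rate=0.01, rng=rng)
        ll = lk.saf_likelihood(lk.genotype_likelihoods(rc, 0.01))
        # extreme allele-count corners may underflow to log 0, but the
        # spectrum itself must be well-defined and normalisable
        assert not np.isnan(ll).any()
        assert np.isfinite(ll.max(axis=1)).all()
        lin = np.exp(ll - ll.max(axis=1, keepdims=True))
        assert np.isfinite(lin).all() and np.all(lin.sum(axis=1) > 0)


class TestAlleleFrequencyEM:
    def test_certain_genotypes_recover_count_fraction(self):
        g = np.array([[0, 1, 2, 1, 0]])
        post = lk.point_mass_posteriors(g)
        logl = np.log(np.maximum(post, 1e-300))
        f = lk.estimate_allele_freq_ml(lk.GenotypeLikelihoods(logl=logl, flip=0.0))
        assert f[0] == pytest.approx(g.sum() / (2 * g.shape[1]), abs=1e-4)

    def test_all_hom_ancestral_gives_zero(self):
        g = np.zeros((3, 6), dtype=int)
        post = lk.point_mass_posteriors(g)
        logl = np.log(np.maximum(post, 1e-300))
        f = lk.estimate_allele_freq_ml(lk.GenotypeLikelihoods(logl=logl, flip=0.0))
        assert np.allclose(f, 0.0, atol=1e-5)

    def test_em_matches_grid_search(self, rng, gl_factory):
        gl = gl_factory(rng, 40, 3)
        lin = gl.linear()
        f_em = lk.estimate_allele_freq_ml(gl)
        grid = np.linspace(0, 1, 1001)
        for s in range(lin.shape[0]):
            ll = np.array(
                [
                    np.sum(
                        np.log(
                            lin[s, :, 0] * (1 - f) ** 2
                            + lin[s, :, 1] * 2 * f * (1 - f)
                            + lin[s, :, 2] * f**2
                        )
                    )
                    for f in grid
                ]
            )
            # the optimiser must land on the grid optimum — or, when the
            # likelihood is too flat to pin the frequency down, on a point
            # at least as good as the grid's best
            f_here = f_em[s]
            ll_em = np.sum(
                np.log(
                    lin[s, :, 0] * (1 - f_here) ** 2
                    + lin[s, :, 1] * 2 * f_here * (1 - f_here)
                    + lin[s, :, 2] * f_here**2
                )
            )
            assert (
                abs(f_here - grid[np.argmax(ll)]) < 1e-3
                or ll_em >= ll.max() - 1e-6
            )


class TestSAFPosterior:
    def test_uniform_prior_concentrated_likelihood(self):
        ll = np.full((1, 7), -np.inf)
        ll[0, 3] = 0.0
        post = lk.saf_posterior(ll, prior="uniform")
        assert post.post[0, 3] == pytest.approx(1.0)
        assert post.p_variable[0] == pytest.approx(1.0)

    def test_posterior_normalisation_random_sites(self, rng, gl_factory):
        gl = gl_factory(rng, 1000, 3)
        f = lk.estimate_allele_freq_ml(gl)
        post = lk.saf_posterior(lk.saf_likelihood(gl), prior="hwe_f_ml", f_ml=f)
        assert np.allclose(post.post.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(post.p_variable >= 0) and np.all(post.p_variable <= 1)

    def test_hwe_posterior_equals_enumeration(self, rng, gl_factory):
        gl = gl_factory(rng, 20, 2)
        lin = gl.linear()
        f = lk.estimate_allele_freq_ml(gl)
        post = lk.saf_posterior(lk.saf_likelihood(gl), prior="hwe_f_ml", f_ml=f)
        j = np.arange(5)
        for s in range(lin.shape[0]):
            prior = comb(4, j) * f[s] ** j * (1 - f[s]) ** (4 - j)
            brute = brute_force_saf(lin[s]) * prior
            brute /= brute.sum()
            assert np.abs(post.post[s] - brute).max() < 1e-9

    def test_degenerate_likelihood_raises(self):
        ll = np.full((1, 5), -np.inf)
        with pytest.raises(ValueError):
            lk.saf_posterior(ll, prior="uniform")


class TestFastPathIdentities:
    """The O(N) closed forms must agree exactly with the DP route."""

    def test_site_variability_matches_dp(self, rng, gl_factory):
        gl = gl_factory(rng, 200, 5)
        f = lk.estimate_allele_freq_ml(gl)
        fast = lk.site_variability(gl, f)
        post = lk.saf_posterior(lk.saf_likelihood(gl), prior="hwe_f_ml", f_ml=f)
        assert np.abs(fast - post.p_variable).max() < 1e-10

    def test_expected_heterozygosity_matches_dp(self, rng, gl_factory):
        gl = gl_factory(rng, 200, 5)
        f = lk.estimate_allele_freq_ml(gl)
        fast = lk.expected_sample_heterozygosity(gl, f)
        post = lk.saf_posterior(lk.saf_likelihood(gl), prior="hwe_f_ml", f_ml=f)
        j = np.arange(11)
        want = post.post @ (2 * (j / 10) * (1 - j / 10))
        assert np.abs(fast - want).max() < 1e-10

    def test_mixture_stats_match_dp_with_mixture_prior(self, rng, gl_factory):
        gl = gl_factory(rng, 50, 3)
        f_grid = np.array([0.01, 0.1, 0.4, 0.9])
        comp = lk.component_site_stats(gl, f_grid)
        mix = lk.MixtureSFS(f_grid=f_grid, weights=np.array([0.4, 0.3, 0.2, 0.1]), pi=0.2)
        stats = lk.mixture_site_stats(comp, mix)
        # oracle: full DP likelihood x the same prior expressed over j
        n2 = 6
        j = np.arange(n2 + 1)
        prior = np.zeros(n2 + 1)
        prior[0] += 1 - mix.pi
        for w, fk in zip(mix.weights, f_grid):
            prior += mix.pi * w * comb(n2, j) * fk**j * (1 - fk) ** (n2 - j)
        ll = lk.saf_likelihood(gl)
        lin_post = np.exp(ll - ll.max(axis=1, keepdims=True)) * prior
        lin_post /= lin_post.sum(axis=1, keepdims=True)
        p_var = 1 - lin_post[:, 0] - lin_post[:, -1]
        het = lin_post @ (2 * (j / n2) * (1 - j / n2))
        assert np.abs(stats.p_variable - p_var).max() < 1e-9
        assert np.abs(stats.het - het).max() < 1e-9

    def test_mixture_em_recovers_variable_fraction(self, rng):
        # half the sites carry strong variable signal, half are blank
        logl = np.zeros((400, 8, 3))
        logl[:200, :, 0] = 0.0
        logl[:200, :, 1:] = -30.0
        logl[200:, :, 1] = 0.0
        logl[200:, :, [0, 2]] = -30.0
        gl = lk.GenotypeLikelihoods(logl=logl, flip=0.01)
        comp = lk.component_site_stats(gl, lk.default_f_grid())
        mix = lk.fit_sfs_mixture(comp)
        assert mix.pi == pytest.approx(0.5, abs=0.02)


class TestMixtureGenotypePosteriors:
    def test_mean_dosage_equals_posterior_mean_frequency(self, rng, gl_factory):
        gl = gl_factory(rng, 60, 8)
        grid = lk.default_f_grid()
        comp = lk.component_site_stats(gl, grid)
        mix = lk.fit_sfs_mixture(comp)
        stats = lk.mixture_site_stats(comp, mix)
        post = lk.mixture_genotype_posteriors(gl, comp, mix)
        assert np.allclose(post.sum(axis=-1), 1.0, atol=1e-10)
        dosage = post[..., 1] + 2 * post[..., 2]
        assert np.abs(dosage.mean(axis=1) / 2 - stats.mean_freq).max() < 1e-9

    def test_blank_sites_shrink_to_ancestral(self, rng):
        # strong invariable signal everywhere: posterior mass goes to g=0
        from ngsdesign import sim

        g = np.zeros((500, 10), dtype=np.int8)
        rc = sim.simulate_reads(g, mean_depth=4.0, error_rate=0.01, rng=rng)
        gl = lk.genotype_likelihoods(rc, 0.01)
        comp = lk.component_site_stats(gl, lk.default_f_grid())
        mix = lk.fit_sfs_mixture(comp)
        post = lk.mixture_genotype_posteriors(gl, comp, mix)
        assert post[..., 0].mean() > 0.99


class TestGenotypePosterior:
    def test_flat_likelihood_returns_prior(self):
        logl = np.zeros((1, 1, 3))
        post = lk.genotype_posteriors(
            lk.GenotypeLikelihoods(logl=logl, flip=0.01), np.array([0.5])
        )
        assert post[0, 0] == pytest.approx([0.25, 0.5, 0.25])

    def test_certain_genotype_overrides_prior(self):
        logl = np.full((1, 1, 3), -700.0)
        logl[0, 0, 2] = 0.0
        post = lk.genotype_posteriors(
            lk.GenotypeLikelihoods(logl=logl, flip=0.01), np.array([0.2])
        )
        assert post[0, 0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_direct_formula_identity(self):
        eps = flip_rate(0.015, "flip_only")
        counts = make_counts(0, 4)
        gl = lk.genotype_likelihoods(counts, 0.015, "flip_only")
        f = 0.1
        post = lk.genotype_posteriors(gl, np.array([f]))[0, 0]
        lik = np.array([eps**4, 0.5**4, (1 - eps) ** 4])
        prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        want = lik * prior / (lik * prior).sum()
        assert np.abs(post - want).max() < 1e-12


def test_point_mass_posteriors_one_hot():
    g = np.array([[0, 1], [2, 1]])
    post = lk.point_mass_posteriors(g)
    assert post.shape == (2, 2, 3)
    np.testing.assert_array_equal(post.argmax(axis=-1), g)
    assert np.all(post.sum(axis=-1) == 1.0)


def test_high_depth_posterior_mode_recovers_true_allele_count(rng):
    """At 50X the SAF posterior mode equals the true sample count nearly always."""
    from ngsdesign import sim

    p = np.clip(sim.neutral_diffusion_freqs(5e-4, 500, rng), 0.0, 1.0)
    g = sim.draw_genotypes(p, 10, rng=rng)
    rc = sim.simulate_reads(g, mean_depth=50.0, error_rate=0.01, rng=rng)
    gl = lk.genotype_likelihoods(rc, 0.01)
    f = lk.estimate_allele_freq_ml(gl, init=lk.freq_init_from_counts(rc))
    post = lk.saf_posterior(lk.saf_likelihood(gl), prior="hwe_f_ml", f_ml=f)
    true_counts = g.sum(axis=1)
    variable = (true_counts > 0) & (true_counts < 20)
    agree = post.mode[variable] == true_counts[variable]
    assert agree.mean() >= 0.99


def test_variability_vanishes_on_invariable_input(rng):
    from ngsdesign import sim

    g = np.zeros((2000, 20), dtype=np.int8)
    rc = sim.simulate_reads(g, mean_depth=5.0, error_rate=0.01, rng=rng)
    gl = lk.genotype_likelihoods(rc, 0.01)
    comp = lk.component_site_stats(gl, lk.default_f_grid())
    mix = lk.fit_sfs_mixture(comp)
    stats = lk.mixture_site_stats(comp, mix)
    assert stats.p_variable.mean() < 0.01
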
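"""The NOIA orthogonal partition: codings, pair partitions, genetic values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import noiasim as ns
from noiasim.noia import _clamp_genotype_freq
from conftest import hwe, wls_partition_oracle


def random_genotype_freq(draw_floats):
    """Build a valid, non-degenerate genotype-frequency vector from three
    positive weights."""
    w = np.array(draw_floats)
    gf = w / w.sum()
    return gf


freq_weights = st.lists(
    st.floats(min_value=0.05, max_value=1.0), min_size=3, max_size=3
)


class TestNoiaCoding:
    def test_symmetric_locus(self):
        cod = ns.noia_coding(hwe(0.5))
        np.testing.assert_allclose(cod.w_a, [1.0, 0.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(cod.w_d, [-0.5, 0.5, -0.5], atol=1e-12)

    def test_hwe_p03(self):
        cod = ns.noia_coding(hwe(0.3))
        np.testing.assert_allclose(cod.w_a, [1.4, 0.4, -0.6], atol=1e-12)

    @given(freq_weights)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_orthogonality_under_own_frequencies(self, w):
        gf = random_genotype_freq(w)
        cod = ns.noia_coding(gf)
        gfc = cod.genotype_freq
        assert abs(gfc @ cod.w_a) < 1e-9
        assert abs(gfc @ cod.w_d) < 1e-9
        assert abs(gfc @ (cod.w_a * cod.w_d)) < 1e-9

    def test_fixed_locus_is_clamped_not_fatal(self):
        cod = ns.noia_coding(np.array([1.0, 0.0, 0.0]))
        assert np.all(np.isfinite(cod.W))
        p = cod.genotype_freq[0] + cod.genotype_freq[1] / 2
        assert p == pytest.approx(0.995)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            ns.noia_coding(np.array([0.5, 0.4, 0.4]))


class TestPartitionPair:
    def test_zero_epistasis_gives_zero_effects(self):
        t = ns.build_contrast("E_DD")
        cod = ns.noia_coding(hwe(0.4))
        f9 = np.kron(hwe(0.4), hwe(0.4))
        part = ns.partition_pair(t, 0.0, cod, cod, f9)
        np.testing.assert_allclose(part.b, 0.0, atol=1e-12)

    def test_additive_by_additive_at_half_loads_only_aa(self):
        t = ns.build_contrast("E_AA")
        cod = ns.noia_coding(hwe(0.5))
        f9 = np.kron(hwe(0.5), hwe(0.5))
        b = ns.partition_pair(t, 1.0, cod, cod, f9).b
        assert b[4] == pytest.approx(1.5)
        others = np.delete(b, 4)
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    @given(
        st.lists(st.floats(-2, 2), min_size=9, max_size=9),
        freq_weights,
        freq_weights,
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_weighted_regression_oracle(self, cells, wk, wl):
        c = np.array(cells)
        gk, gl = random_genotype_freq(wk), random_genotype_freq(wl)
        ck, cl = ns.noia_coding(gk), ns.noia_coding(gl)
        f9 = (cl.genotype_freq[:, None] * ck.genotype_freq[None, :]).ravel()
        b = ns.partition_pair(c, 1.0, ck, cl, f9).b
        W9 = np.kron(cl.W, ck.W)
        expected = wls_partition_oracle(W9, f9, c)
        np.testing.assert_allclose(b, expected, atol=1e-8)

    @given(freq_weights, freq_weights, st.floats(-3, 3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_exact_reconstruction(self, wk, wl, eps):
        # full-rank reparameterization: W_kl b == epsilon * t cell by cell
        t = ns.build_contrast("E_C")
        gk, gl = random_genotype_freq(wk), random_genotype_freq(wl)
        ck, cl = ns.noia_coding(gk), ns.noia_coding(gl)
        f9 = (cl.genotype_freq[:, None] * ck.genotype_freq[None, :]).ravel()
        b = ns.partition_pair(t, eps, ck, cl, f9).b
        np.testing.assert_allclose(np.kron(cl.W, ck.W) @ b, eps * t, atol=1e-10)


class TestAverageEffects:
    def _one_locus_arch(self, a, d):
        cfg = ns.EffectConfig("D", "small", mu_delta=0.2, sigma_delta=0.3)
        return ns.TraitArchitecture(
            np.array([a]), np.array([d / abs(a) if a else 0.0]), np.array([d]),
            np.empty((0, 2), dtype=int), np.empty(0), np.empty(0), None, cfg,
        )

    def test_dominance_shifts_alpha_by_one_minus_2p(self):
        arch = self._one_locus_arch(1.0, 0.5)
        eff = ns.average_effects(arch, hwe(0.3)[None, :])
        assert eff.alpha[0] == pytest.approx(1.0 + (1 - 2 * 0.3) * 0.5)
        assert eff.d_star[0] == pytest.approx(0.5)

    def test_alpha_equals_a_at_half(self):
        arch = self._one_locus_arch(1.0, 0.5)
        eff = ns.average_effects(arch, hwe(0.5)[None, :])
        assert eff.alpha[0] == pytest.approx(1.0)

    def test_additive_model_alpha_equals_a_any_frequency(self):
        arch = ns.sample_architecture(ns.EffectConfig.from_preset("A"), 30, 1)
        rng = np.random.default_rng(2)
        gf = _clamp_genotype_freq(
            np.stack([hwe(p) for p in rng.uniform(0.05, 0.95, 30)])
        )
        eff = ns.average_effects(arch, gf)
        np.testing.assert_allclose(eff.alpha, arch.a, atol=1e-10)
        np.testing.assert_allclose(eff.d_star, 0.0, atol=1e-10)

    def test_effects_export_table(self, small_pop_fixture):
        arch = small_pop_fixture["architecture"]
        pop = small_pop_fixture["population"]
        eff = ns.average_effects(arch, pop.genotype_freq)
        frame = eff.to_frame(population="P1", generation=5)
        assert list(frame.columns) == ["qtl_id", "population", "generation",
                                       "alpha", "d_star"]
        np.testing.assert_array_equal(frame["alpha"], eff.alpha)

    def test_identical_frequencies_give_identical_alphas(self, small_pop_fixture):
        # rg = 1 whenever the two populations share allele frequencies
        arch = small_pop_fixture["architecture"]
        pop = small_pop_fixture["population"]
        e1 = ns.average_effects(arch, pop.genotype_freq)
        e2 = ns.average_effects(arch, pop.genotype_freq)
        np.testing.assert_allclose(e1.alpha, e2.alpha, atol=1e-12)
        assert ns.genetic_correlation(pop, e1, e2) == pytest.approx(1.0, abs=1e-12)


class TestGeneticValues:
    def test_zero_alpha_gives_zero_breeding_values(self, small_pop_fixture):
        arch = small_pop_fixture["architecture"]
        pop = small_pop_fixture["population"]
        eff = ns.average_effects(arch, pop.genotype_freq)
        zeroed = ns.StatisticalEffects(
            np.zeros_like(eff.alpha), eff.d_star, eff.W, eff.pairs,
            eff.pair_b, eff.genotype_freq,
        )
        np.testing.assert_allclose(ns.breeding_values(pop, zeroed), 0.0)

    def test_breeding_values_centered_and_scaled(self):
        # single locus, alpha = 2, HWE 0.5: v = (counts - mean) * 2
        genome = ns.build_genome(1, 1.0, 1, rng_seed=3)
        pop = ns.sample_founders_fast(genome, 200, 200,
                                      ns.point_mass_spectrum(0.5), rng_seed=4)
        arch = self_arch = ns.TraitArchitecture(
            np.array([2.0]), np.zeros(1), np.zeros(1),
            np.empty((0, 2), dtype=int), np.empty(0), np.empty(0), None,
            ns.EffectConfig("A"),
        )
        eff = ns.average_effects(arch, pop.genotype_freq)
        v = ns.breeding_values(pop, eff)
        counts = pop.allele_counts
        np.testing.assert_allclose(v, (counts[:, 0] - counts[:, 0].mean()) * 2.0)
        assert v.mean() == pytest.approx(0.0, abs=1e-12)

    def test_additive_model_genotypic_equals_breeding_value(self, small_pop_fixture):
        pop = small_pop_fixture["population"]
        arch = ns.sample_architecture(ns.EffectConfig.from_preset("A"),
                                      pop.n_loci, rng_seed=5)
        eff = ns.average_effects(arch, pop.genotype_freq)
        np.testing.assert_allclose(
            ns.genotypic_values(pop, arch, eff),
            ns.breeding_values(pop, eff), atol=1e-10,
        )

    @pytest.mark.parametrize("model,magnitude", [
        ("D", "large"), ("E_AA", "small"), ("E_DD", "intermediate"),
        ("E_C", "large"), ("E_M", "small"),
    ])
    def test_noia_values_equal_functional_oracle_up_to_constant(
        self, model, magnitude,
    ):
        genome = ns.build_genome(2, 1.0, 10, rng_seed=6)
        pop = ns.sample_founders_fast(genome, 100, 100,
                                      ns.u_shaped_spectrum(0.05, 0.95), rng_seed=7)
        n_gamma = 4 if model.startswith("E_") else 5
        arch = ns.sample_architecture(
            ns.EffectConfig.from_preset(model, magnitude, n_gamma=n_gamma),
            pop.n_loci, rng_seed=8,
        )
        eff = ns.average_effects(arch, pop.genotype_freq)
        g_noia = ns.genotypic_values(pop, arch, eff)
        g_func = ns.functional_genotypic_values(pop, arch)
        resid = (g_noia - g_noia.mean()) - (g_func - g_func.mean())
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_two_locus_hand_computed_table(self):
        # a = (1, 1), E_AA with epsilon = 0.5, both loci HWE 0.5: the
        # functional value of each 9-cell genotype is the sum of the two
        # additive terms plus 1.5 * 0.5 * (count_k - 1)(count_l - 1)
        counts = np.array([[ck, cl] for cl in (2, 1, 0) for ck in (2, 1, 0)])
        hap = np.zeros((9, 2, 2), dtype=np.uint8)
        for i, (ck, cl) in enumerate(counts):
            hap[i, 0, :ck] = 1
            hap[i, 1, :cl] = 1
        pop = ns.Population(hap, np.zeros(9, dtype=np.uint8))
        cfg = ns.EffectConfig.from_preset("E_AA", "small", n_gamma=1)
        arch = ns.TraitArchitecture(
            np.array([1.0, 1.0]), np.zeros(2), np.zeros(2),
            np.array([[0, 1]]), np.array([0.5]), np.array([0.5]),
            ns.build_contrast("E_AA"), cfg,
        )
        g = ns.functional_genotypic_values(pop, arch)
        expected = ((counts[:, 0] - 1) + (counts[:, 1] - 1)
                    + 1.5 * 0.5 * (counts[:, 0] - 1) * (counts[:, 1] - 1))
        np.testing.assert_allclose(g, expected, atol=1e-12)


class TestPhenotypes:
    def test_zero_variance_passthrough(self):
        g = np.ones(50)
        with pytest.warns(UserWarning):
            y = ns.phenotypes(g, rng_seed=1)
        np.testing.assert_array_equal(y, g)

    def test_realized_heritability_near_half(self):
        rng = np.random.default_rng(2)
        g = rng.normal(0, 2.0, size=20000)
        y = ns.phenotypes(g, rng_seed=3)
        h2 = np.var(g) / np.var(y)
        assert abs(h2 - 0.5) < 3 * 0.01

    def test_reproducible(self):
        g = np.arange(10.0)
        np.testing.assert_array_equal(ns.phenotypes(g, rng_seed=4),
                                      ns.phenotypes(g, rng_seed=4))


class TestTwoLocusMechanisms:
    @pytest.mark.parametrize("model", ["E_AA", "E_M"])
    def test_partner_frequency_only_models(self, model):
        # the locus at fixed frequency absorbs all the alpha change
        fx = ns.make_fixture("two_locus", model=model)
        assert abs(fx["delta_alpha"][0]) > 1e-6      # locus with fixed p moves
        assert abs(fx["delta_alpha"][1]) < 1e-9      # differing locus does not

    @pytest.mark.parametrize("model", ["E_DD", "E_C"])
    def test_own_frequency_models_move_both_loci(self, model):
        fx = ns.make_fixture("two_locus", model=model)
        assert abs(fx["delta_alpha"][0]) > 1e-6
        assert abs(fx["delta_alpha"][1]) > 1e-6

    @pytest.mark.parametrize("model", ["E_AA", "E_DD", "E_C", "E_M"])
    def test_relative_alpha_change_saturates_in_gamma(self, model):
        # delta_alpha and alpha both grow ~linearly in gamma, so the
        # relative change rises at first and settles on a finite plateau
        def ratio(gamma):
            a1 = ns.two_locus_average_effects(model, 0.10, 0.9, gamma=gamma)
            a2 = ns.two_locus_average_effects(model, 0.10, 0.7, gamma=gamma)
            return abs(a1[0] - a2[0]) / abs(a1[0])

        r = [ratio(g) for g in (0.5, 5.0, 500.0, 5000.0)]
        assert r[1] > r[0]                       # still rising at moderate gamma
        assert abs(r[3] - r[2]) < 0.01 * r[3]    # plateau at large gamma
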
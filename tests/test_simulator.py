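"""Unit, invariant and oracle tests for the replicate generator."""

import numpy as np
import pytest
from scipy import stats

from microbias import (
    CommunityProfile,
    EffectSpec,
    LibrarySizeModel,
    MainEffectBias,
    ReplicateSpec,
    StudyDesign,
    URT_TOP5,
    draw_baseline_abundances,
    draw_counts,
    draw_library_sizes,
    draw_traits,
    observed_abundances,
    select_causal_taxa,
    select_confounder_taxa,
    simulate_replicate,
    synthesize_mean_abundances,
    true_abundances,
)
from microbias.simulator import default_confounder_effects


class TestSynthesizeMeanAbundances:
    def test_pinned_top_is_exact(self, pinned_profile):
        np.testing.assert_array_equal(pinned_profile.pi_bar[:5], URT_TOP5)

    def test_two_taxon_normalization(self, rng):
        prof = synthesize_mean_abundances(2, rng, (0.9,))
        np.testing.assert_allclose(prof.pi_bar, [0.9, 0.1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("pinned", [None, URT_TOP5])
    def test_sorted_and_normalized(self, seed, pinned):
        prof = synthesize_mean_abundances(150, np.random.default_rng(seed), pinned)
        assert prof.pi_bar.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(prof.pi_bar) <= 1e-15)
        assert np.all(prof.pi_bar > 0)

    def test_pinned_sum_must_be_below_one(self, rng):
        with pytest.raises(ValueError):
            synthesize_mean_abundances(10, rng, (0.7, 0.4))


class TestBaselineAbundances:
    def test_vanishing_overdispersion_recovers_the_mean(self, rng):
        prof = CommunityProfile(np.array([0.5, 0.3, 0.2]), overdispersion=1e-8)
        Pi0 = draw_baseline_abundances(prof, 50, rng)
        np.testing.assert_allclose(Pi0, np.tile(prof.pi_bar, (50, 1)), atol=1e-3)

    def test_overdispersion_recovery(self, pinned_profile, rng):
        Pi0 = draw_baseline_abundances(pinned_profile, 1000, rng)
        m, v = Pi0.mean(axis=0), Pi0.var(axis=0)
        est = v.sum() / (m * (1 - m)).sum()
        assert round(float(est), 2) == 0.02

    def test_per_taxon_means(self, rng):
        prof = CommunityProfile(np.array([0.4, 0.35, 0.15, 0.1]), overdispersion=0.02)
        Pi0 = draw_baseline_abundances(prof, 10**4, rng)
        sd = np.sqrt(prof.pi_bar * (1 - prof.pi_bar) * 0.02 / 10**4)
        assert np.all(np.abs(Pi0.mean(axis=0) - prof.pi_bar) < 3 * sd)
        np.testing.assert_allclose(Pi0.sum(axis=1), 1.0, atol=1e-10)


class TestCausalAndConfounderSelection:
    def test_m2_takes_the_top_five(self, pinned_profile):
        np.testing.assert_array_equal(
            select_causal_taxa(pinned_profile, "M2"), np.arange(5)
        )

    def test_m1_excludes_most_abundant_and_respects_threshold(self, pinned_profile, rng):
        for _ in range(5):
            causal = select_causal_taxa(pinned_profile, "M1", rng)
            assert causal.size == 20 and np.unique(causal).size == 20
            assert 0 not in causal  # the most abundant taxon
            assert np.all(pinned_profile.pi_bar[causal] > 0.005)

    def test_confounder_set_composition(self, rng):
        causal = np.arange(20)
        nulls = np.arange(20, 100)
        m1 = select_confounder_taxa(causal, nulls, "M1", rng)
        assert m1.size == 20 and np.intersect1d(m1, causal).size == 10
        m2 = select_confounder_taxa(causal, nulls, "M2", rng)
        assert m2.size == 5 and np.intersect1d(m2, causal).size == 2

    def test_pool_exhaustion(self, rng):
        with pytest.raises(ValueError):
            select_confounder_taxa(np.arange(5), np.arange(5, 10), "M1", rng)


class TestTraits:
    def test_binary_is_balanced(self, rng):
        T, C = draw_traits(StudyDesign(n=100), rng)
        assert T.sum() == 50 and C is None

    def test_continuous_moments(self, rng):
        T, _ = draw_traits(StudyDesign(n=10**5, trait_type="continuous"), rng)
        assert abs(T.mean()) < 3 * np.sqrt(1 / 3 / 10**5)
        assert T.min() >= -1 and T.max() <= 1

    def test_confounder_conditional_rates(self, rng):
        T, C = draw_traits(StudyDesign(n=10**4, confounded=True), rng)
        assert C[T == 1].mean() == pytest.approx(0.8, abs=0.02)
        assert C[T == 0].mean() == pytest.approx(0.2, abs=0.02)

    def test_continuous_with_confounder_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(trait_type="continuous", confounded=True)


class TestTrueAbundances:
    def test_null_tilt_is_identity(self, rng):
        Pi0 = np.random.default_rng(0).dirichlet(np.ones(5), size=4)
        eff = EffectSpec(causal_set=np.array([1, 2]), beta=0.0)
        np.testing.assert_array_equal(true_abundances(Pi0, eff, np.ones(4)), Pi0)

    def test_two_taxon_hand_case(self):
        eff = EffectSpec(causal_set=np.array([0]), beta=np.log(2.0))
        Pi = true_abundances(np.array([[0.5, 0.5]]), eff, np.array([1.0]))
        np.testing.assert_allclose(Pi, [[2 / 3, 1 / 3]])

    def test_null_taxon_ratio_invariance(self, rng):
        Pi0 = rng.dirichlet(np.ones(6), size=8)
        eff = EffectSpec(causal_set=np.array([0, 1]), beta=1.5)
        Pi = true_abundances(Pi0, eff, rng.uniform(-1, 1, 8))
        np.testing.assert_allclose(Pi[:, 3] / Pi[:, 4], Pi0[:, 3] / Pi0[:, 4], rtol=1e-12)


class TestObservedAbundances:
    def test_no_bias_reproduces_truth(self, rng):
        Pi0 = rng.dirichlet(np.ones(5), size=3)
        eff = EffectSpec(causal_set=np.array([0]), beta=1.0)
        T = np.array([0.0, 1.0, 1.0])
        Pi = true_abundances(Pi0, eff, T)
        P, _ = observed_abundances(
            Pi0, Pi, MainEffectBias(np.zeros(5)), np.zeros((5, 5)), eff, T
        )
        np.testing.assert_allclose(P, Pi, atol=1e-15)

    def test_main_effect_ratio_identity(self, rng):
        """With theta=0 observed/baseline log-ratio differences equal gamma differences."""
        Pi0 = rng.dirichlet(np.ones(6), size=10)
        gamma = MainEffectBias(rng.normal(0, 0.8, 6))
        eff = EffectSpec(causal_set=np.array([0]), beta=2.0)
        T = rng.integers(0, 2, 10).astype(float)
        Pi = true_abundances(Pi0, eff, T)
        P, _ = observed_abundances(Pi0, Pi, gamma, np.zeros((6, 6)), eff, T)
        for j, k in [(1, 2), (3, 5), (0, 4)]:
            lhs = np.log(P[:, j] / P[:, k]) - np.log(Pi[:, j] / Pi[:, k])
            np.testing.assert_allclose(lhs, gamma.gamma[j] - gamma.gamma[k], rtol=1e-10)

    def test_two_taxon_hand_case(self):
        eff = EffectSpec(causal_set=np.empty(0, dtype=int), beta=0.0)
        Pi0 = np.array([[0.5, 0.5]])
        P, log_norm = observed_abundances(
            Pi0, Pi0, MainEffectBias(np.array([np.log(2.0), 0.0])),
            np.zeros((2, 2)), eff, np.array([0.0]),
        )
        np.testing.assert_allclose(P, [[2 / 3, 1 / 3]])
        assert log_norm[0] == pytest.approx(np.log(1.5))

    def test_scalar_loop_oracle_equivalence(self, rng):
        """Vectorized expected-abundance formula matches a literal scalar-loop oracle."""
        n, J = 3, 4
        Pi0 = rng.dirichlet(np.ones(J), size=n)
        gamma = rng.normal(0, 0.8, J)
        theta = rng.normal(0, 0.5, (J, J))
        np.fill_diagonal(theta, 0.0)
        beta1 = np.array([1.2, 0.0, 0.0, 0.0])
        T = np.array([0.0, 1.0, 1.0])
        eff = EffectSpec(causal_set=np.array([0]), beta=1.2)
        Pi = true_abundances(Pi0, eff, T)
        P, _ = observed_abundances(Pi0, Pi, MainEffectBias(gamma), theta, eff, T)

        expected = np.zeros((n, J))
        for i in range(n):
            w = []
            for j in range(J):
                eta_ij = sum(theta[j][jp] * Pi[i][jp] for jp in range(J) if jp != j)
                w.append(
                    np.exp(gamma[j] + eta_ij + beta1[j] * T[i]) * Pi0[i][j]
                )
            for j in range(J):
                expected[i][j] = w[j] / sum(w)
        np.testing.assert_allclose(P, expected, atol=1e-12)


class TestLibrarySizes:
    def test_truncation_and_mean(self, rng):
        model = LibrarySizeModel()
        libs = draw_library_sizes(model, 10**5, rng)
        assert libs.min() >= 2000
        a = (model.lower_truncation - model.mean) / model.sd
        expected = stats.truncnorm.mean(a, np.inf, loc=model.mean, scale=model.sd)
        assert libs.mean() == pytest.approx(expected, rel=0.01)
        assert expected > model.mean  # left truncation shifts the mean up

    def test_zero_sd_degenerate(self, rng):
        libs = draw_library_sizes(LibrarySizeModel(sd=0.0), 10, rng)
        assert np.all(libs == 10_000)

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            LibrarySizeModel(mean=1000.0, lower_truncation=2000.0)


class TestCounts:
    def test_row_sums_equal_library_sizes(self, rng):
        P = rng.dirichlet(np.ones(5), size=6)
        libs = np.array([100, 200, 300, 400, 500, 600])
        counts = draw_counts(P, libs, rng)
        np.testing.assert_array_equal(counts.sum(axis=1), libs)

    def test_degenerate_probability(self, rng):
        P = np.tile([1.0, 0.0, 0.0], (3, 1))
        counts = draw_counts(P, np.array([50, 60, 70]), rng)
        np.testing.assert_array_equal(counts[:, 0], [50, 60, 70])
        assert counts[:, 1:].sum() == 0

    def test_multinomial_moments(self, rng):
        p = np.array([0.6, 0.3, 0.1])
        counts = draw_counts(np.tile(p, (10**4, 1)), np.full(10**4, 500), rng)
        sd = np.sqrt(500 * p * (1 - p) / 10**4)
        assert np.all(np.abs(counts.mean(axis=0) - 500 * p) < 3 * sd)


class TestSimulateReplicate:
    def test_determinism(self, small_spec):
        a = simulate_replicate(small_spec, 42)
        b = simulate_replicate(small_spec, 42)
        for f in ("counts", "Pi0", "Pi", "P", "T", "gamma", "eta", "library_sizes"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_all_distortions_off(self, small_profile):
        spec = ReplicateSpec(
            profile=small_profile, scheme="M2", beta=0.0, phi=0.0, sigma_gamma=0.0
        )
        ds = simulate_replicate(spec, 3)
        # identical up to one renormalization of the Dirichlet rows
        np.testing.assert_allclose(ds.P, ds.Pi0, atol=1e-14, rtol=0)
        np.testing.assert_allclose(ds.Pi, ds.Pi0, atol=1e-14, rtol=0)
        assert ds.causal_set.size == 0  # global null: no causal taxa

    def test_invariant_suite(self, small_spec):
        ds = simulate_replicate(small_spec, 11)
        for M in (ds.Pi0, ds.Pi, ds.P):
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(ds.counts.sum(axis=1), ds.library_sizes)
        assert np.all(ds.counts[ds.P == 0.0] == 0)
        assert np.all(ds.counts >= 0)
        assert ds.causal_set.size == 5  # M2

    def test_phi_zero_matches_interactions_disabled(self, small_profile):
        """phi=0 must reproduce the pure main-effect-bias model bitwise."""
        ds = simulate_replicate(
            ReplicateSpec(profile=small_profile, scheme="M2", beta=0.5, phi=0.0), 5
        )
        gamma = MainEffectBias(ds.gamma)
        eff = EffectSpec(causal_set=ds.causal_set, beta=0.5)
        J = small_profile.n_taxa
        P, _ = observed_abundances(
            ds.Pi0, ds.Pi, gamma, np.zeros((J, J)), eff, ds.T
        )
        np.testing.assert_array_equal(ds.P, P)
        assert np.all(ds.eta == 0.0)

    def test_trait_fold_change_recovery(self, small_profile):
        """Geometric-mean group ratio of true abundances on a causal taxon ~ exp(beta)."""
        beta = 0.25
        spec = ReplicateSpec(
            profile=small_profile, scheme="M2", beta=beta, phi=0.0,
            design=StudyDesign(n=1000),
        )
        ratios = []
        for seed in range(5):
            ds = simulate_replicate(spec, seed)
            j = ds.causal_set[-1]
            k = ds.null_mask().nonzero()[0][0]
            # ratio of ratios is free of the per-sample normalization
            r = ds.Pi[:, j] / ds.Pi[:, k]
            log_fc = np.log(r[ds.T == 1]).mean() - np.log(r[ds.T == 0]).mean()
            ratios.append(log_fc)
        assert np.mean(ratios) == pytest.approx(beta, abs=0.03)

    def test_confounder_effects_alternate(self):
        eff = default_confounder_effects(np.arange(4), 1.5)
        np.testing.assert_array_equal(eff, [1.5, -1.5, 1.5, -1.5])
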
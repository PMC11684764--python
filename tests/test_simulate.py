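"""Generative-model tests: admixture draws, local ancestry, genotypes, traits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from admixpca.simulate import (
    AdmixtureModel,
    FeatureSpec,
    TraitSpec,
    VariantPanel,
    draw_admixture,
    draw_feature_indicators,
    draw_genotypes,
    draw_local_ancestry,
    estimate_admixture_from_local,
    make_collider_covariate,
    random_panel,
    simulate_cohort,
    simulate_trait,
)


def _flat_panel(m, chrom="chr1", p1=0.5, p0=0.5):
    return VariantPanel(
        chrom=np.full(m, chrom, dtype=object),
        pos_bp=(np.arange(m) + 1) * 1000,
        p1=np.full(m, p1),
        p0=np.full(m, p0),
    )


class TestDrawAdmixture:
    def test_point_mass_is_degenerate(self):
        pi = draw_admixture(AdmixtureModel(family="point_mass", pi_fixed=0.8), 5, seed=0)
        assert np.all(pi == 0.8)
        assert pi.var() == 0.0

    def test_beta_mean_matches_distribution(self):
        # Beta(8, 2) has mean 0.8 and variance 0.8*0.2/11
        model = AdmixtureModel(family="beta", a=8.0, b=2.0)
        pi = draw_admixture(model, 10_000, seed=1)
        se = np.sqrt(model.variance / 10_000)
        assert abs(pi.mean() - 0.8) < 3 * se
        assert np.all((pi >= 0) & (pi <= 1))

    def test_two_point_has_heterogeneity(self):
        pi = draw_admixture(AdmixtureModel(family="two_point", a=0.2, b=0.9), 100, seed=2)
        assert pi.var() > 0
        assert set(np.unique(pi)) <= {0.2, 0.9}

    def test_invalid_shapes_raise(self):
        with pytest.raises(ValueError):
            AdmixtureModel(family="beta", a=-1.0, b=2.0)
        with pytest.raises(ValueError):
            draw_admixture(AdmixtureModel(), 0, seed=0)

    def test_reproducible_given_seed(self):
        a = draw_admixture(AdmixtureModel(), 50, seed=9)
        b = draw_admixture(AdmixtureModel(), 50, seed=9)
        np.testing.assert_array_equal(a, b)


class TestLocalAncestry:
    def test_extreme_pi_deterministic(self):
        panel = _flat_panel(8)
        A = draw_local_ancestry(np.array([1.0, 0.0]), panel, seed=0)
        assert np.all(A[0] == 2)
        assert np.all(A[1] == 0)

    def test_independent_mode_binomial_mean(self):
        panel = _flat_panel(10_000)
        A = draw_local_ancestry(np.array([0.5]), panel, seed=3)
        se = np.sqrt(0.5 * 0.5 / 2 / 10_000)
        assert abs((A / 2).mean() - 0.5) < 3 * se

    def test_markov_mode_stationary_and_autocorrelated(self):
        panel = _flat_panel(2000)
        pi = np.full(200, 0.7)
        A = draw_local_ancestry(pi, panel, mode="markov", switch_rate_per_mb=5.0, seed=4)
        assert set(np.unique(A)) <= {0, 1, 2}
        assert abs(A.mean() / 2 - 0.7) < 0.02
        # adjacent variants share ancestry far more than under independence
        d = A[:, :-1].astype(float).ravel()
        e = A[:, 1:].astype(float).ravel()
        assert np.corrcoef(d, e)[0, 1] > 0.5

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            draw_local_ancestry(np.array([1.5]), _flat_panel(3), seed=0)


class TestDrawGenotypes:
    def test_fixed_allele_gives_all_twos(self):
        panel = _flat_panel(5, p1=1.0, p0=1.0)
        A = draw_local_ancestry(np.array([0.3, 0.9]), panel, seed=0)
        G = draw_genotypes(A, panel, seed=1)
        assert np.all(G == 2)

    def test_mixture_frequency_at_half(self):
        # q(0.5) = 0.5 * 0.9 + 0.5 * 0.1 = 0.5
        panel = _flat_panel(1, p1=0.9, p0=0.1)
        pi = np.full(10_000, 0.5)
        A = draw_local_ancestry(pi, panel, seed=5)
        G = draw_genotypes(A, panel, seed=6)
        freq = G.mean() / 2
        se = np.sqrt(0.5 * 0.5 / 2 / 10_000)
        # conditional-on-A variance is smaller than the marginal bound used here
        assert abs(freq - 0.5) < 3 * se * 2

    def test_feature_induces_genotype_carrier_correlation(self):
        # brute-force two-group oracle: carriers have per-copy frequency
        # 0.5+0.4, non-carriers 0.5-0.4; the implied point-biserial
        # correlation is sqrt(between / (between + within)) ~ 0.88
        q_hi, q_lo = 0.9, 0.1
        between = 0.25 * (2 * q_hi - 2 * q_lo) ** 2
        within = 0.5 * (2 * q_hi * (1 - q_hi)) + 0.5 * (2 * q_lo * (1 - q_lo))
        oracle_corr = np.sqrt(between / (between + within))
        assert oracle_corr > 0.3

        panel = _flat_panel(20, p1=0.5, p0=0.5)
        spec = FeatureSpec(
            name="f", regions=(("chr1", 1000, 10_001),), carrier_freq=0.5, strength=0.4
        )
        f = draw_feature_indicators([spec], 2000, seed=7)
        A = draw_local_ancestry(np.full(2000, 0.5), panel, seed=8)
        G = draw_genotypes(A, panel, features=[spec], f=f, seed=9)
        mask = spec.member_mask(panel)
        assert mask.sum() == 10
        corrs = [
            np.corrcoef(G[:, j], f["f"])[0, 1] for j in np.flatnonzero(mask)
        ]
        assert np.mean(np.abs(corrs)) > 0.3
        # outside the region the feature has no effect beyond chance
        out = [np.corrcoef(G[:, j], f["f"])[0, 1] for j in np.flatnonzero(~mask)]
        assert np.mean(np.abs(out)) < 0.1

    def test_region_off_panel_warns_and_is_ignored(self):
        panel = _flat_panel(5)
        spec = FeatureSpec(name="f", regions=(("chrX", 1, 100),), strength=0.2)
        f = draw_feature_indicators([spec], 10, seed=0)
        A = draw_local_ancestry(np.full(10, 0.5), panel, seed=1)
        with pytest.warns(UserWarning, match="no panel variants"):
            G = draw_genotypes(A, panel, features=[spec], f=f, seed=2)
        assert G.shape == (10, 5)


class TestTrait:
    def test_null_trait_is_near_zero(self):
        panel = _flat_panel(4)
        cohort = simulate_cohort(panel, 20, seed=3)
        y = simulate_trait(cohort, TraitSpec(causal_index=0, beta1=0, beta_pi=0, noise_sd=1e-8), 0)
        assert np.all(np.abs(y) < 1e-6)

    def test_genotype_contrast_matches_effect(self):
        panel = _flat_panel(3, p1=0.6, p0=0.4)
        cohort = simulate_cohort(panel, 10_000, seed=11)
        y = simulate_trait(cohort, TraitSpec(causal_index=1, beta1=2.0, beta_pi=0.0), seed=12)
        g = cohort.G[:, 1]
        contrast = y[g == 2].mean() - y[g == 0].mean()
        mc_se = np.sqrt(1 / (g == 2).sum() + 1 / (g == 0).sum())
        assert abs(contrast - 4.0) < 4 * mc_se

    def test_effect_size_grid_accepted(self):
        panel = _flat_panel(2)
        cohort = simulate_cohort(panel, 10, seed=0)
        for beta in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            y = simulate_trait(cohort, TraitSpec(causal_index=0, beta1=beta), seed=1)
            assert y.shape == (10,)


class TestColliderCovariate:
    def test_pure_causal_weight_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        g1 = rng.binomial(2, 0.5, 500).astype(float)
        g2 = rng.binomial(2, 0.5, 500).astype(float)
        z = make_collider_covariate(g1, g2, w1=1.0, w2=0.0)
        assert np.corrcoef(z, g1)[0, 1] == pytest.approx(1.0)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_equal_weights_give_half_power_correlation(self):
        # corr(z, g1) = w1 / sqrt(w1^2 + w2^2) = 1/sqrt(2) for independent inputs
        rng = np.random.default_rng(1)
        g1 = rng.binomial(2, 0.5, 200_000).astype(float)
        g2 = rng.binomial(2, 0.5, 200_000).astype(float)
        z = make_collider_covariate(g1, g2)
        assert np.corrcoef(z, g1)[0, 1] == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_same_chromosome_warns(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        with pytest.warns(UserWarning, match="same chromosome"):
            make_collider_covariate(g, g[::-1], chrom_causal="chr4", chrom_other="chr4")

    def test_zero_variance_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            make_collider_covariate(np.ones(10), np.arange(10.0))


class TestAdmixtureEstimate:
    def test_exact_arithmetic(self):
        assert estimate_admixture_from_local(np.array([[2, 2, 2, 2]]))[0] == 1.0
        assert estimate_admixture_from_local(np.array([[0, 1, 2, 1]]))[0] == 0.5

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            estimate_admixture_from_local(np.empty((3, 0)))

    @settings(derandomize=True, max_examples=25)
    @given(arrays(np.int8, (4, 7), elements=st.integers(0, 2)))
    def test_equals_row_mean_identity(self, A):
        np.testing.assert_array_equal(
            estimate_admixture_from_local(A), A.mean(axis=1) / 2.0
        )

    def test_tracks_truth_at_many_variants(self):
        panel = random_panel(n_chrom=2, variants_per_chrom=5000, seed=np.random.default_rng(2))
        cohort = simulate_cohort(panel, 300, seed=21)
        pi_hat = estimate_admixture_from_local(cohort.A)
        assert np.corrcoef(pi_hat, cohort.pi_true)[0, 1] > 0.99


class TestCohortMoments:
    """Moment checks of the genotype mixture law against its closed forms."""

    def test_genotype_ancestry_covariances(self):
        n = 100_000
        model = AdmixtureModel(family="beta", a=3.0, b=1.3)
        panel = VariantPanel(
            chrom=np.array(["chr1", "chr2"], dtype=object),
            pos_bp=np.array([1000, 1000]),
            p1=np.array([0.9, 0.8]),
            p0=np.array([0.1, 0.3]),
        )
        cohort = simulate_cohort(panel, n, admixture=model, seed=31)
        v = model.variance
        d = panel.delta
        g = cohort.G.astype(float)
        # Cov(g_j, pi) = 2 * delta_j * V_pi
        for j in range(2):
            emp = np.cov(g[:, j], cohort.pi_true)[0, 1]
            se = np.sqrt(np.var(
                (g[:, j] - g[:, j].mean()) * (cohort.pi_true - cohort.pi_true.mean())
            ) / n)
            assert abs(emp - 2 * d[j] * v) < 4 * se
        # Cov(g_1, g_2) = 4 * delta_1 * delta_2 * V_pi
        emp12 = np.cov(g[:, 0], g[:, 1])[0, 1]
        se12 = np.sqrt(np.var(
            (g[:, 0] - g[:, 0].mean()) * (g[:, 1] - g[:, 1].mean())
        ) / n)
        assert abs(emp12 - 4 * d[0] * d[1] * v) < 4 * se12

    def test_homogeneous_population_has_no_cross_covariance(self):
        n = 100_000
        panel = VariantPanel(
            chrom=np.array(["chr1", "chr2"], dtype=object),
            pos_bp=np.array([1000, 1000]),
            p1=np.array([0.9, 0.8]),
            p0=np.array([0.1, 0.3]),
        )
        model = AdmixtureModel(family="point_mass", pi_fixed=0.7)
        cohort = simulate_cohort(panel, n, admixture=model, seed=32)
        g = cohort.G.astype(float)
        emp12 = np.cov(g[:, 0], g[:, 1])[0, 1]
        se12 = np.sqrt(g[:, 0].var() * g[:, 1].var() / n)
        assert abs(emp12) < 4 * se12

    def test_same_seed_reproduces_cohort_exactly(self):
        panel = random_panel(n_chrom=2, variants_per_chrom=30, seed=np.random.default_rng(4))
        c1 = simulate_cohort(panel, 50, seed=77)
        c2 = simulate_cohort(panel, 50, seed=77)
        np.testing.assert_array_equal(c1.G, c2.G)
        np.testing.assert_array_equal(c1.A, c2.A)
        np.testing.assert_array_equal(c1.pi_true, c2.pi_true)
        assert c1.seed_record == c2.seed_record


class TestPanelValidation:
    def test_positions_must_increase_within_chromosome(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            VariantPanel(
                chrom=np.array(["chr1", "chr1"], dtype=object),
                pos_bp=np.array([100, 100]),
                p1=np.array([0.5, 0.5]),
                p0=np.array([0.5, 0.5]),
            )

    def test_frequencies_bounded(self):
        with pytest.raises(ValueError, match="frequencies"):
            VariantPanel(
                chrom=np.array(["chr1"], dtype=object),
                pos_bp=np.array([100]),
                p1=np.array([1.5]),
                p0=np.array([0.5]),
            )

    def test_delta_derivable_and_bounded(self):
        panel = random_panel(n_chrom=1, variants_per_chrom=100, seed=np.random.default_rng(0))
        assert np.all(np.abs(panel.delta) <= 1.0)
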
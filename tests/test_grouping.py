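"""Combination schemes, clamping, and the noisy mask map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from flexgpc.grouping import (
    CC,
    RAC,
    FeatureGroupMatrix,
    SelectionWeights,
    clamp_unit,
    convex_combine,
    noisy_mask,
    restricted_affine_combine,
)


def loop_combination(s, G):
    """Independent oracle: explicit sum over groups, element by element."""
    d = G.shape[1]
    out = np.zeros(d)
    for j in range(len(s)):
        for f in range(d):
            out[f] += s[j] * G[j, f]
    return out


def random_cc_weights(rng, k):
    return rng.dirichlet(np.ones(k))


def random_rac_weights(rng, k):
    mags = rng.dirichlet(np.ones(k))
    return mags * (rng.integers(0, 2, size=k) * 2 - 1)


class TestCombinationSchemes:
    def test_one_hot_weights_return_the_group_row(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(4, 6)))
        for j in range(4):
            s = SelectionWeights(np.eye(4)[j], scheme=CC)
            assert np.allclose(convex_combine(s, G), G.values[j])

    def test_equal_weights_average_disjoint_groups(self):
        G = FeatureGroupMatrix([[1, 0], [0, 1]])
        s = SelectionWeights([0.5, 0.5], scheme=CC)
        assert np.allclose(convex_combine(s, G), [0.5, 0.5])

    def test_rac_signed_arithmetic(self):
        G = FeatureGroupMatrix([[1, 1], [0, 1]])
        s = SelectionWeights([0.5, -0.5], scheme=RAC)
        assert np.allclose(restricted_affine_combine(s, G), [0.5, 0.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k, d = rng.integers(1, 6), rng.integers(1, 8)
        G = FeatureGroupMatrix(rng.uniform(size=(k, d)))
        s_cc = SelectionWeights(random_cc_weights(rng, k), scheme=CC)
        assert np.allclose(convex_combine(s_cc, G),
                           loop_combination(s_cc.values, G.values), atol=1e-12)
        s_rac = SelectionWeights(random_rac_weights(rng, k), scheme=RAC)
        assert np.allclose(restricted_affine_combine(s_rac, G),
                           loop_combination(s_rac.values, G.values), atol=1e-12)

    def test_rac_equals_cc_on_nonnegative_weights(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(3, 5)))
        w = random_cc_weights(rng, 3)
        cc = convex_combine(SelectionWeights(w, scheme=CC), G)
        rac = restricted_affine_combine(SelectionWeights(w, scheme=RAC), G)
        assert np.allclose(cc, rac)

    def test_cc_output_stays_in_unit_interval(self, rng):
        for _ in range(50):
            G = FeatureGroupMatrix(rng.uniform(size=(4, 7)))
            s = SelectionWeights(random_cc_weights(rng, 4), scheme=CC)
            out = convex_combine(s, G)
            assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12

    def test_rac_output_bounded_by_one_in_magnitude(self, rng):
        for _ in range(50):
            G = FeatureGroupMatrix(rng.uniform(size=(4, 7)))
            s = SelectionWeights(random_rac_weights(rng, 4), scheme=RAC)
            assert np.abs(restricted_affine_combine(s, G)).max() <= 1 + 1e-12

    def test_dimension_mismatch_raises(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(3, 5)))
        s = SelectionWeights(random_cc_weights(rng, 4), scheme=CC)
        with pytest.raises(ValueError):
            convex_combine(s, G)


class TestInvariantValidation:
    def test_cc_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SelectionWeights([0.5, 0.4], scheme=CC)

    def test_rac_weights_must_have_unit_l1_norm(self):
        with pytest.raises(ValueError):
            SelectionWeights([0.5, -0.6], scheme=RAC)

    def test_group_entries_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            FeatureGroupMatrix([[0.5, 1.2]])


class TestClamp:
    @pytest.mark.parametrize("value,expected", [(-0.3, 0.0), (0.5, 0.5), (1.7, 1.0)])
    def test_pointwise(self, value, expected):
        assert clamp_unit(np.array([value])).values[0] == expected

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent_and_one_lipschitz(self, values):
        w = np.array(values)
        once = clamp_unit(w).values
        assert np.array_equal(clamp_unit(once).values, once)
        v = w + 0.25
        assert np.all(np.abs(clamp_unit(w).values - clamp_unit(v).values)
                      <= np.abs(w - v) + 1e-15)


class TestNoisyMask:
    def test_evaluation_mode_ignores_sigma(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(3, 6)))
        s = SelectionWeights(random_rac_weights(rng, 3), scheme=RAC)
        m = noisy_mask(s, G, sigma=5.0, training=False)
        assert np.allclose(m.values, clamp_unit(s.values @ G.values).values)

    def test_zero_sigma_in_training_is_deterministic(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(3, 6)))
        s = SelectionWeights(random_cc_weights(rng, 3), scheme=CC)
        m = noisy_mask(s, G, sigma=0.0, training=True, rng=rng)
        assert np.allclose(m.values, clamp_unit(s.values @ G.values).values)

    def test_output_always_in_unit_interval(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(2, 4)))
        s = SelectionWeights(random_rac_weights(rng, 2), scheme=RAC)
        for sigma in (0.1, 1.0, 10.0):
            m = noisy_mask(s, G, sigma=sigma, training=True, rng=rng)
            assert m.values.min() >= 0 and m.values.max() <= 1

    def test_negative_sigma_rejected(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(2, 3)))
        s = SelectionWeights([1.0, 0.0], scheme=CC)
        with pytest.raises(ValueError):
            noisy_mask(s, G, sigma=-1.0)

    def test_clamped_mean_matches_closed_form_clamped_gaussian(self):
        """Mean of clamp(0.5 + eps), eps ~ N(0,1), vs the analytic value.

        E[clamp(N(mu, s))] = Phi(-mu/s)*0 + (1 - Phi((1-mu)/s))*1
                             + mu*(Phi(b) - Phi(a)) - s*(phi(b) - phi(a))
        with a = -mu/s, b = (1-mu)/s.
        """
        mu, sd, n = 0.5, 1.0, 100_000
        a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
        expected = ((1.0 - norm.cdf(b))
                    + mu * (norm.cdf(b) - norm.cdf(a))
                    - sd * (norm.pdf(b) - norm.pdf(a)))
        # one-feature group with value mu and full weight on it
        G = FeatureGroupMatrix([[mu]])
        s = SelectionWeights([1.0], scheme=CC)
        rng = np.random.default_rng(7)
        draws = np.array([
            noisy_mask(s, G, sigma=sd, training=True, rng=rng).values[0]
            for _ in range(n)
        ])
        mc_se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * mc_se

    def test_batched_equals_per_row(self, rng):
        G = FeatureGroupMatrix(rng.uniform(size=(3, 5)))
        W = np.stack([random_rac_weights(rng, 3) for _ in range(6)])
        batched = noisy_mask(W, G).values
        for i in range(6):
            row = noisy_mask(SelectionWeights(W[i], scheme=RAC), G).values
            assert np.allclose(batched[i], row)

    def test_shared_noise_option_uses_one_draw_per_mask(self):
        G = FeatureGroupMatrix(np.full((2, 8), 0.5))
        s = SelectionWeights([0.5, 0.5], scheme=CC)
        m = noisy_mask(s, G, sigma=1.0, training=True,
                       rng=np.random.default_rng(0), per_element=False)
        interior = m.values[(m.values > 0) & (m.values < 1)]
        assert len(np.unique(np.round(interior, 12))) <= 1
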
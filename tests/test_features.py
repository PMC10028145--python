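"""Templates, correlation features, frequency calibration, and fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcsp.timefreq import make_grid
from tcsp.features import (
    TemplatePair, compute_templates, correlate_with_templates,
    correlation_profiles, calibrate_frequency, tcsp_features,
    select_one_hot, fuse,
)


def _random_h(rng, n_trials, n_freq=6, t_w=80):
    return rng.uniform(0.1, 2.0, size=(n_trials, n_freq, t_w))


class TestTemplates:
    def test_single_trial_per_class_returns_those_trials(self, rng):
        h = _random_h(rng, 2)
        tpl = compute_templates(h, [1, 2])
        np.testing.assert_array_equal(tpl.template_1, h[0])
        np.testing.assert_array_equal(tpl.template_2, h[1])

    def test_duplicated_trial_is_a_fixed_point_of_the_mean(self, rng):
        h0 = _random_h(rng, 1)[0]
        h = np.stack([h0, h0, _random_h(rng, 1)[0]])
        tpl = compute_templates(h, [1, 1, 2])
        np.testing.assert_allclose(tpl.template_1, h0)

    def test_matches_direct_elementwise_mean(self, rng):
        h = _random_h(rng, 20)
        labels = np.tile([1, 2], 10)
        tpl = compute_templates(h, labels)
        np.testing.assert_allclose(tpl.template_1, h[labels == 1].mean(axis=0),
                                   atol=1e-12)
        np.testing.assert_allclose(tpl.template_2, h[labels == 2].mean(axis=0),
                                   atol=1e-12)

    def test_missing_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            compute_templates(_random_h(rng, 3), [1, 1, 1])


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        h = _random_h(rng, 2)
        tpl = compute_templates(h, [1, 2])
        rho = correlate_with_templates(h[0], tpl)
        np.testing.assert_allclose(rho[:, 0], 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        h = _random_h(rng, 2)
        tpl = compute_templates(h, [1, 2])
        rho = correlate_with_templates(2.0 * h[0] + 5.0, tpl)
        np.testing.assert_allclose(rho[:, 0], 1.0, atol=1e-12)

    def test_matches_textbook_pearson_formula(self, rng):
        h = _random_h(rng, 12)
        tpl = compute_templates(h[:8], np.tile([1, 2], 4))
        trial = h[9]
        rho = correlate_with_templates(trial, tpl)
        for j in range(trial.shape[0]):
            for n, template in enumerate([tpl.template_1, tpl.template_2]):
                a, b = template[j], trial[j]
                oracle = (np.mean((a - a.mean()) * (b - b.mean()))
                          / (a.std() * b.std()))
                assert rho[j, n] == pytest.approx(oracle, abs=1e-12)

    def test_bounded_by_one_in_magnitude(self, rng):
        h = _random_h(rng, 30)
        tpl = compute_templates(h[:10], np.tile([1, 2], 5))
        rho = correlation_profiles(h, tpl)
        assert np.abs(rho).max() <= 1.0

    def test_zero_variance_row_maps_to_zero(self, rng):
        h = _random_h(rng, 2)
        tpl = compute_templates(h, [1, 2])
        flat = h[0].copy()
        flat[2] = 7.0
        rho = correlate_with_templates(flat, tpl)
        np.testing.assert_array_equal(rho[2], [0.0, 0.0])

    def test_no_class_contrast_gives_centered_correlation_difference(self, rng):
        """With exchangeable classes the mean of rho_1 - rho_2 is ~0."""
        h = _random_h(rng, 240, n_freq=4, t_w=60)
        labels = np.tile([1, 2], 120)
        tpl = compute_templates(h[:40], labels[:40])
        rho = correlation_profiles(h[40:], tpl)
        diff = rho[..., 0] - rho[..., 1]
        se = diff.std() / np.sqrt(diff.shape[0])
        assert abs(diff.mean()) < 2 * se + 1e-3


class TestCalibration:
    def _discriminative_h(self, rng, n_trials, j_star=3, n_freq=8, t_w=120):
        """Classes differ only in the temporal profile of row j_star."""
        h = rng.uniform(0.5, 1.5, size=(n_trials, n_freq, t_w))
        labels = np.tile([1, 2], n_trials // 2)
        rise = np.linspace(0.0, 1.0, t_w)
        h[labels == 1, j_star, :] += 2.0 * rise          # ramp up
        h[labels == 2, j_star, :] += 2.0 * rise[::-1]    # ramp down
        return h, labels

    def test_recovers_the_discriminative_frequency(self, rng):
        grid = make_grid((8, 32), 8)
        h, labels = self._discriminative_h(rng, 60)
        res = calibrate_frequency(h[:40], labels[:40], h[40:], labels[40:],
                                  grid, seed=0)
        assert res.f_a_index == 3
        assert res.f_a_freq == grid.freqs[3]
        assert res.q_at_f_a == res.q[3] == res.q.max()

    def test_selector_is_one_hot_at_f_a(self, rng):
        grid = make_grid((8, 32), 8)
        h, labels = self._discriminative_h(rng, 40)
        res = calibrate_frequency(h[:28], labels[:28], h[28:], labels[28:],
                                  grid, seed=1)
        assert res.selector.sum() == 1
        assert res.selector[res.f_a_index] == 1

    def test_bootstrap_strategy_agrees_on_strong_contrast(self, rng):
        grid = make_grid((8, 32), 8)
        h, labels = self._discriminative_h(rng, 60)
        res = calibrate_frequency(h[:40], labels[:40], h[40:], labels[40:],
                                  grid, seed=0, strategy="bootstrap")
        assert res.f_a_index == 3
        assert 0 <= res.q.min() and res.q.max() <= 1

    def test_shuffled_labels_drive_q_to_chance(self, rng):
        grid = make_grid((8, 32), 8)
        h, labels = self._discriminative_h(rng, 80)
        shuffled = rng.permutation(labels[:56])
        res = calibrate_frequency(h[:56], shuffled, h[56:], labels[56:],
                                  grid, seed=2)
        # binomial CI around 0.5 for the pooled 10-fold evaluation (n=80)
        assert abs(res.q.mean() - 0.5) < 2 * np.sqrt(0.25 / 80) + 0.05

    def test_tiny_calibration_set_rejected(self, rng):
        grid = make_grid((8, 32), 4)
        h, labels = self._discriminative_h(rng, 20, n_freq=4)
        with pytest.raises(ValueError, match="calibration"):
            calibrate_frequency(h[:18], labels[:18], h[18:], labels[18:],
                                grid, seed=0)

    def test_unknown_strategy_rejected(self, rng):
        grid = make_grid((8, 32), 4)
        h, labels = self._discriminative_h(rng, 20, n_freq=4)
        with pytest.raises(ValueError, match="strategy"):
            calibrate_frequency(h[:12], labels[:12], h[12:], labels[12:],
                                grid, seed=0, strategy="nope")


class TestSelectionAndFusion:
    def test_feature_extraction_picks_the_profile_row(self):
        profile = np.array([[0.1, 0.2], [0.9, -0.2], [0.3, 0.4]])
        np.testing.assert_array_equal(tcsp_features(profile, 1), [0.9, -0.2])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(IndexError):
            tcsp_features(np.zeros((4, 2)), 4)

    def test_one_hot_product_equals_direct_indexing(self, rng):
        for _ in range(50):
            profile = rng.uniform(-1, 1, size=(16, 2))
            idx = int(rng.integers(16))
            selector = np.zeros(16)
            selector[idx] = 1.0
            np.testing.assert_allclose(select_one_hot(profile, selector),
                                       tcsp_features(profile, idx), atol=1e-15)

    def test_invalid_selector_rejected(self, rng):
        profile = rng.uniform(size=(4, 2))
        with pytest.raises(ValueError):
            select_one_hot(profile, np.array([1.0, 1.0, 0.0, 0.0]))

    def test_fusion_orders_tcsp_first(self):
        y = fuse([0.9, -0.2], np.arange(8.0))
        assert len(y) == 10
        np.testing.assert_array_equal(y[:2], [0.9, -0.2])

    def test_empty_csp_part_gives_tcsp_only(self):
        np.testing.assert_array_equal(fuse([0.5, 0.1], []), [0.5, 0.1])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=5),
           st.lists(st.floats(-5, 5), min_size=0, max_size=8),
           st.lists(st.floats(-5, 5), min_size=0, max_size=8))
    def test_fusion_is_associative_as_concatenation(self, a, b, c):
        one_shot = fuse(a, list(b) + list(c))
        nested = fuse(fuse(a, b), c)
        np.testing.assert_array_equal(one_shot, nested)
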
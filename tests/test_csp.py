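"""CSP fitting against closed forms and the generalized-eigenproblem oracle."""

import numpy as np
import pytest
from scipy import linalg

from tcsp.io import EpochSet
from tcsp.csp import fit_csp, apply_csp, csp_features

from conftest import make_gaussian_epochs, random_spd


def _principal_angles(a, b):
    """Largest principal angle (rad) between the row spaces of a and b."""
    qa = np.linalg.qr(a.T)[0]
    qb = np.linalg.qr(b.T)[0]
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s.min(), -1, 1))


class TestFitCSP:
    def test_decoupled_channels_yield_extreme_eigenvalues(self):
        rng = np.random.default_rng(0)
        n_tr, t = 40, 500
        data = np.zeros((2 * n_tr, 2, t))
        data[:n_tr, 0] = rng.standard_normal((n_tr, t))   # class 1: channel 1
        data[n_tr:, 1] = rng.standard_normal((n_tr, t))   # class 2: channel 2
        epochs = EpochSet(data, np.repeat([1, 2], n_tr), 100.0, 0.0)
        model = fit_csp(epochs, n_keep=1)
        lam1, _ = model.eigvals
        assert lam1[0] == pytest.approx(1.0, abs=1e-6)
        assert lam1[-1] == pytest.approx(0.0, abs=1e-6)
        # filters align with the coordinate axes up to scale and sign
        w = model.filters / np.abs(model.filters).max(axis=1, keepdims=True)
        assert np.abs(w[0, 1]) < 1e-3 and np.abs(w[-1, 0]) < 1e-3

    def test_identical_classes_give_half_eigenvalues(self, rng):
        data = rng.standard_normal((20, 4, 200))
        both = np.concatenate([data, data])
        epochs = EpochSet(both, np.repeat([1, 2], 20), 100.0, 0.0)
        model = fit_csp(epochs, n_keep=2)
        np.testing.assert_allclose(model.eigvals[0], 0.5, atol=1e-10)
        np.testing.assert_allclose(model.eigvals[1], 0.5, atol=1e-10)

    def test_matches_generalized_eigenproblem_oracle(self):
        """Whitening-route filters span the same top/bottom subspaces as
        scipy's generalized eigendecomposition of (C1, C1+C2)."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            m = int(rng.integers(1, n // 2 + 1))
            epochs = make_gaussian_epochs(random_spd(n, rng), random_spd(n, rng),
                                          n_trials=25, n_samples=400,
                                          seed=1000 + trial)
            model = fit_csp(epochs, n_keep=m)
            c1, c2 = model.class_cov
            vals, vecs = linalg.eigh(c1, c1 + c2)
            order = np.argsort(vals)[::-1]
            vecs = vecs[:, order]
            top_oracle = vecs[:, :m].T
            bot_oracle = vecs[:, -m:].T
            w = model.filters
            assert _principal_angles(w[:m], top_oracle) < 1e-6
            assert _principal_angles(w[-m:], bot_oracle) < 1e-6

    def test_eigenvalue_complementarity(self, rng):
        epochs = make_gaussian_epochs(random_spd(6, rng), random_spd(6, rng),
                                      seed=5)
        model = fit_csp(epochs, n_keep=3)
        lam1, lam2 = model.eigvals
        np.testing.assert_allclose(lam1 + lam2, 1.0, atol=1e-8)

    def test_whitening_property(self, rng):
        epochs = make_gaussian_epochs(random_spd(5, rng), random_spd(5, rng),
                                      seed=6)
        model = fit_csp(epochs, n_keep=2)
        ident = model.whitener @ model.composite @ model.whitener.T
        np.testing.assert_allclose(ident, np.eye(5), atol=1e-8)

    def test_diagonalizes_both_class_covariances(self, rng):
        epochs = make_gaussian_epochs(random_spd(5, rng), random_spd(5, rng),
                                      seed=8)
        model = fit_csp(epochs, n_keep=2)
        for cov in model.class_cov:
            d = model.filters @ cov @ model.filters.T
            off = d - np.diag(np.diag(d))
            assert np.abs(off).max() / np.abs(np.diag(d)).max() < 1e-6

    def test_scale_invariance(self, rng):
        epochs = make_gaussian_epochs(random_spd(4, rng), random_spd(4, rng),
                                      seed=9)
        scaled = EpochSet(epochs.data * 37.5, epochs.labels, epochs.rate, 0.0)
        m1 = fit_csp(epochs, n_keep=2)
        m2 = fit_csp(scaled, n_keep=2)
        # same row directions
        for r1, r2 in zip(m1.filters, m2.filters):
            cos = np.dot(r1, r2) / (np.linalg.norm(r1) * np.linalg.norm(r2))
            assert abs(cos) == pytest.approx(1.0, abs=1e-8)
        z1 = apply_csp(m1, epochs)[0]
        z2 = apply_csp(m2, scaled)[0]
        np.testing.assert_allclose(csp_features(z1), csp_features(z2), atol=1e-8)

    def test_single_class_rejected(self, rng):
        data = rng.standard_normal((10, 3, 100))
        epochs = EpochSet(data, np.ones(10, dtype=int), 100.0, 0.0)
        with pytest.raises(ValueError, match="both classes"):
            fit_csp(epochs, n_keep=1)

    def test_too_many_components_rejected(self, rng):
        epochs = make_gaussian_epochs(random_spd(4, rng), random_spd(4, rng))
        with pytest.raises(ValueError, match="2M"):
            fit_csp(epochs, n_keep=3)


class TestApplyCSP:
    def test_zero_trial_maps_to_zero(self, rng):
        epochs = make_gaussian_epochs(random_spd(4, rng), random_spd(4, rng))
        model = fit_csp(epochs, n_keep=2)
        z = apply_csp(model, np.zeros((4, 100)))
        assert np.all(z == 0)

    def test_channel_mismatch_rejected(self, rng):
        epochs = make_gaussian_epochs(random_spd(4, rng), random_spd(4, rng))
        model = fit_csp(epochs, n_keep=2)
        with pytest.raises(ValueError, match="channels"):
            apply_csp(model, np.zeros((5, 100)))

    def test_first_rows_maximize_class1_variance(self, rng):
        epochs = make_gaussian_epochs(random_spd(6, rng), random_spd(6, rng),
                                      n_trials=50, n_samples=500, seed=4)
        model = fit_csp(epochs, n_keep=3)
        z_full = np.einsum("cn,int->ict", model.filters,
                           epochs.data[epochs.labels == 1])
        var1 = z_full.var(axis=2).mean(axis=0)
        var2 = np.einsum("cn,int->ict", model.filters,
                         epochs.data[epochs.labels == 2]).var(axis=2).mean(axis=0)
        ratio = var1 / (var1 + var2)
        # ordering follows the class-1 variance fraction
        assert np.all(np.diff(ratio) < 0.05)
        assert ratio[0] > ratio[-1]


class TestCSPFeatures:
    def test_uniform_variances_give_log_inverse_count(self, rng):
        z = rng.standard_normal((8, 5000))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1,
                                                        keepdims=True)
        sigma = csp_features(z)
        np.testing.assert_allclose(sigma, np.log(1 / 8), atol=1e-10)

    def test_two_component_closed_form(self, rng):
        z = rng.standard_normal((2, 10000))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1,
                                                        keepdims=True)
        z[0] *= np.sqrt(3.0)
        sigma = csp_features(z)
        np.testing.assert_allclose(sigma, [np.log(0.75), np.log(0.25)],
                                   atol=1e-10)

    def test_proportions_sum_to_one(self, rng):
        for _ in range(10):
            z = rng.standard_normal((6, 137)) * rng.uniform(0.1, 10)
            assert np.exp(csp_features(z)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_row_named_in_error(self, rng):
        z = rng.standard_normal((4, 100))
        z[2] = 1.0
        with pytest.raises(ValueError, match="2"):
            csp_features(z)
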
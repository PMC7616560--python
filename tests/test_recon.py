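import numpy as np
import pytest
from scipy import optimize, sparse

from fbsem import tikhonov_prior
from fbsem.projector import ScannerGeometry, SystemModel
from fbsem.recon import (
    ReconConfig,
    em_update,
    fbsem_reconstruct,
    fuse,
    log_posterior,
    mapem_depierro,
    osem,
    tune_gamma,
)
from fbsem.simulate import Sinogram, sample_poisson, scale_to_counts


def _single_bin_model():
    geom = ScannerGeometry(1, 1, 1.0, 1, 1.0)
    H = sparse.csr_matrix(np.array([[1.0]]))
    return geom, SystemModel(geom, H, np.ones(1), [np.array([0])])


class TestLogPosterior:
    @pytest.mark.parametrize("y,expected", [(0, -1.0), (1, -1.0), (3, 3 * np.log(3) - 3)])
    def test_single_bin_closed_forms(self, y, expected):
        geom, model = _single_bin_model()
        sino = Sinogram(np.array([y]), np.zeros(1), geom)
        x = np.array([[float(y) if y > 0 else 1.0]])
        assert np.isclose(log_posterior(model, sino, x), expected)

    def test_zero_mean_positive_count_is_minus_inf(self):
        geom, model = _single_bin_model()
        sino = Sinogram(np.array([2]), np.zeros(1), geom)
        assert log_posterior(model, sino, np.zeros((1, 1))) == -np.inf

    def test_beta_zero_equals_likelihood(self, toy16):
        model, x, bbar, sino = toy16
        prior = tikhonov_prior(model.image_shape)
        L = log_posterior(model, sino, x.data)
        assert log_posterior(model, sino, x.data, prior, 0.0) == L
        assert log_posterior(model, sino, x.data, prior, 1.0) < L


class TestEMUpdate:
    def test_noise_free_data_is_fixed_point(self, model32, phantom32):
        x, _ = scale_to_counts(model32, phantom32.activity, 5e4, randoms_fraction=0.0)
        exact = model32.forward(x.data)
        sino = Sinogram(exact, np.zeros_like(exact), model32.geometry)
        for m in range(model32.n_subsets):
            out = em_update(model32, sino, x.data, m)
            np.testing.assert_allclose(out, x.data, rtol=1e-9, atol=1e-12)

    def test_matches_dense_matrix_oracle(self, model32, problem32):
        x0 = np.ones(model32.image_shape)
        _, _, sino = problem32
        m = 1
        idx = model32.subsets[m]
        Hd = model32.attenuation[idx, None] * model32.H[idx].toarray()
        q = Hd @ x0.ravel() + sino.randoms[idx]
        s = Hd.sum(axis=0)
        expected = np.where(
            s > 0, x0.ravel() / np.maximum(s, 1e-300) * (Hd.T @ (sino.counts[idx] / q)), 0.0
        ).reshape(model32.image_shape)
        np.testing.assert_allclose(em_update(model32, sino, x0, m), expected, atol=1e-10)

    def test_ratio_homogeneity_in_counts(self, model32, problem32):
        x, _, sino = problem32
        doubled = Sinogram(2 * sino.counts, np.zeros_like(sino.randoms), model32.geometry)
        plain = Sinogram(sino.counts, np.zeros_like(sino.randoms), model32.geometry)
        a = em_update(model32, doubled, x.data, 0)
        b = em_update(model32, plain, x.data, 0)
        np.testing.assert_allclose(a, 2.0 * b, rtol=1e-10)


class TestFusion:
    def test_zero_delta_returns_em_image(self):
        rng = np.random.default_rng(0)
        x_em = rng.uniform(0, 2, (16, 16))
        x_reg = rng.uniform(-1, 2, (16, 16))
        np.testing.assert_array_equal(fuse(x_em, x_reg, 0.0), x_em)

    def test_consistent_fixed_point(self):
        c = 1.7
        out = fuse(np.full(4, c), np.full(4, c), np.full(4, 0.3))
        np.testing.assert_allclose(out, c, rtol=1e-12)

    def test_root_of_quadratic_against_root_finder(self):
        rng = np.random.default_rng(1)
        x_em = rng.uniform(1e-3, 5.0, 300)
        x_reg = rng.uniform(-2.0, 5.0, 300)
        delta = 10.0 ** rng.uniform(-6, 2, 300)
        out = fuse(x_em, x_reg, delta)
        resid = delta * out**2 + (1 - delta * x_reg) * out - x_em
        scale = delta * out**2 + np.abs(1 - delta * x_reg) * out + x_em
        assert np.max(np.abs(resid) / np.maximum(scale, 1e-300)) < 1e-10
        assert np.all(out >= 0)
        for i in range(0, 300, 37):  # independent bracketed root finder
            f = lambda z: delta[i] * z**2 + (1 - delta[i] * x_reg[i]) * z - x_em[i]
            hi = max(x_em[i], x_reg[i], 1.0) * 10 + 10
            root = optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
            assert np.isclose(out[i], root, rtol=1e-9, atol=1e-12)

    def test_nonnegative_even_for_negative_reg(self):
        out = fuse(np.array([0.5]), np.array([-30.0]), np.array([2.0]))
        assert out[0] >= 0


class TestFBSEMLoop:
    def test_no_prior_equals_osem_exactly(self, model32, problem32):
        _, _, sino = problem32
        ref = osem(model32, sino, n_iterations=5)
        cfg = ReconConfig(n_iterations=5, n_subsets=4, prior=None)
        alt = fbsem_reconstruct(model32, sino, cfg)
        np.testing.assert_array_equal(ref.image.data, alt.image.data)

    def test_infinite_gamma_with_prior_equals_osem(self, model32, problem32, phantom32):
        _, _, sino = problem32
        prior = tikhonov_prior(model32.image_shape, mr=phantom32.mr)
        cfg = ReconConfig(n_iterations=5, n_subsets=4, gamma=np.inf, prior=prior)
        with_prior = fbsem_reconstruct(model32, sino, cfg)
        ref = osem(model32, sino, n_iterations=5)
        nz = ref.image.data > 0
        rel = np.abs(with_prior.image.data[nz] - ref.image.data[nz]) / ref.image.data[nz]
        assert rel.max() <= 1e-12

    def test_mlem_monotone_log_likelihood(self, toy16):
        model, _, _, sino = toy16
        cfg = ReconConfig(n_iterations=20, n_subsets=1, prior=None, record_objective=True)
        trace = fbsem_reconstruct(model, sino, cfg).objective_trace
        assert np.all(np.diff(trace) >= -1e-9)

    def test_depierro_monotone_penalized_objective(self, toy16):
        model, _, _, sino = toy16
        prior = tikhonov_prior(model.image_shape)
        cfg = ReconConfig(
            n_iterations=20, n_subsets=1, prior=prior, depierro=True, beta=1.0,
            record_objective=True,
        )
        trace = fbsem_reconstruct(model, sino, cfg).objective_trace
        assert np.all(np.diff(trace) >= -1e-9)

    def test_mlem_count_preservation(self, toy16):
        # classical MLEM property: sum_j s_j x_j = sum_i y_i from iteration 1 on
        model, x, _, _ = toy16
        sino = sample_poisson(model, x, None, seed=3)  # no randoms
        s = model.sensitivity()
        for n_it in (1, 3):
            res = fbsem_reconstruct(
                model, sino, ReconConfig(n_iterations=n_it, n_subsets=1)
            )
            assert np.isclose(np.sum(s * res.image.data), sino.counts.sum(), rtol=1e-8)

    def test_subset_mismatch_raises(self, model32, problem32):
        _, _, sino = problem32
        with pytest.raises(ValueError):
            fbsem_reconstruct(model32, sino, ReconConfig(n_iterations=1, n_subsets=3))


class TestTuneGamma:
    def test_single_point_grid(self, model32, problem32, phantom32):
        from fbsem.simulate import DatasetRecord

        x, _, sino = problem32
        rec = DatasetRecord(phantom32, x, sino, model32, 6e4)
        cfg = ReconConfig(n_iterations=3, n_subsets=4)
        assert tune_gamma([rec], [0.5], cfg) == 0.5

    def test_result_is_grid_member(self, model32, problem32, phantom32):
        from fbsem.simulate import DatasetRecord

        x, _, sino = problem32
        rec = DatasetRecord(phantom32, x, sino, model32, 6e4)
        cfg = ReconConfig(n_iterations=3, n_subsets=4)
        grid = [0.05, 0.5, 5.0]
        assert tune_gamma([rec], grid, cfg) in grid
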
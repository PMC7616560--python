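import numpy as np
import pytest

from fbsem.fbsemnet import (
    TrainConfig,
    _fuse_backward,
    _fuse_forward,
    _unit_backward,
    _unit_forward,
    _unrolled_backward,
    _unrolled_states,
    build_unit,
    count_parameters,
    infer,
    reg_step_net,
    train,
    unrolled_forward,
)
from fbsem.recon import osem
from fbsem.simulate import simulate_dataset


@pytest.fixture(scope="module")
def tiny_records():
    return simulate_dataset(
        2, n_rotations=1, size_px=32, count_levels=6e4, split="train", seed=3,
        n_subsets=4, n_lesions=4,
    )


class TestArchitecture:
    def test_pet_only_parameter_budget(self):
        # 320 + 3*9248 + 289 conv scalars, 4*64 + 2 BN affines, + gamma
        net = build_unit("pet")
        assert count_parameters(net) == 320 + 3 * 9248 + 289 + 4 * 64 + 2 + 1

    def test_pet_mr_first_layer_widened(self):
        net = build_unit("petmr")
        assert net.params["conv0_W"].shape == (32, 2, 3, 3)
        assert count_parameters(net) == 28612 + 32 * 9  # extra input channel only

    def test_gamma_positive_and_log_parameterized(self):
        net = build_unit("pet")
        net.params["log_gamma"] = np.array(-3.0)
        assert net.gamma == pytest.approx(np.exp(-3.0))
        assert net.gamma > 0


class TestRegStep:
    def test_zero_final_layer_is_identity_on_nonnegative(self):
        net = build_unit("pet", seed=0)
        net.params["conv4_W"][:] = 0.0
        net.params["conv4_b"][:] = 0.0
        x = np.random.default_rng(0).uniform(0, 2, (16, 16))
        np.testing.assert_allclose(reg_step_net(net, x), x, atol=1e-12)

    @pytest.mark.parametrize("size", [32, 64])
    def test_output_shape_and_nonnegativity(self, size):
        net = build_unit("pet", seed=1)
        x = np.random.default_rng(1).standard_normal((size, size))
        out = reg_step_net(net, x)
        assert out.shape == (size, size)
        assert np.all(out >= 0)

    def test_mr_channel_changes_output(self):
        net = build_unit("petmr", seed=2)
        x = np.random.default_rng(2).uniform(0, 1, (16, 16))
        a = reg_step_net(net, x, mr=np.zeros((16, 16)))
        b = reg_step_net(net, x, mr=np.ones((16, 16)))
        assert not np.allclose(a, b)


class TestGradients:
    def test_unit_backward_matches_finite_differences(self):
        net = build_unit("pet", seed=0)
        rng = np.random.default_rng(1)
        x = rng.uniform(0.1, 1.0, (2, 1, 8, 8))

        def loss(net):
            out, cache = _unit_forward(net, x, None, True)
            return 0.5 * np.sum(out**2), out, cache

        L, out, cache = loss(net)
        grads = {k: np.zeros_like(v) for k, v in net.params.items()}
        dx = _unit_backward(net, out, cache, grads)
        eps = 1e-6
        for key in ["conv0_W", "conv2_W", "conv4_b", "bn1_g", "bn3_b"]:
            p = net.params[key]
            idx = tuple(rng.integers(0, d) for d in p.shape)
            old = p[idx]
            p[idx] = old + eps
            Lp = loss(net)[0]
            p[idx] = old - eps
            Lm = loss(net)[0]
            p[idx] = old
            fd = (Lp - Lm) / (2 * eps)
            assert abs(fd - grads[key][idx]) / max(abs(fd), 1e-8) < 1e-4
        i0 = (0, 0, 3, 4)
        xp = x.copy()
        xp[i0] += eps
        xm = x.copy()
        xm[i0] -= eps
        fd = (0.5 * np.sum(_unit_forward(net, xp, None, True)[0] ** 2)
              - 0.5 * np.sum(_unit_forward(net, xm, None, True)[0] ** 2)) / (2 * eps)
        assert abs(fd - dx[i0]) / max(abs(fd), 1e-8) < 1e-4

    def test_fusion_vjps_match_finite_differences(self):
        rng = np.random.default_rng(5)
        E = rng.uniform(0.01, 2, 200)
        R = rng.uniform(-1, 2, 200)
        D = rng.uniform(0.01, 5, 200)
        g = rng.standard_normal(200)
        out, cache = _fuse_forward(E, R, D)
        dR, dDelta = _fuse_backward(g, cache)
        eps = 1e-7
        fdR = (_fuse_forward(E, R + eps, D)[0] - _fuse_forward(E, R - eps, D)[0]) / (2 * eps) * g
        fdD = (_fuse_forward(E, R, D + eps)[0] - _fuse_forward(E, R, D - eps)[0]) / (2 * eps) * g
        np.testing.assert_allclose(dR, fdR, rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(dDelta, fdD, rtol=1e-3, atol=1e-6)

    def test_single_state_chain_matches_finite_differences(self):
        # with one state the input is constant, so the EM block carries no
        # parameter dependence and full finite differences apply
        recs = simulate_dataset(
            2, n_rotations=1, size_px=32, count_levels=6e4, split="train", seed=3,
            n_subsets=1, n_lesions=4,
        )
        net = build_unit("pet", seed=0)
        refs = np.stack([r.reference.data for r in recs])[:, None]

        def loss(net):
            x, _ = _unrolled_states(net, recs, 1, training=True, keep_cache=False)
            return 0.5 * np.sum((x - refs) ** 2)

        x, states = _unrolled_states(net, recs, 1, training=True, keep_cache=True)
        grads = {k: np.zeros_like(v) for k, v in net.params.items()}
        _unrolled_backward(net, x - refs, states, grads)
        rng = np.random.default_rng(2)
        eps = 1e-6
        for key in ["log_gamma", "conv0_W", "conv4_W", "bn0_g"]:
            p = net.params[key]
            if p.shape:
                idx = tuple(rng.integers(0, d) for d in p.shape)
                old = p[idx]
                p[idx] = old + eps
                Lp = loss(net)
                p[idx] = old - eps
                Lm = loss(net)
                p[idx] = old
                analytic = grads[key][idx]
            else:
                old = float(p)
                net.params[key] = np.array(old + eps)
                Lp = loss(net)
                net.params[key] = np.array(old - eps)
                Lm = loss(net)
                net.params[key] = np.array(old)
                analytic = float(grads[key])
            fd = (Lp - Lm) / (2 * eps)
            assert abs(fd - analytic) / max(abs(fd), 1e-8) < 1e-4

    def test_em_block_stops_gradient_flow(self, tiny_records):
        # over several states, full finite differences see the EM path but the
        # backward pass deliberately does not: the two must disagree
        net = build_unit("pet", seed=0)
        refs = np.stack([r.reference.data for r in tiny_records])[:, None]
        x, states = _unrolled_states(net, tiny_records, 2, training=True, keep_cache=True)
        grads = {k: np.zeros_like(v) for k, v in net.params.items()}
        _unrolled_backward(net, x - refs, states, grads)
        eps = 1e-6
        old = float(net.params["log_gamma"])
        net.params["log_gamma"] = np.array(old + eps)
        Lp = 0.5 * np.sum(
            (_unrolled_states(net, tiny_records, 2, training=True, keep_cache=False)[0] - refs) ** 2
        )
        net.params["log_gamma"] = np.array(old - eps)
        Lm = 0.5 * np.sum(
            (_unrolled_states(net, tiny_records, 2, training=True, keep_cache=False)[0] - refs) ** 2
        )
        net.params["log_gamma"] = np.array(old)
        fd = (Lp - Lm) / (2 * eps)
        assert abs(fd - float(grads["log_gamma"])) / max(abs(fd), 1e-8) > 1e-3


class TestUnrolled:
    def test_degenerates_to_osem_with_identity_unit_and_large_gamma(self, tiny_records):
        rec = tiny_records[0]
        net = build_unit("pet", seed=0)
        net.params["conv4_W"][:] = 0.0
        net.params["conv4_b"][:] = 0.0
        net.params["log_gamma"] = np.array(25.0)
        img = unrolled_forward(net, rec.model, rec.sinogram, n_iterations=3)
        ref = osem(rec.model, rec.sinogram, n_iterations=3).image.data
        np.testing.assert_allclose(img, ref, rtol=1e-8, atol=1e-10)

    def test_state_count(self, tiny_records, monkeypatch):
        import fbsem.fbsemnet as fn

        calls = {"n": 0}
        orig = fn.em_update

        def counting(*a, **kw):
            calls["n"] += 1
            return orig(*a, **kw)

        monkeypatch.setattr(fn, "em_update", counting)
        rec = tiny_records[0]
        net = build_unit("pet", seed=0)
        unrolled_forward(net, rec.model, rec.sinogram, n_iterations=2)
        assert calls["n"] == 2 * rec.model.n_subsets

    def test_weights_shared_across_states(self, tiny_records):
        # the unit parameters are a single shared object: mutating them
        # changes every state of a subsequent pass
        rec = tiny_records[0]
        net = build_unit("pet", seed=0)
        a = unrolled_forward(net, rec.model, rec.sinogram, n_iterations=2)
        net.params["conv0_b"][:] += 0.5
        b = unrolled_forward(net, rec.model, rec.sinogram, n_iterations=2)
        assert not np.allclose(a, b)


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self, tiny_records):
        cfg = TrainConfig(
            epochs=4, n_minibatches=2, learning_rate=0.02, seed=1, n_iterations=2
        )
        net1, hist1 = train(tiny_records, cfg)
        net2, hist2 = train(tiny_records, cfg)
        assert hist1[-1] < hist1[0]
        np.testing.assert_allclose(hist1, hist2, rtol=1e-12)
        np.testing.assert_allclose(
            net1.params["conv0_W"], net2.params["conv0_W"], rtol=1e-12
        )

    def test_infer_returns_image(self, tiny_records):
        cfg = TrainConfig(epochs=1, n_minibatches=1, learning_rate=0.02, seed=0,
                          n_iterations=1)
        net, _ = train(tiny_records, cfg)
        img = infer(net, tiny_records[0], n_iterations=1)
        assert img.data.shape == tiny_records[0].model.image_shape
        assert np.all(img.data >= 0)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(epochs=1))
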
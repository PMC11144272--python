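"""Diffusion core: schedule, forward/inverse algebra, loss, sampler, net."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from emrestore import diffusion as dif
from emrestore import nn


class TestSchedule:
    def test_two_step_alpha_bar_by_hand(self):
        # betas 0.1, 0.2 -> alpha_bar = 0.9, 0.9*0.8 = 0.72
        sch = dif.build_schedule(T=2, beta_min=0.1, beta_max=0.2)
        np.testing.assert_allclose(sch.alpha_bar[1:], [0.9, 0.72])

    def test_alpha_bar_strictly_decreasing(self):
        sch = dif.build_schedule(T=100, beta_min=1e-3, beta_max=0.1)
        assert np.all(np.diff(sch.alpha_bar[1:]) < 0)

    def test_default_schedule_reaches_noise(self):
        sch = dif.build_schedule()
        assert sch.T == 1000
        assert sch.alpha_bar[-1] < 0.01

    @pytest.mark.parametrize("kwargs", [dict(T=1), dict(beta_min=0.0),
                                        dict(beta_min=0.3, beta_max=0.2),
                                        dict(beta_max=1.5)])
    def test_invalid_bounds(self, kwargs):
        with pytest.raises(ValueError):
            dif.build_schedule(**kwargs)


class TestForwardNoise:
    def test_zero_eps(self):
        sch = dif.build_schedule(T=10, beta_min=0.01, beta_max=0.2)
        x0 = np.random.default_rng(0).standard_normal((8, 8))
        out = dif.forward_noise(x0, 5, np.zeros_like(x0), sch)
        np.testing.assert_allclose(out, np.sqrt(sch.alpha_bar[5]) * x0)

    def test_scalar_hand_value(self):
        # abar = 0.64: x_t = 0.8*1 + 0.6*0.5 = 1.1
        sch = dif.build_schedule(T=2, beta_min=0.2, beta_max=0.55)
        np.testing.assert_allclose(sch.alpha_bar[2], 0.36, atol=1e-12)
        sch2 = dif.NoiseSchedule(
            T=1, beta=np.array([0.0, 0.36]), alpha=np.array([1.0, 0.64]),
            alpha_bar=np.array([1.0, 0.64]), sigma2=np.array([0.0, 0.36]))
        out = dif.forward_noise(np.array(1.0), 1, np.array(0.5), sch2)
        np.testing.assert_allclose(out, 1.1)

    def test_inversion_identity(self):
        """(x_t - sqrt(1-abar) eps) / sqrt(abar) == x0 to 1e-6."""
        rng = np.random.default_rng(1)
        sch = dif.build_schedule(T=50, beta_min=1e-3, beta_max=0.3)
        for t in (1, 17, 50):
            x0 = rng.standard_normal((16, 16))
            eps = rng.standard_normal((16, 16))
            xt = dif.forward_noise(x0, t, eps, sch)
            ab = sch.alpha_bar[t]
            back = (xt - np.sqrt(1 - ab) * eps) / np.sqrt(ab)
            np.testing.assert_allclose(back, x0, atol=1e-6)

    def test_t_out_of_range(self):
        sch = dif.build_schedule(T=10, beta_min=0.01, beta_max=0.1)
        with pytest.raises(IndexError):
            dif.forward_noise(np.zeros((4, 4)), 11, np.zeros((4, 4)), sch)


class TestDifficultyLoss:
    def test_phi_one_reduces_to_half_mse(self):
        rng = np.random.default_rng(2)
        e1, e2 = rng.standard_normal((2, 32, 32))
        loss = dif.difficulty_loss(e1, e2, np.ones_like(e1))
        np.testing.assert_allclose(loss, np.mean((e1 - e2) ** 2) / 2,
                                   atol=1e-7)

    def test_scalar_values(self):
        # e = 2: phi=1 -> 2.0 ; phi=2 -> 0.5 + ln 2
        assert dif.difficulty_loss(np.array([2.0]), np.array([0.0]),
                                   np.array([1.0])) == pytest.approx(2.0)
        assert dif.difficulty_loss(np.array([2.0]), np.array([0.0]),
                                   np.array([2.0])) == pytest.approx(
            0.5 + np.log(2.0))

    def test_pixelwise_minimizer_is_abs_error(self):
        """Numeric minimization over phi recovers the analytic optimum
        phi* = |e| (from d/dphi [e^2/(2 phi^2) + log phi] = 0)."""
        for e in (0.3, 1.7):
            res = minimize_scalar(
                lambda p: dif.difficulty_loss(np.array([e]), np.array([0.0]),
                                              np.array([p])),
                bounds=(1e-3, 10.0), method="bounded",
                options={"xatol": 1e-8})
            assert res.x == pytest.approx(abs(e), abs=1e-4)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            dif.difficulty_loss(np.ones(3), np.zeros(3), np.zeros(3))


class _OracleEpsNet:
    """Returns a fixed eps field regardless of input (teacher trajectory)."""

    def __init__(self, eps):
        self.eps = eps

    def __call__(self, x_t, cond, t, j=None):
        e = np.broadcast_to(self.eps, (1, 1) + self.eps.shape)
        return nn.Tensor(e), nn.Tensor(np.ones_like(e))


class TestReverseStep:
    def test_scalar_hand_value(self):
        # alpha=0.9, abar=0.9: (1/sqrt(0.9)) (1 - (0.1/sqrt(0.1)) 0.5)
        sch = dif.NoiseSchedule(
            T=1, beta=np.array([0.0, 0.1]), alpha=np.array([1.0, 0.9]),
            alpha_bar=np.array([1.0, 0.9]), sigma2=np.array([0.0, 0.1]))
        net = _OracleEpsNet(np.array([[0.5]]))
        out = dif.reverse_step(np.array([[1.0]]), 1, np.array([[[0.0]]]),
                               None, net, sch, np.random.default_rng(0),
                               clip_denoised=False)
        expected = (1.0 - 0.1 / np.sqrt(0.1) * 0.5) / np.sqrt(0.9)
        np.testing.assert_allclose(out, [[expected]], atol=1e-12)
        assert expected == pytest.approx(0.8874, abs=5e-5)

    def test_one_step_inversion(self):
        """T=1 with the true eps recovers x0 (final step adds no noise)."""
        rng = np.random.default_rng(3)
        x0 = np.clip(rng.standard_normal((8, 8)) * 0.3, -1, 1)
        eps = rng.standard_normal((8, 8))
        sch = dif.NoiseSchedule(
            T=1, beta=np.array([0.0, 0.5]), alpha=np.array([1.0, 0.5]),
            alpha_bar=np.array([1.0, 0.5]), sigma2=np.array([0.0, 0.5]))
        xt = dif.forward_noise(x0, 1, eps, sch)
        out = dif.reverse_step(xt, 1, np.zeros((1, 8, 8)), None,
                               _OracleEpsNet(eps), sch,
                               np.random.default_rng(0))
        np.testing.assert_allclose(out, x0, atol=1e-5)

    def test_injected_noise_variance_matches_sigma(self):
        """Monte-Carlo: the reverse-step noise has variance 1 - alpha_t."""
        sch = dif.build_schedule(T=10, beta_min=0.05, beta_max=0.3)
        t = 5
        net = _OracleEpsNet(np.zeros((100, 1000)))
        rng = np.random.default_rng(4)
        x_t = np.zeros((100, 1000))
        out = dif.reverse_step(x_t, t, np.zeros((1, 100, 1000)), None, net,
                               sch, rng, clip_denoised=False)
        assert out.var() == pytest.approx(1 - sch.alpha[t], rel=0.03)


class TestSample:
    def test_deterministic_given_seed(self, toy_schedule):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=0))
        cond = np.zeros((1, 16, 16))
        a = dif.sample(cond, None, net, toy_schedule, seed=5)
        b = dif.sample(cond, None, net, toy_schedule, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_oracle_chain_recovers_teacher(self):
        """With an eps-oracle and the exact reverse recursion, the full
        chain started from the teacher's x_T lands on the teacher's x0."""
        rng = np.random.default_rng(5)
        x0 = np.clip(rng.standard_normal((8, 8)) * 0.4, -0.9, 0.9)
        T = 6
        sch = dif.build_schedule(T=T, beta_min=0.05, beta_max=0.4)

        class ExactEps:
            def __call__(self, x_t, cond, t, j=None):
                t = int(np.atleast_1d(t)[0])
                ab = sch.alpha_bar[t]
                x = np.asarray(getattr(x_t, "data", x_t))
                eps = (x - np.sqrt(ab) * x0[None, None]) / np.sqrt(1 - ab)
                return nn.Tensor(eps), nn.Tensor(np.ones_like(eps))

        rng2 = np.random.default_rng(9)
        x = rng2.standard_normal((8, 8))
        for t in range(T, 0, -1):
            x = dif.reverse_step(x, t, np.zeros((1, 8, 8)), None,
                                 ExactEps(), sch, rng2, clip_denoised=False)
        # exact-eps consistency pins every step's implied x0 to the teacher
        np.testing.assert_allclose(x, x0, atol=1e-4)


class TestEmbeddings:
    def test_channel_embed_deterministic_and_distinct(self):
        R, dim = 5, 64
        vecs = [dif.channel_embed(j, R, dim) for j in range(1, R + 1)]
        np.testing.assert_array_equal(vecs[2], dif.channel_embed(3, R, dim))
        for a in range(R):
            for b in range(a + 1, R):
                assert np.linalg.norm(vecs[a] - vecs[b]) > 0

    @pytest.mark.parametrize("j", [0, 6])
    def test_channel_embed_range(self, j):
        with pytest.raises(ValueError):
            dif.channel_embed(j, 5, 64)

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            dif.sinusoidal_embedding(1.0, 33)


class TestNetwork:
    def test_output_shapes_and_phi_positive(self):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=1))
        rng = np.random.default_rng(0)
        for trial in range(10):
            x = rng.standard_normal((1, 1, 64, 64))
            c = rng.standard_normal((1, 1, 64, 64))
            eps_hat, phi = net(x, c, trial + 1)
            assert eps_hat.data.shape == (1, 1, 64, 64)
            assert phi.data.shape == (1, 1, 64, 64)
            assert np.all(phi.data > 0)

    def test_parameter_groups_partition(self):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=1))
        groups = net.parameter_groups()
        names = [k for g in groups.values() for k in g]
        assert len(names) == len(set(names))
        assert set(names) == set(net.parameters())

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            dif.make_network(dif.NetConfig(base_width=0))
        with pytest.raises(ValueError):
            dif.make_network(dif.NetConfig(emb_dim=33))


def _tiny_dataset(n=6, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x0 = np.clip(rng.standard_normal((size, size)) * 0.3, -1, 1)
        cond = np.clip(x0 + 0.1 * rng.standard_normal((size, size)), -1, 1)
        out.append(dif.DiffusionSample(x0=x0, cond=cond[None]))
    return out


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self, toy_schedule):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=2))
        before = net.state_dict()
        net, _ = dif.train(net, _tiny_dataset(), dif.TrainConfig(
            max_epochs=0, batch_size=2, seed=0), toy_schedule)
        after = net.state_dict()
        assert max(np.abs(after[k] - before[k]).max() for k in before) == 0

    def test_loss_decreases_on_smoke_run(self, toy_schedule):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=2))
        cfg = dif.TrainConfig(learning_rate=1e-3, batch_size=4,
                              max_epochs=10, patience=50, seed=0,
                              augment=())
        net, hist = dif.train(net, _tiny_dataset(12), cfg, toy_schedule)
        assert hist["train"][-1] < hist["train"][0]

    def test_empty_dataset_rejected(self, toy_schedule):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=2))
        with pytest.raises(ValueError):
            dif.train(net, [], dif.TrainConfig(), toy_schedule)

    def test_paper_defaults(self):
        cfg = dif.TrainConfig()
        assert cfg.learning_rate == 5e-5
        assert cfg.batch_size == 64
        assert cfg.finetune_lr == 1e-5
        assert cfg.finetune_epochs == 200
        assert cfg.patience == 20

    def test_finetune_freezes_encoder(self, toy_schedule):
        net = dif.make_network(dif.NetConfig(base_width=4, seed=3))
        groups_before = {
            g: {k: p.data.copy() for k, p in d.items()}
            for g, d in net.parameter_groups().items()}
        cfg = dif.TrainConfig(finetune_lr=1e-3, finetune_epochs=3,
                              batch_size=4, seed=0, augment=())
        net, _ = dif.finetune(net, _tiny_dataset(8), cfg, toy_schedule)
        groups_after = net.parameter_groups()
        for k, v in groups_before["encoder"].items():
            assert np.abs(groups_after["encoder"][k].data - v).max() == 0
        changed = any(
            np.abs(groups_after[g][k].data - v).max() > 0
            for g in ("decoder", "bottleneck", "heads")
            for k, v in groups_before[g].items())
        assert changed


def test_checkpoint_round_trip(tmp_path, toy_schedule):
    net = dif.make_network(dif.NetConfig(base_width=4, seed=4))
    path = tmp_path / "ckpt.npz"
    dif.save_checkpoint(path, net, toy_schedule, extra={"task": "denoise"})
    net2, sch2, extra = dif.load_checkpoint(path)
    assert extra["task"] == "denoise"
    assert sch2.T == toy_schedule.T
    np.testing.assert_allclose(sch2.alpha_bar, toy_schedule.alpha_bar)
    s1, s2 = net.state_dict(), net2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)
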
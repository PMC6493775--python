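"""Critic, WGAN-GP losses, gating, and the training loop."""

import numpy as np
import pytest

import circuitfit.autodiff as ad
from circuitfit.adversarial import (
    Discriminator,
    DiscriminatorSpec,
    TrainConfig,
    TrainRecord,
    discriminator_forward,
    gradient_penalty,
    loss_discriminator,
    loss_generator,
    normality_gate,
    rate_penalty,
    train,
)
from circuitfit.data_io import TuningCurveSet


class ToyLocationGenerator:
    """G_theta(z) = theta + z with z ~ N(0, 1): Wasserstein minimum at the
    matched mean, the oracle for recovery tests."""

    conditional = False
    param_names = ("loc",)
    n_conditions = 1

    def __init__(self, theta0, penalty=0.0):
        self.theta = ad.parameter(np.array([float(theta0)]))
        self._penalty = penalty

    def clip_(self):
        pass

    def condition_values(self):
        return np.zeros(1)

    def generate(self, m, rng, conditions=None, with_grad=True):
        z = rng.standard_normal((m, 1))
        th = self.theta if with_grad else self.theta.detach()
        return ad.reshape(th, (1, 1)) + ad.constant(z), ad.constant(self._penalty)

    def curves_all_probes(self, m, rng, with_grad=True):
        out, pen = self.generate(m, rng, with_grad=with_grad)
        return ad.reshape(out, (m, 1, 1)), pen


def _linear_disc(weights_row):
    """A critic computing w . x exactly (no hidden layers)."""
    spec = DiscriminatorSpec(input_dim=len(weights_row), hidden_layers=0)
    disc = Discriminator(spec, np.random.default_rng(0))
    disc.weights[-1].data[:] = np.asarray(weights_row, dtype=float)[:, None]
    disc.biases[-1].data[:] = 0.0
    return disc


class TestDiscriminatorForward:
    def test_zero_weights_give_zero(self):
        spec = DiscriminatorSpec(input_dim=3, hidden_layers=2, hidden_units=8)
        disc = Discriminator(spec, np.random.default_rng(0))
        for p in disc.parameters:
            p.data[:] = 0.0
        x = np.random.default_rng(1).standard_normal((4, 3))
        assert np.allclose(discriminator_forward(disc, x), 0.0)

    def test_condition_changes_output(self):
        spec = DiscriminatorSpec(input_dim=3, condition_dim=1,
                                 hidden_layers=2, hidden_units=16)
        disc = Discriminator(spec, np.random.default_rng(0))
        x = np.ones((2, 3))
        out = discriminator_forward(disc, x, np.array([0.0, 0.7]))
        assert out[0] != pytest.approx(out[1])

    def test_hand_computed_tiny_network(self):
        # 2-4-1 ReLU network with printed weights, checked by hand arithmetic
        spec = DiscriminatorSpec(input_dim=2, hidden_layers=1, hidden_units=4)
        disc = Discriminator(spec, np.random.default_rng(0))
        W1 = np.array([[1.0, -1.0, 0.5, 0.0],
                       [0.0, 2.0, -0.5, 1.0]])
        b1 = np.array([0.0, 1.0, -0.25, 0.5])
        W2 = np.array([[1.0], [-2.0], [3.0], [0.5]])
        b2 = np.array([0.25])
        disc.weights[0].data[:] = W1
        disc.biases[0].data[:] = b1
        disc.weights[1].data[:] = W2
        disc.biases[1].data[:] = b2
        x = np.array([[1.0, 2.0]])
        h = np.maximum(x @ W1 + b1, 0.0)       # = [1, 4, 0, 2.5]
        expect = (h @ W2 + b2).item()          # = 1 - 8 + 0 + 1.25 + 0.25
        assert expect == pytest.approx(-5.5)
        assert discriminator_forward(disc, x)[0] == pytest.approx(expect)

    def test_shape_mismatch_rejected(self):
        spec = DiscriminatorSpec(input_dim=3)
        disc = Discriminator(spec, np.random.default_rng(0))
        with pytest.raises(ValueError):
            disc.forward(np.ones((2, 5)))

    def test_missing_condition_rejected(self):
        spec = DiscriminatorSpec(input_dim=3, condition_dim=1)
        disc = Discriminator(spec, np.random.default_rng(0))
        with pytest.raises(ValueError):
            disc.forward(np.ones((2, 3)))


class TestGradientPenalty:
    def test_unit_gradient_zero_penalty(self):
        disc = _linear_disc([1.0, 0.0])
        x_hat = np.random.default_rng(0).standard_normal((6, 2))
        assert gradient_penalty(disc, x_hat, gp_lambda=10.0).item() == \
            pytest.approx(0.0, abs=1e-5)

    def test_double_gradient_penalty_is_lambda(self):
        disc = _linear_disc([2.0, 0.0])
        x_hat = np.random.default_rng(0).standard_normal((6, 2))
        assert gradient_penalty(disc, x_hat, gp_lambda=7.0).item() == \
            pytest.approx(7.0, rel=1e-6)

    def test_gradient_norm_matches_finite_differences(self):
        spec = DiscriminatorSpec(input_dim=3, hidden_layers=2, hidden_units=8)
        disc = Discriminator(spec, np.random.default_rng(5))
        x = np.random.default_rng(6).standard_normal(3)

        xt = ad.parameter(x[None, :])
        gx = ad.grad(ad.tsum(disc.forward(xt)), xt, create_graph=True).data[0]
        for i in range(3):
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (discriminator_forward(disc, xp[None])[0]
                  - discriminator_forward(disc, xm[None])[0]) / (2 * h)
            assert gx[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestLosses:
    def test_identical_batches_leave_only_penalty(self):
        spec = DiscriminatorSpec(input_dim=2, hidden_layers=1, hidden_units=8)
        disc = Discriminator(spec, np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((5, 2))
        eps = np.full(5, 0.5)
        loss = loss_discriminator(disc, x, x, eps=eps, gp_lambda=10.0)
        gp = gradient_penalty(disc, x, gp_lambda=10.0)  # x_hat == x here
        assert loss.item() == pytest.approx(gp.item(), rel=1e-9)

    def test_zero_discriminator_loss_is_lambda(self):
        spec = DiscriminatorSpec(input_dim=2, hidden_layers=1, hidden_units=4)
        disc = Discriminator(spec, np.random.default_rng(0))
        for p in disc.parameters:
            p.data[:] = 0.0
        x = np.random.default_rng(1).standard_normal((4, 2))
        y = np.random.default_rng(2).standard_normal((4, 2))
        loss = loss_discriminator(disc, x, y, eps=np.full(4, 0.3), gp_lambda=10.0)
        assert loss.item() == pytest.approx(10.0, rel=1e-5)

    def test_two_sample_fixture_hand_computed(self):
        disc = _linear_disc([1.0, -1.0])
        real = np.array([[1.0, 0.0], [0.0, 1.0]])    # D = [1, -1]
        fake = np.array([[2.0, 0.0], [0.0, 0.0]])    # D = [2, 0]
        eps = np.array([0.5, 0.5])
        # main term: mean([2,0]) - mean([1,-1]) = 1; ||grad D|| = sqrt(2)
        lam = 10.0
        expect = 1.0 + lam * (np.sqrt(2.0) - 1.0) ** 2
        loss = loss_discriminator(disc, real, fake, eps=eps, gp_lambda=lam)
        assert loss.item() == pytest.approx(expect, rel=1e-6)

    def test_generator_loss_zero_critic(self):
        spec = DiscriminatorSpec(input_dim=2, hidden_layers=1, hidden_units=4)
        disc = Discriminator(spec, np.random.default_rng(0))
        for p in disc.parameters:
            p.data[:] = 0.0
        fake = ad.constant(np.ones((3, 2)))
        assert loss_generator(disc, fake, penalty_G=0.0).item() == 0.0

    def test_generator_loss_fixture(self):
        disc = _linear_disc([1.0, 2.0])
        fake = ad.constant(np.array([[1.0, 1.0], [3.0, 0.0]]))  # D = [3, 3]
        loss = loss_generator(disc, fake, penalty_G=0.5)
        assert loss.item() == pytest.approx(-3.0 + 0.5)


class TestRatePenalty:
    def test_all_below_cap(self):
        assert rate_penalty(np.full((2, 5, 4), 100.0)) == 0.0

    def test_single_neuron_just_over(self):
        N, T = 10, 6
        traj = np.zeros((1, T, N))
        traj[0, :, 3] = 201.0
        assert rate_penalty(traj, eta=100.0) == pytest.approx(100.0 / N)

    def test_matches_direct_sum(self, rng):
        traj = rng.uniform(0, 300, size=(3, 7, 5))
        expect = 100.0 / (5 * 7 * 3) * np.maximum(traj - 200.0, 0).sum()
        assert rate_penalty(traj) == pytest.approx(expect)

    def test_generator_penalty_matches_oracle(self, ssn_truth, probes):
        # the SSN generator's internal penalty equals the direct-sum oracle
        from circuitfit.model_ssn import RATE_CAP, SSNFixedConfig, SSNGenerator, integrate_ssn, sample_ssn_realization

        cfg = SSNFixedConfig.reduced()  # N=50: truth ensemble exceeds the cap
        gen = SSNGenerator(ssn_truth, cfg, probes)
        rng = np.random.default_rng(0)
        z = rng.uniform(size=(2, cfg.N, cfg.N))
        zF = rng.uniform(-1, 1, size=(2, cfg.N))
        _, pen = gen._simulate_numpy(z, zF)
        # oracle: integrate each realization/stimulus separately
        total = 0.0
        theta = ad.constant(gen.theta.data)
        from circuitfit.model_ssn import _weights_graph, stimulus_input

        W = _weights_graph(theta, ad.constant(z), gen._d2, gen._masks,
                           gen._signs).data
        for j in range(2):
            real = sample_ssn_realization(ssn_truth, cfg, 0)
            real.W = W[j]
            real.F_diag = 1.0 + zF[j] * gen.theta.data[12]
            for b in cfg.sizes:
                drive = stimulus_input(b, cfg.positions(), cfg)
                traj = integrate_ssn(real, drive, cfg)
                window = traj[cfg.t1_steps + 1:cfg.t2_steps + 1]
                total += np.maximum(window - RATE_CAP, 0).sum()
        expect = 100.0 / (cfg.N * cfg.T * 2) * total
        assert pen == pytest.approx(expect, rel=1e-9)


class TestGate:
    def test_zero_passes(self):
        assert normality_gate(0.0) is True

    def test_large_fails(self):
        assert normality_gate(1.5) is False

    def test_exactly_one_fails(self):
        assert normality_gate(1.0) is False


class TestTrain:
    def _data(self, mean=3.0, sd=0.5, n=256, seed=42):
        rng = np.random.default_rng(seed)
        return TuningCurveSet(rng.standard_normal((n, 1)) * sd + mean, [0])

    def test_toy_location_recovery(self):
        data = self._data()
        gen = ToyLocationGenerator(2.0)
        spec = DiscriminatorSpec(input_dim=1, hidden_layers=2, hidden_units=32)
        cfg = TrainConfig(n_D=5, batch_size=64, alpha_D=2e-2, alpha_G=1e-3,
                          max_updates=1500, seed=1)
        rec = train(gen, data, spec, cfg)
        theta_hat = rec.theta[-200:, 0].mean()
        assert theta_hat == pytest.approx(3.0, abs=0.1)

    def test_five_discriminator_attempts_per_update(self):
        data = self._data(n=64)
        gen = ToyLocationGenerator(1.0)
        spec = DiscriminatorSpec(input_dim=1, hidden_layers=1, hidden_units=8)
        cfg = TrainConfig(n_D=5, batch_size=16, max_updates=3, seed=0)
        rec = train(gen, data, spec, cfg)
        assert np.all(rec.gate_passes[1:] == 5)

    def test_deterministic_given_seed(self):
        data = self._data(n=64)
        spec = DiscriminatorSpec(input_dim=1, hidden_layers=1, hidden_units=8)
        recs = []
        for _ in range(2):
            gen = ToyLocationGenerator(1.0)
            cfg = TrainConfig(n_D=2, batch_size=16, max_updates=5, seed=9)
            recs.append(train(gen, data, spec, cfg))
        assert np.array_equal(recs[0].theta, recs[1].theta)
        assert np.array_equal(recs[0].loss_D, recs[1].loss_D, equal_nan=True)

    def test_linear_discriminator_matches_mean_only(self):
        # degenerate critic class: adversarial fit reduces to mean matching
        # a small gp_lambda keeps the linear critic able to change sign (the
        # penalty otherwise creates a barrier at slope zero)
        rng = np.random.default_rng(7)
        data = TuningCurveSet(rng.uniform(0.5, 3.5, size=(256, 1)), [0])
        gen = ToyLocationGenerator(1.0)
        spec = DiscriminatorSpec(input_dim=1, hidden_layers=0)
        cfg = TrainConfig(n_D=5, batch_size=64, alpha_D=2e-2, alpha_G=2e-3,
                          gp_lambda=0.05, max_updates=1000, seed=1)
        rec = train(gen, data, spec, cfg)
        theta_hat = rec.theta[-200:, 0].mean()
        assert theta_hat == pytest.approx(data.responses.mean(), abs=0.15)

    def test_gate_blocks_discriminator_updates(self):
        data = self._data(n=64)
        gen = ToyLocationGenerator(1.0, penalty=5.0)  # always abnormal
        spec = DiscriminatorSpec(input_dim=1, hidden_layers=1, hidden_units=8)
        cfg = TrainConfig(n_D=5, batch_size=16, max_updates=3, seed=0)
        rec = train(gen, data, spec, cfg)
        assert np.all(rec.gate_passes[1:] == 0)
        assert np.all(np.isnan(rec.loss_D[1:]))

    def test_gradient_isolation(self):
        # critic loss has no path to theta; generator step touches only theta
        data = self._data(n=32)
        gen = ToyLocationGenerator(1.0)
        spec = DiscriminatorSpec(input_dim=1, hidden_layers=1, hidden_units=8)
        disc = Discriminator(spec, np.random.default_rng(0))
        rng = np.random.default_rng(0)
        fake, _ = gen.generate(8, rng, with_grad=False)
        loss_d = loss_discriminator(disc, data.responses[:8], fake.data,
                                    eps=np.full(8, 0.5))
        g_theta = ad.grad(loss_d, gen.theta)
        assert np.all(g_theta.data == 0.0)
        w_before = disc.state()
        fake, pen = gen.generate(8, rng, with_grad=True)
        lg = loss_generator(disc, fake, penalty_G=pen)
        ad.grad(lg, gen.theta)
        for before, p in zip(w_before, disc.parameters):
            assert np.array_equal(before, p.data)


class TestTrainRecord:
    def test_save_load_round_trip(self, tmp_path):
        rec = TrainRecord(param_names=("a", "b"))
        rec.append([1.0, 2.0])
        rec.append([1.5, 2.5], loss_D=-0.3, loss_G=0.7, penalty=0.0, gate_passes=5)
        rec.finalize()
        path = tmp_path / "rec.csv"
        rec.save(path)
        back = TrainRecord.load(path)
        assert np.allclose(back.theta, rec.theta)
        assert back.param_names == ("a", "b")
        assert back.gate_passes[1] == 5
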
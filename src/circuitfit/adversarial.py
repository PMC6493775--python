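"""WGAN-GP / conditional WGAN training of tuning-curve generators.

The critic is a dense ReLU network scoring a tuning curve (optionally
concatenated with a scalar condition).  Training alternates ``n_D`` gated
critic updates with one generator update; the critic enforces the Lipschitz
constraint through a gradient penalty on random interpolates between real
and generated curves.  For the SSN generator a rate penalty keeps the
network out of runaway-rate regions, and critic updates are skipped while
that penalty exceeds 1 so that pathological generator output cannot corrupt
the critic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .optim import make_optimizer

__all__ = [
    "DiscriminatorSpec",
    "Discriminator",
    "TrainConfig",
    "TrainRecord",
    "discriminator_forward",
    "gradient_penalty",
    "loss_discriminator",
    "loss_generator",
    "rate_penalty",
    "normality_gate",
    "train",
]


@dataclass
class DiscriminatorSpec:
    input_dim: int                 # tuning-curve length S
    condition_dim: int = 0         # 1 for the conditional WGAN, else 0
    hidden_layers: int = 4
    hidden_units: int = 128
    layer_norm: bool = False
    weight_decay: float = 0.0      # gamma, applied as a post-step subtraction

    @classmethod
    def m1_profile(cls, input_dim: int = 27) -> "DiscriminatorSpec":
        return cls(input_dim=input_dim, hidden_layers=4, hidden_units=128,
                   layer_norm=False, weight_decay=0.0)

    @classmethod
    def ssn_profile(cls, input_dim: int, condition_dim: int = 1,
                    hidden_units: int = 128) -> "DiscriminatorSpec":
        return cls(input_dim=input_dim, condition_dim=condition_dim,
                   hidden_layers=4, hidden_units=hidden_units,
                   layer_norm=True, weight_decay=0.001)


class Discriminator:
    """Dense feedforward critic ``D_w(x; c) -> R``.

    Weight init: biases zero; first (input) layer Glorot-uniform, deeper
    layers standard normal.  Layer normalization, when enabled, is applied
    to the deeper hidden layers but never to the first layer, so the raw
    scale of the tuning curve stays visible to the critic.
    """

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        dims = [spec.input_dim + spec.condition_dim] + \
            [spec.hidden_units] * spec.hidden_layers + [1]
        self.weights, self.biases = [], []
        for li, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            if li == 0:
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            else:
                w = rng.standard_normal((fan_in, fan_out))
            self.weights.append(ad.parameter(w))
            self.biases.append(ad.parameter(np.zeros(fan_out)))
        self.ln_gain, self.ln_bias = [], []
        if spec.layer_norm:
            for _ in range(max(spec.hidden_layers - 1, 0)):
                self.ln_gain.append(ad.parameter(np.ones(spec.hidden_units)))
                self.ln_bias.append(ad.parameter(np.zeros(spec.hidden_units)))

    @property
    def parameters(self):
        return self.weights + self.biases + self.ln_gain + self.ln_bias

    def state(self):
        return [p.data.copy() for p in self.parameters]

    def forward(self, x, c=None) -> Tensor:
        """Critic values, shape (m, 1); ``x`` is (m, S), ``c`` is (m,) or (m, k)."""
        x = ad.as_tensor(x)
        if self.spec.condition_dim:
            if c is None:
                raise ValueError("this critic requires a condition input")
            c = ad.as_tensor(c)
            if c.ndim == 1:
                c = ad.reshape(c, (c.shape[0], 1))
            h = ad.concatenate([x, c], axis=1)
        else:
            h = x
        if h.shape[1] != self.spec.input_dim + self.spec.condition_dim:
            raise ValueError(
                f"critic expects {self.spec.input_dim + self.spec.condition_dim} inputs, "
                f"got {h.shape[1]}")
        for li in range(self.spec.hidden_layers):
            pre = ad.matmul(h, self.weights[li]) + self.biases[li]
            if self.spec.layer_norm and li > 0:
                mu = ad.tmean(pre, axis=1, keepdims=True)
                var = ad.tmean((pre - mu) * (pre - mu), axis=1, keepdims=True)
                pre = self.ln_gain[li - 1] * ((pre - mu) / ad.sqrt(var + 1e-5)) \
                    + self.ln_bias[li - 1]
            h = ad.relu(pre)
        return ad.matmul(h, self.weights[-1]) + self.biases[-1]

    __call__ = forward


def discriminator_forward(disc: Discriminator, x, c=None) -> np.ndarray:
    """Plain-array critic values (m,)."""
    return disc.forward(x, c).data[:, 0]


def gradient_penalty(disc: Discriminator, x_hat: np.ndarray, c=None,
                     gp_lambda: float = 10.0) -> Tensor:
    """lambda * E[(||grad_x D(x_hat; c)||_2 - 1)^2], differentiable in w."""
    x_hat_t = ad.parameter(np.asarray(x_hat, dtype=float))
    out = disc.forward(x_hat_t, c)
    # rows are independent, so the gradient of the sum recovers each row's gradient
    gx = ad.grad(ad.tsum(out), x_hat_t, create_graph=True)
    norms = ad.sqrt(ad.tsum(gx * gx, axis=1) + 1e-12)
    return gp_lambda * ad.tmean((norms - 1.0) * (norms - 1.0))


def loss_discriminator(disc: Discriminator, real_x, fake_x, c=None,
                       eps=None, gp_lambda: float = 10.0,
                       rng: np.random.Generator = None) -> Tensor:
    """E[D(fake)] - E[D(real)] + gradient penalty (fresh eps per sample)."""
    real_x = np.asarray(real_x, dtype=float)
    fake_x = np.asarray(fake_x, dtype=float)
    if eps is None:
        rng = rng or np.random.default_rng()
        eps = rng.uniform(size=(real_x.shape[0], 1))
    else:
        eps = np.asarray(eps, dtype=float).reshape(-1, 1)
    x_hat = eps * real_x + (1.0 - eps) * fake_x
    main = ad.tmean(disc.forward(fake_x, c)) - ad.tmean(disc.forward(real_x, c))
    return main + gradient_penalty(disc, x_hat, c, gp_lambda)


def loss_generator(disc: Discriminator, fake_x, c=None, penalty_G=0.0) -> Tensor:
    """-E[D(G(z; c); c)] + Penalty_G; gradients reach theta through fake_x."""
    return -ad.tmean(disc.forward(fake_x, c)) + ad.as_tensor(penalty_G)


def rate_penalty(trajectories, eta: float = 100.0, cap: float = 200.0) -> float:
    """eta / (N T m) * sum of rate excesses over a (m, T, N) window."""
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3:
        raise ValueError("expected a (batch, steps, neurons) array")
    m, T, N = traj.shape
    return float(eta / (N * T * m) * np.sum(np.maximum(traj - cap, 0.0)))


def normality_gate(penalty_value: float) -> bool:
    """Critic updates proceed only while the generator penalty is < 1."""
    return float(penalty_value) < 1.0


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    n_D: int = 5
    batch_size: int = 30
    alpha_D: float = 1e-3
    alpha_G: float = 1e-3
    optimizer_D: str = "adam"
    optimizer_G: str = "adam"
    gp_lambda: float = 10.0
    max_updates: int = 200
    seed: int = 0
    stopping: object = None      # optional evaluation.StoppingConfig
    log_every: int = 0           # 0 silences progress output

    @classmethod
    def m1_profile(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(n_D=5, batch_size=30, alpha_D=1e-3, alpha_G=1e-3,
                             optimizer_D="adam", optimizer_G="adam"), **kw})

    @classmethod
    def ssn_profile(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(n_D=5, batch_size=128, alpha_D=0.02, alpha_G=1e-4,
                             optimizer_D="adam", optimizer_G="rmsprop"), **kw})


@dataclass
class TrainRecord:
    """Per-generator-update trace of a fitting run."""

    param_names: tuple
    theta: np.ndarray = None          # (n_updates + 1, P); row 0 = initial
    loss_D: np.ndarray = None         # mean critic loss over attempted updates
    loss_G: np.ndarray = None
    penalty: np.ndarray = None
    gate_passes: np.ndarray = None    # critic updates that ran, out of n_D
    stopped_at: int = None
    _rows: list = field(default_factory=list, repr=False)

    def append(self, theta, loss_D=np.nan, loss_G=np.nan, penalty=np.nan,
               gate_passes=-1):
        self._rows.append((np.array(theta, dtype=float), loss_D, loss_G,
                           penalty, gate_passes))

    def finalize(self) -> "TrainRecord":
        self.theta = np.stack([r[0] for r in self._rows])
        self.loss_D = np.array([r[1] for r in self._rows])
        self.loss_G = np.array([r[2] for r in self._rows])
        self.penalty = np.array([r[3] for r in self._rows])
        self.gate_passes = np.array([r[4] for r in self._rows])
        return self

    @property
    def n_updates(self) -> int:
        return self.theta.shape[0] - 1

    def save(self, path):
        header = ",".join(
            ["step"] + list(self.param_names) +
            ["loss_D", "loss_G", "penalty", "gate_passes"])
        body = np.column_stack([
            np.arange(self.theta.shape[0]), self.theta, self.loss_D,
            self.loss_G, self.penalty, self.gate_passes])
        np.savetxt(path, body, delimiter=",", header=header, comments="",
                   fmt="%.9g")

    @classmethod
    def load(cls, path):
        with open(path) as f:
            names = f.readline().strip().split(",")
        body = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        P = len(names) - 5
        rec = cls(param_names=tuple(names[1:1 + P]))
        rec.theta = body[:, 1:1 + P]
        rec.loss_D = body[:, 1 + P]
        rec.loss_G = body[:, 2 + P]
        rec.penalty = body[:, 3 + P]
        rec.gate_passes = body[:, 4 + P].astype(int)
        return rec


def _condition_setup(generator, data):
    """Map data rows to generator probe indices (conditional models only)."""
    if not getattr(generator, "conditional", False):
        return None, None
    values = data.require_conditions()
    probe_vals = generator.condition_values()
    idx = np.argmin(np.abs(values[:, None] - probe_vals[None, :]), axis=1)
    if not np.allclose(probe_vals[idx], values, atol=1e-9):
        raise ValueError("data conditions do not match the generator's probe offsets")
    return values, idx


def train(generator, data, disc_spec: DiscriminatorSpec, cfg: TrainConfig) -> TrainRecord:
    """Alternate n_D gated critic updates with one generator update."""
    from .data_io import named_streams

    streams = named_streams(cfg.seed, ["winit", "data", "z", "eps"])
    disc = Discriminator(disc_spec, streams["winit"])
    opt_D = make_optimizer(cfg.optimizer_D, disc.parameters, cfg.alpha_D)
    opt_G = make_optimizer(cfg.optimizer_G, [generator.theta], cfg.alpha_G)

    cond_values, cond_idx = _condition_setup(generator, data)
    responses = data.responses
    R = responses.shape[0]
    m = cfg.batch_size
    gamma = disc_spec.weight_decay

    record = TrainRecord(param_names=tuple(generator.param_names))
    record.append(generator.theta.data)

    for update in range(cfg.max_updates):
        # -- critic updates (n_D attempts, gated) --------------------------
        d_losses, passes = [], 0
        for _ in range(cfg.n_D):
            rows = streams["data"].integers(0, R, size=m)
            real_x = responses[rows]
            c = cond_values[rows] if cond_values is not None else None
            fake_cond = cond_idx[rows] if cond_idx is not None else None
            fake_x, pen = generator.generate(m, streams["z"], conditions=fake_cond,
                                             with_grad=False)
            eps = streams["eps"].uniform(size=m)
            if normality_gate(pen.item()):
                loss = loss_discriminator(disc, real_x, fake_x.data, c, eps,
                                          cfg.gp_lambda)
                grads = ad.grad(loss, disc.parameters)
                pre_step = [p.data.copy() for p in disc.parameters] if gamma else None
                opt_D.step(grads)
                if gamma:
                    for p, old in zip(disc.parameters, pre_step):
                        p.data -= gamma * old
                d_losses.append(loss.item())
                passes += 1

        # -- generator update ----------------------------------------------
        rows = streams["data"].integers(0, R, size=m)
        c = cond_values[rows] if cond_values is not None else None
        gen_cond = cond_idx[rows] if cond_idx is not None else None
        fake_x, pen = generator.generate(m, streams["z"], conditions=gen_cond,
                                         with_grad=True)
        loss_G = loss_generator(disc, fake_x, c, pen)
        g_theta = ad.grad(loss_G, generator.theta)
        opt_G.step([g_theta])
        generator.clip_()

        record.append(generator.theta.data,
                      loss_D=float(np.mean(d_losses)) if d_losses else np.nan,
                      loss_G=loss_G.item(), penalty=pen.item(),
                      gate_passes=passes)
        if cfg.log_every and (update + 1) % cfg.log_every == 0:
            print(f"  update {update + 1}: loss_G={loss_G.item():+.4f} "
                  f"penalty={pen.item():.3g}")

        if cfg.stopping is not None:
            from .evaluation import check_stop

            theta_trace = np.stack([r[0] for r in record._rows])
            n0 = check_stop(theta_trace, cfg.stopping)
            if n0 is not None:
                record.stopped_at = n0
                break

    return record.finalize()
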
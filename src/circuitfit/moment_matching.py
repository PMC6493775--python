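"""Moment-matching baseline: fit per-condition means and variances.

The loss compares minibatch moments of generated curves against empirical
moments of the full training set, one term per (stimulus condition, probe)
combination, under one of three weighting schemes.  The variance ``s_d`` is
the biased (1/m) minibatch variance; the empirical targets use the same
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .adversarial import TrainRecord
from .optim import make_optimizer

__all__ = ["MomentTargets", "MMWeights", "mm_loss", "train_mm", "MMConfig"]

SCHEMES = ("uniform", "element-wise", "relative")


@dataclass
class MomentTargets:
    mu: np.ndarray       # (D,) empirical per-condition means
    sigma2: np.ndarray   # (D,) empirical per-condition (biased) variances

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have matching shapes")

    @property
    def D(self) -> int:
        return self.mu.size

    @classmethod
    def from_dataset(cls, data, probe_values=None) -> "MomentTargets":
        """Empirical moments, ordered probe-major then stimulus condition.

        For conditional datasets ``probe_values`` fixes the probe ordering
        (defaults to sorted unique neuron conditions).
        """
        if data.neuron_conditions is None:
            mu = data.responses.mean(axis=0)
            s2 = data.responses.var(axis=0)
            return cls(mu, s2)
        if probe_values is None:
            probe_values = np.unique(data.neuron_conditions)
        mus, s2s = [], []
        for v in np.asarray(probe_values, dtype=float):
            rows = data.responses[np.isclose(data.neuron_conditions, v, atol=1e-9)]
            if rows.size == 0:
                raise ValueError(f"no data rows with condition value {v}")
            mus.append(rows.mean(axis=0))
            s2s.append(rows.var(axis=0))
        return cls(np.concatenate(mus), np.concatenate(s2s))


@dataclass
class MMWeights:
    scheme: str = "element-wise"
    ell: object = 1.0          # variance weight; scalar or per-term vector
    eps: float = 1e-3

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")

    def compute(self, targets: MomentTargets):
        """(w1, w2) arrays of length D."""
        mu, s2, eps = targets.mu, targets.sigma2, self.eps
        ell = np.asarray(self.ell, dtype=float)
        if self.scheme == "uniform":
            w1 = np.full(targets.D, mu.mean() ** -2.0)
            w2 = ell * w1**2
        elif self.scheme == "element-wise":
            w1 = (mu + eps) ** -2.0
            w2 = ell * w1**2
        else:  # relative
            w1 = (mu + eps) ** -2.0
            w2 = ell * (s2 + eps) ** -2.0
        return w1, np.broadcast_to(w2, (targets.D,))


def mm_loss(generated, targets: MomentTargets, weights: MMWeights) -> Tensor:
    """Weighted squared moment mismatch, averaged over the D combinations.

    ``generated`` is an (m, n_probes, S) tensor (or array) of minibatch
    curves; moments are taken across the minibatch axis.
    """
    g = ad.as_tensor(generated)
    if g.ndim == 2:
        g = ad.reshape(g, (g.shape[0], 1, g.shape[1]))
    m, O, S = g.shape
    if O * S != targets.D:
        raise ValueError(f"generated moments ({O * S}) do not match targets ({targets.D})")
    flat = ad.reshape(g, (m, O * S))
    md = ad.tmean(flat, axis=0)
    centered = flat - ad.reshape(md, (1, targets.D))
    sd = ad.tmean(centered * centered, axis=0)   # biased variance
    w1, w2 = weights.compute(targets)
    dm = md - Tensor(targets.mu)
    dv = sd - Tensor(targets.sigma2)
    terms = Tensor(w1) * dm * dm + Tensor(w2) * dv * dv
    return ad.tsum(terms) * (1.0 / targets.D)


@dataclass
class MMConfig:
    batch_size: int = 32
    lr: float = 0.001
    optimizer: str = "adam"
    max_updates: int = 500
    seed: int = 0
    stopping: object = None
    log_every: int = 0


def train_mm(generator, data, weights: MMWeights, cfg: MMConfig) -> TrainRecord:
    """Gradient descent on the moment loss plus the generator penalty."""
    from .data_io import named_streams
    from .evaluation import check_stop

    streams = named_streams(cfg.seed, ["z"])
    probe_values = generator.condition_values() if getattr(generator, "conditional", False) else None
    targets = MomentTargets.from_dataset(data, probe_values)
    opt = make_optimizer(cfg.optimizer, [generator.theta], cfg.lr)

    record = TrainRecord(param_names=tuple(generator.param_names))
    record.append(generator.theta.data)
    for update in range(cfg.max_updates):
        curves, pen = generator.curves_all_probes(cfg.batch_size, streams["z"],
                                                  with_grad=True)
        loss = mm_loss(curves, targets, weights) + pen
        g = ad.grad(loss, generator.theta)
        opt.step([g])
        generator.clip_()
        record.append(generator.theta.data, loss_G=loss.item(),
                      penalty=pen.item())
        if cfg.log_every and (update + 1) % cfg.log_every == 0:
            print(f"  mm update {update + 1}: loss={loss.item():.5g}")
        if cfg.stopping is not None:
            theta_trace = np.stack([r[0] for r in record._rows])
            n0 = check_stop(theta_trace, cfg.stopping)
            if n0 is not None:
                record.stopped_at = n0
                break
    return record.finalize()
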
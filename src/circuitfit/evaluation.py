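"""Run termination, parameter averaging, and sMAPE recovery scoring.

Training stops at the first generator update where a moving average of the
parameter speed-of-change drops below a tolerance; the estimate is the mean
of the trailing parameter window, scored against ground truth by the
symmetric mean absolute percentage error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StoppingConfig",
    "RecoveryReport",
    "check_stop",
    "average_params",
    "smape",
    "recovery_experiment",
]


@dataclass
class StoppingConfig:
    tol: float = 0.01
    kappa: int = 100
    nu: int = 100
    omega: int = 100

    def __post_init__(self):
        for name in ("kappa", "nu", "omega"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_learning_rate(cls, alpha_G: float, tol: float = 0.01) -> "StoppingConfig":
        """kappa = nu = omega = 1/alpha_G, rounded, at least 1."""
        w = max(1, round(1.0 / alpha_G))
        return cls(tol=tol, kappa=w, nu=w, omega=w)


def check_stop(theta_trace, cfg: StoppingConfig):
    """First update index where the windowed parameter speed drops below tol.

    ``theta_trace`` has one row per generator update, row 0 being the initial
    parameters.  Returns None while the trace is too short or the criterion
    has not yet been met.
    """
    theta = np.asarray(theta_trace, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None]
    n_max = theta.shape[0] - 1
    first = cfg.kappa + cfg.nu - 1
    if n_max < first:
        return None
    # speed(n) = (theta(n) - theta(n - kappa)) / kappa for n >= kappa
    speeds = (theta[cfg.kappa:] - theta[:-cfg.kappa]) / cfg.kappa
    csum = np.cumsum(speeds, axis=0)
    win = csum[cfg.nu - 1:].copy()
    win[1:] -= csum[:-(cfg.nu)]
    norms = np.abs(win / cfg.nu).sum(axis=1)
    hits = np.nonzero(norms < cfg.tol)[0]
    if hits.size == 0:
        return None
    return int(hits[0] + first)


def average_params(theta_trace, n0: int, omega: int) -> np.ndarray:
    """Mean of theta over the omega updates ending at (and including) n0."""
    theta = np.asarray(theta_trace, dtype=float)
    if n0 - omega + 1 < 0 or n0 >= theta.shape[0]:
        raise ValueError("trace does not cover the averaging window")
    return theta[n0 - omega + 1:n0 + 1].mean(axis=0)


def smape(theta_hat, theta_truth) -> float:
    """100% * mean of |a_i - b_i| / (|a_i + b_i| / 2); NaN if any pair sums to 0."""
    a = np.asarray(theta_hat, dtype=float)
    b = np.asarray(theta_truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parameter vectors must have equal length")
    denom = np.abs(a + b) / 2.0
    if np.any(denom == 0.0):
        return float("nan")
    return float(100.0 * np.mean(np.abs(a - b) / denom))


@dataclass
class RecoveryReport:
    method: str
    hyperparams: dict
    seed: int
    theta_hat: np.ndarray
    theta_truth: np.ndarray
    smape: float
    per_param_error: np.ndarray
    stopped_at: int = None
    hit_cap: bool = False
    record: object = field(default=None, repr=False)


def _score_record(record, truth_vec, alpha_G, method, hyper, seed):
    stop_cfg = StoppingConfig.from_learning_rate(alpha_G)
    n0 = record.stopped_at
    if n0 is None:
        n0 = check_stop(record.theta, stop_cfg)
    hit_cap = n0 is None
    omega = min(stop_cfg.omega, record.theta.shape[0])
    if n0 is None:
        n0 = record.theta.shape[0] - 1  # capped run: score the final window
    omega = min(omega, n0 + 1)
    theta_hat = average_params(record.theta, n0, omega)
    denom = np.abs(theta_hat + truth_vec) / 2.0
    per_param = np.abs(theta_hat - truth_vec) / np.where(denom == 0, np.nan, denom)
    return RecoveryReport(
        method=method, hyperparams=hyper, seed=seed,
        theta_hat=theta_hat, theta_truth=truth_vec,
        smape=smape(theta_hat, truth_vec), per_param_error=per_param,
        stopped_at=None if hit_cap else n0, hit_cap=hit_cap, record=record,
    )


def recovery_experiment(truth, data, make_generator, grid, seed: int = 0,
                        max_updates: int = 500):
    """Fit one generator per hyperparameter cell and score parameter recovery.

    ``grid`` is a list of dicts, each with a ``method`` key ('cwgan' or 'mm')
    plus that method's hyperparameters; ``make_generator`` builds a fresh
    generator (closing over the initial theta, network profile and probes).
    Non-converged runs are reported with ``stopped_at`` None, never dropped.
    """
    from .adversarial import DiscriminatorSpec, TrainConfig, train
    from .moment_matching import MMConfig, MMWeights, train_mm

    truth_vec = np.asarray(truth, dtype=float)
    reports = []
    for cell, hyper in enumerate(grid):
        hyper = dict(hyper)
        method = hyper.pop("method")
        cell_seed = seed * 10007 + cell
        gen = make_generator()
        if method in ("cwgan", "wgan"):
            if method == "wgan":
                gen.conditional = False  # critic sees curves only
            alpha_G = hyper.get("alpha_G", 1e-4)
            spec = DiscriminatorSpec.ssn_profile(
                input_dim=gen.n_conditions,
                condition_dim=1 if method == "cwgan" else 0,
                hidden_units=hyper.get("hidden_units", 128))
            cfg = TrainConfig.ssn_profile(
                alpha_G=alpha_G,
                alpha_D=hyper.get("alpha_D", 0.02),
                batch_size=hyper.get("batch_size", 128),
                optimizer_D=hyper.get("optimizer_D", "adam"),
                max_updates=max_updates, seed=cell_seed,
                stopping=StoppingConfig.from_learning_rate(alpha_G))
            record = train(gen, data, spec, cfg)
        elif method == "mm":
            alpha_G = hyper.get("lr", 1e-3)
            weights = MMWeights(scheme=hyper.get("scheme", "element-wise"),
                                ell=hyper.get("ell", 1.0))
            cfg = MMConfig(lr=alpha_G, batch_size=hyper.get("batch_size", 32),
                           max_updates=max_updates, seed=cell_seed,
                           stopping=StoppingConfig.from_learning_rate(alpha_G))
            record = train_mm(gen, data, weights, cfg)
        else:
            raise ValueError(f"unknown method {method!r}")
        reports.append(_score_record(record, truth_vec, alpha_G, method,
                                     hyper, cell_seed))
    return reports


def paper_hyperparameter_grid():
    """The published hyperparameter sweep for the identification benchmark."""
    grid = []
    for alpha_G in (1e-4, 2e-4, 4e-4):
        for units in (32, 64, 128):
            for opt in ("adam", "rmsprop"):
                grid.append({"method": "cwgan", "alpha_G": alpha_G,
                             "hidden_units": units, "optimizer_D": opt})
    for lr in (1e-4, 2e-4, 4e-4, 1e-3, 2e-3, 4e-3):
        for ell in (0.01, 0.1, 1.0):
            for scheme in ("element-wise", "relative"):
                grid.append({"method": "mm", "lr": lr, "ell": ell,
                             "scheme": scheme})
    return grid
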
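"""Topographic E/I stabilized supralinear network as a tuning-curve generator.

One excitatory and one inhibitory neuron sit at each of ``M`` sites on a
regular 1-D grid spanning [-0.5, 0.5].  Recurrent weights are drawn uniformly
with cell-type- and distance-dependent mean and spread; the feedforward gain
of each neuron is jittered by ``V``.  Rates follow

    tau dr/dt = -r + f(W r + F I(s))

integrated by forward Euler, where ``f`` is a supralinear rectified power law
smoothly joined to a saturating branch above ``r0`` (so runaway excitation
cannot produce numerical overflow during fitting).  The generator output is
the window-averaged "sustained" response of designated excitatory probe
neurons across a set of stimulus diameters.

The 13 trainable parameters are the four lower bounds ``J<_ab``, four widths
``dJ_ab``, four length scales ``sigma_ab`` (a = postsynaptic, b = presynaptic
type) and the feedforward heterogeneity ``V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "SSNParams",
    "SSNFixedConfig",
    "SSNRealization",
    "ProbeSpec",
    "DivergenceError",
    "sample_ssn_realization",
    "ssn_nonlinearity",
    "stimulus_input",
    "integrate_ssn",
    "sustained_response",
    "ssn_generate",
    "SSNGenerator",
    "PARAM_NAMES",
    "ground_truth_params",
]

# theta layout: 4 lower bounds, 4 widths, 4 length scales (row-major over
# (post, pre) in {E,I} x {E,I}), then V
_PAIRS = ("EE", "EI", "IE", "II")
PARAM_NAMES = tuple(f"J_lower_{p}" for p in _PAIRS) + \
    tuple(f"delta_J_{p}" for p in _PAIRS) + \
    tuple(f"sigma_{p}" for p in _PAIRS) + ("V",)

CLIP_LO, CLIP_HI = 1e-3, 10.0
RATE_CAP = 200.0  # Hz; ceiling enforced by the generator penalty


class DivergenceError(FloatingPointError):
    """Non-finite rates encountered during integration."""

    def __init__(self, step):
        super().__init__(f"non-finite rates at Euler step {step}")
        self.step = step


@dataclass
class SSNParams:
    J_lower: np.ndarray   # (2, 2), rows = postsynaptic type, cols = presynaptic
    delta_J: np.ndarray   # (2, 2)
    sigma: np.ndarray     # (2, 2)
    V: float

    def __post_init__(self):
        self.J_lower = np.asarray(self.J_lower, dtype=float)
        self.delta_J = np.asarray(self.delta_J, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        for name in ("J_lower", "delta_J", "sigma"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} entries must be non-negative")
        if not 0.0 <= self.V <= 1.0:
            raise ValueError("V must lie in [0, 1]")

    @property
    def J_mean(self) -> np.ndarray:
        """Mean connection strengths, J< + dJ/2."""
        return self.J_lower + self.delta_J / 2.0

    def as_vector(self) -> np.ndarray:
        return np.concatenate([
            self.J_lower.ravel(), self.delta_J.ravel(), self.sigma.ravel(),
            [self.V],
        ])

    @classmethod
    def from_vector(cls, v) -> "SSNParams":
        v = np.asarray(v, dtype=float)
        return cls(v[0:4].reshape(2, 2), v[4:8].reshape(2, 2),
                   v[8:12].reshape(2, 2), float(v[12]))

    @classmethod
    def from_means(cls, J_mean, delta_J, sigma, V) -> "SSNParams":
        J_mean = np.asarray(J_mean, dtype=float)
        delta_J = np.asarray(delta_J, dtype=float)
        return cls(J_mean - delta_J / 2.0, delta_J, sigma, V)


def ground_truth_params() -> SSNParams:
    """The connectivity ensemble used to generate all synthetic training sets."""
    return SSNParams.from_means(
        J_mean=[[0.3, 0.5], [0.4, 0.2]],
        delta_J=[[0.3, 0.4], [0.6, 0.19]],
        sigma=[[0.15, 0.025], [0.1, 0.025]],
        V=0.1,
    )


@dataclass
class SSNFixedConfig:
    N: int = 402
    k: float = 0.01
    n: float = 2.2
    r0: float = 200.0
    r1: float = 1000.0
    tau_E: float = 20.0          # in units of dt
    tau_I: float = 10.0          # tau_I / tau_E = 1/2
    A: float = 20.0
    l: float = 2.0**-5
    dt: float = 1.0
    t1_steps: int = 200
    t2_steps: int = 240
    sizes: tuple = (0.0, 1 / 16, 1 / 8, 3 / 16, 1 / 4, 1 / 2, 3 / 4, 1.0)

    def __post_init__(self):
        if self.N % 2:
            raise ValueError("N must be even (one E and one I neuron per site)")
        if self.t2_steps <= self.t1_steps:
            raise ValueError("sustained window is empty")

    @property
    def M(self) -> int:
        return self.N // 2

    @property
    def u0(self) -> float:
        return (self.r0 / self.k) ** (1.0 / self.n)

    @property
    def T(self) -> int:
        return self.t2_steps - self.t1_steps

    @property
    def S(self) -> int:
        return len(self.sizes)

    def positions(self) -> np.ndarray:
        """Topographic location of each neuron; E block then I block."""
        x = np.linspace(-0.5, 0.5, self.M)
        return np.concatenate([x, x])

    def cell_types(self) -> np.ndarray:
        """0 for excitatory, 1 for inhibitory."""
        return np.concatenate([np.zeros(self.M, int), np.ones(self.M, int)])

    def tau(self) -> np.ndarray:
        return np.where(self.cell_types() == 0, self.tau_E, self.tau_I)

    @classmethod
    def reduced(cls, N=50, t1_steps=40, t2_steps=60,
                sizes=(0.0, 1 / 8, 1 / 4, 1 / 2, 1.0)) -> "SSNFixedConfig":
        """Small profile used by the unit tests and desk-scale fits."""
        return cls(N=N, t1_steps=t1_steps, t2_steps=t2_steps, sizes=tuple(sizes))


@dataclass
class SSNRealization:
    W: np.ndarray          # (N, N)
    F_diag: np.ndarray     # (N,)
    cell_types: np.ndarray  # (N,), 0=E, 1=I
    positions: np.ndarray  # (N,)


@dataclass
class ProbeSpec:
    offsets: tuple = (0.0,)

    def __post_init__(self):
        self.offsets = tuple(float(c) for c in self.offsets)
        if not self.offsets or self.offsets[0] != 0.0:
            raise ValueError("the first probe must sit at the stimulus center")

    @property
    def n_probes(self) -> int:
        return len(self.offsets)

    def indices(self, config: SSNFixedConfig) -> np.ndarray:
        """Excitatory neuron index nearest each requested offset."""
        x = np.linspace(-0.5, 0.5, config.M)
        return np.array([int(np.argmin(np.abs(x - c))) for c in self.offsets])


# ---------------------------------------------------------------------------
# structure sampling
# ---------------------------------------------------------------------------

def _structure_constants(config: SSNFixedConfig):
    x = config.positions()
    types = config.cell_types()
    d2 = (x[:, None] - x[None, :]) ** 2
    masks = []
    for a in (0, 1):          # postsynaptic type
        for b in (0, 1):      # presynaptic type
            masks.append(((types[:, None] == a) & (types[None, :] == b)).astype(float))
    signs = np.where(types == 0, 1.0, -1.0)[None, :]  # sign of the *pre*synaptic column
    return d2, masks, signs


def _weights_graph(theta: Tensor, z: Tensor, d2, masks, signs) -> Tensor:
    """W as a differentiable function of theta given quenched noise z."""
    w = None
    for k in range(4):
        prof = ad.exp(Tensor(-d2 / 2.0) / (theta[8 + k] * theta[8 + k]))
        term = (theta[k] + z * theta[4 + k]) * prof * Tensor(masks[k])
        w = term if w is None else w + term
    return w * Tensor(signs)


def sample_ssn_realization(params: SSNParams, config: SSNFixedConfig,
                           rng_seed) -> SSNRealization:
    """Draw one network realization (plain arrays, for inspection and tests)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    N = config.N
    z = rng.uniform(size=(N, N))
    zF = rng.uniform(-1.0, 1.0, size=N)
    d2, masks, signs = _structure_constants(config)
    theta = ad.constant(params.as_vector())
    W = _weights_graph(theta, ad.constant(z), d2, masks, signs)
    return SSNRealization(
        W=W.data,
        F_diag=1.0 + zF * params.V,
        cell_types=config.cell_types(),
        positions=config.positions(),
    )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _f_graph(u: Tensor, config: SSNFixedConfig) -> Tensor:
    k, n, r0, r1, u0 = config.k, config.n, config.r0, config.r1, config.u0
    lo = k * ad.power(ad.relu(u), n)
    if not np.any(u.data >= u0):
        # saturating branch inactive everywhere: identical value and gradient
        return lo
    hi = r0 + (r1 - r0) * ad.tanh((n * r0 / (r1 - r0)) * (u - u0) * (1.0 / u0))
    return ad.where(u.data < u0, lo, hi)


def _f_numpy(u: np.ndarray, config: SSNFixedConfig) -> np.ndarray:
    k, n, r0, r1, u0 = config.k, config.n, config.r0, config.r1, config.u0
    lo = k * np.maximum(u, 0.0) ** n
    hi = r0 + (r1 - r0) * np.tanh((n * r0 / (r1 - r0)) * (u - u0) / u0)
    return np.where(u < u0, lo, hi)


def ssn_nonlinearity(u, config: SSNFixedConfig = None):
    """Saturating power-law rate function; scalar or array in, same out."""
    config = config or SSNFixedConfig()
    out = _f_numpy(np.asarray(u, dtype=float), config)
    return float(out) if np.isscalar(u) or np.ndim(u) == 0 else out


def stimulus_input(b: float, positions, config: SSNFixedConfig) -> np.ndarray:
    """Drive to each neuron from a centered stimulus of diameter ``b``."""
    if b < 0:
        raise ValueError("stimulus diameter must be non-negative")
    x = np.asarray(positions, dtype=float)

    def logistic(u):
        return 1.0 / (1.0 + np.exp(-u))

    return config.A * logistic((b / 2.0 + x) / config.l) * logistic((b / 2.0 - x) / config.l)


def integrate_ssn(realization: SSNRealization, drive, config: SSNFixedConfig,
                  r_init=None) -> np.ndarray:
    """Forward-Euler rate trajectory; row ``k`` is ``r(k * dt)``.

    Raises :class:`DivergenceError` (with the step index) on non-finite rates.
    """
    N = config.N
    drive = np.asarray(drive, dtype=float)
    r = np.zeros(N) if r_init is None else np.asarray(r_init, dtype=float).copy()
    if np.any(r < 0):
        raise ValueError("initial rates must be non-negative")
    dt_over_tau = config.dt / config.tau()
    FI = realization.F_diag * drive
    traj = np.empty((config.t2_steps + 1, N))
    traj[0] = r
    for step in range(1, config.t2_steps + 1):
        u = realization.W @ r + FI
        r = r + dt_over_tau * (_f_numpy(u, config) - r)
        if not np.all(np.isfinite(r)):
            raise DivergenceError(step)
        traj[step] = r
    return traj


def sustained_response(trajectory, config: SSNFixedConfig) -> np.ndarray:
    """Temporal average of the rows ``t1+1 .. t2`` of a trajectory."""
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape[0] < config.t2_steps + 1:
        raise ValueError(
            f"trajectory has {trajectory.shape[0]} rows; needs at least {config.t2_steps + 1}"
        )
    return trajectory[config.t1_steps + 1:config.t2_steps + 1].mean(axis=0)


# ---------------------------------------------------------------------------
# fused Euler integration (forward + hand-vectorized BPTT)
# ---------------------------------------------------------------------------

def _f_and_fprime(u: np.ndarray, cfg: SSNFixedConfig):
    """Rate function and its derivative, vectorized; fast path below u0."""
    k, n, r0, r1, u0 = cfg.k, cfg.n, cfg.r0, cfg.r1, cfg.u0
    up = np.maximum(u, 0.0)
    if not np.any(u >= u0):
        upn1 = up ** (n - 1.0)
        return k * upn1 * up, k * n * upn1
    lo = k * up**n
    lo_p = k * n * up ** (n - 1.0)
    arg = (n * r0 / (r1 - r0)) * (u - u0) / u0
    th = np.tanh(arg)
    hi = r0 + (r1 - r0) * th
    hi_p = (n * r0 / u0) * (1.0 - th * th)
    below = u < u0
    return np.where(below, lo, hi), np.where(below, lo_p, hi_p)


def _euler_run(W: np.ndarray, drive: np.ndarray, cfg: SSNFixedConfig,
               need_grad: bool):
    """Integrate a batch of realizations for all stimuli simultaneously.

    Returns (rbar, pen_sum, r_hist, fp_hist); the histories are None when
    ``need_grad`` is false.  ``pen_sum`` is the raw sum of rate excesses in
    the sustained window (callers apply the eta / (N T m) scale).
    """
    m, N = W.shape[0], W.shape[1]
    S = drive.shape[2]
    gamma = (cfg.dt / cfg.tau())[None, :, None]
    r = np.zeros((m, N, S))
    acc = np.zeros_like(r)
    pen_sum = 0.0
    r_hist = [r] if need_grad else None
    fp_hist = [] if need_grad else None
    for step in range(1, cfg.t2_steps + 1):
        u = np.matmul(W, r) + drive
        phi, fp = _f_and_fprime(u, cfg)
        r = r + gamma * (phi - r)
        if need_grad:
            r_hist.append(r)
            fp_hist.append(fp)
        if step > cfg.t1_steps:
            acc += r
            if np.any(r > RATE_CAP):
                pen_sum += np.sum(r[r > RATE_CAP] - RATE_CAP)
    return acc / cfg.T, pen_sum, r_hist, fp_hist


def _euler_backward(W, drive, cfg, r_hist, fp_hist, g_rbar, g_pen):
    """BPTT through the Euler loop.

    ``g_rbar`` is the cotangent of the (m, N, S) sustained response (or
    None); ``g_pen`` the scalar cotangent of the raw penalty sum.  Returns
    cotangents for W and drive.
    """
    m, N = W.shape[0], W.shape[1]
    S = drive.shape[2]
    gamma = (cfg.dt / cfg.tau())[None, :, None]
    WT = np.swapaxes(W, -1, -2)
    gr = np.zeros((m, N, S))
    g_drive = np.zeros_like(drive)
    gu_blocks, rprev_blocks = [], []
    coef = (1.0 / cfg.T) * g_rbar if g_rbar is not None else None
    for step in range(cfg.t2_steps, 0, -1):
        if step > cfg.t1_steps:
            if coef is not None:
                gr = gr + coef
            if g_pen:
                over = r_hist[step] > RATE_CAP
                if over.any():
                    gr = gr + g_pen * over
        gu = fp_hist[step - 1] * (gamma * gr)
        g_drive += gu
        gu_blocks.append(gu)
        rprev_blocks.append(r_hist[step - 1])
        gr = (1.0 - gamma) * gr + np.matmul(WT, gu)
    # sum_t gu_t @ r_{t-1}^T as a single stacked matmul
    gu_all = np.concatenate(gu_blocks, axis=2)
    rprev_all = np.concatenate(rprev_blocks, axis=2)
    g_W = np.matmul(gu_all, np.swapaxes(rprev_all, -1, -2))
    return g_W, g_drive


def _euler_core(W: Tensor, drive: Tensor, cfg: SSNFixedConfig):
    """Graph node wrapping the fused Euler loop.

    First-order differentiable w.r.t. ``W`` and ``drive`` (the backward pass
    is numeric, so these nodes cannot be differentiated twice; the
    adversarial losses never require that through the generator).
    """
    need_grad = W.requires_grad or drive.requires_grad
    rbar, pen_sum, r_hist, fp_hist = _euler_run(W.data, drive.data, cfg, need_grad)
    if not need_grad:
        return ad.constant(rbar), ad.constant(pen_sum)

    def vjp_rbar(g):
        g_W, g_drive = _euler_backward(W.data, drive.data, cfg, r_hist,
                                       fp_hist, g.data, 0.0)
        return Tensor(g_W), Tensor(g_drive)

    def vjp_pen(g):
        if pen_sum == 0.0:
            # no rate ever exceeded the cap: the penalty is identically zero
            # in a neighborhood, so its gradient is exactly zero
            return Tensor(np.zeros_like(W.data)), Tensor(np.zeros_like(drive.data))
        g_W, g_drive = _euler_backward(W.data, drive.data, cfg, r_hist,
                                       fp_hist, None, float(g.data))
        return Tensor(g_W), Tensor(g_drive)

    rbar_node = Tensor(rbar, True, (W, drive), vjp_rbar)
    pen_node = Tensor(np.asarray(pen_sum), True, (W, drive), vjp_pen)
    return rbar_node, pen_node


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

class SSNGenerator:
    """Differentiable sampler of size-tuning curves from the SSN ensemble."""

    conditional = True
    param_names = PARAM_NAMES

    def __init__(self, params: SSNParams, config: SSNFixedConfig = None,
                 probes: ProbeSpec = None, eta: float = 100.0):
        self.config = config or SSNFixedConfig()
        self.probes = probes or ProbeSpec()
        self.eta = float(eta)
        self.theta = ad.parameter(params.as_vector())
        self._d2, self._masks, self._signs = _structure_constants(self.config)
        self._stim = np.stack(
            [stimulus_input(b, self.config.positions(), self.config)
             for b in self.config.sizes], axis=1)  # (N, S)
        self._probe_idx = self.probes.indices(self.config)

    # -- bookkeeping -------------------------------------------------------
    @property
    def params(self) -> SSNParams:
        return SSNParams.from_vector(np.clip(self.theta.data, 0, None))

    @property
    def n_conditions(self) -> int:
        return self.config.S

    def condition_values(self) -> np.ndarray:
        return np.asarray(self.probes.offsets)

    def clip_(self):
        th = self.theta.data
        np.clip(th[:12], CLIP_LO, CLIP_HI, out=th[:12])
        th[12] = min(max(th[12], 0.0), 1.0)

    # -- simulation --------------------------------------------------------
    def _simulate_graph(self, z, zF, theta: Tensor):
        """(m, N, S) sustained responses plus the rate penalty, as a graph.

        The Euler loop runs as one fused primitive (:func:`_euler_core`)
        whose backward pass is a hand-vectorized BPTT; theta -> (W, drive)
        stays in ordinary graph ops.
        """
        cfg = self.config
        m = z.shape[0]
        W = _weights_graph(theta, ad.constant(z), self._d2, self._masks, self._signs)
        F = 1.0 + ad.constant(zF) * theta[12]                       # (m, N)
        drive = ad.reshape(F, (m, cfg.N, 1)) * Tensor(self._stim)   # (m, N, S)
        rbar, pen_sum = _euler_core(W, drive, cfg)
        penalty = pen_sum * (self.eta / (cfg.N * cfg.T * m))
        return rbar, penalty

    def _simulate_numpy(self, z, zF):
        """Fast no-gradient path used for fake batches and data generation."""
        cfg = self.config
        theta = ad.constant(self.theta.data)
        W = _weights_graph(theta, ad.constant(z), self._d2, self._masks, self._signs).data
        F = 1.0 + zF * self.theta.data[12]
        drive = F[:, :, None] * self._stim[None]
        rbar, pen_sum, _, _ = _euler_run(W, drive, cfg, need_grad=False)
        penalty = pen_sum * (self.eta / (cfg.N * cfg.T * W.shape[0]))
        return rbar, penalty

    def _draw_noise(self, m, rng):
        cfg = self.config
        z = rng.uniform(size=(m, cfg.N, cfg.N))
        zF = rng.uniform(-1.0, 1.0, size=(m, cfg.N))
        return z, zF

    def curves_all_probes(self, m: int, rng: np.random.Generator,
                          with_grad: bool = True):
        """(m, n_probes, S) tuning curves for every probe of each realization."""
        z, zF = self._draw_noise(m, rng)
        if with_grad:
            rbar, penalty = self._simulate_graph(z, zF, self.theta)
            out = rbar[:, self._probe_idx, :]
        else:
            rbar, penalty = self._simulate_numpy(z, zF)
            out = ad.constant(rbar[:, self._probe_idx, :])
            penalty = ad.constant(penalty)
        return out, penalty

    def generate(self, m: int, rng: np.random.Generator, conditions=None,
                 with_grad: bool = True):
        """Sample ``m`` curves; ``conditions`` are probe-offset indices."""
        if conditions is None:
            conditions = np.zeros(m, dtype=int)
        conditions = np.asarray(conditions, dtype=int)
        if conditions.shape != (m,):
            raise ValueError("need one probe-offset index per sample")
        z, zF = self._draw_noise(m, rng)
        rows = np.arange(m)
        pidx = self._probe_idx[conditions]
        if with_grad:
            rbar, penalty = self._simulate_graph(z, zF, self.theta)
            out = rbar[rows, pidx, :]
        else:
            rbar, penalty = self._simulate_numpy(z, zF)
            out = ad.constant(rbar[rows, pidx, :])
            penalty = ad.constant(penalty)
        return out, penalty


def ssn_generate(params: SSNParams, config: SSNFixedConfig, probes: ProbeSpec,
                 rng_seed, n_networks: int = 1):
    """Sample tuning curves for every probe of ``n_networks`` realizations.

    Returns a :class:`~circuitfit.data_io.TuningCurveSet` with one row per
    (network, probe) pair and the probe offset as the per-neuron condition.
    """
    from .data_io import TuningCurveSet

    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    gen = SSNGenerator(params, config, probes)
    curves, _ = gen.curves_all_probes(n_networks, rng, with_grad=False)
    arr = curves.data  # (n_networks, O, S)
    responses = arr.reshape(n_networks * probes.n_probes, config.S)
    offsets = np.tile(np.asarray(probes.offsets), n_networks)
    return TuningCurveSet(
        responses=responses,
        condition_labels=list(config.sizes),
        neuron_conditions=offsets,
        meta={
            "generator": "ssn",
            "theta": params.as_vector().tolist(),
            "n_networks": n_networks,
        },
    )
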
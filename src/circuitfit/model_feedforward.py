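"""Two-layer feedforward generator of 3-D hand-position tuning curves.

The input layer is a cubic grid of units with Gaussian receptive fields whose
widths are drawn uniformly from ``[sigma_l, sigma_l + delta_sigma]``.  A
single output unit receives sparse random feedforward weights (Bernoulli mask
at density 0.01, strengths uniform on ``[0, J]``) and applies a rectified
linear response with a threshold drawn uniformly from
``[phi_l, phi_l + delta_phi]``.  Each generated tuning curve corresponds to a
fresh realization of all structural noise, so the five distribution
parameters ``theta = (sigma_l, delta_sigma, J, phi_l, delta_phi)`` fully
determine the tuning-curve distribution.

All forward computations are written against the autodiff engine so that
generated curves are differentiable in ``theta``; plain-array convenience
wrappers simply unwrap the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "M1Params",
    "M1Latents",
    "HandGrid",
    "DegenerateWidthError",
    "make_hand_grid",
    "sample_m1_latents",
    "input_activations",
    "m1_tuning_curve",
    "M1Generator",
    "MASK_DENSITY",
    "N_CONDITIONS",
]

MASK_DENSITY = 0.01
N_CONDITIONS = 27
DEFAULT_GRID_SIZE = 40

PARAM_NAMES = ("sigma_l", "delta_sigma", "J", "phi_l", "delta_phi")


class DegenerateWidthError(ValueError):
    """Raised when every receptive-field width would be exactly zero."""


@dataclass
class M1Params:
    sigma_l: float
    delta_sigma: float
    J: float
    phi_l: float
    delta_phi: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, v) -> "M1Params":
        return cls(*[float(x) for x in np.asarray(v)])


@dataclass
class M1Latents:
    """Quenched structural noise for one network realization."""

    z_sigma: np.ndarray  # (n_units,), U[0,1]
    z_J: np.ndarray      # (n_units,), U[0,1]
    z_phi: float         # scalar, U[0,1]
    mask: np.ndarray     # (n_units,), Bernoulli(MASK_DENSITY)

    @property
    def n_units(self) -> int:
        return self.z_sigma.shape[0]


@dataclass
class HandGrid:
    stimulus_positions: np.ndarray  # (27, 3), 3x3x3 lattice, spacing 1
    rf_centers: np.ndarray          # (grid_size**3, 3)
    grid_size: int
    # pairwise squared distances, (n_units, 27); precomputed once
    dist2: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.dist2 is None:
            diff = self.rf_centers[:, None, :] - self.stimulus_positions[None, :, :]
            self.dist2 = np.sum(diff**2, axis=2)


def make_hand_grid(grid_size: int = DEFAULT_GRID_SIZE) -> HandGrid:
    """Stimulus lattice plus an input-layer RF grid spanning 3x its extent."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    axis = np.array([-1.0, 0.0, 1.0])
    sx, sy, sz = np.meshgrid(axis, axis, axis, indexing="ij")
    stimulus = np.stack([sx.ravel(), sy.ravel(), sz.ravel()], axis=1)
    # stimulus cube spans [-1, 1]; the RF grid covers 3x that, centered
    raxis = np.linspace(-3.0, 3.0, grid_size)
    rx, ry, rz = np.meshgrid(raxis, raxis, raxis, indexing="ij")
    centers = np.stack([rx.ravel(), ry.ravel(), rz.ravel()], axis=1)
    return HandGrid(stimulus, centers, grid_size)


def sample_m1_latents(rng_seed, grid_size: int = DEFAULT_GRID_SIZE) -> M1Latents:
    """Draw one realization of the structural noise ``z``."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = grid_size**3
    return M1Latents(
        z_sigma=rng.uniform(size=n),
        z_J=rng.uniform(size=n),
        z_phi=float(rng.uniform()),
        mask=(rng.uniform(size=n) < MASK_DENSITY).astype(float),
    )


def _check_widths(params: M1Params):
    if params.sigma_l == 0.0 and params.delta_sigma == 0.0:
        raise DegenerateWidthError("all receptive-field widths would be zero")


def input_activations(latents: M1Latents, params: M1Params, grid: HandGrid,
                      condition: int) -> np.ndarray:
    """Normalized input-layer activations ``h_i(s)`` for one condition (1..27)."""
    if not 1 <= condition <= N_CONDITIONS:
        raise ValueError("condition must be in 1..27")
    _check_widths(params)
    sigma = params.sigma_l + latents.z_sigma * params.delta_sigma
    logh = -grid.dist2[:, condition - 1] / (2.0 * sigma**2)
    # subtracting the max is underflow-safe and cancels in the normalization
    h = np.exp(logh - logh.max())
    return h / h.sum()


def _curve_graph(z_sigma: Tensor, z_J: Tensor, z_phi: Tensor, mask: np.ndarray,
                 theta: Tensor, dist2: np.ndarray) -> Tensor:
    """Batched tuning curves as an autodiff graph.

    ``z_*`` carry a leading batch axis; ``theta`` is the 5-vector
    (sigma_l, delta_sigma, J, phi_l, delta_phi).  Returns (batch, 27).
    """
    sigma = theta[0] + z_sigma * theta[1]                      # (m, n)
    denom = 2.0 * sigma * sigma
    # shift each condition's distances by the per-condition minimum: the
    # common factor cancels in numer/Z and keeps Z >= 1 (no underflow)
    d2 = dist2 - dist2.min(axis=0, keepdims=True)
    a = ad.exp(-Tensor(d2) / ad.reshape(denom, denom.shape + (1,)))  # (m, n, 27)
    z = ad.tsum(a, axis=1)                                     # (m, 27)
    w = theta[2] * Tensor(mask) * z_J                          # (m, n)
    numer = ad.tsum(ad.reshape(w, w.shape + (1,)) * a, axis=1)  # (m, 27)
    phi = theta[3] + z_phi * theta[4]                          # (m,)
    return ad.relu(numer / z - ad.reshape(phi, phi.shape + (1,)))


def m1_tuning_curve(latents: M1Latents, params: M1Params, grid: HandGrid) -> np.ndarray:
    """Tuning curve (length 27) of one output neuron for fixed noise."""
    _check_widths(params)
    theta = ad.constant(params.as_vector())
    out = _curve_graph(
        ad.constant(latents.z_sigma[None, :]),
        ad.constant(latents.z_J[None, :]),
        ad.constant(np.array([latents.z_phi])),
        latents.mask[None, :],
        theta,
        grid.dist2,
    )
    return out.data[0]


class M1Generator:
    """WGAN-facing generator: fresh noise in, differentiable curves out."""

    n_conditions = N_CONDITIONS
    conditional = False
    param_names = PARAM_NAMES

    # box constraints applied after every optimizer step
    LOWER = np.array([1e-3, 0.0, 0.0, 0.0, 0.0])
    UPPER = np.array([np.inf, np.inf, np.inf, np.inf, np.inf])

    def __init__(self, params: M1Params, grid_size: int = DEFAULT_GRID_SIZE):
        _check_widths(params)
        self.grid = make_hand_grid(grid_size)
        self.theta = ad.parameter(params.as_vector())

    @property
    def params(self) -> M1Params:
        return M1Params.from_vector(self.theta.data)

    def clip_(self):
        np.clip(self.theta.data, self.LOWER, self.UPPER, out=self.theta.data)

    def generate(self, m: int, rng: np.random.Generator, conditions=None,
                 with_grad: bool = True):
        """Sample ``m`` tuning curves.  Returns (curves, penalty).

        ``conditions`` is accepted for interface parity and ignored; the
        generator penalty is identically zero for this model.
        """
        n = self.grid.grid_size**3
        z_sigma = rng.uniform(size=(m, n))
        z_J = rng.uniform(size=(m, n))
        z_phi = rng.uniform(size=m)
        mask = (rng.uniform(size=(m, n)) < MASK_DENSITY).astype(float)
        theta = self.theta if with_grad else self.theta.detach()
        out = _curve_graph(
            ad.constant(z_sigma), ad.constant(z_J), ad.constant(z_phi),
            mask, theta, self.grid.dist2,
        )
        return out, ad.constant(0.0)

    def curves_all_probes(self, m, rng, with_grad=True):
        """Moment-matching view: a single 'probe' (the output neuron)."""
        out, pen = self.generate(m, rng, with_grad=with_grad)
        return ad.reshape(out, (m, 1, self.n_conditions)), pen
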
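"""Tuning-curve containers, text/HDF5 round-trips, and fixture generators.

Tuning curves have no standard bioscience file format, so the package defines
a small self-describing comma-delimited dialect::

    # {"generator": "ssn", "theta": [...], "seed": 1}
    neuron_id,condition_value,r_0,r_0.125,...
    0,0,12.3456789,...

The optional ``condition_value`` column carries a per-neuron condition (for
the SSN: the probe's topographic offset) and is required by the conditional
WGAN.  Values round-trip through text at 9 significant digits; the HDF5
container is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TuningCurveSet",
    "ValidationError",
    "RunConfig",
    "read_tuning_curves",
    "write_tuning_curves",
    "read_tuning_curves_h5",
    "write_tuning_curves_h5",
    "split_half",
    "make_ground_truth_ssn_dataset",
    "make_synthetic_m1_dataset",
    "named_streams",
]


class ValidationError(ValueError):
    pass


@dataclass
class TuningCurveSet:
    """R tuning curves over S stimulus conditions, with optional per-neuron labels."""

    responses: np.ndarray                  # (R, S), Hz, non-negative finite
    condition_labels: list                 # length S stimulus descriptors
    neuron_conditions: np.ndarray = None   # optional (R,) per-neuron condition
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValidationError("responses must be a 2-D (neurons x conditions) array")
        if len(self.condition_labels) != self.responses.shape[1]:
            raise ValidationError("condition_labels length must match response columns")
        bad = ~np.isfinite(self.responses)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValidationError(f"non-finite response at row {row}")
        neg = self.responses < 0
        if neg.any():
            row = int(np.argwhere(neg)[0, 0])
            raise ValidationError(f"negative response at row {row}")
        if self.neuron_conditions is not None:
            self.neuron_conditions = np.asarray(self.neuron_conditions, dtype=float)
            if self.neuron_conditions.shape != (self.responses.shape[0],):
                raise ValidationError("neuron_conditions must have one entry per row")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.responses.shape[1]

    def require_conditions(self):
        if self.neuron_conditions is None:
            raise ValidationError("this operation needs per-neuron condition values")
        return self.neuron_conditions

    def subset(self, idx) -> "TuningCurveSet":
        nc = None if self.neuron_conditions is None else self.neuron_conditions[idx]
        return TuningCurveSet(self.responses[idx], list(self.condition_labels), nc,
                              dict(self.meta))


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def write_tuning_curves(tcs: TuningCurveSet, path):
    path = Path(path)
    with_cond = tcs.neuron_conditions is not None
    lines = ["# " + json.dumps(tcs.meta, sort_keys=True)]
    cols = ["neuron_id"] + (["condition_value"] if with_cond else []) + \
        [f"r_{_fmt(c)}" for c in tcs.condition_labels]
    lines.append(",".join(cols))
    for i, row in enumerate(tcs.responses):
        fields = [str(i)]
        if with_cond:
            fields.append(_fmt(tcs.neuron_conditions[i]))
        fields.extend(_fmt(v) for v in row)
        lines.append(",".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_tuning_curves(path) -> TuningCurveSet:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = {}
    if lines and lines[0].startswith("#"):
        meta = json.loads(lines[0][1:].strip() or "{}")
        lines = lines[1:]
    if not lines:
        raise ValidationError(f"{path} has no header line")
    header = lines[0].split(",")
    with_cond = len(header) > 1 and header[1] == "condition_value"
    first_resp = 2 if with_cond else 1
    labels = [float(h[2:]) for h in header[first_resp:]]
    rows, conds = [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split(",")
        if with_cond:
            conds.append(float(parts[1]))
        rows.append([float(v) for v in parts[first_resp:]])
    return TuningCurveSet(
        responses=np.array(rows, dtype=float).reshape(len(rows), len(labels)),
        condition_labels=labels,
        neuron_conditions=np.array(conds) if with_cond else None,
        meta=meta,
    )


def write_tuning_curves_h5(tcs: TuningCurveSet, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=tcs.responses)
        f.create_dataset("condition_labels", data=np.asarray(tcs.condition_labels, dtype=float))
        if tcs.neuron_conditions is not None:
            f.create_dataset("neuron_conditions", data=tcs.neuron_conditions)
        f.attrs["meta"] = json.dumps(tcs.meta, sort_keys=True)


def read_tuning_curves_h5(path) -> TuningCurveSet:
    import h5py

    with h5py.File(path, "r") as f:
        return TuningCurveSet(
            responses=f["responses"][...],
            condition_labels=f["condition_labels"][...].tolist(),
            neuron_conditions=f["neuron_conditions"][...] if "neuron_conditions" in f else None,
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def split_half(tcs: TuningCurveSet, seed: int):
    """Random train/test halves (train gets ``floor(R/2)`` rows)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(tcs.n_neurons)
    half = tcs.n_neurons // 2
    return tcs.subset(perm[:half]), tcs.subset(perm[half:])


def named_streams(seed, names):
    """Independent, reproducible random streams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# synthetic ground-truth fixtures
# ---------------------------------------------------------------------------

def make_ground_truth_ssn_dataset(seed, n_curves: int = 2048, probes=None,
                                  config=None, chunk: int = 128) -> TuningCurveSet:
    """Size-tuning curves from the ground-truth SSN connectivity ensemble."""
    from .model_ssn import ProbeSpec, SSNFixedConfig, SSNGenerator, ground_truth_params

    probes = probes or ProbeSpec((0.0,))
    config = config or SSNFixedConfig()
    params = ground_truth_params()
    gen = SSNGenerator(params, config, probes)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_networks = -(-n_curves // probes.n_probes)
    blocks = []
    done = 0
    while done < n_networks:
        m = min(chunk, n_networks - done)
        curves, _ = gen.curves_all_probes(m, rng, with_grad=False)
        blocks.append(curves.data.reshape(m * probes.n_probes, config.S))
        done += m
    responses = np.concatenate(blocks, axis=0)[:n_curves]
    offsets = np.tile(np.asarray(probes.offsets), n_networks)[:n_curves]
    return TuningCurveSet(
        responses=responses,
        condition_labels=list(config.sizes),
        neuron_conditions=offsets,
        meta={"generator": "ssn-ground-truth", "theta": params.as_vector().tolist(),
              "seed": int(seed), "N": config.N},
    )


def make_synthetic_m1_dataset(seed, n_curves: int = 200, truth=None,
                              grid_size: int = 40, chunk: int = 8) -> TuningCurveSet:
    """Hand-position tuning curves from a fixed, documented feedforward truth."""
    from .model_feedforward import M1Generator, M1Params

    truth = truth or M1Params(sigma_l=0.6, delta_sigma=1.4, J=2000.0,
                              phi_l=2.0, delta_phi=8.0)
    gen = M1Generator(truth, grid_size=grid_size)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    blocks = []
    done = 0
    while done < n_curves:
        m = min(chunk, n_curves - done)
        curves, _ = gen.generate(m, rng, with_grad=False)
        blocks.append(curves.data)
        done += m
    return TuningCurveSet(
        responses=np.concatenate(blocks, axis=0),
        condition_labels=list(range(1, 28)),
        neuron_conditions=None,
        meta={"generator": "m1-synthetic", "theta": truth.as_vector().tolist(),
              "seed": int(seed), "grid_size": grid_size},
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of a full fitting run."""

    model: dict
    method: dict
    evaluation: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"model": self.model, "method": self.method,
             "evaluation": self.evaluation, "seed": self.seed},
            indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists() else str(source)
        d = json.loads(text)
        return cls(model=d.get("model", {}), method=d.get("method", {}),
                   evaluation=d.get("evaluation", {}), seed=int(d.get("seed", 0)))
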
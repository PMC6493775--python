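# circuitfit

Fit mechanistic neural-circuit models to *distributions* of tuning curves.

Circuit models with random connectivity or heterogeneous cell parameters are
treated as implicit generative models: a low-dimensional parameter vector θ
describes the *statistics* of network structure, standard noise **z** is
mapped through a reparametrized sampler to a concrete network realization,
and simulating that network yields one tuning curve. `circuitfit` trains θ
so that the distribution of generated curves matches an empirical dataset,
using a Wasserstein GAN with gradient penalty (plain or conditional) or a
moment-matching baseline, and scores goodness of fit (KS distances over
summary statistics) and parameter recovery (sMAPE).

Two generators are included:

- **Feedforward hand-position model** (`model_feedforward`): a two-layer
  network producing 27-condition 3-D hand-position tuning curves;
  θ = (σ_l, δσ, J, φ_l, δφ) controls receptive-field widths, sparse
  feedforward strengths, and output thresholds.
- **Topographic E/I stabilized supralinear network** (`model_ssn`): a
  recurrent rate network with a saturating power-law nonlinearity,
  integrated by forward Euler with full backpropagation through time;
  θ = (J<_ab, δJ_ab, σ_ab, V) (13 parameters) controls the connectivity
  ensemble and feedforward heterogeneity. Output: size-tuning curves of
  excitatory probe neurons at chosen topographic offsets (the conditional
  WGAN's condition variable).

Everything runs on numpy: the package ships a small reverse-mode autodiff
engine (`circuitfit.autodiff`) with double-backprop support for the
gradient penalty, plus Adam/RMSProp optimizers.

## CLI

```bash
# synthetic ground-truth data (SSN size-tuning curves, or feedforward M1)
circuitfit simulate --model ssn --seed 1 --n-curves 512 \
    --config run.json --out data.csv

# fit: --method {wgan,cwgan,mm}
circuitfit train --method cwgan --model ssn --config run.json \
    --data data.csv --out fit/

# per-curve statistics + KS distances between two datasets
circuitfit evaluate --data-a data.csv --data-b generated.csv \
    --kind size --out eval/

# parameter-recovery sweep over a hyperparameter grid
circuitfit benchmark --config run.json --out bench.csv
```

`run.json` is a `RunConfig` document with `model`, `method`, `evaluation`
and `seed` sections, e.g.

```json
{
  "model": {"kind": "ssn", "N": 82, "t1_steps": 60, "t2_steps": 100,
             "sizes": [0.0, 0.125, 0.25, 0.5, 1.0],
             "probes": [0.0, 0.125, 0.375]},
  "method": {"alpha_G": 0.001, "batch_size": 16, "max_updates": 2000},
  "evaluation": {"stopping": true},
  "seed": 1
}
```

Datasets are comma-delimited text with a `#`-prefixed JSON metadata line, a
header, one row per neuron (`neuron_id[,condition_value],r_*...`); an HDF5
container with the same schema is available for large sets.

## Notes

- Training is fully reproducible given a seed (all randomness flows through
  named substreams).
- WGAN training is genuinely adversarial: some seeds show slow
  oscillation/overshoot around the optimum (the gradient penalty resists
  critic sign flips). The stopping rule plus trailing average is the
  intended remedy; box constraints keep θ bounded throughout.
- The linear-fit R² statistic uses the uncentered denominator
  (Σ r̄(s)²) by design; pass `centered=True` for the conventional version.
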
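# fbsem

Bayesian PET image reconstruction by forward–backward splitting
expectation-maximisation (FBSEM), together with its unrolled
recurrent-network form in which the regularization step is a small trained
residual CNN, exercised end-to-end on synthetic 2D brain phantoms with
Poisson sinogram simulation.

The package is aimed at reconstruction researchers who want a compact,
fully-testable reference implementation of the splitting MAP-EM family —
from plain OSEM through anatomically guided MAPEM to a model-based
deep-learning reconstructor — with every moving part (phantoms, projector,
noise, priors, training) synthetic, seeded and reproducible.

## The algorithm

The maximum a-posteriori estimate maximizes the penalized Poisson
log-likelihood

```
x̂ = argmax_x  L(y|x) − β R(x),      L(y|x) = Σ_i y_i log([Hx]_i + b̄_i) − ([Hx]_i + b̄_i)
```

Forward–backward splitting with an EM surrogate for `L` and ordered subsets
turns each subset state into three steps:

```
x_Reg = x − γ β ∇R(x)                                    (prior gradient step)
x_EM,j = (x_j / s_j⁽ᵐ⁾) Σ_{i∈Ω_m} h_ij y_i/([Hx]_i + b̄_i)   (OS-EM update)
x_j   = root of  δ_j x² + (1 − δ_j x_Reg,j) x − x_EM,j = 0,  δ_j = 1/(γ s_j⁽ᵐ⁾)
```

For the MR-weighted Tikhonov prior `R(x) = ½ Σ_j Σ_b w_jb (x_j − x_b)²` the
substitution β = ½, γ_j = 1/Σ_b w_jb reduces the loop to De Pierro's MAPEM
(monotone with one subset); as γ → ∞ it reduces to OSEM. Unrolling
N_it × N_sub states and replacing the gradient step with
`x_Reg = ReLU(x + CNN(x[, MR]))` — a 5-layer residual unit with batch
normalization, 28612 trainable scalars in PET-only mode shared across all
states, plus a trainable γ — gives the FBSEM network, trained end-to-end by
mean-squared error against noise-free references with gradients flowing only
through the regularization and fusion computations. See `docs/methods.md`
for conventions, derivations and limitations.

## Worked example

```python
import numpy as np
from fbsem import (make_base_phantom, add_lesions, default_geometry, build_system,
                   scale_to_counts, sample_poisson, tikhonov_prior, osem, nrmse)
from fbsem.recon import ReconConfig, fbsem_reconstruct
from fbsem.evaluate import gaussian_post_filter

# a 64x64 brain-like slice with 10 hot/cold lesions, attenuation included
sample = add_lesions(make_base_phantom(64, 2.08, seed=1), n_lesions=10,
                     radius_range_mm=(2, 10), seed=2)
geom = default_geometry(64, 2.08, n_subsets=6)
model = build_system(geom, sample.mumap, n_subsets=6)

# low-dose sinogram: 2.5e5 expected prompts, 20% randoms
x_ref, bbar = scale_to_counts(model, sample.activity, 2.5e5, randoms_fraction=0.2)
sino = sample_poisson(model, x_ref, bbar, seed=3)

rec_osem = osem(model, sino, n_iterations=10).image.data
prior = tikhonov_prior(model.image_shape, mr=sample.mr)
cfg = ReconConfig(n_iterations=10, n_subsets=6, gamma=0.1, prior=prior)
rec_mapem = fbsem_reconstruct(model, sino, cfg).image.data

print(f"total prompts:        {sino.total_prompts}")
print(f"OSEM NRMSE:           {nrmse(rec_osem, x_ref.data):.3f}")
print(f"OSEM + 4 mm filter:   {nrmse(gaussian_post_filter(rec_osem, 4.0, 2.08), x_ref.data):.3f}")
print(f"MR-guided MAPEM:      {nrmse(rec_mapem, x_ref.data):.3f}")
```

prints

```
total prompts:        249378
OSEM NRMSE:           0.298
OSEM + 4 mm filter:   0.214
MR-guided MAPEM:      0.118
```

The sampled sinogram lands within Poisson fluctuation of the requested
2.5×10⁵ prompts. Unfiltered OSEM at this dose is noise-limited (global NRMSE
0.30 against the noise-free reference); a 4-mm Gaussian post-filter trades
resolution for noise (0.21); the MR-guided quadratic prior inside the
splitting loop does markedly better (0.12) because it smooths within — not
across — anatomical boundaries.

Training the unrolled network on a simulated paired dataset:

```python
from fbsem import simulate_dataset, train, TrainConfig
records = simulate_dataset(n_slices=4, n_rotations=4, size_px=64,
                           count_levels=2.5e5, split="train", seed=11,
                           n_subsets=4, n_lesions=10)
net, history = train(records, TrainConfig(epochs=8, n_minibatches=4,
                                          learning_rate=0.05, seed=0,
                                          n_iterations=2))
```

`history` is the per-epoch MSE loss; `fbsem.fbsemnet.infer(net, record)`
reconstructs held-out sinograms. A `fbsem` command-line interface wraps the
same functions (`fbsem simulate-phantoms`, `simulate-data`, `recon`,
`train`, `infer`, `evaluate`).

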
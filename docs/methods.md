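# Methods

## The reconstruction problem

PET reconstruction estimates a non-negative activity image `x` from
coincidence counts `y` whose means are `[Hx]_i + b̄_i`, where `H` is the
linear system model (geometry and attenuation) and `b̄` the expected
accidental coincidences. The maximum a-posteriori estimate maximizes

    Φ(x) = L(y|x) − β R(x),
    L(y|x) = Σ_i  y_i log([Hx]_i + b̄_i) − ([Hx]_i + b̄_i),

with `R` a convex differentiable smoothness penalty of strength `β`.

## The splitting loop

This package solves the MAP problem by forward–backward splitting: alternate
a gradient step on the prior with a proximal step on the Poisson likelihood.
With an EM separable surrogate for the likelihood and ordered subsets
`Ω_1 … Ω_{N_sub}` of the lines of response, each subset state computes

1. regularization: `x_Reg = x − γ β g(x)` where `g` is the prior gradient
   field (see the convention below);
2. EM update with randoms:
   `x_EM,j = (x_j / s_j^(m)) Σ_{i∈Ω_m} h_ij y_i / ([Hx]_i + b̄_i)`,
   with `s_j^(m) = Σ_{i∈Ω_m} h_ij` the subset sensitivity;
3. fusion: the non-negative root of
   `δ_j x² + (1 − δ_j x_Reg,j) x − x_EM,j = 0` with `δ_j = 1/(γ s_j^(m))`.

The loop starts from a uniform image of ones. As `γ → ∞`, `δ → 0` and the
fusion returns `x_EM`: the loop is exactly OSEM (the implementation takes
this branch explicitly, so the equivalence is bitwise, not approximate).

### Quadratic prior and the gradient convention

The shipped prior is the pairwise (optionally MR-weighted) Tikhonov penalty

    R(x) = ½ Σ_j Σ_{b∈N_j} w_jb (x_j − x_b)²

on the 8-connected stencil, each unordered pair appearing twice in the double
sum. The regularization step uses the one-sided stencil sum
`g_j = Σ_b w_jb (x_j − x_b)`, which for symmetric weights is exactly half the
Euclidean gradient of `R`. This is a deliberate convention, not an error:
it is the form in which the splitting step reduces algebraically to
De Pierro's neighbourhood average — substituting `β = ½` and per-voxel
`γ_j = 1/Σ_b w_jb` into step 1 gives

    x_Reg,j = (1 / 2Σ_b w_jb) Σ_b w_jb (x_j + x_b),

the classical De Pierro MAPEM regularized image (verified to 1e−12 in the
tests). Code needing the Euclidean gradient multiplies the stencil sum by 2;
the finite-difference consistency test asserts exactly that factor.

### De Pierro mode and monotonicity

`depierro=True` runs the neighbourhood-average step with
`δ_j = β Σ_b w_jb / s_j^(m)`. Working out the separable optimization-transfer
surrogate for the pairwise penalty shows this update is the exact monotone
MAPEM for the objective `L − (β/4) R` with `R` as printed above (the factor
¼ reflects the double counting of pairs in `R` relative to the surrogate
algebra). The objective trace recorded in De Pierro mode therefore uses the
effective coefficient `β/4`, and with a single subset it is non-decreasing
at every iteration — a property the tests check over 50 iterations, for both
MLEM (`β = 0`) and the MAPEM mode. With multiple subsets the usual OSEM
caveat applies: iterates enter a limit cycle and no monotonicity is claimed.

### MR guidance

Anatomical weights are `w_jb = exp(−(m_j − m_b)²/(2σ²))` on MR intensities,
symmetrized, optionally divided by inter-voxel distance (default on).
`σ = "auto"` uses the standard deviation of neighbour MR differences over
the brain mask; a constant MR image falls back to uniform weights. The MAPEM
baseline tunes the scalar `γ` by grid search on mean global NRMSE against
the reference images (`tune_gamma`), mirroring how a practitioner would set
it; the returned value is always a grid member.

## The unrolled network

The loop is unrolled into `N = N_it × N_sub` states. Step 1 is replaced by a
residual learning unit, `x_Reg = ReLU(x + CNN(x [, MR]))`, with five 3×3
convolutions (32, 32, 32, 32, 1 filters), each followed by affine batch
normalization, ReLU between hidden layers, and a final non-negativity clamp.
The caption count of 28612 trainable scalars in PET-only mode closes only if
the fifth layer has a single output filter and batch normalization follows
all five convolutions: 320 + 3·9248 + 289 convolution scalars, 258 BN
affines, plus the fusion weight — that reading is adopted. PET+MR mode
widens the first layer to two input channels (+288 scalars). One parameter
set is shared across all states; the fusion weight `γ` is trained on a log
scale (initialized at 1) so it stays positive.

Training minimizes the mean squared error between the unrolled output and
the noise-free reference with Adam. The reference protocol is 50 epochs,
10 mini-batches per epoch, learning rate 0.05 — these are the `TrainConfig`
defaults. Backpropagation passes only through the regularization and fusion
computations: the EM update is treated as a fixed block, so the gradient
reaching state `t−1` flows solely through the unit's input branch. All layers
and their backward passes are implemented directly in numpy (`_nnops`), and
every backward pass is finite-difference checked; a dedicated test confirms
that full finite differences (which see the EM path) disagree with the
blocked gradient, i.e. the stop-gradient semantics are real.

Batch normalization uses batch statistics during training and running
averages at inference; hidden activations follow BN. Mini-batches are
processed as true batches (B, C, H, W), so BN statistics pool over the
mini-batch and both spatial axes.

## System model

A generic 2D parallel-beam geometry stands in for a clinical scanner ring;
the algorithms are geometry-agnostic. Defaults: `n_angles ≈ 2×` image size
(rounded up to a multiple of the subset count so interleaving is even),
`n_radial_bins = 1.5×` image size at the 2.08 mm pixel pitch. `H` is
assembled once as a sparse matrix of pixel-driven linear-interpolation
weights with 2×2 subpixel deposition; the subpixel split suppresses radial
aliasing so that projections of a smooth disk match analytic chord lengths
to within ~1% (tested at 2%). Backprojection is the exact sparse transpose,
so the adjoint identity holds to machine precision. Attenuation
`exp(−∫μ)` is kept as a separate per-LOR factor, letting one geometry
matrix serve phantoms with different μ-maps. Subsets interleave angles
(`m, m+N_sub, …`), the standard OSEM schedule, applied sequentially within
each outer iteration. EM denominators carry a 1e−12 guard and voxels with
zero subset sensitivity are frozen at zero.

## Synthetic data

The phantom generator emulates a 2D brain slice protocol: jittered nested
ellipses with a harmonically perturbed grey/white boundary at 2.08 mm pixels,
activity grey:white:background = 4:1:0 with a smooth ±8% texture per seed,
an independent T1-like MR contrast (white bright), and a piecewise-constant
511-keV μ-map (tissue 0.0096 mm⁻¹, skull ring 0.0146 mm⁻¹). Ten circular
lesions of 2–10 mm radius are placed uniformly inside the brain, hot (×2) or
cold (×0.25) with equal probability, applied multiplicatively to activity
and with milder contrast to MR; a configurable fraction appears in only one
modality (PET-only / MR-only) to emulate mismatched findings. No standard
lesion-contrast values exist for such phantoms, so these were fixed once to
make lesions clearly visible at low-dose count levels and are exposed as
arguments. Each slice is augmented by random rotations (±5° train, ±10°
test; bilinear for images, nearest-neighbour for masks, activity clipped at
zero), and test phantoms draw from a distinct seed stream.

Emission data: the activity is rescaled so expected total prompts hit the
requested count level, with a spatially uniform randoms background carrying
20% of the total by default; counts are independent Poisson draws per LOR.
The reconstruction reference is the noise-free scaled phantom itself rather
than a 100M-count reconstruction — cleaner for parameter-recovery testing,
and the two coincide in the high-count limit.

What the generator does **not** emulate: real anatomy (procedural ellipses,
no gyri or partial-volume tissue fractions), scatter, detector blur/PSF,
normalization, deadtime, 3D effects, or structured randoms. Passing tests
therefore demonstrate the correctness and the relative behaviour of the
algorithms under an idealized Poisson model, not clinical image quality.

## Problem sizes and defaults

Classical reconstructions run at `N_it = 10`, `N_sub = 6`. The package's own
study conditions are desk-scale: 64×64 grids, count levels around 1–2.5×10⁵
(2.5×10⁵ at 64² matches the per-voxel statistics of 10⁶ counts at 128², the
reference protocol's training dose). The training preset used by the test
suite and the acceptance script is 16 samples (4 slices × 4 rotations),
8 states (`N_it = 2`, `N_sub = 4`), 8 epochs, 4 mini-batches, learning rate
0.05 — a size at which one CPU trains in a few minutes while the trained
network still beats unfiltered OSEM on held-out samples. Full-scale settings
(500 samples, 60 states, 50 epochs) are plain `TrainConfig`/dataset
arguments, not a separate code path.

## Numerical notes

- The fusion root uses the rationalized form
  `2 x_EM / ((1−δx_Reg) + √((1−δx_Reg)² + 4δx_EM))`, falling back to the
  textbook quadratic formula when the denominator underflows; `δ = 0`
  returns `x_EM` exactly. Residuals are assessed with the backward-stable
  normalization (relative to the quadratic's term magnitudes), since for
  large `δ` the raw residual is condition-amplified.
- Objective evaluation defines `0·log(0)` as 0 and returns −∞ when a bin has
  counts but zero modelled mean; −∞ is a legal value, not an error.
- NRMSE is root-sum-square error over root-sum-square of the reference,
  optionally over an ROI; ROI tables erode tissue and pooled lesion masks by
  one pixel to reduce boundary ambiguity. The 4-mm Gaussian-filtered OSEM
  baseline uses `σ = FWHM/(2√(2 ln 2))` in pixels.
- Every operation is a pure function of its arguments including seeds;
  dataset builds and training are reproducible bit-for-bit on the same
  hardware class.

## Known limitations

- The generic (gradient-step) mode is only guaranteed monotone via the
  De Pierro specialization; for arbitrary `γ` and priors the fusion is a
  surrogate proximal step and monotonicity is not asserted.
- With an unbounded prior gradient the `γ → ∞` limit of the *gradient-step*
  mode does not tend to OSEM (the step `γβg(x)` grows with `γ`); the OSEM
  limit statement applies to the no-prior/bounded-regularizer case, which is
  how the unrolled network (whose `x_Reg` does not scale with `γ`) behaves.
- Training on one CPU limits the practical unrolling depth; the 60-state
  configuration trains, but the shipped tests use 8 states.
- The parallel-beam sinogram is an idealization; absolute NRMSE values are
  internally comparable across methods but not comparable to scanner data.
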
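"""Unrolled splitting reconstruction as a recurrent network.

The iterative loop of :mod:`fbsem.recon` is unrolled into
``N = N_it x N_sub`` reconstruction states. Each state replaces the
model-based regularization step by a small residual learning unit

    x_Reg = ReLU(x + unit(x [, MR]))

where ``unit`` is a 5-layer CNN (3x3 kernels; layers 1-4 with 32 filters,
layer 5 with 1; batch normalization after every convolution; ReLU between
hidden layers), then applies the non-trainable ordered-subset EM update and
the quadratic fusion with ``delta = 1/(gamma s^(m))``, where gamma is a
trainable scalar kept positive by parameterizing its logarithm. One copy of
all parameters (d = 28612 in PET-only mode) is shared across every state.

Training minimizes the mean squared error between the unrolled output and
the noise-free reference over the dataset, with Adam. Backpropagation passes
only through the regularization and fusion computations: the EM update is
treated as a fixed operation, so no gradient flows through it — the gradient
reaching a state's input comes solely from the residual unit's input branch.
All forward/backward passes are plain numpy (see :mod:`fbsem._nnops`) and
are finite-difference checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nnops import (
    Adam,
    bn_backward,
    bn_forward,
    conv3_backward,
    conv3_forward,
    relu_backward,
    relu_forward,
)
from .grids import EmissionImage
from .recon import em_update

__all__ = [
    "NetParams",
    "TrainConfig",
    "build_unit",
    "count_parameters",
    "reg_step_net",
    "unrolled_forward",
    "train",
    "infer",
]

N_HIDDEN = 32
N_LAYERS = 5


@dataclass
class NetParams:
    """Trainable parameters and BN running statistics of the learning unit."""

    params: dict[str, np.ndarray]
    state: dict[str, np.ndarray]
    input_mode: str = "pet"  # "pet" | "petmr"

    @property
    def gamma(self) -> float:
        """The fusion weight, always positive."""
        return float(np.exp(self.params["log_gamma"]))


@dataclass
class TrainConfig:
    """Training protocol; defaults follow the reference protocol
    (Adam, 50 epochs, 10 mini-batches per epoch, learning rate 0.05)."""

    epochs: int = 50
    n_minibatches: int = 10
    learning_rate: float = 0.05
    seed: int = 0
    input_mode: str = "pet"
    n_iterations: int = 10

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_mode not in ("pet", "petmr"):
            raise ValueError("input_mode must be 'pet' or 'petmr'")


def _layer_channels(input_mode: str) -> list[tuple[int, int]]:
    c_in = 1 if input_mode == "pet" else 2
    chans = [(c_in, N_HIDDEN)]
    chans += [(N_HIDDEN, N_HIDDEN)] * (N_LAYERS - 2)
    chans += [(N_HIDDEN, 1)]
    return chans


def build_unit(input_mode: str = "pet", seed: int = 0) -> NetParams:
    """Initialize the residual learning unit (He-normal convolutions, unit BN
    scale, gamma initialized at 1 on the log scale)."""
    if input_mode not in ("pet", "petmr"):
        raise ValueError("input_mode must be 'pet' or 'petmr'")
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    state: dict[str, np.ndarray] = {}
    for l, (cin, cout) in enumerate(_layer_channels(input_mode)):
        std = np.sqrt(2.0 / (cin * 9))
        params[f"conv{l}_W"] = rng.normal(0.0, std, size=(cout, cin, 3, 3))
        params[f"conv{l}_b"] = np.zeros(cout)
        params[f"bn{l}_g"] = np.ones(cout)
        params[f"bn{l}_b"] = np.zeros(cout)
        state[f"bn{l}_mean"] = np.zeros(cout)
        state[f"bn{l}_var"] = np.ones(cout)
    params["log_gamma"] = np.zeros(())
    return NetParams(params, state, input_mode)


def count_parameters(net: NetParams) -> int:
    """Number of trainable scalars (convolutions, biases, BN affines, gamma)."""
    return int(sum(np.asarray(v).size for v in net.params.values()))


# ------------------------------------------------------------------ unit pass
def _unit_forward(net: NetParams, x_pet: np.ndarray, mr: np.ndarray | None, training: bool):
    """x_Reg = ReLU(x + unit(x [, mr])) on (B, 1, H, W) tensors."""
    p, s = net.params, net.state
    h = x_pet if mr is None else np.concatenate([x_pet, mr], axis=1)
    caches = []
    for l in range(N_LAYERS):
        h, c_cache = conv3_forward(h, p[f"conv{l}_W"], p[f"conv{l}_b"])
        h, b_cache = bn_forward(
            h, p[f"bn{l}_g"], p[f"bn{l}_b"], s[f"bn{l}_mean"], s[f"bn{l}_var"], training
        )
        if l < N_LAYERS - 1:
            h, r_mask = relu_forward(h)
        else:
            r_mask = None
        caches.append((c_cache, b_cache, r_mask))
    out, f_mask = relu_forward(x_pet + h)
    return out, (caches, f_mask)


def _unit_backward(net: NetParams, dout: np.ndarray, cache, grads: dict) -> np.ndarray:
    """Accumulate parameter gradients; return the gradient w.r.t. the PET input."""
    p = net.params
    caches, f_mask = cache
    d = relu_backward(dout, f_mask)
    dx_pet = d.copy()  # residual branch
    dh = d
    for l in reversed(range(N_LAYERS)):
        c_cache, b_cache, r_mask = caches[l]
        if r_mask is not None:
            dh = relu_backward(dh, r_mask)
        dh, dg, dbb = bn_backward(dh, b_cache)
        grads[f"bn{l}_g"] += dg
        grads[f"bn{l}_b"] += dbb
        dh, dW, dcb = conv3_backward(dh, p[f"conv{l}_W"], c_cache)
        grads[f"conv{l}_W"] += dW
        grads[f"conv{l}_b"] += dcb
    dx_pet += dh[:, :1]  # unit's PET input channel
    return dx_pet


def reg_step_net(
    net: NetParams, x: np.ndarray, mr: np.ndarray | None = None, training: bool = False
) -> np.ndarray:
    """The learned regularization step on a single 2D image (or batch)."""
    single = x.ndim == 2
    xb = x[None, None] if single else x
    mrb = None
    if mr is not None:
        mrb = mr[None, None] if single else mr
    if mrb is not None and mrb.shape != xb.shape:
        raise ValueError("MR shape does not match the PET image")
    out, _ = _unit_forward(net, xb, mrb, training)
    return out[0, 0] if single else out


# -------------------------------------------------------------- unrolled chain
def _fuse_forward(x_em, x_reg, delta):
    b = 1.0 - delta * x_reg
    disc = np.sqrt(b * b + 4.0 * delta * x_em)
    out = 2.0 * x_em / np.maximum(b + disc, 1e-300)
    return out, (x_em, x_reg, delta, b, disc)


def _fuse_backward(dout, cache):
    """VJPs of the fusion w.r.t. x_reg and delta (x_em held fixed)."""
    x_em, x_reg, delta, b, disc = cache
    denom = np.maximum(b + disc, 1e-300)
    disc_s = np.maximum(disc, 1e-300)
    A = 2.0 * x_em / (denom * denom)
    d_reg = dout * A * delta * (1.0 + b / disc_s)
    d_delta = dout * A * (x_reg - (2.0 * x_em - b * x_reg) / disc_s)
    zero = x_em <= 0.0
    d_reg[zero] = 0.0
    d_delta[zero] = 0.0
    return d_reg, d_delta


def _unrolled_states(net, records, n_iterations, training, keep_cache):
    """Run the unrolled chain over a mini-batch; optionally keep state caches."""
    B = len(records)
    models = [r.model for r in records]
    n_sub = models[0].n_subsets
    H, W = models[0].image_shape
    mr = None
    if net.input_mode == "petmr":
        mr = np.stack([r.sample.mr for r in records])[:, None]
    gamma = net.gamma
    # per-sample, per-subset delta = 1/(gamma s^(m)); zero-sensitivity voxels
    # never leave zero (EM yields 0 there and the fusion VJPs vanish with it)
    deltas = [
        np.stack([1.0 / (gamma * np.maximum(m.sensitivity(sub), 1e-12)) for m in models])[
            :, None
        ]
        for sub in range(n_sub)
    ]
    x = np.ones((B, 1, H, W))
    states = []
    for _ in range(n_iterations):
        for sub in range(n_sub):
            x_reg, u_cache = _unit_forward(net, x, mr, training)
            x_em = np.stack(
                [em_update(models[b], records[b].sinogram, x[b, 0], sub) for b in range(B)]
            )[:, None]
            x, f_cache = _fuse_forward(x_em, x_reg, deltas[sub])
            if not np.all(np.isfinite(x)):
                raise FloatingPointError("non-finite image in the unrolled chain")
            if keep_cache:
                states.append((u_cache, f_cache))
    return x, states


def _unrolled_backward(net, dx, states, grads):
    """Backpropagate through the chain; EM updates are constant blocks, so the
    recurrence into the previous state flows only through the unit input."""
    for u_cache, f_cache in reversed(states):
        d_reg, d_delta = _fuse_backward(dx, f_cache)
        delta = f_cache[2]
        grads["log_gamma"] += -np.sum(d_delta * delta)  # d(delta)/d(log gamma) = -delta
        dx = _unit_backward(net, d_reg, u_cache, grads)
    return grads


def unrolled_forward(
    net: NetParams,
    model,
    sinogram,
    mr: np.ndarray | None = None,
    n_iterations: int = 10,
    training: bool = False,
) -> np.ndarray:
    """Reconstruct one sinogram with the unrolled network (inference by
    default: BN uses running statistics)."""

    class _Rec:
        pass

    rec = _Rec()
    rec.model = model
    rec.sinogram = sinogram
    rec.sample = _Rec()
    rec.sample.mr = mr
    if net.input_mode == "petmr" and mr is None:
        raise ValueError("petmr mode requires an MR image")
    x, _ = _unrolled_states(net, [rec], n_iterations, training, keep_cache=False)
    return x[0, 0]


def train(records, config: TrainConfig) -> tuple[NetParams, list[float]]:
    """Train the unrolled network on paired (sinogram, reference) records.

    Minimizes the mean squared error between the unrolled output and the
    reference with Adam; deterministic given ``config.seed``. Returns the
    trained parameters and the per-epoch loss history.
    """
    if not records:
        raise ValueError("empty training set")
    net = build_unit(config.input_mode, seed=config.seed)
    opt = Adam(net.params.keys(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history: list[float] = []
    refs_all = [r.reference.data for r in records]
    for _ in range(config.epochs):
        order = rng.permutation(len(records))
        losses = []
        for batch in np.array_split(order, min(config.n_minibatches, len(records))):
            if batch.size == 0:
                continue
            recs = [records[i] for i in batch]
            x, states = _unrolled_states(
                net, recs, config.n_iterations, training=True, keep_cache=True
            )
            refs = np.stack([refs_all[i] for i in batch])[:, None]
            resid = x - refs
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}, gamma={net.gamma:.3g})"
                )
            grads = {k: np.zeros_like(v) for k, v in net.params.items()}
            _unrolled_backward(net, 2.0 * resid / resid.size, states, grads)
            opt.step(net.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history


def infer(net: NetParams, record, n_iterations: int = 10) -> EmissionImage:
    """Reconstruct one dataset record with a trained network."""
    mr = record.sample.mr if net.input_mode == "petmr" else None
    img = unrolled_forward(
        net, record.model, record.sinogram, mr=mr, n_iterations=n_iterations
    )
    return EmissionImage(img, record.model.geometry.image_spacing_mm)
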
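"""3D convolutional dose-prediction surrogate.

A fully-convolutional encoder-decoder that maps a voxel anatomy feature map
(relative electron density) to a predicted dose grid. The default
architecture reproduces, layer by layer, the published parameter counts of
the reference configuration: 3x3x3 no-bias convolutions (1,728 / 221,184 /
27,648 weights), 3x3x1 no-bias convolution (73,728), batch-norm stages
counted as 4 x channels (scale, offset, tracked mean, tracked variance:
256 / 512 / 256 / 128), a 2x2x4 stride-2 transposed convolution (32,768)
and a final biased 3x3x1 convolution (289). Being fully convolutional the
network accepts any cubic input (16^3 for tests, 64^3 in the production
default).

Everything here — forward, backward, Adam/SGD, batch norm, dropout — is
implemented on numpy arrays with layout ``(batch, channels, z, y, x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .transport import DoseGrid

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "LossConfig",
    "TrainingConfig",
    "TrainedModel",
    "reference_architecture",
    "build_network",
    "composite_loss",
    "train",
    "predict_dose",
    "mc_dropout_uncertainty",
    "SGD",
    "Adam",
]


# ---------------------------------------------------------------------------
# Specs and configs
# ---------------------------------------------------------------------------

@dataclass
class LayerSpec:
    """One layer descriptor: kind in {input, conv, batchnorm, maxpool,
    transposed_conv, dropout}, with kernel/stride/padding in (z, y, x)."""

    kind: str
    out_channels: int = 0
    kernel: tuple[int, int, int] = (1, 1, 1)
    stride: tuple[int, int, int] = (1, 1, 1)
    padding: tuple[int, int, int] = (0, 0, 0)
    bias: bool = False
    activation: str = "-"  # -, relu, linear


@dataclass
class ArchitectureSpec:
    layers: list
    input_shape: tuple[int, int, int, int] = (64, 64, 64, 1)  # (z, y, x, channels)

    def parameter_counts(self) -> list[int]:
        """Closed-form learnable+state parameter count per layer."""
        counts = []
        in_c = self.input_shape[3]
        for layer in self.layers:
            if layer.kind == "input":
                counts.append(0)
            elif layer.kind == "conv":
                n = int(np.prod(layer.kernel)) * in_c * layer.out_channels
                if layer.bias:
                    n += layer.out_channels
                counts.append(n)
                in_c = layer.out_channels
            elif layer.kind == "transposed_conv":
                counts.append(int(np.prod(layer.kernel)) * in_c * layer.out_channels)
                in_c = layer.out_channels
            elif layer.kind == "batchnorm":
                counts.append(4 * in_c)  # scale, offset, tracked mean, tracked var
            elif layer.kind in ("maxpool", "dropout"):
                counts.append(0)
            else:
                raise ValueError(f"unknown layer kind {layer.kind!r}")
        return counts


def reference_architecture(
    input_shape: tuple[int, int, int, int] = (64, 64, 64, 1),
    with_dropout: bool = True,
) -> ArchitectureSpec:
    """The default encoder-decoder configuration (counts are the contract)."""
    layers = [
        LayerSpec("input"),
        LayerSpec("conv", 64, (3, 3, 3), padding=(1, 1, 1), activation="relu"),
        LayerSpec("batchnorm"),
        LayerSpec("maxpool", kernel=(2, 2, 2), stride=(2, 2, 2)),
        LayerSpec("conv", 128, (3, 3, 3), padding=(1, 1, 1), activation="relu"),
        LayerSpec("batchnorm"),
        LayerSpec("conv", 64, (3, 3, 1), padding=(1, 1, 0), activation="relu"),
        LayerSpec("batchnorm"),
    ]
    if with_dropout:
        layers.append(LayerSpec("dropout"))
    layers += [
        LayerSpec(
            "transposed_conv", 32, (2, 2, 4), stride=(2, 2, 2), padding=(0, 0, 1),
            activation="relu",
        ),
        LayerSpec("conv", 32, (3, 3, 3), padding=(1, 1, 1), activation="relu"),
        LayerSpec("batchnorm"),
        LayerSpec("conv", 1, (3, 3, 1), padding=(1, 1, 0), bias=True, activation="linear"),
    ]
    return ArchitectureSpec(layers=layers, input_shape=input_shape)


@dataclass
class LossConfig:
    """Composite objective: mse_weight*MSE + mae_weight*MAE + lambda*R(theta),
    with R the L2 norm of all weights."""

    mse_weight: float = 1.0
    mae_weight: float = 1.0
    lam: float = 1e-4
    regularizer: str = "L2"

    def __post_init__(self) -> None:
        if self.mse_weight < 0 or self.mae_weight < 0 or self.lam < 0:
            raise ValueError("loss weights and lambda must be >= 0")
        if self.regularizer != "L2":
            raise ValueError("only the L2 regularizer is supported")


@dataclass
class TrainingConfig:
    """Training hyperparameters; defaults follow the reference configuration."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    validation_split: float = 0.2
    optimizer: str = "adam"       # adam | sgd | sgd_momentum
    momentum: float = 0.9
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_split < 1.0):
            raise ValueError("validation_split must lie in (0, 1)")
        if self.optimizer not in ("adam", "sgd", "sgd_momentum"):
            raise ValueError("optimizer must be adam, sgd or sgd_momentum")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv3D:
    """Stride-1 3D convolution with symmetric zero padding."""

    def __init__(self, in_c: int, spec: LayerSpec, rng: np.random.Generator, zero_init: bool = False):
        k = spec.kernel
        fan_in = in_c * int(np.prod(k))
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.W = rng.standard_normal((spec.out_channels, in_c, *k)) * scale
        self.b = np.zeros(spec.out_channels) if spec.bias else None
        self.pad = spec.padding
        self.spec = spec
        self._x_pad: Optional[np.ndarray] = None

    @property
    def params(self) -> list:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _cols(self, x_pad_1: np.ndarray) -> np.ndarray:
        # (C, Zp, Yp, Xp) -> (Z*Y*X, C*kz*ky*kx)
        k = self.W.shape[2:]
        v = sliding_window_view(x_pad_1, k, axis=(1, 2, 3))  # (C, Z, Y, X, kz, ky, kx)
        v = v.transpose(1, 2, 3, 0, 4, 5, 6)
        return v.reshape(-1, self.W.shape[1] * int(np.prod(k)))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pz, py, px = self.pad
        x_pad = np.pad(x, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
        if train:
            self._x_pad = x_pad
        B = x.shape[0]
        O = self.W.shape[0]
        out_spatial = x.shape[2:]
        Wm = self.W.reshape(O, -1)
        out = np.empty((B, O, *out_spatial))
        for i in range(B):
            y = self._cols(x_pad[i]) @ Wm.T
            out[i] = y.T.reshape(O, *out_spatial)
        if self.b is not None:
            out += self.b[None, :, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list]:
        assert self._x_pad is not None
        B, O = dout.shape[:2]
        spatial = dout.shape[2:]
        Wm = self.W.reshape(O, -1)
        dW = np.zeros_like(Wm)
        for i in range(B):
            dmat = dout[i].reshape(O, -1)  # (O, P)
            dW += dmat @ self._cols(self._x_pad[i])
        dW = dW.reshape(self.W.shape)
        db = dout.sum(axis=(0, 2, 3, 4)) if self.b is not None else None
        # dx = same-padded correlation of dout with the flipped, swapped kernel
        Wn = self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)  # (C, O, k)
        k = Wn.shape[2:]
        pads = tuple(ks - 1 - p for ks, p in zip(k, self.pad))
        dz = np.pad(dout, ((0, 0), (0, 0), (pads[0],) * 2, (pads[1],) * 2, (pads[2],) * 2))
        C = Wn.shape[0]
        Wnm = Wn.reshape(C, -1)
        dx = np.empty((B, C, *spatial))
        for i in range(B):
            v = sliding_window_view(dz[i], k, axis=(1, 2, 3)).transpose(1, 2, 3, 0, 4, 5, 6)
            cols = v.reshape(-1, Wnm.shape[1])
            dx[i] = (cols @ Wnm.T).T.reshape(C, *spatial)
        self._x_pad = None
        grads = [dW] + ([db] if db is not None else [])
        return dx, grads


class _TransposedConv3D:
    """Stride-2 transposed convolution (learned upsampler), no bias."""

    def __init__(self, in_c: int, spec: LayerSpec, rng: np.random.Generator):
        k = spec.kernel
        fan_in = in_c * int(np.prod(k))
        self.W = rng.standard_normal((in_c, spec.out_channels, *k)) * np.sqrt(2.0 / fan_in)
        self.stride = spec.stride
        self.pad = spec.padding
        self.spec = spec
        self._x: Optional[np.ndarray] = None

    @property
    def params(self) -> list:
        return [self.W]

    def _full_shape(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        k = self.W.shape[2:]
        return tuple((n - 1) * s + ks for n, s, ks in zip(spatial, self.stride, k))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        B, C = x.shape[:2]
        O = self.W.shape[1]
        spatial = x.shape[2:]
        full = self._full_shape(spatial)
        out = np.zeros((B, O, *full))
        kz, ky, kx = self.W.shape[2:]
        sz, sy, sx = self.stride
        for a in range(kz):
            for b_ in range(ky):
                for c in range(kx):
                    contrib = np.einsum("bczyx,co->bozyx", x, self.W[:, :, a, b_, c])
                    out[
                        :, :,
                        a : a + sz * spatial[0] : sz,
                        b_ : b_ + sy * spatial[1] : sy,
                        c : c + sx * spatial[2] : sx,
                    ] += contrib
        pz, py, px = self.pad
        sl = tuple(
            slice(p, f - p) if p else slice(None) for p, f in zip(self.pad, full)
        )
        return out[(slice(None), slice(None)) + sl]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list]:
        assert self._x is not None
        x = self._x
        spatial = x.shape[2:]
        full = self._full_shape(spatial)
        pz, py, px = self.pad
        dfull = np.zeros((dout.shape[0], dout.shape[1], *full))
        sl = tuple(slice(p, f - p) if p else slice(None) for p, f in zip(self.pad, full))
        dfull[(slice(None), slice(None)) + sl] = dout
        kz, ky, kx = self.W.shape[2:]
        sz, sy, sx = self.stride
        dx = np.zeros_like(x)
        dW = np.zeros_like(self.W)
        for a in range(kz):
            for b_ in range(ky):
                for c in range(kx):
                    dslice = dfull[
                        :, :,
                        a : a + sz * spatial[0] : sz,
                        b_ : b_ + sy * spatial[1] : sy,
                        c : c + sx * spatial[2] : sx,
                    ]
                    dx += np.einsum("bozyx,co->bczyx", dslice, self.W[:, :, a, b_, c])
                    dW[:, :, a, b_, c] += np.einsum("bczyx,bozyx->co", x, dslice)
        self._x = None
        return dx, [dW]


class _BatchNorm3D:
    """Per-channel batch normalization with tracked running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list]:
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        g = self.gamma[None, :, None, None, None]
        dxhat = dout * g
        dx = (
            inv_std[None, :, None, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)[None, :, None, None, None]
                - xhat * (dxhat * xhat).sum(axis=axes)[None, :, None, None, None]
            )
        )
        self._cache = None
        return dx, [dgamma, dbeta]


class _MaxPool3D:
    """2x2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, Z, Y, X = x.shape
        v = x.reshape(B, C, Z // 2, 2, Y // 2, 2, X // 2, 2)
        v = v.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, Z // 2, Y // 2, X // 2, 8)
        arg = v.argmax(axis=-1)
        out = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list]:
        arg, shape = self._cache
        B, C, Z, Y, X = shape
        dv = np.zeros((B, C, Z // 2, Y // 2, X // 2, 8))
        np.put_along_axis(dv, arg[..., None], dout[..., None], axis=-1)
        dx = (
            dv.reshape(B, C, Z // 2, Y // 2, X // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, Z, Y, X)
        )
        self._cache = None
        return dx, []


class _Dropout:
    """Inverted dropout; active during training and MC-dropout inference."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if not train or self.rate <= 0 or rng is None:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list]:
        if self._mask is None:
            return dout, []
        dx = dout * self._mask
        self._mask = None
        return dx, []


class _ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list]:
        dx = dout * self._mask
        self._mask = None
        return dx, []


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class TrainedModel:
    """A built (possibly trained) surrogate network.

    ``theta`` exposes all learnable parameters as a flat list of arrays;
    ``history`` holds per-epoch train/validation losses.
    """

    def __init__(self, architecture: ArchitectureSpec, seed: int = 0, dropout_rate: float = 0.3):
        self.architecture = architecture
        self.seed = seed
        self.dropout_rate = dropout_rate
        self.history: list[dict] = []
        rng = np.random.default_rng(seed)
        self._ops: list = []
        in_c = architecture.input_shape[3]
        specs = architecture.layers
        conv_specs = [s for s in specs if s.kind in ("conv", "transposed_conv")]
        last_conv = conv_specs[-1] if conv_specs else None
        for i, spec in enumerate(specs):
            if spec.kind == "input":
                continue
            if spec.kind == "conv":
                if spec.out_channels < 1:
                    raise ValueError(f"layer {i}: conv needs out_channels >= 1")
                zero_init = spec is last_conv  # untrained network predicts zero dose
                self._ops.append(_Conv3D(in_c, spec, rng, zero_init=zero_init))
                in_c = spec.out_channels
            elif spec.kind == "transposed_conv":
                self._ops.append(_TransposedConv3D(in_c, spec, rng))
                in_c = spec.out_channels
            elif spec.kind == "batchnorm":
                self._ops.append(_BatchNorm3D(in_c))
            elif spec.kind == "maxpool":
                self._ops.append(_MaxPool3D())
            elif spec.kind == "dropout":
                self._ops.append(_Dropout(dropout_rate))
            else:
                raise ValueError(f"unknown layer kind {spec.kind!r}")
            if spec.activation == "relu":
                self._ops.append(_ReLU())

    # -- parameters -------------------------------------------------------
    @property
    def theta(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for op in self._ops:
            out.extend(op.params)
        return out

    @property
    def weights(self) -> list[np.ndarray]:
        """Weight tensors subject to L2 regularization (no BN scale/offset, no bias)."""
        out = []
        for op in self._ops:
            if isinstance(op, (_Conv3D, _TransposedConv3D)):
                out.append(op.W)
        return out

    def parameter_count(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.theta) + sum(
            2 * op.running_mean.size for op in self._ops if isinstance(op, _BatchNorm3D)
        )

    def parameter_counts(self) -> list[int]:
        return self.architecture.parameter_counts()

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, dropout_rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for op in self._ops:
            if isinstance(op, _Dropout):
                x = op.forward(x, train=dropout_rng is not None, rng=dropout_rng)
            else:
                x = op.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        grads_rev: list[np.ndarray] = []
        for op in reversed(self._ops):
            dout, g = op.backward(dout)
            grads_rev.extend(reversed(g))
        return list(reversed(grads_rev))

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {}
        for i, p in enumerate(self.theta):
            arrays[f"theta_{i}"] = p
        for i, op in enumerate(self._ops):
            if isinstance(op, _BatchNorm3D):
                arrays[f"bn_{i}_mean"] = op.running_mean
                arrays[f"bn_{i}_var"] = op.running_var
        manifest = {
            "input_shape": list(self.architecture.input_shape),
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
            "layers": [
                {
                    "kind": s.kind, "out_channels": s.out_channels,
                    "kernel": list(s.kernel), "stride": list(s.stride),
                    "padding": list(s.padding), "bias": s.bias,
                    "activation": s.activation,
                }
                for s in self.architecture.layers
            ],
            "history": self.history,
        }
        np.savez_compressed(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            spec = ArchitectureSpec(
                layers=[
                    LayerSpec(
                        kind=L["kind"], out_channels=L["out_channels"],
                        kernel=tuple(L["kernel"]), stride=tuple(L["stride"]),
                        padding=tuple(L["padding"]), bias=L["bias"],
                        activation=L["activation"],
                    )
                    for L in manifest["layers"]
                ],
                input_shape=tuple(manifest["input_shape"]),
            )
            model = cls(spec, seed=manifest["seed"], dropout_rate=manifest["dropout_rate"])
            for i, p in enumerate(model.theta):
                p[...] = z[f"theta_{i}"]
            for i, op in enumerate(model._ops):
                if isinstance(op, _BatchNorm3D):
                    op.running_mean[...] = z[f"bn_{i}_mean"]
                    op.running_var[...] = z[f"bn_{i}_var"]
            model.history = manifest["history"]
        return model


def build_network(
    spec: Optional[ArchitectureSpec] = None, seed: int = 0, dropout_rate: float = 0.3
) -> tuple[TrainedModel, list[int]]:
    """Build an untrained network and return it with per-layer parameter counts.

    Raises when consecutive layers cannot be chained (spatial shape
    bookkeeping), naming both layers.
    """
    spec = spec or reference_architecture()
    shape = np.asarray(spec.input_shape[:3], dtype=int)
    prev_name = "input"
    for i, layer in enumerate(spec.layers):
        if layer.kind == "maxpool":
            if np.any(shape % 2):
                raise ValueError(
                    f"shape mismatch between layers {prev_name!r} and "
                    f"{layer.kind!r} (#{i}): {tuple(shape)} not divisible by 2"
                )
            shape = shape // 2
        elif layer.kind == "transposed_conv":
            shape = (shape - 1) * np.asarray(layer.stride) + np.asarray(layer.kernel) - 2 * np.asarray(layer.padding)
        elif layer.kind == "conv":
            out = shape + 2 * np.asarray(layer.padding) - (np.asarray(layer.kernel) - 1)
            if np.any(out != shape):
                raise ValueError(
                    f"shape mismatch between layers {prev_name!r} and conv (#{i}): "
                    f"padding {layer.padding} does not preserve {tuple(shape)}"
                )
        prev_name = layer.kind
        if np.any(shape < 1):
            raise ValueError(f"layer {layer.kind!r} (#{i}) collapses the spatial shape")
    model = TrainedModel(spec, seed=seed, dropout_rate=dropout_rate)
    return model, spec.parameter_counts()


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def composite_loss(
    pred: np.ndarray,
    true: np.ndarray,
    theta: Sequence[np.ndarray] = (),
    config: Optional[LossConfig] = None,
) -> tuple[float, dict]:
    """MSE+MAE composite loss with L2 penalty; returns (total, components)."""
    config = config or LossConfig()
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    diff = pred - true
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    reg = float(sum(np.sum(p**2) for p in theta))
    total = config.mse_weight * mse + config.mae_weight * mae + config.lam * reg
    return total, {"mse": mse, "mae": mae, "l2": reg, "total": total}


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    """Plain / momentum gradient descent: theta <- theta - lr * grad."""

    def __init__(self, lr: float = 0.001, momentum: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self._v: Optional[list[np.ndarray]] = None

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        if self.momentum == 0.0:
            for p, g in zip(params, grads):
                p -= self.lr * g
            return
        if self._v is None:
            self._v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._v):
            v *= self.momentum
            v += g
            p -= self.lr * v


class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = None
        self._v = None
        self._t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1 - self.beta1**self._t
        b2t = 1 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def _make_optimizer(cfg: TrainingConfig):
    if cfg.optimizer == "adam":
        return Adam(lr=cfg.learning_rate)
    if cfg.optimizer == "sgd_momentum":
        return SGD(lr=cfg.learning_rate, momentum=cfg.momentum)
    return SGD(lr=cfg.learning_rate)


def train(
    model: TrainedModel,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    training_config: Optional[TrainingConfig] = None,
    loss_config: Optional[LossConfig] = None,
) -> TrainedModel:
    """Train the surrogate on (anatomy features, dose) volume pairs.

    Gradient of the composite objective: ``d/dpred = 2*mse_w*(pred-true)/n
    + mae_w*sign(pred-true)/n`` plus ``2*lambda*W`` on the regularized
    weights. History records per-epoch mean train and validation losses.
    Bit-reproducible for a fixed seed.
    """
    tcfg = training_config or TrainingConfig()
    lcfg = loss_config or LossConfig()
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(tcfg.seed)
    idx = rng.permutation(len(dataset))
    n_val = max(1, int(round(len(dataset) * tcfg.validation_split))) if len(dataset) > 1 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = idx, idx[:0]
    opt = _make_optimizer(tcfg)

    def as_batch(pairs):
        xs = np.stack([np.asarray(p[0], dtype=float)[None] for p in pairs])  # (B,1,z,y,x)
        ys = np.stack([np.asarray(p[1], dtype=float)[None] for p in pairs])
        return xs, ys

    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = [dataset[i] for i in order[start : start + tcfg.batch_size]]
            xb, yb = as_batch(batch)
            pred = model.forward(xb, train=True, dropout_rng=rng)
            total, comps = composite_loss(pred, yb, model.weights, lcfg)
            losses.append(total)
            n = pred.size
            dpred = (
                2.0 * lcfg.mse_weight * (pred - yb) / n
                + lcfg.mae_weight * np.sign(pred - yb) / n
            )
            grads = model.backward(dpred)
            # add L2 gradient on the regularized weight tensors
            if lcfg.lam > 0:
                wset = {id(w) for w in model.weights}
                for p, g in zip(model.theta, grads):
                    if id(p) in wset:
                        g += 2.0 * lcfg.lam * p
            opt.step(model.theta, grads)
        val_loss = float("nan")
        if val_idx.size:
            xv, yv = as_batch([dataset[i] for i in val_idx])
            pv = model.forward(xv, train=False)
            val_loss, _ = composite_loss(pv, yv, model.weights, lcfg)
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": float(val_loss)}
        )
    return model


def predict_dose(model: TrainedModel, phantom_features: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> DoseGrid:
    """Predict a dose grid from an anatomy feature volume (z, y, x).

    The output spatial shape equals the input shape; negativity is clamped.
    """
    x = np.asarray(phantom_features, dtype=float)
    if x.ndim != 3:
        raise ValueError("phantom_features must be a 3D (z, y, x) volume")
    out = model.forward(x[None, None], train=False)[0, 0]
    return DoseGrid(dose=np.clip(out, 0, None), spacing=tuple(spacing))


def mc_dropout_uncertainty(
    model: TrainedModel,
    phantom_features: np.ndarray,
    n_passes: int = 50,
    seed: int = 0,
) -> dict:
    """Monte Carlo dropout predictive uncertainty.

    Runs ``n_passes`` stochastic forward passes with dropout active at
    inference, returning the per-voxel mean, sample sd (ddof=1) and the
    2.5/97.5 percentile interval.
    """
    if n_passes < 2:
        raise ValueError("n_passes must be >= 2 (sd undefined otherwise)")
    if not any(isinstance(op, _Dropout) for op in model._ops):
        raise ValueError("model contains no dropout layers")
    x = np.asarray(phantom_features, dtype=float)[None, None]
    rng = np.random.default_rng(seed)
    passes = np.stack(
        [np.clip(model.forward(x, train=False, dropout_rng=rng)[0, 0], 0, None) for _ in range(n_passes)]
    )
    return {
        "mean": passes.mean(axis=0),
        "sd": passes.std(axis=0, ddof=1),
        "interval_low": np.percentile(passes, 2.5, axis=0),
        "interval_high": np.percentile(passes, 97.5, axis=0),
        "n_passes": n_passes,
    }
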
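"""Micro-network (3-layer 3-D CNN) and comparator U-net.

The micro-network is deliberately tiny: three stride-1, zero-padded 3-D
convolutions (default 32 kernels of width 5, 32 of width 3, and one 1x1x1
output kernel), sigmoid activations on the hidden layers and an ELU on
the output. Applied to four input channels that is 43 745 trainable
parameters and a receptive field of 7 voxels — orders of magnitude fewer
parameters than training voxels, which is what makes it robust to
training on a single subject.

The four input channels are the low-count reconstruction without
resolution modeling, the low-count reconstruction with RM, the T1-like
guide, and a guided-NLM filtering of the RM reconstruction. The first
three are standardized to zero mean / unit variance; the NLM channel is
computed from the already-standardized RM and T1 channels and passed on
without re-standardization. Predictions are rescaled by a single
constant so the total intensity matches the pre-normalization primary
PET channel.

The comparator U-net has a 4-level stride-2 encoder, a trilinear-
upsampling decoder with skip concatenations, ELU activations throughout,
and a residual connection that adds the NLM input channel to the
decoder's single-channel output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _conv
from ._conv import (apply_activation, activation_grad, conv3d, conv3d_backward,
                    upsample2_linear, upsample2_linear_adjoint)
from .filters import nlm_guided

__all__ = [
    "LayerSpec", "MuNetSpec", "UNetSpec", "WeightSet", "NormState",
    "MuNet", "UNet", "layer_apply", "count_parameters", "receptive_field",
    "he_init", "build_munet", "build_unet", "normalize_inputs", "rescale_output",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("mlem", "mlem_rm", "t1", "nlm_of_rm")


@dataclass(frozen=True)
class LayerSpec:
    n_kernels: int
    kernel_width: int
    activation: str = "sigmoid"

    def __post_init__(self):
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.kernel_width < 1 or self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd >= 1")
        if self.activation not in _conv.ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def _default_layers():
    return [LayerSpec(32, 5, "sigmoid"), LayerSpec(32, 3, "sigmoid"), LayerSpec(1, 1, "elu")]


@dataclass(frozen=True)
class MuNetSpec:
    """Stride-1, zero-padded whole-volume CNN specification."""

    in_channels: int = 4
    layers: list[LayerSpec] = field(default_factory=_default_layers)

    def __post_init__(self):
        if not self.layers:
            raise ValueError("need at least one layer")
        if self.layers[-1].n_kernels != 1:
            raise ValueError("last layer must have exactly 1 kernel (single output channel)")


@dataclass(frozen=True)
class UNetSpec:
    """Encoder/decoder comparator network specification."""

    in_channels: int = 4
    encoder_kernels: tuple = (32, 64, 128, 256)
    decoder_kernels: tuple = (128, 64, 32, 1)
    kernel_width: int = 3  # width unconstrained by the 3-layer design; 3^3 standard
    activation: str = "elu"
    residual_channel: int = 3  # NLM input channel index

    def __post_init__(self):
        if len(self.encoder_kernels) != len(self.decoder_kernels):
            raise ValueError("encoder and decoder depths must match")
        if self.decoder_kernels[-1] != 1:
            raise ValueError("final decoder layer must output a single channel")


@dataclass
class WeightSet:
    """Per-layer kernels kappa and biases beta."""

    kernels: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "WeightSet":
        return WeightSet([k.copy() for k in self.kernels], [b.copy() for b in self.biases])


@dataclass
class NormState:
    """Standardization record allowing inversion and output rescaling."""

    offsets: dict
    scales: dict
    primary_total: float      # voxel sum of the raw primary (non-RM) PET channel
    target_scale: float = 1.0  # std of the raw training target (set by the trainer)
    nlm_omega: float = 1.0
    nlm_window: int = 5


def count_parameters(spec: MuNetSpec) -> int:
    """sum_j (n_{j-1} s_j^3 + 1) n_j with n_0 the input channel count."""
    n_prev = spec.in_channels
    total = 0
    for layer in spec.layers:
        total += (n_prev * layer.kernel_width ** 3 + 1) * layer.n_kernels
        n_prev = layer.n_kernels
    return total


def receptive_field(spec: MuNetSpec) -> int:
    """Width (voxels) of the input neighborhood affecting one output voxel."""
    return 1 + sum(layer.kernel_width - 1 for layer in spec.layers)


def he_init(spec: MuNetSpec, seed: int, fan_in: str = "paper") -> WeightSet:
    """He-style normal initialization; biases zero.

    ``fan_in='paper'`` draws kernel weights from N(0, 2/n_{j-1}) — the
    kernel volume is not part of the fan-in. ``fan_in='standard'`` uses
    the conventional N(0, 2/(n_{j-1} s^3)).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4E7]))
    kernels, biases = [], []
    n_prev = spec.in_channels
    for layer in spec.layers:
        fan = n_prev if fan_in == "paper" else n_prev * layer.kernel_width ** 3
        std = np.sqrt(2.0 / fan)
        s = layer.kernel_width
        kernels.append(rng.normal(0.0, std, size=(layer.n_kernels, n_prev, s, s, s))
                       .astype(np.float32))
        biases.append(np.zeros(layer.n_kernels, dtype=np.float32))
        n_prev = layer.n_kernels
    return WeightSet(kernels=kernels, biases=biases)


def layer_apply(inputs: np.ndarray, kernels: np.ndarray, biases: np.ndarray,
                activation: str) -> np.ndarray:
    """One network layer on an unbatched multichannel volume (C, D, H, W)."""
    x = np.asarray(inputs, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("inputs must be (channels, D, H, W)")
    W = np.asarray(kernels, dtype=np.float32)
    if W.shape[1] != x.shape[0]:
        raise ValueError(f"kernels expect {W.shape[1]} channels, input has {x.shape[0]}")
    z = conv3d(x[None], W, np.asarray(biases, dtype=np.float32))[0]
    return apply_activation(z, activation)


class _ConvLayer:
    """Convolution + activation on channels-last activations, with
    cached forward state for backprop."""

    def __init__(self, W: np.ndarray, b: np.ndarray, activation: str, stride: int = 1):
        self.W, self.b = W, b
        self.activation = activation
        self.stride = stride
        self.dW = np.zeros_like(W)
        self.db = np.zeros_like(b)
        self._fast = _conv._FastConv1()
        self._x = self._z = self._a = None

    def forward(self, x_cl: np.ndarray) -> np.ndarray:
        if self.stride == 1:
            z = self._fast.forward(x_cl, self.W, self.b)
        else:
            z = _conv._conv_cl_stride2(x_cl, self.W, self.b)
        a = apply_activation(z, self.activation)
        self._x, self._z, self._a = x_cl, z, a
        return a

    def backward(self, da: np.ndarray, need_dx: bool = True) -> Optional[np.ndarray]:
        dz = da * activation_grad(self._a, self._z, self.activation)
        if self.stride == 1:
            dx, dW, db = self._fast.backward(dz, self._x, self.W, need_dx=need_dx)
        else:
            dx, dW, db = _conv._conv_cl_stride2_backward(dz, self._x, self.W,
                                                         need_dx=need_dx)
        self.dW, self.db = dW, db
        return dx

    def clear_cache(self):
        self._x = self._z = self._a = None
        self._fast.clear_cache()


class _NetBase:
    layers: list[_ConvLayer]

    def parameters(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend([l.W, l.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend([l.dW, l.db])
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> WeightSet:
        return WeightSet([l.W.copy() for l in self.layers],
                         [l.b.copy() for l in self.layers])

    def set_weights(self, ws: WeightSet) -> None:
        for l, W, b in zip(self.layers, ws.kernels, ws.biases):
            if l.W.shape != W.shape:
                raise ValueError("weight shape mismatch")
            l.W[...] = W
            l.b[...] = b

    _cl_cache: Optional[dict] = None

    def clear_caches(self):
        for l in self.layers:
            l.clear_cache()
        self._cl_cache = None

    def enable_input_col_cache(self):
        """Cache per-input conversions and the first layer's im2col matrix
        (training inputs are fixed across epochs)."""
        self._cl_cache = {}
        if self.layers and self.layers[0].stride == 1:
            self.layers[0]._fast.enable_cache()

    def _to_cl(self, x):
        if self._cl_cache is None:
            return np.ascontiguousarray(
                np.moveaxis(np.asarray(x, dtype=np.float32), 1, -1))
        key = (id(x), x.ctypes.data if isinstance(x, np.ndarray) else None)
        if key not in self._cl_cache:
            while len(self._cl_cache) >= 4:
                self._cl_cache.pop(next(iter(self._cl_cache)))
            self._cl_cache[key] = np.ascontiguousarray(
                np.moveaxis(np.asarray(x, dtype=np.float32), 1, -1))
        return self._cl_cache[key]

    @staticmethod
    def _from_cl(y):
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))


class MuNet(_NetBase):
    """Sequential whole-volume CNN built from a :class:`MuNetSpec`."""

    def __init__(self, spec: MuNetSpec, weights: Optional[WeightSet] = None,
                 seed: int = 0, fan_in: str = "paper"):
        self.spec = spec
        ws = weights if weights is not None else he_init(spec, seed, fan_in)
        self.layers = [
            _ConvLayer(W.astype(np.float32).copy(), b.astype(np.float32).copy(),
                       layer.activation)
            for W, b, layer in zip(ws.kernels, ws.biases, spec.layers)
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self._to_cl(x)
        for l in self.layers:
            a = l.forward(a)
        return self._from_cl(a)

    def backward(self, dout: np.ndarray) -> None:
        g = self._to_cl(dout)
        for i in range(len(self.layers) - 1, -1, -1):
            g = self.layers[i].backward(g, need_dx=(i > 0))


class UNet(_NetBase):
    """Encoder/decoder with skip concatenation and NLM-residual output."""

    def __init__(self, spec: UNetSpec, seed: int = 0, fan_in: str = "paper"):
        self.spec = spec
        rng_seed = seed
        k = spec.kernel_width
        enc_in = [spec.in_channels] + list(spec.encoder_kernels[:-1])
        # decoder conv d inputs: upsampled previous decoder/bottleneck channels
        # + the matching encoder (or raw input) skip
        skip_ch = list(spec.encoder_kernels[:-1])[::-1] + [spec.in_channels]
        dec_prev = [spec.encoder_kernels[-1]] + list(spec.decoder_kernels[:-1])
        dec_in = [p + s for p, s in zip(dec_prev, skip_ch)]
        sizes = [(n_out, n_in) for n_in, n_out in zip(enc_in, spec.encoder_kernels)] + \
                [(n_out, n_in) for n_in, n_out in zip(dec_in, spec.decoder_kernels)]
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x0E7]))
        self.layers = []
        for (n_out, n_in) in sizes:
            fan = n_in if fan_in == "paper" else n_in * k ** 3
            W = rng.normal(0.0, np.sqrt(2.0 / fan), size=(n_out, n_in, k, k, k)) \
                .astype(np.float32)
            b = np.zeros(n_out, dtype=np.float32)
            self.layers.append(_ConvLayer(W, b, spec.activation, stride=1))
        self.n_levels = len(spec.encoder_kernels)
        for l in self.layers[:self.n_levels]:
            l.stride = 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        div = 2 ** self.n_levels
        if any(d % div for d in x.shape[2:]):
            raise ValueError(
                f"spatial dims {tuple(x.shape[2:])} must be divisible by {div}; "
                f"zero-pad the volume to the next multiple of {div}")
        xc = self._to_cl(x)
        skips = [xc]
        a = xc
        for l in self.layers[:self.n_levels]:
            a = l.forward(a)
            skips.append(a)
        skips = skips[:-1][::-1]  # deepest encoder output first, raw input last
        self._concat_splits = []
        for l, skip in zip(self.layers[self.n_levels:], skips):
            up = upsample2_linear(a, axes=(1, 2, 3))
            a = np.concatenate([up, skip], axis=-1)
            self._concat_splits.append(up.shape[-1])
            a = l.forward(a)
        rc = self.spec.residual_channel
        return self._from_cl(a + xc[..., rc:rc + 1])

    def backward(self, dout: np.ndarray) -> None:
        g = self._to_cl(dout)
        dres = g[..., 0].copy()
        # dskips, in append order: [grad wrt raw-input skip, grad e1, grad e2, ...]
        dskips = []
        for i in range(len(self.layers) - 1, self.n_levels - 1, -1):
            gcat = self.layers[i].backward(g)
            split = self._concat_splits[i - self.n_levels]
            g = upsample2_linear_adjoint(gcat[..., :split], axes=(1, 2, 3))
            dskips.append(gcat[..., split:])
        dx_skip = dskips[0]
        for i in range(self.n_levels - 1, -1, -1):
            if i < self.n_levels - 1:
                g = g + dskips[i + 1]
            g = self.layers[i].backward(g, need_dx=True)
        # gradient wrt the input (skip + encoder + residual NLM channel paths);
        # kept for gradient checking, inputs themselves are not optimized
        dx = g + dx_skip
        dx[..., self.spec.residual_channel] += dres
        self._dx = self._from_cl(dx)


def build_munet(spec: Optional[MuNetSpec] = None, seed: int = 0,
                fan_in: str = "paper") -> MuNet:
    return MuNet(spec or MuNetSpec(), seed=seed, fan_in=fan_in)


def build_unet(spec: Optional[UNetSpec] = None, seed: int = 0,
               fan_in: str = "paper") -> UNet:
    return UNet(spec or UNetSpec(), seed=seed, fan_in=fan_in)


def normalize_inputs(mlem: np.ndarray, mlem_rm: np.ndarray, t1: np.ndarray, *,
                     nlm_omega: float, nlm_window: int = 5,
                     norm: Optional[NormState] = None):
    """Build the 4-channel network input and its normalization record.

    ``mlem``, ``mlem_rm`` and ``t1`` are standardized to zero mean and
    unit variance. The fourth channel is the guided-NLM filtering of the
    *standardized* RM channel using the *standardized* T1 guide (so
    ``nlm_omega`` lives on the standardized-guide scale) and is not
    re-standardized afterwards. Passing an existing ``norm`` reuses its
    offsets/scales (prediction on new data with training-time statistics
    is deliberately NOT done here — each input set is standardized from
    its own statistics, mirroring per-scan normalization).
    """
    chans = {"mlem": np.asarray(mlem, dtype=np.float64),
             "mlem_rm": np.asarray(mlem_rm, dtype=np.float64),
             "t1": np.asarray(t1, dtype=np.float64)}
    shape = chans["mlem"].shape
    for name, c in chans.items():
        if c.shape != shape:
            raise ValueError(f"channel {name} shape {c.shape} != {shape}")
    if norm is None:
        offsets = {n: float(c.mean()) for n, c in chans.items()}
        scales = {n: float(c.std()) for n, c in chans.items()}
        for n, s in scales.items():
            if s == 0:
                raise ValueError(f"channel {n} is constant; cannot standardize")
        norm = NormState(offsets=offsets, scales=scales,
                         primary_total=float(chans["mlem"].sum()),
                         nlm_omega=float(nlm_omega), nlm_window=int(nlm_window))
    std = {n: (c - norm.offsets[n]) / norm.scales[n] for n, c in chans.items()}
    nlm_chan = nlm_guided(std["mlem_rm"], std["t1"], omega=norm.nlm_omega,
                          window=norm.nlm_window)
    stacked = np.stack([std["mlem"], std["mlem_rm"], std["t1"], nlm_chan]) \
        .astype(np.float32)
    return stacked, norm


def rescale_output(pred: np.ndarray, norm: NormState) -> np.ndarray:
    """Scale a prediction so its total intensity matches the raw primary input."""
    pred = np.asarray(pred, dtype=np.float64)
    if not np.all(np.isfinite(pred)):
        raise ValueError("prediction contains non-finite values")
    total = pred.sum()
    if total == 0:
        raise ValueError("prediction sums to zero; rescale undefined")
    return pred * (norm.primary_total / total)
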
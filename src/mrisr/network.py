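"""Super-resolution network: residual trunk, PCFB, sub-pixel reconstruction.

The generator ``G`` maps a single-channel low-resolution slice to a
single-channel output enlarged by the configured scale factor:

    head conv (1 -> C) + PReLU
      -> n residual blocks (conv -> LayerNorm -> PReLU -> conv, skip add)
      -> trunk conv + global skip from the head output
      -> parameter-free chunking fusion block (PCFB)
      -> reconstruction: [3x3 conv to C*f^2 -> PixelShuffle(f) -> PReLU] per
         upsampling stage, then a 1x1 conv down to one channel.

Scale factors 1-3 use a single upsampling stage; x4 stacks two x2 stages.
PCFB sits between the trunk and the reconstruction head by default and can
additionally be inserted after every residual block
(``ModelConfig.pcfb_every_block``); being parameter-free it never changes
the parameter count either way.

Layers carry their parameters as autodiff leaf tensors; a forward pass on an
ndarray runs pure numpy, a forward pass on a Tensor builds the gradient
graph used by the training loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from typing import Iterator, List, Tuple, Union

import numpy as np

from . import autodiff as ad
from .attention import DEFAULT_LAMBDA, pcfb
from .autodiff import Tensor, parameter

__all__ = [
    "ModelConfig",
    "Module",
    "Conv2d",
    "PReLU",
    "LayerNorm",
    "ResidualBlock",
    "pixel_shuffle",
    "SRNetwork",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters of the generator.

    Defaults follow the SRResNet-style trunk the method builds on: 16
    residual blocks of 64 features, channel chunking ``n = 2``, and the
    standard SimAM regularizer ``lambda = 1e-4``.
    """

    scale_factor: int = 2
    n_chunks: int = 2
    n_res_blocks: int = 16
    n_features: int = 64
    simam_lambda: float = DEFAULT_LAMBDA
    simam_ddof: int = 1
    prelu_init: float = 0.25
    layer_norm_eps: float = 1e-5
    layer_norm_mode: str = "chw"  # "chw": per-sample over (C,H,W); "channel": over C
    use_pcfb: bool = True
    pcfb_every_block: bool = False
    global_skip: bool = True

    def validate(self) -> None:
        problems = []
        if self.scale_factor not in (1, 2, 3, 4):
            problems.append(f"scale_factor must be in {{1,2,3,4}}, got {self.scale_factor}")
        if self.n_features < 1:
            problems.append(f"n_features must be >= 1, got {self.n_features}")
        if self.n_chunks < 1:
            problems.append(f"n_chunks must be >= 1, got {self.n_chunks}")
        if self.n_features % max(self.n_chunks, 1) != 0:
            problems.append(
                f"n_features={self.n_features} not divisible by n_chunks={self.n_chunks}"
            )
        if self.n_res_blocks < 1:
            problems.append(f"n_res_blocks must be >= 1, got {self.n_res_blocks}")
        if self.simam_lambda < 0:
            problems.append(f"simam_lambda must be >= 0, got {self.simam_lambda}")
        if self.simam_ddof not in (0, 1):
            problems.append(f"simam_ddof must be 0 or 1, got {self.simam_ddof}")
        if not 0.0 <= self.prelu_init <= 1.0:
            problems.append(f"prelu_init must lie in [0,1], got {self.prelu_init}")
        if self.layer_norm_eps <= 0:
            problems.append(f"layer_norm_eps must be > 0, got {self.layer_norm_eps}")
        if self.layer_norm_mode not in ("chw", "channel"):
            problems.append(f"layer_norm_mode must be 'chw' or 'channel'")
        if problems:
            raise ValueError("invalid ModelConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        names = {f.name for f in fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in names})
        cfg.validate()
        return cfg


class Module:
    """Tiny container base class: tracks parameters and sub-modules by name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def _register(self, name: str, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor):
            self._params[name] = value
        else:
            raise TypeError(f"cannot register {type(value)}")
        return value

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def init_params(self, rng: np.random.Generator) -> None:
        """Re-draw parameters (Xavier for convolutions, canonical constants
        elsewhere).  Sub-modules are visited in registration order so the
        draw sequence is deterministic."""
        for mod in self._modules.values():
            mod.init_params(rng)

    def __call__(self, x):
        return self.forward(x)


def _xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, padding: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.kernel, self.padding = cin, cout, kernel, padding
        self.weight = self._register("weight", parameter(np.zeros((cout, cin, kernel, kernel))))
        self.bias = self._register("bias", parameter(np.zeros(cout)))
        self.init_params(rng)

    def init_params(self, rng: np.random.Generator) -> None:
        k2 = self.kernel * self.kernel
        self.weight.data = _xavier_uniform(
            rng, self.weight.data.shape, self.cin * k2, self.cout * k2
        )
        self.bias.data = np.zeros(self.cout)

    def forward(self, x: ArrayLike) -> ArrayLike:
        tm = isinstance(x, Tensor)
        w = self.weight if tm else self.weight.data
        b = self.bias if tm else self.bias.data
        return ad.conv2d(x, w, b, padding=self.padding)


class PReLU(Module):
    """Rectifier with one learnable negative-branch slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.channels = channels
        self.init = init
        self.slope = self._register("slope", parameter(np.full(channels, init)))

    def init_params(self, rng: np.random.Generator) -> None:
        self.slope.data = np.full(self.channels, self.init)

    def forward(self, x: ArrayLike) -> ArrayLike:
        tm = isinstance(x, Tensor)
        a = self.slope if tm else self.slope.data
        a = a.reshape(1, self.channels, 1, 1) if tm else a.reshape(1, -1, 1, 1)
        return ad.where(ad.as_array(x) > 0, x, a * x)


class LayerNorm(Module):
    """Per-sample normalization with learnable per-channel scale and shift.

    Statistics are independent of the batch: in ``"chw"`` mode each sample is
    normalized by the mean/variance of all its entries, in ``"channel"`` mode
    each spatial position is normalized across channels.
    """

    def __init__(self, channels: int, eps: float = 1e-5, mode: str = "chw"):
        super().__init__()
        if mode not in ("chw", "channel"):
            raise ValueError(f"unknown LayerNorm mode {mode!r}")
        self.channels, self.eps, self.mode = channels, eps, mode
        self.gamma = self._register("gamma", parameter(np.ones(channels)))
        self.beta = self._register("beta", parameter(np.zeros(channels)))

    def init_params(self, rng: np.random.Generator) -> None:
        self.gamma.data = np.ones(self.channels)
        self.beta.data = np.zeros(self.channels)

    def forward(self, x: ArrayLike) -> ArrayLike:
        tm = isinstance(x, Tensor)
        axes = (1, 2, 3) if self.mode == "chw" else (1,)
        mu = ad.mean(x, axis=axes, keepdims=True)
        var = ad.mean((x - mu) ** 2, axis=axes, keepdims=True)
        xhat = (x - mu) / ad.sqrt(var + self.eps)
        g = self.gamma if tm else self.gamma.data
        b = self.beta if tm else self.beta.data
        return xhat * g.reshape(1, self.channels, 1, 1) + b.reshape(1, self.channels, 1, 1)


class ResidualBlock(Module):
    """``x + conv(PReLU(LayerNorm(conv(x))))`` with 3x3 shape-preserving convs."""

    def __init__(self, channels: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = self._register("conv1", Conv2d(channels, channels, 3, 1, rng))
        self.norm = self._register(
            "norm", LayerNorm(channels, cfg.layer_norm_eps, cfg.layer_norm_mode)
        )
        self.act = self._register("act", PReLU(channels, cfg.prelu_init))
        self.conv2 = self._register("conv2", Conv2d(channels, channels, 3, 1, rng))

    def forward(self, x: ArrayLike) -> ArrayLike:
        return x + self.conv2(self.act(self.norm(self.conv1(x))))


def pixel_shuffle(x: ArrayLike, r: int) -> ArrayLike:
    """Rearrange ``r^2`` channel groups into an ``r``-times larger grid.

    ``out[b, c, h*r + i, w*r + j] = in[b, c*r^2 + i*r + j, h, w]``; the pixel
    multiset is preserved, only positions change.
    """
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise ValueError(f"upscale factor must be a positive integer, got {r!r}")
    B, C, H, W = ad.as_array(x).shape
    if C % (r * r) != 0:
        raise ValueError(f"channel count {C} not divisible by r^2={r * r}")
    if r == 1:
        return x
    c_out = C // (r * r)
    y = x.reshape(B, c_out, r, r, H, W)
    y = y.transpose(0, 1, 4, 2, 5, 3)  # (B, c, H, i, W, j)
    return y.reshape(B, c_out, H * r, W * r)


_STAGE_FACTORS = {1: (1,), 2: (2,), 3: (3,), 4: (2, 2)}


class SRNetwork(Module):
    """The full generator; construction is deterministic in (config, seed)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        C = config.n_features

        self.head = self._register("head", Conv2d(1, C, 3, 1, rng))
        self.head_act = self._register("head_act", PReLU(C, config.prelu_init))
        self.blocks = [
            self._register(f"block{i}", ResidualBlock(C, config, rng))
            for i in range(config.n_res_blocks)
        ]
        self.trunk_conv = self._register("trunk_conv", Conv2d(C, C, 3, 1, rng))
        self.stages = []
        for s, f in enumerate(_STAGE_FACTORS[config.scale_factor]):
            conv = self._register(f"up{s}_conv", Conv2d(C, C * f * f, 3, 1, rng))
            act = self._register(f"up{s}_act", PReLU(C, config.prelu_init))
            self.stages.append((conv, f, act))
        self.out_conv = self._register("out_conv", Conv2d(C, 1, 1, 0, rng))

    def _attend(self, x: ArrayLike) -> ArrayLike:
        cfg = self.config
        return pcfb(x, cfg.n_chunks, cfg.simam_lambda, cfg.simam_ddof)

    def forward(self, lr: ArrayLike) -> ArrayLike:
        data = ad.as_array(lr)
        if data.ndim != 4 or data.shape[1] != 1:
            raise ValueError(f"expected input of shape (B, 1, H, W); got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("input contains non-finite values")

        cfg = self.config
        f0 = self.head_act(self.head(lr))
        f = f0
        for block in self.blocks:
            f = block(f)
            if cfg.use_pcfb and cfg.pcfb_every_block:
                f = self._attend(f)
        f = self.trunk_conv(f)
        if cfg.global_skip:
            f = f + f0
        if cfg.use_pcfb:
            f = self._attend(f)
        for conv, factor, act in self.stages:
            f = act(pixel_shuffle(conv(f), factor))
        return self.out_conv(f)

    def predict(self, lr: np.ndarray) -> np.ndarray:
        """Super-resolve one 2-D image in [0,1]; output clipped to [0,1]."""
        lr = np.asarray(lr, dtype=np.float64)
        if lr.ndim != 2:
            raise ValueError("predict expects a single 2-D image")
        sr = self.forward(lr[None, None])
        return np.clip(sr[0, 0], 0.0, 1.0)


def build_model(config: ModelConfig, seed: int = 0) -> SRNetwork:
    return SRNetwork(config, seed)


def count_parameters(model: Module) -> int:
    """Total number of learnable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: SRNetwork, path) -> None:
    """Write parameters + config + seed; the parameter round trip is bit-exact."""
    arrays = {f"param:{name}": p.data for name, p in model.named_parameters()}
    meta = json.dumps({"config": model.config.to_dict(), "seed": model.seed})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path) -> SRNetwork:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        model = SRNetwork(ModelConfig.from_dict(meta["config"]), meta["seed"])
        names = {name for name, _ in model.named_parameters()}
        stored = {k[len("param:"):]: npz[k] for k in npz.files if k.startswith("param:")}
        if set(stored) != names:
            raise ValueError("checkpoint parameter names do not match the model")
        for name, p in model.named_parameters():
            if p.data.shape != stored[name].shape:
                raise ValueError(f"checkpoint shape mismatch for {name}")
            p.data = stored[name].astype(np.float64)
    return model
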
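"""The shared attention-gated residual encoder-decoder architecture.

Both reconstruction networks instantiate the same backbone: four encoder
blocks, one bottleneck block, and four decoder blocks.  An encoder block
is a BN -> PReLU -> conv stack whose input is concatenated with the output
of its final layer (residual concatenation); stride-2 convolutions
downsample between stages.  A decoder block upsamples with a stride-2
transpose convolution (BN + PReLU), gates the matching encoder skip
through an additive attention gate, and merges with a 3-tap convolution.

* SD-CNN: 2D convolutions; maps a standardized two-channel patch (image +
  wavenumber layer) to a one-channel patch of the same spatial size.
* FD-CNN: 1D convolutions along the depth-frequency axis; maps one A-scan
  DFT amplitude column to a refined amplitude column, with a softplus
  output so the amplitude stays non-negative.  A-scans are processed
  independently as the batch dimension.

Kernel size 3, channel doubling per stage, and stride-2 up/downsampling
are this package's choices; the tiny preset (base 8 channels) keeps the
models CPU-trainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import (Adam, BatchNorm, Conv1d, Conv2d, ConvTranspose1d,
                       ConvTranspose2d, Module, PReLU, Tensor)

__all__ = [
    "NetConfig", "SpectrumPair", "build_encoder_block",
    "build_attention_gate", "build_sd_cnn", "build_fd_cnn",
    "count_parameters", "model_state", "set_model_state",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters shared by the SD-CNN and FD-CNN."""

    conv_dim: str = "2D"            # {"2D", "1D"}
    n_encoder_blocks: int = 4
    n_decoder_blocks: int = 4
    bottleneck_blocks: int = 1
    base_channels: int = 32         # "tiny" preset: 8
    use_attention: bool = True
    use_residual: bool = True
    in_channels: int = 2
    out_channels: int = 1
    output_activation: Optional[str] = None  # {None, "softplus",
                                             #  "residual_relu"}

    def __post_init__(self):
        if self.conv_dim not in ("2D", "1D"):
            raise ValueError("conv_dim must be '2D' or '1D'")
        if self.n_encoder_blocks != self.n_decoder_blocks:
            raise ValueError("encoder and decoder depths must be equal")
        if self.output_activation not in (None, "softplus", "residual_relu"):
            raise ValueError("output_activation must be None, 'softplus' "
                             "or 'residual_relu'")
        if (self.output_activation == "residual_relu"
                and self.in_channels != self.out_channels):
            raise ValueError("residual output needs in_channels =="
                             " out_channels")

    @classmethod
    def preset(cls, name: str, **overrides) -> "NetConfig":
        base = {"tiny": 8, "paper": 32}
        if name not in base:
            raise ValueError(f"unknown preset {name!r}")
        return cls(base_channels=base[name], **overrides)


@dataclass
class SpectrumPair:
    """Per-A-scan DFT amplitude and phase of a B-scan image.

    Both arrays are (depth-frequency bins x lateral); the full two-sided
    spectrum is kept so the inversion is exact.
    """

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, float)
        self.phase = np.asarray(self.phase, float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude/phase shape mismatch")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    @classmethod
    def from_image(cls, pixels: np.ndarray) -> "SpectrumPair":
        spec = np.fft.fft(np.asarray(pixels, float), axis=0)
        return cls(amplitude=np.abs(spec), phase=np.angle(spec))

    @property
    def power(self) -> np.ndarray:
        return self.amplitude ** 2

    def to_image(self) -> np.ndarray:
        spec = self.amplitude * np.exp(1j * self.phase)
        return np.fft.ifft(spec, axis=0).real


# ---------------------------------------------------------------------------
# building blocks


def _conv(dim, cin, cout, k=3, stride=1, rng=None):
    return (Conv2d if dim == "2D" else Conv1d)(cin, cout, k=k, stride=stride,
                                               rng=rng)


def _convT(dim, cin, cout, rng=None):
    return (ConvTranspose2d if dim == "2D" else ConvTranspose1d)(cin, cout,
                                                                 rng=rng)


class ConvBlock(Module):
    """BN -> PReLU -> conv, twice; optional residual concatenation of the
    block input with the output of the final layer."""

    def __init__(self, dim, cin, cout, residual=True, rng=None):
        self.residual = residual
        self.cin, self.cout = cin, cout
        self.bn1 = BatchNorm(cin)
        self.act1 = PReLU(cin)
        self.conv1 = _conv(dim, cin, cout, rng=rng)
        self.bn2 = BatchNorm(cout)
        self.act2 = PReLU(cout)
        self.conv2 = _conv(dim, cout, cout, rng=rng)

    @property
    def out_channels(self):
        return self.cin + self.cout if self.residual else self.cout

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(self.act1(self.bn1(x)))
        h = self.conv2(self.act2(self.bn2(h)))
        return ad.concat([x, h], axis=1) if self.residual else h


class EncoderStage(Module):
    """One encoder block plus the stride-2 downsampling into the next
    stage.  ``forward`` returns (skip features, downsampled features)."""

    def __init__(self, dim, cin, cout, down_out, residual=True, rng=None):
        self.block = ConvBlock(dim, cin, cout, residual=residual, rng=rng)
        self.down = _conv(dim, self.block.out_channels, down_out, stride=2,
                          rng=rng)

    @property
    def skip_channels(self):
        return self.block.out_channels

    def forward(self, x: Tensor):
        skip = self.block(x)
        return skip, self.down(skip)


class AttentionGate(Module):
    """Additive attention gate: coefficients in [0, 1] scale the skip.

    att = sigmoid(psi(relu(theta(skip) + phi(gate)))), computed at the
    skip's resolution; the single-channel coefficient map multiplies every
    skip channel.
    """

    def __init__(self, dim, skip_ch, gate_ch, inter_ch=None, rng=None):
        inter_ch = inter_ch or max(skip_ch // 2, 1)
        self.theta = _conv(dim, skip_ch, inter_ch, k=1, rng=rng)
        self.phi = _conv(dim, gate_ch, inter_ch, k=1, rng=rng)
        self.psi = _conv(dim, inter_ch, 1, k=1, rng=rng)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        if skip.shape[2:] != gate.shape[2:]:
            raise ValueError("gating and skip spatial sizes must match "
                             f"({skip.shape[2:]} vs {gate.shape[2:]})")
        return ad.sigmoid(self.psi(ad.relu(ad.add(self.theta(skip),
                                                  self.phi(gate)))))

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        return ad.mul(skip, self.coefficients(skip, gate))


class DecoderStage(Module):
    """Stride-2 transpose conv (BN + PReLU), attention-gated skip merge."""

    def __init__(self, dim, cin, skip_ch, cout, use_attention=True, rng=None):
        self.up = _convT(dim, cin, cout, rng=rng)
        self.bn = BatchNorm(cout)
        self.act = PReLU(cout)
        self.gate = (AttentionGate(dim, skip_ch, cout, rng=rng)
                     if use_attention else None)
        self.merge = _conv(dim, cout + skip_ch, cout, rng=rng)
        self.bn2 = BatchNorm(cout)
        self.act2 = PReLU(cout)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.act(self.bn(self.up(x)))
        gated = self.gate(skip, up) if self.gate is not None else skip
        h = self.merge(ad.concat([up, gated], axis=1))
        return self.act2(self.bn2(h))


class EncoderDecoder(Module):
    """The full backbone (see module docstring)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        dim, b = cfg.conv_dim, cfg.base_channels
        body = [b * 2 ** i for i in range(cfg.n_encoder_blocks)]
        self.encoder = []
        cin = cfg.in_channels
        for i in range(cfg.n_encoder_blocks):
            stage = EncoderStage(dim, cin, body[i], body[i],
                                 residual=cfg.use_residual, rng=rng)
            self.encoder.append(stage)
            cin = body[i]
        self.bottleneck = [ConvBlock(dim, cin, body[-1],
                                     residual=cfg.use_residual, rng=rng)
                           for _ in range(cfg.bottleneck_blocks)]
        cur = cin
        for blk in self.bottleneck:
            cur = blk.out_channels
        self.decoder = []
        for i in reversed(range(cfg.n_decoder_blocks)):
            stage = DecoderStage(dim, cur, self.encoder[i].skip_channels,
                                 body[i], use_attention=cfg.use_attention,
                                 rng=rng)
            self.decoder.append(stage)
            cur = body[i]
        self.head = _conv(dim, cur, cfg.out_channels, k=1, rng=rng)
        if cfg.output_activation == "residual_relu":
            # zero-init the correction head: the untrained model is the
            # identity on its input
            self.head.weight.data[...] = 0.0
            self.head.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        depth = 2 ** len(self.encoder)
        for extent in x.shape[2:]:
            if extent % depth:
                raise ValueError(
                    f"input spatial extent {extent} not divisible by {depth}")
        skips = []
        h = x
        for stage in self.encoder:
            skip, h = stage(h)
            skips.append(skip)
        for blk in self.bottleneck:
            h = blk(h)
        for stage, skip in zip(self.decoder, reversed(skips)):
            h = stage(h, skip)
        out = self.head(h)
        if self.cfg.output_activation == "softplus":
            out = ad.softplus(out)
        elif self.cfg.output_activation == "residual_relu":
            # identity-at-init refinement: predict a correction to the
            # input, clamp at zero to keep the amplitude non-negative
            out = ad.relu(ad.add(x, out))
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference on a numpy batch (eval mode)."""
        self.eval()
        out = self.forward(Tensor(x)).data
        self.train()
        return out


# ---------------------------------------------------------------------------
# builders


def build_encoder_block(cfg: NetConfig, stage: int,
                        in_channels: Optional[int] = None,
                        seed: int = 0) -> EncoderStage:
    """Standalone encoder stage ``stage`` (0-based) of the backbone."""
    body = cfg.base_channels * 2 ** stage
    if in_channels is None:
        in_channels = (cfg.in_channels if stage == 0
                       else cfg.base_channels * 2 ** (stage - 1))
    return EncoderStage(cfg.conv_dim, in_channels, body, body,
                        residual=cfg.use_residual,
                        rng=np.random.default_rng(seed))


def build_attention_gate(cfg: NetConfig, skip_channels: int,
                         gate_channels: int, seed: int = 0) -> AttentionGate:
    return AttentionGate(cfg.conv_dim, skip_channels, gate_channels,
                         rng=np.random.default_rng(seed))


def build_sd_cnn(cfg: Optional[NetConfig] = None, seed: int = 0
                 ) -> EncoderDecoder:
    """Spatial-domain network: 2D, two input channels (image + k layer),
    one output channel, size-preserving."""
    cfg = cfg or NetConfig()
    if cfg.conv_dim != "2D" or cfg.in_channels != 2 or cfg.out_channels != 1:
        raise ValueError("SD-CNN requires conv_dim='2D', in=2, out=1")
    return EncoderDecoder(cfg, seed=seed)


def build_fd_cnn(cfg: Optional[NetConfig] = None, seed: int = 0
                 ) -> EncoderDecoder:
    """Fourier-domain network: 1D along the depth-frequency axis, one
    amplitude channel in and out, non-negative output.

    The default output is "residual_relu": the network predicts a
    correction added to the input amplitude and clamped at zero, so an
    untrained model is the identity and training can only refine the
    spectrum.  "softplus" (a free non-negative head) is also accepted.
    """
    cfg = cfg or NetConfig(conv_dim="1D", in_channels=1, out_channels=1,
                           output_activation="residual_relu")
    if cfg.conv_dim != "1D" or cfg.in_channels != 1 or cfg.out_channels != 1:
        raise ValueError("FD-CNN requires conv_dim='1D', in=1, out=1")
    if cfg.output_activation not in ("softplus", "residual_relu"):
        raise ValueError("FD-CNN output must be non-negative "
                         "(softplus or residual_relu)")
    return EncoderDecoder(cfg, seed=seed)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# checkpoints


def model_state(model: Module) -> dict:
    """All trainable parameters plus batch-norm running statistics."""
    state = {f"p{i}": p.data.copy() for i, p in enumerate(model.parameters())}
    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    for j, bn in enumerate(bns):
        state[f"bn{j}_mean"] = bn.running_mean.copy()
        state[f"bn{j}_var"] = bn.running_var.copy()
    return state


def set_model_state(model: Module, state: dict) -> None:
    for i, p in enumerate(model.parameters()):
        p.data[...] = state[f"p{i}"]
    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    for j, bn in enumerate(bns):
        bn.running_mean[...] = state[f"bn{j}_mean"]
        bn.running_var[...] = state[f"bn{j}_var"]


def save_checkpoint(path, model: Module, cfg: NetConfig,
                    extra: Optional[dict] = None) -> None:
    """Persist weights + architecture config (+ JSON-serializable extras)
    as a single .npz file."""
    meta = {"config": asdict(cfg), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model_state(model))


def load_checkpoint(path):
    """Return (model, cfg, extra) rebuilt from a checkpoint."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = NetConfig(**meta["config"])
    model = EncoderDecoder(cfg, seed=0)
    set_model_state(model, state)
    return model, cfg, meta["extra"]
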
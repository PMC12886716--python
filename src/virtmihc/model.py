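"""The three networks of the virtual staining framework and the warp operator.

A single conditional generator G maps a 5-channel input — the four
autofluorescence channels plus a constant digital staining matrix (DSM)
channel — to a 3-channel brightfield image.  The DSM code selects the
virtual stain: −1 → ERG, 1 → PanCK, 2 → H&E.  Codes are fed raw, not
normalized.  A discriminator D receives (image, DSM) and scores realism;
a registration network R receives (generator output, target) and predicts
a per-pixel 2-component displacement field used to warp the generator
output onto the imperfectly aligned target during training ("∘").
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, concat, grid_sample
from .io import CODE_TO_STAIN, DSM_CODES

G_DIV = 16  # generator: 4 pooling levels


@dataclass(frozen=True)
class DSM:
    """Constant conditioning plane selecting the virtual stain."""

    code: int
    height: int
    width: int

    def __post_init__(self):
        if self.code not in CODE_TO_STAIN:
            raise ValueError(f"unknown DSM code {self.code}; "
                             f"valid: {sorted(CODE_TO_STAIN)}")

    @property
    def stain_class(self) -> str:
        return CODE_TO_STAIN[self.code]

    @property
    def matrix(self) -> np.ndarray:
        return np.full((self.height, self.width), float(self.code),
                       dtype=np.float32)


def make_dsm(stain_class: str, height: int, width: int) -> DSM:
    if stain_class not in DSM_CODES:
        raise ValueError(f"unknown stain class {stain_class!r}; "
                         f"valid: {sorted(DSM_CODES)}")
    return DSM(code=DSM_CODES[stain_class], height=height, width=width)


@dataclass
class DisplacementField:
    """Per-pixel (dy, dx) offsets in pixel units, gather semantics."""

    dy: np.ndarray
    dx: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.dy, self.dx], axis=0)

    @classmethod
    def zero(cls, height: int, width: int) -> "DisplacementField":
        return cls(np.zeros((height, width), dtype=np.float32),
                   np.zeros((height, width), dtype=np.float32))


def _field_to_batch(field, n: int, h: int, w: int):
    if isinstance(field, DisplacementField):
        field = field.as_array()
    if isinstance(field, Tensor):
        arr_shape = field.shape
    else:
        field = np.asarray(field, dtype=np.float32)
        arr_shape = field.shape
    if arr_shape == (2, h, w):
        if isinstance(field, Tensor):
            field = field.reshape(1, 2, h, w)
            if n != 1:
                raise ValueError("unbatched Tensor field with batched image")
            return field
        field = np.broadcast_to(field[None], (n, 2, h, w))
    elif arr_shape != (n, 2, h, w):
        raise ValueError(f"field shape {arr_shape} incompatible with image "
                         f"batch ({n}, ·, {h}, {w})")
    return field


def warp(image, field):
    """Resample `image` along `field`: out(x) = image(x + T(x)).

    Accepts (C, H, W) or (N, C, H, W) images as numpy arrays or Tensors;
    the result has the input's layout.  Bilinear, border-replicated,
    differentiable in both arguments.
    """
    unbatched = False
    numpy_in = not (isinstance(image, Tensor) or isinstance(field, Tensor))
    if isinstance(image, Tensor):
        if image.ndim == 3:
            image = image.reshape(1, *image.shape)
            unbatched = True
    else:
        image = np.asarray(image)
        if image.ndim == 3:
            image = image[None]
            unbatched = True
    n, c, h, w = image.shape
    field = _field_to_batch(field, n, h, w)
    out = grid_sample(image, field)
    if unbatched:
        out = out.reshape(c, h, w)
    return out.data if numpy_in else out


# ------------------------------------------------------------------ networks
class GeneratorNet(nn.Module):
    """Attention U-Net: 4 pooling levels, channel doubling, 3-channel output."""

    def __init__(self, base_width: int = 64, in_channels: int = 5,
                 rng: np.random.Generator | None = None,
                 output_activation: str = "sigmoid"):
        if base_width < 4:
            raise ValueError("base_width must be >= 4")
        rng = rng or np.random.default_rng(0)
        w = base_width
        self.base_width = base_width
        self.in_channels = in_channels
        self.output_activation = output_activation
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.enc = [nn.ResBlock3(in_channels if i == 0 else widths[i - 1],
                                 widths[i], rng=rng) for i in range(4)]
        self.bottleneck = nn.ResBlock3(widths[3], 16 * w, rng=rng)
        self.gates = [nn.AttentionGate(widths[i],
                                       (16 * w) if i == 3 else widths[i + 1],
                                       rng=rng)
                      for i in range(3, -1, -1)]
        self.dec = [nn.ResBlock3(((16 * w) if i == 3 else widths[i + 1])
                                 + widths[i], widths[i], rng=rng)
                    for i in range(3, -1, -1)]
        self.head = nn.ResBlock3(w, w, rng=rng)
        self.out_conv = nn.Conv2d(w, 3, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w_ = x.shape
        if c != self.in_channels:
            raise ValueError(f"generator expects {self.in_channels} input "
                             f"channels (4 AF + 1 DSM), got {c}")
        if h % G_DIV or w_ % G_DIV:
            raise ValueError(f"generator input dims must be divisible by "
                             f"{G_DIV}, got {h}x{w_}")
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = x.maxpool2()
        x = self.bottleneck(x)
        for gate, blk, skip in zip(self.gates, self.dec, reversed(skips)):
            x = x.upsample2()
            x = concat([x, gate(skip, x)], axis=1)
            x = blk(x)
        x = self.head(x)
        x = self.out_conv(x)
        return x.sigmoid() if self.output_activation == "sigmoid" else x


class DiscriminatorNet(nn.Module):
    """Conv stem, 5 stride-2 residual blocks, global pool, 2 dense layers.

    Returns the pre-sigmoid logit; the sigmoid lives inside the stable BCE.
    """

    def __init__(self, stem_width: int = 64, in_channels: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.stem_width = stem_width
        self.stem = nn.Conv2d(in_channels, stem_width, 3, rng=rng)
        self.blocks = [nn.ResBlock2Down(stem_width * 2 ** i, rng=rng)
                       for i in range(5)]
        feat = stem_width * 32
        self.fc1 = nn.Linear(feat, max(stem_width, 8), rng=rng)
        # zero-init head: D starts exactly at chance with zero input
        # gradient, so early adversarial pressure on G reflects learned
        # discrimination rather than the random initialization
        self.fc2 = nn.Linear(max(stem_width, 8), 1, rng=rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"discriminator expects {self.in_channels} "
                             f"channels (RGB + DSM), got {x.shape[1]}")
        x = self.stem(x).leaky_relu(nn.LEAKY_SLOPE)
        for blk in self.blocks:
            x = blk(x)
        x = nn.global_mean_pool(x)
        x = self.fc1(x).leaky_relu(nn.LEAKY_SLOPE)
        return self.fc2(x)

    def score(self, x: Tensor) -> Tensor:
        """Probability in (0, 1)."""
        return self.forward(x).sigmoid()


class RegistrationNet(nn.Module):
    """Residual U-Net predicting a 2-component displacement field.

    Default depth is 7 encoder/decoder pairs (inputs divisible by 128);
    scaled-down presets shrink the depth.  The bottleneck doubles the
    channels, applies 3 residual blocks, then halves them.  The output
    convolution is zero-initialized so the initial field is identically
    zero (the identity warp).
    """

    def __init__(self, base_width: int = 16, depth: int = 7,
                 in_channels: int = 6, rng: np.random.Generator | None = None,
                 field_scale: float = 10.0, head_level: int = 0):
        rng = rng or np.random.default_rng(0)
        self.base_width = base_width
        self.depth = depth
        self.in_channels = in_channels
        # fixed multiplier on the displacement head (flow-network practice):
        # lets few-step optimization reach multi-pixel fields
        self.field_scale = field_scale
        # head_level > 0 predicts the field on a 2^level-coarser grid and
        # bilinearly upsamples: staining distortion is large-scale smooth,
        # and the coarse parametrization conditions few-step optimization
        if not 0 <= head_level < depth:
            raise ValueError("head_level must be in [0, depth)")
        self.head_level = head_level
        widths = [base_width * 2 ** i for i in range(depth)]
        self.enc = [nn.ResBlock3(in_channels if i == 0 else widths[i - 1],
                                 widths[i], rng=rng) for i in range(depth)]
        wb = widths[-1]
        self.b_expand = nn.Conv2d(wb, 2 * wb, 3, rng=rng)
        self.b_blocks = [nn.ResBlock3(2 * wb, 2 * wb, rng=rng)
                         for _ in range(3)]
        self.b_reduce = nn.Conv2d(2 * wb, wb, 3, rng=rng)
        self.dec = [nn.ResBlock3(widths[i] + widths[i]
                                 if i == depth - 1 else
                                 widths[i + 1] + widths[i], widths[i], rng=rng)
                    for i in range(depth - 1, head_level - 1, -1)]
        self.out_conv = nn.Conv2d(widths[head_level], 2, 1, rng=rng,
                                  zero_init=True)

    @property
    def divisor(self) -> int:
        return 2 ** self.depth

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"registration net expects {self.in_channels} "
                             f"channels (output + target), got {c}")
        if h % self.divisor or w % self.divisor:
            raise ValueError(f"registration input dims must be divisible by "
                             f"{self.divisor}, got {h}x{w}")
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = x.maxpool2()
        x = self.b_expand(x).leaky_relu(nn.LEAKY_SLOPE)
        for blk in self.b_blocks:
            x = blk(x)
        x = self.b_reduce(x).leaky_relu(nn.LEAKY_SLOPE)
        for blk, skip in zip(self.dec, reversed(skips[self.head_level:])):
            x = x.upsample2()
            x = concat([x, skip], axis=1)
            x = blk(x)
        x = self.out_conv(x) * self.field_scale
        for _ in range(self.head_level):
            x = x.upsample2()
        return x


def build_generator(base_width: int = 64, in_channels: int = 5,
                    rng=None, output_activation: str = "sigmoid"
                    ) -> GeneratorNet:
    return GeneratorNet(base_width, in_channels, rng, output_activation)


def build_discriminator(stem_width: int = 64, rng=None) -> DiscriminatorNet:
    return DiscriminatorNet(stem_width, rng=rng)


def build_registration(base_width: int = 16, depth: int = 7,
                       rng=None, head_level: int = 0) -> RegistrationNet:
    return RegistrationNet(base_width, depth, rng=rng,
                           head_level=head_level)


# -------------------------------------------------------------------- bundle
@dataclass
class ModelBundle:
    """Generator + discriminator + registration net with optimizer state."""

    generator: GeneratorNet
    discriminator: DiscriminatorNet
    registration: RegistrationNet
    opt_g: nn.Adam
    opt_d: nn.Adam
    opt_r: nn.Adam
    config: dict = dc_field(default_factory=dict)
    step: int = 0

    @classmethod
    def create(cls, config: dict, rng: np.random.Generator) -> "ModelBundle":
        g = build_generator(config["g_base_width"], rng=rng,
                            output_activation=config.get("activation",
                                                         "sigmoid"))
        d = build_discriminator(config["d_stem_width"], rng=rng)
        r = build_registration(config["r_base_width"],
                               depth=config["r_depth"], rng=rng,
                               head_level=config.get("r_head_level", 0))
        betas = tuple(config.get("adam_betas", (0.9, 0.999)))
        return cls(g, d, r,
                   nn.Adam(g.parameters(), config["lr_generator"], betas),
                   nn.Adam(d.parameters(), config["lr_discriminator"], betas),
                   nn.Adam(r.parameters(), config["lr_registration"], betas),
                   config=dict(config))

    def save(self, path) -> None:
        import json
        path = Path(path)
        payload = {"step": np.asarray(self.step),
                   "config": np.frombuffer(
                       json.dumps(self.config, default=str).encode(),
                       dtype=np.uint8)}
        for name, net, opt in (("g", self.generator, self.opt_g),
                               ("d", self.discriminator, self.opt_d),
                               ("r", self.registration, self.opt_r)):
            for i, arr in enumerate(net.state_arrays()):
                payload[f"{name}_p{i}"] = arr
            for i, arr in enumerate(opt.m):
                payload[f"{name}_m{i}"] = arr
            for i, arr in enumerate(opt.v):
                payload[f"{name}_v{i}"] = arr
            payload[f"{name}_t"] = np.asarray(opt.t)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        import json
        with np.load(path) as z:
            config = json.loads(bytes(z["config"].tobytes()).decode())
            bundle = cls.create(config, np.random.default_rng(0))
            bundle.step = int(z["step"])
            for name, net, opt in (("g", bundle.generator, bundle.opt_g),
                                   ("d", bundle.discriminator, bundle.opt_d),
                                   ("r", bundle.registration, bundle.opt_r)):
                n = len(net.parameters())
                net.load_arrays([z[f"{name}_p{i}"] for i in range(n)])
                opt.load_state({"t": z[f"{name}_t"],
                                "m": [z[f"{name}_m{i}"] for i in range(n)],
                                "v": [z[f"{name}_v{i}"] for i in range(n)]})
        return bundle
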
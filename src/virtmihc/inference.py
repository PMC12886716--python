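"""Apply a trained generator to autofluorescence fields of arbitrary size.

Fields larger than one tile are processed in overlapping tiles whose
outputs are feather-blended (cosine ramp over the overlap); the blend
weights sum to one at every pixel, so constant inputs produce constant
outputs and zero-overlap tilings stitch bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .io import STAINS
from .model import G_DIV, ModelBundle, make_dsm


@dataclass(frozen=True)
class TilingPlan:
    tile_size: int = 512
    overlap: int = 64

    def __post_init__(self):
        if self.tile_size % G_DIV:
            raise ValueError(f"tile_size must be divisible by {G_DIV}")
        if not 0 <= self.overlap < self.tile_size:
            raise ValueError("overlap must satisfy 0 <= overlap < tile_size")


def _feather_profile(tile: int, overlap: int) -> np.ndarray:
    """1-D blend weights: cosine ramps of length `overlap` at both ends."""
    w = np.ones(tile, dtype=np.float32)
    if overlap > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(overlap) + 0.5)
                                  / overlap)
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]
    return w


def _tile_starts(extent: int, tile: int, overlap: int) -> list[int]:
    if extent <= tile:
        return [0]
    stride = tile - overlap
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)
    return starts


def _run_generator(bundle: ModelBundle, af_tile: np.ndarray,
                   code: int) -> np.ndarray:
    dsm = np.full((1, 1) + af_tile.shape[1:], float(code), dtype=np.float32)
    x = np.concatenate([af_tile[None].astype(np.float32), dsm], axis=1)
    out = bundle.generator(Tensor(x)).data[0]
    # brightfield images live in [0, 1]; a linear output head may overshoot
    return np.clip(out, 0.0, 1.0)


def stain_field(af_field: np.ndarray, stain_class: str, bundle: ModelBundle,
                plan: TilingPlan | None = None) -> np.ndarray:
    """Virtually stain a (4, H, W) AF field; returns (3, H, W) RGB in [0,1].

    Fields smaller than one tile are padded (edge replication) to the
    generator's divisibility requirement and cropped back.
    """
    plan = plan or TilingPlan()
    af_field = np.asarray(af_field, dtype=np.float32)
    if af_field.ndim != 3 or af_field.shape[0] != 4:
        raise ValueError(f"expected (4, H, W) AF field, got {af_field.shape}")
    code = make_dsm(stain_class, 1, 1).code
    _, h, w = af_field.shape

    if h <= plan.tile_size and w <= plan.tile_size:
        ph, pw = (-h) % G_DIV, (-w) % G_DIV
        padded = np.pad(af_field, ((0, 0), (0, ph), (0, pw)), mode="edge") \
            if (ph or pw) else af_field
        return _run_generator(bundle, padded, code)[:, :h, :w]

    out = np.zeros((3, h, w), dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    prof = _feather_profile(plan.tile_size, plan.overlap)
    w2d = np.outer(prof, prof)
    for y0 in _tile_starts(h, plan.tile_size, plan.overlap):
        for x0 in _tile_starts(w, plan.tile_size, plan.overlap):
            tile = af_field[:, y0:y0 + plan.tile_size,
                            x0:x0 + plan.tile_size]
            pred = _run_generator(bundle, tile, code)
            out[:, y0:y0 + plan.tile_size, x0:x0 + plan.tile_size] += \
                pred * w2d
            weight[y0:y0 + plan.tile_size, x0:x0 + plan.tile_size] += w2d
    return (out / weight).astype(np.float32)


def stain_multiplex(af_field: np.ndarray, bundle: ModelBundle,
                    plan: TilingPlan | None = None,
                    stains=STAINS) -> dict[str, np.ndarray]:
    """All requested stains from one AF field; outputs share the pixel grid
    and tile decomposition by construction."""
    return {s: stain_field(af_field, s, bundle, plan) for s in stains}
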
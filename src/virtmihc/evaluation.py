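"""Quantitative evaluation of virtual vs histochemical staining.

Image-level fidelity (PSNR, SSIM, optional perceptual distance) for all
stains; stain-specific statistics on the DAB chromogen: connected-component
nuclei count/area for ERG (the nuclear endothelial marker) and down-sampled
IoU of epithelial masks for PanCK, plus paired two-tailed t-tests.

Color deconvolution inverts the Beer–Lambert mixture: OD(x) = −ln rgb(x),
concentrations = OD · V⁻¹ where the rows of V are unit optical-density
stain vectors.  Natural-log OD matches the phantom renderer, so rendered
images deconvolve back to their generating concentration maps exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.metrics import structural_similarity
from skimage.morphology import dilation, erosion, disk

from .losses import mse, psnr  # noqa: F401  (re-exported metrics)
from .phantom import DAB_OD, EOSIN_OD, HEMATOXYLIN_OD, _unit


@dataclass(frozen=True)
class StainVectors:
    """3x3 matrix of unit OD vectors (rows); must be invertible."""

    matrix: tuple
    names: tuple = ("hematoxylin", "dab", "residual")

    def __post_init__(self):
        m = self.as_matrix()
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vectors must be unit norm")
        if np.linalg.cond(m) > 1e6:
            raise ValueError("stain matrix is singular or ill-conditioned")

    def as_matrix(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=np.float64)

    @classmethod
    def from_rows(cls, rows, names) -> "StainVectors":
        rows = [np.asarray(r, dtype=np.float64) for r in rows]
        if len(rows) == 2:
            rows.append(_unit(np.cross(rows[0], rows[1])))
            names = tuple(names) + ("residual",)
        return cls(tuple(tuple(r) for r in rows), tuple(names))

    @classmethod
    def h_dab(cls) -> "StainVectors":
        return cls.from_rows([_unit(HEMATOXYLIN_OD), _unit(DAB_OD)],
                             ("hematoxylin", "dab"))

    @classmethod
    def h_e(cls) -> "StainVectors":
        return cls.from_rows([_unit(HEMATOXYLIN_OD), _unit(EOSIN_OD)],
                             ("hematoxylin", "eosin"))


def color_deconvolve(rgb: np.ndarray, vectors: StainVectors,
                     eps: float = 1e-6) -> np.ndarray:
    """(H, W, 3) per-stain concentration maps in the order `vectors.names`.

    Raw values are returned (negatives are not clamped here; clamping
    happens only when building masks).
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got {rgb.shape}")
    od = -np.log(np.clip(rgb, eps, None))
    return od @ np.linalg.inv(vectors.as_matrix())


def reconstruct_rgb(conc: np.ndarray, vectors: StainVectors) -> np.ndarray:
    """Inverse of `color_deconvolve` (before any clamping)."""
    return np.exp(-(np.asarray(conc) @ vectors.as_matrix()))


def dab_mask(dab_map: np.ndarray, morphology_radius: int = 2,
             ) -> np.ndarray:
    """Otsu threshold on the DAB concentration map, then dilation followed
    by erosion with a disk structuring element.

    A constant map has no Otsu threshold; an empty mask is returned.
    `morphology_radius=0` skips the morphological step.
    """
    dab_map = np.asarray(dab_map, dtype=np.float64)
    if not np.all(np.isfinite(dab_map)):
        raise ValueError("DAB map contains non-finite values")
    dab_map = np.maximum(dab_map, 0.0)   # clamp only at mask-building time
    if np.ptp(dab_map) == 0:
        import warnings
        warnings.warn("constant DAB map: Otsu threshold undefined, "
                      "returning empty mask", stacklevel=2)
        return np.zeros(dab_map.shape, dtype=bool)
    mask = dab_map > threshold_otsu(dab_map)
    if morphology_radius > 0:
        se = disk(morphology_radius)
        mask = erosion(dilation(mask, se), se)
    return mask.astype(bool)


@dataclass(frozen=True)
class NucleiStats:
    count: int
    mean_area: float          # NaN sentinel when count == 0
    areas: tuple

    @property
    def defined(self) -> bool:
        return self.count > 0


def erg_nuclei_stats(mask: np.ndarray, connectivity: int = 2,
                     min_area: int = 4) -> NucleiStats:
    """Connected-component count and mean area (pixels^2) of a binary mask.

    Default 8-connectivity (skimage connectivity=2).  Components smaller
    than `min_area` pixels are discarded as artifacts — a nucleus cannot
    occupy a single pixel at this magnification; pass 0 for the raw count.
    """
    mask = np.asarray(mask).astype(bool)
    labels = cc_label(mask, connectivity=connectivity)
    areas = tuple(int(r.area) for r in regionprops(labels)
                  if r.area >= min_area)
    count = len(areas)
    return NucleiStats(count=count,
                       mean_area=float(np.mean(areas)) if count else
                       float("nan"),
                       areas=areas)


def d_iou(mask_vs: np.ndarray, mask_hs: np.ndarray, factor: int = 8,
          bin_thresh: float = 0.01) -> float:
    """Down-sampled IoU: mean-pool by `factor`, binarize at > bin_thresh,
    then sum(M_vs * M_hs) / sum(min(M_vs + M_hs, 1)).

    Robust to small misalignments.  Two empty down-sampled masks are
    defined as perfectly concordant (1.0).  Dims not divisible by the
    factor are zero-padded.
    """
    a = np.asarray(mask_vs, dtype=np.float64)
    b = np.asarray(mask_hs, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")

    def pool(m):
        h, w = m.shape
        ph, pw = (-h) % factor, (-w) % factor
        if ph or pw:
            m = np.pad(m, ((0, ph), (0, pw)))
        h, w = m.shape
        return m.reshape(h // factor, factor, w // factor,
                         factor).mean(axis=(1, 3))

    da = pool(a) > bin_thresh
    db = pool(b) > bin_thresh
    union = np.minimum(da + db, 1).sum()
    if union == 0:
        return 1.0
    return float((da & db).sum() / union)


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Standard windowed SSIM on luminance-converted images."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"ssim: shape mismatch {a.shape} vs {b.shape}")
    if a.ndim == 3 and a.shape[-1] == 3:
        a, b = rgb2gray(a), rgb2gray(b)
    return float(structural_similarity(a, b, data_range=data_range,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False))


class IdentityExtractor:
    """Fallback feature extractor: the image itself as a single layer.

    With this extractor the perceptual distance degenerates to a
    normalized MSE; it requires no pretrained weights and exists so the
    perceptual-metric plumbing is testable offline.
    """

    def __call__(self, image: np.ndarray) -> list[np.ndarray]:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 3 and arr.shape[-1] == 3:
            arr = np.moveaxis(arr, -1, 0)
        elif arr.ndim == 2:
            arr = arr[None]
        return [arr]


def perceptual_distance(a: np.ndarray, b: np.ndarray,
                        extractor=None) -> float | None:
    """Layer-weighted mean squared distance of unit-normalized feature maps.

    `extractor(image) -> [feature maps (C, H, W)]` is pluggable (e.g., a
    pretrained CNN); `None` means no extractor is available and the metric
    is reported as absent (None), never silently substituted.
    """
    if extractor is None:
        return None
    fa, fb = extractor(a), extractor(b)
    dists = []
    for la, lb in zip(fa, fb):
        la = np.asarray(la, dtype=np.float64)
        lb = np.asarray(lb, dtype=np.float64)
        na = la / (np.linalg.norm(la, axis=0, keepdims=True) + 1e-10)
        nb = lb / (np.linalg.norm(lb, axis=0, keepdims=True) + 1e-10)
        dists.append(np.mean(np.sum((na - nb) ** 2, axis=0)))
    return float(np.mean(dists))


def paired_t(values_vs, values_hs) -> tuple[float, float]:
    """Paired two-tailed t-test on the per-pair differences.

    Zero-variance nonzero differences give an infinite-statistic sentinel
    (p = 0); identical lists give (0, 1).
    """
    a = np.asarray(values_vs, dtype=np.float64)
    b = np.asarray(values_hs, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length 1-D arrays, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ----------------------------------------------------------------- reporting
def evaluate_pairs(pairs, stain: str, extractor=None,
                   stain_vectors: StainVectors | None = None,
                   morphology_radius: int = 2) -> dict:
    """Evaluate (virtual, histochemical) RGB pairs for one stain.

    `pairs` is an iterable of (virtual, histochemical) images (H, W, 3) in
    [0, 1].  Returns {"rows": DataFrame, "summary": dict}; pairs with
    mismatched dims are skipped with a logged reason and counted.
    """
    if stain_vectors is None:
        stain_vectors = StainVectors.h_dab() if stain in ("erg", "panck") \
            else StainVectors.h_e()
    rows, skipped = [], []
    nuclei_vs, nuclei_hs, area_vs, area_hs = [], [], [], []
    for i, (vs, hs) in enumerate(pairs):
        vs, hs = np.asarray(vs), np.asarray(hs)
        if vs.shape != hs.shape:
            skipped.append({"pair": i,
                            "reason": f"dims {vs.shape} vs {hs.shape}"})
            continue
        row = {"pair": i, "psnr": psnr(vs, hs), "ssim": ssim(vs, hs)}
        pd_ = perceptual_distance(vs, hs, extractor)
        row["perceptual"] = pd_ if pd_ is not None else np.nan
        if stain == "erg":
            dab_idx = stain_vectors.names.index("dab")
            st_vs = erg_nuclei_stats(dab_mask(
                color_deconvolve(vs, stain_vectors)[..., dab_idx],
                morphology_radius))
            st_hs = erg_nuclei_stats(dab_mask(
                color_deconvolve(hs, stain_vectors)[..., dab_idx],
                morphology_radius))
            row.update(nuclei_count_vs=st_vs.count,
                       nuclei_count_hs=st_hs.count,
                       nuclei_area_vs=st_vs.mean_area,
                       nuclei_area_hs=st_hs.mean_area)
            nuclei_vs.append(st_vs.count)
            nuclei_hs.append(st_hs.count)
            if st_vs.defined and st_hs.defined:
                area_vs.append(st_vs.mean_area)
                area_hs.append(st_hs.mean_area)
        elif stain == "panck":
            dab_idx = stain_vectors.names.index("dab")
            m_vs = dab_mask(color_deconvolve(vs, stain_vectors)[..., dab_idx],
                            morphology_radius)
            m_hs = dab_mask(color_deconvolve(hs, stain_vectors)[..., dab_idx],
                            morphology_radius)
            row["d_iou"] = d_iou(m_vs, m_hs)
        rows.append(row)
    rows_df = pd.DataFrame(rows)
    summary = {"stain": stain, "n_pairs": len(rows),
               "n_skipped": len(skipped), "skipped": skipped,
               "stain_vectors": [list(r) for r in stain_vectors.matrix]}
    if len(rows):
        finite_psnr = rows_df["psnr"][np.isfinite(rows_df["psnr"])]
        summary["psnr_mean"] = float(finite_psnr.mean()) if len(finite_psnr) \
            else float("inf")
        summary["ssim_mean"] = float(rows_df["ssim"].mean())
        if stain == "erg" and len(nuclei_vs) >= 2:
            t, p = paired_t(nuclei_vs, nuclei_hs)
            summary["nuclei_count_t"] = t
            summary["nuclei_count_p"] = p
            if len(area_vs) >= 2:
                t, p = paired_t(area_vs, area_hs)
                summary["nuclei_area_t"] = t
                summary["nuclei_area_p"] = p
        if stain == "panck":
            summary["d_iou_mean"] = float(rows_df["d_iou"].mean())
    return {"rows": rows_df, "summary": summary}


def write_report(report: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report["rows"].to_csv(out_dir / "per_pair.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(report["summary"], indent=2, default=float))
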
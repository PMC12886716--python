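"""Tissue-phantom simulator: co-registered AF/brightfield pairs with truth.

A phantom is a latent tissue geometry — stromal background, smoothed
epithelial regions, vessels (a lumen ringed by small endothelial nuclei)
and elliptical generic nuclei — from which both the 4-channel
autofluorescence input and the three stain targets are rendered.  Because
the three stains are rendered from one geometry, every sample triplet is
perfectly co-registered, and every evaluation statistic (nuclei count and
area, epithelial masks, DAB masks) has an exact ground truth.

Stain rendering follows the Beer–Lambert absorbance model: for per-pixel
chromogen concentrations c_k and unit optical-density vectors v_k,
rgb(x) = exp(−Σ_k c_k(x) · v_k).  Natural-log optical density is used
consistently here and in the deconvolution (evaluation module), so the
round trip recovers concentrations exactly.

AF rendering is a linear compartment mixture plus optional smooth texture
and Gaussian noise; no attempt is made to model real fluorophore spectra —
only relative contrast between compartments matters for learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import DSM_CODES, STAINS, substream, write_af_tiff, write_manifest, \
    write_mask
from .model import warp

# class-map labels
BACKGROUND, STROMA, EPITHELIAL_CYTOPLASM, VESSEL_LUMEN = 0, 1, 2, 3

# classical optical-density stain vectors (unit norm): hematoxylin, eosin, DAB
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
EOSIN_OD = np.array([0.092789, 0.954111, 0.283111])
DAB_OD = np.array([0.268, 0.570, 0.776])


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


class PhantomConfigError(ValueError):
    """Requested structures cannot be placed in the given dimensions."""


@dataclass(frozen=True)
class PhantomSpec:
    """Structure densities/sizes for one phantom tile."""

    n_nuclei: int = 12
    n_vessels: int = 2
    n_epithelial_blobs: int = 2
    nucleus_semi_axes: tuple = (2.0, 5.0)
    vessel_lumen_radius: tuple = (4.0, 7.0)
    endothelial_radius: float = 1.6
    endothelial_spacing_px: float = 8.0
    background_fraction: float = 0.08
    # latent tissue-density texture modulating AF and chromogen uptake
    density_amplitude: float = 0.25
    density_sigma_px: float = 6.0

    def __post_init__(self):
        if self.n_nuclei < 0 or self.n_vessels < 0 or \
                self.n_epithelial_blobs < 0:
            raise PhantomConfigError("structure counts must be nonnegative")

    @classmethod
    def scaled(cls, height: int, width: int, **overrides) -> "PhantomSpec":
        """Defaults scaled to tile area (reference: 12 nuclei per 64x64)."""
        area = height * width / (64.0 * 64.0)
        base = dict(n_nuclei=max(1, round(12 * area)),
                    n_vessels=max(1, round(2 * area)),
                    n_epithelial_blobs=max(1, round(2 * area)))
        base.update(overrides)
        return cls(**base)


@dataclass
class TissuePhantom:
    height: int
    width: int
    class_map: np.ndarray          # per-pixel compartment label
    nuclei_labels: np.ndarray      # integer instance ids, 0 = none
    endothelial_nuclei_mask: np.ndarray
    epithelial_mask: np.ndarray
    rng_seed: int
    density: np.ndarray | None = None  # smooth multiplicative texture, ~1
    ground_truth: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class ChromogenRecipe:
    """Chromogens and the compartments they deposit in.

    `concentration_rules` maps a phantom compartment
    ({background, stroma, epithelial_cytoplasm, vessel_lumen, nuclei,
    endothelial_nuclei, epithelial_mask}) to {stain_name: concentration}.
    """

    stain_class: str
    stain_vectors: tuple           # ((name, unit 3-vector), ...)
    concentration_rules: dict

    def __post_init__(self):
        if self.stain_class not in DSM_CODES:
            raise ValueError(f"unknown stain class {self.stain_class!r}")
        mat = np.array([v for _, v in self.stain_vectors])
        if not np.allclose(np.linalg.norm(mat, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        if np.linalg.matrix_rank(mat) < len(self.stain_vectors):
            raise ValueError("stain vectors must be linearly independent")
        names = {n for n, _ in self.stain_vectors}
        for comp, rules in self.concentration_rules.items():
            for stain, conc in rules.items():
                if stain not in names:
                    raise ValueError(f"rule references unknown stain {stain!r}")
                if conc < 0:
                    raise ValueError(f"negative concentration for {stain!r} "
                                     f"in {comp!r}")
        if self.stain_class == "erg":
            dab_targets = {c for c, r in self.concentration_rules.items()
                           if r.get("dab", 0) > 0}
            if dab_targets - {"endothelial_nuclei"}:
                raise ValueError("ERG recipe may assign DAB only to "
                                 "endothelial nuclei")
        if self.stain_class == "panck":
            dab_targets = {c for c, r in self.concentration_rules.items()
                           if r.get("dab", 0) > 0}
            if dab_targets - {"epithelial_mask"}:
                raise ValueError("PanCK recipe may assign DAB only to the "
                                 "epithelial mask")


def default_recipe(stain_class: str) -> ChromogenRecipe:
    h = ("hematoxylin", tuple(_unit(HEMATOXYLIN_OD)))
    e = ("eosin", tuple(_unit(EOSIN_OD)))
    d = ("dab", tuple(_unit(DAB_OD)))
    if stain_class == "h-and-e":
        return ChromogenRecipe("h-and-e", (h, e), {
            "nuclei": {"hematoxylin": 0.9},
            "stroma": {"eosin": 0.35},
            "epithelial_cytoplasm": {"eosin": 0.55},
        })
    if stain_class == "erg":
        return ChromogenRecipe("erg", (h, d), {
            "nuclei": {"hematoxylin": 0.7},
            "endothelial_nuclei": {"dab": 0.8},
        })
    if stain_class == "panck":
        return ChromogenRecipe("panck", (h, d), {
            "nuclei": {"hematoxylin": 0.7},
            "epithelial_mask": {"dab": 1.0},
        })
    raise ValueError(f"unknown stain class {stain_class!r}")


@dataclass
class MultiplexSample:
    """One co-registered (AF, DSM code, target, stain) unit."""

    af: np.ndarray                 # (4, H, W) in [0, 1]
    dsm_code: int
    target: np.ndarray             # (3, H, W) in [0, 1]
    stain_class: str
    true_displacement: np.ndarray | None = None   # (2, H, W) or None
    sample_id: str = ""
    seed: int = 0
    endothelial_nuclei_mask: np.ndarray | None = None
    epithelial_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.af.shape[1:] != self.target.shape[1:]:
            raise ValueError(f"AF {self.af.shape} and target "
                             f"{self.target.shape} spatial dims differ")
        if DSM_CODES[self.stain_class] != self.dsm_code:
            raise ValueError(f"dsm_code {self.dsm_code} inconsistent with "
                             f"stain {self.stain_class!r}")


# ---------------------------------------------------------------- generation
def _disk_coords(cy, cx, radius, h, w):
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    mask = yy ** 2 + xx ** 2 <= radius ** 2
    ys, xs = yy[mask] + int(round(cy)), xx[mask] + int(round(cx))
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    return ys[keep], xs[keep]


def _ellipse_coords(cy, cx, a, b, theta, h, w):
    r = int(np.ceil(max(a, b)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    ys, xs = yy[mask] + int(round(cy)), xx[mask] + int(round(cx))
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    return ys[keep], xs[keep]


def generate_phantom(height: int, width: int,
                     spec: PhantomSpec | None = None,
                     seed: int = 0) -> TissuePhantom:
    """Generate one phantom; a pure function of (height, width, spec, seed)."""
    if height < 64 or width < 64:
        raise PhantomConfigError(f"tile must be at least 64x64, got "
                                 f"{height}x{width}")
    spec = spec or PhantomSpec.scaled(height, width)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(101,)))
    class_map = np.full((height, width), STROMA, dtype=np.uint8)

    # background gaps from smoothed-noise thresholding
    if spec.background_fraction > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=min(height, width) / 8)
        thresh = np.quantile(noise, spec.background_fraction)
        class_map[noise < thresh] = BACKGROUND

    # epithelial regions: smoothed random blobs
    epith_region = np.zeros((height, width), dtype=bool)
    if spec.n_epithelial_blobs > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=min(height, width) / 10)
        frac = min(0.45, 0.14 * spec.n_epithelial_blobs)
        epith_region = noise > np.quantile(noise, 1.0 - frac)
        epith_region &= class_map == STROMA
        class_map[epith_region] = EPITHELIAL_CYTOPLASM

    nuclei_labels = np.zeros((height, width), dtype=np.int32)
    occupied = np.zeros((height, width), dtype=bool)   # nuclei + margins

    # vessels: lumen disks with endothelial nuclei studding the ring
    endo_ids = []
    vessel_centers = []
    next_id = spec.n_nuclei + 1   # generic nuclei take ids 1..n_nuclei
    margin = max(spec.vessel_lumen_radius) + 4
    for _ in range(spec.n_vessels):
        placed = False
        for _try in range(300):
            r = rng.uniform(*spec.vessel_lumen_radius)
            cy = rng.uniform(margin, height - margin)
            cx = rng.uniform(margin, width - margin)
            if all((cy - vy) ** 2 + (cx - vx) ** 2 > (4 * r) ** 2
                   for vy, vx in vessel_centers):
                placed = True
                break
        if not placed:
            raise PhantomConfigError(
                f"could not place {spec.n_vessels} vessels in "
                f"{height}x{width}")
        vessel_centers.append((cy, cx))
        ys, xs = _disk_coords(cy, cx, r, height, width)
        class_map[ys, xs] = VESSEL_LUMEN
        ring_r = r + 1.0 + spec.endothelial_radius
        k = max(3, int(2 * np.pi * ring_r / spec.endothelial_spacing_px))
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(k):
            ang = phase + 2 * np.pi * i / k
            ny = cy + ring_r * np.sin(ang)
            nx = cx + ring_r * np.cos(ang)
            ys, xs = _disk_coords(ny, nx, spec.endothelial_radius,
                                  height, width)
            if len(ys) == 0 or occupied[ys, xs].any():
                continue
            nuclei_labels[ys, xs] = next_id
            endo_ids.append(next_id)
            next_id += 1
            oy, ox = _disk_coords(ny, nx, spec.endothelial_radius + 5,
                                  height, width)
            occupied[oy, ox] = True

    # generic nuclei: non-overlapping random ellipses outside lumina
    a_lo, a_hi = spec.nucleus_semi_axes
    placed_nuclei = 0
    epith_nucleus_ids = []
    for nid in range(1, spec.n_nuclei + 1):
        ok = False
        for _try in range(800):
            # crowded tiles: progressively relax toward the smallest
            # allowed nuclei so dense specs remain placeable
            shrink = 1.0 if _try < 300 else (0.8 if _try < 550 else 0.6)
            hi = max(a_lo, a_lo + (a_hi - a_lo) * shrink)
            cy = rng.uniform(a_hi, height - a_hi)
            cx = rng.uniform(a_hi, width - a_hi)
            a = rng.uniform(a_lo, hi) * (1.0 if _try < 550 else shrink)
            b = rng.uniform(a_lo, hi) * (1.0 if _try < 550 else shrink)
            a, b = max(a, 1.2), max(b, 1.2)
            theta = rng.uniform(0, np.pi)
            ys, xs = _ellipse_coords(cy, cx, a, b, theta, height, width)
            if len(ys) == 0:
                continue
            if occupied[ys, xs].any() or \
                    (class_map[ys, xs] == VESSEL_LUMEN).any():
                continue
            nuclei_labels[ys, xs] = nid
            oy, ox = _ellipse_coords(cy, cx, a + 2, b + 2, theta,
                                     height, width)
            occupied[oy, ox] = True
            if class_map[int(round(cy)), int(round(cx))] == \
                    EPITHELIAL_CYTOPLASM:
                epith_nucleus_ids.append(nid)
            ok = True
            break
        if not ok:
            raise PhantomConfigError(
                f"could not place nucleus {nid}/{spec.n_nuclei} in "
                f"{height}x{width}; reduce density or enlarge the tile")
        placed_nuclei += 1

    endothelial_mask = np.isin(nuclei_labels, endo_ids)
    epithelial_mask = (class_map == EPITHELIAL_CYTOPLASM) | \
        np.isin(nuclei_labels, epith_nucleus_ids)

    # shared latent texture: local tissue density modulates both the AF
    # signal and chromogen uptake, so the two modalities are correlated
    if spec.density_amplitude > 0:
        d = ndimage.gaussian_filter(rng.standard_normal((height, width)),
                                    sigma=spec.density_sigma_px)
        d /= max(np.abs(d).max(), 1e-12)
        density = 1.0 + spec.density_amplitude * d
    else:
        density = np.ones((height, width))

    return TissuePhantom(
        height=height, width=width, class_map=class_map,
        nuclei_labels=nuclei_labels,
        endothelial_nuclei_mask=endothelial_mask,
        epithelial_mask=epithelial_mask, rng_seed=int(seed),
        density=density,
        ground_truth={"n_nuclei": placed_nuclei,
                      "n_endothelial_nuclei": len(endo_ids),
                      "n_vessels": spec.n_vessels,
                      "endothelial_ids": endo_ids})


# ----------------------------------------------------------------- rendering
def _compartment_masks(phantom: TissuePhantom) -> dict[str, np.ndarray]:
    nuc = phantom.nuclei_labels > 0
    return {
        "background": (phantom.class_map == BACKGROUND) & ~nuc,
        "stroma": (phantom.class_map == STROMA) & ~nuc,
        "epithelial_cytoplasm":
            (phantom.class_map == EPITHELIAL_CYTOPLASM) & ~nuc,
        "vessel_lumen": (phantom.class_map == VESSEL_LUMEN) & ~nuc,
        "nuclei": nuc,
        "endothelial_nuclei": phantom.endothelial_nuclei_mask,
        "epithelial_mask": phantom.epithelial_mask,
    }


def concentration_maps(phantom: TissuePhantom,
                       recipe: ChromogenRecipe) -> np.ndarray:
    """(H, W, n_stains) chromogen concentrations implied by the recipe."""
    masks = _compartment_masks(phantom)
    names = [n for n, _ in recipe.stain_vectors]
    conc = np.zeros((phantom.height, phantom.width, len(names)))
    for comp, rules in recipe.concentration_rules.items():
        for stain, c in rules.items():
            conc[..., names.index(stain)] += c * masks[comp]
    if phantom.density is not None:
        conc *= phantom.density[..., None]
    return conc


def render_stain(phantom: TissuePhantom, recipe: ChromogenRecipe,
                 noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Beer–Lambert rendering: rgb = exp(−C · V), white where C = 0.

    Returns (H, W, 3) in [0, 1]; optional Gaussian noise in RGB space.
    """
    conc = concentration_maps(phantom, recipe)
    vecs = np.array([v for _, v in recipe.stain_vectors])
    rgb = np.exp(-(conc @ vecs))
    if noise_sd > 0:
        rng = substream(seed, "noise")
        rgb = rgb + rng.normal(0, noise_sd, rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


DEFAULT_AF_MIXING = {
    #                DAPI  FITC  TxRed  Cy5
    "background":          (0.00, 0.02, 0.02, 0.02),
    "stroma":              (0.08, 0.50, 0.25, 0.20),
    "epithelial_cytoplasm": (0.12, 0.32, 0.60, 0.28),
    "vessel_lumen":        (0.02, 0.06, 0.10, 0.55),
    "nuclei":              (0.85, 0.15, 0.20, 0.10),
    "endothelial_nuclei":  (0.05, 0.00, 0.00, 0.10),  # additive on nuclei
}


def render_af(phantom: TissuePhantom, mixing: dict | None = None,
              noise_sd: float = 0.0, seed: int = 0,
              texture_amplitude: float = 0.0) -> np.ndarray:
    """(4, H, W) autofluorescence image: compartment mixture (+ texture
    + noise), clipped to [0, 1]; deterministic under a fixed seed."""
    mixing = mixing if mixing is not None else DEFAULT_AF_MIXING
    for comp, vals in mixing.items():
        if len(vals) != 4 or any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"mixing for {comp!r} must be four values in "
                             "[0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    masks = _compartment_masks(phantom)
    af = np.zeros((4, phantom.height, phantom.width))
    for comp, vals in mixing.items():
        m = masks[comp]
        for ch in range(4):
            af[ch] += vals[ch] * m
    if phantom.density is not None:
        af *= phantom.density[None]
    rng = substream(seed, "noise")
    if texture_amplitude > 0:
        sigma = min(phantom.height, phantom.width) / 12
        tex = ndimage.gaussian_filter(
            rng.standard_normal(af.shape), sigma=(0, sigma, sigma))
        tex /= max(np.abs(tex).max(), 1e-12)
        af = af + texture_amplitude * tex
    if noise_sd > 0:
        af = af + rng.normal(0, noise_sd, af.shape)
    return np.clip(af, 0.0, 1.0).astype(np.float32)


def make_sample(phantom: TissuePhantom, stain_class: str,
                af: np.ndarray | None = None, noise_sd: float = 0.02,
                texture_amplitude: float = 0.0,
                sample_id: str = "") -> MultiplexSample:
    """Render one (AF, target) pair for a stain from a phantom."""
    if af is None:
        af = render_af(phantom, noise_sd=noise_sd,
                       texture_amplitude=texture_amplitude,
                       seed=phantom.rng_seed)
    target = render_stain(phantom, default_recipe(stain_class))
    return MultiplexSample(
        af=af, dsm_code=DSM_CODES[stain_class],
        target=np.moveaxis(target, -1, 0).astype(np.float32),
        stain_class=stain_class, sample_id=sample_id, seed=phantom.rng_seed,
        endothelial_nuclei_mask=phantom.endothelial_nuclei_mask,
        epithelial_mask=phantom.epithelial_mask)


# -------------------------------------------------------------- misalignment
def smooth_random_field(height: int, width: int, amplitude: float,
                        smoothness_sigma: float, seed: int = 0) -> np.ndarray:
    """(2, H, W) Gaussian-smoothed random displacement, max norm = amplitude."""
    rng = substream(seed, "misalign")
    f = ndimage.gaussian_filter(rng.standard_normal((2, height, width)),
                                sigma=(0, smoothness_sigma, smoothness_sigma))
    norm = np.sqrt(f[0] ** 2 + f[1] ** 2).max()
    if norm > 0 and amplitude > 0:
        f *= amplitude / norm
    else:
        f[:] = 0.0
    return f.astype(np.float32)


def make_misaligned_pair(sample: MultiplexSample, amplitude: float,
                         smoothness_sigma: float | None = None,
                         seed: int = 0) -> MultiplexSample:
    """Warp the target by a smooth random field emulating staining
    distortion; the true field is stored for registration experiments."""
    h, w = sample.target.shape[1:]
    if amplitude > 0.1 * min(h, w):
        raise ValueError(f"amplitude {amplitude} exceeds 10% of the image "
                         f"side ({min(h, w)}); invertibility not guaranteed")
    if smoothness_sigma is None:
        smoothness_sigma = min(h, w) / 2
    field = smooth_random_field(h, w, amplitude, smoothness_sigma, seed)
    warped = warp(sample.target, field) if amplitude > 0 \
        else sample.target.copy()
    return replace(sample, target=np.asarray(warped, dtype=np.float32),
                   true_displacement=field)


# ---------------------------------------------------------------- dataset IO
def write_dataset(samples: list[MultiplexSample], directory) -> Path:
    """Write AF/target/mask files plus a manifest; lossless round trip."""
    directory = Path(directory)
    (directory / "af").mkdir(parents=True, exist_ok=True)
    (directory / "targets").mkdir(exist_ok=True)
    (directory / "masks").mkdir(exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        sid = s.sample_id or f"tile_{i:04d}"
        af_path = f"af/{sid}.tif"
        target_path = f"targets/{sid}_{s.stain_class}.tif"
        write_af_tiff(s.af, directory / af_path)
        import tifffile
        tifffile.imwrite(str(directory / target_path),
                         s.target.astype(np.float32),
                         photometric="minisblack")
        mask_paths = []
        for name, mask in (("endo", s.endothelial_nuclei_mask),
                           ("epith", s.epithelial_mask)):
            if mask is not None:
                mp = f"masks/{sid}_{name}.png"
                write_mask(mask, directory / mp)
                mask_paths.append(mp)
        rows.append({"id": sid, "stain": s.stain_class,
                     "dsm_code": s.dsm_code, "af_path": af_path,
                     "target_path": target_path,
                     "mask_paths": ";".join(mask_paths), "seed": s.seed})
    manifest_path = directory / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path


def read_dataset(manifest_path) -> list[MultiplexSample]:
    """Load samples written by `write_dataset` (pixel-identical arrays)."""
    import tifffile
    from .io import load_manifest, read_af_tiff, read_mask
    man = load_manifest(manifest_path)
    samples = []
    for _, r in man.rows.iterrows():
        af = read_af_tiff(man.root / r["af_path"])
        target = tifffile.imread(str(man.root / r["target_path"]))
        masks = {}
        mask_field = r["mask_paths"]
        if isinstance(mask_field, str) and mask_field:
            for mp in mask_field.split(";"):
                key = "endothelial_nuclei_mask" if "_endo" in mp \
                    else "epithelial_mask"
                masks[key] = read_mask(man.root / mp)
        samples.append(MultiplexSample(
            af=af, dsm_code=int(r["dsm_code"]),
            target=np.asarray(target, dtype=np.float32),
            stain_class=str(r["stain"]), sample_id=str(r["id"]),
            seed=int(r["seed"]), **masks))
    return samples


def phantom_cohort(n_phantoms: int, height: int, width: int, seed: int,
                   stains=STAINS, spec: PhantomSpec | None = None,
                   noise_sd: float = 0.02, texture_amplitude: float = 0.0
                   ) -> dict[str, list[MultiplexSample]]:
    """Per-stain sample lists over `n_phantoms` shared geometries."""
    rng = substream(seed, "phantom")
    out = {s: [] for s in stains}
    for i in range(n_phantoms):
        ph_seed = int(rng.integers(0, 2 ** 31 - 1))
        ph = generate_phantom(height, width, spec, seed=ph_seed)
        af = render_af(ph, noise_sd=noise_sd,
                       texture_amplitude=texture_amplitude, seed=ph_seed)
        for stain in stains:
            out[stain].append(make_sample(ph, stain, af=af,
                                          sample_id=f"ph{i:03d}"))
    return out
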
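"""Readers/writers, manifests and seeding shared by all stages.

The manifest (a CSV with a commented header) is the single source of truth
for stain classes, staining-matrix codes and the autofluorescence channel
order; image files carry no trusted metadata.  A single master seed is
expanded into independent named substreams so that, e.g., consuming phantom
randomness never shifts the batch-sampler stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

AF_CHANNELS = ("DAPI", "FITC", "TxRed", "Cy5")
MANIFEST_VERSION = 1
MANIFEST_COLUMNS = ["id", "stain", "dsm_code", "af_path", "target_path",
                    "mask_paths", "seed"]

# stain class <-> staining-matrix code (constant conditioning channel)
DSM_CODES = {"h-and-e": 2, "panck": 1, "erg": -1}
CODE_TO_STAIN = {v: k for k, v in DSM_CODES.items()}
STAINS = tuple(DSM_CODES)

# fixed, documented substream labels for the master seed
_STREAM_IDS = {"phantom": 1, "sampler": 2, "augment": 3, "init": 4,
               "noise": 5, "misalign": 6}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (master seed, named stream)."""
    if name not in _STREAM_IDS:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(_STREAM_IDS)}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STREAM_IDS[name],)))


def seed_all(seed: int) -> dict[str, np.random.Generator]:
    """One generator per named component, all derived from `seed`."""
    return {name: substream(seed, name) for name in _STREAM_IDS}


# --------------------------------------------------------------------- images
def write_af_tiff(image: np.ndarray, path) -> None:
    """Write a 4-channel AF tile (channel order DAPI, FITC, TxRed, Cy5)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != len(AF_CHANNELS):
        raise ValueError(f"expected ({len(AF_CHANNELS)}, H, W) AF image with "
                         f"channel order {AF_CHANNELS}, got {image.shape}")
    tifffile.imwrite(str(path), image.astype(np.float32),
                     photometric="minisblack")


def read_af_tiff(path) -> np.ndarray:
    """Read a 4-channel AF tile; 16-bit files are scaled to [0, 1]."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] == len(AF_CHANNELS) and \
            arr.shape[0] != len(AF_CHANNELS):
        arr = np.moveaxis(arr, -1, 0)
    if arr.ndim != 3 or arr.shape[0] != len(AF_CHANNELS):
        raise ValueError(f"{path}: expected {len(AF_CHANNELS)} channels in "
                         f"order {AF_CHANNELS}, got array of shape {arr.shape}")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    elif arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    return np.ascontiguousarray(arr, dtype=np.float32)


def write_rgb(image: np.ndarray, path) -> None:
    """Write an RGB image in [0, 1] as 8-bit TIFF/PNG (round half to even)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got {image.shape}")
    q = np.rint(np.clip(image, 0, 1) * 255).astype(np.uint8)
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, q, photometric="rgb")
    else:
        import imageio.v3 as iio
        iio.imwrite(path, q)


def read_rgb(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    return np.ascontiguousarray(arr, dtype=np.float32)


def write_mask(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio
    iio.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio
    return (np.asarray(iio.imread(str(path))) > 0)


# ------------------------------------------------------------------- manifest
@dataclass
class Manifest:
    rows: pd.DataFrame
    root: Path = field(default_factory=Path)
    version: int = MANIFEST_VERSION
    channel_order: tuple = AF_CHANNELS

    def __len__(self):
        return len(self.rows)


def write_manifest(rows: pd.DataFrame, path) -> None:
    path = Path(path)
    header = (f"# virtmihc manifest v{MANIFEST_VERSION}; "
              f"af_channels={','.join(AF_CHANNELS)}\n")
    with open(path, "w") as fh:
        fh.write(header)
        rows.to_csv(fh, index=False)


def load_manifest(path) -> Manifest:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# virtmihc manifest"):
            raise ValueError(f"{path}: missing manifest header line")
        rows = pd.read_csv(fh, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return Manifest(rows=rows, root=path.parent)


def validate_manifest(manifest: Manifest) -> dict:
    """Flag missing files, stain/code conflicts and duplicate ids."""
    problems = {"missing_files": [], "stain_code_conflicts": [],
                "duplicate_ids": [], "warnings": []}
    rows = manifest.rows
    if len(rows) == 0:
        problems["warnings"].append("manifest has zero rows")
    dup = rows["id"][rows["id"].duplicated()].tolist()
    problems["duplicate_ids"] = dup
    for _, r in rows.iterrows():
        stain = str(r["stain"])
        code = int(r["dsm_code"])
        if DSM_CODES.get(stain) != code:
            problems["stain_code_conflicts"].append(
                f"id {r['id']}: stain {stain!r} with code {code} "
                f"(expected {DSM_CODES.get(stain)})")
        for col in ("af_path", "target_path"):
            p = manifest.root / str(r[col])
            if not p.exists():
                problems["missing_files"].append(str(p))
    problems["ok"] = not (problems["missing_files"]
                          or problems["stain_code_conflicts"]
                          or problems["duplicate_ids"])
    return problems


def write_run_config(out_dir, config: dict) -> Path:
    """Serialize the merged run configuration before any computation."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"virtmihc_version": __version__, **config}
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
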
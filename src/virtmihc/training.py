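"""Optimization loop: balanced three-stain sampling, augmentation, and
alternating generator / registration / discriminator updates.

Schedule: the generator is updated 4 times per discriminator update
(G,G,G,G,D repeating); the registration module is updated alongside every
generator update on its own objective.  Gradients are isolated: each
optimizer steps only its own network's parameters, and the warp field used
in the generator's Huber term is treated as a constant with respect to the
registration parameters (gradients still flow through the warp into the
generator's output).

Two presets are provided.  `paper` carries the full-scale settings
(512-pixel crops, Adam at 2e-5 / 2e-6 / 2e-6, base width 64, depth-7
registration net) and exists as configuration only.  `tiny` is the
scaled-down study used throughout the tests: 64-pixel tiles, base width 8,
a depth-4 registration net with a coarse-grid displacement head, a linear
generator output head, Adam at 1e-3 / 1e-4 / 1e-3 with (0.9, 0.99)
moments — chosen so a few hundred steps on CPU reach a meaningful
operating point.  Loss coefficients, batch size and the 4:1 schedule are
identical in both presets; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .autodiff import Tensor, concat
from .io import DSM_CODES, substream, write_run_config
from .losses import LossCoefficients, discriminator_loss, generator_loss, \
    registration_loss
from .model import ModelBundle
from .phantom import MultiplexSample

LOG_COLUMNS = ["step", "stain", "l_huber", "l_adv", "l_tv", "l_reg",
               "l_smth", "l_disc"]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr_generator: float = 2e-5
    lr_discriminator: float = 2e-6
    lr_registration: float = 2e-6
    batch_size: int = 4
    g_updates_per_d_update: int = 4
    crop: int = 512
    steps: int = 1000
    seed: int = 0
    augment: bool = True
    g_base_width: int = 64
    d_stem_width: int = 64
    r_base_width: int = 16
    r_depth: int = 7
    r_head_level: int = 0
    activation: str = "sigmoid"
    adam_betas: tuple = (0.9, 0.999)
    checkpoint_every: int = 0           # 0 = final only
    coefficients: LossCoefficients = dc_field(default_factory=LossCoefficients)

    def __post_init__(self):
        if min(self.lr_generator, self.lr_discriminator,
               self.lr_registration) < 0:
            raise ValueError("learning rates must be >= 0")
        if self.crop % max(16, 2 ** self.r_depth):
            raise ValueError(f"crop {self.crop} must be divisible by "
                             f"{max(16, 2 ** self.r_depth)}")

    def model_config(self) -> dict:
        return {"g_base_width": self.g_base_width,
                "d_stem_width": self.d_stem_width,
                "r_base_width": self.r_base_width, "r_depth": self.r_depth,
                "r_head_level": self.r_head_level,
                "activation": self.activation,
                "adam_betas": list(self.adam_betas),
                "lr_generator": self.lr_generator,
                "lr_discriminator": self.lr_discriminator,
                "lr_registration": self.lr_registration,
                "dsm_codes": DSM_CODES}


PRESETS = {
    "paper": {},
    "tiny": {"g_base_width": 8, "d_stem_width": 8, "r_base_width": 8,
             "r_depth": 4, "r_head_level": 3, "crop": 64, "lr_generator": 1e-3,
             "lr_discriminator": 1e-4, "lr_registration": 1e-3,
             "activation": "linear", "adam_betas": (0.9, 0.99)},
}


def make_config(preset: str = "paper", **overrides) -> TrainConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {list(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


# ------------------------------------------------------------------ sampling
def balanced_batches(datasets: dict[str, list], batch_size: int,
                     rng: np.random.Generator):
    """Infinite stream of batches; each draw's stain is uniform over the
    three stains, independent across draws (sampling with replacement)."""
    stains = sorted(datasets)
    for stain in stains:
        if len(datasets[stain]) == 0:
            raise ValueError(f"stain dataset {stain!r} is empty; "
                             "equal-probability sampling is impossible")
    while True:
        batch = []
        for _ in range(batch_size):
            stain = stains[rng.integers(len(stains))]
            pool = datasets[stain]
            batch.append(pool[rng.integers(len(pool))])
        yield batch


def apply_dihedral(sample: MultiplexSample, k: int,
                   flip: bool) -> MultiplexSample:
    """Rotate by k*90 degrees then optionally flip; identical transform on
    AF, target and masks (the DSM plane is constant and unaffected)."""
    h, w = sample.af.shape[1:]
    if k % 2 and h != w:
        raise ValueError("90/270-degree rotations require square tiles")

    def tf(arr):
        if arr is None:
            return None
        out = np.rot90(arr, k, axes=(-2, -1))
        if flip:
            out = out[..., ::-1]
        return np.ascontiguousarray(out)

    identity = (k % 4 == 0) and not flip
    return replace(sample, af=tf(sample.af), target=tf(sample.target),
                   endothelial_nuclei_mask=tf(sample.endothelial_nuclei_mask),
                   epithelial_mask=tf(sample.epithelial_mask),
                   true_displacement=sample.true_displacement if identity
                   else None)


def invert_dihedral(sample: MultiplexSample, k: int,
                    flip: bool) -> MultiplexSample:
    if flip:
        sample = apply_dihedral(sample, 0, True)
    return apply_dihedral(sample, (-k) % 4, False)


def augment(sample: MultiplexSample,
            rng: np.random.Generator) -> MultiplexSample:
    """Random rotation in {0, 90, 180, 270} degrees plus random flip."""
    k = int(rng.integers(4))
    flip = bool(rng.integers(2))
    return apply_dihedral(sample, k, flip)


def random_crop(sample: MultiplexSample, crop: int,
                rng: np.random.Generator) -> MultiplexSample:
    h, w = sample.af.shape[1:]
    if h == crop and w == crop:
        return sample
    if h < crop or w < crop:
        raise ValueError(f"tile {h}x{w} smaller than crop {crop}")
    y = int(rng.integers(h - crop + 1))
    x = int(rng.integers(w - crop + 1))

    def cut(a):
        return None if a is None else \
            np.ascontiguousarray(a[..., y:y + crop, x:x + crop])

    return replace(sample, af=cut(sample.af), target=cut(sample.target),
                   endothelial_nuclei_mask=cut(sample.endothelial_nuclei_mask),
                   epithelial_mask=cut(sample.epithelial_mask),
                   true_displacement=cut(sample.true_displacement))


# ---------------------------------------------------------------- train step
def _stack_batch(batch: list[MultiplexSample]):
    af = np.stack([s.af for s in batch]).astype(np.float32)
    dsm = np.stack([np.full(s.af.shape[1:], float(s.dsm_code),
                            dtype=np.float32)[None] for s in batch])
    x = np.concatenate([af, dsm], axis=1)
    target = np.stack([s.target for s in batch]).astype(np.float32)
    return x, dsm, target


def _check_finite(value: float, step: int, stains, components: dict):
    if not np.isfinite(value):
        snapshot = {k: float(getattr(v, "data", v)) for k, v in
                    components.items()}
        raise TrainingDiverged(f"non-finite loss at step {step} "
                               f"(stains {stains}): {snapshot}")


def g_update(bundle: ModelBundle, batch, coeffs: LossCoefficients,
             update: bool = True) -> dict:
    """One generator update (with its riding registration update)."""
    x_np, dsm_np, target_np = _stack_batch(batch)
    stains = ",".join(s.stain_class for s in batch)

    x = Tensor(x_np)
    target_t = Tensor(target_np)
    g_out = bundle.generator(x)
    g_np = g_out.data

    # --- registration update: only R's parameters receive gradients
    bundle.registration.zero_grad()
    g_const = Tensor(g_np)
    field = bundle.registration(concat([g_const, target_t], axis=1))
    r_total, r_comp = registration_loss(g_const, target_t, field,
                                        coeffs=coeffs)
    _check_finite(float(r_total.data), bundle.step, stains, r_comp)
    if update:
        r_total.backward()
        bundle.opt_r.step()
    field_const = field.detach()

    # --- generator update: warp field held constant, gradients flow
    # through the warp and the discriminator into G only
    bundle.generator.zero_grad()
    bundle.discriminator.zero_grad()
    d_logit = bundle.discriminator(concat([g_out, Tensor(dsm_np)], axis=1))
    g_total, g_comp = generator_loss(g_out, target_t, d_logit, field_const,
                                     coeffs=coeffs)
    _check_finite(float(g_total.data), bundle.step, stains, g_comp)
    if update:
        g_total.backward()
        bundle.opt_g.step()
        bundle.discriminator.zero_grad()   # discard D grads from G's pass

    rec = {"step": bundle.step, "stain": stains,
           "l_huber": float(g_comp["l_huber"].data),
           "l_adv": float(g_comp["l_adv"].data),
           "l_tv": float(g_comp["l_tv"].data),
           "l_reg": float(r_comp["l_reg"].data),
           "l_smth": float(r_comp["l_smth"].data),
           "l_disc": np.nan}
    rec["_g_np"] = g_np
    return rec


def d_update(bundle: ModelBundle, batch, update: bool = True,
             g_np: np.ndarray | None = None) -> float:
    x_np, dsm_np, target_np = _stack_batch(batch)
    if g_np is None:
        g_np = bundle.generator(Tensor(x_np)).data   # detached output
    bundle.discriminator.zero_grad()
    logit_fake = bundle.discriminator(
        concat([Tensor(g_np), Tensor(dsm_np)], axis=1))
    logit_real = bundle.discriminator(
        concat([Tensor(target_np), Tensor(dsm_np)], axis=1))
    loss = discriminator_loss(logit_fake, logit_real)
    _check_finite(float(loss.data), bundle.step, "D", {"l_disc": loss})
    if update:
        loss.backward()
        bundle.opt_d.step()
    return float(loss.data)


def train_step(bundle: ModelBundle, batches, coeffs: LossCoefficients,
               update: bool = True) -> list[dict]:
    """One scheduled unit: 4 generator updates then 1 discriminator update.

    `batches` is a list of batches cycled across the generator updates
    (pass one batch to reuse it); the last batch feeds the discriminator.
    """
    if isinstance(batches[0], MultiplexSample):
        batches = [batches]
    records = []
    n_g = 4
    for i in range(n_g):
        batch = batches[i % len(batches)]
        rec = g_update(bundle, batch, coeffs, update=update)
        bundle.step += 1
        records.append(rec)
    last_batch = batches[(n_g - 1) % len(batches)]
    records[-1]["l_disc"] = d_update(bundle, last_batch, update=update,
                                     g_np=records[-1]["_g_np"])
    for rec in records:
        rec.pop("_g_np", None)
    return records


# -------------------------------------------------------------- full training
def _rng_state_blob(rngs: dict) -> np.ndarray:
    state = {k: v.bit_generator.state for k, v in rngs.items()}
    return np.frombuffer(json.dumps(state).encode(), dtype=np.uint8)


def _restore_rngs(blob: np.ndarray) -> dict:
    state = json.loads(bytes(blob.tobytes()).decode())
    out = {}
    for k, s in state.items():
        g = np.random.default_rng(0)
        g.bit_generator.state = s
        out[k] = g
    return out


def train(config: TrainConfig, datasets: dict[str, list[MultiplexSample]],
          out_dir, resume_from=None) -> tuple[ModelBundle, pd.DataFrame]:
    """Train on per-stain sample lists; reproducible under (config, seed).

    Writes the merged run configuration up front, checkpoints at the
    configured cadence plus a final one, and the structured loss log.
    Resuming from a checkpoint reproduces the uninterrupted trajectory
    bitwise (optimizer moments and sampler/augmentation streams are part
    of the checkpoint).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    write_run_config(out_dir, cfg_dict)

    if resume_from is not None:
        bundle = ModelBundle.load(resume_from)
        with np.load(resume_from) as z:
            rngs = _restore_rngs(z["rng_state"])
    else:
        init_rng = substream(config.seed, "init")
        bundle = ModelBundle.create(config.model_config(), init_rng)
        rngs = {"sampler": substream(config.seed, "sampler"),
                "augment": substream(config.seed, "augment")}

    stream = balanced_batches(datasets, config.batch_size, rngs["sampler"])
    records: list[dict] = []
    coeffs = config.coefficients

    def prep(batch):
        out = []
        for s in batch:
            s = random_crop(s, min(config.crop, s.af.shape[1]),
                            rngs["augment"])
            if config.augment:
                s = augment(s, rngs["augment"])
            out.append(s)
        return out

    def save_ckpt(path):
        bundle.save(path)
        with np.load(path) as z:
            payload = dict(z)
        payload["rng_state"] = _rng_state_blob(rngs)
        np.savez(path, **payload)

    n_units = (config.steps - bundle.step + 3) // 4
    best_huber = float("inf")
    for _ in range(max(n_units, 0)):
        batches = [prep(next(stream)) for _ in range(4)]
        records.extend(train_step(bundle, batches, coeffs))
        if config.checkpoint_every and \
                bundle.step % config.checkpoint_every == 0:
            save_ckpt(out_dir / f"ckpt_{bundle.step:06d}.npz")
        recent = np.mean([r["l_huber"] for r in records[-20:]])
        if len(records) >= 20 and recent < best_huber:
            best_huber = recent
            save_ckpt(out_dir / "best.npz")

    save_ckpt(out_dir / "final.npz")
    log = pd.DataFrame(records, columns=LOG_COLUMNS)
    log_path = out_dir / "loss_log.tsv"
    header = not (resume_from is not None and log_path.exists())
    log.to_csv(log_path, sep="\t", index=False, mode="w" if header else "a",
               header=header)
    return bundle, log


# ------------------------------------------------- registration-only training
def train_registration_only(pairs, steps: int, config: TrainConfig,
                            coeffs: LossCoefficients | None = None):
    """Train only the registration net on (reference, misaligned) pairs.

    The generator is bypassed (its role is played by the already-rendered
    reference image), isolating the registration module's ability to
    recover known smooth misalignment fields.  Returns (net, history)
    where history rows are (step, huber_aligned, smth).
    """
    coeffs = coeffs or config.coefficients
    rng_init = substream(config.seed, "init")
    from .model import build_registration
    net = build_registration(config.r_base_width, depth=config.r_depth,
                             rng=rng_init, head_level=config.r_head_level)
    opt = nn.Adam(net.parameters(), config.lr_registration,
                  betas=tuple(config.adam_betas))
    rng = substream(config.seed, "sampler")
    history = []
    full_batch = config.batch_size >= len(pairs)
    for step in range(steps):
        # deterministic full-batch updates when the cohort fits in a batch
        idx = list(range(len(pairs))) if full_batch else \
            [int(rng.integers(len(pairs))) for _ in range(config.batch_size)]
        ref = Tensor(np.stack([pairs[i][0] for i in idx]))
        mis = Tensor(np.stack([pairs[i][1] for i in idx]))
        net.zero_grad()
        field = net(concat([ref, mis], axis=1))
        total, comp = registration_loss(ref, mis, field, coeffs=coeffs)
        if not np.isfinite(float(total.data)):
            raise TrainingDiverged(f"registration loss diverged at {step}")
        total.backward()
        opt.step()
        history.append({"step": step,
                        "huber_aligned": float(comp["l_reg"].data),
                        "smth": float(comp["l_smth"].data)})
    return net, pd.DataFrame(history)
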
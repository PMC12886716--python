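"""Training objectives of the staining framework.

The generator objective combines a registration-warped Huber term, an
adversarial binary cross-entropy term and a total-variation regularizer:

    l_G = alpha * L_phi(target, G(x, c) o T) + beta * BCE(D(G(x, c), c), 1)
          + gamma * TV(G(x, c)),        alpha, beta, gamma = 10, 10, 1e-4

where T = R(G(x, c), target) is the displacement field and "o" the warp.
The discriminator minimizes BCE(D(G, c), 0) + BCE(D(target, c), 1); the
registration module minimizes lambda * L_phi(target, G o T) + mu * SMTH(T)
with lambda, mu = 20, 10.  L_phi is the Huber loss with threshold phi = 1,
normalized by the pixel count; TV is a raw sum over interior forward
differences (the small gamma compensates the deliberate scale mismatch);
SMTH is the mean squared forward difference of the field.

All functions accept numpy arrays or autodiff Tensors; with Tensor inputs
the returned value participates in the gradient tape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, where
from .model import warp


@dataclass(frozen=True)
class LossCoefficients:
    alpha: float = 10.0
    beta: float = 10.0
    gamma: float = 0.0001
    lambda_: float = 20.0
    mu: float = 10.0
    phi: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "lambda_", "mu", "phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"coefficient {name} must be > 0")


def _lift(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64)
                  if not isinstance(x, np.ndarray) else x)


def _maybe_float(t: Tensor):
    if t._parents:
        return t
    return float(t.data)


def _check_shapes(a: Tensor, b: Tensor, op: str):
    if a.shape != b.shape:
        raise ValueError(f"{op}: shape mismatch {a.shape} vs {b.shape}")


def huber(a, b, phi: float = 1.0):
    """Pixel-mean Huber loss: quadratic below phi, linear above.

    (1/MN) [ sum_{|d|<phi} d^2/(2 phi) + sum_{|d|>=phi} (|d| - phi/2) ]
    """
    if phi <= 0:
        raise ValueError("phi must be > 0")
    a, b = _lift(a), _lift(b)
    _check_shapes(a, b, "huber")
    d = a - b
    absd = d.abs()
    small = np.abs(d.data) < phi
    per_pixel = where(small, d * d * (1.0 / (2.0 * phi)), absd - 0.5 * phi)
    return _maybe_float(per_pixel.mean())


def bce(score, label, from_logits: bool = False):
    """Binary cross-entropy −[y ln p + (1−y) ln(1−p)], mean over elements.

    With `from_logits`, `score` is the pre-sigmoid value and the loss is
    computed as softplus(z) − y·z, which is stable for large |z|.
    """
    s = _lift(score)
    y = float(label)
    if y not in (0.0, 1.0):
        raise ValueError("label must be 0 or 1")
    if from_logits:
        out = s.softplus() - s * y
    else:
        out = -(Tensor._lift(y) * s.log() + (1.0 - y) * (1.0 - s).log())
    return _maybe_float(out.mean())


def tv(image):
    """Total variation: raw sum of |forward differences|, both directions.

    Summed over channels (and batch); no normalization, per the printed
    training objective.
    """
    x = _lift(image)
    if x.shape[-1] < 2 or x.shape[-2] < 2:
        raise ValueError("tv needs at least 2x2 spatial dims")
    nd = x.ndim
    sl = [slice(None)] * nd
    sl_a, sl_b = list(sl), list(sl)
    sl_a[-2], sl_b[-2] = slice(1, None), slice(None, -1)
    dv = (x[tuple(sl_a)] - x[tuple(sl_b)]).abs().sum()
    sl_a, sl_b = list(sl), list(sl)
    sl_a[-1], sl_b[-1] = slice(1, None), slice(None, -1)
    dh = (x[tuple(sl_a)] - x[tuple(sl_b)]).abs().sum()
    return _maybe_float(dv + dh)


def smth(field):
    """Mean squared forward difference of the displacement field.

    Sum over the two components and both difference directions, divided by
    the number of spatial elements X*Y (and batch size, if batched).
    """
    from .model import DisplacementField
    if isinstance(field, DisplacementField):
        field = field.as_array()
    t = _lift(field)
    if t.shape[-1] < 2 or t.shape[-2] < 2:
        raise ValueError("smth needs at least a 2x2 field")
    h, w = t.shape[-2], t.shape[-1]
    n_batch = int(np.prod(t.shape[:-3])) if t.ndim > 3 else 1
    nd = t.ndim
    sl = [slice(None)] * nd
    sl_a, sl_b = list(sl), list(sl)
    sl_a[-2], sl_b[-2] = slice(1, None), slice(None, -1)
    dv = ((t[tuple(sl_a)] - t[tuple(sl_b)]) ** 2).sum()
    sl_a, sl_b = list(sl), list(sl)
    sl_a[-1], sl_b[-1] = slice(1, None), slice(None, -1)
    dh = ((t[tuple(sl_a)] - t[tuple(sl_b)]) ** 2).sum()
    return _maybe_float((dv + dh) * (1.0 / (h * w * n_batch)))


def generator_loss(g_out, target, d_logit_fake, field,
                   coeffs: LossCoefficients = LossCoefficients()):
    """Total generator objective and its three components.

    `field` (from the registration net, treated as a constant here) is
    mandatory: the Huber term is always computed on the warped output.
    """
    if field is None:
        raise ValueError("generator_loss requires the registration field; "
                         "the warped Huber term is not optional")
    g_out, target = _lift(g_out), _lift(target)
    _check_shapes(g_out, target, "generator_loss")
    warped = warp(g_out, field)
    l_huber = huber(target, warped, coeffs.phi)
    l_adv = bce(d_logit_fake, 1, from_logits=True)
    # the TV formula is a raw per-image sum; batches average across samples
    n_batch = g_out.shape[0] if g_out.ndim == 4 else 1
    l_tv = tv(g_out) * (1.0 / n_batch)
    total = coeffs.alpha * l_huber + coeffs.beta * l_adv + coeffs.gamma * l_tv
    return total, {"l_huber": l_huber, "l_adv": l_adv, "l_tv": l_tv}


def discriminator_loss(d_logit_fake, d_logit_real):
    """BCE(D(fake), 0) + BCE(D(real), 1), from pre-sigmoid logits."""
    return (bce(d_logit_fake, 0, from_logits=True)
            + bce(d_logit_real, 1, from_logits=True))


def registration_loss(g_out, target, field,
                      coeffs: LossCoefficients = LossCoefficients()):
    """lambda * Huber(target, g_out o field) + mu * SMTH(field)."""
    g_out, target = _lift(g_out), _lift(target)
    _check_shapes(g_out, target, "registration_loss")
    warped = warp(g_out, field)
    l_huber = huber(target, warped, coeffs.phi)
    l_smth = smth(field)
    total = coeffs.lambda_ * l_huber + coeffs.mu * l_smth
    return total, {"l_reg": l_huber, "l_smth": l_smth}


# ----------------------------------------------------------- fidelity metrics
def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error with W*H normalization (mean across channels)."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"mse: shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """10*log10(max(b)^2 / MSE(a, b)); `b` is the histochemical reference.

    Identical images have zero MSE; infinity is returned as the documented
    sentinel.
    """
    m = mse(a, b)
    if m == 0.0:
        return float("inf")
    peak = float(np.max(np.asarray(b, dtype=np.float64)))
    return float(10.0 * np.log10(peak ** 2 / m))
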
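"""Independent brute-force reference implementations used by the tests.

Everything here is written as literal loops over pixels, straight from the
mathematical definitions, deliberately sharing no code with the package.
"""

import numpy as np


def huber_oracle(a, b, phi=1.0):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    total = 0.0
    for x, y in zip(a, b):
        d = abs(x - y)
        total += d * d / (2 * phi) if d < phi else d - 0.5 * phi
    return total / a.size


def bce_oracle(p, label):
    return -(label * np.log(p) + (1 - label) * np.log(1 - p))


def tv_oracle(image):
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    img = img.reshape(-1, img.shape[-2], img.shape[-1])
    total = 0.0
    for ch in img:
        h, w = ch.shape
        for n in range(h - 1):
            for m in range(w):
                total += abs(ch[n + 1, m] - ch[n, m])
        for n in range(h):
            for m in range(w - 1):
                total += abs(ch[n, m + 1] - ch[n, m])
    return total


def smth_oracle(field):
    f = np.asarray(field, dtype=np.float64)
    if f.ndim == 3:
        f = f[None]
    total = 0.0
    n_batch, n_comp, h, w = f.shape
    for b in range(n_batch):
        for c in range(n_comp):
            t = f[b, c]
            for x in range(h - 1):
                for y in range(w):
                    total += (t[x + 1, y] - t[x, y]) ** 2
            for x in range(h):
                for y in range(w - 1):
                    total += (t[x, y + 1] - t[x, y]) ** 2
    return total / (h * w * n_batch)


def mse_oracle(a, b):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    return sum((x - y) ** 2 for x, y in zip(a, b)) / a.size


def psnr_oracle(a, b):
    m = mse_oracle(a, b)
    if m == 0:
        return float("inf")
    return 10.0 * np.log10(float(np.max(b)) ** 2 / m)


def d_iou_oracle(mask_a, mask_b, factor=8, thresh=0.01):
    a = np.asarray(mask_a, dtype=np.float64)
    b = np.asarray(mask_b, dtype=np.float64)
    h, w = a.shape
    assert h % factor == 0 and w % factor == 0
    da = np.zeros((h // factor, w // factor))
    db = np.zeros_like(da)
    for i in range(h // factor):
        for j in range(w // factor):
            da[i, j] = a[i * factor:(i + 1) * factor,
                         j * factor:(j + 1) * factor].mean()
            db[i, j] = b[i * factor:(i + 1) * factor,
                         j * factor:(j + 1) * factor].mean()
    da, db = da > thresh, db > thresh
    inter = 0.0
    union = 0.0
    for i in range(da.shape[0]):
        for j in range(da.shape[1]):
            inter += da[i, j] * db[i, j]
            union += min(da[i, j] + db[i, j], 1)
    return 1.0 if union == 0 else inter / union


def shift_oracle(image, dy, dx):
    """Integer-shift an image (C, H, W) with edge clamping: the expected
    result of warping by a constant integer field (gather semantics)."""
    img = np.asarray(image)
    c, h, w = img.shape
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            out[:, i, j] = img[:, min(max(i + dy, 0), h - 1),
                               min(max(j + dx, 0), w - 1)]
    return out


def numerical_gradient(f, x, eps=1e-6):
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f(x)
        x[i] -= 2 * eps
        fm = f(x)
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
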
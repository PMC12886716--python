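"""Layers, parameter containers and the Adam optimizer.

Only what the three networks of the staining framework need: 3x3/1x1
convolutions, dense layers, a 3-convolution residual block with a
convolutional residual path, and an additive attention gate.  No
normalization layers are inserted anywhere: the architecture description
mentions only convolutions, residual paths and Leaky ReLU activations.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

LEAKY_SLOPE = 0.1


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Container tracking parameters through attribute order."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, "
                             f"model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"parameter shape mismatch: {p.data.shape} "
                                 f"vs {a.shape}")
            p.data = a.astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for leaky-relu stacks
        w = np.zeros((cout, cin, k, k)) if zero_init else \
            rng.normal(0.0, scale, size=(cout, cin, k, k))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))
        self.stride = stride
        self.padding = k // 2

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, fin: int, fout: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fin)
        w = np.zeros((fin, fout)) if zero_init else \
            rng.normal(0.0, scale, (fin, fout))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(fout, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class ResBlock3(Module):
    """Three consecutive convolutions plus a convolutional residual path.

    The last convolution is zero-initialized so each block starts as its
    residual path alone — the usual identity-dominant initialization for
    deep networks without normalization layers.
    """

    def __init__(self, cin: int, cout: int, rng=None, stride: int = 1):
        self.c1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.c2 = Conv2d(cout, cout, 3, rng=rng)
        self.c3 = Conv2d(cout, cout, 3, rng=rng, zero_init=True)
        self.skip = Conv2d(cin, cout, 1, stride=stride, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.c1(x).leaky_relu(LEAKY_SLOPE)
        y = self.c2(y).leaky_relu(LEAKY_SLOPE)
        y = self.c3(y)
        return (y + self.skip(x)).leaky_relu(LEAKY_SLOPE)


class ResBlock2Down(Module):
    """Two-convolution residual block; second conv strides 2 and doubles width."""

    def __init__(self, cin: int, rng=None):
        self.c1 = Conv2d(cin, 2 * cin, 3, rng=rng)
        self.c2 = Conv2d(2 * cin, 2 * cin, 3, stride=2, rng=rng)
        self.skip = Conv2d(cin, 2 * cin, 1, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.c1(x).leaky_relu(LEAKY_SLOPE)
        y = self.c2(y)
        return (y + self.skip(x)).leaky_relu(LEAKY_SLOPE)


class AttentionGate(Module):
    """Additive attention over a skip connection: 3 convolutions + sigmoid."""

    def __init__(self, c_skip: int, c_gate: int, rng=None):
        inter = max(c_skip // 2, 1)
        self.theta = Conv2d(c_skip, inter, 1, rng=rng)
        self.phi = Conv2d(c_gate, inter, 1, rng=rng)
        self.psi = Conv2d(inter, 1, 1, rng=rng)

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        a = (self.theta(skip) + self.phi(gate)).leaky_relu(LEAKY_SLOPE)
        att = self.psi(a).sigmoid()
        return skip * att


class Adam:
    """Adam with the usual (0.9, 0.999) moments and bias correction."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        # float64 moments: float32 squared-gradient accumulators overflow
        self.m = [np.zeros(p.data.shape, dtype=np.float64)
                  for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64)
                  for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64, copy=False)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr * (m / b1t)
                       / (np.sqrt(v / b2t) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]


def global_mean_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


__all__ = ["Parameter", "Module", "Conv2d", "Linear", "ResBlock3",
           "ResBlock2Down", "AttentionGate", "Adam", "global_mean_pool",
           "concat", "LEAKY_SLOPE"]
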
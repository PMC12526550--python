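"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "LayerNorm", "Linear",
    "ConvBNSiLU", "Bottleneck", "C2f", "SPPF", "Adam",
]


class Module:
    """Base class: parameter discovery, train/eval mode, graph signature."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for name, child in self._children():
            yield from child.named_modules(f"{prefix}{name}.")

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def count_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                out[f"{name}.running_mean"] = mod.running_mean.copy()
                out[f"{name}.running_var"] = mod.running_var.copy()
        return out

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.array(state[f"{name}.running_mean"])
                mod.running_var = np.array(state[f"{name}.running_var"])

    def graph_signature(self):
        """Structural fingerprint: (qualified name, type, param shapes)."""
        sig = []
        for name, mod in self.named_modules():
            shapes = tuple(
                (pn, tuple(p.data.shape))
                for pn, p in sorted(vars(mod).items())
                if isinstance(p, Parameter)
            )
            sig.append((name, type(mod).__name__, shapes))
        return tuple(sig)


def _kaiming(rng, shape, fan_in, dtype):
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=None, bias=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.k = k
        fan_in = cin * k * k
        self.weight = Parameter(_kaiming(rng, (cout, cin, k, k), fan_in, dtype),
                                dtype=dtype)
        self.bias = Parameter(np.zeros(cout), dtype=dtype) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(c), dtype=dtype)
        self.beta = Parameter(np.zeros(c), dtype=dtype)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def forward(self, x):
        xs = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / T.sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(xs).astype(x.data.dtype)
            sd = np.sqrt(self.running_var + self.eps).reshape(xs).astype(x.data.dtype)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(xs) + self.beta.reshape(xs)


class LayerNorm(Module):
    """Normalizes over the channel axis of an (N, C, H, W) tensor."""

    def __init__(self, c, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(c), dtype=dtype)
        self.beta = Parameter(np.zeros(c), dtype=dtype)

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) / T.sqrt(var + self.eps)
        xs = (1, -1, 1, 1)
        return xhat * self.gamma.reshape(xs) + self.beta.reshape(xs)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (cout, cin), cin, dtype), dtype=dtype)
        self.bias = Parameter(np.zeros(cout), dtype=dtype) if bias else None

    def forward(self, x):
        out = T.matmul(x, T.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBNSiLU(Module):
    """Conv -> BatchNorm -> SiLU, the detector's basic block."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(cout, dtype=dtype)

    def forward(self, x):
        return T.silu(self.bn(self.conv(x)))


class Bottleneck(Module):
    def __init__(self, c, shortcut=True, rng=None, dtype=np.float32):
        super().__init__()
        self.cv1 = ConvBNSiLU(c, c, 3, rng=rng, dtype=dtype)
        self.cv2 = ConvBNSiLU(c, c, 3, rng=rng, dtype=dtype)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Split/merge CSP-style block with n bottlenecks."""

    def __init__(self, cin, cout, n=1, shortcut=True, rng=None, dtype=np.float32):
        super().__init__()
        self.c = cout // 2
        self.cv1 = ConvBNSiLU(cin, 2 * self.c, 1, rng=rng, dtype=dtype)
        self.blocks = [Bottleneck(self.c, shortcut, rng=rng, dtype=dtype)
                       for _ in range(n)]
        self.cv2 = ConvBNSiLU((2 + n) * self.c, cout, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        cur = b
        for blk in self.blocks:
            cur = blk(cur)
            outs.append(cur)
        return self.cv2(T.concat(outs, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c, rng=None, dtype=np.float32):
        super().__init__()
        self.cv1 = ConvBNSiLU(c, c // 2, 1, rng=rng, dtype=dtype)
        self.cv2 = ConvBNSiLU(2 * c, c, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        y = self.cv1(x)
        p1 = T.max_pool2d(y, 5, 1, 2)
        p2 = T.max_pool2d(p1, 5, 1, 2)
        p3 = T.max_pool2d(p2, 5, 1, 2)
        return self.cv2(T.concat([y, p1, p2, p3], axis=1))


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
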
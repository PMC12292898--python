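"""Neural-network building blocks on top of the autodiff core.

Weight init is Glorot-uniform from a per-module ``numpy`` Generator, so a
fixed seed gives bit-identical parameters and (with a seeded training loop)
bit-identical trained weights.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor, conv1d, conv3d


class Module:
    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data.copy()
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = state[name].copy()
            elif isinstance(v, Module):
                v.load_state_dict({k.split(".", 1)[1]: a for k, a in state.items()
                                   if k.startswith(name + ".")})
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        prefix = f"{name}.{i}."
                        item.load_state_dict(
                            {k[len(prefix):]: a for k, a in state.items()
                             if k.startswith(prefix)})


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...],
            fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.w = _glorot(rng, (c_out, c_in, k), c_in * k, c_out * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: Tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__()
        fan = c_in * int(np.prod(k))
        self.w = _glorot(rng, (c_out, c_in, *k), fan, c_out * int(np.prod(k)))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(len(x.shape)) if i != 1)
        shape = [1] * len(x.shape)
        shape[1] = x.shape[1]
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        return xn * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * Tensor(mask)


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state. Input (B, T, F)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_hidden = n_hidden
        self.wx = _glorot(rng, (n_in, 4 * n_hidden), n_in, 4 * n_hidden)
        self.wh = _glorot(rng, (n_hidden, 4 * n_hidden), n_hidden, 4 * n_hidden)
        self.b = Tensor(np.zeros(4 * n_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.wx + h @ self.wh + self.b
            i = z[:, 0:H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention over token axis.

    Input (B, n_tokens, d); the most recent attention map (B, n_tokens,
    n_tokens) is kept in ``last_weights`` for inspection.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.d = d
        self.wq = _glorot(rng, (d, d), d, d)
        self.wk = _glorot(rng, (d, d), d, d)
        self.wv = _glorot(rng, (d, d), d, d)
        self.last_weights: Optional[np.ndarray] = None

    def __call__(self, x: Tensor) -> Tensor:
        q = x @ self.wq
        k = x @ self.wk
        v = x @ self.wv
        scores = (q @ k.transpose((0, 2, 1))) * (1.0 / np.sqrt(self.d))
        attn = scores.softmax(axis=-1)
        self.last_weights = attn.data.copy()
        return attn @ v


class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
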
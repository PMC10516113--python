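"""Neural-network building blocks: dense layers, MLPs, GRUs, Adam.

Layers hold their parameters as :class:`~flownode.autodiff.Tensor` leaves and
expose ``__call__`` on graph tensors.  Initialization is seeded through a
numpy ``Generator`` so a model is a pure function of its config and seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor, concatenate

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
}


class Module:
    """Base class; collects parameters from attributes and submodules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Linear(Module):
    """Affine map with uniform fan-in init (optionally zero-initialized)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float64):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            bound = 1.0 / np.sqrt(n_in)
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        b = np.zeros(n_out)
        self.W = Tensor(w.astype(dtype), requires_grad=True)
        self.b = Tensor(b.astype(dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Fully connected stack: hidden layers with a fixed nonlinearity, linear head.

    ``zero_last`` zero-initializes the output layer, so the network starts as
    the zero map — used for vector fields and flow updates so that early
    dynamics/embeddings are near-identity.
    """

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 activation: str = "relu", zero_last: bool = False,
                 dtype=np.float64):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.activation = activation
        self._act = _ACTIVATIONS[activation]
        self.layers = [
            Linear(sizes[i], sizes[i + 1], rng,
                   zero_init=(zero_last and i == len(sizes) - 2), dtype=dtype)
            for i in range(len(sizes) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self._act(layer(x))
        return self.layers[-1](x)


class GRU(Module):
    """Single-direction GRU over a (trials, T, n_in) input, fused-gate form.

    Gate order in the fused weight matrices is (reset, update, candidate).
    The input projection for all timesteps is computed in one matmul.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.n_hidden = n_hidden
        bound = 1.0 / np.sqrt(n_hidden)
        self.Wx = Tensor(rng.uniform(-bound, bound, (n_in, 3 * n_hidden)).astype(dtype),
                         requires_grad=True)
        self.Wh = Tensor(rng.uniform(-bound, bound, (n_hidden, 3 * n_hidden)).astype(dtype),
                         requires_grad=True)
        self.bx = Tensor(np.zeros(3 * n_hidden, dtype=dtype), requires_grad=True)
        self.bh = Tensor(np.zeros(3 * n_hidden, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        """Run the recurrence; returns the final hidden state (trials, n_hidden).

        The whole recurrence is one fused graph node with a hand-coded
        backward pass (BPTT), which avoids per-timestep graph bookkeeping.
        The input is treated as constant (spike counts); only parameter
        gradients are produced.
        """
        x = x if isinstance(x, Tensor) else Tensor(x)
        n_trials, T, _ = x.shape
        H = self.n_hidden
        Wx, Wh, bx, bh = self.Wx, self.Wh, self.bx, self.bh
        X = x.data
        xp = (X.reshape(n_trials * T, -1) @ Wx.data + bx.data).reshape(n_trials, T, 3 * H)
        order = range(T - 1, -1, -1) if reverse else range(T)
        steps = list(order)
        h = np.zeros((n_trials, H), dtype=Wx.data.dtype)
        # cached per step for backward: previous h, gates r/z/n, hidden proj n-part
        cache = []
        for t in steps:
            hp = h @ Wh.data + bh.data
            r = _sigmoid(xp[:, t, :H] + hp[:, :H])
            z = _sigmoid(xp[:, t, H:2 * H] + hp[:, H:2 * H])
            n = np.tanh(xp[:, t, 2 * H:] + r * hp[:, 2 * H:])
            cache.append((h, r, z, n, hp[:, 2 * H:]))
            h = (1.0 - z) * n + z * h

        def backward(g):
            dWx = np.zeros_like(Wx.data)
            dWh = np.zeros_like(Wh.data)
            dbx = np.zeros_like(bx.data)
            dbh = np.zeros_like(bh.data)
            dXP = np.zeros_like(xp)
            dh = g
            for t, (h_prev, r, z, n, hp_n) in zip(reversed(steps), reversed(cache)):
                dz = dh * (h_prev - n)
                dn = dh * (1.0 - z)
                dh_prev = dh * z
                dn_pre = dn * (1.0 - n * n)
                dr = dn_pre * hp_n
                d_hp_n = dn_pre * r
                dr_pre = dr * r * (1.0 - r)
                dz_pre = dz * z * (1.0 - z)
                d_hp = np.concatenate([dr_pre, dz_pre, d_hp_n], axis=1)
                dWh += h_prev.T @ d_hp
                dbh += d_hp.sum(axis=0)
                dh_prev = dh_prev + d_hp @ Wh.data.T
                dXP[:, t, :] = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
                dh = dh_prev
            flatXP = dXP.reshape(n_trials * T, 3 * H)
            dWx[:] = X.reshape(n_trials * T, -1).T @ flatXP
            dbx[:] = flatXP.sum(axis=0)
            return (None, dWx, dWh, dbx, dbh)

        return Tensor._from_op(h, (x, Wx, Wh, bx, bh), backward)


class BiGRU(Module):
    """Bidirectional GRU encoder; returns [h_fwd | h_bwd] of the final steps."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.fwd = GRU(n_in, n_hidden, rng, dtype=dtype)
        self.bwd = GRU(n_in, n_hidden, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return concatenate([self.fwd(x), self.bwd(x, reverse=True)], axis=-1)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float = 5e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float | Sequence[float] = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        if np.isscalar(weight_decay):
            self.weight_decay = [float(weight_decay)] * len(self.params)
        else:
            self.weight_decay = [float(w) for w in weight_decay]
            if len(self.weight_decay) != len(self.params):
                raise ValueError("per-parameter weight_decay length mismatch")
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bias1) / (
                np.sqrt(self.v[i] / bias2) + self.eps)
            if self.weight_decay[i]:
                # decoupled weight decay (AdamW-style)
                p.data = p.data - self.lr * self.weight_decay[i] * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
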
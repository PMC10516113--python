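"""Approximately injective flow readout.

The forward pass zero-pads a latent state z in R^Dhat up to the neural
dimensionality N (an initial log-rate estimate), then applies K small
additive refinements sharing one MLP:

    u_0 = [z | 0],    u_{k+1} = u_k + beta * MLP(u_k),    log-rates = u_K

The reverse pass approximates the inverse by serially subtracting the same
MLP evaluated at the current state, then trimming back to the first Dhat
coordinates:

    v_K = log-rates,    v_{k-1} = v_k - beta * MLP(v_k),    z ~= v_0[:Dhat]

Because the subtraction is evaluated at the current (not pre-update) state,
the composition reverse(forward(z)) is the identity only up to O((beta*L)^2)
per step, where L is the MLP's Lipschitz constant; the map is injective when
beta * L < 1.  ``lipschitz_estimate`` reports an empirical lower bound and a
spectral-norm-product upper bound on beta * L.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate
from .nn import MLP, Module

__all__ = ["FlowReadout", "lipschitz_estimate"]


class FlowReadout(Module):
    """K-step additive residual stack between latent and log-rate space."""

    def __init__(self, d_hat: int, n_neurons: int, rng: np.random.Generator,
                 hidden_layers=(150, 150), K: int = 20, beta: float = 0.1,
                 dtype=np.float64):
        if d_hat > n_neurons:
            raise ValueError("flow readout requires D_hat <= N (zero-padding)")
        if K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 < beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        self.d_hat = d_hat
        self.n_neurons = n_neurons
        self.K = K
        self.beta = beta
        self.mlp = MLP([n_neurons, *hidden_layers, n_neurons], rng,
                       activation="relu", zero_last=True, dtype=dtype)

    def pad(self, z: Tensor) -> Tensor:
        """[z | 0]: append N - Dhat zero coordinates."""
        z = as_tensor(z)
        n_pad = self.n_neurons - self.d_hat
        if n_pad == 0:
            return z
        zeros = Tensor(np.zeros((*z.shape[:-1], n_pad), dtype=z.data.dtype))
        return concatenate([z, zeros], axis=-1)

    def forward(self, z) -> Tensor:
        """Latent state (... x Dhat) -> log-rates (... x N)."""
        z = as_tensor(z)
        if z.shape[-1] != self.d_hat:
            raise ValueError(f"expected last dim {self.d_hat}, got {z.shape[-1]}")
        return self._residual_stack(self.pad(z), +1.0)

    __call__ = forward

    def reverse(self, log_rates) -> Tensor:
        """Log-rates (... x N) -> latent state (... x Dhat), by serial subtraction."""
        v = as_tensor(log_rates)
        if v.shape[-1] != self.n_neurons:
            raise ValueError(f"expected last dim {self.n_neurons}, got {v.shape[-1]}")
        return self._residual_stack(v, -1.0)[..., : self.d_hat]

    def _residual_stack(self, u0: Tensor, sign: float) -> Tensor:
        """K additive (sign=+1) or subtractive (sign=-1) ReLU-MLP refinements.

        Fused into one graph node with a hand-coded backward pass: per step
        only the layer inputs are cached, and gradients for the shared MLP
        parameters are accumulated across all K steps.
        """
        layers = self.mlp.layers
        scale = sign * self.beta
        Ws = [l.W for l in layers]
        bs = [l.b for l in layers]
        u = u0.data
        caches = []  # per step: (u_k, [hidden activations])
        for _ in range(self.K):
            h = u
            hiddens = []
            for W, b in zip(Ws[:-1], bs[:-1]):
                h = np.maximum(h @ W.data + b.data, 0)
                hiddens.append(h)
            m = h @ Ws[-1].data + bs[-1].data
            caches.append((u, hiddens))
            u = u + scale * m

        def backward(g):
            dWs = [np.zeros_like(W.data) for W in Ws]
            dbs = [np.zeros_like(b.data) for b in bs]
            du = g
            for u_k, hiddens in reversed(caches):
                dm = scale * du
                last_in = hiddens[-1] if hiddens else u_k
                dWs[-1] += last_in.T @ dm
                dbs[-1] += dm.sum(axis=0)
                dh = dm @ Ws[-1].data.T
                for i in range(len(hiddens) - 1, -1, -1):
                    da = dh * (hiddens[i] > 0)
                    layer_in = hiddens[i - 1] if i > 0 else u_k
                    dWs[i] += layer_in.T @ da
                    dbs[i] += da.sum(axis=0)
                    dh = da @ Ws[i].data.T
                du = du + dh
            return (du, *dWs, *dbs)

        return Tensor._from_op(u, (u0, *Ws, *bs), backward)


def _spectral_norm(W: np.ndarray) -> float:
    return float(np.linalg.svd(W, compute_uv=False)[0])


def lipschitz_estimate(flow: FlowReadout, probe_points: np.ndarray) -> tuple[float, float]:
    """Bounds on the Lipschitz constant of the scaled update ``beta * MLP``.

    Returns ``(lower, upper)``: an empirical lower bound from pairwise finite
    differences over the probe points, and the product of per-layer spectral
    norms (ReLU is 1-Lipschitz) as an upper bound.  The flow is injective
    whenever the upper bound is < 1.
    """
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 probe points")
    out = flow.mlp(Tensor(pts)).data * flow.beta
    diff_in = pts[:, None, :] - pts[None, :, :]
    diff_out = out[:, None, :] - out[None, :, :]
    din = np.linalg.norm(diff_in, axis=-1)
    dout = np.linalg.norm(diff_out, axis=-1)
    mask = din > 0
    lower = float((dout[mask] / din[mask]).max()) if mask.any() else 0.0
    upper = flow.beta
    for layer in flow.mlp.layers:
        upper *= _spectral_norm(layer.W.data)
    return lower, float(upper)
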
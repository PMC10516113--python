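"""Evaluation metrics: reconstruction, latent accuracy, injectivity, embedding recovery.

The suite covers five complementary views of a trained model:

* reconstruction — ``spike_nll`` (Poisson NLL of counts under inferred rates)
  and ``rate_r2`` (per-neuron R^2 against true rates, averaged);
* latent accuracy — ``state_r2``, the R^2 of an affine regression from the
  true latent trajectories to the inferred ones (high = the model invented no
  latent structure unexplained by the truth; note it can be high trivially if
  the inference is a low-dimensional projection, so it is read together with
  reconstruction);
* readout injectivity — ``effective_rank`` of a linear readout's weight
  matrix, and ``cycle_consistency`` (recovering latents from noise-corrupted
  predicted log-rates with a probe regressor);
* embedding recovery — ``activation_recovery``, the per-neuron R^2 of an
  affine fit from the model-derived activation curve to the true one;
* ``co_bps`` — co-smoothing bits per spike, the likelihood improvement over a
  mean-rate null normalized by the total spike count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.neural_network import MLPRegressor

__all__ = ["AffineMap", "spike_nll", "rate_r2", "state_r2", "effective_rank",
           "cycle_consistency", "activation_recovery", "co_bps"]


@dataclass
class AffineMap:
    """Least-squares affine map x -> x @ linear + offset, with its fit R^2."""

    linear: np.ndarray   # D x D_hat
    offset: np.ndarray   # D_hat
    r2: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x @ self.linear + self.offset


def _flatten_time(a: np.ndarray) -> np.ndarray:
    """(trials, T, d) -> (trials*T, d); 2-D inputs pass through."""
    a = np.asarray(a)
    return a.reshape(-1, a.shape[-1]) if a.ndim == 3 else a


def spike_nll(X: np.ndarray, rates: np.ndarray) -> float:
    """Mean Poisson NLL per bin-neuron: lambda - x log lambda + log(x!)."""
    X = np.asarray(X, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if X.shape != rates.shape:
        raise ValueError("shape mismatch between counts and rates")
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    return float(np.mean(rates - X * np.log(rates) + gammaln(X + 1.0)))


def rate_r2(Y_true: np.ndarray, Y_inferred: np.ndarray) -> float:
    """Per-neuron R^2 over all flattened bins, unweighted mean across neurons.

    Neurons whose true rate is constant carry no R^2 information and are
    excluded with a warning.
    """
    Yt = _flatten_time(Y_true)
    Yi = _flatten_time(Y_inferred)
    if Yt.shape != Yi.shape:
        raise ValueError("shape mismatch")
    sse = ((Yt - Yi) ** 2).sum(axis=0)
    sst = ((Yt - Yt.mean(axis=0)) ** 2).sum(axis=0)
    valid = sst > 0
    if not valid.all():
        warnings.warn(f"excluding {(~valid).sum()} zero-variance neuron(s) from Rate R2")
    if not valid.any():
        raise ValueError("all neurons have zero-variance true rates")
    return float(np.mean(1.0 - sse[valid] / sst[valid]))


def state_r2(Z_true: np.ndarray, Z_hat: np.ndarray) -> tuple[float, AffineMap]:
    """Affine regression true latents -> inferred latents; variance-weighted R^2.

    Fits one multioutput least-squares map on all flattened timepoints and
    aggregates R^2 = 1 - SSE/SST over output dimensions (variance-weighted,
    the standard multioutput convention).  Returns the fitted map so the same
    alignment can be reused for fixed-point and encoding-vector transforms.
    """
    Zt = _flatten_time(Z_true)
    Zh = _flatten_time(Z_hat)
    if Zt.shape[0] != Zh.shape[0]:
        raise ValueError("shape mismatch between true and inferred latents")
    n, d = Zt.shape
    if n < d + 1:
        raise ValueError("need at least D+1 points for the affine fit")
    A = np.column_stack([Zt, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, Zh, rcond=None)
    pred = A @ coef
    sse = ((Zh - pred) ** 2).sum()
    sst = ((Zh - Zh.mean(axis=0)) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return float(r2), AffineMap(linear=coef[:-1], offset=coef[-1], r2=float(r2))


def effective_rank(W: np.ndarray) -> float:
    """exp(entropy) of the nuclear-norm-normalized singular value spectrum."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("effective_rank expects a matrix")
    s = np.linalg.svd(W, compute_uv=False)
    total = s.sum()
    if total == 0:
        raise ValueError("effective rank of the zero matrix is undefined")
    p = s / total
    p = p[p > 0]
    return float(np.exp(-(p * np.log(p)).sum()))


def cycle_consistency(log_rates: np.ndarray, Z_hat: np.ndarray,
                      noise_levels=(0.0, 0.1, 0.25, 0.5, 1.0),
                      seed: int = 0, hidden=(64, 64), max_iter: int = 500,
                      train_frac: float = 0.8) -> np.ndarray:
    """Held-out R^2 of recovering inferred latents from corrupted log-rates.

    For each noise level sigma, Gaussian noise N(0, sigma^2) is added to the
    predicted log-rates and a fresh probe MLP is fit (on a train split) to
    predict the inferred latents; the held-out R^2 measures how much latent
    information survives in the rates — an empirical injectivity probe.
    """
    LR = _flatten_time(log_rates)
    ZH = _flatten_time(Z_hat)
    if LR.shape[0] != ZH.shape[0]:
        raise ValueError("shape mismatch")
    if np.allclose(ZH.std(axis=0), 0):
        raise ValueError("degenerate (constant) latents")
    rng = np.random.default_rng(seed)
    n = LR.shape[0]
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    tr, te = perm[:n_train], perm[n_train:]
    # standardize the probe inputs so noise sigma is on a comparable scale
    mu, sd = LR.mean(axis=0), LR.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out = []
    for sigma in noise_levels:
        if sigma < 0:
            raise ValueError("noise levels must be nonnegative")
        noisy = LR + rng.normal(0.0, sigma, size=LR.shape)
        Xp = (noisy - mu) / sd
        probe = MLPRegressor(hidden_layer_sizes=tuple(hidden), max_iter=max_iter,
                             random_state=int(rng.integers(2 ** 31)),
                             early_stopping=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(Xp[tr], ZH[tr])
        out.append(probe.score(Xp[te], ZH[te]))
    return np.asarray(out)


def activation_recovery(ground_truth, Z_hat: np.ndarray, rates_inferred: np.ndarray,
                        affine_map: AffineMap) -> np.ndarray:
    """Per-neuron R^2 of recovering the true activation function.

    For each neuron: its encoding vector is carried into the model's latent
    space by the linear part of the true->inferred alignment map; inferred
    latents are projected onto the transformed vector to give predicted
    activations; the (predicted activation, predicted rate) curve is then
    affine-calibrated (activation scale/offset) against the true activation
    curve reconstructed from the stored standardization statistics, and the
    R^2 of the resulting rate fit is reported.
    """
    if ground_truth is None:
        raise ValueError("activation recovery requires ground truth")
    emb = ground_truth.embedding
    if emb.standardization_mean is None:
        raise ValueError("embedding lacks standardization statistics")
    ZH = _flatten_time(Z_hat)
    R = _flatten_time(rates_inferred)
    C = emb.encoding_matrix  # D x N
    r2s = np.empty(emb.n_neurons)
    for i in range(emb.n_neurons):
        v = C[:, i] @ affine_map.linear          # encoding vector in model space
        norm = np.linalg.norm(v)
        if norm == 0:
            r2s[i] = np.nan
            continue
        a_pred = ZH @ (v / norm)                  # predicted activation (arbitrary scale)
        y_pred = R[:, i]
        # the model's activation axis is arbitrarily scaled/shifted relative
        # to the true one, so calibrate a_true ~ s * a_pred + c by least
        # squares before comparing rate curves
        y_true_fn = emb.activation_curve
        s, c = _fit_activation_affine(a_pred, y_pred, y_true_fn, i)
        y_true = y_true_fn(i, s * a_pred + c)
        sst = ((y_pred - y_pred.mean()) ** 2).sum()
        sse = ((y_pred - y_true) ** 2).sum()
        r2s[i] = 1.0 - sse / sst if sst > 0 else np.nan
    return r2s


def _fit_activation_affine(a_pred, y_pred, curve_fn, neuron):
    """Least-squares scale/offset of the activation axis via coarse-to-fine search."""
    from scipy.optimize import minimize

    def loss(theta):
        s, c = theta
        resid = y_pred - curve_fn(neuron, s * a_pred + c)
        return float((resid ** 2).mean())

    best = None
    for s0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
        res = minimize(loss, x0=np.array([s0, 0.0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])


def co_bps(X_heldout: np.ndarray, rates_heldout: np.ndarray,
           null_rates: np.ndarray) -> float:
    """Co-smoothing bits per spike: (NLL_null - NLL_model) / (n_spikes * log 2).

    NLLs are summed over all bins and neurons; ``null_rates`` are the
    per-neuron mean rates (broadcast to the data shape).
    """
    X = np.asarray(X_heldout, dtype=float)
    lam = np.asarray(rates_heldout, dtype=float)
    null = np.broadcast_to(np.asarray(null_rates, dtype=float), X.shape)
    if X.shape != lam.shape:
        raise ValueError("shape mismatch")
    total_spikes = X.sum()
    if total_spikes == 0:
        raise ValueError("co-bps undefined with zero spikes")
    nll_model = float(np.sum(lam - X * np.log(lam)))
    nll_null = float(np.sum(null - X * np.log(null)))
    return (nll_null - nll_model) / (total_spikes * np.log(2.0))
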
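"""Fixed-point analysis of learned and ground-truth dynamics.

A fixed point of the discrete update map z -> z + f(z) is a zero of the
vector field f.  Candidates are found by quasi-Newton minimization of
q(z) = 0.5 * ||f(z)||^2 from many seeds sampled from the model's inferred
latent states, kept when q converges below tolerance, and deduplicated by
radius.  Each fixed point is characterized by the Jacobian of the *update
map* J = I + df/dz, whose eigenvalues sit inside (attracting) or outside
(repelling) the unit circle.

For the ground-truth system, the one-bin discrete map is the RK4 step of the
continuous flow; its Jacobian eigenvalues equal expm(J_cont * dt) eigenvalues
up to the integrator's truncation error, which gives a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

__all__ = ["FixedPointSet", "find_fixed_points", "linearize", "classify",
           "compare_to_truth", "candidate_seeds_from_latents"]


@dataclass
class FixedPointSet:
    """Deduplicated fixed points with local linearizations."""

    locations: np.ndarray      # M x D
    residuals: np.ndarray      # M (||f|| at each point)
    jacobians: np.ndarray      # M x D x D, of the update map z -> z + f(z)
    eigenvalues: np.ndarray    # M x D, complex
    labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.locations.shape[0]


def numerical_jacobian(f: Callable, point: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference Jacobian of the vector field f at `point`."""
    point = np.asarray(point, dtype=float)
    d = point.size
    J = np.empty((d, d))
    for j in range(d):
        dp = np.zeros(d)
        dp[j] = eps
        J[:, j] = (np.asarray(f(point + dp)) - np.asarray(f(point - dp))) / (2 * eps)
    if not np.isfinite(J).all():
        raise FloatingPointError("non-finite derivative in Jacobian")
    return J


def linearize(f: Callable, point: np.ndarray, jacobian_fn: Callable | None = None,
              eps: float = 1e-5) -> np.ndarray:
    """Jacobian of the update map z -> z + f(z): I + df/dz.

    ``jacobian_fn``, when given, supplies df/dz analytically (e.g. via
    autodiff); otherwise central finite differences are used.
    """
    point = np.asarray(point, dtype=float)
    Jf = (np.asarray(jacobian_fn(point)) if jacobian_fn is not None
          else numerical_jacobian(f, point, eps=eps))
    if not np.isfinite(Jf).all():
        raise FloatingPointError("non-finite derivative in linearization")
    return np.eye(point.size) + Jf


def classify(eigenvalues: np.ndarray, tol: float = 1e-3) -> str:
    """Discrete-time stability label from update-map eigenvalue magnitudes."""
    ev = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    mags = np.abs(ev)
    rotational = bool(np.any(np.abs(ev.imag) > tol))
    if np.all(np.abs(mags - 1.0) < tol):
        return "center-like"
    if np.all(mags < 1.0 + tol):
        return "spiral-in" if rotational else "attractor"
    if np.all(mags > 1.0 - tol):
        return "spiral-out" if rotational else "repeller"
    return "saddle"


def candidate_seeds_from_latents(Z_hat: np.ndarray, n_seeds: int = 256,
                                 jitter: float = 0.05, seed: int = 0) -> np.ndarray:
    """Sample candidate start points uniformly from inferred latents + jitter."""
    pts = np.asarray(Z_hat, dtype=float).reshape(-1, Z_hat.shape[-1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pts.shape[0], size=n_seeds)
    scale = jitter * (pts.max(axis=0) - pts.min(axis=0))
    return pts[idx] + rng.normal(0.0, 1.0, size=(n_seeds, pts.shape[1])) * scale


def find_fixed_points(f: Callable, candidates: np.ndarray, tol: float = 1e-6,
                      dedup_radius: float | None = None, max_iter: int = 500,
                      jacobian_fn: Callable | None = None) -> FixedPointSet:
    """Minimize q(z) = 0.5 ||f(z)||^2 from each candidate; keep and dedup roots.

    Converged points with q < tol are kept and merged when closer than
    ``dedup_radius`` (default: 1% of the candidate cloud's coordinate range).
    Deterministic given the candidate set.  Returns an empty set (with a
    warning) when nothing converges.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if candidates.shape[0] < 1:
        raise ValueError("need at least one candidate seed")
    d = candidates.shape[1]
    if dedup_radius is None:
        span = candidates.max(axis=0) - candidates.min(axis=0)
        dedup_radius = max(0.01 * float(span.max()), 1e-8)

    def q_and_grad(z):
        fz = np.asarray(f(z), dtype=float)
        Jf = (np.asarray(jacobian_fn(z)) if jacobian_fn is not None
              else numerical_jacobian(f, z))
        return 0.5 * float(fz @ fz), Jf.T @ fz

    found: list[np.ndarray] = []
    residuals: list[float] = []
    for z0 in candidates:
        res = minimize(q_and_grad, z0, jac=True, method="BFGS",
                       options={"maxiter": max_iter, "gtol": 1e-12})
        if not np.isfinite(res.x).all() or res.fun >= tol:
            continue
        z_star = res.x
        merged = False
        for i, existing in enumerate(found):
            if np.linalg.norm(existing - z_star) < dedup_radius:
                if res.fun < residuals[i] ** 2 / 2:
                    found[i], residuals[i] = z_star, float(np.sqrt(2 * res.fun))
                merged = True
                break
        if not merged:
            found.append(z_star)
            residuals.append(float(np.sqrt(2 * res.fun)))
    if not found:
        import warnings
        warnings.warn("no fixed-point candidates converged below tolerance")
        return FixedPointSet(locations=np.empty((0, d)), residuals=np.empty(0),
                             jacobians=np.empty((0, d, d)),
                             eigenvalues=np.empty((0, d), dtype=complex), labels=[])
    locations = np.array(found)
    order = np.argsort(locations[:, 0])
    locations = locations[order]
    residuals = np.array(residuals)[order]
    jacobians = np.array([linearize(f, z, jacobian_fn=jacobian_fn) for z in locations])
    eigenvalues = np.array([np.linalg.eigvals(J) for J in jacobians])
    labels = [classify(ev) for ev in eigenvalues]
    return FixedPointSet(locations=locations, residuals=residuals,
                         jacobians=jacobians, eigenvalues=eigenvalues, labels=labels)


def _eigen_set_distance(ev_a: np.ndarray, ev_b: np.ndarray) -> float:
    """Hausdorff distance between two eigenvalue sets in the complex plane."""
    a = np.atleast_1d(ev_a)[:, None]
    b = np.atleast_1d(ev_b)[None, :]
    d = np.abs(a - b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def compare_to_truth(model_fps: FixedPointSet, truth_fps: FixedPointSet,
                     affine_map) -> dict:
    """Greedy-match affine-transformed truth FPs to model FPs.

    The truth locations are carried into the model's latent space with the
    true->inferred alignment map; each transformed truth FP is matched to its
    nearest unused model FP.  Reports per-pair location errors, Hausdorff
    distances between eigenvalue sets, and any cardinality mismatch.
    """
    if len(model_fps) == 0 or len(truth_fps) == 0:
        raise ValueError("both fixed-point sets must be nonempty")
    truth_mapped = affine_map(truth_fps.locations)
    n_truth, n_model = len(truth_fps), len(model_fps)
    dists = np.linalg.norm(truth_mapped[:, None, :] - model_fps.locations[None, :, :],
                           axis=-1)
    pairs: list[tuple[int, int]] = []
    used_t: set[int] = set()
    used_m: set[int] = set()
    flat = [(dists[i, j], i, j) for i in range(n_truth) for j in range(n_model)]
    for _, i, j in sorted(flat):
        if i in used_t or j in used_m:
            continue
        pairs.append((i, j))
        used_t.add(i)
        used_m.add(j)
    location_errors = np.array([dists[i, j] for i, j in pairs])
    eig_distances = np.array([
        _eigen_set_distance(truth_fps.eigenvalues[i], model_fps.eigenvalues[j])
        for i, j in pairs])
    return {
        "pairs": pairs,
        "location_errors": location_errors,
        "eigenvalue_distances": eig_distances,
        "n_truth": n_truth,
        "n_model": n_model,
        "cardinality_mismatch": n_truth != n_model,
        "truth_mapped": truth_mapped,
    }
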
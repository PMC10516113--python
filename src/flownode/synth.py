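"""Synthetic spiking benchmark: chaotic latent dynamics embedded into Poisson spikes.

The generator draws trajectories of a low-dimensional chaotic system (the
Arneodo system by default, D=3), projects them onto random per-neuron
encoding vectors, standardizes the resulting activations, warps each
neuron's activation through a scaled sigmoid (or a linear-exponential
alternative), and samples Poisson spike counts at each time bin.  The true
latents, rates and embedding parameters are retained so that latent-,
embedding- and dynamics-recovery metrics can be evaluated against ground
truth.

Default conditions: 70-bin segments, 12 neurons, encoding-vector entries
drawn from U[-0.5, 0.5], sigmoid scales log-spaced over [10**0.2, 10], an
80/20 trial-level train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import h5py
import numpy as np

__all__ = [
    "ChaoticSystemSpec",
    "EmbeddingSpec",
    "GroundTruthSystem",
    "SpikeDataset",
    "ARNEODO_PARAMS",
    "arneodo_field",
    "vector_field",
    "continuous_jacobian",
    "analytic_fixed_points",
    "integrate_system",
    "discrete_update_map",
    "make_embedding",
    "embed_latents",
    "sample_spikes",
    "split_dataset",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

# Conventional chaotic coefficient set for the Arneodo-Coullet system
#   x' = y, y' = z, z' = -a x - b y - c z + d x^3
# (bounded strange attractor; three fixed points at x = 0, +/- sqrt(a/d)).
# b = 3.8 keeps the attractor stable over very long horizons; nearby values
# (e.g. b = 3.5) show transient chaos with eventual escape.
ARNEODO_PARAMS = {"a": -5.8, "b": 3.8, "c": 1.0, "d": -1.0}

# With dt = 0.07 a 70-bin segment spans ~1.5 periods of the attractor's
# dominant oscillation (period ~3.3 time units).
DEFAULT_DT = 0.07

SYSTEM_DIMS = {"arneodo": 3, "zero": 3}


@dataclass(frozen=True)
class ChaoticSystemSpec:
    """Ground-truth latent system: named vector field + integration settings."""

    name: str = "arneodo"
    params: dict = field(default_factory=lambda: dict(ARNEODO_PARAMS))
    dt: float = DEFAULT_DT
    integrator: str = "rk4"
    burn_in_steps: int = 1000
    substeps: int = 10  # integrator substeps per bin; the one-bin map stays 4th order
                        # locally but its truncation error shrinks as substeps^-4

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be nonnegative")
        if self.integrator not in ("rk4", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.name not in SYSTEM_DIMS:
            raise ValueError(f"unknown system {self.name!r}")
        if self.name == "arneodo" and set(self.params) != {"a", "b", "c", "d"}:
            raise ValueError("arneodo requires params a, b, c, d")

    @property
    def dim(self) -> int:
        return SYSTEM_DIMS[self.name]


@dataclass
class EmbeddingSpec:
    """Latent-to-rate embedding: encoding vectors + per-neuron activation warp.

    ``encoding_matrix`` is D x N; column i is neuron i's encoding vector.
    For ``scaled_sigmoid``, neuron i fires at
    ``rate_scale * sigmoid(s_i * a_i)`` where ``a_i`` is its standardized
    activation and ``s_i`` its sigmoid scale.  ``lin_exp``/``linear`` use
    ``exp(a_i + log(rate_scale / 2))`` so log-rates are affine in the
    activations (rates exactly log-linear in the latents).
    """

    encoding_matrix: np.ndarray
    activation: str = "scaled_sigmoid"
    sigmoid_scales: np.ndarray | None = None
    rate_scale: float = 1.0
    standardization_mean: np.ndarray | None = None
    standardization_std: np.ndarray | None = None

    def __post_init__(self):
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.activation not in ("scaled_sigmoid", "lin_exp", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.activation == "scaled_sigmoid" and self.sigmoid_scales is None:
            raise ValueError("scaled_sigmoid requires sigmoid_scales")

    @property
    def n_neurons(self) -> int:
        return self.encoding_matrix.shape[1]

    @property
    def latent_dim(self) -> int:
        return self.encoding_matrix.shape[0]

    def activation_curve(self, neuron: int, activations: np.ndarray) -> np.ndarray:
        """True rate of `neuron` as a function of standardized activation."""
        if self.activation == "scaled_sigmoid":
            s = self.sigmoid_scales[neuron]
            return self.rate_scale / (1.0 + np.exp(-s * activations))
        return np.exp(activations + np.log(self.rate_scale / 2.0))


@dataclass
class GroundTruthSystem:
    """A fully observed synthetic dataset: latents, activations, rates, spikes."""

    Z: np.ndarray          # trials x T x D latent states
    activations: np.ndarray  # trials x T x N standardized activations
    Y: np.ndarray          # trials x T x N firing rates (spikes / bin)
    X: np.ndarray          # trials x T x N Poisson spike counts
    system: ChaoticSystemSpec
    embedding: EmbeddingSpec
    seed: int


@dataclass
class SpikeDataset:
    """Spike-count tensor with a trial-level train/validation split."""

    X: np.ndarray
    bin_width: float
    train_idx: np.ndarray
    valid_idx: np.ndarray
    ground_truth: GroundTruthSystem | None = None

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.X.shape[2]

    @property
    def T(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# Vector fields and integration
# ---------------------------------------------------------------------------

def arneodo_field(params: dict) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized Arneodo vector field on arrays with last axis (x, y, z)."""
    a, b, c, d = params["a"], params["b"], params["c"], params["d"]

    def f(state: np.ndarray) -> np.ndarray:
        x, y, z = state[..., 0], state[..., 1], state[..., 2]
        return np.stack([y, z, -a * x - b * y - c * z + d * x ** 3], axis=-1)

    return f


def vector_field(spec: ChaoticSystemSpec) -> Callable[[np.ndarray], np.ndarray]:
    if spec.name == "arneodo":
        return arneodo_field(spec.params)
    if spec.name == "zero":  # testing variant: constant trajectories
        return lambda state: np.zeros_like(state)
    raise ValueError(f"unknown system {spec.name!r}")


def continuous_jacobian(spec: ChaoticSystemSpec, point: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the continuous-time vector field at `point`."""
    if spec.name == "zero":
        return np.zeros((3, 3))
    if spec.name != "arneodo":
        raise ValueError(f"no analytic Jacobian for {spec.name!r}")
    a, b, c, d = (spec.params[k] for k in "abcd")
    x = point[0]
    return np.array([
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [-a + 3 * d * x ** 2, -b, -c],
    ])


def analytic_fixed_points(spec: ChaoticSystemSpec) -> np.ndarray:
    """Roots of the cubic nullcline: (x, 0, 0) with x in {0, +/-sqrt(a/d)}.

    The Arneodo field vanishes iff y = z = 0 and x(-a + d x^2) = 0.
    """
    if spec.name != "arneodo":
        raise ValueError("analytic fixed points only available for arneodo")
    a, d = spec.params["a"], spec.params["d"]
    ratio = a / d
    xs = [0.0]
    if ratio > 0:
        xs.extend([np.sqrt(ratio), -np.sqrt(ratio)])
    return np.array([[x, 0.0, 0.0] for x in sorted(xs)])


def _rk4_step(f: Callable, state: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _euler_step(f: Callable, state: np.ndarray, dt: float) -> np.ndarray:
    return state + dt * f(state)


def _bin_step(spec: ChaoticSystemSpec, f: Callable, state: np.ndarray) -> np.ndarray:
    """Advance one bin (dt) using the spec's integrator with substeps."""
    step = _rk4_step if spec.integrator == "rk4" else _euler_step
    h = spec.dt / spec.substeps
    for _ in range(spec.substeps):
        state = step(f, state, h)
    return state


def discrete_update_map(spec: ChaoticSystemSpec) -> Callable[[np.ndarray], np.ndarray]:
    """One-bin discrete map z -> F(z) induced by the spec's integrator."""
    f = vector_field(spec)

    def F(state: np.ndarray) -> np.ndarray:
        return _bin_step(spec, f, np.asarray(state, dtype=float))

    return F


def integrate_system(spec: ChaoticSystemSpec, n_traj: int, T: int,
                     seed: int) -> np.ndarray:
    """Sample `n_traj` on-attractor trajectories of length `T`.

    Initial conditions are drawn from U[-1, 1]^D and burned in for
    ``spec.burn_in_steps`` bins so recorded segments start on the attractor.
    Deterministic given (spec, seed); randomness enters only through the
    initial conditions.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    f = vector_field(spec)

    # Trial initial conditions are random phases along one reference orbit:
    # a pinned near-attractor point is burned in, then the orbit is extended
    # and each trial starts at a seeded random offset along it.  Chaotic
    # divergence decorrelates trials; every state is on the attractor, so no
    # initial condition can escape the basin.
    state = np.full(spec.dim, 0.1) + 0.1 * np.arange(spec.dim)
    for i in range(spec.burn_in_steps):
        state = _bin_step(spec, f, state)
        if not np.isfinite(state).all():
            raise FloatingPointError(f"non-finite state at burn-in step {i}")
    gap = 100  # bins between candidate phases (~2 oscillation periods)
    horizon = n_traj * gap
    offsets = np.sort(rng.choice(horizon, size=n_traj, replace=False))
    orbit = np.empty((horizon, spec.dim))
    orbit[0] = state
    for i in range(1, horizon):
        state = _bin_step(spec, f, state)
        if not np.isfinite(state).all():
            raise FloatingPointError(f"non-finite state at orbit step {i}")
        orbit[i] = state
    starts = orbit[offsets]
    out = np.empty((n_traj, T, spec.dim))
    out[:, 0] = starts
    state = starts
    for t in range(1, T):
        state = _bin_step(spec, f, state)
        if not np.isfinite(state).all():
            raise FloatingPointError(f"non-finite state at step {t}")
        out[:, t] = state
    return out


# ---------------------------------------------------------------------------
# Embedding and spiking
# ---------------------------------------------------------------------------

def make_embedding(D: int, N: int, activation: str = "scaled_sigmoid",
                   seed: int = 0, rate_scale: float = 1.0) -> EmbeddingSpec:
    """Draw random encoding vectors and per-neuron sigmoid scales.

    Encoding-matrix entries ~ U[-0.5, 0.5]; sigmoid scales evenly spaced on a
    log scale over [10**0.2, 10] (a single neuron gets the start of the range).
    """
    if D < 1 or N < 1:
        raise ValueError("D and N must be >= 1")
    rng = np.random.default_rng(seed)
    C = rng.uniform(-0.5, 0.5, size=(D, N))
    scales = np.logspace(0.2, 1.0, N) if N > 1 else np.array([10.0 ** 0.2])
    return EmbeddingSpec(encoding_matrix=C, activation=activation,
                         sigmoid_scales=scales, rate_scale=rate_scale)


def embed_latents(Z: np.ndarray, emb: EmbeddingSpec) -> tuple[np.ndarray, np.ndarray]:
    """Project latents onto encoding vectors, standardize, warp into rates.

    Standardization statistics (per-neuron mean/std over all trials and bins)
    are stored on `emb` so the true activation curves can be reconstructed
    later for embedding-recovery metrics.
    """
    if Z.shape[-1] != emb.latent_dim:
        raise ValueError("latent dimension mismatch with encoding matrix")
    raw = Z @ emb.encoding_matrix
    if not np.isfinite(raw).all():
        raise FloatingPointError("non-finite activations")
    mean = raw.reshape(-1, emb.n_neurons).mean(axis=0)
    std = raw.reshape(-1, emb.n_neurons).std(axis=0)
    if np.any(std == 0):
        raise FloatingPointError("zero-variance activation; degenerate encoding")
    emb.standardization_mean = mean
    emb.standardization_std = std
    act = (raw - mean) / std
    if emb.activation == "scaled_sigmoid":
        Y = emb.rate_scale / (1.0 + np.exp(-emb.sigmoid_scales * act))
    else:  # lin_exp / linear: log-rate affine in the activation
        Y = np.exp(act + np.log(emb.rate_scale / 2.0))
    return act, Y


def sample_spikes(Y: np.ndarray, seed: int) -> np.ndarray:
    """Poisson spike counts with per-bin rates `Y` (spikes/bin)."""
    if np.any(Y < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(Y).astype(np.int64)


def split_dataset(X: np.ndarray, train_frac: float = 0.8, seed: int = 0,
                  bin_width: float = DEFAULT_DT,
                  ground_truth: GroundTruthSystem | None = None) -> SpikeDataset:
    """Random trial-level split into train/validation sets."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    return SpikeDataset(X=X, bin_width=bin_width,
                        train_idx=np.sort(perm[:n_train]),
                        valid_idx=np.sort(perm[n_train:]),
                        ground_truth=ground_truth)


def generate_dataset(n_trials: int = 1175, T: int = 70, n_neurons: int = 12,
                     activation: str = "scaled_sigmoid", rate_scale: float = 1.0,
                     seed: int = 0, system: ChaoticSystemSpec | None = None,
                     train_frac: float = 0.8) -> SpikeDataset:
    """End-to-end benchmark generation with a single controlling seed."""
    spec = system if system is not None else ChaoticSystemSpec()
    ss = np.random.SeedSequence(seed)
    s_traj, s_emb, s_spk, s_split = (int(c.generate_state(1)[0] % (2 ** 31))
                                     for c in ss.spawn(4))
    Z = integrate_system(spec, n_trials, T, seed=s_traj)
    emb = make_embedding(spec.dim, n_neurons, activation=activation,
                         seed=s_emb, rate_scale=rate_scale)
    act, Y = embed_latents(Z, emb)
    X = sample_spikes(Y, seed=s_spk)
    gt = GroundTruthSystem(Z=Z, activations=act, Y=Y, X=X, system=spec,
                           embedding=emb, seed=seed)
    return split_dataset(X, train_frac=train_frac, seed=s_split,
                         bin_width=spec.dt, ground_truth=gt)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_dataset(path: str, ds: SpikeDataset) -> None:
    """Write a dataset (and ground truth, if present) to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ds.X)
        f.create_dataset("train_idx", data=ds.train_idx)
        f.create_dataset("valid_idx", data=ds.valid_idx)
        f.attrs["bin_width"] = ds.bin_width
        gt = ds.ground_truth
        if gt is not None:
            f.create_dataset("Z", data=gt.Z)
            f.create_dataset("activations", data=gt.activations)
            f.create_dataset("Y", data=gt.Y)
            f.create_dataset("encoding_matrix", data=gt.embedding.encoding_matrix)
            if gt.embedding.sigmoid_scales is not None:
                f.create_dataset("sigmoid_scales", data=gt.embedding.sigmoid_scales)
            f.create_dataset("standardization_mean",
                             data=gt.embedding.standardization_mean)
            f.create_dataset("standardization_std",
                             data=gt.embedding.standardization_std)
            f.attrs["seed"] = gt.seed
            f.attrs["activation"] = gt.embedding.activation
            f.attrs["rate_scale"] = gt.embedding.rate_scale
            f.attrs["system_name"] = gt.system.name
            f.attrs["system_dt"] = gt.system.dt
            f.attrs["system_integrator"] = gt.system.integrator
            f.attrs["system_burn_in"] = gt.system.burn_in_steps
            for k, v in gt.system.params.items():
                f.attrs[f"system_param_{k}"] = v


def load_dataset(path: str) -> SpikeDataset:
    with h5py.File(path, "r") as f:
        X = f["X"][...]
        ds = SpikeDataset(X=X, bin_width=float(f.attrs["bin_width"]),
                          train_idx=f["train_idx"][...],
                          valid_idx=f["valid_idx"][...])
        if "Z" in f:
            params = {k[len("system_param_"):]: float(v)
                      for k, v in f.attrs.items() if k.startswith("system_param_")}
            spec = ChaoticSystemSpec(name=str(f.attrs["system_name"]),
                                     params=params,
                                     dt=float(f.attrs["system_dt"]),
                                     integrator=str(f.attrs["system_integrator"]),
                                     burn_in_steps=int(f.attrs["system_burn_in"]))
            scales = f["sigmoid_scales"][...] if "sigmoid_scales" in f else None
            emb = EmbeddingSpec(encoding_matrix=f["encoding_matrix"][...],
                                activation=str(f.attrs["activation"]),
                                sigmoid_scales=scales,
                                rate_scale=float(f.attrs["rate_scale"]),
                                standardization_mean=f["standardization_mean"][...],
                                standardization_std=f["standardization_std"][...])
            ds.ground_truth = GroundTruthSystem(
                Z=f["Z"][...], activations=f["activations"][...],
                Y=f["Y"][...], X=X, system=spec, embedding=emb,
                seed=int(f.attrs["seed"]))
    return ds
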
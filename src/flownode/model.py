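"""Sequential autoencoders for latent dynamics inference from spike counts.

Three variants share one architecture and differ only in the readout g:

* ``linear``  — a single affine layer from latent state to log-rates;
* ``mlp``     — an MLP with two ReLU hidden layers;
* ``flow``    — the approximately injective flow readout
  (:class:`~flownode.flow.FlowReadout`).

The pipeline is: a bidirectional GRU encoder consumes the spike-count window
x_{1:T} and emits its final hidden states h_T; an initial-condition map phi
turns h_T into z0; a Neural-ODE generator with vector field ``alpha * MLP``
is unrolled by Euler steps of one bin to produce z_{1:T}; the readout maps
each latent state to log-rates, and rates are exp(log-rates).  Training
minimizes the Poisson negative log-likelihood of the observed counts
(mean over bins and neurons; the constant log(x!) term is dropped from the
training objective but included in reported Spike NLL).

For linear/MLP readouts phi is affine into R^Dhat; for the flow readout phi
is affine into R^N followed by the flow's reverse pass, so the initial
condition lives where the readout can represent it.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, no_grad, stack
from .flow import FlowReadout
from .nn import MLP, Adam, BiGRU, Linear, Module

__all__ = ["ModelConfig", "SequentialAutoencoder", "LatentInference",
           "train_model", "infer", "save_model", "load_model"]


@dataclass
class ModelConfig:
    """Architecture and optimization settings for one autoencoder."""

    n_neurons: int
    d_hat: int = 3
    readout: str = "flow"          # linear | mlp | flow
    encoder_hidden: int = 100
    node_hidden_layers: tuple = (128, 128)
    alpha: float = 0.1             # NODE output scale
    readout_hidden_layers: tuple = (150, 150)
    flow_K: int = 20
    beta: float = 0.1              # flow update scale
    epochs: int = 1500
    learning_rate: float = 5e-3
    batch_size: int | None = None  # None = full batch
    lr_decay_epochs: tuple = ()    # epochs at which to multiply lr by lr_decay_factor
    lr_decay_factor: float = 0.3
    node_zero_init: bool = True    # zero-init the NODE MLP's output layer
    weight_decay: float = 0.0      # decoupled weight decay, all parameters
    node_weight_decay: float = 0.0  # extra decay on the NODE MLP (simple-dynamics bias)
    grad_clip: float | None = 200.0  # global gradient-norm clip
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self):
        if self.d_hat < 1:
            raise ValueError("d_hat must be >= 1")
        if self.readout not in ("linear", "mlp", "flow"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        if self.flow_K < 1:
            raise ValueError("flow_K must be >= 1")
        self.node_hidden_layers = tuple(self.node_hidden_layers)
        self.readout_hidden_layers = tuple(self.readout_hidden_layers)
        self.lr_decay_epochs = tuple(self.lr_decay_epochs)


@dataclass
class LatentInference:
    """Inferred initial conditions, latent trajectories and firing rates."""

    z0_hat: np.ndarray     # trials x Dhat
    Z_hat: np.ndarray      # trials x T x Dhat
    log_rates: np.ndarray  # trials x T x N
    rates: np.ndarray      # trials x T x N


class SequentialAutoencoder(Module):
    """Encoder + initial-condition map + NODE generator + readout."""

    def __init__(self, config: ModelConfig):
        self.config = config
        cfg = config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.encoder = BiGRU(cfg.n_neurons, cfg.encoder_hidden, rng, dtype=dtype)
        # vector field; optionally zero-init the final layer so early
        # dynamics are near-identity (complements the alpha scaling)
        self.node_mlp = MLP([cfg.d_hat, *cfg.node_hidden_layers, cfg.d_hat], rng,
                            activation="tanh", zero_last=cfg.node_zero_init,
                            dtype=dtype)
        if cfg.readout == "flow":
            self.readout = FlowReadout(cfg.d_hat, cfg.n_neurons, rng,
                                       hidden_layers=cfg.readout_hidden_layers,
                                       K=cfg.flow_K, beta=cfg.beta, dtype=dtype)
            self.phi = Linear(2 * cfg.encoder_hidden, cfg.n_neurons, rng, dtype=dtype)
        else:
            if cfg.readout == "linear":
                self.readout = MLP([cfg.d_hat, cfg.n_neurons], rng, dtype=dtype)
            else:
                self.readout = MLP([cfg.d_hat, *cfg.readout_hidden_layers,
                                    cfg.n_neurons], rng, activation="relu",
                                   dtype=dtype)
            self.phi = Linear(2 * cfg.encoder_hidden, cfg.d_hat, rng, dtype=dtype)
        self.training_log: list[dict] = []

    # -- forward components ---------------------------------------------------

    def encode(self, X) -> Tensor:
        """Spike window (trials x T x N) -> concatenated BiGRU states h_T."""
        X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=self.config.dtype))
        if X.shape[1] == 0:
            raise ValueError("empty time axis")
        if X.shape[2] != self.config.n_neurons:
            raise ValueError(f"expected {self.config.n_neurons} neurons, got {X.shape[2]}")
        return self.encoder(X)

    def init_condition(self, h_T: Tensor) -> Tensor:
        """h_T -> z0.  Flow models map into R^N then run the flow's reverse pass."""
        out = self.phi(h_T)
        if self.config.readout == "flow":
            out = self.readout.reverse(out)
        return out

    def unroll_dynamics(self, z0: Tensor, T: int) -> Tensor:
        """Euler-unroll z_{t+1} = z_t + alpha * MLP(z_t); returns z_{1:T}."""
        if T < 1:
            raise ValueError("T must be >= 1")
        states = []
        z = z0
        for t in range(T):
            z = z + self.config.alpha * self.node_mlp(z)
            if not np.isfinite(z.data).all():
                raise FloatingPointError(f"non-finite latent state at unroll step {t + 1}")
            states.append(z)
        return stack(states, axis=1)

    def readout_rates(self, Z_hat: Tensor) -> tuple[Tensor, Tensor]:
        """Latent trajectories -> (log-rates, rates)."""
        n_trials, T, d = Z_hat.shape
        flat = Z_hat.reshape(n_trials * T, d)
        log_rates = self.readout(flat).reshape(n_trials, T, self.config.n_neurons)
        return log_rates, log_rates.exp()

    def forward(self, X) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Full pass; returns (z0, Z_hat, log_rates, rates)."""
        X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=self.config.dtype))
        h = self.encode(X)
        z0 = self.init_condition(h)
        Z_hat = self.unroll_dynamics(z0, X.shape[1])
        log_rates, rates = self.readout_rates(Z_hat)
        return z0, Z_hat, log_rates, rates

    def dynamics_fn(self):
        """The learned vector field f(z) = alpha * MLP(z) as a numpy function."""
        alpha = self.config.alpha

        def f(z: np.ndarray) -> np.ndarray:
            squeeze = z.ndim == 1
            arr = np.atleast_2d(np.asarray(z, dtype=float))
            out = alpha * self.node_mlp(Tensor(arr)).data
            return out[0] if squeeze else out

        return f

    def dynamics_jacobian_fn(self):
        """Analytic (autodiff) Jacobian of f(z) = alpha * MLP(z) at a point."""
        alpha = self.config.alpha
        d = self.config.d_hat

        def jac(z: np.ndarray) -> np.ndarray:
            J = np.empty((d, d))
            for i in range(d):
                zt = Tensor(np.asarray(z, dtype=float).reshape(1, d),
                            requires_grad=True)
                out = self.node_mlp(zt)
                out[0, i].backward(np.ones(()))
                J[i] = alpha * zt.grad[0]
            return J

        return jac


def poisson_nll_terms(X: Tensor | np.ndarray, log_rates: Tensor) -> Tensor:
    """Mean over bins/neurons of (lambda - x * log lambda); log(x!) omitted."""
    X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=log_rates.dtype))
    return (log_rates.exp() - X * log_rates).mean()


def train_model(dataset, config: ModelConfig, verbose: bool = False,
                callback=None) -> SequentialAutoencoder:
    """Train an autoencoder on the dataset's training trials.

    Minimizes the Poisson NLL with Adam for ``config.epochs`` epochs
    (full-batch unless ``config.batch_size`` is set).  The per-epoch training
    and validation objective values are appended to ``model.training_log``.
    Deterministic given the config seed and backend thread count.
    """
    X_train = np.asarray(dataset.X[dataset.train_idx], dtype=config.dtype)
    X_valid = np.asarray(dataset.X[dataset.valid_idx], dtype=config.dtype)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    model = SequentialAutoencoder(config)
    params = model.parameters()
    node_ids = {id(p) for p in model.node_mlp.parameters()}
    decay = [config.weight_decay
             + (config.node_weight_decay if id(p) in node_ids else 0.0)
             for p in params]
    opt = Adam(params, lr=config.learning_rate, weight_decay=decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA7C4]))
    n = X_train.shape[0]
    bs = config.batch_size or n
    for epoch in range(config.epochs):
        if epoch in config.lr_decay_epochs:
            opt.lr *= config.lr_decay_factor
        perm = rng.permutation(n) if bs < n else np.arange(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            batch = X_train[perm[start:start + bs]]
            opt.zero_grad()
            _, _, log_rates, _ = model.forward(batch)
            loss = poisson_nll_terms(batch, log_rates)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches}")
            loss.backward()
            if config.grad_clip is not None:
                total = np.sqrt(sum(float((p.grad * p.grad).sum())
                                    for p in opt.params if p.grad is not None))
                if total > config.grad_clip:
                    scale = config.grad_clip / total
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        entry = {"epoch": epoch, "train_nll": epoch_loss / n_batches}
        if X_valid.shape[0] and (epoch % 25 == 0 or epoch == config.epochs - 1):
            with no_grad():
                _, _, vlr, _ = model.forward(X_valid)
                entry["valid_nll"] = float(poisson_nll_terms(X_valid, vlr).data)
        model.training_log.append(entry)
        if verbose and epoch % 25 == 0:
            print(f"epoch {epoch:5d}  train NLL {entry['train_nll']:.4f}"
                  + (f"  valid NLL {entry['valid_nll']:.4f}" if "valid_nll" in entry else ""))
        if callback is not None:
            callback(model, entry)
    return model


def infer(dataset, model: SequentialAutoencoder,
          split: str | None = None) -> LatentInference:
    """Forward pass over a dataset split ('train', 'valid' or None = all trials)."""
    if split == "train":
        X = dataset.X[dataset.train_idx]
    elif split == "valid":
        X = dataset.X[dataset.valid_idx]
    elif split is None:
        X = dataset.X
    else:
        raise ValueError(f"unknown split {split!r}")
    if X.shape[2] != model.config.n_neurons:
        raise ValueError("dataset neuron count differs from model config")
    chunks = {"z0": [], "Z": [], "lr": [], "r": []}
    with no_grad():
        for start in range(0, X.shape[0], 256):
            part = np.asarray(X[start:start + 256], dtype=model.config.dtype)
            z0, Z_hat, log_rates, rates = model.forward(part)
            chunks["z0"].append(z0.data)
            chunks["Z"].append(Z_hat.data)
            chunks["lr"].append(log_rates.data)
            chunks["r"].append(rates.data)
    return LatentInference(z0_hat=np.concatenate(chunks["z0"]),
                           Z_hat=np.concatenate(chunks["Z"]),
                           log_rates=np.concatenate(chunks["lr"]),
                           rates=np.concatenate(chunks["r"]))


# ---------------------------------------------------------------------------
# Checkpoints: single zip with JSON config + NPZ parameter arrays
# ---------------------------------------------------------------------------

def save_model(path: str, model: SequentialAutoencoder) -> None:
    import io
    buf = io.BytesIO()
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(model.config)))
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("training_log.json", json.dumps(model.training_log))


def load_model(path: str) -> SequentialAutoencoder:
    import io
    with zipfile.ZipFile(path, "r") as zf:
        cfg_dict = json.loads(zf.read("config.json"))
        cfg_dict["node_hidden_layers"] = tuple(cfg_dict["node_hidden_layers"])
        cfg_dict["readout_hidden_layers"] = tuple(cfg_dict["readout_hidden_layers"])
        config = ModelConfig(**cfg_dict)
        model = SequentialAutoencoder(config)
        with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
            model.load_arrays([npz[f"param_{i}"] for i in range(len(npz.files))])
        model.training_log = json.loads(zf.read("training_log.json"))
    return model
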
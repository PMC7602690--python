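"""Gaussian-Bernoulli restricted Boltzmann machine.

A bipartite latent-variable model with ``D`` Gaussian visible units and
``N_h`` binary hidden units, joint density ``p(v, h) = exp(-E(v, h)) / Z``
with energy

    E(v, h) = sum_i (v_i - b_i)^2 / (2 s_i^2)
            - sum_j c_j h_j
            - sum_ij (v_i / s_i^2) W_ij h_j.

Marginalising the hidden layer induces effective interactions of all
orders among the visibles, which is what makes the GRBM the most
expressive generative model in this package.  The marginal is available
up to normalisation through the free energy ``F(v)``; the partition
function is estimated by annealed importance sampling (AIS) from the
decoupled ``W = 0`` base model, whose normalisation is closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .dataset_io import FluctuationData

__all__ = [
    "GRBMModel",
    "GrbmTrainParams",
    "free_energy",
    "train_grbm",
    "sample_grbm",
    "estimate_log_z_ais",
    "grbm_log_density",
    "base_log_z",
]


def _softplus(x: np.ndarray) -> np.ndarray:
    return -log_expit(-x)  # log(1 + e^x), overflow-safe


@dataclass
class GrbmTrainParams:
    """CD training settings.

    ``sigma_factor`` sets the fixed visible scales to this fraction of the
    per-column data standard deviation.  The GRBM marginal variance is the
    visible noise plus what the hidden layer contributes, so on
    standardised data the noise floor must sit below the data scale or the
    hidden units have nothing left to model.
    """

    n_epochs: int = 600
    cd_k: int = 1
    persistent: bool = False  # persistent (PCD) negative chains
    mean_calibration_rounds: int = 25  # post-training first-moment calibration
    batch_size: int = 64
    learning_rate: float = 5e-3
    momentum_start: float = 0.5
    momentum_end: float = 0.9
    momentum_switch_epoch: int = 5
    weight_init_scale: float = 0.01
    sigma_factor: float = 0.5
    sigma_override: np.ndarray | None = None  # explicit visible scales


@dataclass
class GRBMModel:
    """GRBM parameters: couplings ``W`` (D x N_h), biases ``b``/``c``,
    visible scales ``sigma`` (all 1 on standardised data)."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    sigma: np.ndarray
    log_z: float | None = None
    log_z_stderr: float | None = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")

    @property
    def dim(self) -> int:
        return self.b.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def hidden_activation(self, v: np.ndarray) -> np.ndarray:
        return self.c + (v / self.sigma**2) @ self.W

    def log_density(self, v: np.ndarray) -> float | np.ndarray:
        return grbm_log_density(self, v)

    def to_json(self) -> str:
        return json.dumps(
            {
                "W": self.W.tolist(),
                "b": self.b.tolist(),
                "c": self.c.tolist(),
                "sigma": self.sigma.tolist(),
                "n_hidden": self.n_hidden,
                "log_z": self.log_z,
                "log_z_stderr": self.log_z_stderr,
                "training_meta": {
                    k: v
                    for k, v in self.training_meta.items()
                    if k != "reconstruction_trace"
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GRBMModel":
        d = json.loads(text)
        return cls(
            W=np.array(d["W"]),
            b=np.array(d["b"]),
            c=np.array(d["c"]),
            sigma=np.array(d["sigma"]),
            log_z=d["log_z"],
            log_z_stderr=d["log_z_stderr"],
            training_meta=d.get("training_meta", {}),
        )


def free_energy(model: GRBMModel, v: np.ndarray) -> float | np.ndarray:
    """Negative log of the hidden-marginalised unnormalised density.

    ``F(v) = sum_i (v_i - b_i)^2 / (2 s_i^2) - sum_j softplus(c_j + (v/s^2) W)_j``
    so that the marginal is ``exp(-F(v)) / Z``.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = np.atleast_2d(v)
    quad = np.sum((V - model.b) ** 2 / (2 * model.sigma**2), axis=1)
    hid = np.sum(_softplus(model.hidden_activation(V)), axis=1)
    out = quad - hid
    return float(out[0]) if single else out


def base_log_z(model: GRBMModel) -> float:
    """Closed-form ``log Z`` of the decoupled (``W = 0``) model."""
    return float(
        np.sum(np.log(np.sqrt(2 * np.pi) * model.sigma))
        + np.sum(_softplus(model.c))
    )


def _gibbs_step(
    model: GRBMModel, V: np.ndarray, rng: np.random.Generator, beta: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """One block-Gibbs sweep h | v then v | h (couplings scaled by beta)."""
    p_h = expit(model.c + beta * (V / model.sigma**2) @ model.W)
    H = (rng.uniform(size=p_h.shape) < p_h).astype(float)
    mean_v = model.b + beta * H @ model.W.T
    V_new = mean_v + model.sigma * rng.standard_normal(V.shape)
    return V_new, H


def train_grbm(
    fluct: FluctuationData | np.ndarray,
    n_hidden: int = 20,
    train_params: GrbmTrainParams | None = None,
    seed: int | np.random.Generator = 0,
) -> GRBMModel:
    """Contrastive-divergence (CD-k) training on standardised fluctuations.

    Visible scales are fixed at ``sigma_factor`` times the per-column data
    standard deviation (see :class:`GrbmTrainParams`); visible biases
    start at the data mean, hidden biases at 0.  Returns the model with a
    per-epoch reconstruction-error trace in ``training_meta``.
    """
    tp = train_params or GrbmTrainParams()
    rng = np.random.default_rng(seed)
    X = fluct.deltas if isinstance(fluct, FluctuationData) else np.asarray(fluct)
    S, dim = X.shape
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")

    if tp.sigma_override is not None:
        sigma = np.broadcast_to(np.asarray(tp.sigma_override, float), (dim,)).copy()
    else:
        sigma = tp.sigma_factor * X.std(axis=0, ddof=0)
    if np.any(sigma <= 0):
        raise ValueError("zero-variance column: cannot set visible scales")
    model = GRBMModel(
        W=tp.weight_init_scale * rng.standard_normal((dim, n_hidden)),
        b=X.mean(axis=0),
        c=np.zeros(n_hidden),
        sigma=sigma,
    )
    vel_W = np.zeros_like(model.W)
    vel_b = np.zeros_like(model.b)
    vel_c = np.zeros_like(model.c)
    recon_trace = []
    # persistent negative chains track the model distribution across
    # updates, removing the short-chain bias of plain CD
    chains = X[rng.integers(S, size=min(tp.batch_size, S))].copy()

    for epoch in range(tp.n_epochs):
        mom = (
            tp.momentum_start
            if epoch < tp.momentum_switch_epoch
            else tp.momentum_end
        )
        perm = rng.permutation(S)
        sq_err = 0.0
        for start in range(0, S, tp.batch_size):
            V0 = X[perm[start : start + tp.batch_size]]
            m = V0.shape[0]
            p_h0 = expit(model.hidden_activation(V0))
            Vk = chains if tp.persistent else V0
            for _ in range(tp.cd_k):
                Vk, _ = _gibbs_step(model, Vk, rng)
            if tp.persistent:
                chains = Vk
            p_hk = expit(model.hidden_activation(Vk))

            s2 = model.sigma**2
            g_W = ((V0 / s2).T @ p_h0 / m) - ((Vk / s2).T @ p_hk / len(Vk))
            g_b = (V0.mean(axis=0) - Vk.mean(axis=0)) / s2
            g_c = p_h0.mean(axis=0) - p_hk.mean(axis=0)

            vel_W = mom * vel_W + tp.learning_rate * g_W
            vel_b = mom * vel_b + tp.learning_rate * g_b
            vel_c = mom * vel_c + tp.learning_rate * g_c
            model.W += vel_W
            model.b += vel_b
            model.c += vel_c
            if not (
                np.all(np.isfinite(model.W))
                and np.all(np.isfinite(model.b))
                and np.all(np.isfinite(model.c))
            ):
                raise RuntimeError(f"NaN in GRBM parameters at epoch {epoch}")
            recon = model.b + p_h0 @ model.W.T
            sq_err += float(np.sum((V0 - recon) ** 2))
        recon_trace.append(sq_err / S)

    # CD's short negative chains match the reconstruction mean, not the
    # equilibrium mean; calibrate the visible biases so that the model's
    # first moment matches the data (damped fixed-point iteration)
    target = X.mean(axis=0)
    # the mean responds to b with gain ~ Var_model / sigma^2 >= 1, so the
    # damped step is scaled by its inverse for a stable contraction
    step = 0.5 * model.sigma**2 / np.maximum(X.var(axis=0, ddof=0), model.sigma**2)
    V = model.b + model.sigma * rng.standard_normal((1024, dim))
    for _ in range(tp.mean_calibration_rounds):
        for _ in range(20):
            V, _ = _gibbs_step(model, V, rng)
        model.b += step * (target - V.mean(axis=0))

    model.training_meta = {
        "epochs": tp.n_epochs,
        "cd_k": tp.cd_k,
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
        "reconstruction_trace": recon_trace,
    }
    return model


def sample_grbm(
    model: GRBMModel,
    n: int,
    gibbs_steps: int = 200,
    seed: int | np.random.Generator = 0,
) -> FluctuationData:
    """Block-Gibbs sampling: ``n`` independent chains, final visible states."""
    rng = np.random.default_rng(seed)
    V = model.b + model.sigma * rng.standard_normal((n, model.dim))
    for _ in range(gibbs_steps):
        V, _ = _gibbs_step(model, V, rng)
    return FluctuationData(
        deltas=V,
        mean=np.zeros(model.dim),
        subject_ids=np.array([f"gibbs{i}" for i in range(n)], dtype=object),
        gender=np.array(["NA"] * n, dtype=object),
    )


def _free_energy_beta(model: GRBMModel, V: np.ndarray, beta: float) -> np.ndarray:
    quad = np.sum((V - model.b) ** 2 / (2 * model.sigma**2), axis=1)
    hid = np.sum(
        _softplus(model.c + beta * (V / model.sigma**2) @ model.W), axis=1
    )
    return quad - hid


def estimate_log_z_ais(
    model: GRBMModel,
    n_runs: int = 100,
    n_temperatures: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Annealed importance sampling estimate of ``log Z``.

    Anneals from the ``W = 0`` base model (closed-form normalisation) to
    the target along the geometric path obtained by scaling ``W`` by
    ``beta in [0, 1]``; one block-Gibbs transition per temperature.  The
    estimate and its standard error (over runs, delta method) are stored
    on the model.
    """
    import warnings

    rng = np.random.default_rng(seed)
    betas = np.linspace(0.0, 1.0, n_temperatures + 1)
    V = model.b + model.sigma * rng.standard_normal((n_runs, model.dim))
    log_w = np.zeros(n_runs)
    for k in range(1, len(betas)):
        log_w += _free_energy_beta(model, V, betas[k - 1]) - _free_energy_beta(
            model, V, betas[k]
        )
        V, _ = _gibbs_step(model, V, rng, beta=betas[k])
    m = log_w.max()
    w = np.exp(log_w - m)
    log_ratio = m + np.log(w.mean())
    stderr = float(w.std(ddof=1) / (w.mean() * np.sqrt(n_runs)))
    if stderr > 1.0:
        warnings.warn(
            f"AIS stderr {stderr:.2f} nat > 1; increase runs/temperatures",
            stacklevel=2,
        )
    model.log_z = float(base_log_z(model) + log_ratio)
    model.log_z_stderr = stderr
    return model.log_z, stderr


def grbm_log_density(model: GRBMModel, v: np.ndarray) -> float | np.ndarray:
    """Normalised log marginal density ``-F(v) - log Z``."""
    if model.log_z is None:
        raise ValueError(
            "log_z not estimated; call estimate_log_z_ais on the model first"
        )
    fe = free_energy(model, v)
    return -fe - model.log_z
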
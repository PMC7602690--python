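"""Third-order maximum-entropy model: cubic Hamiltonian on a hypercube.

The order-3 model extends the Gaussian model with a symmetric tensor ``Q``
of three-wise interaction constants:

    L(Delta) = exp(-[H2(Delta) + H3(Delta)]) * 1(|Delta_mu| <= B) / Z3
    H3(Delta) = 1/6 sum_{mnk} Delta_m Delta_n Delta_k Q_{mnk}

A cubic Hamiltonian alone is not normalisable, so the density is truncated
to the hypercube ``[-B, B]^D`` (``B = 6`` in standardised units, i.e. six
standard deviations).  The inverse problem has no closed form; parameters
are learned by moment-matching gradient ascent with persistent Metropolis
chains, and ``Z3`` is computed by quadrature in low dimension or by
annealed importance sampling from the truncated Gaussian part.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import (
    FluctuationData,
    MomentStatistics,
    _sym3_indices,
    sym3_to_dense,
)
from .maxent2 import GaussianMaxEntModel, fit_gaussian_maxent

__all__ = [
    "CubicMaxEntModel",
    "LearnParams",
    "McmcParams",
    "cubic_hamiltonian",
    "metropolis_sample",
    "fit_cubic_maxent",
    "estimate_log_z3",
    "cubic_log_density",
    "LOG_ZERO",
]

#: finite stand-in for log(0) outside the support, so classifiers can still rank
LOG_ZERO = -1e30

DEFAULT_B = 6.0


@dataclass
class McmcParams:
    """Metropolis sampler settings (full-vector Gaussian proposals)."""

    step_scale: float = 0.4
    burn_in: int = 500
    thin: int = 5
    n_chains: int = 32
    adapt_target: float = 0.4
    adapt_interval: int = 50


@dataclass
class LearnParams:
    """Moment-matching gradient-ascent settings.

    ``learning_rate`` decays as ``lr / sqrt(t)``.  Model moments are
    estimated from the persistent chains and smoothed with an exponential
    moving average (``moment_ema``) before entering the gradient and the
    stopping rule, which fires when the largest smoothed moment residual
    drops below ``tol``.
    """

    learning_rate: float = 0.05
    tol: float = 0.02
    max_iters: int = 2000
    n_chains: int = 64
    sweeps_per_iter: int = 5
    moment_ema: float = 0.995  # cap; the effective window grows as ~t/10
    step_scale: float = 0.4
    adapt_burn_in: int = 400
    divergence_patience: int = 100
    average_tail_fraction: float = 0.5  # Polyak-average params over this tail
    gradient_clip: float = 1.0  # per-moment residual clip for updates
    readapt_interval: int = 50  # iterations between proposal re-adaptations
    mode_guard_margin: float = 15.0  # reset chains this many nats below median


@dataclass
class CubicMaxEntModel:
    """Parameters ``(h, J, Q)`` of the cubic model with support ``[-B, B]^D``.

    ``Q`` is stored compactly: ``q_indices`` holds the triples
    ``mu <= nu <= kappa`` and ``q_values`` the corresponding entries.
    """

    h: np.ndarray
    J: np.ndarray
    q_indices: np.ndarray
    q_values: np.ndarray
    B: float = DEFAULT_B
    log_z3: float | None = None
    log_z3_stderr: float | None = None
    fit_diagnostics: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.h.shape[0]

    def q_dense(self) -> np.ndarray:
        return sym3_to_dense(self.dim, self.q_indices, self.q_values)

    def log_density(self, delta: np.ndarray) -> np.ndarray:
        return cubic_log_density(self, delta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "h": self.h.tolist(),
                "J": self.J.tolist(),
                "q_indices": self.q_indices.tolist(),
                "q_values": self.q_values.tolist(),
                "B": self.B,
                "log_z3": self.log_z3,
                "log_z3_stderr": self.log_z3_stderr,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CubicMaxEntModel":
        d = json.loads(text)
        return cls(
            h=np.array(d["h"]),
            J=np.array(d["J"]),
            q_indices=np.array(d["q_indices"], dtype=int),
            q_values=np.array(d["q_values"]),
            B=float(d["B"]),
            log_z3=d["log_z3"],
            log_z3_stderr=d["log_z3_stderr"],
        )


def _h2_batch(X: np.ndarray, h: np.ndarray, J: np.ndarray) -> np.ndarray:
    return 0.5 * np.einsum("sa,ab,sb->s", X, J, X) - X @ h


def _h3_batch(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if not np.any(Q):
        return np.zeros(X.shape[0])
    M = np.einsum("abc,sc->sab", Q, X)
    return np.einsum("sa,sab,sb->s", X, M, X) / 6.0


def cubic_hamiltonian(
    delta: np.ndarray,
    h: np.ndarray,
    J: np.ndarray,
    Q: np.ndarray,
) -> float | np.ndarray:
    """``H2 + H3`` with ``Q`` given as a dense symmetric tensor.

    ``H2 = 1/2 Delta' J Delta - h' Delta``; the cubic sum runs over all
    ordered triples with the symmetric tensor expanded.
    """
    delta = np.asarray(delta, dtype=float)
    single = delta.ndim == 1
    X = np.atleast_2d(delta)
    out = _h2_batch(X, h, J) + _h3_batch(X, np.asarray(Q, dtype=float))
    return float(out[0]) if single else out


def _model_hamiltonian(model: CubicMaxEntModel, X: np.ndarray) -> np.ndarray:
    return _h2_batch(X, model.h, model.J) + _h3_batch(X, model.q_dense())


class _MetropolisState:
    """Vectorised parallel Metropolis chains on the hypercube."""

    def __init__(
        self,
        dim: int,
        B: float,
        n_chains: int,
        step_scale: float,
        proposal_cov: np.ndarray | None,
        rng: np.random.Generator,
    ):
        self.B = B
        self.step_scale = step_scale
        self.rng = rng
        if proposal_cov is not None:
            evals, evecs = np.linalg.eigh(proposal_cov)
            evals = np.clip(evals, 1e-12, None)
            self.chol = evecs * np.sqrt(evals)
        else:
            self.chol = np.eye(dim)
        self.x = np.clip(
            rng.standard_normal((n_chains, dim)) @ self.chol.T, -0.9 * B, 0.9 * B
        )
        self.energy: np.ndarray | None = None
        self.accepted = 0
        self.proposed = 0

    def sweeps(self, model: CubicMaxEntModel, n_sweeps: int) -> None:
        if self.energy is None:
            self.energy = _model_hamiltonian(model, self.x)
        for _ in range(n_sweeps):
            step = self.step_scale * (
                self.rng.standard_normal(self.x.shape) @ self.chol.T
            )
            prop = self.x + step
            inside = np.all(np.abs(prop) <= self.B, axis=1)
            e_prop = np.where(
                inside, _model_hamiltonian(model, prop), np.inf
            )
            log_u = np.log(self.rng.uniform(size=self.x.shape[0]))
            accept = log_u < (self.energy - e_prop)
            self.x[accept] = prop[accept]
            self.energy = np.where(accept, e_prop, self.energy)
            self.accepted += int(accept.sum())
            self.proposed += accept.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / max(self.proposed, 1)

    def adapt(self, target: float) -> None:
        rate = self.acceptance_rate
        self.step_scale *= float(np.exp(0.6 * (rate - target)))
        self.accepted = 0
        self.proposed = 0


def metropolis_sample(
    model: CubicMaxEntModel,
    n: int,
    mcmc_params: McmcParams | None = None,
    seed: int | np.random.Generator = 0,
) -> FluctuationData:
    """Sample the cubic density with parallel Metropolis chains.

    Gaussian full-vector proposals shaped by the model's Gaussian part;
    proposals outside the hypercube are rejected outright.  The proposal
    scale is adapted towards the target acceptance rate during burn-in and
    then frozen; ``n`` post-burn-in draws, thinned, pooled over chains.
    """
    p = mcmc_params or McmcParams()
    rng = np.random.default_rng(seed)
    try:
        prop_cov = np.linalg.inv(model.J)
    except np.linalg.LinAlgError:
        prop_cov = None
    st = _MetropolisState(model.dim, model.B, p.n_chains, p.step_scale, prop_cov, rng)
    for start in range(0, p.burn_in, p.adapt_interval):
        st.sweeps(model, min(p.adapt_interval, p.burn_in - start))
        st.adapt(p.adapt_target)
    draws = []
    collected = 0
    while collected < n:
        st.sweeps(model, p.thin)
        take = min(p.n_chains, n - collected)
        draws.append(st.x[:take].copy())
        collected += take
    rate = st.acceptance_rate
    if not 0.05 <= rate <= 0.95:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.2f} outside [0.05, 0.95] "
            "after adaptation",
            stacklevel=2,
        )
    X = np.vstack(draws)
    return FluctuationData(
        deltas=X,
        mean=np.zeros(model.dim),
        subject_ids=np.array([f"mc{i}" for i in range(len(X))], dtype=object),
        gender=np.array(["NA"] * len(X), dtype=object),
    )


def _chain_moments(
    X: np.ndarray, jj: tuple, tidx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, upper-tri second moments, compact third moments) of chain states."""
    m1 = X.mean(axis=0)
    m2 = (X.T @ X) / X.shape[0]
    a, b, c = tidx.T
    m3 = np.einsum("sa,sb,sc->abc", X, X, X)[a, b, c] / X.shape[0]
    return m1, m2[jj], m3


def fit_cubic_maxent(
    data_moments: MomentStatistics,
    init: GaussianMaxEntModel | None = None,
    learn_params: LearnParams | None = None,
    seed: int | np.random.Generator = 0,
    B: float = DEFAULT_B,
) -> CubicMaxEntModel:
    """Moment-matching gradient ascent for the cubic model.

    Starts from the Gaussian fit (``Q = 0``) and ascends the likelihood:
    the gradient with respect to each independent parameter is the data
    moment minus the model moment (model moments from persistent
    Metropolis chains, smoothed by an exponential moving average).  Stops
    when the largest smoothed residual over all three moment orders falls
    below ``tol``.  Data are expected standardised (unit variances), so
    all residuals share a common scale.
    """
    if not data_moments.has_third:
        raise ValueError("third-order data moments required (max_order=3)")
    lp = learn_params or LearnParams()
    rng = np.random.default_rng(seed)
    dim = data_moments.dim

    if init is None:
        init = fit_gaussian_maxent(data_moments)
    h = init.h.copy()
    J = init.J.copy()
    tidx = _sym3_indices(dim)
    q = np.zeros(len(tidx))

    jj = np.triu_indices(dim)
    diag_mask = jj[0] == jj[1]
    data_m1 = data_moments.mean
    data_m2 = data_moments.cov[jj]
    data_m3 = data_moments.third_values

    model = CubicMaxEntModel(h=h, J=J, q_indices=tidx, q_values=q, B=B)
    st = _MetropolisState(
        dim, B, lp.n_chains, lp.step_scale, np.linalg.pinv(init.J), rng
    )
    # adapt the proposal scale on the initial (Gaussian) model, then freeze
    for _ in range(lp.adapt_burn_in // 50):
        st.sweeps(model, 50)
        st.adapt(0.4)

    ema1 = ema2 = ema3 = None
    best_resid = np.inf
    grow_streak = 0
    resid_trace = []
    converged = False
    t_avg_start = int((1 - lp.average_tail_fraction) * lp.max_iters)
    avg_params = None
    n_avg = 0
    n_guard_resets = 0
    for t in range(1, lp.max_iters + 1):
        st.sweeps(model, lp.sweeps_per_iter)
        # mode guard: during learning, transient parameters can open deep
        # metastable spikes in remote hypercube corners; chains falling in
        # get pinned and wreck the moment estimates.  The data live on the
        # central mode, so chains far below the ensemble's median energy
        # are reset to central draws.
        med = float(np.median(st.energy))
        stuck = st.energy < med - lp.mode_guard_margin
        if np.any(stuck):
            n_guard_resets += int(stuck.sum())
            fresh = st.rng.standard_normal((int(stuck.sum()), dim)) @ st.chol.T
            st.x[stuck] = np.clip(fresh, -0.9 * B, 0.9 * B)
            st.energy[stuck] = _model_hamiltonian(model, st.x[stuck])
        st.energy = None  # parameters change below; recompute lazily
        m1, m2, m3 = _chain_moments(st.x, jj, tidx)
        if ema1 is None:
            ema1, ema2, ema3 = m1, m2, m3
        else:
            # growing window: low-noise residuals late in training
            a = min(lp.moment_ema, 1.0 - 1.0 / (1.0 + 0.1 * t))
            ema1 = a * ema1 + (1 - a) * m1
            ema2 = a * ema2 + (1 - a) * m2
            ema3 = a * ema3 + (1 - a) * m3
        r1 = data_m1 - ema1
        r2 = data_m2 - ema2
        r3 = data_m3 - ema3
        resid = max(np.abs(r1).max(), np.abs(r2).max(), np.abs(r3).max())
        resid_trace.append(float(resid))
        if resid < lp.tol and t > 20:
            converged = True
            break
        # only catastrophic, sustained growth counts as divergence; the
        # stochastic residual oscillates while chains and parameters settle
        if resid > max(10.0 * best_resid, 5.0 * resid_trace[0]):
            grow_streak += 1
            if grow_streak >= lp.divergence_patience:
                raise RuntimeError(
                    f"moment residual diverging for {grow_streak} iterations "
                    f"(residual {resid:.3f} at iter {t})"
                )
        else:
            grow_streak = 0
        best_resid = min(best_resid, resid)

        lr = lp.learning_rate / np.sqrt(t)
        # ascent: raising h raises the model mean; raising J or Q lowers the
        # corresponding model moment.  Residuals are clipped so that a
        # transient chain collapse into a hypercube corner (model moments
        # of order B^3) cannot throw the parameters; the clipped dynamics
        # walks the parameters back until the chains recover.
        gc = lp.gradient_clip
        h += lr * np.clip(r1, -gc, gc)
        dJ = np.zeros_like(J)
        dJ[jj] = -lr * np.clip(r2, -gc, gc)
        J += dJ + dJ.T - np.diag(np.diag(dJ))
        q += -lr * np.clip(r3, -gc, gc)
        if t % lp.readapt_interval == 0:
            st.adapt(0.3)  # diminishing re-adaptation as the model drifts
        model.h, model.J = h, J
        model.q_values = q
        if t >= t_avg_start:
            cur = (h.copy(), J.copy(), q.copy())
            if avg_params is None:
                avg_params = cur
                n_avg = 1
            else:
                n_avg += 1
                avg_params = tuple(
                    a + (c - a) / n_avg for a, c in zip(avg_params, cur)
                )

    if not converged and avg_params is not None:
        # Polyak tail average damps the MCMC noise in the final parameters
        model.h, model.J, model.q_values = avg_params

    model.fit_diagnostics = {
        "iterations": t,
        "n_guard_resets": n_guard_resets,
        "converged": converged,
        "final_residual": resid_trace[-1] if resid_trace else None,
        "residual_trace": resid_trace,
        "acceptance_rate": st.acceptance_rate,
    }
    return model


def _log_z3_quadrature(model: CubicMaxEntModel) -> tuple[float, float]:
    """Adaptive quadrature of ``int exp(-H)`` over the hypercube (D <= 2)."""
    from scipy import integrate

    if model.dim > 2:
        raise ValueError("quadrature normalisation only supported for D <= 2")
    Q = model.q_dense()
    B = model.B
    if model.dim == 1:

        def f(x, off):
            return np.exp(
                -cubic_hamiltonian(np.array([x]), model.h, model.J, Q) - off
            )

        # offset by the minimum Hamiltonian to keep the integrand in range
        grid = np.linspace(-B, B, 2001)
        hvals = cubic_hamiltonian(grid[:, None], model.h, model.J, Q)
        off = -float(hvals.min())
        val, err = integrate.quad(f, -B, B, args=(off,), limit=200)
    else:

        def f2(y, x, off):
            return np.exp(
                -cubic_hamiltonian(np.array([x, y]), model.h, model.J, Q) - off
            )

        g = np.linspace(-B, B, 201)
        GX, GY = np.meshgrid(g, g)
        pts = np.column_stack([GX.ravel(), GY.ravel()])
        off = -float(cubic_hamiltonian(pts, model.h, model.J, Q).min())
        val, err = integrate.dblquad(
            f2, -B, B, -B, B, args=(off,), epsabs=1e-10, epsrel=1e-9
        )
    log_z3 = float(np.log(val) + off)
    stderr = float(err / val)
    model.log_z3 = log_z3
    model.log_z3_stderr = stderr
    return log_z3, stderr


def estimate_log_z3(
    model: CubicMaxEntModel,
    n_samples: int = 50_000,
    seed: int | np.random.Generator = 0,
    n_temperatures: int = 200,
    sweeps_per_temp: int = 2,
    method: str = "auto",
) -> tuple[float, float]:
    """Estimate ``log Z3`` and its standard error; stores both on the model.

    For ``D <= 2`` (``method='auto'``) the normalising integral is
    computed by deterministic adaptive quadrature over the hypercube —
    for strong cubic couplings the mass concentrates at the hypercube
    boundary, many nats above the central Gaussian mode, where any
    sampler anchored at the Gaussian part is unreliable, while quadrature
    is cheap and exact in low dimension.

    In higher dimension (``method='ais'``) annealed importance sampling
    is used: the base distribution is the Gaussian part truncated to the
    hypercube (normalisation ``Z2`` times the box probability, estimated
    by direct Monte Carlo), and the cubic term is switched on along a
    linear path ``exp(-H2 - beta * H3)`` with Metropolis transitions at
    each temperature.  ``n_samples`` controls the box-probability stage;
    the number of annealing chains is ``max(200, n_samples // 50)``.
    """
    if method not in ("auto", "quadrature", "ais"):
        raise ValueError("method must be 'auto', 'quadrature' or 'ais'")
    if method == "quadrature" or (method == "auto" and model.dim <= 2):
        return _log_z3_quadrature(model)
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eigh(model.J)
    if evals.min() <= 0:
        raise ValueError("Gaussian part is not positive definite: no proposal")
    cov_evals = 1.0 / evals
    mean = evecs @ ((evecs.T @ model.h) * cov_evals)
    log_z2 = 0.5 * model.dim * np.log(2 * np.pi) + 0.5 * float(
        np.sum(np.log(cov_evals))
    ) + 0.5 * float(model.h @ mean)

    # stage 1: box probability of the Gaussian part
    z = rng.standard_normal((n_samples, model.dim))
    X = mean + (z * np.sqrt(cov_evals)) @ evecs.T
    inside = np.all(np.abs(X) <= model.B, axis=1)
    p_box = inside.mean()
    if p_box == 0:
        raise RuntimeError("no Gaussian draw landed inside the hypercube")
    se_log_p = float(np.sqrt((1 - p_box) / (p_box * n_samples)))

    Q = model.q_dense()
    if not np.any(Q):
        model.log_z3 = float(log_z2 + np.log(p_box))
        model.log_z3_stderr = se_log_p
        return model.log_z3, model.log_z3_stderr

    # stage 2: anneal the cubic term on, starting from in-box draws
    n_chains = max(200, n_samples // 50)
    pool = X[inside]
    x = pool[rng.integers(len(pool), size=n_chains)].copy()
    h3 = _h3_batch(x, Q)
    h2 = _h2_batch(x, model.h, model.J)
    log_w = np.zeros(n_chains)
    chol = evecs * np.sqrt(cov_evals)
    step_scale = 0.5
    betas = np.linspace(0.0, 1.0, n_temperatures + 1)
    for k in range(1, len(betas)):
        d_beta = betas[k] - betas[k - 1]
        log_w += -d_beta * h3
        for _ in range(sweeps_per_temp):
            prop = x + step_scale * rng.standard_normal(x.shape) @ chol.T
            ok = np.all(np.abs(prop) <= model.B, axis=1)
            h2p = _h2_batch(prop, model.h, model.J)
            h3p = _h3_batch(prop, Q)
            e_cur = h2 + betas[k] * h3
            e_prop = np.where(ok, h2p + betas[k] * h3p, np.inf)
            accept = np.log(rng.uniform(size=n_chains)) < (e_cur - e_prop)
            x[accept] = prop[accept]
            h2 = np.where(accept, h2p, h2)
            h3 = np.where(accept, h3p, h3)

    m = log_w.max()
    w = np.exp(log_w - m)
    ess = w.sum() ** 2 / (w**2).sum()
    if ess < 100:
        raise RuntimeError(
            f"effective sample size {ess:.0f} < 100; increase n_samples "
            "or n_temperatures"
        )
    log_ratio = m + np.log(w.mean())
    se_ais = float(w.std(ddof=1) / (w.mean() * np.sqrt(n_chains)))
    model.log_z3 = float(log_z2 + np.log(p_box) + log_ratio)
    model.log_z3_stderr = float(np.hypot(se_ais, se_log_p))
    return model.log_z3, model.log_z3_stderr


def cubic_log_density(model: CubicMaxEntModel, delta: np.ndarray) -> float | np.ndarray:
    """Normalised log density; a finite ``LOG_ZERO`` outside the hypercube."""
    if model.log_z3 is None:
        raise ValueError("log_z3 not estimated; call estimate_log_z3 first")
    delta = np.asarray(delta, dtype=float)
    single = delta.ndim == 1
    X = np.atleast_2d(delta)
    out = np.full(X.shape[0], LOG_ZERO)
    inside = np.all(np.abs(X) <= model.B, axis=1)
    if np.any(inside):
        out[inside] = -_model_hamiltonian(model, X[inside]) - model.log_z3
    return float(out[0]) if single else out
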
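"""Order-1 and order-2 maximum-entropy models of landmark fluctuations.

The order-2 (Gaussian) model is the maximum-entropy density consistent
with the empirical means and pairwise correlations ``C = <Delta Delta^T>``:

    L(Delta) = exp(-H2(Delta)) / Z,   H2 = 1/2 Delta' J Delta - h' Delta

whose maximum-likelihood solution is closed form, ``J = C^+`` (the
pseudo-inverse, discarding the null modes induced by the face-space
constraints) and ``h = J <Delta>``.  The density lives on the constraint
subspace; the partition function uses the pseudo-determinant and
``(2 pi)^(rank/2)``.

The order-1 model keeps only the means and per-coordinate variances
(``J`` diagonal), i.e. independent landmark coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .dataset_io import (
    DEFAULT_REL_TOL,
    ConstraintBasis,
    FluctuationData,
    MomentStatistics,
)

__all__ = [
    "GaussianMaxEntModel",
    "fit_gaussian_maxent",
    "fit_independent_maxent",
    "gaussian_log_density",
    "sample_gaussian",
    "parameter_count",
    "OffSupportWarning",
]


class OffSupportWarning(UserWarning):
    """A point handed to the density had components off the model support."""


@dataclass
class GaussianMaxEntModel:
    """Gaussian maximum-entropy model ``(h, J)`` with exact normalisation.

    ``cov`` caches ``C = J^+`` (eigendecomposition in ``evals``/``evecs``,
    null modes excluded), ``log_z`` the log partition function on the
    support, and ``order_tag`` whether the fit used order-1 or order-2
    sufficient statistics.
    """

    h: np.ndarray
    J: np.ndarray
    mean: np.ndarray
    log_z: float
    evals: np.ndarray  # non-null eigenvalues of C
    evecs: np.ndarray  # corresponding eigenvectors, (dim, rank)
    order_tag: int = 2
    rel_tol: float = DEFAULT_REL_TOL

    @property
    def dim(self) -> int:
        return self.h.shape[0]

    @property
    def rank(self) -> int:
        return self.evals.shape[0]

    @property
    def cov(self) -> np.ndarray:
        return (self.evecs * self.evals) @ self.evecs.T

    def log_density(self, delta: np.ndarray) -> np.ndarray:
        return gaussian_log_density(self, delta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order_tag,
                "h": self.h.tolist(),
                "J": self.J.tolist(),
                "mean": self.mean.tolist(),
                "log_z": self.log_z,
                "support_evecs": self.evecs.tolist(),
                "support_evals": self.evals.tolist(),
                "rel_tol": self.rel_tol,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GaussianMaxEntModel":
        d = json.loads(text)
        return cls(
            h=np.array(d["h"]),
            J=np.array(d["J"]),
            mean=np.array(d["mean"]),
            log_z=float(d["log_z"]),
            evals=np.array(d["support_evals"]),
            evecs=np.array(d["support_evecs"]),
            order_tag=int(d["order"]),
            rel_tol=float(d["rel_tol"]),
        )


def _finish_fit(
    mean: np.ndarray,
    evals: np.ndarray,
    evecs: np.ndarray,
    order_tag: int,
    rel_tol: float,
) -> GaussianMaxEntModel:
    J = (evecs / evals) @ evecs.T
    h = J @ mean
    rank = evals.shape[0]
    # log Z on the support: (rank/2) log 2pi + 1/2 log pdet(C) + 1/2 h' C h
    log_z = (
        0.5 * rank * np.log(2 * np.pi)
        + 0.5 * float(np.sum(np.log(evals)))
        + 0.5 * float(h @ ((evecs * evals) @ (evecs.T @ h)))
    )
    return GaussianMaxEntModel(
        h=h,
        J=J,
        mean=mean,
        log_z=log_z,
        evals=evals,
        evecs=evecs,
        order_tag=order_tag,
        rel_tol=rel_tol,
    )


def fit_gaussian_maxent(
    moments: MomentStatistics,
    basis: ConstraintBasis | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
) -> GaussianMaxEntModel:
    """Closed-form order-2 fit: ``J = C^+``, ``h = J <Delta>``.

    Eigenvalues of the (second-moment-about-the-mean) covariance below
    ``rel_tol`` times the largest are treated as exact null modes and
    excluded from the inversion.  A ``basis`` narrows nothing numerically
    (the null modes are re-detected from the spectrum) but is accepted for
    interface symmetry with the reduced-frame workflow.
    """
    mean = np.asarray(moments.mean, dtype=float)
    # central covariance: C about the mean, so the model reproduces both
    # <Delta> and <Delta Delta'> exactly
    C = np.asarray(moments.cov, dtype=float) - np.outer(mean, mean)
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise ValueError("degenerate covariance")
    if evals[0] < -rel_tol * lam_max - 1e-300:
        if evals[0] < -1e-8 * lam_max:
            raise ValueError(f"covariance has negative eigenvalue {evals[0]:.3e}")
    keep = evals > rel_tol * lam_max
    return _finish_fit(mean, evals[keep], evecs[:, keep], 2, rel_tol)


def fit_independent_maxent(
    moments: MomentStatistics, rel_tol: float = DEFAULT_REL_TOL
) -> GaussianMaxEntModel:
    """Order-1 fit: fields only, ``J_ij = sigma_i^{-2} delta_ij``."""
    mean = np.asarray(moments.mean, dtype=float)
    var = np.diag(moments.cov) - mean**2
    if np.any(var <= 0):
        raise ValueError("zero-variance coordinate: cannot fit independent model")
    dim = mean.shape[0]
    order = np.argsort(var)  # eigh convention: ascending eigenvalues
    evecs = np.eye(dim)[:, order]
    return _finish_fit(mean, var[order], evecs, 1, rel_tol)


def gaussian_log_density(model: GaussianMaxEntModel, delta: np.ndarray) -> np.ndarray:
    """Log density w.r.t. Lebesgue measure on the support subspace.

    Components of ``delta`` off the support (along null modes) are
    projected out with a warning — measurement noise routinely puts real
    vectors slightly off-support, and ranking points is still meaningful.
    Accepts a single vector or an ``(m, dim)`` batch.
    """
    delta = np.asarray(delta, dtype=float)
    single = delta.ndim == 1
    delta = np.atleast_2d(delta)
    centred = delta - model.mean
    coeff = centred @ model.evecs  # components in the support frame
    recon = coeff @ model.evecs.T
    off = centred - recon
    off_norm = np.linalg.norm(off, axis=1)
    scale = max(float(np.max(model.evals)), 1.0) ** 0.5
    if model.rank < model.dim and np.any(off_norm > 1e-8 * scale):
        warnings.warn(
            "point has off-support components; projecting onto the model support",
            OffSupportWarning,
            stacklevel=2,
        )
    quad = np.sum(coeff**2 / model.evals, axis=1)
    # H2(mean + c) - log-density form: -1/2 c'Jc - log_z + (h'C h)/2 folds into log_z
    out = -0.5 * quad - 0.5 * model.rank * np.log(2 * np.pi) - 0.5 * float(
        np.sum(np.log(model.evals))
    )
    return float(out[0]) if single else out


def sample_gaussian(
    model: GaussianMaxEntModel, n: int, seed: int | np.random.Generator = 0
) -> FluctuationData:
    """Draw ``n`` exact samples: ``mean + sum_k sqrt(lam_k) u_k z_k``.

    Null directions carry exactly zero fluctuation, so samples respect the
    face-space constraints to machine precision.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.rank))
    X = model.mean + (z * np.sqrt(model.evals)) @ model.evecs.T
    return FluctuationData(
        deltas=X,
        mean=np.zeros(model.dim),
        subject_ids=np.array([f"sample{i}" for i in range(n)], dtype=object),
        gender=np.array(["NA"] * n, dtype=object),
    )


def parameter_count(order: int, D: int) -> int:
    """Independent-parameter count of the order-``p`` model in dimension D.

    Order 1: D fields + D variances.  Order 2: D + D(D+1)/2.  Order 3 uses
    the printed closed form D^3/6 + D^2/3 + 5D/2, rounded to the nearest
    integer (it is not integral for every D)."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if order == 1:
        return 2 * D
    if order == 2:
        return D + D * (D + 1) // 2
    if order == 3:
        exact = D**3 / 6 + D**2 / 3 + 5 * D / 2
        rounded = round(exact)
        if abs(exact - rounded) > 1e-9:
            warnings.warn(
                f"order-3 parameter-count formula is non-integer for D={D} "
                f"({exact}); reporting the nearest integer",
                stacklevel=2,
            )
        return int(rounded)
    raise ValueError("order must be 1, 2 or 3")
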
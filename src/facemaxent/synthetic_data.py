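"""Synthetic landmark studies with the statistical structure of sculpting data.

Generates datasets that emulate what the analysis pipeline assumes about
sculpted facial-landmark data, so that every downstream stage can be
exercised without the original study files:

* exact linear constraints — the ``2n`` raw coordinates are confined to a
  ``2n - k`` dimensional subspace by a seeded random orthogonal projector;
* subject structure — each subject has a latent preferred face, and their
  repeated sculpts scatter around it with a within-subject variance that
  is a fraction of the between-subject variance;
* two classes (gender labels) whose distributions differ at a chosen
  interaction order: means only (order 1), pairwise covariance (order 2),
  or third-order structure with first and second moments matched across
  classes (order 3).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import (
    ConstraintBasis,
    FluctuationData,
    LandmarkDataset,
    MomentStatistics,
    find_constraints,
)
from .maxent3 import CubicMaxEntModel, McmcParams, metropolis_sample

__all__ = [
    "SyntheticStudySpec",
    "ClassParams",
    "DEFAULT_LANDMARKS",
    "make_constraint_projector",
    "sample_gaussian_population",
    "sample_cubic_population",
    "make_two_class_study",
]

#: plausible mean landmark layout (x, y) in units of facial height, y down:
#: eye corners, nose tip and wings, mouth corners, chin
DEFAULT_LANDMARKS = np.array(
    [
        [0.32, 0.40],
        [0.68, 0.40],
        [0.50, 0.58],
        [0.40, 0.62],
        [0.60, 0.62],
        [0.36, 0.76],
        [0.64, 0.76],
        [0.50, 0.95],
    ]
)

#: typical inter-subject fluctuation scale, in facial heights
DEFAULT_FLUCT_SCALE = 0.02


@dataclass
class ClassParams:
    """Optional per-class override of the inter-subject Gaussian."""

    mean: np.ndarray | None = None  # full-frame mean fluctuation, length 2n
    cov: np.ndarray | None = None  # full-frame inter-subject covariance


@dataclass
class SyntheticStudySpec:
    """Design of a two-class synthetic sculpting study.

    ``difference_order`` selects where the classes differ: 0 = identical
    distributions, 1 = mean shift only, 2 = covariance only (means
    matched), 3 = third-order structure only (first and second moments
    affinely matched).  ``intra_to_inter_ratio`` is the within-subject to
    between-subject variance ratio.
    """

    n_subjects_per_class: int = 48
    reps_per_subject: int = 28
    n_landmarks: int = 8
    n_constraints: int = 6
    intra_to_inter_ratio: float = 0.25
    difference_order: int = 3
    mean_shift_scale: float = 0.5  # order-1 shift, in units of sigma_inter
    cov_stretch: float = 1.75  # order-2 per-mode variance stretch factor
    gamma_shape: float = 1.0  # order-3 latent skewness = 2 / sqrt(shape)
    fluct_scale: float = DEFAULT_FLUCT_SCALE
    class_params: dict[str, ClassParams] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_class, self.reps_per_subject) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_constraints < 2 * self.n_landmarks:
            raise ValueError("n_constraints must be < 2 * n_landmarks")
        if self.intra_to_inter_ratio <= 0:
            raise ValueError("intra_to_inter_ratio must be > 0")
        if self.difference_order not in (0, 1, 2, 3):
            raise ValueError("difference_order must be 0, 1, 2 or 3")


def make_constraint_projector(
    dim: int, n_constraints: int, seed: int | np.random.Generator = 0
) -> ConstraintBasis:
    """Seeded random orthonormal constraint basis and subspace projector."""
    if not 0 <= n_constraints < dim:
        raise ValueError("need 0 <= n_constraints < dim")
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((dim, dim))
    Qmat, _ = np.linalg.qr(M)
    null_vectors = Qmat[:, :n_constraints]
    projector = np.eye(dim) - null_vectors @ null_vectors.T
    # reuse the greedy retained-coordinate rule on the projector itself
    # (its eigenvalues are exactly 0 / 1)
    proxy = MomentStatistics(mean=np.zeros(dim), cov=projector, n_samples=1)
    basis = find_constraints(proxy, rel_tol=1e-10)
    return ConstraintBasis(
        null_vectors=null_vectors,
        retained_indices=basis.retained_indices,
        projector=projector,
    )


def sample_gaussian_population(
    mean: np.ndarray,
    cov: np.ndarray,
    n: int,
    basis: ConstraintBasis | None = None,
    seed: int | np.random.Generator = 0,
) -> FluctuationData:
    """Gaussian draws mapped through the constraint projector.

    The sample covariance converges to ``P C P`` and every sample lies
    exactly on the constraint subspace.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    evals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if evals[0] < -1e-10 * max(evals[-1], 1e-300):
        raise ValueError("covariance is not positive semidefinite")
    X = rng.multivariate_normal(mean, cov, size=n, method="eigh")
    if basis is not None:
        X = X @ basis.projector.T
        mean = basis.projector @ mean
    return FluctuationData(
        deltas=X - mean,
        mean=mean,
        subject_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        gender=np.array(["NA"] * n, dtype=object),
    )


def sample_cubic_population(
    model: CubicMaxEntModel,
    n: int,
    mcmc_params: McmcParams | None = None,
    seed: int | np.random.Generator = 0,
) -> FluctuationData:
    """Draws from a cubic maximum-entropy density (Metropolis sampling)."""
    if model.B <= 0:
        raise ValueError("model hypercube half-width must be positive")
    return metropolis_sample(model, n, mcmc_params=mcmc_params, seed=seed)


def _default_inter_cov(dim: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded anisotropic SPD covariance with a gently decaying spectrum."""
    Qmat, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    lam = np.geomspace(1.0, 0.2, dim) * scale**2
    return (Qmat * lam) @ Qmat.T


def _support_frame(basis: ConstraintBasis) -> np.ndarray:
    """Orthonormal basis U (dim x rank) of the data subspace."""
    evals, evecs = np.linalg.eigh(basis.projector)
    return evecs[:, evals > 0.5]


def _match_moments(
    X: np.ndarray, target: np.ndarray, U: np.ndarray
) -> np.ndarray:
    """Affinely map rows of X (on the support) to the sample mean/cov of target.

    The whitening / re-colouring happens in the support frame ``U``, where
    both sample covariances are full rank.  Third cumulants are carried
    along (transformed, not destroyed) by the affine map.
    """

    def sqrt_and_inv(C):
        ev, evec = np.linalg.eigh(C)
        ev = np.clip(ev, 1e-15, None)
        return (evec * np.sqrt(ev)) @ evec.T, (evec / np.sqrt(ev)) @ evec.T

    Y = X @ U
    T = target @ U
    my, mt = Y.mean(axis=0), T.mean(axis=0)
    Cy = np.cov(Y, rowvar=False, ddof=0)
    Ct = np.cov(T, rowvar=False, ddof=0)
    sq_t, _ = sqrt_and_inv(Ct)
    _, inv_sq_y = sqrt_and_inv(Cy)
    Y2 = (Y - my) @ inv_sq_y @ sq_t + mt
    return Y2 @ U.T


def _subject_means(
    spec: SyntheticStudySpec,
    label: str,
    mean: np.ndarray,
    cov: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inter-subject latent preferred faces for one class (full frame)."""
    dim = 2 * spec.n_landmarks
    ev, evec = np.linalg.eigh(cov)
    ev = np.clip(ev, 0, None)
    L = evec * np.sqrt(ev)
    if label == "B" and spec.difference_order == 3:
        # skewed latents: standardised gamma, skewness 2 / sqrt(shape)
        k = spec.gamma_shape
        u = (rng.gamma(k, 1.0, size=(spec.n_subjects_per_class, dim)) - k) / np.sqrt(k)
    else:
        u = rng.standard_normal((spec.n_subjects_per_class, dim))
    return mean + u @ L.T


def make_two_class_study(spec: SyntheticStudySpec) -> LandmarkDataset:
    """Generate a labelled two-class landmark study.

    Class A carries gender label ``F`` and class B label ``M``.  Subject
    latent faces are drawn from the class distribution; each subject's
    repetitions add within-subject Gaussian noise scaled by
    ``intra_to_inter_ratio``; everything is finally mapped through the
    constraint projector and anchored to the mean landmark geometry.
    For ``difference_order = 3`` class B's records are affinely corrected
    post hoc so its first and second sample moments match class A's.
    """
    rng = np.random.default_rng(spec.seed)
    dim = 2 * spec.n_landmarks
    basis = make_constraint_projector(dim, spec.n_constraints, rng)
    P = basis.projector

    if spec.n_landmarks == DEFAULT_LANDMARKS.shape[0]:
        geometry = DEFAULT_LANDMARKS
    else:
        theta = np.linspace(0, 2 * np.pi, spec.n_landmarks, endpoint=False)
        geometry = 0.5 + 0.3 * np.column_stack([np.cos(theta), np.sin(theta)])
    base = np.concatenate([geometry[:, 0], geometry[:, 1]])

    cov_A = _default_inter_cov(dim, spec.fluct_scale, rng)
    mean_A = np.zeros(dim)
    cov_B, mean_B = cov_A, mean_A
    if spec.difference_order == 1:
        direction = P @ rng.standard_normal(dim)
        direction /= np.linalg.norm(direction)
        mean_B = mean_A + spec.mean_shift_scale * spec.fluct_scale * direction
    elif spec.difference_order == 2:
        ev, evec = np.linalg.eigh(cov_A)
        stretch = np.where(
            np.arange(dim) % 2 == 0, spec.cov_stretch, 1.0 / spec.cov_stretch
        )
        cov_B = (evec * (ev * stretch)) @ evec.T
    for label, cp in spec.class_params.items():
        if cp.mean is not None:
            if label == "A":
                mean_A = np.asarray(cp.mean, float)
            else:
                mean_B = np.asarray(cp.mean, float)
        if cp.cov is not None:
            if label == "A":
                cov_A = np.asarray(cp.cov, float)
            else:
                cov_B = np.asarray(cp.cov, float)

    records = {}
    for label, mean, cov, code in (
        ("A", mean_A, cov_A, "F"),
        ("B", mean_B, cov_B, "M"),
    ):
        mus = _subject_means(spec, label, mean, cov, rng)
        noise_cov = spec.intra_to_inter_ratio * cov
        evn, evecn = np.linalg.eigh(noise_cov)
        Ln = evecn * np.sqrt(np.clip(evn, 0, None))
        reps = (
            mus[:, None, :]
            + rng.standard_normal(
                (spec.n_subjects_per_class, spec.reps_per_subject, dim)
            )
            @ Ln.T
        )
        X = reps.reshape(-1, dim) @ P.T
        records[label] = (X, code)

    if spec.difference_order == 3:
        U = _support_frame(basis)
        XB, code = records["B"]
        records["B"] = (_match_moments(XB, records["A"][0], U), code)

    coords, sids, reps_idx, genders = [], [], [], []
    for label in ("A", "B"):
        X, code = records[label]
        for si in range(spec.n_subjects_per_class):
            for ri in range(spec.reps_per_subject):
                coords.append(base + X[si * spec.reps_per_subject + ri])
                sids.append(f"{code}{si + 1:03d}")
                reps_idx.append(ri + 1)
                genders.append(code)

    return LandmarkDataset(
        coords=np.array(coords),
        subject_ids=np.array(sids, dtype=object),
        rep_index=np.array(reps_idx),
        gender=np.array(genders, dtype=object),
        n_landmarks=spec.n_landmarks,
    )
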
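"""Landmark tables, fluctuation vectors, moments, constraints and angle histograms.

The data unit is a *facial vector*: the stacked ``(x, y)`` coordinates of
``n`` facial landmarks, in units of the facial height, annotated with the
identity and gender of the subject who sculpted it and a repetition index.
Coordinates are stored in the order ``(x_1 .. x_n, y_1 .. y_n)``, so
coordinate index ``i`` is the x-component of landmark ``i`` and ``n + i``
its y-component.

Because the landmarks live in a constrained face-space, the ``2n``
coordinates are redundant: a set of exact linear constraints confines the
data to a lower-dimensional subspace.  :func:`find_constraints` detects the
corresponding null modes of the covariance, and
:func:`reduce_and_standardize` maps the data onto a non-redundant,
unit-variance representation suitable for the non-linear models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkDataset",
    "FluctuationData",
    "MomentStatistics",
    "ConstraintBasis",
    "AngleHistogram",
    "FormatError",
    "fluctuations_from_array",
    "read_landmark_table",
    "write_landmark_table",
    "compute_fluctuations",
    "moment_statistics",
    "find_constraints",
    "reduce_and_standardize",
    "angle_histogram",
]

GENDER_CODES = ("F", "M", "NA")

#: relative spectral tolerance below which a covariance eigenvalue is a null mode
DEFAULT_REL_TOL = 1e-10


class FormatError(ValueError):
    """Raised when a landmark table violates the declared CSV dialect."""


@dataclass
class LandmarkDataset:
    """Facial vectors with subject / repetition / gender annotations.

    ``coords`` has shape ``(S, 2n)`` with columns ``x_1..x_n, y_1..y_n``.
    """

    coords: np.ndarray
    subject_ids: np.ndarray
    rep_index: np.ndarray
    gender: np.ndarray
    n_landmarks: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.rep_index = np.asarray(self.rep_index, dtype=int)
        self.gender = np.asarray(self.gender, dtype=object)
        if self.n_landmarks < 2:
            raise ValueError("need at least 2 landmarks")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 * self.n_landmarks:
            raise ValueError(
                f"coords must be (S, {2 * self.n_landmarks}), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate in dataset")
        bad = set(np.unique(self.gender)) - set(GENDER_CODES)
        if bad:
            raise FormatError(f"unknown gender code(s): {sorted(bad)}")
        keys = list(zip(self.subject_ids, self.rep_index))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject_id, rep_index) pair")

    @property
    def n_records(self) -> int:
        return self.coords.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        """Distinct subject ids, in order of first appearance."""
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    def select(self, mask: np.ndarray) -> "LandmarkDataset":
        """Row-subset of the dataset (boolean or index mask)."""
        return LandmarkDataset(
            coords=self.coords[mask],
            subject_ids=self.subject_ids[mask],
            rep_index=self.rep_index[mask],
            gender=self.gender[mask],
            n_landmarks=self.n_landmarks,
        )

    def by_gender(self, code: str) -> "LandmarkDataset":
        return self.select(self.gender == code)

    def mean_geometry(self) -> np.ndarray:
        """Average landmark positions as an ``(n, 2)`` array."""
        m = self.coords.mean(axis=0)
        n = self.n_landmarks
        return np.column_stack([m[:n], m[n:]])


@dataclass
class FluctuationData:
    """Deviations of facial vectors from the population mean.

    ``deltas`` is ``(S, 2n)`` (or ``(S, D)`` after reduction); ``mean`` is
    the full-frame mean that was subtracted.  ``scales`` holds per-column
    standard deviations when the data has been standardised (``None``
    otherwise).  ``retained_indices`` records, for a reduced set, which
    original coordinate each column corresponds to.
    """

    deltas: np.ndarray
    mean: np.ndarray
    subject_ids: np.ndarray
    gender: np.ndarray
    scales: np.ndarray | None = None
    retained_indices: np.ndarray | None = None
    zero_variance_columns: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    @property
    def n_samples(self) -> int:
        return self.deltas.shape[0]

    @property
    def dim(self) -> int:
        return self.deltas.shape[1]

    def to_json(self) -> str:
        payload = {
            "deltas": self.deltas.tolist(),
            "mean": self.mean.tolist(),
            "subject_ids": [str(s) for s in self.subject_ids],
            "gender": [str(g) for g in self.gender],
            "scales": None if self.scales is None else self.scales.tolist(),
            "retained_indices": None
            if self.retained_indices is None
            else self.retained_indices.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FluctuationData":
        d = json.loads(text)
        return cls(
            deltas=np.array(d["deltas"], dtype=float),
            mean=np.array(d["mean"], dtype=float),
            subject_ids=np.array(d["subject_ids"], dtype=object),
            gender=np.array(d["gender"], dtype=object),
            scales=None if d["scales"] is None else np.array(d["scales"]),
            retained_indices=None
            if d["retained_indices"] is None
            else np.array(d["retained_indices"], dtype=int),
        )


def _sym3_indices(dim: int) -> np.ndarray:
    """All index triples (mu <= nu <= kappa) for a symmetric rank-3 tensor."""
    idx = [
        (a, b, c)
        for a in range(dim)
        for b in range(a, dim)
        for c in range(b, dim)
    ]
    return np.array(idx, dtype=int)


def sym3_multiplicity(indices: np.ndarray) -> np.ndarray:
    """Number of distinct permutations of each (mu <= nu <= kappa) triple."""
    a, b, c = indices.T
    mult = np.full(len(indices), 6)
    mult[(a == b) | (b == c)] = 3
    mult[(a == b) & (b == c)] = 1
    return mult


def sym3_to_dense(dim: int, indices: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Expand compactly stored symmetric rank-3 entries to a dense tensor."""
    t = np.zeros((dim, dim, dim))
    for (a, b, c), v in zip(indices, values):
        for p in {(a, b, c), (a, c, b), (b, a, c), (b, c, a), (c, a, b), (c, b, a)}:
            t[p] = v
    return t


@dataclass
class MomentStatistics:
    """Sufficient statistics of a fluctuation set up to third order.

    ``cov`` is the second-moment matrix ``C = <Delta Delta^T>`` of the
    (already centred) fluctuations; ``third`` stores the unique entries
    ``C3_{mnk} = <Delta_m Delta_n Delta_k>`` for ``m <= n <= k`` (``None``
    unless third-order statistics were requested).
    """

    mean: np.ndarray
    cov: np.ndarray
    n_samples: int
    third_indices: np.ndarray | None = None
    third_values: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @property
    def has_third(self) -> bool:
        return self.third_values is not None

    def third_dense(self) -> np.ndarray:
        if not self.has_third:
            raise ValueError("third-order moments were not computed")
        return sym3_to_dense(self.dim, self.third_indices, self.third_values)


@dataclass
class ConstraintBasis:
    """Orthonormal null modes of a covariance and the induced projector.

    ``projector = I - N N^T`` maps onto the data subspace;
    ``retained_indices`` lists the ``D = dim - k`` coordinates kept for the
    non-redundant representation.
    """

    null_vectors: np.ndarray  # (dim, k), orthonormal columns
    retained_indices: np.ndarray
    projector: np.ndarray

    @property
    def dim(self) -> int:
        return self.projector.shape[0]

    @property
    def n_constraints(self) -> int:
        return self.null_vectors.shape[1]

    @property
    def rank(self) -> int:
        return self.dim - self.n_constraints

    def to_json(self) -> str:
        return json.dumps(
            {
                "null_vectors": self.null_vectors.tolist(),
                "retained_indices": self.retained_indices.tolist(),
                "projector": self.projector.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConstraintBasis":
        d = json.loads(text)
        return cls(
            null_vectors=np.array(d["null_vectors"], dtype=float),
            retained_indices=np.array(d["retained_indices"], dtype=int),
            projector=np.array(d["projector"], dtype=float),
        )


@dataclass
class AngleHistogram:
    """Density histogram of landmark fluctuation angles on (-pi, pi]."""

    landmark_index: int
    bin_edges: np.ndarray
    densities: np.ndarray
    n_samples: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        total = float(np.sum(self.densities * widths))
        if self.n_samples > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"histogram does not integrate to 1 (got {total})")


def fluctuations_from_array(X: np.ndarray, center: bool = True) -> FluctuationData:
    """Wrap a plain ``(S, D)`` array as a :class:`FluctuationData`."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    return FluctuationData(
        deltas=X - mean,
        mean=mean,
        subject_ids=np.array([f"r{i}" for i in range(len(X))], dtype=object),
        gender=np.array(["NA"] * len(X), dtype=object),
    )


# ---------------------------------------------------------------------------
# I/O


def _dialect_columns(n_landmarks: int) -> list[str]:
    return (
        ["subject_id", "rep_index", "gender"]
        + [f"x{i}" for i in range(1, n_landmarks + 1)]
        + [f"y{i}" for i in range(1, n_landmarks + 1)]
    )


def read_landmark_table(
    path,
    n_landmarks: int = 8,
    column_map: dict[str, str] | None = None,
    gender_map: dict[str, str] | None = None,
) -> LandmarkDataset:
    """Read a landmark-table CSV into a :class:`LandmarkDataset`.

    The native dialect has header ``subject_id,rep_index,gender,x1..xn,y1..yn``
    with gender codes ``F``/``M``/``NA``.  Files in a different layout are
    adapted through ``column_map`` (source column -> dialect column) and
    ``gender_map`` (source gender code -> ``F``/``M``/``NA``).
    """
    df = pd.read_csv(path, sep=",")
    if column_map:
        df = df.rename(columns=column_map)
    if gender_map and "gender" in df.columns:
        df["gender"] = df["gender"].map(lambda g: gender_map.get(str(g), str(g)))

    expected = _dialect_columns(n_landmarks)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    if len(df.columns) != len(set(df.columns)):
        raise FormatError("duplicate columns in header")

    coord_cols = expected[3:]
    coords = np.empty((len(df), 2 * n_landmarks))
    for j, c in enumerate(coord_cols):
        col = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise FormatError(
                f"non-numeric coordinate in column {c!r}, data row {bad[0]}"
            )
        coords[:, j] = col

    gender = df["gender"].astype(str).str.strip().to_numpy(dtype=object)
    bad_codes = set(gender) - set(GENDER_CODES)
    if bad_codes:
        raise FormatError(
            f"unknown gender code(s) {sorted(bad_codes)} in column 'gender'"
        )

    return LandmarkDataset(
        coords=coords,
        subject_ids=df["subject_id"].astype(str).to_numpy(dtype=object),
        rep_index=pd.to_numeric(df["rep_index"]).to_numpy(dtype=int),
        gender=gender,
        n_landmarks=n_landmarks,
    )


def write_landmark_table(dataset: LandmarkDataset, path) -> None:
    """Write a dataset in the native CSV dialect (12 significant digits)."""
    cols = _dialect_columns(dataset.n_landmarks)
    df = pd.DataFrame(
        {
            "subject_id": dataset.subject_ids,
            "rep_index": dataset.rep_index,
            "gender": dataset.gender,
        }
    )
    for j, c in enumerate(cols[3:]):
        df[c] = dataset.coords[:, j]
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Statistics


def compute_fluctuations(
    dataset: LandmarkDataset, standardize: bool = False
) -> FluctuationData:
    """Centre the facial vectors: ``Delta = r - <r>``.

    With ``standardize=True`` each column is additionally divided by its
    sample standard deviation; zero-variance columns are left unscaled and
    recorded in ``zero_variance_columns``.
    """
    if dataset.n_records < 2:
        raise ValueError("need at least 2 records to define fluctuations")
    mean = dataset.coords.mean(axis=0)
    deltas = dataset.coords - mean
    scales = None
    zero_cols = np.array([], dtype=int)
    if standardize:
        scales = deltas.std(axis=0, ddof=0)
        zero_cols = np.flatnonzero(scales == 0)
        safe = scales.copy()
        safe[zero_cols] = 1.0
        deltas = deltas / safe
        scales = safe
    return FluctuationData(
        deltas=deltas,
        mean=mean,
        subject_ids=dataset.subject_ids.copy(),
        gender=dataset.gender.copy(),
        scales=scales,
        zero_variance_columns=zero_cols,
    )


def moment_statistics(fluct: FluctuationData, max_order: int = 2) -> MomentStatistics:
    """Empirical moments ``<Delta>``, ``C = <Delta Delta^T>`` and, for
    ``max_order=3``, the symmetric third-moment tensor ``<D_m D_n D_k>``."""
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    X = fluct.deltas
    if X.shape[0] == 0:
        raise ValueError("empty fluctuation set")
    S, dim = X.shape
    mean = X.mean(axis=0)
    cov = (X.T @ X) / S
    third_idx = third_val = None
    if max_order == 3:
        third_idx = _sym3_indices(dim)
        a, b, c = third_idx.T
        third_val = np.einsum("sa,sb,sc->abc", X, X, X) / S
        third_val = third_val[a, b, c]
    return MomentStatistics(
        mean=mean,
        cov=cov,
        n_samples=S,
        third_indices=third_idx,
        third_values=third_val,
    )


def find_constraints(
    moments: MomentStatistics, rel_tol: float = DEFAULT_REL_TOL
) -> ConstraintBasis:
    """Detect exact linear constraints as null modes of the covariance.

    Eigenvectors whose eigenvalue is below ``rel_tol`` times the largest
    eigenvalue span the constraint directions.  The retained coordinates
    for the reduced representation are chosen by greedy elimination: while
    the covariance restricted to the remaining coordinates is rank
    deficient, drop the coordinate with the largest total squared loading
    on the current null basis (ties broken by lowest index).
    """
    C = np.asarray(moments.cov, dtype=float)
    C = 0.5 * (C + C.T)
    dim = C.shape[0]
    evals, evecs = np.linalg.eigh(C)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise ValueError("all-zero covariance: degenerate data")
    thresh = rel_tol * lam_max
    null_mask = evals < thresh
    null_vectors = evecs[:, null_mask]
    projector = np.eye(dim) - null_vectors @ null_vectors.T

    retained = list(range(dim))
    while True:
        sub = C[np.ix_(retained, retained)]
        sev, svec = np.linalg.eigh(sub)
        null_sub = svec[:, sev < thresh]
        if null_sub.shape[1] == 0:
            break
        loading = (null_sub**2).sum(axis=1)
        # argmax returns the first (lowest-index) maximiser: deterministic ties
        drop = retained[int(np.argmax(loading))]
        retained.remove(drop)

    return ConstraintBasis(
        null_vectors=null_vectors,
        retained_indices=np.array(retained, dtype=int),
        projector=projector,
    )


def reduce_and_standardize(
    fluct: FluctuationData, basis: ConstraintBasis, rel_tol: float = DEFAULT_REL_TOL
) -> FluctuationData:
    """Map fluctuations to the non-redundant, unit-variance representation.

    Keeps the coordinates in ``basis.retained_indices``, re-centres and
    scales each to unit variance.  The output's ``retained_indices`` and
    ``scales`` record the mapping back to the full frame.
    """
    if fluct.dim != basis.dim:
        raise ValueError("basis dimensionality does not match fluctuations")
    idx = basis.retained_indices
    X = fluct.deltas[:, idx]
    X = X - X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    if np.any(scales == 0):
        raise ValueError("retained coordinate with zero variance: basis error")
    X = X / scales
    red_cov = (X.T @ X) / X.shape[0]
    sev = np.linalg.eigvalsh(red_cov)
    if sev[0] < rel_tol * sev[-1]:
        raise ValueError("reduced covariance still singular: basis error")
    return FluctuationData(
        deltas=X,
        mean=fluct.mean,
        subject_ids=fluct.subject_ids.copy(),
        gender=fluct.gender.copy(),
        scales=scales,
        retained_indices=idx.copy(),
    )


def embedding_matrix(basis: ConstraintBasis) -> np.ndarray:
    """Matrix ``B`` mapping retained (unscaled) coordinates to the full frame.

    For any vector on the data subspace, the full ``2n`` coordinates are a
    fixed linear function of the retained subset: ``Delta = B Delta[idx]``,
    with ``B = P E^T (E P E^T)^{-1}`` where ``P`` is the subspace projector
    and ``E`` selects the retained rows.
    """
    P = basis.projector
    idx = basis.retained_indices
    G = P[np.ix_(idx, idx)]  # E P E^T
    return P[:, idx] @ np.linalg.inv(G)


def angle_histogram(
    fluct: FluctuationData,
    landmark_index: int,
    n_bins: int = 24,
    y_axis: str = "down",
) -> AngleHistogram:
    """Histogram of the angles of one landmark's fluctuation vectors.

    The angle is the quadrant-aware arctangent of ``(Delta_y, Delta_x)``,
    on ``(-pi, pi]``.  Records with an exactly zero fluctuation for this
    landmark are excluded (and counted).  ``y_axis`` flips the sign of the
    y-component for display orientation only ("down" is the image
    convention in which the raw coordinates are given).
    """
    if fluct.retained_indices is not None:
        raise ValueError("angle histograms require full-frame fluctuations")
    n = fluct.dim // 2
    if not 0 <= landmark_index < n:
        raise ValueError(f"landmark_index out of range [0, {n})")
    dx = fluct.deltas[:, landmark_index]
    dy = fluct.deltas[:, n + landmark_index]
    if y_axis == "up":
        dy = -dy
    elif y_axis != "down":
        raise ValueError("y_axis must be 'up' or 'down'")
    nonzero = (dx != 0) | (dy != 0)
    n_excluded = int((~nonzero).sum())
    if not np.any(nonzero):
        raise ValueError("all fluctuations are zero for this landmark")
    phi = np.arctan2(dy[nonzero], dx[nonzero])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, edges = np.histogram(phi, bins=edges)
    widths = np.diff(edges)
    dens = counts / (counts.sum() * widths)
    return AngleHistogram(
        landmark_index=landmark_index,
        bin_edges=edges,
        densities=dens,
        n_samples=int(nonzero.sum()),
        n_excluded=n_excluded,
    )
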
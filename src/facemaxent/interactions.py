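"""Longitudinal / torsion decomposition of pairwise couplings.

The 2x2 cross-block of the effective-interaction matrix ``J`` (or the raw
correlation matrix ``C``) between landmarks ``i`` and ``j`` is projected
onto the direction of the mean inter-landmark segment and its normal:

    J_par  = u' M_ij u,   J_perp = v' M_ij v

with ``u = (cos a_ij, sin a_ij)`` the segment's unit vector (``a_ij`` the
quadrant-aware angle of ``<r_j> - <r_i>``) and ``v`` its perpendicular.
Read as elastic constants, ``|J_par|`` resists changes of the segment's
length and ``|J_perp|`` changes of its angle.  Uncertainties come from a
subject-level bootstrap; entries with ``t = |value| / sigma`` above a
threshold (1 by default) are reported as significant.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .dataset_io import LandmarkDataset

__all__ = [
    "longitudinal_torsion_table",
    "bootstrap_errors",
    "attach_bootstrap",
    "significant_segments",
    "segment_pairs",
]


def segment_pairs(n_landmarks: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_landmarks) for j in range(i + 1, n_landmarks)]


def _cross_block(matrix: np.ndarray, i: int, j: int, n: int) -> np.ndarray:
    """2x2 block of a (2n x 2n) matrix between landmarks i and j
    (coordinate layout x_1..x_n, y_1..y_n)."""
    return np.array(
        [
            [matrix[i, j], matrix[i, n + j]],
            [matrix[n + i, j], matrix[n + i, n + j]],
        ]
    )


def longitudinal_torsion_table(
    matrix: np.ndarray,
    mean_geometry: np.ndarray,
    value_name: str = "J",
) -> pd.DataFrame:
    """Per-pair longitudinal and torsion components of a coupling matrix.

    ``matrix`` is ``2n x 2n`` in the full coordinate frame; ``mean_geometry``
    the ``(n, 2)`` mean landmark positions.  Returns one row per unordered
    pair with columns ``i, j, r_mean_x, r_mean_y, r_len, alpha,
    <name>_par, <name>_perp``.
    """
    geom = np.asarray(mean_geometry, dtype=float)
    n = geom.shape[0]
    if matrix.shape != (2 * n, 2 * n):
        raise ValueError(f"matrix must be {2 * n}x{2 * n} for {n} landmarks")
    rows = []
    for i, j in segment_pairs(n):
        seg = geom[j] - geom[i]
        r_len = float(np.linalg.norm(seg))
        if r_len == 0:
            raise ValueError(f"coincident mean landmarks {i}, {j}: angle undefined")
        alpha = float(np.arctan2(seg[1], seg[0]))
        u = np.array([np.cos(alpha), np.sin(alpha)])
        v = np.array([-np.sin(alpha), np.cos(alpha)])
        M = _cross_block(matrix, i, j, n)
        rows.append(
            {
                "i": i,
                "j": j,
                "r_mean_x": seg[0],
                "r_mean_y": seg[1],
                "r_len": r_len,
                "alpha": alpha,
                f"{value_name}_par": float(u @ M @ u),
                f"{value_name}_perp": float(v @ M @ v),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_errors(
    dataset: LandmarkDataset,
    estimator: Callable[[LandmarkDataset], pd.DataFrame],
    n_boot: int = 100,
    resample_unit: str = "subject",
    seed: int | np.random.Generator = 0,
    max_failure_fraction: float = 0.1,
) -> pd.DataFrame:
    """Bootstrap standard errors of a per-pair estimator.

    ``estimator`` maps a dataset to a table with an ``(i, j)`` index pair
    and numeric value columns; the whole pipeline (fluctuations, fit,
    decomposition) is re-run on each resample.  Subjects are resampled
    with replacement by default because vectors within a subject are
    dependent; ``resample_unit='vector'`` resamples records instead.
    Returns a table with one ``<col>_sigma`` per value column.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for stable sigma estimates")
    if resample_unit not in ("subject", "vector"):
        raise ValueError("resample_unit must be 'subject' or 'vector'")
    rng = np.random.default_rng(seed)
    replicas = []
    failures = 0
    for _ in range(n_boot):
        if resample_unit == "subject":
            subjects = dataset.subjects
            pick = rng.choice(len(subjects), size=len(subjects), replace=True)
            parts = []
            for new_id, si in enumerate(pick):
                sub = dataset.select(dataset.subject_ids == subjects[si])
                # re-key so (subject_id, rep_index) stays unique after replacement
                sub = LandmarkDataset(
                    coords=sub.coords,
                    subject_ids=np.array(
                        [f"b{new_id}"] * sub.n_records, dtype=object
                    ),
                    rep_index=np.arange(1, sub.n_records + 1),
                    gender=sub.gender,
                    n_landmarks=sub.n_landmarks,
                )
                parts.append(sub)
            resampled = LandmarkDataset(
                coords=np.vstack([p.coords for p in parts]),
                subject_ids=np.concatenate([p.subject_ids for p in parts]),
                rep_index=np.concatenate(
                    [p.rep_index + 1000 * k for k, p in enumerate(parts)]
                ),
                gender=np.concatenate([p.gender for p in parts]),
                n_landmarks=dataset.n_landmarks,
            )
        else:
            pick = rng.choice(dataset.n_records, size=dataset.n_records, replace=True)
            resampled = LandmarkDataset(
                coords=dataset.coords[pick],
                subject_ids=np.array(
                    [f"b{k}" for k in range(len(pick))], dtype=object
                ),
                rep_index=np.ones(len(pick), dtype=int),
                gender=dataset.gender[pick],
                n_landmarks=dataset.n_landmarks,
            )
        try:
            replicas.append(estimator(resampled))
        except Exception:
            failures += 1
            if failures > max_failure_fraction * n_boot:
                raise RuntimeError(
                    f"estimator failed on {failures}/{n_boot} bootstrap replicas"
                )
    value_cols = [
        c
        for c in replicas[0].columns
        if c not in ("i", "j") and np.issubdtype(replicas[0][c].dtype, np.number)
    ]
    stacked = {c: np.stack([r[c].to_numpy() for r in replicas]) for c in value_cols}
    out = replicas[0][["i", "j"]].copy()
    for c in value_cols:
        out[f"{c}_sigma"] = stacked[c].std(axis=0, ddof=1)
    return out


def attach_bootstrap(
    table: pd.DataFrame, sigma_table: pd.DataFrame, value_cols: list[str]
) -> pd.DataFrame:
    """Merge point estimates with bootstrap sigmas and compute t-values."""
    merged = table.merge(sigma_table, on=["i", "j"], how="left")
    for c in value_cols:
        sig = merged[f"{c}_sigma"].to_numpy()
        val = merged[c].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(val) / sig
        t[(sig == 0) & (val != 0)] = np.inf
        t[(sig == 0) & (val == 0)] = 0.0
        merged[f"{c}_t"] = t
        merged[f"{c}_sigma_zero"] = sig == 0
    return merged


def significant_segments(
    table: pd.DataFrame, value_col: str = "J_par", t_threshold: float = 1.0
) -> pd.DataFrame:
    """Rows whose ``|value| / sigma`` exceeds the threshold, by t descending."""
    tcol = f"{value_col}_t"
    if tcol not in table.columns:
        raise ValueError(f"table has no column {tcol}; attach bootstrap errors first")
    keep = table[table[tcol] > t_threshold].copy()
    keep["significant"] = True
    return keep.sort_values(tcol, ascending=False).reset_index(drop=True)
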
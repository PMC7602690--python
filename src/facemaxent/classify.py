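"""Generative likelihood-ratio gender classification and baselines.

The protocol: split each class (the sets of vectors sculpted by female /
male subjects) into training and test parts, fit a generative model to
each class's training vectors, and score every test vector with the
log-likelihood ratio

    s(Delta) = ln L(Delta | theta_A) - ln L(Delta | theta_B).

Sweeping a threshold over ``s`` yields a ROC curve; we report the area
under it and the maximal accuracy over thresholds.  Preprocessing (the
constraint basis and the standardisation) is fitted on the pooled
training data and applied frozen everywhere, so scores reflect
distributional differences only.  Discriminative baselines: a random
forest and a principal-component t-test score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .dataset_io import (
    LandmarkDataset,
    compute_fluctuations,
    find_constraints,
    moment_statistics,
    reduce_and_standardize,
)
from .grbm import GrbmTrainParams, estimate_log_z_ais, train_grbm
from .maxent2 import fit_gaussian_maxent, fit_independent_maxent
from .maxent3 import LearnParams, estimate_log_z3, fit_cubic_maxent

__all__ = [
    "SplitSpec",
    "ROCResult",
    "Preprocessor",
    "split_train_test",
    "likelihood_ratio_scores",
    "roc_analysis",
    "pc_ttest_scores",
    "rf_scores",
    "run_gender_pipeline",
    "PipelineConfig",
]

METHODS = ("1-MaxEnt", "2-MaxEnt", "3-MaxEnt", "GRBM", "RF", "PC-ttest")


@dataclass
class SplitSpec:
    """Train/test split design: fraction assigned to training, the unit
    kept together ('vector' or 'subject'), and the seed."""

    train_fraction: float = 0.2
    unit: str = "vector"
    seed: int = 0
    stratify_by_class: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.unit not in ("vector", "subject"):
            raise ValueError("unit must be 'vector' or 'subject'")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    max_accuracy: float
    max_accuracy_threshold: float
    scores: np.ndarray
    labels: np.ndarray


def _split_one(
    ds: LandmarkDataset, spec: SplitSpec, rng: np.random.Generator
) -> tuple[LandmarkDataset, LandmarkDataset]:
    if spec.unit == "vector":
        S = ds.n_records
        n_train = int(round(spec.train_fraction * S))
        if not 0 < n_train < S:
            raise ValueError("class too small to split at this fraction")
        perm = rng.permutation(S)
        return ds.select(perm[:n_train]), ds.select(perm[n_train:])
    subjects = ds.subjects
    n_train = int(round(spec.train_fraction * len(subjects)))
    if not 0 < n_train < len(subjects):
        raise ValueError("class has too few subjects to split at this fraction")
    perm = rng.permutation(len(subjects))
    train_subj = set(subjects[perm[:n_train]])
    mask = np.array([s in train_subj for s in ds.subject_ids])
    return ds.select(mask), ds.select(~mask)


def split_train_test(
    dataset: LandmarkDataset,
    spec: SplitSpec,
    class_labels: tuple[str, str] = ("F", "M"),
) -> tuple[LandmarkDataset, LandmarkDataset, LandmarkDataset, LandmarkDataset]:
    """Per-class train/test split; subject mode keeps a subject's vectors
    together. Returns (train_A, test_A, train_B, test_B)."""
    rng = np.random.default_rng(spec.seed)
    ds_A = dataset.by_gender(class_labels[0])
    ds_B = dataset.by_gender(class_labels[1])
    if ds_A.n_records == 0 or ds_B.n_records == 0:
        raise ValueError("both classes must be non-empty")
    train_A, test_A = _split_one(ds_A, spec, rng)
    train_B, test_B = _split_one(ds_B, spec, rng)
    return train_A, test_A, train_B, test_B


class Preprocessor:
    """Frozen pooled-training preprocessing: centre on the pooled mean,
    drop redundant coordinates, standardise the retained ones."""

    def __init__(self, rel_tol: float = 1e-10):
        self.rel_tol = rel_tol

    def fit(self, train: LandmarkDataset) -> "Preprocessor":
        fluct = compute_fluctuations(train)
        moments = moment_statistics(fluct, max_order=2)
        self.basis = find_constraints(moments, rel_tol=self.rel_tol)
        reduced = reduce_and_standardize(fluct, self.basis, rel_tol=self.rel_tol)
        self.mean_full = fluct.mean
        self.retained = reduced.retained_indices
        self.scales = reduced.scales
        return self

    def transform(self, ds: LandmarkDataset) -> np.ndarray:
        X = (ds.coords - self.mean_full)[:, self.retained]
        return X / self.scales


def likelihood_ratio_scores(model_A, model_B, test_vectors: np.ndarray) -> np.ndarray:
    """Per-vector generative score ``s = ln L_A - ln L_B`` (higher = A-like).

    Both models must expose ``log_density`` on the same reduced frame.
    """
    X = np.atleast_2d(np.asarray(test_vectors, dtype=float))
    dim_a = getattr(model_A, "dim", X.shape[1])
    dim_b = getattr(model_B, "dim", X.shape[1])
    if dim_a != X.shape[1] or dim_b != X.shape[1]:
        raise ValueError(
            f"frame mismatch: models expect dims {dim_a}/{dim_b}, "
            f"vectors have {X.shape[1]}"
        )
    return np.asarray(model_A.log_density(X)) - np.asarray(model_B.log_density(X))


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve, trapezoidal auROC and maximal accuracy over thresholds.

    ``labels`` is boolean (True = class A, the positive class).  Tied
    scores share one threshold, so the curve steps diagonally through
    ties; maximal accuracy uses the empirical class proportions.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("need both classes in the test labels")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    P = int(labels.sum())
    N = int((~labels).sum())
    acc = (tpr * P + (1 - fpr) * N) / (P + N)
    best = int(np.argmax(acc))
    return ROCResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auroc=auroc,
        max_accuracy=float(acc[best]),
        max_accuracy_threshold=float(thr[best]),
        scores=scores,
        labels=labels,
    )


def pc_ttest_scores(
    train_A: np.ndarray, train_B: np.ndarray, test_vectors: np.ndarray
) -> np.ndarray:
    """Principal-component t-test score.

    Principal axes are estimated from the pooled training data; each axis
    gets a Welch t-statistic comparing the A and B training projections;
    a test vector's score is the t-weighted sum of its standardised
    projections.  Test vectors play no role in estimating the axes.
    """
    A = np.atleast_2d(train_A)
    B = np.atleast_2d(train_B)
    pooled = np.vstack([A, B])
    if pooled.shape[0] <= pooled.shape[1]:
        raise ValueError("too few training vectors for a stable PCA")
    centre = pooled.mean(axis=0)
    cov = np.cov(pooled - centre, rowvar=False, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("degenerate PCA: zero total variance")
    keep = evals > 1e-12 * evals[0]
    axes = evecs[:, keep]

    proj_A = (A - centre) @ axes
    proj_B = (B - centre) @ axes
    t_stats = stats.ttest_ind(proj_A, proj_B, axis=0, equal_var=False).statistic
    pooled_proj = (pooled - centre) @ axes
    sd = pooled_proj.std(axis=0, ddof=0)
    z = ((np.atleast_2d(test_vectors) - centre) @ axes) / sd
    return z @ t_stats


def rf_scores(
    train_X: np.ndarray,
    train_is_A: np.ndarray,
    test_X: np.ndarray,
    n_estimators: int = 500,
    seed: int = 0,
    **rf_params,
) -> np.ndarray:
    """Random-forest baseline: score = predicted probability of class A."""
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, **rf_params
    )
    clf.fit(train_X, np.asarray(train_is_A, dtype=int))
    proba = clf.predict_proba(test_X)
    col = list(clf.classes_).index(1)
    return proba[:, col]


@dataclass
class PipelineConfig:
    """Settings for the full six-method comparison."""

    split: SplitSpec = field(default_factory=SplitSpec)
    class_labels: tuple[str, str] = ("F", "M")
    methods: tuple[str, ...] = METHODS
    n_hidden: int = 20
    grbm_params: GrbmTrainParams = field(default_factory=GrbmTrainParams)
    maxent3_params: LearnParams = field(default_factory=LearnParams)
    ais_runs: int = 100
    ais_temperatures: int = 1000
    log_z3_samples: int = 50_000
    rf_trees: int = 500
    seed: int = 0


def _fit_class_models(Z, cfg, rng, methods):
    """Per-class generative fits on standardised reduced vectors."""
    models = {}
    # moments about the pooled-frame origin: the class mean is part of the
    # sufficient statistics (it is what the order-1 model discriminates on)
    moments2 = moment_statistics(
        _as_fluct(Z, center=False), max_order=3 if "3-MaxEnt" in methods else 2
    )
    if "1-MaxEnt" in methods:
        models["1-MaxEnt"] = fit_independent_maxent(moments2)
    if "2-MaxEnt" in methods or "3-MaxEnt" in methods:
        gauss = fit_gaussian_maxent(moments2)
        models["2-MaxEnt"] = gauss
    if "3-MaxEnt" in methods:
        cubic = fit_cubic_maxent(
            moments2,
            init=models["2-MaxEnt"],
            learn_params=cfg.maxent3_params,
            seed=int(rng.integers(2**31)),
        )
        try:
            estimate_log_z3(
                cubic, n_samples=cfg.log_z3_samples, seed=int(rng.integers(2**31))
            )
        except RuntimeError:
            # likelihood-ratio ROCs are invariant to the per-class constant
            # log Z3, so a Gaussian-part surrogate keeps scoring usable when
            # the annealed estimate is unreliable (strongly non-Gaussian fit)
            evals = np.linalg.eigvalsh(cubic.J)
            cubic.log_z3 = float(
                0.5 * cubic.dim * np.log(2 * np.pi) - 0.5 * np.sum(np.log(evals))
            )
            cubic.log_z3_stderr = float("inf")
        models["3-MaxEnt"] = cubic
    if "GRBM" in methods:
        m = train_grbm(
            Z,
            n_hidden=cfg.n_hidden,
            train_params=cfg.grbm_params,
            seed=int(rng.integers(2**31)),
        )
        estimate_log_z_ais(
            m,
            n_runs=cfg.ais_runs,
            n_temperatures=cfg.ais_temperatures,
            seed=int(rng.integers(2**31)),
        )
        models["GRBM"] = m
    return models


def _as_fluct(Z: np.ndarray, center: bool = True):
    from .dataset_io import fluctuations_from_array

    return fluctuations_from_array(Z, center=center)


def run_gender_pipeline(
    dataset: LandmarkDataset, config: PipelineConfig | None = None
) -> dict:
    """Full comparison: split, per-class generative fits, scores, ROC.

    Returns a report dict with, per method, the auROC, maximal accuracy
    and (for diagnostics) the ROC arrays; failing methods are isolated
    and reported under ``errors``.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    train_A, test_A, train_B, test_B = split_train_test(
        dataset, cfg.split, cfg.class_labels
    )

    pooled_train = LandmarkDataset(
        coords=np.vstack([train_A.coords, train_B.coords]),
        subject_ids=np.concatenate([train_A.subject_ids, train_B.subject_ids]),
        rep_index=np.concatenate(
            [train_A.rep_index, 10_000 + train_B.rep_index]
        ),
        gender=np.concatenate([train_A.gender, train_B.gender]),
        n_landmarks=dataset.n_landmarks,
    )
    prep = Preprocessor().fit(pooled_train)
    Z_train_A = prep.transform(train_A)
    Z_train_B = prep.transform(train_B)
    Z_test = np.vstack([prep.transform(test_A), prep.transform(test_B)])
    labels = np.concatenate(
        [np.ones(test_A.n_records, bool), np.zeros(test_B.n_records, bool)]
    )

    generative = [m for m in cfg.methods if m in ("1-MaxEnt", "2-MaxEnt", "3-MaxEnt", "GRBM")]
    report = {
        "n_train": int(len(Z_train_A) + len(Z_train_B)),
        "n_test": int(len(Z_test)),
        "reduced_dim": int(Z_test.shape[1]),
        "split": {"fraction": cfg.split.train_fraction, "unit": cfg.split.unit},
        "seed": cfg.seed,
        "methods": {},
        "errors": {},
    }

    models_A = models_B = {}
    if generative:
        try:
            models_A = _fit_class_models(Z_train_A, cfg, rng, generative)
            models_B = _fit_class_models(Z_train_B, cfg, rng, generative)
        except Exception as exc:  # pragma: no cover - isolation path
            report["errors"]["generative-fits"] = repr(exc)

    roc_curves = {}
    for method in cfg.methods:
        try:
            if method in ("1-MaxEnt", "2-MaxEnt", "3-MaxEnt", "GRBM"):
                scores = likelihood_ratio_scores(
                    models_A[method], models_B[method], Z_test
                )
            elif method == "RF":
                scores = rf_scores(
                    np.vstack([Z_train_A, Z_train_B]),
                    np.concatenate(
                        [np.ones(len(Z_train_A), bool), np.zeros(len(Z_train_B), bool)]
                    ),
                    Z_test,
                    n_estimators=cfg.rf_trees,
                    seed=int(rng.integers(2**31)),
                )
            elif method == "PC-ttest":
                scores = pc_ttest_scores(Z_train_A, Z_train_B, Z_test)
            else:
                raise ValueError(f"unknown method {method!r}")
            roc = roc_analysis(scores, labels)
            roc_curves[method] = roc
            report["methods"][method] = {
                "auroc": roc.auroc,
                "max_accuracy": roc.max_accuracy,
            }
        except Exception as exc:
            report["errors"][method] = repr(exc)
    report["roc_curves"] = roc_curves
    return report
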
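"""Kernel SVM training and repeated twofold cross-validated evaluation.

Evaluates soft-margin kernel SVMs (linear/quadratic/cubic polynomial and
fine/medium/coarse Gaussian) with stratified random half/half splits repeated
over iterations, pooling the swapped halves' predictions per iteration and
reporting mean +- SD of sensitivity, specificity, accuracy (%) and AUC.
Includes the kernel-comparison and wavelength-range experiment drivers.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.svm import SVC

from .errors import ConfigError, NumericalError
from .preprocess import FeatureScaler, SpectraDataset, subset_wavelengths

__all__ = [
    "SVMConfig",
    "SVMModel",
    "Metrics",
    "CVResult",
    "PAPER_KERNELS",
    "TABLE4_RANGES",
    "kernel_value",
    "train_svm",
    "auto_kernel_scale",
    "compute_metrics",
    "evaluate_cv",
    "kernel_comparison",
    "wavelength_range_experiment",
    "results_table",
    "config_by_name",
]

_POLY_ORDER = {"linear": 1, "poly2": 2, "poly3": 3}


@dataclass(frozen=True)
class SVMConfig:
    """Kernel specification: type, order/width, penalty and kernel scale.

    Polynomial kernels compute (x1.x2 / s^2 + 1)^p where s is the kernel
    scale (``"auto"`` -> median pairwise distance heuristic, resolved per
    training set).  Gaussian kernels compute exp(-||x1 - x2||^2 / (2 sigma^2)).
    """

    kernel: str  # linear | poly2 | poly3 | gaussian
    C: float = 1.0
    gaussian_sigma: float | None = None
    kernel_scale: float | str = "auto"
    name: str = ""

    def __post_init__(self):
        if self.kernel not in (*_POLY_ORDER, "gaussian"):
            raise ConfigError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ConfigError("penalty strength C must be > 0")
        if self.kernel == "gaussian":
            if self.gaussian_sigma is None or self.gaussian_sigma <= 0:
                raise ConfigError("gaussian kernel requires sigma > 0")
        elif isinstance(self.kernel_scale, str):
            if self.kernel_scale != "auto":
                raise ConfigError("kernel_scale must be positive or 'auto'")
        elif self.kernel_scale <= 0:
            raise ConfigError("kernel_scale must be positive or 'auto'")
        if not self.name:
            object.__setattr__(self, "name", self.kernel)

    @property
    def poly_order(self) -> int | None:
        return _POLY_ORDER.get(self.kernel)


PAPER_KERNELS = (
    SVMConfig("linear", name="Linear"),
    SVMConfig("poly2", name="Quadratic"),
    SVMConfig("poly3", name="Cubic"),
    SVMConfig("gaussian", gaussian_sigma=0.5, name="Fine Gaussian"),
    SVMConfig("gaussian", gaussian_sigma=2.0, name="Medium Gaussian"),
    SVMConfig("gaussian", gaussian_sigma=8.0, name="Coarse Gaussian"),
)

QUADRATIC = PAPER_KERNELS[1]


def config_by_name(name: str) -> SVMConfig:
    key = name.strip().lower().replace("_", " ").replace("-", " ")
    for cfg in PAPER_KERNELS:
        if cfg.name.lower() == key:
            return cfg
    raise ConfigError(f"unknown kernel name {name!r}; expected one of "
                      f"{[c.name for c in PAPER_KERNELS]}")


#: wavelength-range experiment specifications (intervals in nm, scalars are
#: discrete wavelengths mapped to the nearest grid column)
TABLE4_RANGES: dict[str, list] = {
    "From 350 to 760 nm": [(350, 760)],
    "From 350 to 800 nm": [(350, 800)],
    "From 400 to 440 nm and from 540 to 580 nm": [(400, 440), (540, 580)],
    "From 400 to 1000 nm": [(400, 1000)],
    "From 405 to 665 nm": [(405, 665)],
    "From 405 to 750 nm": [(405, 750)],
    "From 470 to 700 nm": [(470, 700)],
    "From 415 to 425, 495 to 505, 525 to 545 nm plus 465 and 625 nm":
        [(415, 425), (495, 505), (525, 545), 465.0, 625.0],
    "Eleven discrete bands between 405 and 1001 nm":
        [405.235, 406.42, 408.794, 414.736, 422.48, 468.76, 559.489,
         577.506, 594.342, 957.948, 1000.31],
    "From 900 to 1300 nm": [(900, 1300)],
    "From 1000 to 1919 nm": [(1000, 1919)],
    "From 350 to 1919 nm": [(350, 1919)],
}


def _resolve_scale(config: SVMConfig, X: np.ndarray, seed: int | None) -> float:
    if config.kernel == "gaussian":
        return float(config.gaussian_sigma)
    if config.kernel_scale == "auto":
        return auto_kernel_scale(X, seed=0 if seed is None else seed)
    return float(config.kernel_scale)


def kernel_value(x1, x2, config: SVMConfig, kernel_scale: float | None = None) -> float:
    """Evaluate the kernel function for two feature vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise NumericalError("kernel arguments must have equal length")
    if config.kernel == "gaussian":
        sigma = float(config.gaussian_sigma)
        return float(np.exp(-np.sum((x1 - x2) ** 2) / (2.0 * sigma ** 2)))
    s = kernel_scale
    if s is None:
        if config.kernel_scale == "auto":
            raise ConfigError("kernel scale 'auto' must be resolved before "
                              "evaluating the kernel")
        s = float(config.kernel_scale)
    return float((np.dot(x1 / s, x2 / s) + 1.0) ** config.poly_order)


def auto_kernel_scale(X: np.ndarray, seed: int = 0, max_rows: int = 1000) -> float:
    """Median pairwise Euclidean distance over a seeded subsample of <= max_rows.

    Stand-in for the undocumented MATLAB subsampling heuristic; falls back to 1
    when all rows are identical.  Uses the full population when n <= max_rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        return 1.0
    if n > max_rows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=max_rows, replace=False)
        X = X[idx]
    d = pdist(X)
    s = float(np.median(d))
    return s if s > 0 else 1.0


@dataclass
class SVMModel:
    """Fitted soft-margin kernel SVM (libsvm-backed) plus its configuration."""

    svc: SVC
    config: SVMConfig
    kernel_scale: float

    @property
    def dual_coef(self) -> np.ndarray:
        """Signed dual coefficients y_i * alpha_i of the support vectors."""
        return self.svc.dual_coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.svc.intercept_[0])

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(np.atleast_2d(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(np.atleast_2d(X)).astype(int)


def train_svm(X: np.ndarray, y: np.ndarray, config: SVMConfig,
              kernel_scale: float | None = None, seed: int = 0,
              tol: float = 1e-6) -> SVMModel:
    """Train a soft-margin kernel SVM; prediction = sign(sum y_i a_i K + w0)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise NumericalError("training data contains a single class")
    if kernel_scale is None:
        kernel_scale = _resolve_scale(config, X, seed)
    if config.kernel == "gaussian":
        svc = SVC(C=config.C, kernel="rbf",
                  gamma=1.0 / (2.0 * config.gaussian_sigma ** 2), tol=tol)
    else:
        svc = SVC(C=config.C, kernel="poly", degree=config.poly_order,
                  gamma=1.0 / kernel_scale ** 2, coef0=1.0, tol=tol)
    svc.fit(X, y)
    return SVMModel(svc=svc, config=config, kernel_scale=float(kernel_scale))


@dataclass
class Metrics:
    """Classification metrics: percentages plus AUC; tumor (+1) is positive."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    flags: tuple = ()


def compute_metrics(y_true, y_pred, scores) -> Metrics:
    """Sensitivity/specificity/accuracy (x100) and concordance AUC.

    AUC is the probability a random positive outscores a random negative with
    ties counted 1/2 (equivalent to the trapezoidal ROC area).  Metrics whose
    class is absent are NaN and flagged.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    neg = y_true == -1
    flags = []
    tp = int(np.sum(pos & (y_pred == 1)))
    tn = int(np.sum(neg & (y_pred == -1)))
    if pos.any():
        sens = 100.0 * tp / pos.sum()
    else:
        sens = np.nan
        flags.append("no positive samples")
    if neg.any():
        spec = 100.0 * tn / neg.sum()
    else:
        spec = np.nan
        flags.append("no negative samples")
    acc = 100.0 * (tp + tn) / y_true.size
    if pos.any() and neg.any():
        # Mann-Whitney form with midranks: numerator is an exact sum of
        # halves, so this equals all-pairs concordance counting bitwise
        ranks = rankdata(scores, method="average")
        n_pos = int(pos.sum())
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        auc = float(u / (n_pos * int(neg.sum())))
    else:
        auc = np.nan
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc, auc=auc,
                   flags=tuple(flags))


@dataclass
class CVResult:
    """Per-iteration metrics with mean +- SD, plus the audit trail."""

    name: str
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    auc: np.ndarray
    seed: int
    fold_assignments: list = field(default_factory=list)
    kernel_scales: list = field(default_factory=list)

    def _ms(self, a: np.ndarray) -> tuple[float, float]:
        return float(np.mean(a)), float(np.std(a, ddof=1) if a.size > 1 else 0.0)

    @property
    def mean_sensitivity(self): return self._ms(self.sensitivity)[0]
    @property
    def sd_sensitivity(self): return self._ms(self.sensitivity)[1]
    @property
    def mean_specificity(self): return self._ms(self.specificity)[0]
    @property
    def sd_specificity(self): return self._ms(self.specificity)[1]
    @property
    def mean_accuracy(self): return self._ms(self.accuracy)[0]
    @property
    def sd_accuracy(self): return self._ms(self.accuracy)[1]
    @property
    def mean_auc(self): return self._ms(self.auc)[0]
    @property
    def sd_auc(self): return self._ms(self.auc)[1]

    def summary_row(self) -> dict:
        return {
            "name": self.name,
            "sensitivity": f"{self.mean_sensitivity:.1f}±{self.sd_sensitivity:.1f}",
            "specificity": f"{self.mean_specificity:.1f}±{self.sd_specificity:.1f}",
            "accuracy": f"{self.mean_accuracy:.1f}±{self.sd_accuracy:.1f}",
            "auc": f"{self.mean_auc:.3f}±{self.sd_auc:.3f}",
        }


def fold_assignment(ids: np.ndarray, y: np.ndarray, n_folds: int, seed: int,
                    iteration: int, stratified: bool = True) -> np.ndarray:
    """Random fold labels keyed to stable sample ids.

    Each class group is permuted by an RNG seeded from (seed, iteration, a
    checksum of the group's member ids) and dealt round-robin into folds.
    Keying the RNG to the member ids makes the assignment invariant to row
    order and symmetric under label swaps.
    """
    n = ids.shape[0]
    assign = np.empty(n, dtype=int)
    if stratified:
        groups = [np.nonzero(y == cls)[0] for cls in np.unique(y)]
    else:
        groups = [np.arange(n)]
    for members in groups:
        members = members[np.argsort(ids[members], kind="stable")]
        key = zlib.crc32(np.ascontiguousarray(ids[members]).tobytes())
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed), int(iteration), int(key)]))
        perm = rng.permutation(members.shape[0])
        assign[members[perm]] = np.arange(members.shape[0]) % n_folds
    return assign


def evaluate_cv(dataset: SpectraDataset, config: SVMConfig,
                n_iterations: int = 10, n_folds: int = 2, seed: int = 0,
                stratified: bool = True, scale_mode: str = "per_fold",
                tol: float = 1e-6) -> CVResult:
    """Repeated k-fold cross-validation with pooled per-iteration metrics.

    Per iteration: one random stratified split into ``n_folds`` equal parts;
    each part serves as the test set once while the rest trains (for two folds
    this is the classic train/test swap); feature scaling is refit on each
    training part (``scale_mode="full"`` fits once on the whole dataset,
    leaking, for comparison); both test parts' predictions are pooled and the
    metrics computed once per iteration.  Reports mean +- SD over iterations.
    """
    if scale_mode not in ("per_fold", "full"):
        raise ConfigError(f"unknown scale_mode {scale_mode!r}")
    classes, counts = np.unique(dataset.y, return_counts=True)
    if len(classes) < 2:
        raise NumericalError("cross-validation requires both classes")
    if np.any(counts < n_folds):
        raise NumericalError("each class needs at least n_folds members")
    # id-sorted view: makes every downstream computation row-order invariant
    order = np.argsort(dataset.ids, kind="stable")
    ds = dataset.select_rows(order)
    n = ds.n_samples
    sens = np.empty(n_iterations)
    spec = np.empty(n_iterations)
    acc = np.empty(n_iterations)
    auc = np.empty(n_iterations)
    assignments = []
    scales_used = []
    full_scaler = FeatureScaler.fit(ds.X, np.arange(n)) if scale_mode == "full" else None
    for it in range(n_iterations):
        folds = fold_assignment(ds.ids, ds.y, n_folds, seed, it, stratified)
        scores = np.empty(n)
        preds = np.empty(n, dtype=int)
        iter_scales = []
        for f in range(n_folds):
            test = folds == f
            train = ~test
            if scale_mode == "per_fold":
                scaler = FeatureScaler.fit(ds.X, np.nonzero(train)[0])
            else:
                scaler = full_scaler
            Xtr = scaler.transform(ds.X[train].copy())
            Xte = scaler.transform(ds.X[test].copy())
            kscale = _resolve_scale(
                config, Xtr,
                seed=int(np.random.SeedSequence([seed, it, f, 0xA0]).generate_state(1)[0]))
            model = train_svm(Xtr, ds.y[train], config, kernel_scale=kscale,
                              tol=tol)
            scores[test] = model.decision_function(Xte)
            preds[test] = model.predict(Xte)
            iter_scales.append(kscale)
        m = compute_metrics(ds.y, preds, scores)
        sens[it], spec[it], acc[it], auc[it] = (m.sensitivity, m.specificity,
                                                m.accuracy, m.auc)
        assignments.append((ds.ids.copy(), folds))
        scales_used.append(iter_scales)
    return CVResult(name=config.name, sensitivity=sens, specificity=spec,
                    accuracy=acc, auc=auc, seed=seed,
                    fold_assignments=assignments, kernel_scales=scales_used)


def kernel_comparison(dataset: SpectraDataset,
                      configs: Sequence[SVMConfig] = PAPER_KERNELS,
                      n_iterations: int = 10, n_folds: int = 2,
                      seed: int = 0) -> dict[str, CVResult]:
    """Evaluate each kernel configuration on one dataset (kernel table rows)."""
    return {cfg.name: evaluate_cv(dataset, cfg, n_iterations=n_iterations,
                                  n_folds=n_folds, seed=seed)
            for cfg in configs}


def wavelength_range_experiment(dataset: SpectraDataset,
                                range_specs: Mapping[str, list] | None = None,
                                config: SVMConfig = QUADRATIC,
                                n_iterations: int = 10, n_folds: int = 2,
                                seed: int = 0) -> dict[str, CVResult]:
    """Evaluate one kernel on each wavelength-range subset of the dataset."""
    if range_specs is None:
        range_specs = TABLE4_RANGES
    out = {}
    for label, ranges in range_specs.items():
        sub = subset_wavelengths(dataset, ranges)
        out[label] = evaluate_cv(sub, config, n_iterations=n_iterations,
                                 n_folds=n_folds, seed=seed)
    return out


def results_table(results: Mapping[str, CVResult],
                  index_name: str = "name") -> pd.DataFrame:
    """Summary table of CV results, one ``mean±sd`` row per configuration."""
    rows = [r.summary_row() for r in results.values()]
    df = pd.DataFrame(rows).rename(columns={"name": index_name})
    return df.set_index(index_name)
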
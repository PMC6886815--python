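"""Concrete morphisms: encoding, standardization, PCA, regression, classifier
wrappers, resamplers for imbalanced risks, and the decision threshold."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import clone as sk_clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from mapperflow.core import (
    ContractError,
    Morphism,
    Prior,
    SpaceDescriptor,
    register_kind,
)

__all__ = [
    "EncoderMap",
    "StandardizeParams",
    "ThresholdParams",
    "infer_column_spec",
    "fit_encoder",
    "encode",
    "encoder_mlm",
    "kl_to_standard_normal",
    "fit_standardize",
    "apply_standardize",
    "standardize_mlm",
    "fit_pca",
    "pca_project",
    "pca_reconstruction_error",
    "pca_mlm",
    "fit_linear_regression",
    "linear_regression_mlm",
    "identity_mlm",
    "classifier_mlm",
    "ClassifierModel",
    "ConstantPriorModel",
    "smote",
    "smote_balance",
    "rose_sample",
    "threshold_apply",
    "threshold_fit",
]


# ----------------------------------------------------------------- encoding
def infer_column_spec(X: pd.DataFrame) -> list[dict]:
    """Column-type sidecar inferred from dtypes: numeric → continuous,
    everything else → categorical."""
    spec = []
    for name in X.columns:
        kind = "continuous" if pd.api.types.is_numeric_dtype(X[name]) else "categorical"
        spec.append({"name": str(name), "kind": kind})
    return spec


@dataclass
class EncoderMap:
    """Fitted dummy-coding map: categoricals expand to full one-hot blocks
    (level order = first appearance in training data), continuous columns
    pass through."""

    columns: list[dict] = field(default_factory=list)
    # each entry: {name, kind, levels: list | None}

    @property
    def output_dim(self) -> int:
        return sum(
            1 if c["kind"] == "continuous" else len(c["levels"]) for c in self.columns
        )

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for c in self.columns:
            if c["kind"] == "continuous":
                names.append(c["name"])
            else:
                names.extend(f"{c['name']}={lv}" for lv in c["levels"])
        return names

    def to_jsonable(self) -> dict:
        return {"__encoder__": self.columns}


def fit_encoder(X_raw: pd.DataFrame, column_spec: list[dict] | None = None) -> EncoderMap:
    if column_spec is None:
        column_spec = infer_column_spec(X_raw)
    cols = []
    for c in column_spec:
        name, kind = c["name"], c["kind"]
        if kind == "continuous":
            cols.append({"name": name, "kind": kind, "levels": None})
        elif kind == "categorical":
            seen: list = []
            for v in X_raw[name]:
                if v not in seen:
                    seen.append(v)
            cols.append({"name": name, "kind": kind, "levels": seen})
        else:
            raise ContractError(f"unknown column kind {kind!r} for {name!r}")
    return EncoderMap(columns=cols)


def encode(enc: EncoderMap, X_raw: pd.DataFrame) -> np.ndarray:
    """Dummy-code a raw table into a dense float matrix.

    Unseen categorical levels map to an all-zero indicator block (with a
    warning) so downstream models still receive a well-formed row.
    """
    n = len(X_raw)
    out = np.zeros((n, enc.output_dim))
    j = 0
    for c in enc.columns:
        col = X_raw[c["name"]]
        if c["kind"] == "continuous":
            out[:, j] = np.asarray(col, dtype=float)
            j += 1
        else:
            levels = c["levels"]
            index = {lv: i for i, lv in enumerate(levels)}
            unseen = 0
            for r, v in enumerate(col):
                i = index.get(v)
                if i is None:
                    unseen += 1
                else:
                    out[r, j + i] = 1.0
            if unseen:
                warnings.warn(
                    f"column {c['name']!r}: {unseen} unseen level(s) encoded "
                    "as all-zero blocks"
                )
            j += len(levels)
    return out


def encoder_mlm(column_spec: list[dict] | None = None) -> Morphism:
    """Dummy-coding as an unsupervised morphism from tables to R^m."""

    def _solver(X: Any, Y: Any, prior: Prior) -> EncoderMap:
        return fit_encoder(X, column_spec)

    def _morphism(x: Any, params: EncoderMap) -> np.ndarray:
        return encode(params, x)

    return Morphism(
        kind="encoder",
        input_space=SpaceDescriptor.abstract(),
        output_space=SpaceDescriptor.abstract(),
        morphism=_morphism,
        solver=_solver,
        supervised=False,
        validate_input=lambda x: None,
    )


# ------------------------------------------------------------ standardization
@dataclass(frozen=True)
class StandardizeParams:
    c: np.ndarray  # per-column shift
    s: np.ndarray  # per-column scale, strictly positive

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.s) <= 0):
            raise ContractError("scale s must be strictly positive")


def kl_to_standard_normal(X: np.ndarray) -> float:
    """KL divergence of a Gaussian model of ``X`` from N(0, I).

    Computed as ``0.5 * (tr(S) + m·m − d − ln det S)`` with the sample mean
    ``m`` and covariance ``S`` (regularized by ``1e−9·I``).  Zero iff the
    sample has mean 0 and identity covariance, up to regularization.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ContractError("kl_to_standard_normal needs at least 2 rows")
    m = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1).reshape(d, d) + 1e-9 * np.eye(d)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ContractError("sample covariance not positive definite")
    return 0.5 * float(np.trace(S) + m @ m - d - logdet)


def fit_standardize(X: np.ndarray) -> StandardizeParams:
    """Column means and sample (n−1) standard deviations; constant columns
    get scale 1 with a warning."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ContractError("empty X")
    c = X.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    bad = ~(s > 0)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} constant column(s); scale set to 1")
        s = np.where(bad, 1.0, s)
    return StandardizeParams(c=c, s=s)


def apply_standardize(X: np.ndarray, params: StandardizeParams) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.c) / params.s


def standardize_mlm() -> Morphism:
    def _solver(X: Any, Y: Any, prior: Prior) -> tuple[np.ndarray, np.ndarray]:
        p = fit_standardize(X)
        return (p.c, p.s)

    def _morphism(x: Any, params: tuple) -> np.ndarray:
        c, s = params
        return apply_standardize(x, StandardizeParams(c=np.asarray(c), s=np.asarray(s)))

    def _risk(params: tuple, X: Any, Y: Any) -> float:
        return kl_to_standard_normal(_morphism(np.atleast_2d(X), params))

    return Morphism(
        kind="standardize",
        input_space=SpaceDescriptor.abstract(),
        output_space=SpaceDescriptor.abstract(),
        morphism=_morphism,
        risk=_risk,
        solver=_solver,
        supervised=False,
        validate_input=lambda x: None,
    )


# ----------------------------------------------------------------------- PCA
def _principal_axes(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a covariance matrix, eigenvalues descending,
    each axis sign-fixed so its largest-magnitude loading is positive."""
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evals, evecs


def fit_pca(X: np.ndarray, c: int) -> np.ndarray:
    """Loading matrix (c × m, orthonormal rows) of the standardized data.

    Standardization is applied internally; projections of the training data
    maximise retained variance and the reconstruction error equals the sum
    of the discarded covariance eigenvalues.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    if not (1 <= c <= m):
        raise ContractError(f"target dimension c={c} outside [1, {m}]")
    Z = apply_standardize(X, fit_standardize(X))
    S = np.cov(Z, rowvar=False, ddof=1).reshape(m, m)
    _, evecs = _principal_axes(S)
    return evecs[:, :c].T


def pca_project(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    return np.atleast_2d(np.asarray(X, dtype=float)) @ A.T


def pca_reconstruction_error(X: np.ndarray, A: np.ndarray) -> float:
    """Covariance-scale reconstruction error ``‖Z − Z AᵀA‖²_F / (n−1)`` of the
    standardized data; equals the sum of discarded covariance eigenvalues."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = apply_standardize(X, fit_standardize(X))
    R = Z - (Z @ A.T) @ A
    return float(np.sum(R * R) / (Z.shape[0] - 1))


def pca_mlm(c: int) -> Morphism:
    """PCA to ``c`` dimensions (standardizes internally); unsupervised."""

    def _solver(X: Any, Y: Any, prior: Prior) -> tuple:
        p = fit_standardize(np.atleast_2d(np.asarray(X, dtype=float)))
        A = fit_pca(X, c)
        return (p.c, p.s, A)

    def _morphism(x: Any, params: tuple) -> np.ndarray:
        cc, ss, A = params
        Z = apply_standardize(x, StandardizeParams(np.asarray(cc), np.asarray(ss)))
        return Z @ np.asarray(A).T

    def _risk(params: tuple, X: Any, Y: Any) -> float:
        return pca_reconstruction_error(X, np.asarray(params[2]))

    return Morphism(
        kind="pca",
        input_space=SpaceDescriptor.abstract(),
        output_space=SpaceDescriptor.continuous(c),
        morphism=_morphism,
        risk=_risk,
        solver=_solver,
        supervised=False,
        validate_input=lambda x: None,
    )


# ----------------------------------------------------------- linear regression
def fit_linear_regression(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients.  Singular designs fall back to the
    minimum-norm pseudoinverse solution."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape[0] != Y.shape[0]:
        raise ContractError("X rows and Y length differ")
    p, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return p


def linear_regression_mlm(dim: int, prior: Prior | None = None) -> Morphism:
    def _solver(X: Any, Y: Any, pr: Prior) -> np.ndarray:
        return fit_linear_regression(X, Y)

    def _morphism(x: Any, p: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(x, dtype=float)) @ np.asarray(p)

    def _risk(p: Any, X: Any, Y: Any) -> float:
        r = np.asarray(Y, dtype=float).ravel() - _morphism(X, np.asarray(p)).ravel()
        return float(r @ r)

    return Morphism(
        kind="linreg",
        input_space=SpaceDescriptor.continuous(dim),
        output_space=SpaceDescriptor.continuous(1),
        morphism=_morphism,
        risk=_risk,
        solver=_solver,
        prior=prior if prior is not None else Prior(),
        supervised=True,
    )


def identity_mlm(dim: int | None = None) -> Morphism:
    space = SpaceDescriptor.continuous(dim) if dim else SpaceDescriptor.abstract()
    m = Morphism(
        kind="identity",
        input_space=space,
        output_space=space,
        morphism=lambda x, p: x,
        solver=lambda X, Y, pr: (),
        supervised=False,
        validate_input=(None if dim else (lambda x: None)),
    )
    return m


register_kind("linreg", lambda: linear_regression_mlm(1))
register_kind("standardize", standardize_mlm)
register_kind("identity", identity_mlm)


# ---------------------------------------------------------------- classifiers
class ConstantPriorModel:
    """Degenerate fallback for single-class training data: predicts the
    class-1 prior probability for every input."""

    def __init__(self, prior: float) -> None:
        self.prior = float(prior)

    def fit(self, X: Any, y: Any) -> "ConstantPriorModel":
        return self

    def predict_proba(self, X: Any) -> np.ndarray:
        p = np.full(len(X), self.prior)
        return np.column_stack([1 - p, p])


_CLASSIFIER_FACTORIES: dict[str, Callable[[int], Any]] = {
    "logistic": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed
    ),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
}


class ClassifierModel:
    """Binary classifier wrapper producing class-1 probabilities.

    Hyperparameters (if a grid is given) are chosen by ``cv_folds``-fold
    stratified CV maximising ROC AUC.  Margin classifiers are calibrated to
    probabilities through a logistic link (Platt scaling for the SVM).
    Single-class training data degrades to a constant-prior predictor.
    """

    def __init__(
        self,
        kind: str = "logistic",
        hyper_grid: dict | None = None,
        cv_folds: int = 10,
        seed: int = 0,
    ) -> None:
        if kind not in _CLASSIFIER_FACTORIES:
            raise ContractError(f"unknown classifier kind {kind!r}")
        self.kind = kind
        self.hyper_grid = hyper_grid or {}
        self.cv_folds = cv_folds
        self.seed = seed
        self.model_: Any = None
        self.best_params_: dict = {}

    def _cv_auc(self, est: Any, X: np.ndarray, y: np.ndarray, n_splits: int) -> float:
        from mapperflow.evaluation import roc_auc

        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
        aucs = []
        for tr, va in cv.split(X, y):
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            m = sk_clone(est).fit(X[tr], y[tr])
            aucs.append(roc_auc(y[va], m.predict_proba(X[va])[:, 1]))
        return float(np.mean(aucs)) if aucs else 0.5

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).astype(int).ravel()
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            warnings.warn("single-class training data; using constant-prior model")
            self.model_ = ConstantPriorModel(float(classes[0]))
            return self
        base = _CLASSIFIER_FACTORIES[self.kind](self.seed)
        if self.hyper_grid:
            n_splits = min(self.cv_folds, int(counts.min()))
            if n_splits < self.cv_folds:
                warnings.warn(f"CV folds reduced to {n_splits}")
            if n_splits >= 2:
                best_auc, best = -np.inf, {}
                for hp in ParameterGrid(self.hyper_grid):
                    auc = self._cv_auc(sk_clone(base).set_params(**hp), X, y, n_splits)
                    if auc > best_auc:
                        best_auc, best = auc, hp
                self.best_params_ = best
                base.set_params(**best)
        self.model_ = base.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise ContractError("classifier not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.clip(self.model_.predict_proba(X), 0.0, 1.0)


def classifier_mlm(
    kind: str = "logistic",
    hyper_grid: dict | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> Morphism:
    """A tuned binary classifier as a morphism to class-1 probabilities."""

    def _solver(X: Any, Y: Any, prior: Prior) -> ClassifierModel:
        return ClassifierModel(kind, hyper_grid, cv_folds, seed).fit(X, Y)

    def _morphism(x: Any, model: ClassifierModel) -> np.ndarray:
        return model.predict_proba(np.atleast_2d(np.asarray(x, dtype=float)))[:, 1]

    return Morphism(
        kind=f"classifier:{kind}",
        input_space=SpaceDescriptor.abstract(),
        output_space=SpaceDescriptor.probability(),
        morphism=_morphism,
        solver=_solver,
        supervised=True,
        validate_input=lambda x: None,
    )


# ------------------------------------------------------------------ samplers
def smote(
    X_minority: np.ndarray,
    k_neighbors: int = 5,
    n_synthetic: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic minority points by uniform interpolation towards one of the
    k nearest minority neighbours (Euclidean, in encoded space)."""
    X = np.atleast_2d(np.asarray(X_minority, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ContractError("need at least 2 minority points")
    if n <= k_neighbors:
        warnings.warn(f"k_neighbors reduced from {k_neighbors} to {n - 1}")
        k_neighbors = n - 1
    if n_synthetic <= 0:
        return np.empty((0, X.shape[1]))
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)  # column 0 is the point itself
    base = rng.integers(0, n, size=n_synthetic)
    pick = rng.integers(1, k_neighbors + 1, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    nbr = idx[base, pick]
    return X[base] + u[:, None] * (X[nbr] - X[base])


def smote_balance(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class with SMOTE to an exact 1:1 ratio."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("both classes required")
    minority = classes[int(np.argmin(counts))]
    need = int(counts.max() - counts.min())
    if need == 0:
        return X, y
    Xs = smote(X[y == minority], k_neighbors, need, seed)
    return np.vstack([X, Xs]), np.concatenate([y, np.full(need, minority)])


def _silverman_bandwidths(X: np.ndarray) -> np.ndarray:
    n, d = X.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
    sd = np.where(np.isfinite(sd), sd, 0.0)
    return (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0)) * sd


def rose_sample(
    X: np.ndarray,
    y: np.ndarray,
    n_out: int,
    h_scale: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced smoothed bootstrap.

    Each output row draws a class with probability 1/2, resamples a row of
    that class, and perturbs it with Gaussian noise of per-feature Silverman
    bandwidth scaled by ``h_scale``; ``h_scale=0`` is a plain balanced
    bootstrap.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ContractError("both classes required")
    if h_scale < 0:
        raise ContractError("h_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    by_class = {c: np.flatnonzero(y == c) for c in classes}
    h = {c: h_scale * _silverman_bandwidths(X[by_class[c]]) for c in classes}
    out_X = np.empty((n_out, X.shape[1]))
    out_y = np.empty(n_out, dtype=int)
    draws = rng.integers(0, 2, size=n_out)
    for i in range(n_out):
        c = classes[draws[i]]
        row = X[rng.choice(by_class[c])]
        out_X[i] = row + rng.standard_normal(X.shape[1]) * h[c]
        out_y[i] = c
    return out_X, out_y


# ----------------------------------------------------------------- threshold
@dataclass(frozen=True)
class ThresholdParams:
    T: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.T <= 1.0):
            raise ContractError("threshold T must lie in [0, 1]")


def threshold_apply(x: np.ndarray | float, T: float | ThresholdParams) -> np.ndarray:
    """Boundary-inclusive decision rule: 1 iff score ≥ T."""
    t = T.T if isinstance(T, ThresholdParams) else float(T)
    return (np.asarray(x, dtype=float) >= t).astype(int)


def _youden(y: np.ndarray, pred: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens + spec - 1.0


_THRESHOLD_CRITERIA: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "youden": _youden,
    "accuracy": lambda y, pred: float(np.mean(pred == y)),
}


def threshold_fit(
    scores: np.ndarray, labels: np.ndarray, criterion: str = "youden"
) -> ThresholdParams:
    """Scan midpoints of consecutive observed scores (plus the extremes) and
    return the smallest T maximising the criterion (default Youden J)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if np.any((scores < 0) | (scores > 1)):
        raise ContractError("scores must lie in [0, 1]")
    if criterion not in _THRESHOLD_CRITERIA:
        raise ContractError(f"unknown criterion {criterion!r}")
    if len(np.unique(labels)) < 2:
        warnings.warn("degenerate labels; falling back to T=0.5")
        return ThresholdParams(T=0.5)
    fn = _THRESHOLD_CRITERIA[criterion]
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    best_t, best_val = 0.5, -np.inf
    for t in candidates:  # ascending → ties keep the smallest T
        val = fn(labels, threshold_apply(scores, t))
        if val > best_val + 1e-12:
            best_val, best_t = val, float(t)
    return ThresholdParams(T=best_t)
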
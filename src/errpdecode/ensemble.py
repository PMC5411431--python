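"""Posterior-averaging ensemble of discriminant and logistic learners.

Four weak learners — linear discriminant analysis, regularized quadratic
discriminant analysis (covariance shrinkage gamma = 0.07), and logistic
regression with L1 and L2 penalties (penalty weight lambda = 0.15) — are
each fitted on M resamples of the training set (the training splits of a
stratified k-fold partition, M = k = 10 by default).  The ensemble error
posterior is the arithmetic mean of all L x M per-estimator posteriors;
a trial is labelled Error when that posterior reaches the decision
threshold (0.5).

Features are z-scored with training-set statistics before any learner
sees them; the standardizer is part of the stored model.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

QDA_SHRINKAGE = 0.07
LOGISTIC_PENALTY = 0.15
LDA_RIDGE = 1e-6

ERROR_CLASS = 1
NOERROR_CLASS = 0


@dataclass
class LabeledFeatureSet:
    """n x d feature matrix with binary labels (Error = 1, NoError = 0)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be (n, d) and y (n,)")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain non-finite values")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be 0 (NoError) or 1 (Error)")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ResamplePlan:
    """Index lists defining the M training resamples."""

    indices: tuple[np.ndarray, ...]
    k: int
    seed: int
    with_replacement: bool = False

    @property
    def M(self) -> int:
        return len(self.indices)


def build_resamples(y: np.ndarray, k: int = 10, M: int | None = None,
                    seed: int = 0, with_replacement: bool = False
                    ) -> ResamplePlan:
    """Build the M resamples used to train each learner.

    Default: the M = k training splits of a stratified k-fold partition
    (each of size n(k-1)/k, without replacement).  The alternative
    bootstrap reading — m draws with replacement per resample — is
    available via ``with_replacement``.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if n < k or k < 2:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify "
            f"into {k} folds")
    M = k if M is None else M
    rng = np.random.default_rng(seed)
    if with_replacement:
        m = n * (k - 1) // k
        idx = tuple(np.sort(rng.choice(n, size=m, replace=True))
                    for _ in range(M))
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = [train for train, _ in skf.split(np.zeros(n), y)]
        idx = tuple(np.sort(splits[m % k]) for m in range(M))
    return ResamplePlan(indices=idx, k=k, seed=seed,
                        with_replacement=with_replacement)


class _GaussianDiscriminant:
    """Closed-form Gaussian class-conditional classifier.

    ``pooled=True`` gives linear discriminant analysis (shared covariance
    with a small ridge); otherwise per-class covariances shrunk toward a
    scaled identity: Sigma_c <- (1 - gamma) Sigma_c + gamma tr(Sigma_c)/d I.
    Priors come from class frequencies in the fitted resample.
    """

    def __init__(self, pooled: bool, shrinkage: float = 0.0,
                 ridge: float = 0.0):
        self.pooled = pooled
        self.shrinkage = shrinkage
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GaussianDiscriminant":
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.means_, covs, self.log_priors_ = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            self.means_.append(Xc.mean(axis=0))
            centred = Xc - self.means_[-1]
            covs.append(centred.T @ centred / Xc.shape[0])
            self.log_priors_.append(np.log(Xc.shape[0] / X.shape[0]))
        if self.pooled:
            weights = [np.mean(y == c) for c in self.classes_]
            pooled_cov = sum(w * S for w, S in zip(weights, covs))
            covs = [pooled_cov] * len(self.classes_)
        self._factors, self._logdets = [], []
        for S in covs:
            Sr = self._regularize(S, d)
            cho, logdet = self._factor(Sr, d)
            self._factors.append(cho)
            self._logdets.append(logdet)
            if self.pooled:  # identical matrices: factor once
                self._factors = [cho] * len(self.classes_)
                self._logdets = [logdet] * len(self.classes_)
                break
        return self

    def _regularize(self, S: np.ndarray, d: int) -> np.ndarray:
        if self.shrinkage > 0:
            S = ((1 - self.shrinkage) * S
                 + self.shrinkage * (np.trace(S) / d) * np.eye(d))
        if self.ridge > 0:
            S = S + self.ridge * np.eye(d)
        return S

    def _factor(self, S: np.ndarray, d: int):
        jitter = 0.0
        for _ in range(8):
            try:
                cho = linalg.cho_factor(S + jitter * np.eye(d), lower=True)
                logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
                if jitter:
                    logger.warning(
                        "singular class covariance: proceeded with "
                        "ridge jitter %.1e", jitter)
                return cho, logdet
            except linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-8)
        raise linalg.LinAlgError("covariance not factorizable even with jitter")

    def _log_likelihood(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((X.shape[0], len(self.classes_)))
        for j, (mu, cho, logdet, lp) in enumerate(zip(
                self.means_, self._factors, self._logdets, self.log_priors_)):
            diff = X - mu
            sol = linalg.cho_solve(cho, diff.T)
            maha = np.einsum("ij,ji->i", diff, sol)
            out[:, j] = -0.5 * (maha + logdet) + lp
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        ll = self._log_likelihood(np.asarray(X, float))
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)


def _make_lda() -> _GaussianDiscriminant:
    return _GaussianDiscriminant(pooled=True, ridge=LDA_RIDGE)


def _make_qda() -> _GaussianDiscriminant:
    return _GaussianDiscriminant(pooled=False, shrinkage=QDA_SHRINKAGE)


def _make_logistic(penalty: str) -> LogisticRegression:
    # C = 1 / lambda; liblinear (L1) regularizes the intercept, so a large
    # intercept_scaling keeps it effectively unpenalized.
    if penalty == "l1":
        kwargs = dict(C=1.0 / LOGISTIC_PENALTY, solver="liblinear",
                      intercept_scaling=100.0, max_iter=2000, tol=1e-8,
                      random_state=0)
        ratio = {"l1_ratio": 1.0}
    else:
        kwargs = dict(C=1.0 / LOGISTIC_PENALTY, solver="lbfgs",
                      max_iter=2000, tol=1e-8)
        ratio = {"l1_ratio": 0.0}
    # sklearn >= 1.8 spells the penalty kind via l1_ratio
    return LogisticRegression(**kwargs, **ratio)


LEARNER_NAMES = ("lda", "qda", "logistic_l1", "logistic_l2")

_FACTORIES = {
    "lda": _make_lda,
    "qda": _make_qda,
    "logistic_l1": lambda: _make_logistic("l1"),
    "logistic_l2": lambda: _make_logistic("l2"),
}


@dataclass
class Standardizer:
    """Per-feature z-scoring with training-set statistics."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale


@dataclass
class EnsembleModel:
    """L learners x M resamples of fitted estimators plus preprocessing.

    ``estimators[l][m]`` is learner ``learner_names[l]`` fitted on
    resample ``m``; predictions average all L x M error posteriors.
    """

    learner_names: tuple[str, ...]
    estimators: list[list]
    scaler: Standardizer | None
    plan: ResamplePlan
    threshold: float = 0.5
    selected_channels: tuple[str, ...] | None = None
    seed: int = 0
    config_hash: str = ""
    d: int = field(default=0)

    @property
    def n_estimators(self) -> int:
        return sum(len(row) for row in self.estimators)


def fit_ensemble(data: LabeledFeatureSet, plan: ResamplePlan | None = None,
                 learners: tuple[str, ...] = LEARNER_NAMES,
                 standardize: bool = True, threshold: float = 0.5,
                 seed: int = 0,
                 selected_channels: tuple[str, ...] | None = None
                 ) -> EnsembleModel:
    """Fit every learner on every resample (L x M estimators).

    The standardizer is fit once on the full training set; each resample
    must contain both classes (guaranteed by the stratified default
    plan).
    """
    if plan is None:
        plan = build_resamples(data.y, seed=seed)
    scaler = Standardizer.fit(data.X) if standardize else None
    Xs = scaler.transform(data.X) if scaler else data.X
    estimators: list[list] = []
    for name in learners:
        if name not in _FACTORIES:
            raise ValueError(f"unknown learner {name!r}")
        row = []
        for idx in plan.indices:
            yr = data.y[idx]
            if len(np.unique(yr)) < 2:
                raise ValueError("a resample lost one of the classes")
            est = _FACTORIES[name]()
            est.fit(Xs[idx], yr)
            row.append(est)
        estimators.append(row)
    cfg = {"learners": learners, "threshold": threshold, "k": plan.k,
           "M": plan.M, "standardize": standardize,
           "with_replacement": plan.with_replacement}
    cfg_hash = hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return EnsembleModel(learner_names=tuple(learners), estimators=estimators,
                         scaler=scaler, plan=plan, threshold=threshold,
                         selected_channels=selected_channels, seed=seed,
                         config_hash=cfg_hash, d=data.d)


def ensemble_posterior(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Mean error posterior over all L x M estimators, per row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if model.d and X.shape[1] != model.d:
        raise ValueError(
            f"expected {model.d} features, got {X.shape[1]}")
    Xs = model.scaler.transform(X) if model.scaler else X
    total = np.zeros(X.shape[0])
    count = 0
    for row in model.estimators:
        for est in row:
            proba = est.predict_proba(Xs)
            classes = getattr(est, "classes_", np.array([0, 1]))
            col = int(np.flatnonzero(classes == ERROR_CLASS)[0])
            total += proba[:, col]
            count += 1
    return total / count


def classify(p_error: np.ndarray | float, threshold: float = 0.5) -> np.ndarray:
    """Hard label: Error (1) iff the posterior reaches the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return np.where(np.asarray(p_error) >= threshold, ERROR_CLASS,
                    NOERROR_CLASS)


def save_model(model: EnsembleModel, path) -> None:
    """Persist a fitted model (joblib archive)."""
    import joblib

    joblib.dump(model, path)


def load_model(path) -> EnsembleModel:
    import joblib

    model = joblib.load(path)
    if not isinstance(model, EnsembleModel):
        raise TypeError(f"{path} does not contain an EnsembleModel")
    return model
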
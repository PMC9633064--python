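"""Sequence-context model of editing-driven dropout.

Featurizes 30-nt guide contexts as position-specific k-mer indicators
(k <= 4; every window of every length contributes exactly one active
feature, 114 per guide out of a 9288-feature catalogue) and fits L1-penalized
models: an ordinary lasso on the quantitative log2 fold change and a logistic
lasso on the binary dropout label (log2FC < -0.5). Regularization strength
is chosen by cross-validation with the 1-SE rule.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import pearsonr
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContextParams:
    context_len: int = 30
    kmax: int = 4
    train_size: int = 4928
    test_size: int = 1000
    dropout_threshold: float = -0.5
    cv_folds: int = 10
    n_alphas: int = 30
    rng_seed: int = 0


@dataclass
class FeatureMatrix:
    """Sparse binary guides x features matrix with its feature catalogue."""

    X: sparse.csr_matrix
    features: list[tuple[int, int, str]]  # (start position 1-based, k, k-mer)


@dataclass
class ContextModel:
    family: str  # ordinary | logistic
    coef: np.ndarray
    intercept: float
    alpha: float
    features: list[tuple[int, int, str]]

    def nonzero(self) -> dict[tuple[int, int, str], float]:
        return {
            self.features[i]: float(w)
            for i, w in enumerate(self.coef)
            if w != 0.0
        }

    def predict(self, X: sparse.csr_matrix) -> np.ndarray:
        """Linear predictor (also used for the logistic family)."""
        return np.asarray(X @ self.coef) + self.intercept


def feature_catalogue(params: ContextParams | None = None) -> list[tuple[int, int, str]]:
    """All (position, k, k-mer) features ordered by (position, k, k-mer)."""
    params = params or ContextParams()
    cat = []
    for pos in range(1, params.context_len + 1):
        for k in range(1, params.kmax + 1):
            if pos + k - 1 > params.context_len:
                continue
            for kmer in map("".join, itertools.product("ACGT", repeat=k)):
                cat.append((pos, k, kmer))
    return cat


def featurize_contexts(
    contexts: list[str], params: ContextParams | None = None
) -> FeatureMatrix:
    """Binary position-specific k-mer indicators for each context."""
    params = params or ContextParams()
    cat = feature_catalogue(params)
    col_of = {f: i for i, f in enumerate(cat)}
    n_active = sum(params.context_len - k + 1 for k in range(1, params.kmax + 1))
    indptr = [0]
    indices = []
    for gi, ctx in enumerate(contexts):
        if len(ctx) != params.context_len or set(ctx) - set("ACGT"):
            raise ValueError(f"bad context for guide index {gi}: {ctx!r}")
        cols = []
        for pos in range(1, params.context_len + 1):
            for k in range(1, params.kmax + 1):
                if pos + k - 1 > params.context_len:
                    continue
                cols.append(col_of[(pos, k, ctx[pos - 1 : pos + k - 1])])
        assert len(cols) == n_active
        indices.extend(sorted(cols))
        indptr.append(len(indices))
    X = sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.float64), np.array(indices), np.array(indptr)),
        shape=(len(contexts), len(cat)),
    )
    return FeatureMatrix(X=X, features=cat)


def fit_context_model(
    fm: FeatureMatrix,
    y: np.ndarray,
    family: str = "ordinary",
    params: ContextParams | None = None,
) -> ContextModel:
    """L1-penalized fit with CV-selected regularization (1-SE rule)."""
    params = params or ContextParams()
    y = np.asarray(y, dtype=float)
    if fm.X.shape[0] != y.size:
        raise ValueError("feature matrix and response length mismatch")
    if np.all(y == y[0]):
        raise ValueError("degenerate response: constant y")
    X = fm.X

    if family == "ordinary":
        cv = KFold(params.cv_folds, shuffle=True, random_state=params.rng_seed)
        lcv = LassoCV(alphas=params.n_alphas, cv=cv, max_iter=5000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lcv.fit(X, y)
        # 1-SE rule on the CV error path
        mean_mse = lcv.mse_path_.mean(axis=1)
        se_mse = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
        best = int(np.argmin(mean_mse))
        limit = mean_mse[best] + se_mse[best]
        ok = np.nonzero(mean_mse <= limit)[0]
        # alphas_ are descending; the smallest index among ok is the strongest
        alpha = float(lcv.alphas_[ok.min()])
        model = Lasso(alpha=alpha, max_iter=10000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        return ContextModel(
            family="ordinary",
            coef=model.coef_.copy(),
            intercept=float(model.intercept_),
            alpha=alpha,
            features=fm.features,
        )
    elif family == "logistic":
        yb = y.astype(int)
        if set(np.unique(yb)) - {0, 1}:
            raise ValueError("logistic family requires binary y")
        cv = StratifiedKFold(params.cv_folds, shuffle=True, random_state=params.rng_seed)
        Cs = np.logspace(-3, 1, params.n_alphas)
        lcv = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", max_iter=2000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lcv.fit(X, yb)
        scores = lcv.scores_[1]  # folds x Cs, neg log loss (higher better)
        mean_s = scores.mean(axis=0)
        se_s = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        best = int(np.argmax(mean_s))
        limit = mean_s[best] - se_s[best]
        ok = np.nonzero(mean_s >= limit)[0]
        C = float(Cs[ok.min()])  # smallest C = strongest penalty
        model = LogisticRegression(
            C=C, penalty="l1", solver="liblinear", max_iter=2000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, yb)
        return ContextModel(
            family="logistic",
            coef=model.coef_.ravel().copy(),
            intercept=float(model.intercept_[0]),
            alpha=1.0 / C,
            features=fm.features,
        )
    raise ValueError(f"unknown family {family!r}")


def evaluate_context_model(
    model: ContextModel, X_test: sparse.csr_matrix, y_test: np.ndarray
) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred = model.predict(X_test)
    y = np.asarray(y_test, dtype=float)
    if np.std(pred) == 0 or np.std(y) == 0:
        logger.warning("zero-variance predictions or response; R^2 reported as 0")
        return 0.0
    r, _ = pearsonr(pred, y)
    return float(r * r)


def label_dropout(log2fc, threshold: float = -0.5) -> np.ndarray:
    """Dropout label: strictly below the log2 fold-change threshold."""
    return np.asarray(log2fc, dtype=float) < threshold
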
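"""Baseline methods run against TD-FE on the same inputs.

* per-feature categorical regression (additive two-factor ANOVA, overall
  F-test), vectorised over all features through a single projection matrix;
* multiple non-negative matrix factorization (MNMF) by multiplicative
  Frobenius updates on the column-wise concatenation of the per-condition
  matrices (factorising the concatenation minimises the summed per-block
  objective exactly);
* random-forest importance, delegated to scikit-learn;
* leave-one-out LDA over sample classes using products of sample-mode
  singular value vectors as inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .hosvd import hosvd
from .tensor import as_omics_tensor

__all__ = [
    "DesignLabels",
    "MNMFResult",
    "categorical_regression",
    "CategoricalRegressionFE",
    "mnmf",
    "MultiNMF",
    "nonnegative_shift",
    "rf_importance",
    "RandomForestFE",
    "loo_lda_eval",
    "LOOLDAResult",
]

logger = logging.getLogger(__name__)

#: smallest p-value reported when the residual variance underflows
P_FLOOR = 1e-300


@dataclass
class DesignLabels:
    """Per-sample factor labels for the additive categorical model.

    ``factors`` holds one label array per factor (e.g. tissue group and
    disease group), each of length n_samples, aligned with the columns of
    the feature x samples matrix.
    """

    factors: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        self.factors = tuple(np.asarray(f) for f in self.factors)
        if not self.factors:
            raise ValueError("at least one factor required")
        n = len(self.factors[0])
        for f in self.factors:
            if len(f) != n:
                raise ValueError("all factors must label the same samples")
            if np.unique(f).size < 2:
                raise ValueError("every factor needs at least two levels")

    @property
    def n_samples(self) -> int:
        return len(self.factors[0])

    def design_matrix(self, intercept: bool = False) -> np.ndarray:
        """Dummy-coded design matrix.

        With ``intercept=False`` (the default, matching the no-intercept
        additive model): full dummies for the first factor and
        reference-coded dummies for the rest — the same column space as the
        over-parameterised all-dummies formulation, but full rank.  Note the
        span still contains the constant vector (the first factor's dummies
        sum to one).  With ``intercept=True``: an explicit intercept plus
        reference-coded dummies for every factor.
        """
        if intercept:
            cols = [np.ones(self.n_samples)]
            drop = [True] * len(self.factors)
        else:
            cols = []
            drop = [False] + [True] * (len(self.factors) - 1)
        for f, d1 in zip(self.factors, drop):
            d = pd.get_dummies(pd.Series(f), drop_first=d1, dtype=float)
            cols.append(d.to_numpy())
        return np.column_stack(cols)

    @property
    def interaction(self) -> np.ndarray:
        """Combined (J, K, ...) class label per sample."""
        return np.array(["_".join(str(f[i]) for f in self.factors) for i in range(self.n_samples)])


def categorical_regression(matrix, labels: DesignLabels, intercept: bool = False) -> np.ndarray:
    """Overall F-test p-value of the additive factor model, per feature.

    For every row of ``matrix`` (feature x samples) the additive model
    x_s = sum_J a_J d_Js + sum_K b_K d_Ks is fitted by least squares.  The
    model has no intercept term, so the overall F-test (the single p-value
    a linear-model summary reports for such a fit) compares it against the
    zero model using the uncentered total sum of squares with
    df_model = rank(design).  This is what gives the model its power on
    features whose grand mean is shifted away from zero.  Pass
    ``intercept=True`` for the conventional test against the intercept-only
    model instead.

    All features share one design, so the fit reduces to a single
    hat-matrix product applied to the whole matrix at once.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (features x samples)")
    if X.shape[1] != labels.n_samples:
        raise ValueError("labels do not match the number of samples")
    D = labels.design_matrix(intercept=intercept)
    rank = np.linalg.matrix_rank(D)
    df_model = rank - 1 if intercept else rank
    df_resid = labels.n_samples - rank
    if df_model < 1:
        raise ValueError("design has no model degrees of freedom")
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    H = D @ np.linalg.pinv(D)  # hat matrix, n_samples x n_samples
    fitted = X @ H.T
    sse = np.sum((X - fitted) ** 2, axis=1)
    if intercept:
        sst = np.sum((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1)
    else:
        sst = np.sum(X**2, axis=1)
    ssm = np.clip(sst - sse, 0.0, None)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssm / df_model) / (sse / df_resid)
    p = np.ones(X.shape[0])
    ok = sse > 0
    p[ok] = sps.f.sf(F[ok], df_model, df_resid)
    exact = (~ok) & (ssm > 0)
    if exact.any():
        # zero residual variance with a nonzero fit: numerically perfect
        p[exact] = P_FLOOR
    degenerate = sst <= 0
    if degenerate.any():
        logger.warning("%d constant features set to p = 1", int(degenerate.sum()))
        p[degenerate] = 1.0
    return p


class CategoricalRegressionFE:
    """Feature selector from per-feature ANOVA p-values with BH control.

    fit(X) expects a feature x samples matrix (or a tensor, unfolded on its
    feature mode) and a :class:`DesignLabels`; ``support_`` marks features
    with BH-adjusted p below ``alpha``.
    """

    def __init__(self, labels: DesignLabels, alpha: float = 0.01, intercept: bool = False):
        self.labels = labels
        self.alpha = alpha
        self.intercept = intercept

    def fit(self, X, y=None) -> "CategoricalRegressionFE":
        from .stats import bh_adjust

        M = X
        if not (isinstance(X, np.ndarray) and X.ndim == 2):
            t = as_omics_tensor(X)
            M = t.unfold(t.feature_mode)
        self.p_values_ = categorical_regression(M, self.labels, intercept=self.intercept)
        self.p_adjusted_ = bh_adjust(self.p_values_)
        self.support_ = self.p_adjusted_ < self.alpha
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        return np.flatnonzero(self.support_) if indices else self.support_


# ---------------------------------------------------------------------------
# MNMF


@dataclass
class MNMFResult:
    """Nonnegative factors Q (features x n), H (n x samples) and the
    per-iteration Frobenius objective ||X - QH||_F."""

    Q: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def nonnegative_shift(matrix, mode: str = "min", eps: float = 1e-10) -> np.ndarray:
    """Preprocess a matrix for NMF.

    ``mode="min"`` subtracts the global minimum (synthetic data, which has
    Gaussian negatives); ``mode="epsilon"`` replaces exact zeros with
    ``eps`` (nonnegative coverage data).
    """
    X = np.asarray(matrix, dtype=float)
    if mode == "min":
        return X - X.min()
    if mode == "epsilon":
        if (X < 0).any():
            raise ValueError("epsilon mode requires a nonnegative matrix")
        X = X.copy()
        X[X == 0] = eps
        return X
    raise ValueError(f"unknown preprocessing mode {mode!r}")


def mnmf(
    matrix,
    n: int = 3,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> MNMFResult:
    """Frobenius NMF by multiplicative updates on the concatenated matrix.

    Factorising the column-wise concatenation X = [X_1 ... X_k] with a
    shared Q minimises the sum of the per-block objectives
    sum_k ||X_k - Q H_k||_F^2, since the squared norms add over column
    blocks; this is the "multiple NMF" formulation for matrices sharing a
    row space.

    Initialisation is uniform random scaled to the data, seed-controlled;
    iteration stops at ``max_iter`` or when the relative objective change
    drops below ``tol``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if (X < 0).any():
        raise ValueError("NMF input must be nonnegative (preprocess first)")
    if not 1 <= n <= min(X.shape):
        raise ValueError("n must be between 1 and min(matrix shape)")
    rng = np.random.Generator(np.random.Philox(seed))
    scale = np.sqrt(X.mean() / n) if X.mean() > 0 else 1.0
    Q = rng.uniform(1e-3, 1.0, size=(X.shape[0], n)) * scale
    H = rng.uniform(1e-3, 1.0, size=(n, X.shape[1])) * scale
    eps = 1e-12
    trace = [float(np.linalg.norm(X - Q @ H))]
    for _ in range(max_iter):
        H *= (Q.T @ X) / (Q.T @ Q @ H + eps)
        Q *= (X @ H.T) / (Q @ (H @ H.T) + eps)
        trace.append(float(np.linalg.norm(X - Q @ H)))
        if abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], eps):
            break
    return MNMFResult(Q=Q, H=H, objective_trace=np.asarray(trace))


class MultiNMF:
    """Estimator wrapper around :func:`mnmf`.

    fit(X) stores ``Q_``, ``H_`` and ``objective_trace_``; ``transform``
    returns the latent sample coordinates H for the fitted matrix.
    """

    def __init__(
        self,
        n_components: int = 3,
        seed: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-4,
        shift: str | None = None,
    ):
        self.n_components = n_components
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.shift = shift

    def fit(self, X, y=None) -> "MultiNMF":
        M = np.asarray(X, dtype=float)
        if self.shift is not None:
            M = nonnegative_shift(M, mode=self.shift)
        res = mnmf(M, self.n_components, self.seed, self.max_iter, self.tol)
        self.Q_ = res.Q
        self.H_ = res.H
        self.objective_trace_ = res.objective_trace
        return self

    def transform(self, X=None) -> np.ndarray:
        return self.H_


# ---------------------------------------------------------------------------
# Random forest


def rf_importance(
    matrix,
    class_labels,
    n_estimators: int = 500,
    seed: int | None = None,
    **rf_kwargs,
):
    """Random-forest feature importances for a feature x samples matrix.

    Samples (columns) are classified into ``class_labels``; returns the
    per-feature importance vector and the out-of-bag class predictions.
    Features with nonzero importance constitute the forest's selection;
    ``top_k`` ranking is a plain argsort of the importances.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(class_labels)
    if X.ndim != 2 or X.shape[1] != len(y):
        raise ValueError("matrix must be features x samples matching labels")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=seed, **rf_kwargs
    )
    clf.fit(X.T, y)
    oob = clf.classes_[np.nanargmax(clf.oob_decision_function_, axis=1)]
    return clf.feature_importances_, oob


class RandomForestFE:
    """Feature selector by nonzero random-forest importance (or top-k)."""

    def __init__(
        self,
        class_labels,
        n_estimators: int = 500,
        seed: int | None = None,
        top_k: int | None = None,
    ):
        self.class_labels = class_labels
        self.n_estimators = n_estimators
        self.seed = seed
        self.top_k = top_k

    def fit(self, X, y=None) -> "RandomForestFE":
        M = X
        if not (isinstance(X, np.ndarray) and X.ndim == 2):
            t = as_omics_tensor(X)
            M = t.unfold(t.feature_mode)
        imp, oob = rf_importance(
            M, self.class_labels, self.n_estimators, self.seed
        )
        self.importances_ = imp
        self.oob_predictions_ = oob
        if self.top_k is None:
            self.support_ = imp > 0
        else:
            self.support_ = np.zeros(len(imp), dtype=bool)
            order = np.argsort(imp)[::-1][: self.top_k]
            self.support_[order] = True
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        return np.flatnonzero(self.support_) if indices else self.support_


# ---------------------------------------------------------------------------
# LOO-LDA evaluation


@dataclass
class LOOLDAResult:
    error_rate: float
    confusion: pd.DataFrame


def loo_lda_eval(
    tensor,
    selected,
    class_labels,
    index_ranges: Sequence[int] | None = None,
) -> LOOLDAResult:
    """Leave-one-out LDA over sample classes from sample-factor products.

    The tensor is restricted to the selected features and re-decomposed by
    HOSVD; each sample (one cell of the sample-mode grid) is represented by
    the products of its sample-mode singular-vector coordinates,
    u_{l1 j} * u_{l2 k} * u_{l3 m}, over all index combinations up to
    ``index_ranges`` (default: the full rank of every sample mode).  A
    leave-one-out cross-validated linear discriminant analysis over
    ``class_labels`` (one label per flattened sample, C order over the
    sample modes) yields the error rate and the class confusion matrix.
    """
    t = as_omics_tensor(tensor)
    selected = np.asarray(selected, dtype=bool)
    if selected.shape != (t.n_features,):
        raise ValueError("selected mask must match the feature dimension")
    if not selected.any():
        raise ValueError("no features selected")
    y = np.asarray(class_labels)
    sample_shape = tuple(t.shape[m] for m in t.sample_modes)
    if len(y) != int(np.prod(sample_shape)):
        raise ValueError("one class label per sample required")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least two members for LOO-LDA")

    restricted = np.compress(selected, t.values, axis=t.feature_mode)
    ranks = [
        1 if m == t.feature_mode else min(restricted.shape[m], restricted.size // restricted.shape[m])
        for m in range(t.ndim)
    ]
    dec = hosvd(restricted, ranks)
    sample_factors = [dec.factors[m] for m in t.sample_modes]
    if index_ranges is None:
        index_ranges = [U.shape[1] for U in sample_factors]
    index_ranges = [int(r) for r in index_ranges]
    for r, U in zip(index_ranges, sample_factors):
        if not 1 <= r <= U.shape[1]:
            raise ValueError("index range exceeds available singular vectors")

    # per-sample product features: outer product of the truncated factor rows
    feats = None
    for U, r in zip(sample_factors, index_ranges):
        block = U[:, :r]  # levels x r
        if feats is None:
            feats = block
        else:
            feats = (feats[:, None, :, None] * block[None, :, None, :]).reshape(
                feats.shape[0] * block.shape[0], feats.shape[1] * r
            )
    X_lda = feats

    pred = cross_val_predict(
        LinearDiscriminantAnalysis(), X_lda, y, cv=LeaveOneOut()
    )
    err = float(np.mean(pred != y))
    cm = _sk_confusion(y, pred, labels=classes)
    return LOOLDAResult(
        error_rate=err,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
    )
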
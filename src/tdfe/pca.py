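"""PCA-based unsupervised feature extraction: the matrix-variant baseline.

The tensor is unfolded on the feature mode into a feature x samples matrix
and decomposed by an (uncentered, by default) SVD.  Naming follows the
multiomics-FE convention, which is the reverse of the usual PCA one:
"scores" are the feature-mode coordinates (used for the chi-squared
attribution) and "loadings" are the sample-mode coordinates (inspected for
the contrast of interest).  On a 3-mode tensor whose sample structure is a
plain grid this reduces to the same feature-mode singular vectors as HOSVD,
so PCA-FE and TD-FE select identical feature sets there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .hosvd import unfold
from .selection import SelectionResult
from .stats import assign_pvalues, bh_adjust, score_class_separation
from .tensor import as_omics_tensor

__all__ = ["PCAResult", "PCAFE", "run_pca_fe"]


@dataclass
class PCAResult:
    """Feature-mode scores, orthonormal sample-mode loadings, singular values."""

    scores: np.ndarray  # features x n_components (U * s)
    loadings: np.ndarray  # samples x n_components (columns orthonormal)
    singular_values: np.ndarray
    n_components: int


class PCAFE(BaseEstimator):
    """Unsupervised feature selector from the SVD of the unfolded tensor.

    Parameters
    ----------
    alpha : float, default 0.01
        BH-adjusted p-value threshold (strict inequality).
    loading_index : int or None, default 1
        1-based component whose score vector is used for the attribution;
        ``None`` chooses the component whose loading maximizes eta-squared
        against ``sample_class_labels``.
    sample_class_labels : sequence or None
        Per-sample (flattened, C order over the sample modes) categorical
        labels for the automatic choice.
    n_components : int, default 10
        Components to retain.
    center : bool, default False
        Subtract each sample column's mean over features before the SVD.
        Off by default, mirroring the (uncentered) HOSVD.
    dof, sigma_centered
        Passed to the chi-squared attribution.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        loading_index: int | None = 1,
        sample_class_labels: Sequence | None = None,
        n_components: int = 10,
        center: bool = False,
        dof: int = 1,
        sigma_centered: bool = True,
    ):
        self.alpha = alpha
        self.loading_index = loading_index
        self.sample_class_labels = sample_class_labels
        self.n_components = n_components
        self.center = center
        self.dof = dof
        self.sigma_centered = sigma_centered

    def fit(self, X, y=None) -> "PCAFE":
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        t = as_omics_tensor(X)
        M = unfold(t.values, t.feature_mode)
        if self.center:
            M = M - M.mean(axis=0, keepdims=True)
        if not np.any(M):
            raise ValueError("zero-variance matrix: nothing to decompose")
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        k = min(self.n_components, s.size)
        # sign convention matching HOSVD: largest |entry| of each score
        # column positive
        flip = np.abs(U).argmax(axis=0)
        signs = np.sign(U[flip, np.arange(U.shape[1])])
        signs[signs == 0] = 1.0
        U, Vt = U * signs, Vt * signs[:, None]
        self.pca_ = PCAResult(
            scores=U[:, :k] * s[:k],
            loadings=Vt[:k].T,
            singular_values=s[:k],
            n_components=k,
        )

        if self.loading_index is not None:
            ell = int(self.loading_index)
            if not 1 <= ell <= k:
                raise ValueError(f"loading_index {ell} out of range (1..{k})")
        elif self.sample_class_labels is not None:
            etas = [
                score_class_separation(self.pca_.loadings[:, c], self.sample_class_labels)
                for c in range(k)
            ]
            ell = int(np.argmax(etas)) + 1
        else:
            ell = 1
        self.component_index_ = ell
        u = self.pca_.scores[:, ell - 1]
        self.scores_ = u
        self.sigma_ = (
            float(np.std(u, ddof=1))
            if self.sigma_centered
            else float(np.sqrt(np.mean(u**2)))
        )
        self.p_values_ = assign_pvalues(u, dof=self.dof, center=self.sigma_centered)
        self.p_adjusted_ = bh_adjust(self.p_values_)
        self.support_ = self.p_adjusted_ < self.alpha
        self.n_features_in_ = t.n_features
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    def transform(self, X) -> np.ndarray:
        t = as_omics_tensor(X)
        if t.n_features != self.n_features_in_:
            raise ValueError("feature dimension differs from the fitted tensor")
        return np.compress(self.support_, t.values, axis=t.feature_mode)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def result_(self) -> SelectionResult:
        return SelectionResult(
            feature_vector_index=self.component_index_,
            p=self.p_values_,
            p_adj=self.p_adjusted_,
            selected=self.support_,
            sigma=self.sigma_,
            sample_vector_indices=(self.component_index_,),
            scores=self.scores_,
            audit={"alpha": self.alpha, "dof": self.dof, "method": "pca"},
        )


def run_pca_fe(tensor, loading_index: int | None = 1, alpha: float = 0.01, **kwargs) -> SelectionResult:
    """One-call PCA-FE pipeline; see :class:`PCAFE`."""
    est = PCAFE(alpha=alpha, loading_index=loading_index, **kwargs)
    est.fit(tensor)
    return est.result_()
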
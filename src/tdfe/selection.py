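"""Tensor-decomposition-based unsupervised feature extraction (TD-FE).

The pipeline: HOSVD of the multiomics tensor; identification of the
sample-mode singular value vectors that express the contrast of interest
(three tissue groups, tumour vs normal, constancy across replicates);
screening of the core tensor G along the feature mode with the sample-mode
indices fixed, to find the feature-mode singular value vector that co-varies
with them; chi-squared attribution of per-feature p-values from that
vector's standardized coordinates; BH correction; and selection of features
with adjusted p below a threshold.

All singular-vector indices on the public surface are 1-based (the first
singular value vector of the tissue mode is "u1", selected with index 1);
arrays are of course 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .hosvd import HOSVDResult, hosvd
from .stats import assign_pvalues, bh_adjust, score_class_separation
from .tensor import OmicsTensor, as_omics_tensor

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "TensorFE",
    "screen_core",
    "choose_sample_vectors",
    "run_tdfe",
]


@dataclass
class SelectionConfig:
    """Configuration of one TD-FE run.

    ``sample_vector_indices`` are 1-based, one per non-feature mode in
    ascending mode order; ``None`` triggers automatic choice via
    eta-squared when ``sample_labels`` are given, else the primary (first)
    vector of each sample mode.
    """

    sample_vector_indices: tuple[int, ...] | None = None
    alpha: float = 0.01
    dof: int = 1
    sigma_centered: bool = True
    sample_labels: Mapping[int, Sequence] | None = None
    feature_rank: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if self.feature_rank < 1:
            raise ValueError("feature_rank must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of a TD-FE (or PCA-FE) selection."""

    feature_vector_index: int  # 1-based
    p: np.ndarray
    p_adj: np.ndarray
    selected: np.ndarray
    sigma: float
    sample_vector_indices: tuple[int, ...] = ()
    scores: np.ndarray | None = None
    audit: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self, feature_ids: Sequence | None = None) -> pd.DataFrame:
        n = len(self.p)
        ids = np.arange(1, n + 1) if feature_ids is None else list(feature_ids)
        return pd.DataFrame(
            {
                "feature_id": ids,
                "u": self.scores if self.scores is not None else np.full(n, np.nan),
                "p": self.p,
                "p_adj": self.p_adj,
                "selected": self.selected.astype(int),
            }
        )

    def write(self, prefix: str, feature_ids: Sequence | None = None) -> None:
        """Write ``<prefix>.tsv`` (per-feature table) and ``<prefix>.audit.json``."""
        self.to_frame(feature_ids).to_csv(f"{prefix}.tsv", sep="\t", index=False)
        audit = {
            "feature_vector_index": int(self.feature_vector_index),
            "sample_vector_indices": [int(i) for i in self.sample_vector_indices],
            "sigma": float(self.sigma),
            "n_selected": self.n_selected,
        }
        audit.update(self.audit)
        with open(f"{prefix}.audit.json", "w") as fh:
            json.dump(audit, fh, indent=2)


def screen_core(core: np.ndarray, fixed: Sequence[int], free_mode: int) -> int:
    """Find the feature-mode vector sharing the largest |G| with fixed sample vectors.

    Parameters
    ----------
    core
        The HOSVD core tensor.
    fixed
        1-based singular-vector indices for every mode except ``free_mode``,
        in ascending mode order.
    free_mode
        The feature mode, left free.

    Returns
    -------
    int
        1-based index of the argmax of ``|G|`` along the free mode; ties
        break toward the smaller index.
    """
    core = np.asarray(core)
    if not 0 <= free_mode < core.ndim:
        raise ValueError("free_mode out of range")
    if len(fixed) != core.ndim - 1:
        raise ValueError("one fixed index per non-free mode required")
    index: list = []
    it = iter(fixed)
    for m in range(core.ndim):
        if m == free_mode:
            index.append(slice(None))
        else:
            ell = int(next(it))
            if not 1 <= ell <= core.shape[m]:
                raise ValueError(f"fixed index {ell} out of range for mode {m}")
            index.append(ell - 1)
    fiber = np.abs(core[tuple(index)])
    if np.all(fiber == 0):
        raise ValueError("core fiber is identically zero: no informative component")
    return int(fiber.argmax()) + 1  # argmax returns the first (smallest) maximum


def choose_sample_vectors(
    result: HOSVDResult,
    sample_labels: Mapping[int, Sequence],
    feature_mode: int = 0,
) -> tuple[int, ...]:
    """Pick, per sample mode, the singular vector maximizing eta-squared.

    ``sample_labels`` maps mode index -> categorical labels for that mode's
    levels.  Modes without labels fall back to vector 1.  When every class
    has exactly one level (e.g. a two-level tumor/normal mode), eta-squared
    is identically 1 for any non-constant vector, so the score degenerates;
    the vector expressing the largest between-class contrast relative to
    its own norm (i.e. the least constant vector) is chosen instead.
    Returns 1-based indices in ascending mode order (feature mode excluded).
    """
    chosen: list[int] = []
    for m in range(len(result.factors)):
        if m == feature_mode:
            continue
        labels = sample_labels.get(m)
        U = result.factors[m]
        if labels is None or U.shape[1] == 1:
            chosen.append(1)
            continue
        labels_arr = np.asarray(labels)
        _, counts = np.unique(labels_arr, return_counts=True)
        if counts.max() == 1:
            # singleton classes: rank by non-constancy of the unit vector
            scores = [
                float(np.sum((U[:, c] - U[:, c].mean()) ** 2))
                / float(np.sum(U[:, c] ** 2))
                for c in range(U.shape[1])
            ]
        else:
            scores = [
                score_class_separation(U[:, c], labels_arr)
                for c in range(U.shape[1])
            ]
        chosen.append(int(np.argmax(scores)) + 1)
    return tuple(chosen)


class TensorFE(BaseEstimator):
    """Unsupervised feature selector built on HOSVD of a multiomics tensor.

    Fits on an :class:`~tdfe.tensor.OmicsTensor` (or plain ndarray whose
    first axis is the feature axis) and exposes the selected-feature mask as
    ``support_``; ``transform`` restricts a tensor to the selected features.

    Parameters
    ----------
    alpha : float, default 0.01
        Threshold on BH-adjusted p-values; selection is strict (p_adj < alpha).
    sample_vectors : tuple of int or None
        1-based singular-vector index per sample mode.  None means choose
        automatically with ``sample_labels`` if given, else use the primary
        vector of each sample mode.
    sample_labels : mapping {mode: labels} or None
        Categorical level labels per sample mode for the automatic
        eta-squared choice.
    feature_rank : int, default 10
        Number of feature-mode singular vectors computed and screened; the
        full feature-mode factor is never materialised.
    dof : int, default 1
        Chi-squared degrees of freedom of the null.
    sigma_centered : bool, default True
        Whether sigma removes the mean of the feature-mode vector.

    Attributes
    ----------
    hosvd_ : HOSVDResult
    sample_vector_indices_ : tuple of int (1-based)
    feature_vector_index_ : int (1-based)
    scores_ : ndarray, the chosen feature-mode singular value vector
    sigma_ : float
    p_values_, p_adjusted_ : ndarray
    support_ : boolean ndarray over features
    """

    def __init__(
        self,
        alpha: float = 0.01,
        sample_vectors: tuple[int, ...] | None = None,
        sample_labels: Mapping[int, Sequence] | None = None,
        feature_rank: int = 10,
        dof: int = 1,
        sigma_centered: bool = True,
    ):
        self.alpha = alpha
        self.sample_vectors = sample_vectors
        self.sample_labels = sample_labels
        self.feature_rank = feature_rank
        self.dof = dof
        self.sigma_centered = sigma_centered

    def fit(self, X, y=None) -> "TensorFE":
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        t = as_omics_tensor(X)
        fm = t.feature_mode
        ranks = [
            min(t.shape[m], self.feature_rank)
            if m == fm
            else min(t.shape[m], t.values.size // t.shape[m])
            for m in range(t.ndim)
        ]
        self.hosvd_ = hosvd(t, ranks)

        if self.sample_vectors is not None:
            sv = tuple(int(i) for i in self.sample_vectors)
            if len(sv) != t.ndim - 1:
                raise ValueError("one sample-vector index per sample mode required")
            for i, m in enumerate(t.sample_modes):
                if not 1 <= sv[i] <= self.hosvd_.ranks[m]:
                    raise ValueError(f"sample vector index {sv[i]} out of range")
        elif self.sample_labels is not None:
            sv = choose_sample_vectors(self.hosvd_, dict(self.sample_labels), fm)
        else:
            sv = tuple(1 for _ in t.sample_modes)
        self.sample_vector_indices_ = sv

        self.feature_vector_index_ = screen_core(self.hosvd_.core, sv, fm)
        u = self.hosvd_.factors[fm][:, self.feature_vector_index_ - 1]
        self.scores_ = u
        if self.sigma_centered:
            self.sigma_ = float(np.std(u, ddof=1))
        else:
            self.sigma_ = float(np.sqrt(np.mean(u**2)))
        self.p_values_ = assign_pvalues(u, dof=self.dof, center=self.sigma_centered)
        self.p_adjusted_ = bh_adjust(self.p_values_)
        self.support_ = self.p_adjusted_ < self.alpha
        self.n_features_in_ = t.n_features
        self._feature_mode = fm
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    def transform(self, X) -> np.ndarray:
        """Restrict a tensor (or array) to the selected features."""
        t = as_omics_tensor(X)
        if t.n_features != self.n_features_in_:
            raise ValueError("feature dimension differs from the fitted tensor")
        return np.compress(self.support_, t.values, axis=t.feature_mode)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def result_(self) -> SelectionResult:
        """Bundle the fitted attributes as a :class:`SelectionResult`."""
        return SelectionResult(
            feature_vector_index=self.feature_vector_index_,
            p=self.p_values_,
            p_adj=self.p_adjusted_,
            selected=self.support_,
            sigma=self.sigma_,
            sample_vector_indices=self.sample_vector_indices_,
            scores=self.scores_,
            audit={"alpha": self.alpha, "dof": self.dof},
        )


def run_tdfe(tensor: OmicsTensor, config: SelectionConfig | None = None) -> SelectionResult:
    """One-call TD-FE pipeline over a tensor; see :class:`TensorFE`."""
    config = config or SelectionConfig()
    est = TensorFE(
        alpha=config.alpha,
        sample_vectors=config.sample_vector_indices,
        sample_labels=config.sample_labels,
        feature_rank=config.feature_rank,
        dof=config.dof,
        sigma_centered=config.sigma_centered,
    )
    est.fit(tensor)
    return est.result_()
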
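"""Higher-order singular value decomposition (HOSVD).

The Tucker-form decomposition used throughout this package: the factor
matrix of each mode is the left singular basis of that mode's unfolding,
and the core tensor is the data contracted with every factor transpose,

    x = G x_0 U_0 x_1 U_1 ... x_{n-1} U_{n-1},

so that at full ranks the reconstruction is exact.  Large |G(l_0, l_1, ...)|
indicates that the corresponding singular value vectors co-vary in the data;
downstream selection screens the core along the feature mode for exactly
this.

The feature mode of a genome-scale tensor is huge (10^5 windows); only the
leading feature-mode singular vectors are ever needed, so the feature factor
is truncated (default handled by callers) and a full p x p orthogonal matrix
is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .tensor import OmicsTensor, as_omics_tensor

__all__ = ["unfold", "refold", "hosvd", "HOSVDResult"]


def unfold(values: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricisation of a dense array.

    Rows are the fibers of ``mode``; columns run over the remaining modes in
    ascending index order, last mode fastest (C order).  This ordering is the
    contract relied upon by :func:`refold` and by the matrix-based methods
    (PCA, NMF, per-feature regression) that operate on the feature-mode
    unfolding.
    """
    values = np.asarray(values)
    if not 0 <= mode < values.ndim:
        raise ValueError(f"mode {mode} invalid for a {values.ndim}-mode array")
    return np.moveaxis(values, mode, 0).reshape(values.shape[mode], -1)


def refold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given full shape."""
    shape = tuple(shape)
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode {mode} invalid for shape {shape}")
    rest = shape[:mode] + shape[mode + 1 :]
    return np.moveaxis(np.reshape(matrix, (shape[mode],) + rest), 0, mode)


def _mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Contract ``matrix`` (a x b) with ``tensor`` along ``mode`` (length b)."""
    out = np.tensordot(matrix, tensor, axes=(1, mode))
    return np.moveaxis(out, 0, mode)


@dataclass
class HOSVDResult:
    """Per-mode factor matrices, retained ranks, and the core tensor.

    ``factors[m]`` has orthonormal columns (the leading left singular
    vectors of the mode-m unfolding); ``core`` has shape ``ranks``.  Column
    signs are fixed so that each column's largest-magnitude entry is
    positive, with the core adjusted to keep the reconstruction identical.
    """

    factors: list[np.ndarray]
    core: np.ndarray
    ranks: tuple[int, ...]
    singular_values: list[np.ndarray]

    def reconstruct(self) -> np.ndarray:
        """Multilinear product of the core with all factors."""
        out = self.core
        for m, U in enumerate(self.factors):
            out = _mode_dot(out, U, m)
        return out

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["ranks"] = list(self.ranks)
            fh.create_dataset("core", data=self.core)
            for m, U in enumerate(self.factors):
                fh.create_dataset(f"factors/mode{m}", data=U)
                fh.create_dataset(
                    f"singular_values/mode{m}", data=self.singular_values[m]
                )

    @classmethod
    def from_hdf5(cls, path) -> "HOSVDResult":
        with h5py.File(path, "r") as fh:
            ranks = tuple(int(r) for r in fh.attrs["ranks"])
            core = fh["core"][...]
            factors = [fh[f"factors/mode{m}"][...] for m in range(len(ranks))]
            svals = [fh[f"singular_values/mode{m}"][...] for m in range(len(ranks))]
        return cls(factors, core, ranks, svals)


def hosvd(tensor, ranks: Sequence[int] | None = None) -> HOSVDResult:
    """Higher-order SVD of a dense tensor.

    Parameters
    ----------
    tensor
        :class:`~tdfe.tensor.OmicsTensor` or array-like.
    ranks
        Per-mode number of singular vectors to retain; ``None`` keeps the
        full rank ``min(dim_m, prod(other dims))`` for every mode.

    Returns
    -------
    HOSVDResult
        Orthonormal factors, per-mode singular values, and the core tensor
        contracted with the factor transposes on every mode.
    """
    t = as_omics_tensor(tensor)
    x = t.values
    if ranks is None:
        ranks = [min(x.shape[m], x.size // x.shape[m]) for m in range(x.ndim)]
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != x.ndim:
        raise ValueError("one rank per mode required")
    for m, r in enumerate(ranks):
        if not 1 <= r <= x.shape[m]:
            raise ValueError(f"rank {r} out of range for mode {m}")

    factors: list[np.ndarray] = []
    svals: list[np.ndarray] = []
    for m in range(x.ndim):
        M = unfold(x, m)
        # economy SVD: for a p x q unfolding this costs O(p q min(p, q)),
        # cheap even at p = 1e5 since the sample modes keep q small
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        factors.append(np.ascontiguousarray(U[:, : ranks[m]]))
        svals.append(s[: ranks[m]].copy())

    core = x
    for m, U in enumerate(factors):
        core = _mode_dot(core, U.T, m)

    # sign convention: largest-magnitude entry of each column positive
    for m, U in enumerate(factors):
        flip = np.abs(U).argmax(axis=0)
        signs = np.sign(U[flip, np.arange(U.shape[1])])
        signs[signs == 0] = 1.0
        U *= signs
        shape = [1] * core.ndim
        shape[m] = core.shape[m]
        core = core * signs.reshape(shape)

    return HOSVDResult(factors, core, ranks, svals)
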
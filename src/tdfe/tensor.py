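"""Dense labelled multiomics tensors.

An :class:`OmicsTensor` is a plain dense n-mode array together with mode
names, per-mode level labels and a marked feature mode.  For a typical
multiomics design the modes are (feature, omics_group, tissue, replicate):
the feature mode is large (genes or genomic windows, 10^5 and up) while the
sample modes are small (a handful of assays, tissues and replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import h5py
import numpy as np

__all__ = ["OmicsTensor"]


@dataclass
class OmicsTensor:
    """Dense n-mode array with named modes and per-mode level labels.

    Parameters
    ----------
    values
        The dense data array.  Any order >= 2 is accepted.
    mode_names
        One name per mode, e.g. ``("feature", "tissue", "disease")``.
    level_labels
        Optional per-mode label sequences; each must match the mode length.
        Modes without labels get ``None``.
    feature_mode
        Index of the (large) feature axis.  Defaults to 0.
    metadata
        Free-form dictionary; the synthetic generator stores the
        ground-truth signal mask here under ``"truth_mask"``.
    """

    values: np.ndarray
    mode_names: tuple[str, ...] | None = None
    level_labels: tuple[Sequence | None, ...] | None = None
    feature_mode: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2:
            raise ValueError("an OmicsTensor needs at least two modes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor values must be finite")
        if self.mode_names is None:
            self.mode_names = tuple(f"mode{m}" for m in range(self.values.ndim))
        self.mode_names = tuple(self.mode_names)
        if len(self.mode_names) != self.values.ndim:
            raise ValueError(
                f"{len(self.mode_names)} mode names for a "
                f"{self.values.ndim}-mode tensor"
            )
        if self.level_labels is None:
            self.level_labels = tuple(None for _ in range(self.values.ndim))
        self.level_labels = tuple(
            None if lab is None else tuple(lab) for lab in self.level_labels
        )
        if len(self.level_labels) != self.values.ndim:
            raise ValueError("one label sequence (or None) per mode required")
        for m, lab in enumerate(self.level_labels):
            if lab is not None and len(lab) != self.values.shape[m]:
                raise ValueError(
                    f"mode {m} has {self.values.shape[m]} levels but "
                    f"{len(lab)} labels"
                )
        if not 0 <= self.feature_mode < self.values.ndim:
            raise ValueError(f"feature_mode {self.feature_mode} out of range")

    # -- basic views ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def n_features(self) -> int:
        return self.values.shape[self.feature_mode]

    @property
    def sample_modes(self) -> tuple[int, ...]:
        """Indices of all non-feature modes, in ascending order."""
        return tuple(m for m in range(self.ndim) if m != self.feature_mode)

    def unfold(self, mode: int) -> np.ndarray:
        """Mode-``mode`` matricisation, see :func:`tdfe.hosvd.unfold`."""
        from .hosvd import unfold

        return unfold(self.values, mode)

    # -- persistence ------------------------------------------------------

    def to_hdf5(self, path) -> None:
        """Write values, mode names, labels and metadata to an HDF5 file."""
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=self.values)
            fh.attrs["feature_mode"] = self.feature_mode
            fh.attrs["mode_names"] = [str(n) for n in self.mode_names]
            for m, lab in enumerate(self.level_labels):
                if lab is not None:
                    fh.create_dataset(
                        f"level_labels/mode{m}",
                        data=np.asarray([str(x) for x in lab], dtype="S"),
                    )
            truth = self.metadata.get("truth_mask")
            if truth is not None:
                fh.create_dataset("truth_mask", data=np.asarray(truth, dtype=bool))

    @classmethod
    def from_hdf5(cls, path) -> "OmicsTensor":
        with h5py.File(path, "r") as fh:
            values = fh["values"][...]
            feature_mode = int(fh.attrs["feature_mode"])
            mode_names = tuple(str(n) for n in fh.attrs["mode_names"])
            labels: list[tuple | None] = []
            for m in range(values.ndim):
                key = f"level_labels/mode{m}"
                if key in fh:
                    labels.append(tuple(x.decode() for x in fh[key][...]))
                else:
                    labels.append(None)
            metadata: dict[str, Any] = {}
            if "truth_mask" in fh:
                metadata["truth_mask"] = fh["truth_mask"][...].astype(bool)
        return cls(values, mode_names, tuple(labels), feature_mode, metadata)


def as_omics_tensor(X, feature_mode: int = 0) -> OmicsTensor:
    """Coerce an array-like (or pass through an OmicsTensor)."""
    if isinstance(X, OmicsTensor):
        return X
    return OmicsTensor(np.asarray(X, dtype=float), feature_mode=feature_mode)
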
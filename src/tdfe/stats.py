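"""Statistical primitives shared by the selection pipelines.

The chi-squared attribution converts the coordinates of a chosen
feature-mode singular value vector u into per-feature p-values: under the
null that a feature carries no structure, its standardized coordinate
u_i / sigma is treated as a standard Gaussian, so (u_i / sigma)^2 is
chi-squared with one degree of freedom.  Features in the far tail — those
that dominate the singular vector — get small p-values.  Benjamini–Hochberg
step-up correction then controls the false discovery rate across the 10^5
features.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["assign_pvalues", "bh_adjust", "score_class_separation"]


def assign_pvalues(u, dof: int = 1, center: bool = True) -> np.ndarray:
    """Upper-tail chi-squared p-values for standardized vector coordinates.

    Parameters
    ----------
    u
        Feature-mode singular value vector (or PC score vector).
    dof
        Degrees of freedom of the chi-squared null.  The default 1 treats
        each feature's single standardized coordinate as one squared
        Gaussian.
    center
        If True (default), sigma is the mean-removed standard deviation of
        ``u``; if False, the raw root-mean-square.  The coordinates
        themselves are never centered.

    Returns
    -------
    ndarray
        ``p_i = P[chi2_dof > (u_i / sigma)^2]``.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("u must be a 1-D vector")
    if not np.all(np.isfinite(u)):
        raise ValueError("u must be finite")
    if center:
        sigma = float(np.std(u, ddof=1)) if u.size > 1 else 0.0
    else:
        sigma = float(np.sqrt(np.mean(u**2)))
    if sigma == 0.0:
        raise ValueError("zero standard deviation: no variation to score")
    return sps.chi2.sf((u / sigma) ** 2, df=dof)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def score_class_separation(vector, labels) -> float:
    """Eta-squared: between-class sum of squares over total sum of squares.

    Used to rank candidate sample-mode singular value vectors by how well
    they separate a categorical labelling (e.g. the three tissue groups).
    Returns a value in [0, 1]; 1 means the vector is constant within every
    class and distinct between classes.
    """
    v = np.asarray(vector, dtype=float)
    labels = np.asarray(labels)
    if v.ndim != 1 or labels.shape != v.shape:
        raise ValueError("vector and labels must be 1-D and the same length")
    classes, inverse = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    grand = v.mean()
    total = float(np.sum((v - grand) ** 2))
    if total == 0.0:
        raise ValueError("zero total variance: eta-squared undefined")
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=v)
    means = sums / counts
    between = float(np.sum(counts * (means - grand) ** 2))
    return between / total
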
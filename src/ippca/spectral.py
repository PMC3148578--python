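"""Sample covariance, eigen-decomposition and variance-fraction rank selection.

The covariance is taken between individuals, ``C = (1/n) X X^T`` with ``X``
the m x n encoded genotype matrix, because the number of individuals m is
typically far below the number of allele columns n.  The 1/n scale is a
convention only: both structure criteria downstream are invariant to uniform
scaling of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ippca.exceptions import IppcaError, NoVariationError
from ippca.genotype_io import EncodedMatrix

#: relative floor below which trailing eigenvalues are considered numerically
#: zero (centering always produces at least one) and excluded before any log.
EIGENVALUE_REL_TOL = 1e-12

__all__ = [
    "EIGENVALUE_REL_TOL",
    "EigenSpectrum",
    "RankSelection",
    "covariance",
    "eigendecompose",
    "select_rank",
]


@dataclass
class EigenSpectrum:
    """Descending eigenvalues of C with principal axes and projections.

    ``projections[i, k] = axes[i, k] * sqrt(eigenvalues[k])`` so that pairwise
    Euclidean distances between rows of ``projections`` reproduce the Gram
    geometry of C exactly.
    """

    eigenvalues: np.ndarray
    axes: np.ndarray
    projections: np.ndarray
    total_variance: float


@dataclass
class RankSelection:
    """The number of leading eigenvalues covering a target variance fraction."""

    p: int
    variance_fraction: float
    achieved_fraction: float


def covariance(X: Union[EncodedMatrix, np.ndarray]) -> np.ndarray:
    """Sample covariance between individuals, ``C = (1/n) X X^T``."""
    values = X.values if isinstance(X, EncodedMatrix) else np.asarray(X, dtype=np.float64)
    m, n = values.shape
    if m < 2:
        raise IppcaError(f"need at least 2 individuals, got {m}")
    C = values @ values.T / n
    return (C + C.T) / 2.0  # enforce exact symmetry


def eigendecompose(C: np.ndarray) -> EigenSpectrum:
    """Full eigen-decomposition of a symmetric covariance matrix.

    Eigenvalues are returned in descending order and clamped at zero
    (small negative values are numerical artifacts of a PSD matrix).
    """
    C = np.asarray(C, dtype=np.float64)
    if not np.all(np.isfinite(C)):
        raise IppcaError("covariance matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    projections = vecs * np.sqrt(vals)[None, :]
    return EigenSpectrum(
        eigenvalues=vals,
        axes=vecs,
        projections=projections,
        total_variance=float(vals.sum()),
    )


def select_rank(
    spectrum: EigenSpectrum,
    variance_fraction: float = 0.90,
    m: Optional[int] = None,
    n: Optional[int] = None,
) -> RankSelection:
    """Minimal p whose leading eigenvalues cover ``variance_fraction`` of the variance.

    p is capped at ``min(m, n) - 1`` and floored at 2 (a line fit through
    fewer than two spectrum points is undefined).
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise IppcaError(f"variance_fraction must be in (0, 1], got {variance_fraction}")
    vals = spectrum.eigenvalues
    total = spectrum.total_variance
    if total <= 0.0:
        raise NoVariationError("spectrum has no variance: all individuals identical")
    cum = np.cumsum(vals) / total
    p = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    cap = len(vals)
    if m is not None and n is not None:
        cap = min(cap, min(m, n) - 1)
    p = max(2, min(p, cap))
    achieved = float(cum[p - 1])
    return RankSelection(p=p, variance_fraction=variance_fraction, achieved_fraction=achieved)
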
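"""Structure-detection criteria: the EigenDev statistic and the Tracy-Widom test.

EigenDev quantifies how far the leading part of the eigenvalue spectrum of
the sample covariance departs from the log-linear decay expected of an
unstructured sample.  With descending eigenvalues ``lambda_1 >= ... >=
lambda_p`` (p chosen to cover 90% of the variance) and ``y_i = log
lambda_i``, a least-squares line ``a*i + b`` is fitted to the points ``(i,
y_i), i = 1..p`` and

    EigenDev = sqrt( sum_i y_i^2 - sum_i (a*i + b)^2 )
             = sqrt( sum_i (y_i - a*i - b)^2 ),

the identity holding because least-squares residuals are orthogonal to the
fit.  The radicand is evaluated in the subtractive form and checked: if
rounding drives it negative, p is decremented and the fit recomputed.  Large
values signal substructure; the decision is ``statistic > threshold`` with a
strict inequality (ties resolve to homogeneous).  The statistic is invariant
to uniform scaling of the spectrum -- scaling only shifts the intercept -- so
the covariance scale convention does not matter.

The Tracy-Widom mode re-implements the largest-eigenvalue test of
EIGENSTRAT/SmartPCA: the effective number of markers is estimated from the
spectrum by moment matching, the leading eigenvalue is centered and scaled
toward the TW1 law, and structure is declared when the upper-tail p-value
falls below a cutoff (default 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ippca.exceptions import CriterionError
from ippca.genotype_io import GenotypeTable, encode_table
from ippca.spectral import (
    EIGENVALUE_REL_TOL,
    EigenSpectrum,
    RankSelection,
    covariance,
    eigendecompose,
    select_rank,
)
from ippca.tracy_widom import tw1_sf

#: operative EigenDev threshold for real data (average of the thresholds
#: achieving a 10% false-positive rate at sample sizes 100/200/500)
DEFAULT_EIGENDEV_THRESHOLD = 0.21
#: Tracy-Widom p-value cutoff for declaring structure
DEFAULT_TW_ALPHA = 1e-12
#: smallest group the TW moment matching is attempted on
TW_MIN_SAMPLES = 10

__all__ = [
    "DEFAULT_EIGENDEV_THRESHOLD",
    "DEFAULT_TW_ALPHA",
    "TW_MIN_SAMPLES",
    "LinearSpectrumFit",
    "StructureDecision",
    "eigendev",
    "decide_eigendev",
    "tw_test",
    "decide_tw",
    "eigendev_from_table",
    "tw_from_table",
]


@dataclass
class LinearSpectrumFit:
    """Least-squares line through the log spectrum points ``(i, log lambda_i)``."""

    slope: float
    intercept: float
    residuals: np.ndarray
    radicand: float
    p_used: int
    radicand_adjusted: bool = False


@dataclass
class StructureDecision:
    criterion: str  # 'eigendev' | 'tw'
    statistic: float
    threshold: float
    p_used: int
    verdict: str  # 'structured' | 'homogeneous'
    radicand_flag: bool = False
    p_value: Optional[float] = None


def _line_fit(y: np.ndarray) -> tuple[float, float, np.ndarray, float, float]:
    """Closed-form least squares of y against ranks 1..p.

    Returns (slope, intercept, residuals, radicand, sse): ``radicand`` is the
    quantity under the root evaluated subtractively as sum(y^2) - sum(fit^2)
    -- the form whose sign the algorithm checks -- and ``sse`` is the
    mathematically identical but numerically stable residual sum of squares
    used for the returned statistic.
    """
    p = len(y)
    i = np.arange(1, p + 1, dtype=np.float64)
    ibar, ybar = i.mean(), y.mean()
    sxx = np.sum((i - ibar) ** 2)
    slope = float(np.sum((i - ibar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * ibar)
    fitted = slope * i + intercept
    residuals = y - fitted
    radicand = float(np.sum(y**2) - np.sum(fitted**2))
    sse = float(np.sum(residuals**2))
    return slope, intercept, residuals, radicand, sse


def eigendev(
    spectrum: EigenSpectrum, rank: RankSelection
) -> tuple[float, LinearSpectrumFit]:
    """EigenDev of the leading ``rank.p`` eigenvalues.

    Eigenvalues below ``EIGENVALUE_REL_TOL`` times the largest are excluded
    before the log (centering always leaves at least one numerically zero
    eigenvalue).  If the subtractively-evaluated radicand comes out negative,
    p is decremented and the fit recomputed.
    """
    lam = spectrum.eigenvalues[: rank.p]
    lam = lam[lam > EIGENVALUE_REL_TOL * spectrum.eigenvalues[0]]
    p = len(lam)
    if p < 2:
        raise CriterionError(f"need >= 2 positive eigenvalues for the line fit, have {p}")
    y_full = np.log(lam)
    flagged = False
    while p >= 2:
        slope, intercept, residuals, radicand, sse = _line_fit(y_full[:p])
        if radicand >= 0.0 or np.isclose(radicand, 0.0, atol=1e-9):
            value = float(np.sqrt(sse))
            return value, LinearSpectrumFit(slope, intercept, residuals, radicand, p, flagged)
        flagged = True
        p -= 1
    raise CriterionError("radicand negative for every admissible p")


def decide_eigendev(
    value: float, threshold: float = DEFAULT_EIGENDEV_THRESHOLD, p_used: int = 0,
    radicand_flag: bool = False,
) -> StructureDecision:
    """Structured iff EigenDev strictly exceeds the threshold."""
    if not np.isfinite(value):
        raise CriterionError(f"non-finite EigenDev value: {value}")
    verdict = "structured" if value > threshold else "homogeneous"
    return StructureDecision(
        criterion="eigendev",
        statistic=float(value),
        threshold=float(threshold),
        p_used=p_used,
        verdict=verdict,
        radicand_flag=radicand_flag,
    )


def _tw_moments(m_prime: int, n_eff: float) -> tuple[float, float]:
    """Centering and scaling constants carrying the leading eigenvalue to TW1.

    All TW-specific constants live here: with m' samples-minus-one and n_eff
    the moment-matched effective marker count,

        mu    = (sqrt(n_eff - 1) + sqrt(m'))^2 / n_eff
        sigma = (sqrt(n_eff - 1) + sqrt(m')) / n_eff
                * (1/sqrt(n_eff - 1) + 1/sqrt(m'))^(1/3)
    """
    rn = np.sqrt(n_eff - 1.0)
    rm = np.sqrt(m_prime)
    mu = (rn + rm) ** 2 / n_eff
    sigma = (rn + rm) / n_eff * (1.0 / rn + 1.0 / rm) ** (1.0 / 3.0)
    return float(mu), float(sigma)


def tw_test(spectrum: EigenSpectrum, m: int, n: int) -> tuple[float, float]:
    """Normalized largest-eigenvalue statistic and its TW1 upper-tail p-value.

    Follows the EIGENSTRAT/SmartPCA recipe: the m-1 eigenvalues of the
    individual-by-individual covariance give a moment-matched effective
    marker count  n_eff = (m+1) S1^2 / ((m-1) S2 - S1^2)  (S1, S2 the
    spectrum's first two power sums); the leading eigenvalue, normalized as
    l = (m-1) lambda_1 / S1, is then centered and scaled toward TW1.
    """
    if m < TW_MIN_SAMPLES:
        raise CriterionError(f"TW test needs at least {TW_MIN_SAMPLES} individuals, got {m}")
    lam = spectrum.eigenvalues[: m - 1]
    lam = lam[lam > 0.0]
    m_prime = len(lam)
    if m_prime < 2:
        raise CriterionError("TW test needs at least 2 positive eigenvalues")
    s1 = float(lam.sum())
    s2 = float(np.sum(lam**2))
    denom = (m - 1) * s2 - s1**2
    if denom <= 0.0 or s1 <= 0.0:
        raise CriterionError("degenerate spectrum: effective marker count undefined")
    n_eff = (m + 1) * s1**2 / denom
    if n_eff <= 1.0:
        raise CriterionError(f"effective marker count {n_eff:.3g} too small for TW")
    ell = m_prime * float(lam[0]) / s1
    mu, sigma = _tw_moments(m_prime, n_eff)
    stat = (ell - mu) / sigma
    return float(stat), float(tw1_sf(stat))


def decide_tw(
    statistic: float, p_value: float, alpha: float = DEFAULT_TW_ALPHA, p_used: int = 1
) -> StructureDecision:
    """Structured iff the TW p-value falls strictly below the cutoff."""
    if not (np.isfinite(statistic) and np.isfinite(p_value)):
        raise CriterionError("non-finite TW statistic or p-value")
    verdict = "structured" if p_value < alpha else "homogeneous"
    return StructureDecision(
        criterion="tw",
        statistic=float(statistic),
        threshold=float(alpha),
        p_used=p_used,
        verdict=verdict,
        p_value=float(p_value),
    )


# ---------------------------------------------------------------------------
# Table-level convenience pipelines (shared by the engine and the experiments)
# ---------------------------------------------------------------------------


def eigendev_from_table(
    table: GenotypeTable, variance_fraction: float = 0.90
) -> tuple[float, LinearSpectrumFit]:
    """Encode, center/normalize, decompose and compute EigenDev for a table."""
    enc = encode_table(table)
    spectrum = eigendecompose(covariance(enc))
    rank = select_rank(spectrum, variance_fraction, m=enc.m, n=enc.n)
    return eigendev(spectrum, rank)


def tw_from_table(table: GenotypeTable) -> tuple[float, float]:
    """Encode, center/normalize, decompose and run the TW test for a table."""
    enc = encode_table(table)
    spectrum = eigendecompose(covariance(enc))
    return tw_test(spectrum, enc.m, enc.n)
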
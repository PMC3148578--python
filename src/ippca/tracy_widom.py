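"""The Tracy-Widom GOE (beta = 1) law for the largest sample-covariance eigenvalue.

The distribution itself has no closed form; it is evaluated from an embedded
knot table of log survival values precomputed from the Painleve II
representation (see ``scripts/build_tw1_table.py``), with monotone PCHIP
interpolation on the log scale.  Beyond the right end of the table the
first-order large-deviation asymptote

    S(s) ~ exp(-(2/3) s^{3/2}) / (4 sqrt(pi) s^{3/4})

takes over, so upper-tail p-values remain usable far below 1e-15.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from ippca import _tw1_table

__all__ = ["tw1_sf", "tw1_cdf", "tw1_isf", "TW1_MEAN"]

#: mean of the TW1 law (for reference and sanity checks)
TW1_MEAN = -1.2065335746

_S = _tw1_table.S_MIN + _tw1_table.S_STEP * np.arange(len(_tw1_table.LOG_SF))
_LOG_SF = np.asarray(_tw1_table.LOG_SF, dtype=np.float64)
_INTERP = PchipInterpolator(_S, _LOG_SF)
_S_LO, _S_HI = float(_S[0]), float(_S[-1])


def _log_sf_asymptotic(s: np.ndarray) -> np.ndarray:
    return -(2.0 / 3.0) * s**1.5 - np.log(4.0 * np.sqrt(np.pi)) - 0.75 * np.log(s)


def tw1_sf(x):
    """Upper-tail probability P(TW1 > x)."""
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    lo = x <= _S_LO
    hi = x >= _S_HI
    mid = ~lo & ~hi
    out[lo] = 1.0
    out[mid] = np.exp(_INTERP(x[mid]))
    out[hi] = np.exp(_log_sf_asymptotic(x[hi]))
    return float(out[0]) if scalar else out


def tw1_cdf(x):
    """P(TW1 <= x)."""
    return 1.0 - tw1_sf(x)


def tw1_isf(p: float) -> float:
    """The value s with P(TW1 > s) = p (inverse survival function)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    logp = np.log(p)
    if logp <= _LOG_SF[-1]:
        return float(brentq(lambda s: _log_sf_asymptotic(np.asarray(s)) - logp, _S_HI, 200.0))
    if logp >= _LOG_SF[0]:
        return _S_LO
    return float(brentq(lambda s: _INTERP(s) - logp, _S_LO, _S_HI))
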
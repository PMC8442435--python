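"""qPCR relative-expression utilities: dilution-series efficiency and the
Pfaffl ratio.

Amplification efficiency E is estimated from the standard-curve slope of
Ct against log10(dilution): E = 10**(-1/slope), so a perfect doubling per
cycle gives slope ≈ -3.3219 and E = 2.  Relative expression of a target
gene against a reference gene is the Pfaffl ratio

    ratio = E_target**ΔCt_target / E_ref**ΔCt_ref

with the calibrator-minus-sample sign convention ΔCt = Ct(calibrator) -
Ct(sample): a sample with more template than the calibrator has a lower
Ct, hence a positive ΔCt and a ratio above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class AmplificationCurve:
    """One primer pair's dilution series: dilution factors and Ct values."""

    dilutions: np.ndarray
    ct: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dilutions, dtype=float)
        c = np.asarray(self.ct, dtype=float)
        if d.size != c.size or d.size < 3:
            raise ValueError("need >= 3 matched (dilution, Ct) points")
        if np.any(d <= 0):
            raise ValueError("dilution factors must be strictly positive")
        self.dilutions = d
        self.ct = c


def efficiency_from_dilutions(curve: AmplificationCurve) -> float:
    """Amplification efficiency from the standard-curve slope.

    Least-squares slope of Ct vs log10(dilution); E = 10**(-1/slope).
    A non-negative slope (Ct not decreasing with template amount) is a
    failed standard curve and raises.  Values outside the usual [1.8, 2.2]
    working band are accepted with a warning; E must land in (1, 2.5].
    """
    x = np.log10(curve.dilutions)
    res = stats.linregress(x, curve.ct)
    if res.slope >= 0:
        raise ValueError(
            f"standard-curve slope {res.slope:.3g} is non-negative; "
            "Ct must decrease with template amount")
    e = float(10.0 ** (-1.0 / res.slope))
    if not (1.0 < e <= 2.5):
        raise ValueError(f"implausible efficiency E={e:.3g} (slope {res.slope:.3g})")
    if not (1.8 <= e <= 2.2):
        log.warning("efficiency E=%.3g outside the usual [1.8, 2.2] band", e)
    return e


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Pfaffl relative expression ratio.

    ``dct`` arguments use the calibrator-minus-sample convention.
    """
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    return float(e_target**dct_target / e_ref**dct_ref)
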
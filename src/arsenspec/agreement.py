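"""Agreement between the summed assay (HG-AAS) and the speciated sum (HPLC-ICP-MS).

Two assays that nominally measure the same quantity — total hazardous
urinary arsenic, µg/g-creatinine — can correlate strongly yet disagree
systematically.  Lin's concordance correlation coefficient (CCC) captures
both departures at once: it equals the Pearson correlation multiplied by a
bias-correction factor that penalizes location and scale shifts relative to
the 45° identity line,

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²).

An ordinary least-squares calibration line of the speciated sum on the
summed assay identifies the systematic difference; when the slope is near
unity the intercept is an additive inter-method offset, and adding it back
to the summed assay ("bias correction") moves the point cloud onto the
identity line and raises the CCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementResult",
    "lin_ccc",
    "ols_fit",
    "additive_bias_correction",
    "agreement_analysis",
]


@dataclass(frozen=True)
class AgreementResult:
    """Full agreement report for (x = summed assay, y = speciated sum)."""

    n: int
    pearson_r: float
    ccc: float
    slope: float
    intercept: float
    r_squared: float
    shift: float  # additive correction applied to x (µg/g-cr)
    corrected_ccc: float
    corrected_slope: float
    corrected_intercept: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "ccc": self.ccc,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "shift": self.shift,
            "corrected_ccc": self.corrected_ccc,
            "corrected_slope": self.corrected_slope,
            "corrected_intercept": self.corrected_intercept,
        }


def _moments(x: np.ndarray, y: np.ndarray, ddof: int) -> tuple[float, float, float, float, float]:
    mx, my = x.mean(), y.mean()
    n = x.size
    denom = n - ddof
    sx2 = float(((x - mx) ** 2).sum() / denom)
    sy2 = float(((y - my) ** 2).sum() / denom)
    sxy = float(((x - mx) * (y - my)).sum() / denom)
    return float(mx), float(my), sx2, sy2, sxy

def lin_ccc(x, y, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    Uses population (1/n) moments by default, the convention of Lin's
    original estimator; ``sample_moments=True`` switches to 1/(n−1)
    moments, which differ by O(1/n).  Returns NaN (with a warning) in the
    degenerate case of two constant series with equal means, where the
    ratio is 0/0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    mx, my, sx2, sy2, sxy = _moments(x, y, ddof=1 if sample_moments else 0)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        warnings.warn("CCC undefined: both series constant with equal means")
        return float("nan")
    return 2.0 * sxy / denom


def ols_fit(x, y) -> tuple[float, float, float]:
    """Least-squares line of ``y`` on ``x``: returns (slope, intercept, r²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a calibration line")
    mx, my = x.mean(), y.mean()
    sxx = float(((x - mx) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("x is constant: slope undefined")
    sxy = float(((x - mx) * (y - my)).sum())
    slope = sxy / sxx
    intercept = float(my - slope * mx)
    resid = y - (intercept + slope * x)
    syy = float(((y - my) ** 2).sum())
    r_squared = 0.0 if syy == 0.0 else 1.0 - float((resid**2).sum()) / syy
    return slope, intercept, r_squared


def additive_bias_correction(x, y) -> tuple[float, np.ndarray]:
    """Shift ``x`` by the OLS intercept of ``y`` on ``x``.

    The shift is defined as the calibration intercept (not mean(y−x)): when
    the calibration slope is near 1 the intercept is the additive
    inter-method offset, and ``x + shift`` fits the reference line
    ``y = 1·x``.
    """
    slope, intercept, _ = ols_fit(x, y)
    x = np.asarray(x, dtype=float)
    return intercept, x + intercept


def agreement_analysis(x, y, sample_moments: bool = False) -> AgreementResult:
    """Correlation, concordance, calibration and bias-corrected concordance.

    The corrected slope equals the uncorrected slope exactly (OLS is
    translation-equivariant) and the corrected intercept is
    ``intercept·(1 − slope)``; both are re-fit rather than derived so the
    report reflects the actual corrected series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept, r_squared = ols_fit(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    ccc = lin_ccc(x, y, sample_moments=sample_moments)
    shift, x_corr = additive_bias_correction(x, y)
    c_slope, c_intercept, _ = ols_fit(x_corr, y)
    c_ccc = lin_ccc(x_corr, y, sample_moments=sample_moments)
    return AgreementResult(
        n=int(x.size),
        pearson_r=r,
        ccc=float(ccc),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        shift=float(shift),
        corrected_ccc=float(c_ccc),
        corrected_slope=float(c_slope),
        corrected_intercept=float(c_intercept),
    )
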
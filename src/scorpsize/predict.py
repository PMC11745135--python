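"""Body-size prediction from single linear measurements.

User-facing mirror of the four published prediction helpers: total length
(toL) or carapace length (carL) in mm from one measurement via the bundled
log-log equations, or from two measurements via a fitted two-predictor
coefficient set.  Deviance is the signed difference between predicted and
actual size, the quantity reported when the buthid-trained equations are
applied to other scorpion families.
"""

from __future__ import annotations

import numpy as np

from .coefficients import (
    BUNDLED,
    MULTI_PRIMARY,
    CoefficientSet,
    VALID_PREDICTORS,
    bundled_coefficients,
)
from .traits import canonical_trait


def predict_simple(
    value_mm,
    predictor: str,
    response: str = "toL",
    coeffs: CoefficientSet | None = None,
):
    """Predict toL or carL (mm) from a single measurement (mm).

    Evaluates Y = exp(a + b ln(x)) with the bundled published coefficients
    unless ``coeffs`` overrides them.  Vectorized over ``value_mm``.
    carL is a valid predictor of toL only.
    """
    if coeffs is None:
        coeffs = bundled_coefficients(response, predictor)
    else:
        if canonical_trait(response) != coeffs.response:
            raise ValueError(
                f"coefficient set predicts {coeffs.response}, not {response}"
            )
    return coeffs.predict_mm(value_mm)


def predict_multi(
    x1_mm,
    x2_mm,
    primary: str,
    secondary: str,
    response: str = "toL",
    coeffs: CoefficientSet | None = None,
):
    """Predict toL or carL (mm) from two measurements (mm).

    The primary predictor is fixed by the response (met5L for toL, teL for
    carL).  Two-predictor coefficient values were never published, so a
    fitted :class:`CoefficientSet` (e.g. from
    :func:`scorpsize.pmm.fit_two_predictor`) is required.
    """
    response = canonical_trait(response)
    primary = canonical_trait(primary)
    secondary = canonical_trait(secondary)
    expected = MULTI_PRIMARY.get(response)
    if expected is None:
        raise KeyError(f"response must be toL or carL, got {response!r}")
    if primary != expected:
        raise ValueError(
            f"primary predictor of {response} is fixed to {expected}, got {primary}"
        )
    if secondary == primary:
        raise ValueError("secondary predictor must differ from the primary")
    if coeffs is None:
        raise ValueError(
            "no published two-predictor coefficients are bundled; supply a "
            "fitted CoefficientSet (see scorpsize.pmm.fit_two_predictor)"
        )
    if coeffs.response != response or tuple(coeffs.predictors) != (primary, secondary):
        raise ValueError(
            f"coefficient set is for {coeffs.response} ~ {coeffs.predictors}, "
            f"not {response} ~ ({primary}, {secondary})"
        )
    return coeffs.predict_mm(x1_mm, x2_mm)


def deviance(predicted_mm, actual_mm):
    """Signed difference predicted - actual (mm)."""
    out = np.asarray(predicted_mm, dtype=float) - np.asarray(actual_mm, dtype=float)
    return float(out) if out.ndim == 0 else out


def naive_interval(
    value_mm,
    predictor: str,
    response: str = "toL",
    coeffs: CoefficientSet | None = None,
):
    """Non-calibrated envelope from the coefficients' 95% credible bounds.

    Evaluates [exp(a_lo + b_lo ln x), exp(a_hi + b_hi ln x)].  This brackets
    the equation's coefficient uncertainty only; it is NOT a calibrated
    prediction interval (residual variation is ignored) and for x < 1 mm the
    slope bounds invert, so the envelope is re-ordered numerically.
    """
    if coeffs is None:
        coeffs = bundled_coefficients(response, predictor)
    if coeffs.a_bounds is None or coeffs.b_bounds is None:
        raise ValueError("coefficient set carries no credible bounds")
    x = np.asarray(value_mm, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurements must be positive (mm)")
    lo = np.exp(coeffs.a_bounds[0] + coeffs.b_bounds[0] * np.log(x))
    hi = np.exp(coeffs.a_bounds[1] + coeffs.b_bounds[1] * np.log(x))
    low = np.minimum(lo, hi)
    high = np.maximum(lo, hi)
    if low.ndim == 0:
        return float(low), float(high)
    return low, high
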
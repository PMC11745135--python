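"""Allometric coefficient sets, including the published buthid equations.

A coefficient set encodes the back-transformed log-log prediction equation

    Y_mm = exp(a + b ln(x1_mm) [+ b2 ln(x2_mm)])

for one response (total length toL or carapace length carL) and one or two
predictor measurements.  The bundled single-predictor sets are the published
posterior means and 95% credible bounds from the buthid analysis (n = 195
species), stored at the 2-decimal precision at which they were printed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .traits import canonical_trait


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept/slope(s) of one log-log prediction equation."""

    response: str
    predictors: tuple[str, ...]
    a: float
    b: float
    b2: float | None = None
    a_bounds: tuple[float, float] | None = None
    b_bounds: tuple[float, float] | None = None
    b2_bounds: tuple[float, float] | None = None
    rmse_mm: float | None = None
    source: str = "fitted"

    def __post_init__(self):
        if not all(map(math.isfinite, [self.a, self.b])):
            raise ValueError("coefficients must be finite")
        if len(self.predictors) == 2 and self.b2 is None:
            raise ValueError("two-predictor set needs b2")

    def predict_mm(self, x1_mm, x2_mm=None):
        x1 = np.asarray(x1_mm, dtype=float)
        if np.any(x1 <= 0):
            raise ValueError("measurements must be positive (mm)")
        log_pred = self.a + self.b * np.log(x1)
        if len(self.predictors) == 2:
            if x2_mm is None:
                raise ValueError(
                    f"coefficient set for {self.predictors} needs a second "
                    f"measurement"
                )
            x2 = np.asarray(x2_mm, dtype=float)
            if np.any(x2 <= 0):
                raise ValueError("measurements must be positive (mm)")
            log_pred = log_pred + self.b2 * np.log(x2)
        out = np.exp(log_pred)
        return float(out) if out.ndim == 0 else out

    # ------------------------------------------------------------- JSON

    def to_json(self) -> str:
        d = asdict(self)
        d["predictors"] = list(self.predictors)
        for k in ("a_bounds", "b_bounds", "b2_bounds"):
            if d[k] is not None:
                d[k] = list(d[k])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CoefficientSet":
        d = json.loads(text)
        d["predictors"] = tuple(d["predictors"])
        for k in ("a_bounds", "b_bounds", "b2_bounds"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _row(response, predictor, rmse, a, a_lo, a_hi, b, b_lo, b_hi):
    return CoefficientSet(
        response=response,
        predictors=(predictor,),
        a=a,
        b=b,
        a_bounds=(a_lo, a_hi),
        b_bounds=(b_lo, b_hi),
        rmse_mm=rmse,
        source="bundled",
    )


#: published single-predictor equations: (response, predictor) -> coefficients
BUNDLED: dict[tuple[str, str], CoefficientSet] = {
    (c.response, c.predictors[0]): c
    for c in [
        # total length
        _row("toL", "met5L", 6.41, 2.13, 2.03, 2.22, 0.95, 0.91, 0.99),
        _row("toL", "carL", 6.46, 2.18, 2.08, 2.27, 1.01, 0.97, 1.05),
        _row("toL", "teL", 7.22, 2.32, 2.21, 2.44, 0.90, 0.86, 0.94),
        _row("toL", "cheL", 8.84, 2.27, 2.08, 2.50, 0.72, 0.67, 0.78),
        _row("toL", "teW", 9.27, 3.29, 3.13, 3.44, 0.82, 0.77, 0.86),
        _row("toL", "cheW", 10.70, 3.40, 3.23, 3.57, 0.63, 0.57, 0.69),
        _row("toL", "met5W", 12.24, 3.13, 2.94, 3.34, 0.71, 0.65, 0.77),
        # carapace length
        _row("carL", "teL", 0.68, 0.24, 0.13, 0.34, 0.84, 0.80, 0.87),
        _row("carL", "teW", 0.76, 1.12, 0.99, 1.22, 0.78, 0.74, 0.81),
        _row("carL", "met5L", 0.96, 0.10, -0.02, 0.22, 0.85, 0.80, 0.90),
        _row("carL", "cheL", 0.98, 0.22, 0.04, 0.42, 0.66, 0.61, 0.71),
        _row("carL", "met5W", 1.02, 0.95, 0.75, 1.09, 0.71, 0.66, 0.76),
        _row("carL", "cheW", 1.06, 1.22, 1.08, 1.39, 0.60, 0.55, 0.65),
    ]
}

#: predictor vocabulary exposed to users, per response
VALID_PREDICTORS: dict[str, tuple[str, ...]] = {
    "toL": ("met5L", "met5W", "carL", "teL", "teW", "cheL", "cheW"),
    "carL": ("met5L", "met5W", "teL", "teW", "cheL", "cheW"),
}

#: fixed primary predictor of the two-predictor models, per response
MULTI_PRIMARY: dict[str, str] = {"toL": "met5L", "carL": "teL"}


def bundled_coefficients(response: str, predictor: str) -> CoefficientSet:
    response = canonical_trait(response)
    predictor = canonical_trait(predictor)
    if response not in VALID_PREDICTORS:
        raise KeyError(f"response must be toL or carL, got {response!r}")
    if predictor not in VALID_PREDICTORS[response]:
        raise KeyError(
            f"{predictor!r} is not a valid predictor of {response}; "
            f"choose from {VALID_PREDICTORS[response]}"
        )
    return BUNDLED[(response, predictor)]
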
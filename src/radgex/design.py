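"""Minimum sample size for a continuous-outcome prediction model.

Implements the four published minimum-sample-size criteria for developing
a multivariable linear prediction model (Riley-style):

(i)   acceptable expected shrinkage S:
      n = p / ((S - 1) * ln(1 - R² / S));
(ii)  small apparent-vs-adjusted R² difference (margin δ):
      n = 1 + p * (1 - R²) / δ;
(iii) precise residual standard deviation: a ≤10% multiplicative margin
      requires at least 234 residual degrees of freedom, hence
      n = 234 + p + 1;
(iv)  precise mean predicted outcome: the 95% CI half-width of the mean,
      1.96 * sqrt(σ²_resid / n), within a 10% multiplicative margin of the
      anticipated mean outcome.  With a standardized (zero-mean) outcome —
      the default here — a multiplicative margin is undefined and the
      criterion is reported as not applicable.

The overall minimum is the maximum over the applicable criteria, each
rounded up.  The inverse problem (minimum detectable R² at a given n)
bisects the R²-dependent criteria; a closed-form variant based on the
expected-shrinkage heuristic S = 1 - (p / n) * (1 - R²) / R² is also
exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class RileyInputs:
    n_predictors: int = 5
    anticipated_r2: float = 0.20
    shrinkage: float = 0.90
    r2_difference_margin: float = 0.05
    sd_multiplicative_margin_pct: float = 10.0
    #: anticipated mean outcome; None or 0 for a standardized outcome,
    #: in which case criterion (iv) is not applicable
    anticipated_mean: float | None = None
    outcome_sd: float = 1.0

    def validate(self) -> None:
        if self.n_predictors < 1:
            raise ValueError("need at least 1 predictor")
        if not 0 < self.anticipated_r2 < 1:
            raise ValueError("anticipated R² must be in (0, 1)")
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must be in (0, 1]")
        if self.anticipated_r2 >= self.shrinkage:
            raise ValueError("criterion (i) undefined: R² must be < shrinkage target")
        if self.r2_difference_margin <= 0:
            raise ValueError("R² difference margin must be positive")


def _criterion_shrinkage(p: int, r2: float, s: float) -> float:
    return p / ((s - 1.0) * math.log(1.0 - r2 / s))


def _criterion_r2_difference(p: int, r2: float, delta: float) -> float:
    return 1.0 + p * (1.0 - r2) / delta


def _criterion_residual_sd(p: int, margin_pct: float) -> float:
    # a <=10% multiplicative margin on the residual SD needs >=234 residual df
    if margin_pct < 10.0 - 1e-9:
        raise ValueError("margins tighter than 10% are not tabulated")
    return 234.0 + p + 1.0


def _criterion_mean_precision(p: int, r2: float, mean: float | None, sd: float,
                              margin_pct: float) -> float | None:
    if mean is None or mean == 0:
        return None
    resid_var = sd**2 * (1.0 - r2)
    half_width = abs(mean) * margin_pct / 100.0
    return (1.96**2) * resid_var / half_width**2


def riley_min_n(inputs: RileyInputs | None = None, **kwargs) -> dict:
    """Per-criterion minimum n and the overall maximum.

    Returns a dict with keys ``criterion_1`` .. ``criterion_4`` (None where
    not applicable) and ``n_min``.
    """
    if inputs is None:
        inputs = RileyInputs(**kwargs)
    inputs.validate()
    p, r2, s = inputs.n_predictors, inputs.anticipated_r2, inputs.shrinkage
    c1 = math.ceil(_criterion_shrinkage(p, r2, s))
    c2 = math.ceil(_criterion_r2_difference(p, r2, inputs.r2_difference_margin))
    c3 = math.ceil(_criterion_residual_sd(p, inputs.sd_multiplicative_margin_pct))
    c4_raw = _criterion_mean_precision(p, r2, inputs.anticipated_mean, inputs.outcome_sd,
                                       inputs.sd_multiplicative_margin_pct)
    c4 = math.ceil(c4_raw) if c4_raw is not None else None
    applicable = [c for c in (c1, c2, c3, c4) if c is not None]
    return {"criterion_1": c1, "criterion_2": c2, "criterion_3": c3, "criterion_4": c4,
            "n_min": max(applicable)}


def min_detectable_r2(n: int, p: int, shrinkage: float = 0.90,
                      r2_difference_margin: float = 0.05,
                      method: str = "criteria", tol: float = 1e-6) -> float | None:
    """Smallest anticipated R² supportable at sample size ``n``.

    ``method='criteria'`` bisects the R²-dependent criteria (i) and (ii)
    to the smallest R² whose required n does not exceed ``n`` (the
    precision criteria do not depend on R² and are excluded from the
    inversion).  ``method='shrinkage_heuristic'`` returns the closed form
    R² = 1 / (1 + (1 - S) * n / p) from the expected-shrinkage
    approximation S ≈ 1 - (p / n) * (1 - R²) / R².  Returns None when no
    R² in (0, 1) qualifies.
    """
    if n <= p + 2:
        raise ValueError("n must exceed p + 2")
    if method == "shrinkage_heuristic":
        return 1.0 / (1.0 + (1.0 - shrinkage) * n / p)
    if method != "criteria":
        raise ValueError("method must be 'criteria' or 'shrinkage_heuristic'")

    def required(r2: float) -> float:
        return max(_criterion_shrinkage(p, r2, shrinkage),
                   _criterion_r2_difference(p, r2, r2_difference_margin))

    hi = shrinkage - 1e-9
    if required(hi) > n:
        return None
    lo = 1e-9
    if required(lo) <= n:
        return lo
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if required(mid) <= n:
            hi = mid
        else:
            lo = mid
    return hi
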
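"""Delta-method (first-order Taylor) theory of percent-of-total correlations.

Setting
-------
Write X1 for the concentration of a focal fatty acid, X2 for the summed
concentration of all other fatty acids, S = X1 + X2 for the total pool and
P = X1 / S for the focal fraction. Y is a blood-lipid biomarker (TAG, TC,
LDL, HDL or TC:HDL). The seven moments

    mu1 = E X1, sigma1 = sd X1, mu2 = E X2, sigma2 = sd X2,
    rho  = corr(X1, X2), rho1 = corr(X1, Y), rho2 = corr(X2, Y)

fully determine the first-order behaviour of P. Linearising P about the
mean vector (with M = mu1 + mu2),

    P ≈ mu1/M + [mu2 (X1 - mu1) - mu1 (X2 - mu2)] / M**2,

gives the delta-method approximations

    cov(Y, P) ≈ sigmaY (mu2 rho1 sigma1 - mu1 rho2 sigma2) / M**2
    var(P)    ≈ (mu2^2 sigma1^2 + mu1^2 sigma2^2
                 - 2 mu1 mu2 rho sigma1 sigma2) / M**4
    cov(S, P) ≈ (mu2 sigma1 (sigma1 + rho sigma2)
                 - mu1 sigma2 (sigma2 + rho sigma1)) / M**2
    var(S)    =  sigma1^2 + sigma2^2 + 2 rho sigma1 sigma2   (exact)

Two sign conditions follow immediately (the denominators are positive):

* corr(Y, P) is negative iff rho1 sigma1 mu2 - rho2 sigma2 mu1 < 0, i.e.
  iff rho1 * CV1 < rho2 * CV2 where CVi = sigmai / mui — a biomarker can
  correlate positively with a fatty acid's concentration yet negatively
  with its percentage of total.
* corr(S, P) is negative iff
  sigma1 mu2 (sigma1 + rho sigma2) - sigma2 mu1 (sigma2 + rho sigma1) < 0.

Both conditions are invariant under a common rescaling of all concentration
moments (unit independence) and each defines a straight boundary through
the origin of the (CV2, CV1) plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import DegenerateBoundaryError, ValidationError
from .moments import SummaryMoments

__all__ = [
    "SignCondition",
    "PredictedCorrelation",
    "BoundaryCurve",
    "sign_condition_biomarker",
    "sign_condition_total",
    "predicted_corr_biomarker",
    "predicted_corr_total",
    "boundary_biomarker",
    "boundary_total",
    "round_half_away",
]

Sign = Literal["negative", "positive", "zero"]


def _sign_label(x: float) -> Sign:
    if x < 0:
        return "negative"
    if x > 0:
        return "positive"
    return "zero"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed 2-dp values)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class SignCondition:
    """Outcome of a direction criterion for a percent-of-total correlation.

    ``left_term``/``right_term`` are the two CV products whose comparison
    decides the sign; ``sign_term`` is the equivalent polynomial form whose
    sign is evaluated exactly (the two formulations agree identically up to
    the positive factor mu1 * mu2).
    """

    left_term: float
    right_term: float
    sign_term: float
    predicted_sign: Sign


@dataclass(frozen=True)
class PredictedCorrelation:
    """A delta-method predicted correlation and its ingredients.

    ``value`` is clamped into [-1, 1]; ``clamped`` flags the (large-CV)
    regime where the first-order approximation left the valid range.
    """

    value: float
    cov_YP: float
    var_P: float
    var_Y: float
    moments: SummaryMoments
    clamped: bool = False


@dataclass(frozen=True)
class BoundaryCurve:
    """A sign boundary in the (CV2, CV1) plane: the line y = slope * x.

    The predicted correlation has the sign of ``coef_y * CV1 - coef_x * CV2``
    (exactly the relevant sign term divided by a positive factor), so
    ``slope = coef_x / coef_y`` and the region below the line is negative
    exactly when ``coef_y > 0``.
    """

    kind: Literal["biomarker", "total"]
    coef_y: float  # multiplies CV1 (y-axis)
    coef_x: float  # multiplies CV2 (x-axis)

    @property
    def slope(self) -> float:
        return self.coef_x / self.coef_y

    @property
    def negative_below(self) -> bool:
        return self.coef_y > 0

    def classify(self, cv2: float, cv1: float) -> Sign:
        """Predicted correlation sign for a point (x=CV2, y=CV1)."""
        if cv1 <= 0 or cv2 <= 0:
            raise ValidationError("CVs must be positive")
        return _sign_label(self.coef_y * cv1 - self.coef_x * cv2)

    def sample(self, x_max: float = 1.0, num: int = 100) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) samples of the boundary line for external plotting."""
        if x_max <= 0 or num < 2:
            raise ValidationError("x_max must be > 0 and num >= 2")
        x = np.linspace(0.0, x_max, num)
        return x, self.slope * x

    @property
    def region_labels(self) -> dict[str, Sign]:
        below: Sign = "negative" if self.negative_below else "positive"
        above: Sign = "positive" if self.negative_below else "negative"
        return {"below": below, "above": above}


def _require_positive_means(m: SummaryMoments) -> None:
    if m.mu1 <= 0 or m.mu2 <= 0:
        raise ValidationError(
            f"CVs undefined: means must be positive (mu1={m.mu1}, mu2={m.mu2})"
        )


def sign_condition_biomarker(m: SummaryMoments) -> SignCondition:
    """Direction criterion for corr(Y, percent-of-total focal FA).

    Negative exactly when the focal fatty acid's correlation-times-CV
    product ``rho1 * sigma1/mu1`` is smaller than the corresponding product
    ``rho2 * sigma2/mu2`` for all other fatty acids combined.
    """
    _require_positive_means(m)
    left = m.rho1 * m.sigma1 / m.mu1
    right = m.rho2 * m.sigma2 / m.mu2
    sign_term = m.rho1 * m.sigma1 * m.mu2 - m.rho2 * m.sigma2 * m.mu1
    return SignCondition(left_term=left, right_term=right, sign_term=sign_term,
                         predicted_sign=_sign_label(sign_term))


def sign_condition_total(m: SummaryMoments) -> SignCondition:
    """Direction criterion for corr(total FA concentration, percent focal).

    Depends only on (mu1, sigma1, mu2, sigma2, rho12): negative exactly when
    sigma1*mu2*(sigma1 + rho*sigma2) < sigma2*mu1*(sigma2 + rho*sigma1),
    equivalently CV1*(sigma1 + rho*sigma2) < CV2*(sigma2 + rho*sigma1).
    """
    _require_positive_means(m)
    a = m.sigma1 + m.rho12 * m.sigma2
    b = m.sigma2 + m.rho12 * m.sigma1
    left = m.cv1 * a
    right = m.cv2 * b
    sign_term = m.sigma1 * m.mu2 * a - m.sigma2 * m.mu1 * b
    return SignCondition(left_term=left, right_term=right, sign_term=sign_term,
                         predicted_sign=_sign_label(sign_term))


def _delta_var_P(m: SummaryMoments) -> float:
    M = m.mu1 + m.mu2
    return (m.mu2 ** 2 * m.sigma1 ** 2 + m.mu1 ** 2 * m.sigma2 ** 2
            - 2.0 * m.mu1 * m.mu2 * m.rho12 * m.sigma1 * m.sigma2) / M ** 4


def _clamp(value: float) -> tuple[float, bool]:
    if value > 1.0:
        return 1.0, True
    if value < -1.0:
        return -1.0, True
    return value, False


def predicted_corr_biomarker(m: SummaryMoments) -> PredictedCorrelation:
    """Delta-method prediction of corr(Y, percent-of-total focal FA).

    The result is independent of sigmaY (it cancels) and invariant under a
    common positive rescaling of the concentration moments. Its sign equals
    :func:`sign_condition_biomarker`'s prediction by construction.
    """
    _require_positive_means(m)
    if m.sigmaY <= 0:
        raise ValidationError("sigmaY must be positive")
    M = m.mu1 + m.mu2
    var_p = _delta_var_P(m)
    if var_p <= 0:
        raise DegenerateBoundaryError(
            "degenerate composition: first-order var(P) <= 0 "
            "(only possible at |rho12| = 1)"
        )
    cov_yp = m.sigmaY * (m.mu2 * m.rho1 * m.sigma1 - m.mu1 * m.rho2 * m.sigma2) / M ** 2
    value = cov_yp / (m.sigmaY * math.sqrt(var_p))
    value, clamped = _clamp(value)
    return PredictedCorrelation(value=value, cov_YP=cov_yp, var_P=var_p,
                                var_Y=m.sigmaY ** 2, moments=m, clamped=clamped)


def predicted_corr_total(m: SummaryMoments) -> PredictedCorrelation:
    """Delta-method prediction of corr(total FA concentration, percent focal).

    Uses cov(S, X1) = sigma1*(sigma1 + rho*sigma2) and
    cov(S, X2) = sigma2*(sigma2 + rho*sigma1) with S = X1 + X2;
    var(S) is exact, var(P) first-order.
    """
    _require_positive_means(m)
    M = m.mu1 + m.mu2
    var_p = _delta_var_P(m)
    if var_p <= 0:
        raise DegenerateBoundaryError(
            "degenerate composition: first-order var(P) <= 0 "
            "(only possible at |rho12| = 1)"
        )
    var_s = m.sigma1 ** 2 + m.sigma2 ** 2 + 2.0 * m.rho12 * m.sigma1 * m.sigma2
    if var_s <= 0:
        raise DegenerateBoundaryError("var(total) <= 0: degenerate total pool")
    cov_sp = (m.mu2 * m.sigma1 * (m.sigma1 + m.rho12 * m.sigma2)
              - m.mu1 * m.sigma2 * (m.sigma2 + m.rho12 * m.sigma1)) / M ** 2
    value = cov_sp / (math.sqrt(var_s) * math.sqrt(var_p))
    value, clamped = _clamp(value)
    return PredictedCorrelation(value=value, cov_YP=cov_sp, var_P=var_p,
                                var_Y=var_s, moments=m, clamped=clamped)


def boundary_biomarker(rho1: float, rho2: float) -> BoundaryCurve:
    """Sign boundary of corr(Y, percent focal) in the (CV2, CV1) plane.

    The line CV1 = (rho2/rho1) * CV2; with rho1 > 0 the region below it is
    where the percent-scale correlation is negative.
    """
    for name, v in (("rho1", rho1), ("rho2", rho2)):
        if not math.isfinite(v) or abs(v) > 1:
            raise ValidationError(f"{name} must lie in [-1, 1], got {v}")
    if rho1 == 0:
        raise DegenerateBoundaryError(
            "rho1 = 0: no boundary line; the sign is that of -rho2 everywhere"
        )
    return BoundaryCurve(kind="biomarker", coef_y=float(rho1), coef_x=float(rho2))


def boundary_total(sigma1: float, sigma2: float, rho12: float) -> BoundaryCurve:
    """Sign boundary of corr(total, percent focal) in the (CV2, CV1) plane.

    With the sample sds held fixed (means sweep the CVs), the boundary is
    CV1 = CV2 * (sigma2 + rho*sigma1) / (sigma1 + rho*sigma2).
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValidationError("sigma1 and sigma2 must be positive")
    if not math.isfinite(rho12) or abs(rho12) > 1:
        raise ValidationError(f"rho12 must lie in [-1, 1], got {rho12}")
    a = sigma1 + rho12 * sigma2
    b = sigma2 + rho12 * sigma1
    if a == 0:
        raise DegenerateBoundaryError(
            "sigma1 + rho*sigma2 = 0: the boundary is vertical in the "
            "(CV2, CV1) plane; the sign is that of -(sigma2 + rho*sigma1)*CV2"
        )
    return BoundaryCurve(kind="total", coef_y=float(a), coef_x=float(b))
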
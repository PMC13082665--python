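"""Variance-difference effect sizes computed from published arm-level summaries.

The quantities here contrast outcome *variability* between the two arms of a
randomized trial, using only the per-arm sample size, mean and standard
deviation that trial reports routinely publish:

* ``lnCVR`` — log coefficient-of-variation ratio, the primary statistic. It
  normalises each arm's SD by its mean, which makes it robust to
  mean-variance relationships (common for outcomes such as HbA1c) and to
  SE/SD mislabeling in publications.
* ``lnVR`` — log variability (SD) ratio, the special case of lnCVR when the
  arm means are equal.
* ``lnF`` — log of the classical F variance ratio; identically ``2 * lnVR``.

All three are small-sample bias-corrected, approximately normal on the log
scale, and signed treatment-over-control (positive = treatment arm more
variable). Each estimator comes with a delta-method sampling variance and a
two-sided significance test on a t reference with Welch–Satterthwaite
degrees of freedom formed from the per-arm variance contributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "ArmSummary",
    "DivbtaEstimate",
    "lncvr",
    "lncvr_variance",
    "lnvr",
    "lnf",
    "lnf_exact_p",
    "significance_test",
    "estimate_comparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArmSummary:
    """Published summary statistics for one trial arm.

    Parameters
    ----------
    n
        Number of analysed participants (integer, at least 2: the variance
        formulas divide by ``n - 1``).
    mean
        Outcome mean in outcome units (e.g. HbA1c %). Must be strictly
        positive for CV-based estimators.
    sd
        Outcome standard deviation, same units, strictly positive.
    role
        ``"treatment"`` or ``"control"``; used in error messages and sign
        conventions.
    """

    n: int
    mean: float
    sd: float
    role: str = "treatment"

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise InvalidInputError(
                f"{self.role} arm: n must be an integer >= 2, got {self.n!r}"
            )
        if not math.isfinite(self.mean):
            raise InvalidInputError(f"{self.role} arm: mean must be finite, got {self.mean!r}")
        if not (math.isfinite(self.sd) and self.sd > 0):
            raise InvalidInputError(f"{self.role} arm: sd must be > 0, got {self.sd!r}")
        rep = repr(float(self.sd))
        digits = rep.replace("-", "").replace(".", "").strip("0")
        if len(digits) <= 2 and "e" not in rep:
            # Excessively rounded SDs degrade variance-ratio precision.
            logger.warning(
                "%s arm: sd=%g has <= 2 significant digits; lnCVR precision may suffer",
                self.role,
                self.sd,
            )

    @property
    def cv(self) -> float:
        """Coefficient of variation ``sd / mean`` (requires mean > 0)."""
        if self.mean <= 0:
            raise InvalidInputError(
                f"{self.role} arm: mean must be > 0 for CV-based estimators, got {self.mean!r}"
            )
        return self.sd / self.mean


@dataclass
class DivbtaEstimate:
    """A variance-difference point estimate with its inferential companions.

    ``df`` and ``p_value`` are filled by :func:`significance_test`.
    """

    statistic_kind: str  # "lnCVR" | "lnVR" | "lnF"
    estimate: float
    sampling_variance: float
    df: Optional[float] = None
    p_value: Optional[float] = None
    trial_id: Optional[str] = None
    comparison_id: Optional[str] = None
    time_point: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sampling_variance < 0:
            raise InvalidInputError(
                f"sampling_variance must be >= 0, got {self.sampling_variance!r}"
            )


def _require_positive_mean(arm: ArmSummary) -> None:
    if arm.mean <= 0:
        raise InvalidInputError(
            f"{arm.role} arm: mean must be > 0 for CV-based estimators, got {arm.mean!r}"
        )


def _cv_arm_variance(arm: ArmSummary) -> float:
    """One arm's delta-method contribution to the lnCVR sampling variance."""
    cv = arm.cv
    n = arm.n
    return cv * cv / n + cv**4 / (2 * n * n) + 1.0 / (2 * (n - 1))


def _vr_arm_variance(arm: ArmSummary) -> float:
    """One arm's contribution to the lnVR sampling variance."""
    return 1.0 / (2 * (arm.n - 1))


def lncvr(treatment: ArmSummary, control: ArmSummary, **labels: Optional[str]) -> DivbtaEstimate:
    """Bias-corrected log coefficient-of-variation ratio, treatment over control.

    ``ln(CV_T/CV_C) + 1/2 (1/(n_T-1) - 1/(n_C-1))
    + 1/2 (s_C^2/(n_C xbar_C^2) - s_T^2/(n_T xbar_T^2))``

    Both correction terms vanish for identical arms, so equal summaries give
    exactly 0. The sampling variance is attached (see :func:`lncvr_variance`).
    """
    _require_positive_mean(treatment)
    _require_positive_mean(control)
    est = (
        math.log(treatment.cv / control.cv)
        + 0.5 * (1.0 / (treatment.n - 1) - 1.0 / (control.n - 1))
        + 0.5
        * (
            control.sd**2 / (control.n * control.mean**2)
            - treatment.sd**2 / (treatment.n * treatment.mean**2)
        )
    )
    return DivbtaEstimate(
        statistic_kind="lnCVR",
        estimate=est,
        sampling_variance=lncvr_variance(treatment, control),
        **labels,
    )


def lncvr_variance(treatment: ArmSummary, control: ArmSummary) -> float:
    """Approximate (delta-method) sampling variance of lnCVR.

    Sum over arms of ``CV^2/n + CV^4/(2 n^2) + 1/(2(n-1))``.
    """
    _require_positive_mean(treatment)
    _require_positive_mean(control)
    return _cv_arm_variance(treatment) + _cv_arm_variance(control)


def lnvr(treatment: ArmSummary, control: ArmSummary, **labels: Optional[str]) -> DivbtaEstimate:
    """Bias-corrected log variability (SD) ratio; means are not used."""
    est = math.log(treatment.sd / control.sd) + 0.5 * (
        1.0 / (treatment.n - 1) - 1.0 / (control.n - 1)
    )
    var = _vr_arm_variance(treatment) + _vr_arm_variance(control)
    return DivbtaEstimate(statistic_kind="lnVR", estimate=est, sampling_variance=var, **labels)


def lnf(treatment: ArmSummary, control: ArmSummary, **labels: Optional[str]) -> DivbtaEstimate:
    """Log F variance ratio: exactly twice lnVR, with four times its variance."""
    base = lnvr(treatment, control)
    return DivbtaEstimate(
        statistic_kind="lnF",
        estimate=2.0 * base.estimate,
        sampling_variance=4.0 * base.sampling_variance,
        **labels,
    )


def lnf_exact_p(treatment: ArmSummary, control: ArmSummary) -> float:
    """Two-sided p-value for equal variances from the exact F test.

    Uses ``F = s_T^2 / s_C^2`` on ``(n_T - 1, n_C - 1)`` df; exact under
    normal outcomes, an alternative to the t-approximation on lnF.
    """
    f = treatment.sd**2 / control.sd**2
    dist = stats.f(treatment.n - 1, control.n - 1)
    return 2.0 * min(dist.cdf(f), dist.sf(f))


def significance_test(
    estimate: DivbtaEstimate, treatment: ArmSummary, control: ArmSummary
) -> tuple[float, float]:
    """Two-sided t test of a variance-difference estimate against zero.

    The test statistic is ``estimate / sqrt(sampling_variance)``; the
    reference t distribution uses Welch–Satterthwaite degrees of freedom
    formed from the two per-arm variance contributions:

    ``df = (v_T + v_C)^2 / (v_T^2/(n_T-1) + v_C^2/(n_C-1))``

    Fills ``df`` and ``p_value`` on the estimate and returns ``(df, p)``.
    """
    if estimate.sampling_variance <= 0:
        raise DegenerateInputError("sampling_variance must be > 0 for a significance test")
    if estimate.statistic_kind == "lnCVR":
        v_t, v_c = _cv_arm_variance(treatment), _cv_arm_variance(control)
    elif estimate.statistic_kind == "lnVR":
        v_t, v_c = _vr_arm_variance(treatment), _vr_arm_variance(control)
    elif estimate.statistic_kind == "lnF":
        v_t, v_c = 4.0 * _vr_arm_variance(treatment), 4.0 * _vr_arm_variance(control)
    else:
        raise InvalidInputError(f"unknown statistic_kind {estimate.statistic_kind!r}")
    df = (v_t + v_c) ** 2 / (v_t**2 / (treatment.n - 1) + v_c**2 / (control.n - 1))
    t = estimate.estimate / math.sqrt(estimate.sampling_variance)
    p = 2.0 * stats.t.sf(abs(t), df)
    estimate.df = df
    estimate.p_value = float(min(p, 1.0))
    return df, estimate.p_value


def estimate_comparison(
    treatment: ArmSummary,
    control: ArmSummary,
    kind: str = "lnCVR",
    **labels: Optional[str],
) -> DivbtaEstimate:
    """Point estimate + variance + significance test in one call."""
    fn = {"lnCVR": lncvr, "lnVR": lnvr, "lnF": lnf}.get(kind)
    if fn is None:
        raise InvalidInputError(f"unknown statistic kind {kind!r}")
    est = fn(treatment, control, **labels)
    significance_test(est, treatment, control)
    return est
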
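"""Auxiliary computable trustworthiness checks.

Companions to the variance-difference screen:

* a baseline-plausibility screen in the Carlisle-Stouffer-Fisher spirit —
  per-variable two-arm t tests on reported baseline summaries, combined via
  Stouffer's method into one one-sided p-value; values near 0 (large
  imbalances) or near 1 (too-perfect balance) are both implausible under
  genuine randomization. Reduced here to the continuous summary-statistic
  path, which suffices for the reference-set exclusion rule.
* the implied before/after change-score correlation, which must land in
  [-1, 1] if the three reported SDs are mutually consistent;
* a 3-sigma band check on the treatment effect itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .exceptions import InvalidInputError
from .summary_stats import ArmSummary

__all__ = [
    "BaselineVariable",
    "BaselineScreen",
    "ChangeScoreTriple",
    "baseline_plausibility",
    "implied_change_correlation",
    "effect_size_band_check",
    "DEFAULT_EFFECT_BAND",
]

#: Reference 3-sigma band for the HbA1c treatment effect (% units).
DEFAULT_EFFECT_BAND = (-1.4, 0.8)


@dataclass(frozen=True)
class BaselineVariable:
    """Per-arm summaries of one continuous baseline characteristic."""

    name: str
    treatment: ArmSummary
    control: ArmSummary


@dataclass(frozen=True)
class BaselineScreen:
    combined_p: Optional[float]
    classification: str  # plausible | implausible_low | implausible_high | missing
    z_scores: tuple[float, ...] = ()


def _welch_one_sided_p(t_arm: ArmSummary, c_arm: ArmSummary) -> float:
    # One-sided (treatment > control) p from summary statistics, Welch df.
    se2_t = t_arm.sd**2 / t_arm.n
    se2_c = c_arm.sd**2 / c_arm.n
    t = (t_arm.mean - c_arm.mean) / math.sqrt(se2_t + se2_c)
    df = (se2_t + se2_c) ** 2 / (se2_t**2 / (t_arm.n - 1) + se2_c**2 / (c_arm.n - 1))
    return float(stats.t.sf(t, df))


def baseline_plausibility(
    variables: Sequence[BaselineVariable],
    low: float = 0.025,
    high: float = 0.975,
) -> BaselineScreen:
    """Stouffer-combined plausibility of reported baseline balance.

    Per variable: a two-arm Welch t-test from summaries, converted to a
    one-sided z score (sign = treatment minus control); combined as
    ``zbar = sum(z_i) / sqrt(m)`` with combined one-sided ``p = Phi(zbar)``.
    No usable variables yields the ``missing`` classification, which itself
    triggers exclusion from tolerance-band reference sets.
    """
    zs = []
    for var in variables:
        p_one = _welch_one_sided_p(var.treatment, var.control)
        # Clip to keep z finite for extreme reported imbalances.
        p_one = min(max(p_one, 1e-300), 1.0 - 1e-16)
        zs.append(float(stats.norm.isf(p_one)))
    if not zs:
        return BaselineScreen(combined_p=None, classification="missing")
    zbar = sum(zs) / math.sqrt(len(zs))
    p = float(stats.norm.cdf(zbar))
    if p < low:
        cls = "implausible_low"
    elif p > high:
        cls = "implausible_high"
    else:
        cls = "plausible"
    return BaselineScreen(combined_p=p, classification=cls, z_scores=tuple(zs))


@dataclass(frozen=True)
class ChangeScoreTriple:
    """Reported SDs before, after, and of the within-arm change."""

    sd_before: float
    sd_after: float
    sd_change: float

    def __post_init__(self) -> None:
        for name in ("sd_before", "sd_after", "sd_change"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


def implied_change_correlation(triple: ChangeScoreTriple) -> tuple[float, bool]:
    """Before/after correlation implied by the three reported SDs.

    ``r = (sd_before^2 + sd_after^2 - sd_change^2) / (2 sd_before sd_after)``.
    Returns ``(r, consistent)``; r outside [-1, 1] means the reported SDs
    cannot come from the same dataset (a calculation or data error).
    """
    r = (triple.sd_before**2 + triple.sd_after**2 - triple.sd_change**2) / (
        2.0 * triple.sd_before * triple.sd_after
    )
    return r, -1.0 <= r <= 1.0


def effect_size_band_check(
    effect: float,
    significant: bool,
    band: tuple[float, float] = DEFAULT_EFFECT_BAND,
) -> bool:
    """Flag a statistically significant treatment effect outside the 3-sigma band."""
    lower, upper = band
    return significant and (effect < lower or effect > upper)
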
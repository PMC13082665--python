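"""The two-criterion flagging rule.

A trial comparison is flagged as potentially problematic when its variance
difference is both (1) statistically significant at ``alpha_sig`` and
(2) an outlier, i.e. strictly outside the tolerance band. Boundary values
count as inside (conservative, favoring specificity). The output is a
screen, not an adjudication of fraud versus error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import InvalidInputError
from .summary_stats import DivbtaEstimate
from .tolerance_bands import ToleranceBand

__all__ = ["FlagResult", "flag", "flag_trials"]


@dataclass(frozen=True)
class FlagResult:
    comparison_id: object
    significant: bool
    outlier: bool
    flagged: bool
    band_used: ToleranceBand
    direction: str  # "below" | "inside" | "above"
    estimate: float
    p_value: float


def flag(
    estimate: DivbtaEstimate, band: ToleranceBand, alpha_sig: float = 0.05
) -> FlagResult:
    """Apply the decision rule to one comparison.

    Flagged iff ``p_value <= alpha_sig`` and the point estimate lies strictly
    outside ``[band.lower, band.upper]``.
    """
    if estimate.p_value is None:
        raise InvalidInputError(
            "estimate has no p_value; run significance_test (or estimate_comparison) first"
        )
    significant = estimate.p_value <= alpha_sig
    if estimate.estimate < band.lower:
        direction = "below"
    elif estimate.estimate > band.upper:
        direction = "above"
    else:
        direction = "inside"
    outlier = direction != "inside"
    return FlagResult(
        comparison_id=estimate.comparison_id,
        significant=significant,
        outlier=outlier,
        flagged=significant and outlier,
        band_used=band,
        direction=direction,
        estimate=estimate.estimate,
        p_value=estimate.p_value,
    )


def flag_trials(
    results: Iterable[FlagResult],
    trial_ids: Sequence[object],
    rule: str = "any",
) -> dict[object, bool]:
    """Aggregate comparison-level flags to trial level.

    ``rule="any"`` (default): a trial is flagged if any of its comparisons
    is; ``rule="all"`` requires every comparison flagged.
    """
    agg: dict[object, list[bool]] = {}
    for res, tid in zip(results, trial_ids):
        agg.setdefault(tid, []).append(res.flagged)
    if rule == "any":
        return {tid: any(fs) for tid, fs in agg.items()}
    if rule == "all":
        return {tid: all(fs) for tid, fs in agg.items()}
    raise InvalidInputError(f"unknown aggregation rule {rule!r}")
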
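"""Delimited-text input/output for arm tables, band reports and flag reports.

Arm-table schema (UTF-8 CSV, '.' decimal), one row per arm per time point:

    trial_id, comparison_id, time_point, arm_role {control|treatment},
    n, mean, dispersion, dispersion_type {sd|se}[, homogeneity_derived]

Dispersion typed as ``se`` is converted to ``sd = se * sqrt(n)`` (logged).
Rows whose dispersion was derived under a homogeneity-of-variance assumption
(``homogeneity_derived`` truthy) are kept but the comparison is marked
ineligible for tolerance-band reference sets. Exclusions are counted and
logged so a run can account for every input row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .decision import FlagResult
from .exceptions import InvalidInputError
from .summary_stats import ArmSummary, DivbtaEstimate, estimate_comparison
from .tolerance_bands import MetaFit, ToleranceBand

__all__ = [
    "Comparison",
    "read_arm_table",
    "write_arm_table",
    "compute_estimates",
    "write_estimates",
    "write_band_report",
    "write_flag_report",
]

logger = logging.getLogger(__name__)

ARM_COLUMNS = [
    "trial_id",
    "comparison_id",
    "time_point",
    "arm_role",
    "n",
    "mean",
    "dispersion",
    "dispersion_type",
]


@dataclass
class Comparison:
    """One treatment-vs-control contrast at one post-intervention time point."""

    trial_id: str
    comparison_id: str
    time_point: str
    treatment: ArmSummary
    control: ArmSummary
    homogeneity_derived: bool = False
    shares_control: bool = False  # True when the trial has >1 treatment arm


def _row_to_arm(row: pd.Series, idx: int) -> ArmSummary:
    role = str(row["arm_role"]).strip().lower()
    if role not in ("control", "treatment"):
        raise InvalidInputError(f"row {idx}: arm_role must be control|treatment, got {role!r}")
    n = int(row["n"])
    disp = float(row["dispersion"])
    dtype = str(row["dispersion_type"]).strip().lower()
    if dtype == "se":
        sd = disp * math.sqrt(n)
        logger.info("row %d: converted se=%g to sd=%g (n=%d)", idx, disp, sd, n)
    elif dtype == "sd":
        sd = disp
    else:
        raise InvalidInputError(f"row {idx}: dispersion_type must be sd|se, got {dtype!r}")
    return ArmSummary(n=n, mean=float(row["mean"]), sd=sd, role=role)


def read_arm_table(path: Union[str, Path]) -> list[Comparison]:
    """Read and validate an arm table, grouping rows into comparisons.

    Within each (trial_id, time_point) group there must be exactly one
    control row; every treatment row pairs with it. Rows with missing
    dispersion are excluded (counted); any structural violation aborts.
    """
    df = pd.read_csv(
        path,
        dtype={"trial_id": str, "comparison_id": str, "time_point": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InvalidInputError(f"arm table missing column(s): {missing_cols}")
    n_missing_disp = int(df["dispersion"].isna().sum())
    if n_missing_disp:
        logger.info("excluded %d row(s) with missing dispersion", n_missing_disp)
        df = df[df["dispersion"].notna()]

    comparisons: list[Comparison] = []
    errors: list[str] = []
    for (trial_id, time_point), grp in df.groupby(["trial_id", "time_point"], sort=False):
        roles = grp["arm_role"].str.strip().str.lower()
        controls = grp[roles == "control"]
        treatments = grp[roles == "treatment"]
        if len(controls) != 1:
            errors.append(
                f"trial {trial_id!r} @ {time_point!r}: expected exactly 1 control row, "
                f"got {len(controls)}"
            )
            continue
        if len(treatments) == 0:
            errors.append(f"trial {trial_id!r} @ {time_point!r}: no treatment rows")
            continue
        try:
            control = _row_to_arm(controls.iloc[0], int(controls.index[0]))
        except InvalidInputError as exc:
            errors.append(str(exc))
            continue
        multi = len(treatments) > 1
        for idx, row in treatments.iterrows():
            try:
                treatment = _row_to_arm(row, int(idx))
            except InvalidInputError as exc:
                errors.append(str(exc))
                continue
            cid = row.get("comparison_id")
            if pd.isna(cid) or not str(cid):
                cid = f"{trial_id}:{time_point}:{idx}"
            homo = bool(row.get("homogeneity_derived", False)) or bool(
                controls.iloc[0].get("homogeneity_derived", False)
            )
            comparisons.append(
                Comparison(
                    trial_id=str(trial_id),
                    comparison_id=str(cid),
                    time_point=str(time_point),
                    treatment=treatment,
                    control=control,
                    homogeneity_derived=homo,
                    shares_control=multi,
                )
            )
    if errors:
        raise InvalidInputError("arm table has fatal rows:\n" + "\n".join(errors))
    return comparisons


def write_arm_table(path: Union[str, Path], comparisons: Sequence[Comparison]) -> None:
    """Write comparisons back to the arm-table schema (lossless round trip)."""
    rows = []
    seen_controls: set[tuple[str, str]] = set()
    for c in comparisons:
        key = (c.trial_id, c.time_point)
        if key not in seen_controls:
            seen_controls.add(key)
            rows.append(
                {
                    "trial_id": c.trial_id,
                    "comparison_id": "",
                    "time_point": c.time_point,
                    "arm_role": "control",
                    "n": c.control.n,
                    "mean": repr(c.control.mean),
                    "dispersion": repr(c.control.sd),
                    "dispersion_type": "sd",
                    "homogeneity_derived": c.homogeneity_derived,
                }
            )
        rows.append(
            {
                "trial_id": c.trial_id,
                "comparison_id": c.comparison_id,
                "time_point": c.time_point,
                "arm_role": "treatment",
                "n": c.treatment.n,
                "mean": repr(c.treatment.mean),
                "dispersion": repr(c.treatment.sd),
                "dispersion_type": "sd",
                "homogeneity_derived": c.homogeneity_derived,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def compute_estimates(
    comparisons: Sequence[Comparison],
    kind: str = "lnCVR",
    skip_invalid: bool = True,
) -> list[DivbtaEstimate]:
    """lnCVR (or lnVR/lnF) with significance for every comparison.

    Comparisons where the estimator is undefined (e.g. non-positive mean for
    lnCVR) are skipped with a log entry when ``skip_invalid``; otherwise the
    error propagates.
    """
    out: list[DivbtaEstimate] = []
    n_skipped = 0
    for c in comparisons:
        try:
            out.append(
                estimate_comparison(
                    c.treatment,
                    c.control,
                    kind=kind,
                    trial_id=c.trial_id,
                    comparison_id=c.comparison_id,
                    time_point=c.time_point,
                )
            )
        except InvalidInputError:
            if not skip_invalid:
                raise
            n_skipped += 1
    if n_skipped:
        logger.info("excluded %d comparison(s) where %s is not calculable", n_skipped, kind)
    return out


def estimates_frame(estimates: Sequence[DivbtaEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in estimates],
            "comparison_id": [e.comparison_id for e in estimates],
            "time_point": [e.time_point for e in estimates],
            "statistic_kind": [e.statistic_kind for e in estimates],
            "estimate": [e.estimate for e in estimates],
            "sampling_variance": [e.sampling_variance for e in estimates],
            "df": [e.df for e in estimates],
            "p_value": [e.p_value for e in estimates],
        }
    )


def write_estimates(path: Union[str, Path], estimates: Sequence[DivbtaEstimate]) -> None:
    estimates_frame(estimates).to_csv(path, index=False)


def write_band_report(
    path: Union[str, Path], bands: Sequence[ToleranceBand], fit: Optional[MetaFit] = None
) -> None:
    """Band report: kind, sigma_level, lower, upper, k, tau2, var_mean, method."""
    rows = []
    for b in bands:
        rows.append(
            {
                "kind": b.kind,
                "sigma_level": b.sigma_level,
                # repr keeps the bounds bit-exact through the CSV round trip
                "lower": repr(float(b.lower)),
                "upper": repr(float(b.upper)),
                "k": fit.k if fit else None,
                "tau2": fit.tau2 if fit else None,
                "var_mean": fit.var_mean if fit else None,
                "method": fit.method if fit else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_band_report(path: Union[str, Path]) -> list[ToleranceBand]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ToleranceBand(
            lower=float(r["lower"]),
            upper=float(r["upper"]),
            sigma_level=r.get("sigma_level"),
            kind=str(r.get("kind", "prediction_interval")),
        )
        for _, r in df.iterrows()
    ]


def write_flag_report(path: Union[str, Path], results: Sequence[FlagResult]) -> None:
    """Flag report: comparison_id, estimate, p_value, band bounds, flagged, direction."""
    pd.DataFrame(
        {
            "comparison_id": [r.comparison_id for r in results],
            "estimate": [r.estimate for r in results],
            "p_value": [r.p_value for r in results],
            "band_lower": [r.band_used.lower for r in results],
            "band_upper": [r.band_used.upper for r in results],
            "significant": [r.significant for r in results],
            "outlier": [r.outlier for r in results],
            "flagged": [r.flagged for r in results],
            "direction": [r.direction for r in results],
        }
    ).to_csv(path, index=False)
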
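"""Seeded synthetic reference sets written in the arm-table schema.

These emulate the structure of a systematically sampled body of diabetes
trials (two-arm, post-intervention HbA1c summaries, mixed arm sizes) with
known ground-truth band parameters, so parameter-recovery and end-to-end
flagging behaviour can be tested against the truth. A JSON sidecar records
the generating parameters and any spiked (fraudulent) trial ids.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .exceptions import InvalidInputError
from .io import Comparison, write_arm_table
from .simulator import (
    DEFAULT_HETEROGENEITY,
    DEFAULT_OUTCOME,
    HeterogeneityLayer,
    OutcomeModel,
    ScenarioConfig,
    simulate_trial,
)

__all__ = ["generate_fixture"]


def generate_fixture(
    kind: str,
    k_trials: int,
    seed: Optional[int],
    path: Union[str, Path],
    ground_truth_path: Optional[Union[str, Path]] = None,
    n_per_arm: Optional[int] = None,
    fraud_fraction: float = 0.1,
    fraud_replace_fraction: float = 0.9,
    outcome: OutcomeModel = DEFAULT_OUTCOME,
    heterogeneity: HeterogeneityLayer = DEFAULT_HETEROGENEITY,
) -> dict:
    """Write a synthetic arm table and its ground-truth sidecar; return the truth.

    ``kind="reference_set"``: every trial legitimate (randomization +
    heterogeneity only). ``kind="flagged_mix"``: a ``fraud_fraction`` of
    trials additionally undergo the fraud-duplication mechanism with
    ``fraud_replace_fraction``. Arm sizes are drawn log-uniformly in
    [20, 250] unless ``n_per_arm`` fixes them. Identical seeds give
    byte-identical files.
    """
    if kind not in ("reference_set", "flagged_mix"):
        raise InvalidInputError(f"unknown fixture kind {kind!r}")
    if k_trials < 4:
        raise InvalidInputError("k_trials must be >= 4")
    rng = np.random.default_rng(seed)
    n_fraud = int(round(fraud_fraction * k_trials)) if kind == "flagged_mix" else 0
    fraud_ids = set(rng.choice(k_trials, size=n_fraud, replace=False)) if n_fraud else set()

    comparisons = []
    spiked = []
    for i in range(k_trials):
        n = n_per_arm or int(round(math.exp(rng.uniform(math.log(20), math.log(250)))))
        is_fraud = i in fraud_ids
        cfg = ScenarioConfig(
            outcome=outcome,
            heterogeneity=heterogeneity,
            n_per_arm=n,
            mechanism="fraud_duplication" if is_fraud else "none",
            mechanism_params={"replace_fraction": fraud_replace_fraction} if is_fraud else {},
            iterations=1,
        )
        treatment, control = simulate_trial(cfg, rng)
        tid = f"T{i:04d}"
        if is_fraud:
            spiked.append(tid)
        comparisons.append(
            Comparison(
                trial_id=tid,
                comparison_id=f"{tid}:c1",
                time_point="post",
                treatment=treatment,
                control=control,
            )
        )
    write_arm_table(path, comparisons)

    truth = {
        "kind": kind,
        "k_trials": k_trials,
        "seed": seed,
        "outcome_mean": outcome.mean,
        "outcome_sd": outcome.sd,
        "m_star": heterogeneity.m_star,
        "tau2": heterogeneity.tau2,
        "fraud_replace_fraction": fraud_replace_fraction if n_fraud else None,
        "spiked_trials": spiked,
    }
    if ground_truth_path is None:
        ground_truth_path = Path(path).with_suffix(".truth.json")
    Path(ground_truth_path).write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
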
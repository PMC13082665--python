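import numpy as np
import pytest

from divbta.summary_stats import ArmSummary


@pytest.fixture
def equal_arms():
    """Two identical arms (identity cases)."""
    return (
        ArmSummary(n=20, mean=8.0, sd=1.6180339887, role="treatment"),
        ArmSummary(n=20, mean=8.0, sd=1.6180339887, role="control"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_arm(n=20, mean=8.0, sd=1.5, role="treatment"):
    return ArmSummary(n=n, mean=mean, sd=sd, role=role)
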
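import numpy as np
import pandas as pd
import pytest

from oticrank.matrix import ExpressionMatrix, SampleSheet, LOG2


@pytest.fixture
def small_log2_matrix() -> ExpressionMatrix:
    """4 probes × 6 samples, two groups of three, exact hand-checkable values."""
    values = pd.DataFrame(
        {
            "a1": [3.0, 1.0, 5.0, 2.0],
            "a2": [3.0, 2.0, 5.5, 2.0],
            "a3": [3.0, 3.0, 4.5, 2.0],
            "b1": [1.0, 1.0, 1.0, 2.0],
            "b2": [1.0, 2.0, 2.0, 2.0],
            "b3": [1.0, 3.0, 1.5, 2.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return ExpressionMatrix(values=values, scale=LOG2)


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    return SampleSheet(
        sample_to_group={
            "a1": "A", "a2": "A", "a3": "A",
            "b1": "B", "b2": "B", "b3": "B",
        },
        group_roles={"A": "target", "B": "reference"},
    )


@pytest.fixture
def five_group_sheet() -> SampleSheet:
    """The study design: OV/HC/SC targets, periotic/embryo references."""
    samples = {}
    for g, n in [("OV", 3), ("periotic", 3), ("embryo", 3), ("HC", 4), ("SC", 2)]:
        for i in range(1, n + 1):
            samples[f"{g}_{i}"] = g
    return SampleSheet(
        sample_to_group=samples,
        group_roles={
            "OV": "target", "HC": "target", "SC": "target",
            "periotic": "reference", "embryo": "reference",
        },
        target_order=["OV", "HC", "SC"],
    )


def make_five_group_summary(means: pd.DataFrame, sd: float = 0.1):
    """GroupSummary with constant SDs for hand-built mean tables."""
    from oticrank.diffexpr import GroupSummary

    n = pd.Series({g: 3 for g in means.columns})
    sds = pd.DataFrame(sd, index=means.index, columns=means.columns)
    return GroupSummary(means, sds, n)
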
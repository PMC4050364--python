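import numpy as np
import pandas as pd
import pytest

from surfscreen import CohortDesign, ExpressionMatrix, ProbeAnnotation


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples, values 1..12 (log2 scale)."""
    values = pd.DataFrame(
        np.arange(1, 13, dtype=float).reshape(3, 4),
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, "log2")


@pytest.fixture
def two_group_design() -> CohortDesign:
    return CohortDesign(
        groups={"disease": ("s1", "s2"), "normal": ("s3", "s4")},
        disease_group="disease",
        comparator_groups=("normal",),
    )


@pytest.fixture
def tiny_annotation() -> ProbeAnnotation:
    table = pd.DataFrame(
        {
            "symbol": ["CD3D", "GENEB", "GENEC"],
            "membrane": [True, True, False],
            "family": ["CD3_complex", "other", "other"],
        },
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
    )
    return ProbeAnnotation(table=table, aliases={"CD62L": "SELL"})


def make_matrix(values, probes=None, samples=None, scale="log2"):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(1, arr.shape[0] + 1)]
    samples = samples or [f"s{j}" for j in range(1, arr.shape[1] + 1)]
    return ExpressionMatrix(pd.DataFrame(arr, index=probes, columns=samples), scale)
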
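import numpy as np
import pandas as pd
import pytest

from igsurv.cohort import ExpressionMatrix
from igsurv.isotypes import CONSTANT_GENES, REQUIRED_GENES


def make_expression(values: dict, units: str = "TPM") -> ExpressionMatrix:
    """Build an expression matrix from {gene: per-sample list}."""
    df = pd.DataFrame(values).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(values=df.astype(float), units=units)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_expression(rng):
    """All fourteen required genes, six samples, positive random TPM."""
    vals = {g: rng.lognormal(2, 1, size=6) for g in REQUIRED_GENES}
    return make_expression(vals)


@pytest.fixture
def clinical_frame():
    n = 8
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "os_days": [100.0, 400, 700, 900, 1200, 300, 800, 1500],
            "event": [True, True, False, True, False, True, True, False],
            "stage": ["I", "II", "I", "III", "I", "IV", "II", "I"],
            "gender": ["female", "male"] * 4,
            "age": [60, 65, 70, 55, 62, 68, 71, 59],
            "smoking": ["ever", "never"] * 4,
            "subtype": ["PI", "PP", "TRU", "unknown"] * 2,
            "mutation_burden": [5.0, 8.0, 2.0, 11.0, 3.0, 9.0, 6.0, 4.0],
        },
        index=[f"P{i}" for i in range(n)],
    )
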
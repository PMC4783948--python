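import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dppin import ExpressionMatrix


def make_design(conditions, time_points=None, prefix="S"):
    """Build a design frame from a list of conditions (and time points)."""
    n = len(conditions)
    time_points = time_points or ["4h"] * n
    reps: dict = {}
    rows = []
    for i, (cond, tp) in enumerate(zip(conditions, time_points)):
        reps[(cond, tp)] = reps.get((cond, tp), 0) + 1
        rows.append((f"{prefix}{i + 1}", cond, tp, reps[(cond, tp)]))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "time_point", "replicate"])


def make_expr(values, genes=None, conditions=None, time_points=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    conditions = conditions or ["case"] * values.shape[1]
    design = make_design(conditions, time_points)
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=design["sample_id"]), design
    )


@pytest.fixture
def expr_two_groups():
    """2 genes x 4 samples, two case + two control at one time point."""
    return make_expr(
        [[10.0, 20.0, 5.0, 15.0], [1.0, 3.0, 2.0, 4.0]],
        conditions=["case", "case", "control", "control"],
    )
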
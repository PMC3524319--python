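import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from primescreen.expression import ExpressionMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from primescreen.synth import SyntheticSpec, generate_expression


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale design: fewer probes, same planted classes."""
    return SyntheticSpec(
        n_probes=1200,
        n_ld_induced=12, n_ld_reduced=8, n_hd_early=20, n_hd_late=14,
        n_hd_persistent=10, n_readouts=3,
        n_reshuffle_early=3, n_reshuffle_late=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_expression(small_spec)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size design with the default planted counts."""
    return generate_expression(SyntheticSpec(seed=0))


def toy_matrix(values: dict[str, list[float]], conditions=None, calls=None):
    """Tiny matrix helper: values maps sample -> per-probe column."""
    df = pd.DataFrame(values)
    df.index = pd.Index([f"p{i}" for i in range(len(df))], name="probe")
    if conditions is None:
        conditions = {c: c.rsplit("_", 1)[0] for c in df.columns}
    reps = {}
    seen = {}
    for c in df.columns:
        seen[conditions[c]] = seen.get(conditions[c], 0) + 1
        reps[c] = seen[conditions[c]]
    calls_df = None
    if calls is not None:
        calls_df = pd.DataFrame(calls)
        calls_df.index = df.index
    return ExpressionMatrix(df, conditions, reps, calls=calls_df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
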
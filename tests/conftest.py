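import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plaquehub.io_formats import CASE, CONTROL, EdgeTable, ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_expression(values, genes=None, case=None, control=None) -> ExpressionMatrix:
    """Small expression matrix from a 2-D array; first columns are cases."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i+1}" for i in range(n_genes)]
    case = case if case is not None else n_samples // 2
    control = control if control is not None else n_samples - case
    samples = [f"U{i+1}" for i in range(case)] + [f"S{i+1}" for i in range(control)]
    groups = {s: (CASE if s.startswith("U") else CONTROL) for s in samples}
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


def make_edges(pairs, confidence=900) -> EdgeTable:
    rows = [(p[0], p[1], p[2] if len(p) > 2 else confidence) for p in pairs]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    df["confidence"] = df["confidence"].astype(int)
    return EdgeTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
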
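import numpy as np
import pandas as pd
import pytest

from bclandscape.qcnorm import CountMatrix, normalize, run_qc
from bclandscape.synthdata import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A modest cohort exercising every block of the gene panel."""
    return SimulationConfig(n_samples=150, n_genes=320, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    qc = run_qc(small_cohort.counts)
    return normalize(small_cohort.counts, qc)


def make_count_matrix(counts: np.ndarray, n_hk: int, n_neg: int) -> CountMatrix:
    """Wrap a raw array as endogenous + housekeeping + negative probes."""
    n_s, n_p = counts.shape
    n_endo = n_p - n_hk - n_neg
    probes = (
        [f"G{i}" for i in range(n_endo)]
        + [f"HK{i}" for i in range(n_hk)]
        + [f"NEG{i}" for i in range(n_neg)]
    )
    classes = pd.Series(
        ["endogenous"] * n_endo + ["housekeeping"] * n_hk + ["negative"] * n_neg,
        index=probes,
    )
    frame = pd.DataFrame(
        counts, index=[f"S{i}" for i in range(n_s)], columns=probes
    )
    return CountMatrix(counts=frame, probe_class=classes)
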
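"""Shared setup for the numbered analysis drivers.

Every driver re-derives the same cohort from one fixed seed instead of
reading intermediate files, so each script can be run on its own.
"""

from pathlib import Path

from bclandscape.qcnorm import normalize, run_qc
from bclandscape.synthdata import SimulationConfig, simulate_cohort

SEED = 11
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(**overrides) -> SimulationConfig:
    """The default synthetic study: 600 tumors on an 800-gene panel."""
    kwargs = dict(n_samples=600, n_genes=800, degraded_fraction=0.1, seed=SEED)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def load_cohort(**overrides):
    cohort = simulate_cohort(study_config(**overrides))
    qc = run_qc(cohort.counts)
    expr = normalize(cohort.counts, qc)
    return cohort, qc, expr


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
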
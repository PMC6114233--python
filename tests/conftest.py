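"""Shared fixtures: one large calibrated cohort for distributional checks
and one small end-to-end missing-data run reused across imputation tests.

All fixtures are deterministic (fixed seeds) and generated at test time;
nothing is read from disk.
"""

import numpy as np
import pytest

from attrisim.cohort_generator import default_generative_params, generate_cohort
from attrisim.imputation import apply_pmm, impute_twofold_fcs
from attrisim.missingness_engine import (
    apply_missingness,
    assign_participation,
    default_missingness_params,
)
from attrisim.params import ImputationConfig


@pytest.fixture(scope="session")
def global_params():
    return default_generative_params("global")


@pytest.fixture(scope="session")
def memory_params():
    return default_generative_params("memory")


@pytest.fixture(scope="session")
def global_cohort(global_params):
    """n=20,000 fully observed global-regime cohort."""
    return generate_cohort(global_params, 20_000, 101)


@pytest.fixture(scope="session")
def memory_cohort(memory_params):
    return generate_cohort(memory_params, 20_000, 102)


@pytest.fixture(scope="session")
def memory_mi_run(memory_params):
    """Small memory-regime pipeline: blanked panel, M=3 completed panels and
    the delta-adjusted panels, shared across imputation/PMM tests."""
    panel = generate_cohort(memory_params, 800, 42)
    mparams, report = default_missingness_params(panel, seed=1)
    assigned = assign_participation(panel, mparams, 2)
    blanked = apply_missingness(assigned, mparams, 3)
    cfg = ImputationConfig(M=3, b_W=2, b_A=4)
    completed = impute_twofold_fcs(blanked, cfg, seed=7)
    adjusted = apply_pmm(completed, mparams.k, blanked)
    return {
        "panel": panel,
        "mparams": mparams,
        "report": report,
        "assigned": assigned,
        "blanked": blanked,
        "completed": completed,
        "adjusted": adjusted,
        "config": cfg,
    }
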
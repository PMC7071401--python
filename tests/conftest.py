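import warnings

import numpy as np
import pytest

import pdprognosis as pp

# the no-compression warning fires by design whenever screening leaves
# fewer inputs than hidden units; it is not a test failure
warnings.filterwarnings("ignore", message="hidden_size .* input dimension")


def zero_effects(n_regions: int = 78, n_years: int = 4) -> dict:
    return {m: np.zeros((n_regions, n_years)) for m in ("MoCA", "UPDRS")}


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 1)."""
    cfg = pp.CohortConfig(seed=1)
    return pp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_patients(default_cohort):
    """Patients of the default cohort, exclusion rule applied, imputed."""
    table, outcomes, truth = default_cohort
    work = pp.exclude_incomplete(table)
    work = work.subset(work.patient_ids)
    return pp.impute_median(work, work.subject_ids), outcomes, truth
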
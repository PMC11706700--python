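import numpy as np
import pytest

import outcome_qba as q

# Observed-outcome counts of the motivating study (arm sizes 56 059 / 22 319):
# 529/133 cause-specific hospitalisations, 294/72 cause-specific deaths,
# 1969/574 all-cause deaths.
TOTALS = (56_059, 22_319)


@pytest.fixture(scope="session")
def totals():
    return TOTALS


@pytest.fixture(scope="session")
def hosp_full_table():
    return q.TwoByTwo(529, TOTALS[0] - 529, 133, TOTALS[1] - 133)


@pytest.fixture(scope="session")
def death_full_table():
    return q.TwoByTwo(294, TOTALS[0] - 294, 72, TOTALS[1] - 72)


@pytest.fixture(scope="session")
def death_subpop_table():
    """Cause-specific deaths within the any-cause-death subpopulation."""
    return q.TwoByTwo(294, 1969 - 294, 72, 574 - 72, scope="any_event_subpop")


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized synthetic cohort with a degraded observation layer."""
    cfg = q.CohortConfig(n_exposed=6000, n_comparator=4000, seed=202)
    cohort = q.generate_cohort(cfg)
    params = q.BiasParams.nondifferential(0.75, 0.97)
    cohort = q.apply_misclassification(cohort, params, "death", seed=303)
    cohort = q.apply_misclassification(cohort, params, "hosp", seed=303)
    return cohort
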
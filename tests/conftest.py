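import numpy as np
import pytest

from rvenergetics import (
    CohortSpec,
    HemodynamicState,
    generate_beat_waveforms,
    generate_clinical_cohort,
)
from rvenergetics.cli import compute_breakdown_table
from rvenergetics.cohort_stats import records_from_table


@pytest.fixture(scope="session")
def reference_state() -> HemodynamicState:
    """A representative moderate-PAH state (mPAP and CO at the NYHA II
    group means)."""
    return HemodynamicState.from_measurements(
        HR=75.0, mPAP=47.4, PP=30.0, CO=5600.0, EF=0.46,
        mRV_EP=50.4, RV_EDP=8.0,
    )


@pytest.fixture(scope="session")
def reference_waveforms(reference_state):
    """1 kHz synthetic beats for the reference state, with ground-truth
    timings."""
    return generate_beat_waveforms(reference_state, 1000.0)


@pytest.fixture(scope="session")
def small_cohort_records():
    """The study-sized cohort (8/4/3 by NYHA class) with computed
    breakdowns, as CohortRecords."""
    df = generate_clinical_cohort(CohortSpec(seed=11))
    return records_from_table(compute_breakdown_table(df))


@pytest.fixture(scope="session")
def medium_cohort_table():
    """n = 200 cohort in the study's class proportions."""
    spec = CohortSpec(
        n_per_group={"NYHA_II": 107, "NYHA_III": 53, "NYHA_IV": 40}, seed=7
    )
    return generate_clinical_cohort(spec)
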
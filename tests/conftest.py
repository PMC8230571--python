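import numpy as np
import pytest

from ca1ephys import (
    CohortSpec,
    StimulusStep,
    cell_model_for_group,
    default_group_specs,
    extract_feature_table,
    generate_cohort,
    simulate_step,
)
from ca1ephys.biophys import GROUP_LABELS


@pytest.fixture(scope="session")
def wt1m():
    return cell_model_for_group("WT-1m")


@pytest.fixture(scope="session")
def ad10m():
    return cell_model_for_group("AD-10m")


@pytest.fixture(scope="session")
def wt1m_sweep_m50(wt1m):
    """Noiseless WT-1m response to a -50 pA step at the default grid."""
    return simulate_step(wt1m, StimulusStep(amplitude=-50.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Six groups x 3 cells at a coarser grid; enough for pipeline tests."""
    specs = default_group_specs({k: 3 for k in GROUP_LABELS})
    return generate_cohort(CohortSpec(groups=specs, master_seed=11, dt=0.05))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return extract_feature_table(small_cohort.cells)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
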
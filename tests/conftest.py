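import numpy as np
import pytest

from fusiform.behavior.synth import CohortConfig, generate_cohort
from fusiform.ephys.model import DrugState, protocol_library, simulate
from fusiform.ephys.presets import preset_states


@pytest.fixture(scope="session")
def presets():
    return preset_states()


@pytest.fixture(scope="session")
def protocols():
    return protocol_library()


@pytest.fixture(scope="session")
def control_sag_traces(presets, protocols):
    """Control-preset sag steps before and after HCN block (TTX throughout)."""
    pre = simulate(presets["control"], protocols["sag_step"], DrugState(ttx=True))
    post = simulate(presets["control"], protocols["sag_step"],
                    DrugState(ttx=True, zd7288=True))
    return pre, post


@pytest.fixture(scope="session")
def control_gap_free(presets, protocols):
    return simulate(presets["control"], protocols["gap_free"])


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small cohort with zero trial noise: pipeline output equals latents."""
    cfg = CohortConfig(n_control=6, n_tinnitus=4, n_non_tinnitus=3,
                       trial_noise_sd=0.0, baseline_artifact_rate=0.0, seed=11)
    trials, profiles = generate_cohort(cfg)
    return cfg, trials, profiles
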
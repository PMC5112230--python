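import numpy as np
import pytest

from svvdrift import (
    CohortConfig,
    ObserverParams,
    SessionProtocol,
    VirtualObserver,
    run_session,
    sample_cohort,
    simulate_study,
    summarize,
)

# fixed a priori for all stochastic suite checks
SUITE_SEED = 20160573


@pytest.fixture(scope="session")
def default_params():
    return ObserverParams()


@pytest.fixture(scope="session")
def study():
    """One full default study (12 subjects x 2 conditions) plus its analysis."""
    config = CohortConfig()
    specs = sample_cohort(config, SUITE_SEED)
    bundle = simulate_study(specs, config, SUITE_SEED)
    return bundle, summarize(bundle)


@pytest.fixture(scope="session")
def quiet_session_log():
    """One default session of a stationary, unbiased observer."""
    observer = VirtualObserver(params=ObserverParams(delta_EH=0.0))
    rng = np.random.default_rng(SUITE_SEED)
    return run_session(observer, SessionProtocol(), rng)


def degenerate_config(**overrides) -> CohortConfig:
    """Cohort config with all between-subject SDs collapsed to zero."""
    base = dict(
        baseline_svv=(-0.2, 0.0),
        initial_svv={"left": (0.2, 0.0), "right": (-2.6, 0.0)},
        svv_drift={"left": (-5.4, 0.0), "right": (2.2, 0.0)},
        svv_aftereffect={"left": (-3.9, 0.0), "right": (2.55, 0.0)},
        torsion_gain=(0.20, 0.0),
        torsion_drift={"left": (-0.8, 0.0), "right": (0.6, 0.0)},
        torsion_aftereffect={"left": (-0.2, 0.0), "right": (0.2, 0.0)},
        precision={"baseline": (0.7, 0.0), "tilt": (2.0, 0.0), "posttilt": (1.3, 0.0)},
        rt_mean_ms={
            "baseline": (640.0, 0.0),
            "tilt": (686.0, 0.0),
            "posttilt": (661.0, 0.0),
        },
    )
    base.update(overrides)
    return CohortConfig(**base)
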
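import numpy as np
import pytest

from dccsim import FitTargets, ovine_base
from dccsim.engine import BeatTrace
from dccsim.experiments import run_validation_experiment


@pytest.fixture(scope="session")
def hf_targets() -> FitTargets:
    from dccsim.config import load_targets
    return load_targets("hf_mean")


@pytest.fixture(scope="session")
def baseline_targets() -> FitTargets:
    from dccsim.config import load_targets
    return load_targets("baseline_mean")


@pytest.fixture(scope="session")
def base_params():
    return ovine_base(91.0)


@pytest.fixture(scope="session")
def validation():
    """The full mean-level validation experiment, run once per session."""
    return run_validation_experiment(seed=1)


@pytest.fixture(scope="session")
def hf_trace(validation):
    from dccsim.engine import run_to_steady_state
    return run_to_steady_state(validation.hf_fit.params)


def make_trace(t, pressures, volumes=None, flows=None, hr=60.0,
               steady_tol=0.05) -> BeatTrace:
    """Hand-built BeatTrace for metric/PV unit tests."""
    n = len(t)
    vol = volumes if volumes is not None else np.tile(50.0, (n, 8))
    base_p = {k: np.zeros(n) for k in
              ("lv", "rv", "la", "ra", "sa", "sv", "pa", "pv", "ao",
               "pa_meas")}
    base_p.update(pressures)
    base_q = {k: np.zeros(n) for k in
              ("mitral", "aortic", "systemic", "venous_return", "tricuspid",
               "pulmonic", "pulmonary", "pulm_venous_return")}
    if flows:
        base_q.update(flows)
    return BeatTrace(t=np.asarray(t, float), volumes=np.asarray(vol, float),
                     pressures=base_p, flows=base_q, p_dcc=np.zeros(n),
                     hr=hr, beats_to_converge=1, steady_tol=steady_tol)
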
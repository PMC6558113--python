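import warnings

import numpy as np
import pytest

import cdmscreen as cs


@pytest.fixture(autouse=True)
def _quiet_em_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def taxonomy10():
    return cs.default_taxonomy()


@pytest.fixture(scope="session")
def small_study():
    """Clean K=3, J=12, N=500 simulated study."""
    design = cs.SimulationDesign(
        n_respondents=500, n_items=12, n_criteria=3, seed=123
    )
    return cs.simulate_study(design)


@pytest.fixture(scope="session")
def small_fit(small_study):
    """Saturated fit of the small study (with covariances)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.em_fit(
            small_study.responses.to_numpy(float), small_study.q, "GDINA"
        )


def make_qmatrix(entries, prefix="i"):
    entries = np.asarray(entries, dtype=int)
    ids = tuple(f"{prefix}{j}" for j in range(entries.shape[0]))
    crit = tuple(f"C{k+1}" for k in range(entries.shape[1]))
    return cs.QMatrix(entries, ids, crit)
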
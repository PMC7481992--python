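import numpy as np
import pytest

import hemiconn as hc


@pytest.fixture(scope="session")
def eeg_scheme():
    return hc.default_eeg_scheme()


@pytest.fixture(scope="session")
def mri_scheme():
    return hc.default_mri_scheme()


@pytest.fixture(scope="session")
def small_params():
    """Cheap generator settings for unit tests (short recordings)."""
    return hc.SimulationParams(
        n_subjects=4, eeg_duration=5.0, fmri_volumes=60, seed=7
    )


@pytest.fixture(scope="session")
def small_subject(small_params):
    return hc.simulate_subject(small_params, 0)


@pytest.fixture(scope="session")
def small_result(small_subject):
    return hc.process_subject(small_subject)


def random_connectome(scheme, rng):
    """A random valid correlation-valued connectome (symmetric, diag 1)."""
    n = len(scheme)
    w = rng.uniform(-1.0, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return hc.ConnectivityMatrix(w, scheme)


def mirror_connectome(fc):
    """Swap left and right hemisphere data via the homologue permutation."""
    scheme = fc.scheme
    perm = np.array([scheme.index(n.homologue) for n in scheme.nodes])
    return hc.ConnectivityMatrix(fc.weights[np.ix_(perm, perm)], scheme)
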
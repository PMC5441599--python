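import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230517)


@pytest.fixture(scope="session")
def telegraph_30us():
    """Standard quenching fixture: 30 us binary signal at 30 ps sampling
    (1e6 frames) with the equilibrated-regime contact rates."""
    from petquench.synthetic_data import TelegraphParams, simulate_telegraph

    params = TelegraphParams(k_form_per_us=8.4, k_diss_per_us=5.5,
                             dt_ns=0.03, n_steps=1_000_000, seed=7)
    return params, simulate_telegraph(params)


@pytest.fixture(scope="session")
def telegraph_10ms():
    """Long, well-converged symmetric telegraph record (10 ms at 10 ns):
    sampling noise is far below the correlator-equivalence tolerance."""
    from petquench.synthetic_data import TelegraphParams, simulate_telegraph

    params = TelegraphParams(k_form_per_us=5.0, k_diss_per_us=5.0,
                             dt_ns=10.0, n_steps=1_000_000, seed=13)
    return params, simulate_telegraph(params)


@pytest.fixture(scope="session")
def planted_ensemble():
    """Three well-separated planted clusters with weights 60/30/10%."""
    from petquench.synthetic_data import EnsembleSpec, simulate_ensemble

    gen = np.random.default_rng(11)
    centers = [gen.normal(0.0, 1.0, (20, 3)),
               gen.normal(0.0, 1.0, (20, 3)) * 1.4 + 2.0,
               gen.normal(0.0, 1.0, (20, 3)) * 0.7 - 2.0]
    spec = EnsembleSpec(center_structures=centers, weights=(0.6, 0.3, 0.1),
                        within_cluster_sd_nm=0.03, n_frames=600, seed=4)
    ens, assignment = simulate_ensemble(spec)
    return spec, ens, assignment
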
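import pytest

from blinar.simstudy import SimStudyConfig, estimator_samples, run_sim_study


@pytest.fixture(scope="session")
def grid_table_t1000():
    """Full parameter grid at T=1000, 800 replicates, all three estimators.

    Shared by the estimator-ordering and MSE-monotonicity checks so the
    heavy Monte Carlo runs once per session.
    """
    cfg = SimStudyConfig(lengths=(1000,), replicates=800, seed=11)
    return run_sim_study(cfg)


@pytest.fixture(scope="session")
def cml_replicates_0515():
    """Raw CML replicate estimates at (alpha, theta, T) = (0.5, 1.5, 1000)."""
    return estimator_samples(0.5, 1.5, 1000, 300, master_seed=13, estimator="cml")
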
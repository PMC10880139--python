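import numpy as np
import pytest

from climat import ClimatForecaster, TrajectoryConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """48 subjects, 3 ordinal classes, two follow-up horizons, mild noise."""
    cfg = TrajectoryConfig(
        n_subjects=48,
        T=2,
        n_classes_per_task=(3, 3, 3),
        image_size=(64, 64),
        noise_sd=0.02,
        missing_target_rate=0.2,
        missing_covariate_rate=0.1,
        seed=11,
    )
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def tiny_fitted(small_cohort):
    """A briefly trained forecaster shared by inference-side tests."""
    records, _ = small_cohort
    fc = ClimatForecaster(
        epochs=2, lr=1e-3, depth_p=2, n_classes_per_task=(3, 3, 3), seed=0
    )
    fc.fit(records)
    return fc, records


@pytest.fixture(scope="session")
def recovery_results():
    """Parameter-recovery experiment at its reference conditions, 3 seeds."""
    from climat.experiments import run_parameter_recovery

    return [run_parameter_recovery(seed) for seed in (0, 1, 2)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
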
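import hypothesis
import pytest

from mirqtl import SimConfig, generate_cohort, planted_cascade_config

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cascade_cohort():
    """Small planted-cascade cohort shared by read-only tests."""
    return generate_cohort(planted_cascade_config(seed=42, n_samples=200))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every effect zero, for calibration checks."""
    return generate_cohort(
        SimConfig(n_samples=200, n_variants=20, n_mirna=10, n_mrna=10, seed=11)
    )
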
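import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference():
    from evmir.synthetic import generate_reference

    return generate_reference(20, seed=11)


@pytest.fixture(scope="session")
def null_design_counts():
    """A no-effect 300-feature compartment used by several modules."""
    from evmir.synthetic import SyntheticDesign, generate_counts

    design = SyntheticDesign(n_features=300, seed=99)
    return generate_counts(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def published_tables():
    from evmir.published import load_panel_table

    return {"bdev": load_panel_table("bdev"), "serum": load_panel_table("serum")}
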
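import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from urbancarbon import GeneratorConfig, ModelConstants, ProvinceInputs, calibrate_national
from urbancarbon.synthetic import generate_provinces

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture()
def demo_province() -> ProvinceInputs:
    """A mid-sized province with all four pools populated."""
    return ProvinceInputs(
        province_id="demo",
        region="East",
        area_urban=1000.0,
        green_frac=0.31,
        d_green=1.5,
        d_sgreen=8.0,
        d_simp=6.0,
        sd_simp=2.0,
        pop_urban=2.0e7,
        floor_resid=40_000.0,
        floor_total=70_000.0,
        n_set=1.2,
        n_household=6.5e6,
    )


@pytest.fixture(scope="session")
def synthetic_table():
    table, truth = generate_provinces(GeneratorConfig(seed=7))
    return table, truth


@pytest.fixture(scope="session")
def calibrated_table() -> pd.DataFrame:
    """Synthetic provinces rescaled to the published national aggregates."""
    return calibrate_national(GeneratorConfig(seed=11))
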
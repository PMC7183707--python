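import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ovatriage as ov

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def record_factory():
    """Build a valid PatientRecord with overridable fields."""

    def make(**kwargs):
        defaults = dict(
            id="P001",
            age=45.0,
            menopausal=ov.MenopausalStatus.PRE,
            ca125=35.0,
            he4=50.0,
            ultrasound=ov.UltrasoundFindings(),
            max_diameter_cm=5.0,
            histology=ov.Histology.BENIGN,
        )
        defaults.update(kwargs)
        return ov.PatientRecord(**defaults)

    return make


@pytest.fixture
def random_record_factory(record_factory):
    """Draw random but valid records from a seeded generator."""

    def make(rng: np.random.Generator):
        return record_factory(
            menopausal=rng.choice([ov.MenopausalStatus.PRE, ov.MenopausalStatus.POST]),
            ca125=float(rng.lognormal(3.0, 1.2)),
            he4=float(rng.lognormal(3.8, 0.6)),
            ultrasound=ov.UltrasoundFindings(*(bool(b) for b in rng.random(5) < 0.4)),
            max_diameter_cm=float(rng.lognormal(1.8, 0.4)),
        )

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 155-record synthetic cohort under default conditions."""
    return ov.generate_cohort(ov.default_config(seed=7))
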
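import numpy as np
import pytest

from mrkit import InstrumentSet, harmonize, load_fixture

MICRONUTRIENTS = ("phosphorus", "magnesium", "selenium", "iron", "zinc", "copper")


@pytest.fixture(scope="session")
def fixture_instruments():
    """Harmonized instrument sets for all six packaged micronutrients."""
    out = {}
    for name in MICRONUTRIENTS:
        study = load_fixture(name)
        out[name] = harmonize(study.exposure, study.outcome)
    return out


@pytest.fixture(scope="session")
def iron(fixture_instruments):
    return fixture_instruments["iron"]


@pytest.fixture(scope="session")
def phosphorus(fixture_instruments):
    return fixture_instruments["phosphorus"]


@pytest.fixture(scope="session")
def magnesium(fixture_instruments):
    return fixture_instruments["magnesium"]


def random_instruments(rng, k=6, theta=0.2):
    """A well-behaved random instrument set for property tests."""
    bx = rng.uniform(0.05, 0.4, size=k) * rng.choice([-1.0, 1.0], size=k)
    sx = rng.uniform(0.005, 0.03, size=k)
    sy = rng.uniform(0.02, 0.06, size=k)
    by = theta * bx + rng.normal(0.0, sy)
    return InstrumentSet.from_summary(bx, sx, by, sy)
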
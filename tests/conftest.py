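import numpy as np
import pytest

from aimpanel.synthetic_data import reference_like_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 5-group reference-like cohort (fixed seed)."""
    return reference_like_fixture()


@pytest.fixture(scope="session")
def main4(fixture_cohort):
    """The four primary continental groups of the fixture."""
    return fixture_cohort.table.restrict_groups(["AFR", "EUR", "EAS", "NAM"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
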
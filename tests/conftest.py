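import numpy as np
import pytest

import sexalloc as sa
from sexalloc.config import generate_fixture


@pytest.fixture(scope="session")
def productive():
    return sa.preset("productive")


@pytest.fixture(scope="session")
def poor():
    return sa.preset("poor")


@pytest.fixture(scope="session")
def case1_symmetric_productive(productive):
    """Identical-sexes model built as case 1 with Cm = Cf = 0.5, plus its SS."""
    model = sa.build_case_model(
        1, productive, sa.CostModel(case_id=1, Cm=0.5, Cf=0.5))
    report = sa.find_singular_strategy(model)
    assert isinstance(report, sa.SingularStrategyReport)
    return model, report


@pytest.fixture(scope="session")
def case1_asymmetric_productive(productive):
    model = sa.build_case_model(
        1, productive, sa.CostModel(case_id=1, Cm=0.6, Cf=0.4))
    report = sa.find_singular_strategy(model)
    assert isinstance(report, sa.SingularStrategyReport)
    return model, report


def make_fixture_model(seed: int):
    """Random valid scenario model, deterministic in the seed."""
    return generate_fixture(seed).build_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20160209)
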
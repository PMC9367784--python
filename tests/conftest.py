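import pytest

from cattle_lca.config import paper_scenarios


@pytest.fixture(scope="session")
def ec_spec():
    return paper_scenarios()[0]


@pytest.fixture(scope="session")
def nonec_spec():
    return paper_scenarios()[1]


@pytest.fixture()
def zero_spec(ec_spec):
    """A degenerate but legal scenario: empty herd, no planting area."""
    data = ec_spec.model_dump()
    data["name"] = "zero"
    data["herd"]["herd_size"] = 0.0
    data["planting"]["planting_area"] = 0.0
    data["planting"]["feed_intake_per_head_day"] = 0.0
    data["overrides"] = {}
    from cattle_lca.config import ScenarioSpec

    return ScenarioSpec.model_validate(data)
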
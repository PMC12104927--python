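import pandas as pd
import pytest

from tdabc import SyntheticSpec, generate_clinic, load_paper_fixture, paper_reference


@pytest.fixture(scope="session")
def clinic1():
    return load_paper_fixture("clinic1")


@pytest.fixture(scope="session")
def clinic2():
    return load_paper_fixture("clinic2")


@pytest.fixture(scope="session")
def reference() -> pd.DataFrame:
    """Published per-activity Monte Carlo summaries, indexed by activity id."""
    return paper_reference().set_index("activity_id")


@pytest.fixture(scope="session")
def synthetic():
    """One default synthetic clinic and its analytic truth table."""
    return generate_clinic(SyntheticSpec(seed=7))


def activity_by_id(model, activity_id):
    return model.process_map.activity(activity_id)
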
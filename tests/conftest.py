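import pytest

from natremia.cohort import bundled_paper_cohort


@pytest.fixture(scope="session")
def paper_cohort():
    return bundled_paper_cohort()
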
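import pytest
from hypothesis import settings

import ntd_fortify as nf

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return nf.RiskModelParams()


@pytest.fixture(scope="session")
def delta_us():
    """Serum-folate increment of US-level fortification, nmol/L (3 s.f.)."""
    return 4.26


@pytest.fixture(scope="session")
def table2_dists():
    """Per-country folate distributions from the packaged survey table."""
    return nf.folate_distributions()


@pytest.fixture(scope="session")
def surveyed_dists(table2_dists):
    """Only countries whose survey measured both a median and a log-SD."""
    t2 = nf.load_fixture("table2")
    own = set(
        t2[t2["median_nmol_l"].notna() & t2["log_sd"].notna()]["country_code"]
    )
    return {c: d for c, d in table2_dists.items() if c in own}
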
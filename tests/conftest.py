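import pytest

from climsens import evidence as ev
from climsens import gbd
from climsens import profiles as prof
from climsens.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def synth_tables():
    """One default synthetic cohort (157 pathogens) shared across tests."""
    return generate(SynthConfig())


@pytest.fixture(scope="session")
def cohort(synth_tables):
    """(profiles, attributes) for the default synthetic cohort."""
    attrs_df, evid_df = synth_tables
    profiles = ev.profiles_from_frame(evid_df, list(attrs_df.pathogen_id))
    attributes = prof.attributes_from_frame(attrs_df)
    return profiles, attributes


@pytest.fixture(scope="session")
def burden_rows():
    """The packaged 25-disease GBD 2010 burden table."""
    return gbd.packaged_burden_table()
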
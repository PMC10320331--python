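import numpy as np
import pytest

from pacelife.records import BreedingEvent, IndividualRecord


@pytest.fixture
def simple_record():
    """Three breeding seasons at ages 3-5, death at 8."""
    return IndividualRecord(
        individual_id="ind1",
        species="spA",
        events=[
            BreedingEvent(age=3, attempted=True, offspring=1),
            BreedingEvent(age=4, attempted=True, offspring=2),
            BreedingEvent(age=5, attempted=True, offspring=2),
        ],
        death_age=8,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230511)


def make_record(iid, species, ages_offspring, death_age):
    """Record builder: ages_offspring is a list of (age, offspring)."""
    events = [
        BreedingEvent(age=a, attempted=True, offspring=o)
        for a, o in ages_offspring
    ]
    return IndividualRecord(
        individual_id=iid, species=species, events=events, death_age=death_age
    )
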
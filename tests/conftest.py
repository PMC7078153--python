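import pytest

from oilimpact import (
    MortalityRange,
    MortalityTable,
    OilingCategory,
    Species,
    apply_photo_review,
    default_mortality_table,
    reference_photo_review_updates,
    reference_survey,
    tally,
)


def degenerate_table(species, trace, light, moderate, heavy=None):
    """All ranges collapsed to points: the simulation's analytic test bench."""
    heavy = max(moderate, 0.95) if heavy is None else heavy
    return MortalityTable(
        {
            (species, OilingCategory.TRACE): MortalityRange(trace, trace),
            (species, OilingCategory.LIGHT): MortalityRange(light, light),
            (species, OilingCategory.MODERATE): MortalityRange(moderate, moderate),
            (species, OilingCategory.HEAVY): MortalityRange(heavy, heavy),
        }
    )


@pytest.fixture(scope="session")
def pelican_records():
    return reference_survey(Species.AMWP)


@pytest.fixture(scope="session")
def loon_records():
    return reference_survey(Species.COLO)


@pytest.fixture(scope="session")
def gannet_records():
    """Gannet survey as recorded in the field (before photo review)."""
    return reference_survey(Species.NOGA)


@pytest.fixture(scope="session")
def gannet_reviewed_records(gannet_records):
    """Gannet survey after the two photo-review trace upgrades."""
    return apply_photo_review(
        gannet_records, reference_photo_review_updates(Species.NOGA)
    )


@pytest.fixture(scope="session")
def pelican_tally(pelican_records):
    return tally(pelican_records, Species.AMWP)


@pytest.fixture(scope="session")
def loon_tally(loon_records):
    return tally(loon_records, Species.COLO)


@pytest.fixture(scope="session")
def gannet_tally(gannet_reviewed_records):
    return tally(gannet_reviewed_records, Species.NOGA)


@pytest.fixture(scope="session")
def panel_table():
    return default_mortality_table()
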
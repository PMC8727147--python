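import numpy as np
import pandas as pd
import pytest

from virodiscover import (
    AssociationRecord,
    FilterConfig,
    apply_filters,
    dedupe_to_pairs,
    proportional_config,
    simulate,
)


def rec(
    species="Myotis myotis",
    family="Vespertilionidae",
    order="Chiroptera",
    status="wild",
    virus="Virus A",
    resolution="ictv",
    detection="pcr",
    year=2000,
    source="t",
):
    return AssociationRecord(
        host_species=species,
        host_family=family,
        host_order=order,
        host_status=status,
        virus=virus,
        virus_resolution=resolution,
        detection=detection,
        year=year,
        source=source,
    )


def pairs_from_sim(result, cfg=None):
    """Run a simulation's association table through ingest filtering + dedup."""
    records = [AssociationRecord(**row) for row in result.associations.to_dict("records")]
    return dedupe_to_pairs(apply_filters(records, cfg or FilterConfig()))


@pytest.fixture(scope="session")
def sim_small():
    """A small proportional-sampling world shared by read-only tests."""
    return simulate(proportional_config(seed=11))


@pytest.fixture(scope="session")
def sim_small_pairs(sim_small):
    return pairs_from_sim(sim_small)


@pytest.fixture()
def mixed_records():
    """Hand-built records exercising every filter predicate and the dedup rules."""
    return [
        rec(virus="Virus A", year=1975, detection="serology"),
        rec(virus="Virus A", year=1962, detection="isolation"),
        rec(virus="Virus B", year=1990, detection="pcr"),
        rec(species="Canis lupus", family="Canidae", order="Carnivora", virus="Virus B", year=2001),
        rec(species="Sus scrofa", family="Suidae", order="Artiodactyla", status="domestic", virus="Virus C", year=1985),
        rec(virus="Strain X-001", resolution="unresolved", year=2010),
        rec(species="Canis lupus", family="Canidae", order="Carnivora", virus="Virus D", year=2019),
        rec(virus="Virus E", year=2005, detection="serology"),
    ]
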
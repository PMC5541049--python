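"""Cohort summaries, driver frequencies, co-occurrence and facet breakdowns."""

import pytest

from climsens.evidence import SensitivityProfile
from climsens.ontology import TAXA, TRANSMISSION_ROUTES, HostClass, ValidationError, default_vocabulary
from climsens.profiles import (
    PathogenAttributes,
    attributes_from_frame,
    attributes_frame,
    breakdown_by,
    driver_frequencies,
    driver_pairs,
    summarise,
)

VOCAB = default_vocabulary()
RAIN = VOCAB.get("rainfall")
MOIST = VOCAB.get("moisture")
TEMP = VOCAB.get("temperature")
ALT = VOCAB.get("Alt")


def profile(pid, *drivers):
    return SensitivityProfile(pid, {d: 40.0 for d in drivers})


def attrs(pid, taxon="bacteria", routes=("foodborne",), host=HostClass.ZOONOTIC,
          emerging=False, h=10, countries=5):
    return PathogenAttributes(pid, taxon, frozenset(routes), host, emerging, h, countries)


@pytest.fixture
def tiny_cohort():
    profiles = [
        profile("P1", RAIN, MOIST, TEMP),
        profile("P2", RAIN, ALT),
        profile("P3", ALT),
        profile("P4"),
    ]
    attributes = {
        "P1": attrs("P1", taxon="protozoa", routes=("vector-borne", "waterborne")),
        "P2": attrs("P2", taxon="bacteria", routes=("foodborne",)),
        "P3": attrs("P3", taxon="bacteria", routes=("foodborne", "airborne")),
        "P4": attrs("P4", taxon="viruses", routes=("airborne",)),
    }
    return profiles, attributes


def test_summarise_counts(tiny_cohort):
    profiles, attributes = tiny_cohort
    s = summarise(profiles, attributes)
    assert (s.n_total, s.n_sensitive) == (4, 3)
    assert s.driver_count_histogram == {3: 1, 2: 1, 1: 1, 0: 1}
    assert sum(s.driver_count_histogram.values()) == s.n_total
    assert s.driver_count_histogram[0] == s.n_total - s.n_sensitive
    assert (s.n_has_primary, s.n_has_secondary, s.n_secondary_only) == (2, 2, 1)
    assert s.n_has_primary + s.n_secondary_only == s.n_sensitive


def test_summarise_empty_roster():
    s = summarise([], {})
    assert s.n_total == 0 and s.n_sensitive == 0
    assert s.fraction_sensitive() == 0.0


def test_summarise_roster_mismatch(tiny_cohort):
    profiles, attributes = tiny_cohort
    with pytest.raises(ValidationError):
        summarise(profiles[:-1], attributes)


def test_driver_frequencies_ranking(tiny_cohort):
    profiles, attributes = tiny_cohort
    ranked = driver_frequencies(summarise(profiles, attributes))
    assert ranked[0] in {(ALT, 2), (RAIN, 2)}
    # descending counts, alphabetical tie-break
    counts = [c for _, c in ranked]
    assert counts == sorted(counts, reverse=True)
    assert [d.name for d, _ in ranked[:2]] == ["altitude", "rainfall"]


def test_driver_frequency_conservation(cohort):
    """Driver frequencies recount exactly the per-profile positive sets."""
    profiles, attributes = cohort
    s = summarise(profiles, attributes)
    assert sum(s.driver_frequency.values()) == sum(
        p.n_drivers for p in profiles if p.is_sensitive
    )


def test_driver_pairs_combinatorics(tiny_cohort):
    profiles, attributes = tiny_cohort
    s = summarise(profiles, attributes)
    # P1 has 3 drivers -> contributes C(3,2)=3 pairs; P2 contributes 1
    assert sum(s.pair_counts.values()) == 4
    assert s.pair_counts[frozenset({RAIN, MOIST})] == 1
    assert s.pair_counts[frozenset({RAIN, ALT})] == 1


def test_pair_counts_bounded_by_marginals(cohort):
    profiles, attributes = cohort
    s = summarise(profiles, attributes)
    for pair, count in driver_pairs(s):
        a, b = sorted(pair)
        assert count <= min(s.driver_frequency[a], s.driver_frequency[b])
    # brute-force recount of the most common pair
    if s.pair_counts:
        pair, count = driver_pairs(s)[0]
        recount = sum(1 for p in profiles if pair <= p.positive_drivers)
        assert recount == count


def test_breakdown_taxon_partitions(cohort):
    profiles, attributes = cohort
    by_taxon = breakdown_by(profiles, attributes, "taxon")
    assert set(by_taxon) == set(TAXA)
    assert sum(s.n_total for s in by_taxon.values()) == len(profiles)


def test_breakdown_route_multi_membership(cohort):
    profiles, attributes = cohort
    by_route = breakdown_by(profiles, attributes, "route")
    assert set(by_route) == set(TRANSMISSION_ROUTES)
    assert sum(s.n_total for s in by_route.values()) == sum(
        len(a.routes) for a in attributes.values()
    )


def test_breakdown_single_route_cohort_equals_global(tiny_cohort):
    profiles, attributes = tiny_cohort
    single = {
        pid: attrs(pid, taxon=a.taxon, routes=("foodborne",))
        for pid, a in attributes.items()
    }
    by_route = breakdown_by(profiles, single, "route")
    global_summary = summarise(profiles, single)
    assert by_route["foodborne"].n_total == global_summary.n_total
    assert by_route["foodborne"].driver_count_histogram == global_summary.driver_count_histogram
    assert all(s.n_total == 0 for r, s in by_route.items() if r != "foodborne")


def test_breakdown_unknown_facet(tiny_cohort):
    profiles, attributes = tiny_cohort
    with pytest.raises(ValueError):
        breakdown_by(profiles, attributes, "host")


def test_attributes_frame_roundtrip(cohort):
    _, attributes = cohort
    frame = attributes_frame(attributes)
    back = attributes_from_frame(frame)
    assert back == attributes


def test_attribute_validation():
    with pytest.raises(ValidationError):
        attrs("P1", taxon="prions")
    with pytest.raises(ValidationError):
        attrs("P1", routes=())
    with pytest.raises(ValidationError):
        attrs("P1", routes=("telepathy",))
    with pytest.raises(ValidationError):
        PathogenAttributes("P1", "bacteria", frozenset({"foodborne"}),
                           HostClass.ZOONOTIC, False, -1, 5)
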
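"""Descriptive statistics over sensitivity profiles.

Counts of climate-sensitive pathogens, driver-count histograms, the
primary/secondary split, per-driver frequencies, driver co-occurrence, and
breakdowns by taxon or transmission route.  All outputs are integer counts;
percentages are derived on demand to avoid compounding rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .evidence import SensitivityProfile
from .ontology import (
    TAXA,
    TRANSMISSION_ROUTES,
    ClimateDriver,
    HostClass,
    ValidationError,
)

__all__ = [
    "PathogenAttributes",
    "CohortSummary",
    "summarise",
    "driver_frequencies",
    "driver_pairs",
    "breakdown_by",
    "attributes_from_frame",
    "read_attributes_csv",
    "attributes_frame",
]


@dataclass(frozen=True)
class PathogenAttributes:
    """Static characteristics of one pathogen."""

    pathogen_id: str
    taxon: str
    routes: frozenset[str]
    host_class: HostClass
    emerging: bool
    h_index: int
    n_countries: int

    def __post_init__(self):
        if self.taxon not in TAXA:
            raise ValidationError(f"unknown taxon {self.taxon!r}")
        if not self.routes:
            raise ValidationError(f"{self.pathogen_id!r} has no transmission routes")
        bad = set(self.routes) - set(TRANSMISSION_ROUTES)
        if bad:
            raise ValidationError(f"unknown transmission routes: {sorted(bad)}")
        if self.h_index < 0 or self.n_countries < 0:
            raise ValidationError("h_index and n_countries must be non-negative")

    @property
    def zoonotic(self) -> bool:
        return self.host_class is HostClass.ZOONOTIC


@dataclass
class CohortSummary:
    """Counts describing one cohort (or facet level) of pathogens."""

    n_total: int = 0
    n_sensitive: int = 0
    driver_count_histogram: dict[int, int] = field(default_factory=dict)
    n_has_primary: int = 0
    n_has_secondary: int = 0
    n_secondary_only: int = 0
    driver_frequency: Counter = field(default_factory=Counter)
    pair_counts: Counter = field(default_factory=Counter)

    def fraction_sensitive(self) -> float:
        return self.n_sensitive / self.n_total if self.n_total else 0.0

    def fraction_with_at_least(self, k: int) -> float:
        """Share of the cohort with >= k positive drivers."""
        if not self.n_total:
            return 0.0
        n = sum(c for kk, c in self.driver_count_histogram.items() if kk >= k)
        return n / self.n_total


def _check_roster(
    profiles: Sequence[SensitivityProfile],
    attributes: Mapping[str, PathogenAttributes] | None,
) -> None:
    if attributes is None:
        return
    prof_ids = {p.pathogen_id for p in profiles}
    if prof_ids != set(attributes):
        raise ValidationError("profiles and attributes cover different pathogen rosters")


def summarise(
    profiles: Sequence[SensitivityProfile],
    attributes: Mapping[str, PathogenAttributes] | None = None,
    predicate: Callable[[SensitivityProfile, PathogenAttributes | None], bool] | None = None,
) -> CohortSummary:
    """Summarise a cohort, optionally restricted by a predicate.

    The predicate receives each profile and its attributes (``None`` when no
    attribute table is supplied) and keeps the pathogen when it returns True.
    """
    _check_roster(profiles, attributes)
    summary = CohortSummary()
    for prof in profiles:
        attrs = attributes[prof.pathogen_id] if attributes is not None else None
        if predicate is not None and not predicate(prof, attrs):
            continue
        summary.n_total += 1
        k = prof.n_drivers
        summary.driver_count_histogram[k] = summary.driver_count_histogram.get(k, 0) + 1
        if not prof.is_sensitive:
            continue
        summary.n_sensitive += 1
        if prof.has_primary:
            summary.n_has_primary += 1
        if prof.has_secondary:
            summary.n_has_secondary += 1
        if prof.has_secondary and not prof.has_primary:
            summary.n_secondary_only += 1
        positive = sorted(prof.positive_drivers)
        summary.driver_frequency.update(positive)
        summary.pair_counts.update(frozenset(p) for p in combinations(positive, 2))
    return summary


def driver_frequencies(summary: CohortSummary) -> list[tuple[ClimateDriver, int]]:
    """Drivers ranked by frequency among sensitive pathogens.

    Descending by count; ties broken alphabetically by driver name.
    """
    return sorted(summary.driver_frequency.items(), key=lambda kv: (-kv[1], kv[0].name))


def driver_pairs(summary: CohortSummary) -> list[tuple[frozenset[ClimateDriver], int]]:
    """Unordered driver pairs ranked by co-occurrence among sensitive pathogens."""
    return sorted(
        summary.pair_counts.items(),
        key=lambda kv: (-kv[1], tuple(sorted(d.name for d in kv[0]))),
    )


def breakdown_by(
    profiles: Sequence[SensitivityProfile],
    attributes: Mapping[str, PathogenAttributes],
    facet: str,
) -> dict[str, CohortSummary]:
    """Per-facet summaries; ``facet`` is ``"taxon"`` or ``"route"``.

    Taxa partition the cohort; a pathogen with several transmission routes
    contributes to every one of its routes' summaries.
    """
    if facet == "taxon":
        return {
            taxon: summarise(
                profiles, attributes, lambda p, a, t=taxon: a is not None and a.taxon == t
            )
            for taxon in TAXA
        }
    if facet == "route":
        return {
            route: summarise(
                profiles, attributes, lambda p, a, r=route: a is not None and r in a.routes
            )
            for route in TRANSMISSION_ROUTES
        }
    raise ValueError(f"unknown facet {facet!r}; expected 'taxon' or 'route'")


def attributes_from_frame(df: pd.DataFrame) -> dict[str, PathogenAttributes]:
    """Build validated attributes from an in-memory frame.

    Expected columns: pathogen_id, taxon, routes (semicolon-joined),
    host_class, emerging (0/1), h_index, n_countries.  Extra columns (e.g.
    simulator truth columns) are ignored.
    """
    required = {
        "pathogen_id", "taxon", "routes", "host_class", "emerging", "h_index", "n_countries",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"attributes CSV missing columns: {sorted(missing)}")
    out: dict[str, PathogenAttributes] = {}
    for row in df.itertuples(index=False):
        attrs = PathogenAttributes(
            pathogen_id=str(row.pathogen_id),
            taxon=str(row.taxon),
            routes=frozenset(
                r.strip() for r in str(row.routes).split(";") if r.strip()
            ),
            host_class=HostClass(str(row.host_class)),
            emerging=bool(int(row.emerging)),
            h_index=int(row.h_index),
            n_countries=int(row.n_countries),
        )
        if attrs.pathogen_id in out:
            raise ValidationError(f"duplicate pathogen_id {attrs.pathogen_id!r}")
        out[attrs.pathogen_id] = attrs
    return out


def read_attributes_csv(path) -> dict[str, PathogenAttributes]:
    """Read a pathogen-attribute table keyed by pathogen_id."""
    return attributes_from_frame(pd.read_csv(path, dtype={"pathogen_id": str}))


def attributes_frame(attributes: Mapping[str, PathogenAttributes]) -> pd.DataFrame:
    """Serialise attributes back to the CSV column contract."""
    rows = [
        {
            "pathogen_id": a.pathogen_id,
            "taxon": a.taxon,
            "routes": ";".join(sorted(a.routes)),
            "host_class": a.host_class.value,
            "emerging": int(a.emerging),
            "h_index": a.h_index,
            "n_countries": a.n_countries,
        }
        for a in attributes.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pathogen_id", "taxon", "routes", "host_class",
            "emerging", "h_index", "n_countries",
        ],
    )
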
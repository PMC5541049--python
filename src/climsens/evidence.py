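"""Literature-evidence records and their aggregation into sensitivity profiles.

Each record is one literature finding scoring the link between a pathogen and
a climate driver.  Scores live on a signed semi-quantitative rubric grid
(default ``{5, 20, 40, 60, 80}`` and its negation for contradicting evidence).
Per (pathogen, driver) pair the records are reduced to their median; a pair
carries *positive evidence* when that median is strictly greater than zero.
A pathogen's sensitivity profile is the set of drivers with positive evidence
plus derived flags (has a primary driver / has a secondary driver).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ontology import (
    ClimateDriver,
    ValidationError,
    Vocabulary,
    default_vocabulary,
    format_driver_codes,
)

__all__ = [
    "DEFAULT_RUBRIC_GRID",
    "EvidenceRecord",
    "SensitivityProfile",
    "median_score",
    "aggregate",
    "build_profiles",
    "records_from_frame",
    "profiles_from_frame",
    "read_evidence_csv",
    "medians_frame",
    "profiles_frame",
]

#: Allowed absolute score values for a literature record.
DEFAULT_RUBRIC_GRID: frozenset[float] = frozenset({5.0, 20.0, 40.0, 60.0, 80.0})


@dataclass(frozen=True)
class EvidenceRecord:
    """One literature finding: pathogen x driver x signed strength score.

    ``tag`` is an optional free-text annotation (e.g. direct vs indirect
    action of the driver); no computation consumes it.
    """

    pathogen_id: str
    driver: ClimateDriver
    score: float
    source_id: str = ""
    tag: str | None = None

    def validate(self, grid: frozenset[float] = DEFAULT_RUBRIC_GRID) -> None:
        if abs(self.score) not in grid:
            raise ValidationError(
                f"score {self.score} for {self.pathogen_id!r}/{self.driver.code} "
                f"is not on the rubric grid {sorted(grid)} or its negation"
            )


@dataclass
class SensitivityProfile:
    """Per-pathogen driver->median map with derived sensitivity flags."""

    pathogen_id: str
    median_scores: dict[ClimateDriver, float] = field(default_factory=dict)

    @property
    def positive_drivers(self) -> frozenset[ClimateDriver]:
        return frozenset(d for d, m in self.median_scores.items() if m > 0)

    @property
    def n_drivers(self) -> int:
        return len(self.positive_drivers)

    @property
    def is_sensitive(self) -> bool:
        return self.n_drivers > 0

    @property
    def has_primary(self) -> bool:
        return any(d.is_primary for d in self.positive_drivers)

    @property
    def has_secondary(self) -> bool:
        return any(not d.is_primary for d in self.positive_drivers)


def median_score(scores: Iterable[float]) -> float:
    """Median of a non-empty multiset of signed scores.

    For even counts this is the arithmetic mean of the two middle order
    statistics, so grid midpoints such as 22.5 are reachable.
    """
    values = list(scores)
    if not values:
        raise ValueError("median_score requires at least one score")
    return float(statistics.median(values))


def aggregate(
    records: Sequence[EvidenceRecord],
    grid: frozenset[float] = DEFAULT_RUBRIC_GRID,
) -> dict[tuple[str, ClimateDriver], float]:
    """Reduce records to one median per (pathogen, driver) pair.

    Pairs with no records are absent from the result (distinct from a
    non-positive median).
    """
    for rec in records:
        rec.validate(grid)
    pools: dict[tuple[str, ClimateDriver], list[float]] = {}
    for rec in records:
        pools.setdefault((rec.pathogen_id, rec.driver), []).append(rec.score)
    return {key: median_score(pool) for key, pool in pools.items()}


def build_profiles(
    medians: Mapping[tuple[str, ClimateDriver], float],
    pathogen_ids: Iterable[str],
) -> list[SensitivityProfile]:
    """One profile per roster pathogen, in roster order.

    Pathogens without records get an empty profile.  Medians for pathogens
    missing from the roster are a consistency error.
    """
    roster = list(pathogen_ids)
    roster_set = set(roster)
    if len(roster_set) != len(roster):
        raise ValidationError("pathogen roster contains duplicates")
    unknown = {pid for (pid, _d) in medians if pid not in roster_set}
    if unknown:
        raise ValidationError(
            f"medians reference pathogens absent from roster: {sorted(unknown)[:5]}"
        )
    by_pathogen: dict[str, dict[ClimateDriver, float]] = {pid: {} for pid in roster}
    for (pid, driver), med in medians.items():
        by_pathogen[pid][driver] = med
    return [SensitivityProfile(pid, by_pathogen[pid]) for pid in roster]


def records_from_frame(
    df: pd.DataFrame,
    vocab: Vocabulary | None = None,
    grid: frozenset[float] = DEFAULT_RUBRIC_GRID,
) -> list[EvidenceRecord]:
    """Build validated records from an in-memory evidence frame."""
    vocab = vocab or default_vocabulary()
    required = {"pathogen_id", "driver", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"evidence CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        rec = EvidenceRecord(
            pathogen_id=str(row.pathogen_id),
            driver=vocab.get(str(row.driver)),
            score=float(row.score),
            source_id=str(getattr(row, "source_id", "") or ""),
        )
        rec.validate(grid)
        records.append(rec)
    return records


def read_evidence_csv(
    path,
    vocab: Vocabulary | None = None,
    grid: frozenset[float] = DEFAULT_RUBRIC_GRID,
) -> list[EvidenceRecord]:
    """Read an evidence table (columns pathogen_id, driver, score, source_id)."""
    df = pd.read_csv(path, dtype={"pathogen_id": str, "source_id": str})
    return records_from_frame(df, vocab, grid)


def profiles_from_frame(
    evidence_df: pd.DataFrame,
    pathogen_ids: Iterable[str],
    vocab: Vocabulary | None = None,
    grid: frozenset[float] = DEFAULT_RUBRIC_GRID,
) -> list[SensitivityProfile]:
    """Validate, aggregate and profile an evidence frame in one step."""
    records = records_from_frame(evidence_df, vocab, grid)
    return build_profiles(aggregate(records, grid), pathogen_ids)


def medians_frame(
    medians: Mapping[tuple[str, ClimateDriver], float]
) -> pd.DataFrame:
    """Tidy frame of per-pair medians with a 0/1 positivity column."""
    rows = [
        {
            "pathogen_id": pid,
            "driver": d.name,
            "median_score": med,
            "positive": int(med > 0),
        }
        for (pid, d), med in sorted(
            medians.items(), key=lambda kv: (kv[0][0], kv[0][1].name)
        )
    ]
    return pd.DataFrame(
        rows, columns=["pathogen_id", "driver", "median_score", "positive"]
    )


def profiles_frame(profiles: Sequence[SensitivityProfile]) -> pd.DataFrame:
    """Profile summary: driver count, class flags, semicolon-joined codes."""
    rows = [
        {
            "pathogen_id": p.pathogen_id,
            "n_drivers": p.n_drivers,
            "has_primary": int(p.has_primary),
            "has_secondary": int(p.has_secondary),
            "drivers": ";".join(sorted(d.code for d in p.positive_drivers)),
        }
        for p in profiles
    ]
    return pd.DataFrame(
        rows, columns=["pathogen_id", "n_drivers", "has_primary", "has_secondary", "drivers"]
    )
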
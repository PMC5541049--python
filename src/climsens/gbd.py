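"""Disease-burden attribution: climate sensitivity of GBD diseases.

The input is a burden table in the shape of the 2010 Global Burden of
Disease extract: one row per disease with its all-ages DALYs (thousands),
the climate drivers with positive median evidence for its constituent
pathogen(s), and the matching median scores.  When a disease is caused by
two reviewed pathogens a driver cell may carry two scores joined by "+"
("40 + 12.5"); the disease is sensitive to a driver if any constituent
pathogen's median for it is positive.

Diseases are classed as ``primary`` (at least one primary-class driver),
``secondary_only`` (sensitive, but via secondary drivers only) or ``none``.
DALY fractions are computed on unrounded sums; the relative DALY impact of a
disease is its DALYs divided by the all-cause total (default 2,490,385
thousand), expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .ontology import (
    ClimateDriver,
    ValidationError,
    Vocabulary,
    default_vocabulary,
)

__all__ = [
    "ALL_CAUSE_DALYS_THOUSANDS",
    "DiseaseBurdenRow",
    "BurdenReport",
    "parse_burden_table",
    "packaged_burden_table",
    "classify_disease",
    "attribute_burden",
    "format_burden_table",
]

#: All-cause DALY total (thousands) of the 2010 GBD study.
ALL_CAUSE_DALYS_THOUSANDS: float = 2_490_385.0

_VALID_TAXON_CODES = frozenset({"B", "P", "V"})


@dataclass(frozen=True)
class DiseaseBurdenRow:
    """One GBD disease with burden and per-driver median evidence scores."""

    disease: str
    dalys_thousands: float
    driver_medians: tuple[tuple[ClimateDriver, tuple[float, ...]], ...]
    taxon_codes: frozenset[str]

    def __post_init__(self):
        if self.dalys_thousands < 0:
            raise ValidationError(f"{self.disease!r}: negative DALYs")
        bad = self.taxon_codes - _VALID_TAXON_CODES
        if bad:
            raise ValidationError(f"{self.disease!r}: unknown taxon codes {sorted(bad)}")
        for driver, scores in self.driver_medians:
            if not scores:
                raise ValidationError(f"{self.disease!r}: empty score list for {driver.code}")
            if any(s <= 0 for s in scores):
                raise ValidationError(
                    f"{self.disease!r}: non-positive median listed for {driver.code}"
                )

    @property
    def drivers(self) -> tuple[ClimateDriver, ...]:
        return tuple(d for d, _ in self.driver_medians)

    @property
    def sensitive(self) -> bool:
        return bool(self.driver_medians)

    @property
    def has_primary(self) -> bool:
        return any(d.is_primary for d in self.drivers)


@dataclass
class BurdenReport:
    """Cohort-level burden attribution."""

    n_diseases: int
    n_any_driver: int
    n_primary: int
    n_secondary_only: int
    total_dalys: float
    sensitive_dalys: float
    primary_sensitive_dalys: float
    relative_impacts_pct: dict[str, float]
    classifications: dict[str, str]
    all_cause_total: float

    @property
    def fraction_sensitive(self) -> float:
        return self.sensitive_dalys / self.total_dalys if self.total_dalys else 0.0

    @property
    def fraction_primary_sensitive(self) -> float:
        return self.primary_sensitive_dalys / self.total_dalys if self.total_dalys else 0.0

    def to_dict(self) -> dict:
        return {
            "n_diseases": self.n_diseases,
            "n_any_driver": self.n_any_driver,
            "n_primary": self.n_primary,
            "n_secondary_only": self.n_secondary_only,
            "total_dalys_thousands": self.total_dalys,
            "sensitive_dalys_thousands": self.sensitive_dalys,
            "primary_sensitive_dalys_thousands": self.primary_sensitive_dalys,
            "pct_dalys_sensitive": 100 * self.fraction_sensitive,
            "pct_dalys_primary_sensitive": 100 * self.fraction_primary_sensitive,
            "relative_impacts_pct": dict(self.relative_impacts_pct),
            "classifications": dict(self.classifications),
            "all_cause_total_thousands": self.all_cause_total,
        }


def _parse_score_cell(cell: str) -> tuple[float, ...]:
    return tuple(float(tok.strip()) for tok in cell.split("+") if tok.strip())


def parse_burden_table(path_or_df, vocab: Vocabulary | None = None) -> list[DiseaseBurdenRow]:
    """Parse a burden CSV (columns disease, dalys_thousands, drivers, scores, taxon).

    ``drivers`` is a comma-separated code list; ``scores`` a comma-separated
    list of matching cells, each possibly "+"-joined for multi-pathogen
    diseases.  Driver/score arity mismatch is a parse error.
    """
    vocab = vocab or default_vocabulary()
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, dtype=str)
    required = {"disease", "dalys_thousands", "drivers", "scores", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"burden table missing columns: {sorted(missing)}")
    rows: list[DiseaseBurdenRow] = []
    for raw in df.itertuples(index=False):
        drivers = vocab.parse_codes("" if pd.isna(raw.drivers) else str(raw.drivers))
        score_text = "" if pd.isna(raw.scores) else str(raw.scores)
        score_cells = [c.strip() for c in score_text.split(",") if c.strip()]
        if len(score_cells) != len(drivers):
            raise ValidationError(
                f"{raw.disease!r}: {len(drivers)} drivers but {len(score_cells)} score cells"
            )
        medians = tuple(
            (driver, _parse_score_cell(cell)) for driver, cell in zip(drivers, score_cells)
        )
        taxon_text = "" if pd.isna(raw.taxon) else str(raw.taxon)
        rows.append(
            DiseaseBurdenRow(
                disease=str(raw.disease),
                dalys_thousands=float(raw.dalys_thousands),
                driver_medians=medians,
                taxon_codes=frozenset(t.strip() for t in taxon_text.split(",") if t.strip()),
            )
        )
    return rows


def packaged_burden_table(vocab: Vocabulary | None = None) -> list[DiseaseBurdenRow]:
    """The packaged 25-disease 2010 GBD burden fixture."""
    src = resources.files("climsens.data").joinpath("gbd2010_burden.csv")
    with src.open("r", encoding="utf-8") as fh:
        return parse_burden_table(pd.read_csv(fh, dtype=str), vocab)


def classify_disease(row: DiseaseBurdenRow) -> str:
    """Classify one disease: ``primary``, ``secondary_only`` or ``none``."""
    if row.has_primary:
        return "primary"
    if row.sensitive:
        return "secondary_only"
    return "none"


def attribute_burden(
    rows: Sequence[DiseaseBurdenRow],
    all_cause_total: float = ALL_CAUSE_DALYS_THOUSANDS,
) -> BurdenReport:
    """Attribute DALY burden to climate-sensitive diseases.

    Fractions are shares of the summed burden of the input diseases;
    relative impacts are per-disease percentages of the all-cause total.
    """
    if not rows:
        raise ValidationError("burden table is empty")
    if all_cause_total <= 0:
        raise ValidationError("all_cause_total must be positive")
    classes = {row.disease: classify_disease(row) for row in rows}
    total = sum(r.dalys_thousands for r in rows)
    sensitive = sum(r.dalys_thousands for r in rows if r.sensitive)
    primary = sum(r.dalys_thousands for r in rows if r.has_primary)
    return BurdenReport(
        n_diseases=len(rows),
        n_any_driver=sum(1 for r in rows if r.sensitive),
        n_primary=sum(1 for r in rows if r.has_primary),
        n_secondary_only=sum(1 for c in classes.values() if c == "secondary_only"),
        total_dalys=total,
        sensitive_dalys=sensitive,
        primary_sensitive_dalys=primary,
        relative_impacts_pct={
            r.disease: 100 * r.dalys_thousands / all_cause_total for r in rows
        },
        classifications=classes,
        all_cause_total=all_cause_total,
    )


def format_burden_table(rows: Sequence[DiseaseBurdenRow]) -> pd.DataFrame:
    """Serialise rows back to the CSV schema (inverse of the parser)."""
    def fmt(x: float) -> str:
        return f"{x:g}"

    out = []
    for r in rows:
        out.append(
            {
                "disease": r.disease,
                "dalys_thousands": fmt(r.dalys_thousands),
                "drivers": ", ".join(d.code for d in r.drivers),
                "scores": ", ".join(
                    " + ".join(fmt(s) for s in scores) for _, scores in r.driver_medians
                ),
                "taxon": ", ".join(sorted(r.taxon_codes)),
            }
        )
    return pd.DataFrame(out, columns=["disease", "dalys_thousands", "drivers", "scores", "taxon"])
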
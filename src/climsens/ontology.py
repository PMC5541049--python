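"""Controlled vocabularies: climate drivers, taxa, transmission routes, host classes.

Eleven climate drivers are recognised, split into *primary* drivers (direct
climate variables expected to change under climate change: climate change
itself, oscillations, extreme weather events, moisture, rainfall, temperature,
wind) and *secondary* drivers (combinations, consequences or proxies of the
primary ones: altitude, vegetation, particulate matter, salinity).  Each driver
carries a short code (``CC``, ``O``, ``EWE``, ``M``, ``R``, ``T``, ``W``,
``Alt``, ``V``, ``P``, ``S``) used in burden tables.

The driver vocabulary ships as a packaged CSV and can be overridden from a
YAML file via :func:`load_vocabulary`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "VocabularyError",
    "ValidationError",
    "DriverClass",
    "ClimateDriver",
    "HostClass",
    "Vocabulary",
    "TAXA",
    "TRANSMISSION_ROUTES",
    "default_vocabulary",
    "load_vocabulary",
    "get_driver",
    "classify_driver",
    "parse_driver_codes",
    "format_driver_codes",
]


class VocabularyError(ValueError):
    """A label does not belong to a controlled vocabulary."""


class ValidationError(ValueError):
    """Structurally invalid input (e.g. duplicated driver codes)."""


class DriverClass(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class ClimateDriver:
    """One of the 11 climate-driver sets."""

    name: str
    code: str
    driver_class: DriverClass

    @property
    def is_primary(self) -> bool:
        return self.driver_class is DriverClass.PRIMARY


class HostClass(str, enum.Enum):
    HUMAN_ONLY = "human-only"
    ANIMAL_ONLY = "animal-only"
    ZOONOTIC = "zoonotic"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five pathogen taxonomic divisions.
TAXA: tuple[str, ...] = ("bacteria", "fungi", "helminths", "protozoa", "viruses")

#: The eight transmission routes.
TRANSMISSION_ROUTES: tuple[str, ...] = (
    "airborne",
    "direct nonsexual contact",
    "fomite",
    "foodborne",
    "sexual direct contact",
    "soilborne",
    "vector-borne",
    "waterborne",
)

# Spellings seen in the literature that map onto canonical driver names.
_DRIVER_ALIASES: dict[str, str] = {
    "climate oscillations": "oscillations",
    "particle matter": "particulate matter",
    "rain": "rainfall",
    "humidity": "moisture",
}


class Vocabulary:
    """A driver vocabulary with case-insensitive name/code lookup."""

    def __init__(self, drivers: Sequence[ClimateDriver]):
        self.drivers: tuple[ClimateDriver, ...] = tuple(drivers)
        names = [d.name for d in self.drivers]
        codes = [d.code for d in self.drivers]
        if len(set(n.lower() for n in names)) != len(names):
            raise ValidationError("duplicate driver names in vocabulary")
        if len(set(c.lower() for c in codes)) != len(codes):
            raise ValidationError("duplicate driver codes in vocabulary")
        self._lookup: dict[str, ClimateDriver] = {}
        for d in self.drivers:
            self._lookup[d.name.lower()] = d
            self._lookup[d.code.lower()] = d
        for alias, target in _DRIVER_ALIASES.items():
            if target.lower() in self._lookup:
                self._lookup.setdefault(alias.lower(), self._lookup[target.lower()])

    def __iter__(self):
        return iter(self.drivers)

    def __len__(self) -> int:
        return len(self.drivers)

    @property
    def primary(self) -> tuple[ClimateDriver, ...]:
        return tuple(d for d in self.drivers if d.is_primary)

    @property
    def secondary(self) -> tuple[ClimateDriver, ...]:
        return tuple(d for d in self.drivers if not d.is_primary)

    def get(self, label: str) -> ClimateDriver:
        """Resolve a driver name or code, case-insensitively.

        A trailing plural ``s`` is tolerated ("EWEs" resolves to the
        extreme-weather-events driver).
        """
        key = label.strip().lower()
        if key in self._lookup:
            return self._lookup[key]
        if key.endswith("s") and key[:-1] in self._lookup:
            return self._lookup[key[:-1]]
        raise VocabularyError(f"unknown climate driver label: {label!r}")

    def parse_codes(self, cell: str) -> list[ClimateDriver]:
        """Parse a comma-separated code cell like ``"CC, EWE, M"``.

        Returns drivers in input order; an empty/blank cell yields an empty
        list.  Duplicated codes are a :class:`ValidationError`.
        """
        if cell is None:
            return []
        tokens = [t.strip() for t in str(cell).split(",") if t.strip()]
        drivers = [self.get(t) for t in tokens]
        seen: set[str] = set()
        for d in drivers:
            if d.code in seen:
                raise ValidationError(f"duplicate driver code in cell: {d.code!r}")
            seen.add(d.code)
        return drivers

    @staticmethod
    def format_codes(drivers: Iterable[ClimateDriver]) -> str:
        return ", ".join(d.code for d in drivers)


def _read_vocab_rows(rows: Iterable[dict]) -> Vocabulary:
    drivers = [
        ClimateDriver(
            name=row["name"].strip(),
            code=row["code"].strip(),
            driver_class=DriverClass(row["driver_class"].strip().lower()),
        )
        for row in rows
    ]
    return Vocabulary(drivers)


def _load_packaged_vocabulary() -> Vocabulary:
    src = resources.files("climsens.data").joinpath("climate_drivers.csv")
    with src.open("r", encoding="utf-8") as fh:
        return _read_vocab_rows(csv.DictReader(fh))


_DEFAULT: Vocabulary | None = None


def default_vocabulary() -> Vocabulary:
    """The packaged 11-driver vocabulary (7 primary, 4 secondary)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_packaged_vocabulary()
    return _DEFAULT


def load_vocabulary(path) -> Vocabulary:
    """Load a driver vocabulary override from a YAML file.

    The file holds a list of mappings with keys ``name``, ``code`` and
    ``driver_class``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ValidationError("vocabulary YAML must be a list of driver mappings")
    return _read_vocab_rows(data)


def get_driver(label: str, vocab: Vocabulary | None = None) -> ClimateDriver:
    """Resolve a driver name or code to its :class:`ClimateDriver`."""
    return (vocab or default_vocabulary()).get(label)


def classify_driver(label: str, vocab: Vocabulary | None = None) -> DriverClass:
    """Return the primary/secondary class for a driver name or code."""
    return get_driver(label, vocab).driver_class


def parse_driver_codes(cell: str, vocab: Vocabulary | None = None) -> list[ClimateDriver]:
    """Parse a comma-separated driver-code cell into drivers, in order."""
    return (vocab or default_vocabulary()).parse_codes(cell)


def format_driver_codes(drivers: Iterable[ClimateDriver]) -> str:
    """Inverse of :func:`parse_driver_codes` on any duplicate-free list."""
    return Vocabulary.format_codes(drivers)
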
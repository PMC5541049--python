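"""Seeded synthetic evidence and attribute tables for pipeline testing.

The generator emulates the statistical structure the analysis assumes: a
roster of pathogens with taxa, transmission routes, host class, emergence
flags, H-indices and country counts; a latent binary sensitivity per
(pathogen, driver) pair whose rate depends on transmission route; literature
evidence records whose signed rubric scores are noisy draws around that
latent truth (so observed medians can disagree with it); and a zoonotic flag
whose log-odds differ by ``ln(zoonotic_sensitivity_or)`` between latently
sensitive and insensitive pathogens.

Defaults target a cohort of 157 pathogens of which roughly 6 in 10 carry
positive evidence for at least one of the 11 drivers, with vector-borne >
soilborne > waterborne > foodborne > contact route propensities for climate
links.  All randomness flows from one seeded generator; the same seed gives
byte-identical tables.  The attribute table carries two extra truth columns
(``latent_sensitive``, ``latent_n_drivers``) for parameter-recovery checks;
pipeline readers ignore them.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .ontology import TAXA, TRANSMISSION_ROUTES, ValidationError, default_vocabulary

__all__ = [
    "SIGNED_GRID",
    "SynthConfig",
    "generate",
    "generate_burden_like",
    "expected_fraction_sensitive",
]

SCHEMA_VERSION = "1"

#: Signed rubric grid for observed record scores.
SIGNED_GRID: tuple[float, ...] = (-80.0, -60.0, -40.0, -20.0, -5.0, 5.0, 20.0, 40.0, 60.0, 80.0)

_DEF_TAXON_MIX = {
    "bacteria": 0.42,
    "viruses": 0.36,
    "fungi": 0.135,
    "protozoa": 0.045,
    "helminths": 0.04,
}

# Route prevalences of a 157-pathogen European cohort (fraction of roster).
_DEF_ROUTE_PROPENSITY = {
    "direct nonsexual contact": 81 / 157,
    "foodborne": 68 / 157,
    "airborne": 53 / 157,
    "fomite": 34 / 157,
    "waterborne": 28 / 157,
    "sexual direct contact": 27 / 157,
    "vector-borne": 19 / 157,
    "soilborne": 5 / 157,
}

# Multipliers on the per-pair sensitivity rate, by the strongest route.
_DEF_ROUTE_BOOST = {
    "vector-borne": 4.0,
    "soilborne": 2.8,
    "waterborne": 2.5,
    "foodborne": 2.0,
    "airborne": 1.2,
    "fomite": 0.8,
    "direct nonsexual contact": 0.7,
    "sexual direct contact": 0.5,
}

# Scores for latently sensitive pairs: mostly positive, some contradiction.
_DEF_SCORE_PROBS_SENSITIVE = {
    -80.0: 0.005, -60.0: 0.01, -40.0: 0.015, -20.0: 0.03, -5.0: 0.04,
    5.0: 0.10, 20.0: 0.30, 40.0: 0.25, 60.0: 0.15, 80.0: 0.10,
}

# Scores for insensitive pairs that nevertheless attracted literature:
# mostly negative or weak.
_DEF_SCORE_PROBS_INSENSITIVE = {
    -80.0: 0.02, -60.0: 0.06, -40.0: 0.14, -20.0: 0.35, -5.0: 0.35,
    5.0: 0.05, 20.0: 0.03, 40.0: 0.0, 60.0: 0.0, 80.0: 0.0,
}


@dataclass
class SynthConfig:
    """Tunable study conditions for the generator."""

    n_pathogens: int = 157
    taxon_mix: dict[str, float] = field(default_factory=lambda: dict(_DEF_TAXON_MIX))
    route_propensity: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_ROUTE_PROPENSITY)
    )
    driver_base_rate: float = 0.052  # expected sensitive share ~= 0.63 of the roster
    route_driver_boost: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_ROUTE_BOOST)
    )
    zoonotic_sensitivity_or: float = 6.0
    zoonotic_base_rate: float = 0.30
    p_unknown_host: float = 1 / 157
    emerging_rate: float = 0.25
    records_per_positive_pair: float = 3.0
    insensitive_record_rate: float = 0.08
    records_per_insensitive_pair: float = 1.5
    score_probs_sensitive: dict[float, float] = field(
        default_factory=lambda: dict(_DEF_SCORE_PROBS_SENSITIVE)
    )
    score_probs_insensitive: dict[float, float] = field(
        default_factory=lambda: dict(_DEF_SCORE_PROBS_INSENSITIVE)
    )
    h_index_mean: float = 30.0
    h_index_dispersion: float = 2.0
    n_countries_total: int = 51
    countries_base: float = 10.0
    countries_slope: float = 1.1
    countries_sd: float = 7.0
    seed: int = 20170802

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_pathogens < 1:
            problems.append("n_pathogens must be >= 1")
        if set(self.taxon_mix) != set(TAXA):
            problems.append("taxon_mix must cover exactly the five taxa")
        elif abs(sum(self.taxon_mix.values()) - 1.0) > 1e-9:
            problems.append("taxon_mix must sum to 1")
        if set(self.route_propensity) != set(TRANSMISSION_ROUTES):
            problems.append("route_propensity must cover exactly the eight routes")
        elif not all(0 <= p <= 1 for p in self.route_propensity.values()):
            problems.append("route propensities must lie in [0, 1]")
        if not 0 <= self.driver_base_rate <= 1:
            problems.append("driver_base_rate must lie in [0, 1]")
        if any(b < 0 for b in self.route_driver_boost.values()):
            problems.append("route boosts must be non-negative")
        if self.zoonotic_sensitivity_or <= 0:
            problems.append("zoonotic_sensitivity_or must be positive")
        if not 0 < self.zoonotic_base_rate < 1:
            problems.append("zoonotic_base_rate must lie in (0, 1)")
        if not 0 <= self.p_unknown_host < 1:
            problems.append("p_unknown_host must lie in [0, 1)")
        if not 0 <= self.emerging_rate <= 1:
            problems.append("emerging_rate must lie in [0, 1]")
        if self.records_per_positive_pair < 1:
            problems.append("records_per_positive_pair must be >= 1")
        if not 0 <= self.insensitive_record_rate <= 1:
            problems.append("insensitive_record_rate must lie in [0, 1]")
        for name, probs in (
            ("score_probs_sensitive", self.score_probs_sensitive),
            ("score_probs_insensitive", self.score_probs_insensitive),
        ):
            if set(probs) != set(SIGNED_GRID):
                problems.append(f"{name} must assign a probability to every grid value")
            elif abs(sum(probs.values()) - 1.0) > 1e-9:
                problems.append(f"{name} must sum to 1")
        if self.h_index_mean <= 0 or self.h_index_dispersion <= 0:
            problems.append("h_index_mean and h_index_dispersion must be positive")
        if self.n_countries_total < 1:
            problems.append("n_countries_total must be >= 1")
        if problems:
            raise ValidationError("invalid SynthConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)


def _pair_rates(config: SynthConfig, route_matrix: np.ndarray) -> np.ndarray:
    """Per-pathogen pair sensitivity rate: base rate times strongest-route boost."""
    boosts = np.array([config.route_driver_boost.get(r, 1.0) for r in TRANSMISSION_ROUTES])
    per_route = np.where(route_matrix, boosts[None, :], -np.inf)
    boost = per_route.max(axis=1)
    return np.clip(config.driver_base_rate * boost, 0.0, 1.0)


def expected_fraction_sensitive(config: SynthConfig) -> float:
    """Closed-form expected share of pathogens with >= 1 latently sensitive driver.

    Marginalises over the route-assignment process: independent Bernoulli
    route draws (with a propensity-weighted single route forced when none is
    drawn) and the max-boost rule for the per-pair rate.
    """
    config.validate()
    n_drivers = len(default_vocabulary())
    routes = list(TRANSMISSION_ROUTES)
    props = np.array([config.route_propensity[r] for r in routes])
    boosts = np.array([config.route_driver_boost.get(r, 1.0) for r in routes])

    def p_any(boost: float) -> float:
        rate = min(max(config.driver_base_rate * boost, 0.0), 1.0)
        return 1.0 - (1.0 - rate) ** n_drivers

    order = np.argsort(-boosts)
    total = 0.0
    survive = 1.0  # no route with a larger boost present
    for idx in order:
        total += survive * props[idx] * p_any(boosts[idx])
        survive *= 1.0 - props[idx]
    # all-absent fallback: one route drawn with propensity weights
    weights = props / props.sum()
    total += survive * float(np.sum(weights * [p_any(b) for b in boosts]))
    return total


def _draw_routes(config: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    props = np.array([config.route_propensity[r] for r in TRANSMISSION_ROUTES])
    matrix = rng.random((n, len(TRANSMISSION_ROUTES))) < props[None, :]
    none = ~matrix.any(axis=1)
    if none.any():
        weights = props / props.sum()
        forced = rng.choice(len(TRANSMISSION_ROUTES), size=int(none.sum()), p=weights)
        matrix[np.flatnonzero(none), forced] = True
    return matrix


def generate(config: SynthConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (attributes, evidence) tables under the configured conditions.

    Deterministic given ``config.seed``.  The attribute frame follows the
    pipeline CSV contract plus the two latent truth columns; the evidence
    frame has columns pathogen_id, driver, score, source_id.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pathogens
    vocab = default_vocabulary()
    drivers = [d.name for d in vocab]
    n_dr = len(drivers)

    pathogen_ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    taxa = rng.choice(list(config.taxon_mix), size=n, p=list(config.taxon_mix.values()))
    route_matrix = _draw_routes(config, rng, n)

    rate = _pair_rates(config, route_matrix)
    latent = rng.random((n, n_dr)) < rate[:, None]
    latent_k = latent.sum(axis=1)
    latent_any = latent_k > 0

    alpha = math.log(config.zoonotic_base_rate / (1 - config.zoonotic_base_rate))
    beta = math.log(config.zoonotic_sensitivity_or)
    p_zoo = 1.0 / (1.0 + np.exp(-(alpha + beta * latent_any)))
    zoonotic = rng.random(n) < p_zoo
    host = np.where(zoonotic, "zoonotic", np.where(rng.random(n) < 0.5, "human-only", "animal-only"))
    host[rng.random(n) < config.p_unknown_host] = "unknown"

    emerging = rng.random(n) < config.emerging_rate
    p_nb = config.h_index_dispersion / (config.h_index_dispersion + config.h_index_mean)
    h_index = rng.negative_binomial(config.h_index_dispersion, p_nb, size=n)
    countries = np.rint(
        config.countries_base
        + config.countries_slope * latent_k
        + rng.normal(0.0, config.countries_sd, size=n)
    ).astype(int)
    countries = np.clip(countries, 1, config.n_countries_total)

    attributes = pd.DataFrame(
        {
            "pathogen_id": pathogen_ids,
            "taxon": taxa,
            "routes": [
                ";".join(r for r, flag in zip(TRANSMISSION_ROUTES, row) if flag)
                for row in route_matrix
            ],
            "host_class": host,
            "emerging": emerging.astype(int),
            "h_index": h_index,
            "n_countries": countries,
            "latent_sensitive": latent_any.astype(int),
            "latent_n_drivers": latent_k,
        }
    )

    # evidence records: sensitive pairs always attract literature,
    # insensitive pairs only occasionally
    flat_latent = latent.ravel()
    n_pairs = n * n_dr
    counts = np.zeros(n_pairs, dtype=int)
    sens_idx = np.flatnonzero(flat_latent)
    counts[sens_idx] = np.maximum(
        1, rng.poisson(config.records_per_positive_pair, size=len(sens_idx))
    )
    insens_idx = np.flatnonzero(~flat_latent)
    has_rec = rng.random(len(insens_idx)) < config.insensitive_record_rate
    chosen = insens_idx[has_rec]
    counts[chosen] = np.maximum(
        1, rng.poisson(config.records_per_insensitive_pair, size=len(chosen))
    )

    pair_pathogen = np.repeat(np.arange(n), n_dr)
    pair_driver = np.tile(np.arange(n_dr), n)
    rec_pair = np.repeat(np.arange(n_pairs), counts)
    grid = np.array(SIGNED_GRID)
    p_sens = np.array([config.score_probs_sensitive[g] for g in SIGNED_GRID])
    p_ins = np.array([config.score_probs_insensitive[g] for g in SIGNED_GRID])
    rec_latent = flat_latent[rec_pair]
    scores = np.empty(len(rec_pair))
    scores[rec_latent] = rng.choice(grid, size=int(rec_latent.sum()), p=p_sens)
    scores[~rec_latent] = rng.choice(grid, size=int((~rec_latent).sum()), p=p_ins)

    evidence = pd.DataFrame(
        {
            "pathogen_id": pathogen_ids[pair_pathogen[rec_pair]],
            "driver": np.array(drivers)[pair_driver[rec_pair]],
            "score": scores,
            "source_id": [f"synth:{i + 1:06d}" for i in range(len(rec_pair))],
        }
    )
    return attributes, evidence


def generate_burden_like(
    config: SynthConfig | None = None, n_diseases: int = 25
) -> pd.DataFrame:
    """Generate a burden table in the GBD fixture schema.

    Rows carry comma-separated driver codes with positive rubric medians;
    about one cell in five is a "+"-joined two-pathogen score.  Uses an
    independent stream derived from ``config.seed``.
    """
    config = config or SynthConfig()
    config.validate()
    if n_diseases < 1:
        raise ValidationError("n_diseases must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    vocab = default_vocabulary()
    codes = [d.code for d in vocab]
    positive_grid = np.array([g for g in SIGNED_GRID if g > 0])
    rows = []
    for i in range(n_diseases):
        dalys = float(np.rint(rng.lognormal(mean=8.0, sigma=1.5)))
        k = int(rng.binomial(len(codes), 0.3))
        chosen = sorted(rng.choice(len(codes), size=k, replace=False))
        cells = []
        for _ in chosen:
            scores = rng.choice(positive_grid, size=2 if rng.random() < 0.2 else 1)
            cells.append(" + ".join(f"{s:g}" for s in scores))
        rows.append(
            {
                "disease": f"Disease {i + 1:02d}",
                "dalys_thousands": f"{max(dalys, 1.0):g}",
                "drivers": ", ".join(codes[j] for j in chosen),
                "scores": ", ".join(cells),
                "taxon": str(rng.choice(["B", "P", "V"])),
            }
        )
    return pd.DataFrame(rows, columns=["disease", "dalys_thousands", "drivers", "scores", "taxon"])
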
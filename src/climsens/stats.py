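"""Association statistics for climate-sensitivity questions.

2x2 contingency tests (Pearson chi-square with the phi effect size, odds
ratios with Woolf confidence intervals), Pearson correlation, simple linear
regression with its F test, and univariable/multivariable logistic regression
fitted by iteratively reweighted least squares with Wald intervals.

The chi-square is computed without continuity correction so that
phi = sqrt(chi2 / N) is exact.  All confidence intervals are 95% Wald
intervals (symmetric on the log-odds scale for ratios).  p-values in
[0.05, 0.10) are flagged as borderline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .evidence import SensitivityProfile
from .ontology import HostClass, ValidationError, default_vocabulary
from .profiles import PathogenAttributes

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "LogisticModelSpec",
    "SeparationWarning",
    "chi_square_2x2",
    "odds_ratio",
    "pearson_correlation",
    "ols_slope",
    "h_index_quartiles",
    "logistic_fit",
    "model_frame",
    "run_model_battery",
]

Z_95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


class SeparationWarning(UserWarning):
    """A logistic fit drove fitted probabilities to 0/1 (quasi-separation)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows = exposure yes/no, columns = outcome yes/no."""

    a: int  # exposed, outcome
    b: int  # exposed, no outcome
    c: int  # unexposed, outcome
    d: int  # unexposed, no outcome

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.n < 1:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_booleans(cls, exposure, outcome) -> "ContingencyTable2x2":
        e = np.asarray(exposure, dtype=bool)
        o = np.asarray(outcome, dtype=bool)
        return cls(
            a=int(np.sum(e & o)),
            b=int(np.sum(e & ~o)),
            c=int(np.sum(~e & o)),
            d=int(np.sum(~e & ~o)),
        )


@dataclass(frozen=True)
class AssociationResult:
    """One fitted statistic with its uncertainty and metadata."""

    statistic_name: str  # chi_square | odds_ratio | pearson_r | ols | logistic
    estimate: float
    p_value: float
    term: str = ""
    effect_size_phi: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    df: tuple[int, ...] | None = None
    f_statistic: float | None = None
    n: int | None = None
    separation: bool = False

    @property
    def borderline(self) -> bool:
        return 0.05 <= self.p_value < 0.10

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        out = {
            "statistic": self.statistic_name,
            "term": self.term,
            "estimate": self.estimate,
            "p_value": self.p_value,
        }
        if self.effect_size_phi is not None:
            out["phi"] = self.effect_size_phi
        if self.ci_low is not None:
            out["ci_low"] = self.ci_low
            out["ci_high"] = self.ci_high
        if self.df is not None:
            out["df"] = list(self.df)
        if self.f_statistic is not None:
            out["f_statistic"] = self.f_statistic
        if self.n is not None:
            out["n"] = self.n
        if self.separation:
            out["separation"] = True
        if self.borderline:
            out["borderline"] = True
        return out


def chi_square_2x2(table: ContingencyTable2x2) -> AssociationResult:
    """Pearson chi-square (df=1, no continuity correction) with phi."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("degenerate 2x2 table: a row or column margin is zero")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=False)
    phi = math.sqrt(chi2 / table.n)
    return AssociationResult(
        statistic_name="chi_square",
        estimate=float(chi2),
        p_value=float(p),
        effect_size_phi=phi,
        df=(1,),
        n=table.n,
    )


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> AssociationResult:
    """Cross-product odds ratio ad/bc with a 95% Woolf (log-scale Wald) CI.

    ``haldane`` adds 0.5 to every cell when any cell is zero; otherwise a
    zero off-diagonal cell is a degenerate-table error.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValidationError(
                "zero cell in 2x2 table; enable the Haldane correction or collect data"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    p = 2 * scipy.stats.norm.sf(abs(z))
    return AssociationResult(
        statistic_name="odds_ratio",
        estimate=or_,
        p_value=float(p),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        n=table.n,
    )


def pearson_correlation(x, y) -> AssociationResult:
    """Pearson product-moment correlation with a two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValidationError("correlation requires at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = scipy.stats.pearsonr(x, y)
    return AssociationResult(
        statistic_name="pearson_r",
        estimate=float(r),
        p_value=float(p),
        df=(len(x) - 2,),
        n=len(x),
    )


def ols_slope(x, y) -> AssociationResult:
    """Least-squares slope of y on x with the regression F test, df (1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.var(x) == 0:
        raise ValueError("slope undefined for constant x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    return AssociationResult(
        statistic_name="ols",
        estimate=slope,
        p_value=float(model.f_pvalue),
        ci_low=slope - Z_95 * se,
        ci_high=slope + Z_95 * se,
        df=(1, int(model.df_resid)),
        f_statistic=float(model.fvalue),
        n=len(x),
    )


def h_index_quartiles(h: Sequence[float]) -> np.ndarray:
    """Quartile label (1-4) per value; ties sit in the lower quartile.

    Boundaries are the empirical 25/50/75 percentiles (linear interpolation);
    a value equal to a boundary stays below it.
    """
    h = np.asarray(h, dtype=float)
    if len(h) < 4:
        raise ValidationError("quartiles require at least 4 values")
    q25, q50, q75 = np.percentile(h, [25, 50, 75])
    return (1 + (h > q25).astype(int) + (h > q50) + (h > q75)).astype(int)


@dataclass(frozen=True)
class LogisticModelSpec:
    """A logistic model: binary outcome on binary and/or quartile predictors.

    Quartile predictors (e.g. the H-index) expand into three indicator terms
    against a first-quartile baseline.
    """

    outcome: str
    predictors: tuple[str, ...]
    quartile_predictors: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.predictors:
            raise ValidationError("model needs at least one predictor")
        unknown = self.quartile_predictors - set(self.predictors)
        if unknown:
            raise ValidationError(f"quartile predictors not in predictors: {sorted(unknown)}")


def _design_matrix(data: pd.DataFrame, spec: LogisticModelSpec):
    cols = [spec.outcome, *spec.predictors]
    work = data.loc[:, cols].dropna()  # listwise deletion
    y = work[spec.outcome].astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError(f"outcome {spec.outcome!r} must be binary with both levels present")
    columns: dict[str, np.ndarray] = {}
    for pred in spec.predictors:
        if pred in spec.quartile_predictors:
            q = h_index_quartiles(work[pred].to_numpy())
            for level in (2, 3, 4):
                columns[f"{pred}:Q{level}"] = (q == level).astype(float)
        else:
            v = work[pred].astype(float).to_numpy()
            if not set(np.unique(v)) <= {0.0, 1.0}:
                raise ValidationError(f"predictor {pred!r} is not binary 0/1")
            columns[pred] = v
    X = pd.DataFrame(columns, index=work.index)
    X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient (constant or aliased predictor)")
    return y, X


def logistic_fit(data: pd.DataFrame, spec: LogisticModelSpec) -> list[AssociationResult]:
    """Maximum-likelihood logistic fit via IRLS; one AOR per non-baseline term.

    Convergence when the largest coefficient change drops below 1e-8, up to
    100 iterations.  Quasi-separation (a fitted probability pinned at 0 or 1)
    emits :class:`SeparationWarning` and flags the affected results.
    """
    y, X = _design_matrix(data, spec)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation is re-reported below
        res = model.fit(maxiter=100, tol=1e-8, tol_criterion="params")
    mu = np.asarray(res.fittedvalues)
    separated = bool(np.any(mu < 1e-8) | np.any(mu > 1 - 1e-8))
    if separated:
        warnings.warn(
            "fitted probabilities pinned at 0/1: quasi-separation, Wald CIs diverge",
            SeparationWarning,
            stacklevel=2,
        )
    elif not res.converged:
        raise RuntimeError("logistic fit did not converge in 100 IRLS iterations")
    def safe_exp(v: float) -> float:
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    out: list[AssociationResult] = []
    for term in X.columns:
        if term == "const":
            continue
        coef = float(res.params[term])
        se = float(res.bse[term])
        out.append(
            AssociationResult(
                statistic_name="logistic",
                term=term,
                estimate=safe_exp(coef),
                p_value=float(res.pvalues[term]),
                ci_low=safe_exp(coef - Z_95 * se),
                ci_high=safe_exp(coef + Z_95 * se),
                n=len(y),
                separation=separated,
            )
        )
    return out


# ---------------------------------------------------------------------------
# The full model battery
# ---------------------------------------------------------------------------

_ROUTE_COLS = {
    "direct nonsexual contact": "route_direct_contact",
    "waterborne": "route_waterborne",
    "foodborne": "route_foodborne",
}


def model_frame(
    profiles: Sequence[SensitivityProfile],
    attributes: Mapping[str, PathogenAttributes],
) -> pd.DataFrame:
    """Analysis frame joining profiles and attributes, one row per pathogen.

    ``zoonotic`` is NaN for unknown host class, giving listwise deletion in
    the zoonotic models while other models keep the full roster.
    """
    vocab = default_vocabulary()
    rainfall = vocab.get("rainfall")
    climate_change = vocab.get("climate change")
    rows = []
    for prof in profiles:
        attrs = attributes[prof.pathogen_id]
        zoonotic = (
            np.nan
            if attrs.host_class is HostClass.UNKNOWN
            else float(attrs.host_class is HostClass.ZOONOTIC)
        )
        row = {
            "pathogen_id": prof.pathogen_id,
            "sensitive": int(prof.is_sensitive),
            "n_drivers": prof.n_drivers,
            "zoonotic": zoonotic,
            "human_only": float(attrs.host_class is HostClass.HUMAN_ONLY),
            "animal_only": float(attrs.host_class is HostClass.ANIMAL_ONLY),
            "emerging": int(attrs.emerging),
            "h_index": attrs.h_index,
            "n_countries": attrs.n_countries,
            "n_routes": len(attrs.routes),
            "rain_positive": int(rainfall in prof.positive_drivers),
            "climate_change_positive": int(climate_change in prof.positive_drivers),
        }
        for route, col in _ROUTE_COLS.items():
            row[col] = int(route in attrs.routes)
        rows.append(row)
    return pd.DataFrame(rows)


def _backward_select(
    data: pd.DataFrame, outcome: str, predictors: list[str]
) -> tuple[list[str], list[AssociationResult]]:
    """Backward elimination: drop the weakest term while any p >= 0.05."""
    current = list(predictors)
    while current:
        results = logistic_fit(data, LogisticModelSpec(outcome, tuple(current)))
        worst = max(results, key=lambda r: r.p_value)
        if worst.p_value < 0.05:
            return current, results
        current.remove(worst.term)
    return [], []


def run_model_battery(
    profiles: Sequence[SensitivityProfile],
    attributes: Mapping[str, PathogenAttributes],
) -> dict:
    """Run the full battery of association analyses over one cohort.

    Returns a report dict with:

    - ``zoonotic_chi_square``: zoonotic (vs human-/animal-only) x any-driver
      sensitivity 2x2 with phi,
    - ``or_vs_human_only`` / ``or_vs_animal_only``: zoonotic sensitivity odds
      ratios against each non-zoonotic host class,
    - ``zoonotic_univariable``: zoonotic on direct contact, waterborne and
      foodborne transmission, one model each,
    - ``zoonotic_multivariable``: univariably significant routes, backward
      elimination at p >= 0.05,
    - ``emerging_rain_model`` / ``emerging_climate_change_model``: emerging on
      a driver indicator adjusted for H-index quartiles,
    - ``emerging_chi_square``: emerging x any-driver 2x2,
    - ``routes_vs_drivers_correlation`` and ``countries_on_drivers_ols``.
    """
    frame = model_frame(profiles, attributes)
    report: dict = {}

    known = frame.dropna(subset=["zoonotic"])
    zoo = known["zoonotic"].astype(bool).to_numpy()
    sens = known["sensitive"].astype(bool).to_numpy()
    report["zoonotic_chi_square"] = chi_square_2x2(
        ContingencyTable2x2.from_booleans(zoo, sens)
    )
    for col, key in (("human_only", "or_vs_human_only"), ("animal_only", "or_vs_animal_only")):
        sub = known[(known["zoonotic"] == 1) | (known[col] == 1)]
        report[key] = odds_ratio(
            ContingencyTable2x2.from_booleans(
                sub["zoonotic"].astype(bool), sub["sensitive"].astype(bool)
            )
        )

    uni: dict[str, AssociationResult] = {}
    for col in _ROUTE_COLS.values():
        (result,) = logistic_fit(known, LogisticModelSpec("zoonotic", (col,)))
        uni[col] = result
    report["zoonotic_univariable"] = uni

    candidates = [c for c, r in uni.items() if r.significant]
    kept, multi = _backward_select(known, "zoonotic", candidates)
    report["zoonotic_multivariable"] = {r.term: r for r in multi}
    report["zoonotic_multivariable_terms"] = kept

    for driver_col, key in (
        ("rain_positive", "emerging_rain_model"),
        ("climate_change_positive", "emerging_climate_change_model"),
    ):
        results = logistic_fit(
            frame,
            LogisticModelSpec(
                "emerging", (driver_col, "h_index"), frozenset({"h_index"})
            ),
        )
        report[key] = {r.term: r for r in results}

    report["emerging_chi_square"] = chi_square_2x2(
        ContingencyTable2x2.from_booleans(
            frame["emerging"].astype(bool), frame["sensitive"].astype(bool)
        )
    )

    report["routes_vs_drivers_correlation"] = pearson_correlation(
        frame["n_routes"], frame["n_drivers"]
    )
    report["countries_on_drivers_ols"] = ols_slope(
        frame["n_drivers"], frame["n_countries"]
    )
    return report


def report_to_dict(report: Mapping) -> dict:
    """JSON-serialisable form of a :func:`run_model_battery` report."""
    def conv(v):
        if isinstance(v, AssociationResult):
            return v.to_dict()
        if isinstance(v, Mapping):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v

    return {k: conv(v) for k, v in report.items()}
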
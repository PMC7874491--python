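"""Prevalence estimation, stratified tables, window sweeps, extrapolation.

Point estimates are binomial proportions reported as percentages rounded
half-up to two decimals; interval estimates are Wald (normal-approximation)
95% confidence intervals computed on the unrounded proportion and clamped to
[0, 100].  Wilson and Clopper-Pearson intervals are available behind a flag.
Population extrapolation is exact rational arithmetic (count x N/n, rounded
half-up) so no floating-point intermediate can change the integer result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Optional

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cvd import DEFINITION_NAMES, ObservationWindow

__all__ = [
    "PrevalenceEstimate",
    "ExtrapolationResult",
    "prevalence",
    "extrapolate",
    "window_sweep",
    "stratify",
    "round_half_up",
]


def round_half_up(x: float | Fraction, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of the summary tables)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """One table cell: numerator, denominator, percent and 95% CI bounds."""

    numerator: int
    denominator: int
    percent: float  # 100*n/N, half-up to 2 decimals
    ci_low: float
    ci_high: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(
                f"numerator {self.numerator} outside [0, {self.denominator}]"
            )
        if not (self.ci_low <= self.percent <= self.ci_high):
            raise AssertionError("CI bounds do not bracket the point estimate")

    @property
    def proportion(self) -> Fraction:
        """Exact unrounded proportion n/N."""
        return Fraction(self.numerator, self.denominator)

    @property
    def percent_1dp(self) -> float:
        """One-decimal percentage used in running text (e.g. 46.7)."""
        return round_half_up(100 * self.proportion, 1)

    def __str__(self) -> str:
        return f"{self.percent:.2f}% ({self.ci_low:.2f}; {self.ci_high:.2f})"


def prevalence(
    numerator: int,
    denominator: int,
    z: float = 1.96,
    method: str = "wald",
) -> PrevalenceEstimate:
    """Binomial proportion with a 95% confidence interval on the percent scale.

    ``method`` is ``"wald"`` (default), ``"wilson"`` or ``"beta"``
    (Clopper-Pearson); the alternatives delegate to statsmodels.
    Degenerate proportions (0 or 1) give zero-width Wald intervals after
    clamping.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    p = numerator / denominator
    if method == "wald":
        half = z * math.sqrt(p * (1.0 - p) / denominator)
        lo, hi = p - half, p + half
    elif method in ("wilson", "beta"):
        alpha = 2 * (1 - _normal_cdf(z))
        lo, hi = proportion_confint(numerator, denominator, alpha=alpha, method=method)
    else:
        raise ValueError(f"unknown interval method {method!r}")
    pct = round_half_up(Fraction(100 * numerator, denominator), 2)
    ci_low = min(max(round_half_up(100 * lo, 2), 0.0), 100.0)
    ci_high = min(max(round_half_up(100 * hi, 2), 0.0), 100.0)
    # rounding can push a degenerate bound past the rounded point estimate
    ci_low = min(ci_low, pct)
    ci_high = max(ci_high, pct)
    return PrevalenceEstimate(numerator, denominator, pct, ci_low, ci_high, z)


def _normal_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclass(frozen=True)
class ExtrapolationResult:
    sample_numerator: int
    sample_denominator: int
    reference_population: int
    extrapolated_count: int


def extrapolate(
    numerator: int, denominator: int, reference_population: int
) -> ExtrapolationResult:
    """Scale a sample count to a reference population by exact rational arithmetic."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    exact = Fraction(numerator * reference_population, denominator)
    # round half-up on the exact rational
    count = (exact.numerator * 2 + exact.denominator) // (2 * exact.denominator)
    return ExtrapolationResult(numerator, denominator, reference_population, int(count))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def window_sweep(
    cohort: pd.DataFrame,
    definitions: Iterable[str] = DEFINITION_NAMES,
    windows: Optional[Iterable[ObservationWindow]] = None,
    z: float = 1.96,
) -> pd.DataFrame:
    """Observation-period x definition grid of CVD prevalence among cases.

    Expects ``cvd_{definition}_{start}_{end}`` flag columns as produced by
    :func:`t2d_cvd.cohort.build_cohort`.  Returns one row per (window,
    definition) with numerator, denominator, percent and CI bounds.
    """
    cases = cohort[cohort["is_case"]]
    if len(cases) == 0:
        raise ValueError("empty cohort: no T2D cases to sweep")
    if windows is None:
        windows = [ObservationWindow(y, 2015) for y in range(2010, 2016)]
    rows = []
    for w in windows:
        for name in definitions:
            col = f"cvd_{name}_{w.start_year}_{w.end_year}"
            if col not in cases.columns:
                raise KeyError(f"cohort lacks column {col}; re-run classification")
            est = prevalence(int(cases[col].sum()), len(cases), z=z)
            rows.append(
                {
                    "window": str(w),
                    "window_years": w.n_years,
                    "definition": name,
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "percent": est.percent,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    return pd.DataFrame(rows)


def stratify(
    cohort: pd.DataFrame,
    by: str,
    flag_column: str,
    z: float = 1.96,
) -> pd.DataFrame:
    """Per-stratum prevalence of a flag among T2D cases, plus mean age.

    ``by`` is one of the cohort stratum columns (``sex``, ``age_band``,
    ``duration_category``, ``therapy_class``).  Strata partition the cases,
    so per-stratum numerators sum to the total numerator; a ``total`` row is
    appended.
    """
    allowed = {"sex", "age_band", "duration_category", "therapy_class"}
    if by not in allowed:
        raise ValueError(f"unknown stratum column {by!r}; expected one of {sorted(allowed)}")
    cases = cohort[cohort["is_case"]]
    if len(cases) == 0:
        raise ValueError("empty cohort: no T2D cases to stratify")
    rows = []
    for label, grp in cases.groupby(by, sort=True):
        est = prevalence(int(grp[flag_column].sum()), len(grp), z=z)
        rows.append(
            {
                by: label,
                "numerator": est.numerator,
                "denominator": est.denominator,
                "percent": est.percent,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "mean_age": round_half_up(float(grp["age"].mean()), 2),
            }
        )
    est = prevalence(int(cases[flag_column].sum()), len(cases), z=z)
    rows.append(
        {
            by: "total",
            "numerator": est.numerator,
            "denominator": est.denominator,
            "percent": est.percent,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "mean_age": round_half_up(float(cases["age"].mean()), 2),
        }
    )
    return pd.DataFrame(rows)
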
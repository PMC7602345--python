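"""Visual-fidelity statistics for the TBSA rating study.

Nine expert raters each assessed a virtual burn patient on a Lund-Browder
sheet; for every record we have the reported and the generated (ground-truth)
percent TBSA in three categories: 2nd degree, 3rd degree, and total.  The
study asks whether the raters' absolute error is below a fidelity threshold
mu0 (5% for the depth categories, 10% for the total), i.e. it tests
H0: mu = mu0 against HA: mu < mu0 with a one-sample, one-sided t-test on the
signed errors (reported - generated).

Conventions
-----------
* Standard deviation uses the population convention (divisor n), both for the
  reported descriptive and inside the t statistic.  This is nonstandard for a
  one-sample t-test (the usual choice is the sample SD, divisor n-1); the two
  t values differ by the factor sqrt(n/(n-1)).  The population convention is
  used here because it is the convention of the original rating study this
  module reproduces.
* p is the lower-tail probability of Student's t with n-1 degrees of freedom.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "RaterRecord",
    "FidelityHypothesis",
    "CategoryResult",
    "FidelityStudyResult",
    "CATEGORIES",
    "load_rater_study",
    "signed_errors",
    "describe",
    "one_sided_t_test",
    "run_fidelity_study",
]

CATEGORIES = ("2nd", "3rd", "total")


@dataclass(frozen=True)
class RaterRecord:
    """One rater's sheet for one virtual patient, percent TBSA per category."""

    picture_id: str
    reported_2nd: float
    generated_2nd: float
    reported_3rd: float
    generated_3rd: float
    reported_total: float
    generated_total: float

    def __post_init__(self) -> None:
        for name in (
            "generated_2nd",
            "generated_3rd",
            "generated_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def pair(self, category: str) -> Tuple[float, float]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected {CATEGORIES}")
        suffix = {"2nd": "2nd", "3rd": "3rd", "total": "total"}[category]
        return (
            getattr(self, f"reported_{suffix}"),
            getattr(self, f"generated_{suffix}"),
        )


@dataclass(frozen=True)
class FidelityHypothesis:
    """Null means per category; the alternative is one-sided: mu < mu0."""

    mu0_partial: float = 5.0
    mu0_full: float = 5.0
    mu0_total: float = 10.0

    def __post_init__(self) -> None:
        if min(self.mu0_partial, self.mu0_full, self.mu0_total) <= 0:
            raise ValueError("null means must be positive")

    def mu0(self, category: str) -> float:
        return {
            "2nd": self.mu0_partial,
            "3rd": self.mu0_full,
            "total": self.mu0_total,
        }[category]


@dataclass(frozen=True)
class CategoryResult:
    category: str
    n: int
    mean_error: float
    sd_error: float  # population convention (divisor n)
    mu0: float
    t_stat: float
    p_value: float

    def rounded(self) -> Tuple[float, float, float, float]:
        """(mean, sd, t, p) at the report's printed precision."""
        return (
            round(self.mean_error, 1),
            round(self.sd_error, 1),
            round(self.t_stat, 2),
            round(self.p_value, 4),
        )


@dataclass(frozen=True)
class FidelityStudyResult:
    categories: Dict[str, CategoryResult]

    def __getitem__(self, category: str) -> CategoryResult:
        return self.categories[category]

    def as_table(self) -> List[Dict[str, float]]:
        return [
            {
                "category": c.category,
                "mean_pct": c.mean_error,
                "sd_pct": c.sd_error,
                "t_stat": c.t_stat,
                "p_value": c.p_value,
                "n": c.n,
            }
            for c in self.categories.values()
        ]


def load_rater_study(path=None) -> List[RaterRecord]:
    """Load rater records from CSV (default: the shipped 9-record study)."""
    if path is None:
        ref = resources.files("burnsim.data").joinpath("sme_table1.csv")
        with ref.open(newline="") as fh:
            return _parse_csv(fh)
    with open(path, newline="") as fh:
        return _parse_csv(fh)


def _parse_csv(fh) -> List[RaterRecord]:
    reader = csv.DictReader(fh)
    records = []
    for row in reader:
        records.append(
            RaterRecord(
                picture_id=row["picture_id"],
                reported_2nd=float(row["reported_2nd"]),
                generated_2nd=float(row["generated_2nd"]),
                reported_3rd=float(row["reported_3rd"]),
                generated_3rd=float(row["generated_3rd"]),
                reported_total=float(row["reported_total"]),
                generated_total=float(row["generated_total"]),
            )
        )
    if not records:
        raise ValueError("rater study CSV contains no records")
    return records


def signed_errors(records: Sequence[RaterRecord], category: str) -> np.ndarray:
    """Signed error vector, element i = reported_i - generated_i."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    pairs = np.array([r.pair(category) for r in records], dtype=float)
    return pairs[:, 0] - pairs[:, 1]


def describe(errors: Sequence[float]) -> Tuple[float, float]:
    """Mean and population SD (divisor n) of an error vector; requires n >= 2."""
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two observations to describe spread")
    return float(e.mean()), float(e.std(ddof=0))


def one_sided_t_test(errors: Sequence[float], mu0: float) -> Tuple[float, float]:
    """One-sample lower-tail t-test with the population-SD convention.

    t = (mean - mu0) / (sd_pop / sqrt(n)); p = P(T_{n-1} <= t).
    Raises on zero spread (t undefined).
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two observations")
    mean, sd = describe(e)
    if sd == 0.0:
        raise ValueError("zero standard deviation: t statistic undefined")
    n = e.size
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = float(stats.t.cdf(t, df=n - 1))
    return float(t), p


def run_fidelity_study(
    records: Sequence[RaterRecord],
    hypothesis: FidelityHypothesis = FidelityHypothesis(),
) -> FidelityStudyResult:
    """Signed errors -> descriptives -> one-sided t-test, for every category."""
    out: Dict[str, CategoryResult] = {}
    for category in CATEGORIES:
        errors = signed_errors(records, category)
        mean, sd = describe(errors)
        mu0 = hypothesis.mu0(category)
        t, p = one_sided_t_test(errors, mu0)
        out[category] = CategoryResult(
            category=category,
            n=len(errors),
            mean_error=mean,
            sd_error=sd,
            mu0=mu0,
            t_stat=t,
            p_value=p,
        )
    return FidelityStudyResult(categories=out)
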
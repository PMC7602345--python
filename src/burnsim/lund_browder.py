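"""Lund-Browder chart representation, TBSA computation, and burn-pattern generation.

The Lund-Browder chart partitions the body surface into regions, each carrying a
fixed fraction of total body surface area (TBSA).  A burn pattern assigns every
region a partial-thickness (2nd degree) and full-thickness (3rd degree) burned
fraction; the TBSA burned is the surface-weighted sum.  This module also
generates randomized virtual burn patterns (for training scenarios) and scores
a learner-reported breakdown against the generated ground truth.

All public interfaces use percent (0-100); fractions (0-1) are internal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BodyRegion",
    "LBChart",
    "BurnPattern",
    "TBSABreakdown",
    "CategoryScore",
    "ScoreReport",
    "load_adult_chart",
    "total_tbsa",
    "generate_burn",
    "score_sheet",
]

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BodyRegion:
    """One chart region: a named patch of skin with a fixed share of TBSA."""

    name: str
    surface_fraction: float
    side: Optional[str] = None  # anterior | posterior | None (wraps around)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("region name must be non-empty")
        if not 0.0 < self.surface_fraction <= 1.0:
            raise ValueError(
                f"region {self.name!r}: surface_fraction must be in (0, 1], "
                f"got {self.surface_fraction}"
            )
        if self.side not in (None, "anterior", "posterior"):
            raise ValueError(f"region {self.name!r}: invalid side {self.side!r}")


@dataclass(frozen=True)
class LBChart:
    """A Lund-Browder chart: regions whose surface fractions sum to 1."""

    regions: Tuple[BodyRegion, ...]
    age_band: str = "adult"

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("chart region names must be unique")
        total = sum(r.surface_fraction for r in self.regions)
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(
                f"chart surface fractions must sum to 1.0, got {total:.12f}"
            )

    @property
    def region_names(self) -> Tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def fraction(self, name: str) -> float:
        for r in self.regions:
            if r.name == name:
                return r.surface_fraction
        raise KeyError(name)

    @classmethod
    def from_json(cls, path_or_obj, age_band: str = "adult") -> "LBChart":
        """Load a chart from the versioned JSON layout (age band -> region map)."""
        if isinstance(path_or_obj, Mapping):
            doc = path_or_obj
        else:
            with open(path_or_obj) as fh:
                doc = json.load(fh)
        try:
            band = doc["age_bands"][age_band]
        except KeyError as exc:
            raise KeyError(f"age band {age_band!r} not present in chart file") from exc
        regions = tuple(
            BodyRegion(name, info["surface_fraction"], info.get("side"))
            for name, info in band.items()
        )
        return cls(regions=regions, age_band=age_band)


def load_adult_chart() -> LBChart:
    """The standard adult Lund-Browder chart shipped with the package."""
    with resources.files("burnsim.data").joinpath("lb_chart_adult.json").open() as fh:
        return LBChart.from_json(json.load(fh))


@dataclass(frozen=True)
class BurnPattern:
    """Per-region partial- and full-thickness burned fractions.

    ``fractions`` maps region name -> (partial_fraction, full_fraction), each in
    [0, 1] with partial + full <= 1 (a point of skin has at most one depth).
    """

    fractions: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (p, f) in self.fractions.items():
            if not (0.0 <= p <= 1.0 and 0.0 <= f <= 1.0):
                raise ValueError(
                    f"region {name!r}: burn fractions must lie in [0, 1], got ({p}, {f})"
                )
            if p + f > 1.0 + _FRACTION_SUM_TOL:
                raise ValueError(
                    f"region {name!r}: partial + full = {p + f:.6f} exceeds 1"
                )

    @classmethod
    def zero(cls, chart: LBChart) -> "BurnPattern":
        return cls({name: (0.0, 0.0) for name in chart.region_names})

    def scaled(self, alpha: float) -> "BurnPattern":
        """Pattern with every burned fraction multiplied by ``alpha`` in [0, 1]."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        return BurnPattern(
            {k: (alpha * p, alpha * f) for k, (p, f) in self.fractions.items()}
        )


@dataclass(frozen=True)
class TBSABreakdown:
    """Percent of body surface burned, split by depth. total = partial + full."""

    partial_pct: float
    full_pct: float
    total_pct: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total_pct is None:
            object.__setattr__(self, "total_pct", self.partial_pct + self.full_pct)
        if self.partial_pct < 0 or self.full_pct < 0:
            raise ValueError("burn percentages must be non-negative")
        if abs(self.total_pct - (self.partial_pct + self.full_pct)) > 1e-6:
            raise ValueError("total_pct must equal partial_pct + full_pct")
        if self.total_pct > 100.0 + 1e-6:
            raise ValueError("total_pct cannot exceed 100")


def total_tbsa(chart: LBChart, pattern: BurnPattern) -> TBSABreakdown:
    """Tally a burn pattern on a chart into a percent TBSA breakdown.

    partial_pct = 100 * sum_r surface_fraction(r) * partial_fraction(r), and
    analogously for full thickness; total is their sum.
    """
    chart_names = set(chart.region_names)
    pattern_names = set(pattern.fractions)
    if chart_names != pattern_names:
        missing = sorted(chart_names - pattern_names)
        extra = sorted(pattern_names - chart_names)
        raise ValueError(
            f"pattern does not cover the chart's regions "
            f"(missing {missing}, unexpected {extra})"
        )
    partial = sum(
        chart.fraction(name) * pf[0] for name, pf in pattern.fractions.items()
    )
    full = sum(chart.fraction(name) * pf[1] for name, pf in pattern.fractions.items())
    return TBSABreakdown(partial_pct=100.0 * partial, full_pct=100.0 * full)


def generate_burn(
    chart: LBChart,
    target_total_pct: Tuple[float, float],
    partial_full_split: Tuple[float, float] = (0.2, 0.7),
    seed: int = 0,
) -> BurnPattern:
    """Generate a randomized burn pattern with total TBSA inside a target range.

    An exact target total is drawn uniformly from ``target_total_pct``.  Regions
    are then visited in a seeded random order weighted by surface fraction, each
    burned completely until the remaining budget is smaller than the region, in
    which case the region is burned partially to land exactly on the target.
    Each region's burned area is split into partial/full thickness by a seeded
    draw of the full-thickness share from ``partial_full_split``.

    Pure function of (chart, ranges, seed): the same inputs always return the
    identical pattern.
    """
    lo, hi = target_total_pct
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError(
            f"target range must satisfy 0 <= lo <= hi <= 100, got ({lo}, {hi})"
        )
    s_lo, s_hi = partial_full_split
    if not (0.0 <= s_lo <= s_hi <= 1.0):
        raise ValueError("partial_full_split must be a subrange of [0, 1]")

    rng = np.random.default_rng(seed)
    target_frac = rng.uniform(lo, hi) / 100.0
    if target_frac == 0.0:
        return BurnPattern.zero(chart)

    names = list(chart.region_names)
    weights = np.array([chart.fraction(n) for n in names])
    order = rng.choice(len(names), size=len(names), replace=False, p=weights)

    fractions = {n: (0.0, 0.0) for n in names}
    remaining = target_frac
    for idx in order:
        if remaining <= 0:
            break
        name = names[idx]
        sf = chart.fraction(name)
        burned = min(1.0, remaining / sf)  # fraction of this region burned
        full_share = rng.uniform(s_lo, s_hi)
        fractions[name] = (burned * (1.0 - full_share), burned * full_share)
        remaining -= burned * sf

    pattern = BurnPattern(fractions)
    achieved = total_tbsa(chart, pattern).total_pct
    # constructive fill lands on the drawn target; guard against drift
    if not (lo - 1e-6 <= achieved <= hi + 1e-6):
        raise RuntimeError(
            f"generated total {achieved:.3f}% escaped target range ({lo}, {hi})"
        )
    return pattern


@dataclass(frozen=True)
class CategoryScore:
    reported_pct: float
    generated_pct: float
    signed_error_pct: float
    passed: bool


@dataclass(frozen=True)
class ScoreReport:
    """Per-category comparison of a learner's sheet against the ground truth."""

    partial: CategoryScore
    full: CategoryScore
    total: CategoryScore
    tolerance_pct: float

    @property
    def all_passed(self) -> bool:
        return self.partial.passed and self.full.passed and self.total.passed


def score_sheet(
    reported: TBSABreakdown, truth: TBSABreakdown, tolerance_pct: float
) -> ScoreReport:
    """Score a reported breakdown against the generated truth.

    Signed error is reported - generated for each category; a category passes
    when |error| <= tolerance_pct.
    """
    if tolerance_pct < 0:
        raise ValueError("tolerance_pct must be non-negative")

    def cat(rep: float, gen: float) -> CategoryScore:
        err = rep - gen
        return CategoryScore(rep, gen, err, abs(err) <= tolerance_pct)

    return ScoreReport(
        partial=cat(reported.partial_pct, truth.partial_pct),
        full=cat(reported.full_pct, truth.full_pct),
        total=cat(reported.total_pct, truth.total_pct),
        tolerance_pct=tolerance_pct,
    )
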
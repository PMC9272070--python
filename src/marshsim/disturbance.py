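"""Mowing schedules and their instantaneous stage-specific mortality.

Grassland is cut two to three times per year on fixed days-of-year.  A
schedule is named ``Mww + ww + ww`` for its early/mid/late calendar
weeks, with ``00`` marking an absent slot; the mowing day is the first
day of the calendar week, ``(week − 1) × 7`` under 1-based day counting.
A cut kills a high fraction of the aboveground stages (larva, imago)
and a low fraction of the belowground egg stages; the kill is applied
deterministically to densities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import DAYS_PER_YEAR, WEEKS_PER_YEAR
from .lifecycle import Population, StageSpec

__all__ = [
    "MowingSchedule",
    "MowingImpact",
    "schedule_from_weeks",
    "builtin_schedules",
    "apply_mowing",
]


@dataclass(frozen=True)
class MowingSchedule:
    """Up to three yearly mowing days (early, mid, late)."""

    name: str
    acronym: str
    days: tuple[int | None, int | None, int | None]

    def __post_init__(self):
        present = [d for d in self.days if d is not None]
        if not present:
            raise ValueError("a mowing schedule needs at least one event")
        if any(not 1 <= d <= DAYS_PER_YEAR for d in present):
            raise ValueError(f"mowing days {present} outside [1, {DAYS_PER_YEAR}]")
        if present != sorted(present) or len(set(present)) != len(present):
            raise ValueError("mowing days must be strictly increasing")

    @property
    def event_days(self) -> tuple[int, ...]:
        return tuple(d for d in self.days if d is not None)

    def fires_on(self, day_of_year: int) -> bool:
        return day_of_year in self.event_days


@dataclass(frozen=True)
class MowingImpact:
    """Instantaneous kill fractions of one cut.

    The aboveground fraction applies to larva and imago, the (smaller)
    belowground fraction to the egg stages.  Defaults are this
    package's own choices: a cut removes most of the aboveground
    population and barely touches buried eggs.
    """

    aboveground: float = 0.9
    belowground: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.belowground <= self.aboveground <= 1.0:
            raise ValueError(
                "kill fractions must satisfy 0 <= belowground <= aboveground <= 1"
            )


def schedule_from_weeks(
    early: int | None, mid: int | None, late: int | None
) -> MowingSchedule:
    """Build a schedule from calendar weeks; day = (week − 1) × 7."""
    weeks = (early, mid, late)
    present = [w for w in weeks if w is not None]
    if not present:
        raise ValueError("at least one mowing week is required")
    if any(not 1 <= w <= WEEKS_PER_YEAR for w in present):
        raise ValueError(f"mowing weeks {present} outside [1, {WEEKS_PER_YEAR}]")
    if present != sorted(present) or len(set(present)) != len(present):
        raise ValueError("mowing weeks must be strictly increasing")
    days = tuple((w - 1) * 7 if w is not None else None for w in weeks)
    name = "M" + " + ".join(f"{w:02d}" if w is not None else "00" for w in weeks)
    if mid is not None:
        acronym = f"M{mid:02d}"
    else:
        acronym = "M00"
    return MowingSchedule(name=name, acronym=acronym, days=days)


def builtin_schedules() -> dict[str, MowingSchedule]:
    """The 18 standard schedules, keyed by acronym.

    ``M00`` (weeks 20 and 44) is the low-impact base schedule applied
    to undisturbed grassland; ``M22``–``M25`` replace the early cut by
    an intensive one, ``M26``–``M34`` add a mid-season cut, and
    ``M35``–``M38`` drop the late cut.
    """
    triples: list[tuple[int | None, int | None, int | None]] = [(20, None, 44)]
    triples += [(None, mid, 44) for mid in range(22, 26)]
    triples += [(20, mid, 44) for mid in range(26, 35)]
    triples += [(20, mid, None) for mid in range(35, 39)]
    schedules = [schedule_from_weeks(*t) for t in triples]
    return {s.acronym: s for s in schedules}


def apply_mowing(
    population: Population,
    impact: MowingImpact,
    stage_table: dict[str, StageSpec],
) -> None:
    """Apply one cut's kill fractions to a cell's densities in place.

    Aboveground stages are scaled by ``1 − aboveground``, belowground
    stages by ``1 − belowground``; the kill is deterministic (no
    sampling), so mowing never increases any density.
    """
    for name, cohorts in population.stages.items():
        frac = impact.aboveground if stage_table[name].aboveground else impact.belowground
        if frac > 0.0 and len(cohorts):
            cohorts.scale(1.0 - frac)
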
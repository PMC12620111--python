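"""Invasion and availability schedules for a spatially structured study area.

A study consists of a fixed set of discrete populations monitored over a
contiguous range of calendar years.  An invasive prey species establishes in
different populations in different years (some populations may never be
invaded), and some populations only become available as movement destinations
partway through the study.  The schedule drives both the simulation of
individual movement (availability masking) and the time-since-invasion (tsi)
covariates entering the vital-rate models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["InvasionSchedule", "TsiCovariate", "tsi_covariate", "TSI_FORMS"]

TSI_FORMS = ("null", "linear", "quadratic", "log")


@dataclass(frozen=True)
class InvasionSchedule:
    """Population codes, invasion years and availability windows.

    Parameters
    ----------
    populations
        Ordered population codes (single tokens, e.g. ``"A"`` or ``"KRV"``).
    invasion_year
        Calendar year the invasive prey established per population; omit a
        population to mark it never-invaded.
    study_years
        Inclusive ``(first, last)`` calendar-year range of the study.
    available_from
        First calendar year each population exists as a movement destination.
        Populations absent from the mapping are available from the first
        study year.
    """

    populations: tuple[str, ...]
    invasion_year: dict[str, int] = field(default_factory=dict)
    study_years: tuple[int, int] = (0, 0)
    available_from: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population codes")
        first, last = self.study_years
        if last < first:
            raise ValueError(f"study_years reversed: {self.study_years}")
        for r in self.invasion_year:
            if r not in self.populations:
                raise ValueError(f"invasion_year for unknown population {r!r}")
            if self.invasion_year[r] > last:
                raise ValueError(
                    f"invasion year {self.invasion_year[r]} for {r!r} is after "
                    f"the study end {last}"
                )
        for r, y in self.available_from.items():
            if r not in self.populations:
                raise ValueError(f"available_from for unknown population {r!r}")
            if not (first <= y <= last):
                raise ValueError(
                    f"available_from {y} for {r!r} outside study years"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def years(self) -> range:
        return range(self.study_years[0], self.study_years[1] + 1)

    @property
    def n_years(self) -> int:
        return self.study_years[1] - self.study_years[0] + 1

    def index(self, population: str) -> int:
        return self.populations.index(population)

    def year_index(self, year: int) -> int:
        if not (self.study_years[0] <= year <= self.study_years[1]):
            raise ValueError(f"year {year} outside study range")
        return year - self.study_years[0]

    def is_available(self, population: str, year: int) -> bool:
        return year >= self.available_from.get(population, self.study_years[0])

    def is_invaded(self, population: str, year: int) -> bool:
        inv = self.invasion_year.get(population)
        return inv is not None and year >= inv

    def tsi(self, population: str, year: int) -> int | None:
        """Years since invasion (0 in the invasion year); None pre-invasion."""
        inv = self.invasion_year.get(population)
        if inv is None or year < inv:
            return None
        return year - inv

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "invasion_year": dict(self.invasion_year),
            "study_years": list(self.study_years),
            "available_from": dict(self.available_from),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InvasionSchedule":
        return cls(
            populations=tuple(d["populations"]),
            invasion_year={k: int(v) for k, v in d.get("invasion_year", {}).items()},
            study_years=tuple(int(v) for v in d["study_years"]),
            available_from={k: int(v) for k, v in d.get("available_from", {}).items()},
        )


@dataclass(frozen=True)
class TsiCovariate:
    """Time-since-invasion covariate for one population-year.

    ``post_invasion`` is False before (or absent) invasion, in which case no
    tsi value or transform is defined.  The log transform is ``ln(tsi + 1)``
    so the invasion year itself (tsi = 0) maps to a finite value.
    """

    population: str
    year: int
    post_invasion: bool
    tsi: int | None = None
    form: str = "linear"
    values: tuple[float, ...] = ()


def tsi_covariate(
    schedule: InvasionSchedule, population: str, year: int, form: str = "linear"
) -> TsiCovariate:
    """Build the tsi covariate row for one population-year.

    Forms: ``"null"`` (no covariate), ``"linear"`` (tsi), ``"quadratic"``
    (tsi, tsi^2) and ``"log"`` (ln(tsi + 1)).  A pre-invasion or
    never-invaded population-year yields ``post_invasion=False`` and empty
    values — it is not an error.
    """
    if form not in TSI_FORMS:
        raise ValueError(f"unknown tsi form {form!r}; one of {TSI_FORMS}")
    if population not in schedule.populations:
        raise ValueError(f"unknown population {population!r}")
    t = schedule.tsi(population, year)
    if t is None:
        return TsiCovariate(population, year, False, None, form, ())
    if form == "null":
        vals: tuple[float, ...] = ()
    elif form == "linear":
        vals = (float(t),)
    elif form == "quadratic":
        vals = (float(t), float(t) ** 2)
    else:  # log
        vals = (math.log(t + 1.0),)
    return TsiCovariate(population, year, True, t, form, vals)
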
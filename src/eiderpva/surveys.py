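"""Survey time-series data model and the built-in eider aerial-survey series.

Aerial surveys of spectacled eiders (*Somateria fischeri*) on the Arctic
Coastal Plain (ACP) and Yukon-Kuskokwim Delta (YKD) of Alaska yield annual
detection-adjusted estimates of indicated breeding birds, each with a sampling
standard error.  This module provides the validated container for such series
(:class:`SurveySeries`), CSV readers/writers, and the 2007-2019 estimates for
both Alaskan breeding populations as packaged fixtures.

Missing survey years (no flight, or an estimate deliberately excluded) are
kept as explicit placeholder records so that the state process of the
population model can propagate through every calendar year.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

__all__ = [
    "SurveyObservation",
    "SurveySeries",
    "SurveyValidationError",
    "load_survey_series",
    "write_survey_series",
    "builtin_series",
    "mask_year",
]


class SurveyValidationError(ValueError):
    """Raised when survey input violates the data-model invariants."""


@dataclasses.dataclass(frozen=True)
class SurveyObservation:
    """One survey year: a detection-adjusted estimate of breeding birds.

    ``estimate`` and ``se`` are ``None`` for years without a usable survey
    (``observed`` is False).  Estimates may be non-integer because the
    visibility correction multiplies raw counts by a real-valued factor.
    """

    year: int
    estimate: float | None = None
    se: float | None = None
    observed: bool = True

    def __post_init__(self) -> None:
        if self.observed:
            if self.estimate is None or self.se is None:
                raise SurveyValidationError(
                    f"year {self.year}: observed record needs estimate and se"
                )
            if not (self.estimate > 0):
                raise SurveyValidationError(
                    f"year {self.year}: estimate must be positive, got {self.estimate}"
                )
            if not (self.se > 0):
                raise SurveyValidationError(
                    f"year {self.year}: se must be positive, got {self.se}"
                )
        else:
            if self.estimate is not None or self.se is not None:
                raise SurveyValidationError(
                    f"year {self.year}: missing-year record must not carry values"
                )

    @classmethod
    def missing(cls, year: int) -> "SurveyObservation":
        return cls(year=year, estimate=None, se=None, observed=False)


@dataclasses.dataclass(frozen=True)
class SurveySeries:
    """A contiguous annual series of :class:`SurveyObservation` for one population."""

    population: str
    observations: tuple[SurveyObservation, ...]

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        years = [o.year for o in obs]
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise SurveyValidationError(
                f"{self.population}: years must be contiguous and increasing, got {years}"
            )
        if sum(o.observed for o in obs) < 2:
            raise SurveyValidationError(
                f"{self.population}: need at least 2 observed years"
            )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(o.year for o in self.observations)

    @property
    def first_year(self) -> int:
        return self.observations[0].year

    @property
    def last_year(self) -> int:
        return self.observations[-1].year

    @property
    def n_years(self) -> int:
        return len(self.observations)

    @property
    def n_observed(self) -> int:
        return sum(o.observed for o in self.observations)

    def observation(self, year: int) -> SurveyObservation:
        if not (self.first_year <= year <= self.last_year):
            raise KeyError(f"year {year} outside range {self.first_year}-{self.last_year}")
        return self.observations[year - self.first_year]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with NaN marking missing years."""
        return pd.DataFrame(
            {
                "year": [o.year for o in self.observations],
                "estimate": [o.estimate if o.observed else math.nan for o in self.observations],
                "se": [o.se if o.observed else math.nan for o in self.observations],
            }
        )


def _series_from_frame(df: pd.DataFrame, population: str, source: str) -> SurveySeries:
    required = {"year", "estimate", "se"}
    if not required.issubset(df.columns):
        raise SurveyValidationError(
            f"{source}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    try:
        years = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SurveyValidationError(f"{source}: non-integer year column: {exc}") from exc
    if years.duplicated().any():
        dup = int(years[years.duplicated()].iloc[0])
        raise SurveyValidationError(f"{source}: duplicate year {dup}")
    if not years.is_monotonic_increasing:
        raise SurveyValidationError(f"{source}: years must be increasing")

    by_year: dict[int, SurveyObservation] = {}
    for row in df.itertuples(index=False):
        year = int(row.year)
        est, se = row.estimate, row.se
        est_missing = pd.isna(est)
        se_missing = pd.isna(se)
        if est_missing != se_missing:
            raise SurveyValidationError(
                f"{source}: year {year}: estimate and se must both be present or both blank"
            )
        if est_missing:
            by_year[year] = SurveyObservation.missing(year)
        else:
            try:
                obs = SurveyObservation(year, float(est), float(se))
            except SurveyValidationError as exc:
                raise SurveyValidationError(f"{source}: {exc}") from exc
            by_year[year] = obs

    y0, y1 = min(by_year), max(by_year)
    records = [by_year.get(y, SurveyObservation.missing(y)) for y in range(y0, y1 + 1)]
    return SurveySeries(population=population, observations=tuple(records))


def load_survey_series(path: Union[str, Path], population: str) -> SurveySeries:
    """Read a series from CSV (columns ``year,estimate,se``; blank/NA = missing year).

    Gaps in the year range are filled with missing-year records so the result
    is always a contiguous annual series.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _series_from_frame(df, population=population, source=str(path))


def write_survey_series(series: SurveySeries, path: Union[str, Path]) -> None:
    """Write the CSV dialect that :func:`load_survey_series` reads back exactly."""
    series.to_frame().to_csv(path, index=False)


# Detection-adjusted estimates of indicated breeding birds, 2007-2019
# (no YKD survey was flown in 2011).
_YKD_TABLE: Sequence[tuple[int, float | None, float | None]] = (
    (2007, 12527, 1045),
    (2008, 14580, 1273),
    (2009, 15562, 1232),
    (2010, 13491, 1056),
    (2011, None, None),
    (2012, 14696, 1279),
    (2013, 16178, 1238),
    (2014, 13152, 1075),
    (2015, 5714, 494),
    (2016, 14481, 1086),
    (2017, 16727, 1368),
    (2018, 15544, 1241),
    (2019, 15111, 1137),
)

_ACP_TABLE: Sequence[tuple[int, float | None, float | None]] = (
    (2007, 6555, 961),
    (2008, 7733, 939),
    (2009, 7072, 1226),
    (2010, 6892, 987),
    (2011, 10562, 1258),
    (2012, 6228, 679),
    (2013, 9995, 1302),
    (2014, 9651, 1382),
    (2015, 7745, 969),
    (2016, 5696, 892),
    (2017, 5951, 1073),
    (2018, 6418, 1276),
    (2019, 5108, 725),
)

_BUILTIN = {"YKD": _YKD_TABLE, "ACP": _ACP_TABLE}


def builtin_series(name: str) -> SurveySeries:
    """Return one of the packaged 2007-2019 eider series (``"ACP"`` or ``"YKD"``)."""
    try:
        table = _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_BUILTIN)}"
        ) from None
    records = tuple(
        SurveyObservation(y, e, s) if e is not None else SurveyObservation.missing(y)
        for y, e, s in table
    )
    return SurveySeries(population=name, observations=records)


def mask_year(series: SurveySeries, year: int) -> SurveySeries:
    """Copy of ``series`` with ``year`` treated as a missing data point.

    Used to refit a model with a suspect estimate excluded (e.g. the
    anomalously low 2015 YKD estimate taken by a new observer).  Masking an
    already-missing year is a no-op.
    """
    if not (series.first_year <= year <= series.last_year):
        raise KeyError(
            f"year {year} outside series range {series.first_year}-{series.last_year}"
        )
    records = tuple(
        SurveyObservation.missing(o.year) if o.year == year else o
        for o in series.observations
    )
    return SurveySeries(population=series.population, observations=records)
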
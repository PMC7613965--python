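"""Data model and I/O for stratified linked-cohort mortality tables.

The central object is a :class:`CohortDataset`: per demographic group
(gender x age band x region), year and treatment status it records the
number of fatal drug-related poisonings (fDRPs) linked to the cohort and
the person-years at risk; per group in the estimation year it additionally
records the fDRPs *not* linked to the cohort, the observed cohort
headcount and the population denominator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Categories",
    "GroupKey",
    "CohortCell",
    "GroupObservation",
    "CohortDataset",
    "SchemaError",
    "ValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_table1",
    "aggregate_counts",
    "crude_rate_per_1000",
    "CELL_FIELDS",
    "OBS_FIELDS",
]

#: canonical column names of the cohort CSV format
CELL_FIELDS = ("deaths_linked", "person_years")
OBS_FIELDS = ("deaths_unlinked", "cohort_count", "population")
KEY_FIELDS = ("gender", "age_band", "region", "year")
ALL_COLUMNS = KEY_FIELDS + ("treatment",) + CELL_FIELDS + OBS_FIELDS

TREATMENT_LEVELS = ("on", "off")


class SchemaError(ValueError):
    """A required column is missing or unrecognised."""


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


@dataclass(frozen=True)
class Categories:
    """Declared category levels; order fixes regression reference coding.

    The first declared level of each factor is the reference level.
    """

    genders: tuple[str, ...] = ("male", "female")
    age_bands: tuple[str, ...] = ("young", "old")
    regions: tuple[str, ...] = ("england",)
    years: tuple[str, ...] = ("2005/06", "2006/07", "2007/08", "2008/09")

    def __post_init__(self) -> None:
        for name in ("genders", "age_bands", "regions", "years"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ValidationError(f"no levels declared for {name}")
            if len(set(levels)) != len(levels):
                raise ValidationError(f"duplicate levels in {name}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def index_of(self, factor: str, level: str) -> int:
        levels = getattr(self, factor)
        try:
            return levels.index(level)
        except ValueError:
            raise ValueError(f"unknown {factor} level: {level!r}") from None


@dataclass(frozen=True, order=True)
class GroupKey:
    """One demographic stratum in one year."""

    gender: str
    age_band: str
    region: str
    year: str

    def validate(self, categories: Categories) -> None:
        if self.gender not in categories.genders:
            raise ValueError(f"unknown gender level: {self.gender!r}")
        if self.age_band not in categories.age_bands:
            raise ValueError(f"unknown age_band level: {self.age_band!r}")
        if self.region not in categories.regions:
            raise ValueError(f"unknown region level: {self.region!r}")
        if self.year not in categories.years:
            raise ValueError(f"unknown year level: {self.year!r}")

    @property
    def group(self) -> tuple[str, str, str]:
        """Gender/age/region combination, without the year."""
        return (self.gender, self.age_band, self.region)


@dataclass(frozen=True)
class CohortCell:
    """Linked deaths and person-years for one stratum, year and treatment state."""

    key: GroupKey
    treatment: str
    deaths_linked: int
    person_years: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENT_LEVELS:
            raise ValidationError(f"treatment must be one of {TREATMENT_LEVELS}")
        if self.deaths_linked < 0:
            raise ValidationError("deaths_linked must be non-negative")
        if self.person_years < 0:
            raise ValidationError("person_years must be non-negative")
        if self.person_years == 0 and self.deaths_linked > 0:
            raise ValidationError("deaths_linked > 0 with zero person-years")


@dataclass(frozen=True)
class GroupObservation:
    """Unlinked deaths, cohort headcount and population for one stratum-year."""

    key: GroupKey
    deaths_unlinked: int
    cohort_count: int
    population: int

    def __post_init__(self) -> None:
        if self.deaths_unlinked < 0:
            raise ValidationError("deaths_unlinked must be non-negative")
        if self.cohort_count < 0:
            raise ValidationError("cohort_count must be non-negative")
        if self.population <= 0:
            raise ValidationError("population must be positive")
        if self.cohort_count > self.population:
            raise ValidationError("cohort_count exceeds population")


@dataclass
class CohortDataset:
    """Validated collection of cohort cells and estimation-year observations."""

    categories: Categories
    cells: list[CohortCell] = field(default_factory=list)
    observations: list[GroupObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.cells:
            raise ValidationError("no records")
        seen: set[tuple[GroupKey, str]] = set()
        for cell in self.cells:
            cell.key.validate(self.categories)
            pair = (cell.key, cell.treatment)
            if pair in seen:
                raise ValidationError(f"duplicate (key, treatment) pair: {pair}")
            seen.add(pair)
        cell_keys = {c.key for c in self.cells}
        obs_keys = set()
        for obs in self.observations:
            obs.key.validate(self.categories)
            if obs.key in obs_keys:
                raise ValidationError(f"duplicate observation key: {obs.key}")
            obs_keys.add(obs.key)
            if obs.key not in cell_keys:
                raise ValidationError(f"observation without matching cells: {obs.key}")
            for trt in TREATMENT_LEVELS:
                if (obs.key, trt) not in seen:
                    raise ValidationError(
                        f"estimation-year group {obs.key} missing treatment state {trt!r}"
                    )

    @property
    def estimation_year(self) -> str | None:
        """The (single) year carrying observations, or None."""
        years = {obs.key.year for obs in self.observations}
        if not years:
            return None
        if len(years) > 1:
            raise ValidationError("observations span multiple years")
        return years.pop()

    def cells_frame(self) -> pd.DataFrame:
        """Cells as a DataFrame, one row per (key, treatment)."""
        return pd.DataFrame(
            {
                "gender": [c.key.gender for c in self.cells],
                "age_band": [c.key.age_band for c in self.cells],
                "region": [c.key.region for c in self.cells],
                "year": [c.key.year for c in self.cells],
                "treatment": [c.treatment for c in self.cells],
                "deaths_linked": [c.deaths_linked for c in self.cells],
                "person_years": [c.person_years for c in self.cells],
            }
        )

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gender": [o.key.gender for o in self.observations],
                "age_band": [o.key.age_band for o in self.observations],
                "region": [o.key.region for o in self.observations],
                "year": [o.key.year for o in self.observations],
                "deaths_unlinked": [o.deaths_unlinked for o in self.observations],
                "cohort_count": [o.cohort_count for o in self.observations],
                "population": [o.population for o in self.observations],
            }
        )

    def cells_for(self, key: GroupKey) -> dict[str, CohortCell]:
        return {c.treatment: c for c in self.cells if c.key == key}


def _infer_categories(df: pd.DataFrame) -> Categories:
    def order(col: str) -> tuple[str, ...]:
        return tuple(dict.fromkeys(df[col].astype(str)))

    return Categories(
        genders=order("gender"),
        age_bands=order("age_band"),
        regions=order("region"),
        years=tuple(sorted(dict.fromkeys(df["year"].astype(str)))),
    )


def read_cohort_csv(
    path,
    schema: dict[str, str] | None = None,
    categories: Categories | None = None,
) -> CohortDataset:
    """Read a cohort table from CSV.

    Parameters
    ----------
    path : path-like or buffer
        CSV with one row per (group, year, treatment). Canonical headers are
        gender, age_band, region, year, treatment, deaths_linked,
        person_years; the estimation-year rows additionally carry
        deaths_unlinked, cohort_count and population (repeated on both
        treatment rows of a group; blank elsewhere).
    schema : dict, optional
        Map from canonical column names to the file's column names.
    categories : Categories, optional
        Declared levels; inferred from the file (order of appearance,
        years sorted) when omitted.
    """
    df = pd.read_csv(path, dtype={"year": str})
    if schema:
        rename = {actual: canonical for canonical, actual in schema.items()}
        df = df.rename(columns=rename)
    required = KEY_FIELDS + ("treatment",) + CELL_FIELDS
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    for col in OBS_FIELDS:
        if col not in df.columns:
            df[col] = np.nan
    if len(df) == 0:
        raise ValidationError("no records")

    if categories is None:
        categories = _infer_categories(df)

    cells: list[CohortCell] = []
    obs_rows: dict[GroupKey, tuple[int, int, int]] = {}
    for idx, row in df.iterrows():
        key = GroupKey(
            gender=str(row["gender"]),
            age_band=str(row["age_band"]),
            region=str(row["region"]),
            year=str(row["year"]),
        )
        try:
            cell = CohortCell(
                key=key,
                treatment=str(row["treatment"]),
                deaths_linked=int(row["deaths_linked"]),
                person_years=float(row["person_years"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
        cells.append(cell)
        if not pd.isna(row["deaths_unlinked"]):
            try:
                triple = (
                    int(row["deaths_unlinked"]),
                    int(row["cohort_count"]),
                    int(row["population"]),
                )
            except ValueError:
                raise ValidationError(
                    f"row {idx}: incomplete observation fields"
                ) from None
            prev = obs_rows.get(key)
            if prev is not None and prev != triple:
                raise ValidationError(
                    f"row {idx}: inconsistent observation fields for {key}"
                )
            obs_rows[key] = triple

    observations = [
        GroupObservation(key=k, deaths_unlinked=d, cohort_count=n, population=p)
        for k, (d, n, p) in obs_rows.items()
    ]
    return CohortDataset(categories=categories, cells=cells, observations=observations)


def write_cohort_csv(dataset: CohortDataset, path) -> None:
    """Write a dataset in the canonical CSV layout (round-trips with the reader)."""
    obs_by_key = {o.key: o for o in dataset.observations}
    rows = []
    for cell in dataset.cells:
        row = {
            "gender": cell.key.gender,
            "age_band": cell.key.age_band,
            "region": cell.key.region,
            "year": cell.key.year,
            "treatment": cell.treatment,
            "deaths_linked": cell.deaths_linked,
            "person_years": cell.person_years,
        }
        obs = obs_by_key.get(cell.key)
        if obs is not None:
            row.update(
                deaths_unlinked=obs.deaths_unlinked,
                cohort_count=obs.cohort_count,
                population=obs.population,
            )
        rows.append(row)
    pd.DataFrame(rows, columns=list(ALL_COLUMNS)).to_csv(path, index=False)


def load_table1() -> CohortDataset:
    """Load the packaged England 2005/06-2008/09 summary table.

    Linked/unlinked death counts, person-years and cohort headcounts are
    transcribed from the published national summary (regions collapsed to a
    single level). Population denominators are approximate round mid-year
    figures for the 15-64 population, consistent with the published national
    crude prevalence; they are stand-ins, not official ONS values.
    """
    ref = importlib.resources.files("mortprev.data") / "table1_england.csv"
    with importlib.resources.as_file(ref) as p:
        return read_cohort_csv(p)


def aggregate_counts(data: CohortDataset, year: str, field: str) -> float:
    """Sum a named field over all records of one year.

    Cell fields (deaths_linked, person_years) sum over both treatment
    states; observation fields (deaths_unlinked, cohort_count) sum over
    the year's group observations.
    """
    if year not in data.categories.years:
        raise ValueError(f"unknown year: {year!r}")
    if field in CELL_FIELDS:
        return float(
            sum(getattr(c, field) for c in data.cells if c.key.year == year)
        )
    if field in ("deaths_unlinked", "cohort_count"):
        return float(
            sum(getattr(o, field) for o in data.observations if o.key.year == year)
        )
    raise ValueError(f"unknown field: {field!r}")


def crude_rate_per_1000(deaths: int, person_years: float) -> float:
    """Crude event rate per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    return 1000.0 * deaths / person_years
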
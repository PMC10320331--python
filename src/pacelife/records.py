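"""Individual breeding records and the four dimensioned life-history traits.

A complete individual breeding history is a sequence of yearly breeding
events (age, attempted flag, number of independent offspring) plus the age
at death or last observation.  From it we compute the four traits that
carry either a time-duration dimension (age at first reproduction, adult
lifespan; years) or a time-frequency dimension (breeding frequency,
fecundity; events or offspring per year), plus the individual generation
time (offspring-weighted mean age of reproduction).

Keeping every trait in time or 1/time units is what makes the slow-fast
continuum a dimensionally coherent axis; traits in other units (mass,
clutch size) deliberately have no place here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical trait order used by every downstream stage
TRAITS = ("afr", "adult_lifespan", "breeding_frequency", "fecundity")
ALL_COLUMNS = TRAITS + ("generation_time",)

#: aggregation statistics accepted by :func:`aggregate_species`
AGG_STATISTICS = ("mean", "median", "q1", "q3")


class RecordError(ValueError):
    """A breeding record violates its invariants."""


@dataclass(frozen=True)
class BreedingEvent:
    """One breeding season in an individual's life.

    Parameters
    ----------
    age : float
        Age in years at the event; non-negative.
    attempted : bool
        Whether a breeding attempt was made that year.
    offspring : int
        Number of independent offspring produced; positive offspring
        implies an attempt.
    """

    age: float
    attempted: bool
    offspring: int

    def __post_init__(self) -> None:
        if self.age < 0:
            raise RecordError(f"event age must be >= 0, got {self.age}")
        if self.offspring < 0:
            raise RecordError(f"offspring must be >= 0, got {self.offspring}")
        if self.offspring > 0 and not self.attempted:
            raise RecordError(
                f"offspring={self.offspring} at age {self.age} without a "
                "breeding attempt"
            )


@dataclass
class IndividualRecord:
    """Complete longitudinal breeding history of one animal."""

    individual_id: str
    species: str
    events: list[BreedingEvent]
    death_age: float

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.age)
        self.validate()

    def validate(self) -> None:
        if not self.events:
            raise RecordError(
                f"{self.individual_id}: record has no breeding events"
            )
        if not any(e.attempted for e in self.events):
            raise RecordError(
                f"{self.individual_id}: no breeding attempt in record; "
                "only individuals with complete breeding histories are kept"
            )
        if any(e.age > self.death_age for e in self.events):
            raise RecordError(
                f"{self.individual_id}: event age exceeds death age "
                f"{self.death_age}"
            )


@dataclass(frozen=True)
class LifeHistoryTraits:
    """The four dimensioned traits plus individual generation time.

    ``generation_time`` is None for individuals that attempted breeding
    but never produced an independent offspring (the offspring-weighted
    mean age is then undefined).
    """

    afr: float
    adult_lifespan: float
    breeding_frequency: float
    fecundity: float
    generation_time: float | None

    def as_dict(self) -> dict[str, float]:
        d = {
            "afr": self.afr,
            "adult_lifespan": self.adult_lifespan,
            "breeding_frequency": self.breeding_frequency,
            "fecundity": self.fecundity,
            "generation_time": (
                math.nan if self.generation_time is None else self.generation_time
            ),
        }
        return d


def compute_traits(record: IndividualRecord) -> LifeHistoryTraits:
    """Compute the four life-history traits and generation time.

    Definitions
    -----------
    - afr: age of the first breeding attempt (successful or not).
    - adult_lifespan: death_age - afr, i.e. reproductive lifespan.
    - breeding_frequency: attempts per year of adult life.
    - fecundity: independent offspring per year of adult life.
    - generation_time: sum(age * offspring) / sum(offspring).

    Rates for individuals that die within their first breeding season
    (adult lifespan 0) use a floor of one year in the denominator so that
    annual breeders keep finite annual rates.
    """
    record.validate()
    attempts = [e for e in record.events if e.attempted]
    afr = attempts[0].age
    lifespan = record.death_age - afr
    if lifespan < 0:
        raise RecordError(
            f"{record.individual_id}: death age {record.death_age} before "
            f"first reproduction at {afr}"
        )
    denom = max(lifespan, 1.0)
    n_attempts = len(attempts)
    total_offspring = sum(e.offspring for e in record.events)
    if total_offspring > 0:
        gen_time = (
            sum(e.age * e.offspring for e in record.events) / total_offspring
        )
    else:
        gen_time = None
    return LifeHistoryTraits(
        afr=afr,
        adult_lifespan=lifespan,
        breeding_frequency=n_attempts / denom,
        fecundity=total_offspring / denom,
        generation_time=gen_time,
    )


def traits_table(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    """Per-individual trait table (one row per individual).

    Index: individual_id; columns: species plus the five trait columns.
    """
    rows = []
    index = []
    for rec in records:
        t = compute_traits(rec)
        rows.append({"species": rec.species, **t.as_dict()})
        index.append(rec.individual_id)
    if not rows:
        raise RecordError("no records supplied")
    return pd.DataFrame(rows, index=pd.Index(index, name="individual_id"))


def _quantile(values: np.ndarray, q: float) -> float:
    # linear interpolation between order statistics (numpy default)
    return float(np.quantile(values, q, method="linear"))


def aggregate_species(
    individual_traits: pd.DataFrame, statistic: str = "mean"
) -> pd.DataFrame:
    """Aggregate per-individual traits to one row per species.

    Parameters
    ----------
    individual_traits : DataFrame
        Output of :func:`traits_table`.
    statistic : {"mean", "median", "q1", "q3"}
        Aggregation statistic; quartiles use linear interpolation between
        order statistics.

    Individuals with undefined generation time (zero lifetime offspring)
    are excluded from the generation-time aggregate only.
    """
    if statistic not in AGG_STATISTICS:
        raise ValueError(
            f"statistic must be one of {AGG_STATISTICS}, got {statistic!r}"
        )
    if individual_traits.empty:
        raise RecordError("empty individual trait table")

    def agg(values: pd.Series) -> float:
        v = values.dropna().to_numpy(dtype=float)
        if v.size == 0:
            return math.nan
        if statistic == "mean":
            return float(np.mean(v))
        if statistic == "median":
            return _quantile(v, 0.5)
        if statistic == "q1":
            return _quantile(v, 0.25)
        return _quantile(v, 0.75)

    grouped = individual_traits.groupby("species")
    table = grouped[list(ALL_COLUMNS)].agg(agg)
    table["n_individuals"] = grouped.size()
    table.attrs["aggregation_statistic"] = statistic
    return table


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation: sd (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"CV needs n >= 2, got n = {v.size}")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# delimited-text ingest / export

_REQUIRED_COLUMNS = (
    "individual_id",
    "species",
    "age",
    "attempted",
    "offspring",
    "death_age",
)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def _parse_bool(token: str, line: int) -> bool:
    s = token.strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise RecordError(f"line {line}: cannot parse {token!r} as boolean")


def read_records_csv(source, sep: str = ",") -> list[IndividualRecord]:
    """Read breeding-event rows and assemble individual records.

    Expected columns: individual_id, species, age, attempted, offspring,
    death_age -- one row per breeding season, death_age repeated on every
    row of an individual.  Errors cite 1-based data line numbers.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordError(f"missing required columns: {', '.join(missing)}")

    per_individual: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        line = i
        try:
            age = float(row.age)
            offspring = int(float(row.offspring))
            death_age = float(row.death_age)
        except (TypeError, ValueError) as exc:
            raise RecordError(f"line {line}: non-numeric field ({exc})") from None
        attempted = _parse_bool(str(row.attempted), line)
        try:
            event = BreedingEvent(age=age, attempted=attempted, offspring=offspring)
        except RecordError as exc:
            raise RecordError(f"line {line}: {exc}") from None
        key = str(row.individual_id)
        slot = per_individual.setdefault(
            key,
            {"species": str(row.species), "events": [], "death_age": death_age},
        )
        if slot["species"] != str(row.species):
            raise RecordError(
                f"line {line}: individual {key!r} assigned to two species"
            )
        if slot["death_age"] != death_age:
            raise RecordError(
                f"line {line}: inconsistent death_age for individual {key!r}"
            )
        slot["events"].append(event)

    records = []
    for key, slot in per_individual.items():
        records.append(
            IndividualRecord(
                individual_id=key,
                species=slot["species"],
                events=slot["events"],
                death_age=slot["death_age"],
            )
        )
    if not records:
        raise RecordError("no data rows in input")
    return records


def write_table_csv(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a trait table as CSV with '#'-prefixed metadata header lines."""
    buf = io.StringIO()
    meta = dict(metadata or {})
    meta.update(
        {k: v for k, v in table.attrs.items() if isinstance(v, (str, int, float))}
    )
    for k, v in sorted(meta.items()):
        buf.write(f"# {k}: {v}\n")
    table.to_csv(buf)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
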
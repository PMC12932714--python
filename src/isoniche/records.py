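"""Individual-level stable isotope records: data model, CSV I/O, validation.

A record is one organism's raw δ¹³C (vs VPDB) and δ¹⁵N (vs atmospheric N₂)
in per mil, tagged with a group label (typically species or functional
group), a trophic guild, and the sampling year.  Records whose guild is
``baseline`` anchor the nitrogen standardization and are never fitted as
niche units themselves; every other (group, year) combination is one
candidate ellipse fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DatasetValidationError, SchemaError

GUILDS = ("predator", "omnivore", "detritivore", "baseline")

COLUMNS = ("record_id", "group", "guild", "year", "d13C", "d15N")


@dataclass(frozen=True)
class IsotopeRecord:
    """One individual's raw isotope values with its group/guild/year labels."""

    record_id: str
    group: str
    guild: str
    year: int
    d13C: float
    d15N: float

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise DatasetValidationError(
                f"unknown guild {self.guild!r}; allowed guilds: {', '.join(GUILDS)}"
            )
        if not (isinstance(self.year, (int, np.integer)) and self.year > 0):
            raise DatasetValidationError(
                f"year must be a positive integer, got {self.year!r}"
            )
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DatasetValidationError(f"{name} must be finite, got {v!r}")


@dataclass
class Dataset:
    """An ordered collection of records with a free-text provenance tag."""

    records: list[IsotopeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise DatasetValidationError(
                    f"duplicated record_id {rec.record_id!r}"
                )
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    def consumer_records(self, year: int | None = None) -> list[IsotopeRecord]:
        return [
            r
            for r in self.records
            if r.guild != "baseline" and (year is None or r.year == year)
        ]

    def baseline_records(self, year: int | None = None) -> list[IsotopeRecord]:
        return [
            r
            for r in self.records
            if r.guild == "baseline" and (year is None or r.year == year)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.record_id, r.group, r.guild, r.year, r.d13C, r.d15N)
                for r in self.records
            ],
            columns=list(COLUMNS),
        )


def read_dataset(
    path,
    delimiter: str = ",",
    decimal_mark: str = ".",
    provenance: str | None = None,
) -> Dataset:
    """Read a dataset from delimited text.

    The header must name the six columns ``record_id, group, guild, year,
    d13C, d15N``.  ``decimal_mark=","`` accepts decimal-comma files.  Rows
    failing validation are rejected with a message naming the offending
    (1-based data) row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; header must contain {list(COLUMNS)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            year = int(getattr(row, "year"))
        except ValueError as exc:
            raise DatasetValidationError(
                f"row {i}: non-integer year {getattr(row, 'year')!r}"
            ) from exc
        values = {}
        for col in ("d13C", "d15N"):
            raw = getattr(row, col)
            if decimal_mark != ".":
                raw = raw.replace(decimal_mark, ".")
            try:
                values[col] = float(raw)
            except ValueError as exc:
                raise DatasetValidationError(
                    f"row {i}: non-numeric {col} value {getattr(row, col)!r}"
                ) from exc
        try:
            records.append(
                IsotopeRecord(
                    record_id=str(getattr(row, "record_id")),
                    group=str(getattr(row, "group")),
                    guild=str(getattr(row, "guild")),
                    year=year,
                    d13C=values["d13C"],
                    d15N=values["d15N"],
                )
            )
        except DatasetValidationError as exc:
            raise DatasetValidationError(f"row {i}: {exc}") from exc
    return Dataset(records=records, provenance=provenance or str(path))


def write_dataset(dataset: Dataset, path, delimiter: str = ",") -> None:
    """Write a dataset as delimited text; round-trips numeric fields exactly.

    Floats are written with the shortest representation that reparses to the
    same IEEE double, so ``read_dataset(write_dataset(d))`` reproduces every
    numeric field bit-for-bit.
    """
    dataset.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass
class FitUnit:
    """Points of one non-baseline (group, year) pair, the unit of ellipse fitting."""

    group: str
    year: int
    record_ids: list[str]
    points: np.ndarray  # (n, 2) columns d13C, d15N (or standardized equivalents)
    insufficient_n: bool = False

    @property
    def n(self) -> int:
        return self.points.shape[0]


def fit_units(
    dataset: Dataset, min_n: int = 3, warn_n: int = 10
) -> list[FitUnit]:
    """Partition the non-baseline records into per-(group, year) fit units.

    Units with fewer than ``min_n`` points are flagged ``insufficient_n``
    (SEAc's n−2 denominator needs n ≥ 3), never silently dropped; units below
    ``warn_n`` emit a small-sample warning.
    """
    grouped: dict[tuple[str, int], list[IsotopeRecord]] = {}
    for rec in dataset.consumer_records():
        grouped.setdefault((rec.group, rec.year), []).append(rec)
    units = []
    for (group, year) in sorted(grouped):
        recs = grouped[(group, year)]
        pts = np.array([(r.d13C, r.d15N) for r in recs], dtype=float)
        unit = FitUnit(
            group=group,
            year=year,
            record_ids=[r.record_id for r in recs],
            points=pts,
            insufficient_n=len(recs) < min_n,
        )
        if min_n <= unit.n < warn_n:
            warnings.warn(
                f"fit unit ({group}, {year}) has only n={unit.n} records; "
                f"ellipse estimates will be imprecise",
                stacklevel=2,
            )
        units.append(unit)
    return units
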
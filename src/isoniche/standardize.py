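"""Baseline standardization of raw δ values into the fitting space.

Two per-year corrections put all consumers on a common, ecologically
interpretable scale before any ellipse is fitted:

* carbon is centred on the consumer community and scaled by its spread,

  ``d13C_cor = (d13C_i − mean(d13C_cons)) / range(d13C_cons)``,

  so that within each year the consumer d13C_cor values have mean 0 and
  max − min = 1 (a dimensionless resource-use axis);

* nitrogen is converted to trophic position using the mean δ¹⁵N of the
  baseline guild (primary consumers, anchored at trophic position 2) and a
  trophic discrimination factor (TDF, per mil of ¹⁵N enrichment per step),

  ``d15N_cor = (d15N_i − mean(d15N_baseline)) / TDF + 2``.

The study's TDF is 3.23 ‰ per trophic step.  Constants are computed per
year by default; a pooled-baseline option averages the baseline guild over
all years instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateStandardizationError, MissingBaselineError
from .records import Dataset

DEFAULT_TDF = 3.23
BASELINE_TROPHIC_POSITION = 2.0


@dataclass(frozen=True)
class YearStandardization:
    """Per-year constants entering both correction formulas."""

    year: int
    mean_d13C_consumers: float
    range_d13C_consumers: float
    baseline_mean_d15N: float
    tdf: float = DEFAULT_TDF

    def __post_init__(self) -> None:
        if not self.range_d13C_consumers > 0:
            raise DegenerateStandardizationError(
                f"year {self.year}: consumer d13C range must be > 0, "
                f"got {self.range_d13C_consumers!r}"
            )
        if not self.tdf > 0:
            raise ValueError(f"tdf must be > 0, got {self.tdf!r}")


def compute_year_constants(
    dataset: Dataset,
    year: int,
    tdf: float = DEFAULT_TDF,
    pooled_baseline: bool = False,
) -> YearStandardization:
    """Compute one year's standardization constants from a dataset.

    The carbon mean and range pool all non-baseline individuals of that
    year across groups; the nitrogen baseline averages the baseline-guild
    individuals of that year (or of all years if ``pooled_baseline``).
    """
    consumers = dataset.consumer_records(year)
    if len(consumers) < 2:
        raise DegenerateStandardizationError(
            f"year {year}: need >= 2 consumer records to define a d13C range"
        )
    baseline = dataset.baseline_records(None if pooled_baseline else year)
    if not baseline:
        raise MissingBaselineError(
            f"year {year}: no baseline-guild records for nitrogen standardization"
        )
    d13c = np.array([r.d13C for r in consumers])
    return YearStandardization(
        year=year,
        mean_d13C_consumers=float(d13c.mean()),
        range_d13C_consumers=float(d13c.max() - d13c.min()),
        baseline_mean_d15N=float(np.mean([r.d15N for r in baseline])),
        tdf=tdf,
    )


def standardize_carbon(d13C_i, constants: YearStandardization):
    """Range-scaled carbon: (d13C_i − mean) / range.  Accepts scalars or arrays."""
    return (np.asarray(d13C_i, dtype=float) - constants.mean_d13C_consumers) / (
        constants.range_d13C_consumers
    )


def standardize_nitrogen(
    d15N_i,
    constants: YearStandardization,
    baseline_tp: float = BASELINE_TROPHIC_POSITION,
):
    """Trophic position: (d15N_i − baseline mean) / TDF + baseline position."""
    return (
        np.asarray(d15N_i, dtype=float) - constants.baseline_mean_d15N
    ) / constants.tdf + baseline_tp


def standardize_dataset(
    dataset: Dataset,
    tdf: float = DEFAULT_TDF,
    pooled_baseline: bool = False,
    baseline_tp: float = BASELINE_TROPHIC_POSITION,
) -> pd.DataFrame:
    """Standardize every non-baseline record with its own year's constants.

    Returns a DataFrame with columns ``record_id, group, guild, year,
    d13C_cor, d15N_cor``; baseline records are consumed by the constants and
    excluded from the output.  Errors from constant computation are
    annotated with the year they arose in.
    """
    rows = []
    for year in dataset.years():
        consumers = dataset.consumer_records(year)
        if not consumers:
            continue
        try:
            const = compute_year_constants(
                dataset, year, tdf=tdf, pooled_baseline=pooled_baseline
            )
        except (DegenerateStandardizationError, MissingBaselineError) as exc:
            raise type(exc)(f"standardization failed for year {year}: {exc}") from exc
        c = standardize_carbon([r.d13C for r in consumers], const)
        n = standardize_nitrogen([r.d15N for r in consumers], const, baseline_tp)
        for rec, cc, nn in zip(consumers, c, n):
            rows.append((rec.record_id, rec.group, rec.guild, rec.year, cc, nn))
    return pd.DataFrame(
        rows, columns=["record_id", "group", "guild", "year", "d13C_cor", "d15N_cor"]
    )
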
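"""Per-fraction dose/volume records and percent-deviation series.

A fractionated radiotherapy course delivers the planned dose over ``F`` daily
fractions (30 by default, 2 Gy each).  For every fraction the anatomy-of-the-day
yields recalculated volumetric and dosimetric summaries which are compared with
the planning-CT baseline.  This module holds the tidy data model every
downstream stage consumes: one :class:`FractionRecord` per
(patient, fraction, parameter), percent deviations from plan, and ordered
per-patient :class:`DeviationSeries`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of monitored parameters.  Volumes are in cm^3, doses in Gy.
VOLUME_PARAMETERS = (
    "GTV",
    "CTV",
    "PTV",
    "Lung",
    "Esophagus",
    "Heart",
    "SpinalCord",
)
DOSE_PARAMETERS = (
    "GTV_D95",
    "CTV_D95",
    "PTV_D95",
    "Lung_Dmean",
    "Esophagus_Dmean",
    "Heart_Dmean",
    "SpinalCord_Dmax",
)
PARAMETERS = VOLUME_PARAMETERS + DOSE_PARAMETERS

#: D95 parameters of the three target volumes (candidate representative measures).
TARGET_D95_PARAMETERS = ("GTV_D95", "CTV_D95", "PTV_D95")
#: OAR dose parameters paired with the representative target measure for clustering.
OAR_DOSE_PARAMETERS = ("Lung_Dmean", "Esophagus_Dmean", "Heart_Dmean", "SpinalCord_Dmax")

CSV_COLUMNS = ("patient_id", "fraction", "parameter", "value", "planned_value")


def percent_deviation(value: float, planned_value: float) -> float:
    """Percentage change of a per-fraction value from its planned baseline.

    Returns ``100 * (value - planned_value) / planned_value``; the result is in
    percent units (-9.79 means -9.79 %).

    Raises
    ------
    ValueError
        If ``planned_value`` is zero (relative change undefined).
    """
    if planned_value == 0:
        raise ValueError("planned_value must be non-zero: relative change undefined")
    return 100.0 * (value - planned_value) / planned_value


@dataclass(frozen=True)
class FractionRecord:
    """One (patient, fraction, parameter) measurement with its planned baseline."""

    patient_id: str
    fraction: int
    parameter: str
    value: float
    planned_value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction", int(self.fraction))
        object.__setattr__(self, "value", float(self.value))
        object.__setattr__(self, "planned_value", float(self.planned_value))
        if self.fraction < 1:
            raise ValueError(f"fraction must be >= 1, got {self.fraction}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not self.planned_value > 0:
            raise ValueError(
                f"planned_value must be > 0, got {self.planned_value!r} "
                f"({self.patient_id}, fraction {self.fraction}, {self.parameter})"
            )

    @property
    def deviation(self) -> float:
        """Percent deviation of this record from plan."""
        return percent_deviation(self.value, self.planned_value)


@dataclass
class DeviationSeries:
    """One patient's ordered per-fraction percent deviations for one parameter.

    ``deviations`` has length ``F`` (fraction ``f`` at index ``f - 1``);
    ``mask`` is True where the fraction is present.  Absent fractions hold NaN.
    """

    patient_id: str
    parameter: str
    deviations: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.deviations = np.asarray(self.deviations, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.deviations)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.deviations.shape:
            raise ValueError("mask and deviations must have the same length")
        if not np.all(np.isfinite(self.deviations[self.mask])):
            raise ValueError("present entries must be finite")

    @property
    def n_fractions(self) -> int:
        return len(self.deviations)

    def present(self) -> tuple[np.ndarray, np.ndarray]:
        """(1-based fraction numbers, deviations) at present fractions."""
        fractions = np.flatnonzero(self.mask) + 1
        return fractions, self.deviations[self.mask]


@dataclass
class BivariateSeries:
    """Paired 2-D deviation series (target D95, OAR dose) on one fraction axis."""

    patient_id: str
    parameter_pair: tuple[str, str]
    values: np.ndarray  # F x 2, percent deviations
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be an F x 2 array")
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.values), axis=1)
        self.mask = np.asarray(self.mask, dtype=bool)

    def present(self) -> np.ndarray:
        return self.values[self.mask]


def pair_series(target: DeviationSeries, oar: DeviationSeries) -> BivariateSeries:
    """Combine a target-D95 and an OAR-dose series of one patient into a 2-D series.

    The shared mask is the intersection of the two univariate masks.
    """
    if target.patient_id != oar.patient_id:
        raise ValueError("series belong to different patients")
    if target.n_fractions != oar.n_fractions:
        raise ValueError("series have different fraction axes")
    mask = target.mask & oar.mask
    values = np.column_stack([target.deviations, oar.deviations])
    return BivariateSeries(target.patient_id, (target.parameter, oar.parameter), values, mask)


def build_series(
    records: Iterable[FractionRecord], n_fractions: int = 30
) -> dict[tuple[str, str], DeviationSeries]:
    """Assemble percent-deviation series, one per (patient, parameter).

    Deviations are placed at their 1-based fraction index; absent fractions are
    masked (NaN).  Duplicate (patient, fraction, parameter) keys are an error.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    table: dict[tuple[str, str], np.ndarray] = {}
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        key = (rec.patient_id, rec.fraction, rec.parameter)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
        if rec.fraction > n_fractions:
            raise ValueError(
                f"fraction {rec.fraction} exceeds n_fractions={n_fractions} for {key}"
            )
        sk = (rec.patient_id, rec.parameter)
        if sk not in table:
            table[sk] = np.full(n_fractions, np.nan)
        table[sk][rec.fraction - 1] = rec.deviation
    return {
        (pid, param): DeviationSeries(pid, param, devs)
        for (pid, param), devs in table.items()
    }


def records_to_frame(records: Iterable[FractionRecord]) -> pd.DataFrame:
    """Tidy DataFrame view (one row per record, CSV column order)."""
    return pd.DataFrame(
        [
            (r.patient_id, r.fraction, r.parameter, r.value, r.planned_value)
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )


def write_records(records: Sequence[FractionRecord], path) -> None:
    """Write records as RFC-4180 CSV with the canonical header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.patient_id, r.fraction, r.parameter, repr(r.value), repr(r.planned_value)]
            )


def read_records(path) -> list[FractionRecord]:
    """Read per-fraction records from CSV, validating every row.

    Raises ``ValueError`` naming the offending row (1-based, header = row 1)
    for unknown parameters, non-positive planned values or malformed fields.
    """
    out: list[FractionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(CSV_COLUMNS):
            raise ValueError(
                f"expected header {','.join(CSV_COLUMNS)}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_COLUMNS):
                raise ValueError(f"row {lineno}: expected {len(CSV_COLUMNS)} fields, got {len(row)}")
            pid, frac_s, param, value_s, planned_s = row
            try:
                record = FractionRecord(pid, int(frac_s), param, float(value_s), float(planned_s))
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
            out.append(record)
    return out


def series_by_parameter(
    series: Mapping[tuple[str, str], DeviationSeries], parameter: str
) -> dict[str, DeviationSeries]:
    """All patients' series for one parameter, keyed by patient id."""
    return {pid: s for (pid, param), s in series.items() if param == parameter}
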
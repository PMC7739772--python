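"""Cohort data model, CSV I/O and allometric body-mass normalization.

The single tabular currency of the pipeline is the :class:`CohortTable`:
one row per sprinter with age, height, body mass, the 100-m season-best
time, and three deep-trunk-muscle size measurements — psoas major
cross-sectional area (cm², left+right sum at L4–L5), transversus
abdominis thickness (mm) and multifidus thickness (cm).  Units are fixed
as named in the column headers; nothing in the pipeline converts units
implicitly (the study's mixed-unit reporting — mm, cm, cm² — is kept
as-is).

Linear muscle dimensions are removed of body-size scaling by dividing by
body mass to the power 1/3 (geometric similarity: a length scales with
the cube root of mass), giving values in e.g. mm/kg^(1/3).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "ParticipantRecord",
    "CohortTable",
    "NormalizedSeries",
    "read_cohort",
    "write_cohort",
    "allometric_normalize",
    "NUMERIC_FIELDS",
    "CANONICAL_COLUMNS",
]

#: numeric per-participant fields, in canonical column order
NUMERIC_FIELDS: tuple[str, ...] = (
    "age_years",
    "height_cm",
    "body_mass_kg",
    "sprint_time_s",
    "pm_csa_cm2",
    "ta_thickness_mm",
    "mm_thickness_cm",
)

CANONICAL_COLUMNS: tuple[str, ...] = ("id",) + NUMERIC_FIELDS

#: source unit of each muscle-size field, used for normalized unit tags
FIELD_UNITS: dict[str, str] = {
    "pm_csa_cm2": "cm2",
    "ta_thickness_mm": "mm",
    "mm_thickness_cm": "cm",
    "height_cm": "cm",
    "sprint_time_s": "s",
    "body_mass_kg": "kg",
    "age_years": "years",
}

#: minimum cohort size for any downstream model fitting
MIN_COHORT_SIZE = 5


@dataclass(frozen=True)
class ParticipantRecord:
    """One sprinter's anthropometrics and outcome, in fixed units."""

    id: str
    age_years: float
    height_cm: float
    body_mass_kg: float
    sprint_time_s: float
    pm_csa_cm2: float
    ta_thickness_mm: float
    mm_thickness_cm: float

    def __post_init__(self) -> None:
        for f in NUMERIC_FIELDS:
            v = getattr(self, f)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValidationError(
                    f"participant {self.id!r}: field {f!r} is not numeric ({v!r})"
                )
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"participant {self.id!r}: field {f!r} must be strictly "
                    f"positive and finite, got {v!r}"
                )


@dataclass(frozen=True)
class CohortTable:
    """Ordered, validated collection of participants.

    ``provenance`` is a free-text tag (file path or generator seed string)
    carried into reports.
    """

    records: tuple[ParticipantRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate participant ids: {dupes}")
        if len(self.records) < MIN_COHORT_SIZE:
            raise ValidationError(
                f"cohort has n={len(self.records)} participants; "
                f"n >= {MIN_COHORT_SIZE} is required for model fitting"
            )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def column(self, name: str) -> np.ndarray:
        """Return one numeric field as a float array (row order preserved)."""
        if name not in NUMERIC_FIELDS:
            raise ConfigurationError(
                f"unknown cohort field {name!r}; expected one of {NUMERIC_FIELDS}"
            )
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: [getattr(r, c) for r in self.records] for c in CANONICAL_COLUMNS}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CohortTable":
        records = []
        for pos, row in enumerate(df.itertuples(index=False)):
            raw = dict(zip(df.columns, row))
            rid = str(raw["id"])
            vals = {}
            for f in NUMERIC_FIELDS:
                try:
                    vals[f] = float(raw[f])
                except (TypeError, ValueError) as exc:
                    raise ValidationError(
                        f"row {pos + 1} (id {rid!r}): cell {f!r}={raw[f]!r} "
                        f"is not numeric"
                    ) from exc
            try:
                records.append(ParticipantRecord(id=rid, **vals))
            except ValidationError as exc:
                raise ValidationError(f"row {pos + 1}: {exc}") from exc
        return cls(records=tuple(records), provenance=provenance)


@dataclass(frozen=True)
class NormalizedSeries:
    """A muscle-size series divided by body mass^(1/3).

    ``values[i] * mass[i]**(1/3)`` reproduces the raw input to within
    1e-12 relative tolerance; the exponent is fixed at 1/3.
    """

    values: np.ndarray
    source_unit: str
    exponent: float = field(default=1.0 / 3.0)

    @property
    def unit(self) -> str:
        return f"{self.source_unit}/kg^(1/3)"


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> CohortTable:
    """Read a cohort CSV with canonical headers into a validated table.

    Parameters
    ----------
    path
        CSV file with a header row.  Canonical headers are
        ``id, age_years, height_cm, body_mass_kg, sprint_time_s,
        pm_csa_cm2, ta_thickness_mm, mm_thickness_cm``.
    column_map
        Optional ``{alias: canonical_name}`` renaming applied before
        validation, e.g. ``{"weight": "body_mass_kg"}``.  Dialect
        variation is handled here, never by sniffing.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"cohort file {path} is missing required column(s): {missing}"
        )
    df["id"] = df["id"].astype(str)
    return CohortTable.from_dataframe(df[list(CANONICAL_COLUMNS)], provenance=str(path))


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort to CSV with canonical headers.

    Numbers are serialized with shortest round-tripping precision so that
    ``read_cohort(write_cohort(c)) == c`` exactly, and identical cohorts
    produce byte-identical files.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(",".join(CANONICAL_COLUMNS) + "\n")
    for r in cohort.records:
        cells = [r.id] + [repr(getattr(r, f)) for f in NUMERIC_FIELDS]
        buf.write(",".join(cells) + "\n")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write cohort CSV to {path}: {exc}") from exc
    return path


def allometric_normalize(
    values: Sequence[float] | np.ndarray,
    masses: Sequence[float] | np.ndarray,
    source_unit: str = "mm",
) -> NormalizedSeries:
    """Divide each value by the matching body mass to the power 1/3.

    The exponent 1/3 removes geometric body-size scaling from a linear
    dimension (a length scales with the cube root of mass under
    isometry); an area (cm²) divided the same way is reported in
    cm²/kg^(1/3) for consistency with the thickness series.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.shape != m.shape or v.ndim != 1:
        raise ValidationError(
            f"values and masses must be equal-length 1-D series, "
            f"got shapes {v.shape} and {m.shape}"
        )
    if not np.all(np.isfinite(v)) or not np.all(np.isfinite(m)):
        raise ValidationError("values and masses must be finite")
    if np.any(v <= 0):
        raise ValidationError("all values must be strictly positive")
    if np.any(m <= 0):
        raise ValidationError("all body masses must be strictly positive")
    return NormalizedSeries(values=v / np.cbrt(m), source_unit=source_unit)
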
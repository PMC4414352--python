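"""Sample data model, CSV ingestion, tooth-cohort mapping and descriptive statistics.

A measured specimen is a human tooth, a faunal tooth (pig or dog), or a
sediment leachate. Each carries up to four heavy-isotope ratios
(87Sr/86Sr and the three Pb/204Pb ratios) plus a strontium concentration.
Teeth are grouped into three mineralization cohorts that time-resolve
early life: C1 (first molars and incisors, ~0-3 y), C2 (second molars,
premolars, canines, ~3-7 y) and C3 (third molars, ~8-16 y).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("isoprov")

KINDS = ("human", "fauna", "sediment")
SEXES = ("male", "female", "unknown")
COHORTS = ("C1", "C2", "C3")

#: default tooth-type -> mineralization-cohort mapping
COHORT_MAP: dict[str, str] = {
    "M1": "C1",
    "I1": "C1",
    "M2": "C2",
    "P3": "C2",
    "P4": "C2",
    "C": "C2",
    "M3": "C3",
}

#: approximate enamel mineralization windows per cohort, years of age
COHORT_WINDOWS: dict[str, tuple[float, float]] = {
    "C1": (0.0, 3.0),
    "C2": (3.0, 7.0),
    "C3": (8.0, 16.0),
}

ISOTOPE_FIELDS = ("sr87_86", "pb206_204", "pb207_204", "pb208_204")

#: plausible 87Sr/86Sr window for the study region; values outside are
#: almost certainly transcription or analytical blunders
SR_PLAUSIBLE = (0.70, 0.74)

CSV_COLUMNS = (
    "sample_id", "site", "kind", "taxon", "tooth_type", "cohort_override",
    "sex", "individual_id", "sr87_86", "pb206_204", "pb207_204",
    "pb208_204", "sr_ppm",
)


class ValidationError(ValueError):
    """A structurally invalid sample or sample table."""


class ParseError(ValueError):
    """A malformed cell in an input table; names the offending row/column."""


@dataclass(frozen=True)
class IsotopeSample:
    """One measured specimen with its isotope ratios and Sr concentration.

    ``individual_id`` groups teeth belonging to the same burial; it
    defaults to ``sample_id`` when a burial identifier is not supplied.
    Missing measurements are ``None``, never zero.
    """

    sample_id: str
    site: str
    kind: str
    taxon: str | None = None
    tooth_type: str | None = None
    cohort: str | None = None
    sex: str | None = None
    individual_id: str | None = None
    sr87_86: float | None = None
    pb206_204: float | None = None
    pb207_204: float | None = None
    pb208_204: float | None = None
    sr_ppm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"{self.sample_id}: unknown kind {self.kind!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.cohort is not None and self.cohort not in COHORTS:
            raise ValidationError(f"{self.sample_id}: unknown cohort {self.cohort!r}")
        for name in ISOTOPE_FIELDS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(
                    f"{self.sample_id}: {name} must be strictly positive, got {v}"
                )
        if self.sr87_86 is not None and not (
            SR_PLAUSIBLE[0] < self.sr87_86 < SR_PLAUSIBLE[1]
        ):
            raise ValidationError(
                f"{self.sample_id}: sr87_86={self.sr87_86} outside plausible "
                f"window {SR_PLAUSIBLE}"
            )
        if self.sr_ppm is not None and self.sr_ppm <= 0:
            raise ValidationError(f"{self.sample_id}: sr_ppm must be > 0")
        if self.kind == "sediment" and any(
            getattr(self, f) is not None for f in ("tooth_type", "cohort", "sex")
        ):
            raise ValidationError(
                f"{self.sample_id}: sediment samples carry no tooth/cohort/sex"
            )
        if self.individual_id is None:
            object.__setattr__(self, "individual_id", self.sample_id)


def assign_cohort(tooth_type: str, override: str | None = None) -> str:
    """Map a tooth-type code to its mineralization cohort.

    First molars and incisors fall in C1; second molars, premolars and
    canines in C2 (canine crowns finish forming around 5-6 y); third
    molars in C3. An explicit override always wins.
    """
    if override is not None:
        if override not in COHORTS:
            raise ValidationError(f"unknown cohort override {override!r}")
        return override
    try:
        return COHORT_MAP[tooth_type]
    except KeyError:
        raise ValidationError(
            f"unrecognized tooth type {tooth_type!r}; supply an explicit cohort"
        ) from None


def _parse_cell(raw: str, row: int, column: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        v = float(raw)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None
    if math.isnan(v):
        return None
    return v


def read_samples(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[IsotopeSample]:
    """Read a validated sample table from CSV.

    ``schema`` maps CSV column names to canonical field names, for
    tables transcribed with non-default headers; identity by default.
    Empty cells become ``None``. Raises :class:`ParseError` for a
    malformed numeric cell (naming row and column) and
    :class:`ValidationError` for duplicated ``sample_id``/``tooth_type``
    pairs or invalid field values.
    """
    path = Path(path)
    schema = dict(schema or {})
    samples: list[IsotopeSample] = []
    seen: set[tuple[str, str | None]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: missing header row")
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            rec: dict[str, str] = {}
            for col, raw in row.items():
                rec[schema.get(col, col)] = raw if raw is not None else ""
            kwargs: dict = {}
            for name in ("sample_id", "site", "kind", "taxon", "tooth_type",
                         "sex", "individual_id"):
                v = rec.get(name, "").strip()
                kwargs[name] = v or None
            for name in ("sr87_86", "pb206_204", "pb207_204", "pb208_204",
                         "sr_ppm"):
                kwargs[name] = _parse_cell(rec.get(name, ""), i, name)
            if kwargs["sample_id"] is None or kwargs["site"] is None:
                raise ValidationError(f"row {i}: sample_id and site are required")
            override = rec.get("cohort_override", "").strip() or None
            if kwargs["kind"] != "sediment" and kwargs["tooth_type"] is not None:
                kwargs["cohort"] = assign_cohort(kwargs["tooth_type"], override)
            elif override is not None:
                kwargs["cohort"] = assign_cohort("", override)
            key = (kwargs["sample_id"], kwargs["tooth_type"])
            if key in seen:
                raise ValidationError(
                    f"row {i}: duplicate sample_id/tooth_type {key}"
                )
            seen.add(key)
            samples.append(IsotopeSample(**kwargs))
    return propagate_sex(samples)


def propagate_sex(samples: Sequence[IsotopeSample]) -> list[IsotopeSample]:
    """Propagate sex, determined at the burial level, to every tooth of
    the burial. Conflicting determinations for one individual raise."""
    by_ind: dict[str, str] = {}
    for s in samples:
        if s.sex is not None and s.sex != "unknown":
            prev = by_ind.get(s.individual_id)
            if prev is not None and prev != s.sex:
                raise ValidationError(
                    f"conflicting sex for individual {s.individual_id}: "
                    f"{prev} vs {s.sex}"
                )
            by_ind[s.individual_id] = s.sex
    out = []
    for s in samples:
        sex = by_ind.get(s.individual_id)
        if sex is not None and s.sex != sex:
            s = replace(s, sex=sex)
        out.append(s)
    return out


def write_samples(samples: Iterable[IsotopeSample], path: str | Path) -> None:
    """Write samples to CSV in the canonical column order (round-trips
    with :func:`read_samples`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in samples:
            writer.writerow([
                s.sample_id, s.site, s.kind, s.taxon or "", s.tooth_type or "",
                "", s.sex or "", s.individual_id or "",
                *(("" if getattr(s, f) is None else repr(getattr(s, f)))
                  for f in ("sr87_86", "pb206_204", "pb207_204", "pb208_204",
                            "sr_ppm")),
            ])


def validation_report(samples: Sequence[IsotopeSample]) -> dict:
    """Counts by site, kind and cohort, for a machine-readable ingest log."""
    report: dict = {"n": len(samples), "by_site": {}, "by_kind": {}, "by_cohort": {}}
    for s in samples:
        report["by_site"][s.site] = report["by_site"].get(s.site, 0) + 1
        report["by_kind"][s.kind] = report["by_kind"].get(s.kind, 0) + 1
        if s.cohort:
            report["by_cohort"][s.cohort] = report["by_cohort"].get(s.cohort, 0) + 1
    return report


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD (n-1 denominator), range and count."""

    mean: float
    sd: float
    min: float
    max: float
    n: int


def descriptive_stats(values: Sequence[float]) -> SummaryStats:
    """Descriptive statistics with the sample (n-1) standard deviation.

    A single value yields sd = 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("descriptive_stats requires at least one value")
    if np.isnan(arr).any():
        raise ValidationError("descriptive_stats: input contains missing values")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        mean=float(np.mean(arr)), sd=sd,
        min=float(np.min(arr)), max=float(np.max(arr)), n=int(arr.size),
    )


def values_for(
    samples: Sequence[IsotopeSample], axis: str, warn: bool = True
) -> tuple[list[float], list[IsotopeSample]]:
    """Extract one axis from a sample collection, dropping (with a logged
    warning) samples on which it is missing."""
    vals, kept = [], []
    for s in samples:
        v = getattr(s, axis)
        if v is None:
            if warn:
                logger.warning("sample %s missing %s; excluded", s.sample_id, axis)
            continue
        vals.append(v)
        kept.append(s)
    return vals, kept


def to_table(samples: Sequence[IsotopeSample]) -> "object":
    """Return the collection as a pandas DataFrame (one row per sample)."""
    import pandas as pd

    return pd.DataFrame([
        {f.name: getattr(s, f.name) for f in fields(IsotopeSample)}
        for s in samples
    ])
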
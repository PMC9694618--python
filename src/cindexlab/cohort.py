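"""Fever-episode cohort data model and CSV round-trip I/O.

A cohort is one row per fever onset: an episode identifier, an optional
patient identifier, a binary infection label (1 = microbiologically
documented infection, 0 = fever without documented infection) and three
serum biomarker values measured at fever onset:

* ``pct``  — procalcitonin (mg/mL, as printed on the assay),
* ``crp``  — C-reactive protein (ng/mL),
* ``il6``  — interleukin-6 (pg/mL).

Units are carried as annotations only and never converted; analysis
downstream is unit-free by construction (mean normalization).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed column order of the cohort CSV schema.
COLUMNS = ("episode_id", "patient_id", "infection", "pct", "crp", "il6")

#: Columns that must be present in an input file (patient_id is optional).
REQUIRED_COLUMNS = ("episode_id", "infection", "pct", "crp", "il6")

BIOMARKERS = ("pct", "crp", "il6")

#: Printed assay units, kept as opaque annotations.
UNITS = {"pct": "mg/mL", "crp": "ng/mL", "il6": "pg/mL"}


class CohortSchemaError(ValueError):
    """Input file does not match the cohort CSV schema."""


class CohortValidationError(ValueError):
    """Row content violates an episode or cohort invariant."""


@dataclass(frozen=True)
class Episode:
    """One fever onset with its laboratory values.

    All three biomarker values must be finite and non-negative; zero is a
    legal assay result (below-detection reports). The infection label is
    exactly 0 or 1.
    """

    episode_id: str
    infection: int
    pct: float
    crp: float
    il6: float
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.episode_id:
            raise CohortValidationError("episode_id must be a non-empty string")
        if self.infection not in (0, 1):
            raise CohortValidationError(
                f"episode {self.episode_id!r}: infection label must be 0 or 1, "
                f"got {self.infection!r}"
            )
        for name in BIOMARKERS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise CohortValidationError(
                    f"episode {self.episode_id!r}: {name} must be numeric"
                )
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"episode {self.episode_id!r}: {name}={value!r} must be "
                    "finite and >= 0"
                )

    def value(self, biomarker: str) -> float:
        if biomarker not in BIOMARKERS:
            raise KeyError(biomarker)
        return float(getattr(self, biomarker))


@dataclass
class Cohort:
    """An ordered collection of episodes with unique identifiers."""

    episodes: list[Episode]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ep in self.episodes:
            if ep.episode_id in seen:
                raise CohortValidationError(
                    f"duplicate episode_id {ep.episode_id!r}"
                )
            seen.add(ep.episode_id)

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterator[Episode]:
        return iter(self.episodes)

    @property
    def labels(self) -> list[int]:
        return [ep.infection for ep in self.episodes]

    def n_infection(self) -> int:
        return sum(self.labels)

    def n_no_infection(self) -> int:
        return len(self) - self.n_infection()

    def values(self, biomarker: str) -> list[float]:
        """All values of one biomarker, in episode order."""
        return [ep.value(biomarker) for ep in self.episodes]

    def group_values(self, biomarker: str, infection: int) -> list[float]:
        return [
            ep.value(biomarker) for ep in self.episodes
            if ep.infection == infection
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "episode_id": [ep.episode_id for ep in self.episodes],
                "patient_id": [ep.patient_id or "" for ep in self.episodes],
                "infection": self.labels,
                "pct": self.values("pct"),
                "crp": self.values("crp"),
                "il6": self.values("il6"),
            }
        )


def _parse_row(raw: dict, row_number: int) -> Episode:
    """Build an Episode from one CSV row of strings; raise on any defect."""
    episode_id = (raw.get("episode_id") or "").strip()
    patient_id = (raw.get("patient_id") or "").strip() or None
    infection_raw = (raw.get("infection") or "").strip()
    try:
        infection_f = float(infection_raw)
    except ValueError:
        raise CohortValidationError(
            f"row {row_number}: infection label {infection_raw!r} is not numeric"
        )
    if infection_f not in (0.0, 1.0):
        raise CohortValidationError(
            f"row {row_number}: infection label must be 0 or 1, got {infection_raw!r}"
        )
    values = {}
    for name in BIOMARKERS:
        text = (raw.get(name) or "").strip()
        if not text:
            raise CohortValidationError(f"row {row_number}: missing {name}")
        try:
            values[name] = float(text)
        except ValueError:
            raise CohortValidationError(
                f"row {row_number}: {name}={text!r} is not numeric"
            )
    return Episode(
        episode_id=episode_id,
        patient_id=patient_id,
        infection=int(infection_f),
        **values,
    )


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with header ``episode_id,patient_id,infection,pct,crp,il6``
        (``patient_id`` optional; extra columns ignored with a warning).
    strict
        If True (default) any invalid row raises; if False invalid rows are
        dropped and their count logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, header required")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise CohortSchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        extra = [c for c in header if c not in COLUMNS]
        if extra:
            logger.warning("%s: ignoring extra column(s): %s", path, extra)
        episodes: list[Episode] = []
        dropped = 0
        for i, raw in enumerate(reader, start=2):
            try:
                episodes.append(_parse_row(raw, i))
            except CohortValidationError:
                if strict:
                    raise
                dropped += 1
    if dropped:
        logger.info("%s: dropped %d invalid row(s)", path, dropped)
    if not episodes:
        raise CohortValidationError(f"{path}: no valid data rows")
    cohort = Cohort(episodes=episodes, provenance=str(path))
    cohort.dropped_rows = dropped  # type: ignore[attr-defined]
    return cohort


def _fmt(value: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(value))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV with the fixed schema, at full float precision.

    ``read_cohort(write_cohort(c))`` reproduces every value exactly.
    Absent ``patient_id`` is written as an empty field.
    """
    if len(cohort) == 0:
        raise CohortValidationError("refusing to write an empty cohort")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for ep in cohort:
            writer.writerow(
                [
                    ep.episode_id,
                    ep.patient_id or "",
                    ep.infection,
                    _fmt(ep.pct),
                    _fmt(ep.crp),
                    _fmt(ep.il6),
                ]
            )
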
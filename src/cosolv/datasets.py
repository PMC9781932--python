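"""Tabular solubility data model and CSV I/O.

A saturation point is a :class:`SolubilityRecord`: a solute dissolved in a
neat solvent or a binary solvent mixture at one temperature.  Binary aqueous
organic mixtures are described by the *solute-free* mole fraction ``x2_star``
of the organic component (``x2_star = 1`` is the neat organic solvent,
``x2_star = 0`` is neat water).  Temperatures are stored in kelvin; file
readers accept Celsius behind an explicit dialect flag.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SolubilityRecord",
    "SolventMeta",
    "Dataset",
    "SchemaError",
    "RecordError",
    "read_solubility_table",
    "write_solubility_table",
    "read_solvent_meta",
]

logger = logging.getLogger("cosolv.datasets")

CELSIUS_OFFSET = 273.15

#: canonical CSV header for solubility tables
TABLE_COLUMNS = [
    "solute", "solvent1", "solvent2", "x2_star",
    "temp", "temp_unit", "x", "u_x", "source",
]

REQUIRED_COLUMNS = ["solute", "solvent1", "x2_star", "temp", "x"]


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


class RecordError(ValueError):
    """Raised when a row violates a record invariant."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One measured or predicted saturation point.

    Parameters
    ----------
    solute_id : str
        Opaque solute identifier (e.g. ``"acetaminophen"``).
    solvent1_id : str
        The organic component, or the only solvent for neat systems.
    solvent2_id : str
        The second (aqueous) component; empty string for neat solvents.
    x2_star : float
        Solute-free mole fraction of ``solvent1`` in the mixed solvent,
        in [0, 1].  1.0 for the neat organic, 0.0 for neat solvent2.
    temperature : float
        Absolute temperature in kelvin, > 0.
    x_solute : float
        Mole-fraction solubility in (0, 1].
    uncertainty : float
        Standard uncertainty of ``x_solute`` (same units), >= 0.
    source : str
        Provenance tag: ``literature | measured | curated | predicted``.
    """

    solute_id: str
    solvent1_id: str
    solvent2_id: str = ""
    x2_star: float = 1.0
    temperature: float = 298.15
    x_solute: float = np.nan
    uncertainty: float = 0.0
    source: str = "literature"

    def __post_init__(self) -> None:
        if not 0.0 <= self.x2_star <= 1.0:
            raise RecordError(f"x2_star={self.x2_star} outside [0, 1]")
        if not self.temperature > 0.0:
            raise RecordError(f"temperature={self.temperature} K must be > 0")
        if not 0.0 < self.x_solute <= 1.0:
            raise RecordError(f"x_solute={self.x_solute} outside (0, 1]")
        if self.uncertainty < 0.0:
            raise RecordError(f"uncertainty={self.uncertainty} must be >= 0")

    @property
    def x3_star(self) -> float:
        """Solute-free mole fraction of solvent2 (stored implicitly)."""
        return 1.0 - self.x2_star

    @property
    def is_neat(self) -> bool:
        return self.x2_star in (0.0, 1.0)

    def key(self) -> tuple:
        return (self.solute_id, self.solvent1_id, self.solvent2_id,
                self.x2_star, self.temperature, self.source)


@dataclass(frozen=True)
class SolventMeta:
    """Environmental metadata for one solvent.

    ``green`` is derived, not stored: a solvent is green exactly when its
    environmental index falls strictly below the configured threshold
    (default 0.5).
    """

    solvent_id: str
    ei: float
    notes: str = ""
    ei_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.ei < 0.0:
            raise RecordError(f"EI={self.ei} must be >= 0")

    @property
    def green(self) -> bool:
        return self.ei < self.ei_threshold


@dataclass
class Dataset:
    """Ordered collection of :class:`SolubilityRecord` with provenance."""

    records: list[SolubilityRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def duplicate_keys(self) -> list[tuple]:
        seen: set = set()
        dups = []
        for r in self.records:
            k = r.key()
            if k in seen:
                dups.append(k)
            seen.add(k)
        return dups

    def filter(self, **matches) -> "Dataset":
        """Subset by exact field values, e.g. ``filter(solute_id="A")``."""
        recs = [r for r in self.records
                if all(getattr(r, k) == v for k, v in matches.items())]
        return Dataset(recs, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "solute": r.solute_id, "solvent1": r.solvent1_id,
            "solvent2": r.solvent2_id, "x2_star": r.x2_star,
            "temp": r.temperature, "temp_unit": "K",
            "x": r.x_solute, "u_x": r.uncertainty, "source": r.source,
        } for r in self.records]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records])

    @property
    def x(self) -> np.ndarray:
        return np.array([r.x_solute for r in self.records])

    @property
    def x2(self) -> np.ndarray:
        return np.array([r.x2_star for r in self.records])


def _to_kelvin(value: float, unit: str) -> float:
    unit = unit.strip().upper()
    if unit in ("K", "KELVIN"):
        return float(value)
    if unit in ("C", "°C", "CELSIUS", "DEGC"):
        return float(value) + CELSIUS_OFFSET
    raise SchemaError(f"unknown temperature unit {unit!r}")


def read_solubility_table(path, temp_unit: str | None = None,
                          strict: bool = False) -> Dataset:
    """Read a solubility CSV into a :class:`Dataset`.

    Expected columns: ``solute, solvent1, solvent2, x2_star, temp,
    temp_unit, x, u_x, source`` (``solvent2``, ``temp_unit``, ``u_x`` and
    ``source`` optional).  Temperatures are normalised to kelvin using the
    per-row ``temp_unit`` column, or the ``temp_unit`` argument when the
    column is absent.

    Rows violating record invariants are rejected with a row-indexed
    message on stderr (or raise, when ``strict=True``).
    """
    df = pd.read_csv(path, dtype={"solvent2": str, "source": str},
                     keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[SolubilityRecord] = []
    for idx, row in df.iterrows():
        try:
            unit = (str(row["temp_unit"]) if "temp_unit" in df.columns
                    and str(row["temp_unit"]).strip()
                    else (temp_unit or "K"))
            try:
                x2s = float(row["x2_star"])
                temp = float(row["temp"])
                x = float(row["x"])
            except (TypeError, ValueError) as exc:
                raise RecordError(f"non-numeric value: {exc}") from exc
            rec = SolubilityRecord(
                solute_id=str(row["solute"]),
                solvent1_id=str(row["solvent1"]),
                solvent2_id=str(row.get("solvent2", "") or ""),
                x2_star=x2s,
                temperature=_to_kelvin(temp, unit),
                x_solute=x,
                uncertainty=float(row.get("u_x", 0.0) or 0.0),
                source=str(row.get("source", "") or "literature"),
            )
        except RecordError as exc:
            msg = f"{path} row {idx}: rejected ({exc})"
            if strict:
                raise RecordError(msg) from exc
            logger.warning(msg)
            print(msg, file=sys.stderr)
            continue
        records.append(rec)

    ds = Dataset(records, provenance=str(path))
    for k in ds.duplicate_keys():
        logger.warning("duplicate record key %s (kept; curation decides)", k)
    return ds


def write_solubility_table(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` as RFC-4180-style CSV (kelvin)."""
    dataset.to_frame().to_csv(path, index=False)


def read_solvent_meta(path, ei_threshold: float = 0.5) -> dict[str, SolventMeta]:
    """Read a solvent metadata CSV (``solvent_id, ei, notes``)."""
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("solvent_id", "ei"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out: dict[str, SolventMeta] = {}
    for _, row in df.iterrows():
        ei_raw = str(row["ei"]).strip()
        if not ei_raw:
            logger.warning("solvent %s has no EI; excluded from metadata",
                           row["solvent_id"])
            continue
        meta = SolventMeta(solvent_id=str(row["solvent_id"]),
                           ei=float(ei_raw),
                           notes=str(row.get("notes", "") or ""),
                           ei_threshold=ei_threshold)
        out[meta.solvent_id] = meta
    return out
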
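"""Data model and file input/output for single-plant trial phenotypes.

The pipeline exchanges two tabular formats:

* long-format phenotype CSV/TSV — one row per plant observation
  (:class:`PlotRecord`), the canonical raw/curated/adjusted exchange format;
* wide genotype × environment CSV — BLUP-predicted yields
  (:class:`BlupTable`), the input to index computation, AMMI and GGE.

Environments are labelled by treatment code plus two-digit year, e.g. ``CV19``
for the drought (covered) treatment in 2019 and ``UC21`` for the irrigated
control (uncovered) in 2021.

Missing data are encoded as empty CSV fields; zero is a legitimate
measurement, never a missing code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "PlotRecord",
    "Environment",
    "BlupTable",
    "TrialIOError",
    "ValidationError",
    "read_phenotypes",
    "write_phenotypes",
    "records_to_frame",
    "frame_to_records",
    "compute_dry_yield",
    "read_matrix",
    "write_matrix",
]


class TrialIOError(Exception):
    """Raised for unreadable or structurally invalid input files."""


class ValidationError(TrialIOError):
    """Raised when records violate a data-model invariant."""


class Treatment(str, Enum):
    """Water-regime treatment: CV = covered/drought, UC = uncovered/control."""

    CV = "CV"
    UC = "UC"


# Canonical long-format column order used by every writer.
PHENOTYPE_COLUMNS = (
    "genotype_id",
    "year",
    "treatment",
    "block",
    "row",
    "col",
    "fresh_weight",
    "subsample_fresh",
    "subsample_dry",
    "dry_yield",
    "is_filler",
)


@dataclass(frozen=True)
class PlotRecord:
    """One plant observation with its field position and yield measurements.

    Masses are grams; ``dry_yield`` is g·plant⁻¹. Optional measurements are
    ``None`` when absent. ``is_filler`` marks border/filler plants that never
    enter genotype statistics.
    """

    genotype_id: str
    year: int
    treatment: Treatment
    block: int
    row: int
    col: int
    fresh_weight: float | None = None
    subsample_fresh: float | None = None
    subsample_dry: float | None = None
    dry_yield: float | None = None
    is_filler: bool = False

    def __post_init__(self) -> None:
        for name in ("fresh_weight", "subsample_fresh", "subsample_dry", "dry_yield"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.subsample_fresh is not None and self.subsample_fresh <= 0:
            raise ValidationError("subsample_fresh must be > 0 when present")
        if (
            self.subsample_dry is not None
            and self.subsample_fresh is not None
            and self.subsample_dry > self.subsample_fresh
        ):
            raise ValidationError(
                f"subsample_dry ({self.subsample_dry}) exceeds subsample_fresh "
                f"({self.subsample_fresh})"
            )
        if self.block < 1 or self.row < 1 or self.col < 1:
            raise ValidationError("block, row and col are 1-based positive indices")

    @property
    def position_key(self) -> tuple[int, int, int, str, int]:
        """Unique field-position key (row, col, block, treatment, year)."""
        return (self.row, self.col, self.block, self.treatment.value, self.year)

    def with_dry_yield(self, value: float) -> "PlotRecord":
        return replace(self, dry_yield=value)


@dataclass(frozen=True)
class Environment:
    """A treatment × year combination, labelled e.g. ``CV19`` or ``UC21``."""

    treatment: Treatment
    year: int

    @property
    def label(self) -> str:
        return f"{self.treatment.value}{self.year % 100:02d}"

    @classmethod
    def from_label(cls, label: str, century: int = 2000) -> "Environment":
        if len(label) != 4:
            raise ValidationError(f"environment label must be 4 chars, got {label!r}")
        try:
            trt = Treatment(label[:2])
            year = century + int(label[2:])
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"cannot parse environment label {label!r}") from exc
        return cls(trt, year)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def compute_dry_yield(record: PlotRecord) -> float:
    """Estimate per-plant dry biomass from fresh weight and a dried subsample.

    The oven-dried subsample gives the dry-matter fraction, which scales the
    whole-plant fresh weight::

        dry_yield = fresh_weight * subsample_dry / subsample_fresh

    Raises
    ------
    ValidationError
        If any of the three masses is absent or ``subsample_fresh`` is zero.
    """
    if (
        record.fresh_weight is None
        or record.subsample_fresh is None
        or record.subsample_dry is None
    ):
        raise ValidationError("fresh_weight and both subsample masses are required")
    if record.subsample_fresh == 0:
        raise ValidationError("subsample_fresh must be non-zero")
    return record.fresh_weight * record.subsample_dry / record.subsample_fresh


def _parse_optional_float(raw: object, field: str, line_no: int) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise TrialIOError(f"line {line_no}: bad value {raw!r} for {field}") from exc


def _parse_bool(raw: object) -> bool:
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    return s in {"1", "true", "t", "yes", "y"}


def read_phenotypes(
    path,
    dialect: str = ",",
    aliases: Mapping[str, str] | None = None,
) -> list[PlotRecord]:
    """Read a long-format phenotype table into validated :class:`PlotRecord`s.

    Parameters
    ----------
    path
        CSV/TSV file with one header row.
    dialect
        Field delimiter, ``","`` or ``"\\t"``.
    aliases
        Optional mapping from file header names to canonical field names,
        e.g. ``{"Rep": "block"}``. Matching is case-insensitive after
        aliasing. Raw-file schemas vary between programs, hence the mapping
        is configurable rather than fixed.

    Raises
    ------
    TrialIOError
        Unreadable file, unknown delimiter, malformed values (reported with
        line numbers) or duplicate (row, col, block, treatment, year) keys.
    """
    aliases = {k.lower(): v for k, v in (aliases or {}).items()}
    try:
        df = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialIOError(f"cannot read phenotype file {path}: {exc}") from exc

    colmap: dict[str, str] = {}
    for c in df.columns:
        canon = aliases.get(c.lower(), c).lower()
        if canon in PHENOTYPE_COLUMNS:
            colmap[canon] = c
    required = ("genotype_id", "year", "treatment", "block", "row", "col")
    missing = [c for c in required if c not in colmap]
    if missing:
        raise TrialIOError(f"missing required columns {missing} in {path}")

    records: list[PlotRecord] = []
    seen: set[tuple] = set()
    errors: list[str] = []
    for idx, rowdata in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            rec = PlotRecord(
                genotype_id=str(rowdata[colmap["genotype_id"]]).strip(),
                year=int(rowdata[colmap["year"]]),
                treatment=Treatment(str(rowdata[colmap["treatment"]]).strip().upper()),
                block=int(rowdata[colmap["block"]]),
                row=int(rowdata[colmap["row"]]),
                col=int(rowdata[colmap["col"]]),
                fresh_weight=_parse_optional_float(
                    rowdata.get(colmap.get("fresh_weight", ""), None), "fresh_weight", line_no
                ),
                subsample_fresh=_parse_optional_float(
                    rowdata.get(colmap.get("subsample_fresh", ""), None),
                    "subsample_fresh",
                    line_no,
                ),
                subsample_dry=_parse_optional_float(
                    rowdata.get(colmap.get("subsample_dry", ""), None), "subsample_dry", line_no
                ),
                dry_yield=_parse_optional_float(
                    rowdata.get(colmap.get("dry_yield", ""), None), "dry_yield", line_no
                ),
                is_filler=_parse_bool(rowdata.get(colmap.get("is_filler", ""), False)),
            )
        except (ValueError, ValidationError, TrialIOError) as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        if rec.position_key in seen:
            errors.append(f"line {line_no}: duplicate position {rec.position_key}")
            continue
        seen.add(rec.position_key)
        records.append(rec)
    if errors:
        raise TrialIOError(
            f"{len(errors)} malformed row(s) in {path}:\n" + "\n".join(errors[:20])
        )
    return records


def records_to_frame(records: Iterable[PlotRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in canonical column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "genotype_id": r.genotype_id,
                "year": r.year,
                "treatment": r.treatment.value,
                "block": r.block,
                "row": r.row,
                "col": r.col,
                "fresh_weight": r.fresh_weight,
                "subsample_fresh": r.subsample_fresh,
                "subsample_dry": r.subsample_dry,
                "dry_yield": r.dry_yield,
                "is_filler": r.is_filler,
            }
        )
    return pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[PlotRecord]:
    """Inverse of :func:`records_to_frame` (validates every row)."""

    def opt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return [
        PlotRecord(
            genotype_id=str(r.genotype_id),
            year=int(r.year),
            treatment=Treatment(str(r.treatment)),
            block=int(r.block),
            row=int(r.row),
            col=int(r.col),
            fresh_weight=opt(r.fresh_weight),
            subsample_fresh=opt(r.subsample_fresh),
            subsample_dry=opt(r.subsample_dry),
            dry_yield=opt(r.dry_yield),
            is_filler=bool(r.is_filler),
        )
        for r in df.itertuples(index=False)
    ]


def write_phenotypes(records: Iterable[PlotRecord], path, dialect: str = ",") -> None:
    """Write records as a long-format table; absent values become empty fields."""
    records_to_frame(records).to_csv(path, sep=dialect, index=False)


@dataclass
class BlupTable:
    """Genotype × environment matrix of yield-scale BLUP-predicted values.

    ``values[i, j]`` is the predicted yield (g·plant⁻¹) of genotype ``i`` in
    environment ``j``; NaN marks genotype-environment combinations with no
    prediction.
    """

    genotypes: list[str]
    environments: list[Environment]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotypes), len(self.environments)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genotypes)} genotypes × {len(self.environments)} environments"
            )
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValidationError("duplicate genotype ids")
        labels = [e.label for e in self.environments]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate environment labels")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise ValidationError("BLUP-predicted yields must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.genotypes, name="genotype_id"),
            columns=[e.label for e in self.environments],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BlupTable":
        envs = [Environment.from_label(str(c)) for c in df.columns]
        return cls(
            genotypes=[str(g) for g in df.index],
            environments=envs,
            values=df.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BlupTable):
            return NotImplemented
        return (
            self.genotypes == other.genotypes
            and self.environments == other.environments
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def write_matrix(table: BlupTable, path) -> None:
    """Write a BLUP matrix as wide CSV; NaN cells become empty fields.

    Values are written with the shortest round-tripping decimal
    representation, so the write → read round trip is bit-identical.
    """
    table.to_frame().to_csv(path, na_rep="")


def read_matrix(path) -> BlupTable:
    """Read a wide genotype × environment CSV written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialIOError(f"cannot read matrix file {path}: {exc}") from exc
    return BlupTable.from_frame(df)
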
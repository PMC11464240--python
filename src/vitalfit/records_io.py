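"""Fish-level vitality records: reading, validation and derived fields.

The analysis table holds one row per assessed fish, nested in gear
deployments (hauls) which are nested in fishing trips.  Ten binary
condition attributes are scored per fish: six reflexes (1 = impaired,
0 = response present) and four injury types (1 = present, 0 = absent,
dichotomized from a 0-3 severity scale).  The binary response is
mortality at asymptote, i.e. death status once the captive-monitoring
mortality curve has flattened (0 = alive, 1 = dead).

All attribute scores share one orientation: a 1 contributes to the
reflex-and-injury index.  Input files that code reflexes the other way
round (1 = response present) can be flipped through the schema map.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Canonical attribute order; every weight vector uses this order.
REFLEXES: tuple[str, ...] = (
    "body_flex",
    "righting",
    "head_complex",
    "evasion",
    "stabilize",
    "tail_grab",
)
INJURIES: tuple[str, ...] = (
    "bruising_head",
    "bruising_body",
    "point_head",
    "point_body",
)
ATTRIBUTES: tuple[str, ...] = REFLEXES + INJURIES
RAW_INJURY_COLUMNS: tuple[str, ...] = tuple(f"{a}_raw" for a in INJURIES)

VITALITY_LEVELS: tuple[str, ...] = ("A", "B", "C", "D")
GEAR_TYPES: tuple[str, ...] = ("BT2", "OTB")

# Covariate vocabulary used by complete-case filtering and model designs.
CONTINUOUS_COVARIATES: tuple[str, ...] = (
    "sea_temp",
    "depth",
    "duration",
    "total_catch",
    "air_exposure",
    "length",
)
COVARIATE_VOCABULARY: tuple[str, ...] = CONTINUOUS_COVARIATES + ("gear",)

ID_COLUMNS: tuple[str, ...] = ("fish_id", "trip_id", "deployment_id", "gear_type")

#: Canonical CSV column order for writing.
CANONICAL_COLUMNS: tuple[str, ...] = (
    ID_COLUMNS
    + CONTINUOUS_COVARIATES
    + REFLEXES
    + RAW_INJURY_COLUMNS
    + INJURIES
    + ("vitality", "mortality")
)

DEFAULT_MISSING_SENTINELS: tuple[str, ...] = ("", "NA", "NaN", "nan")


class SchemaError(ValueError):
    """A required column is absent or the file structure is unusable."""


@dataclasses.dataclass
class RowError:
    row: int
    field: str
    code: str
    message: str


@dataclasses.dataclass
class ValidationReport:
    """Row-indexed diagnostics collected while reading or deriving."""

    n_read: int = 0
    n_valid: int = 0
    errors: list[RowError] = dataclasses.field(default_factory=list)

    def add(self, row: int, field: str, code: str, message: str) -> None:
        self.errors.append(RowError(row, field, code, message))

    @property
    def rejected_rows(self) -> list[int]:
        return sorted({e.row for e in self.errors})

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_read": self.n_read,
            "n_valid": self.n_valid,
            "errors": [dataclasses.asdict(e) for e in self.errors],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclasses.dataclass
class RecordSet:
    """An ordered collection of validated fish records.

    ``df`` uses the canonical column names; attribute columns are int
    (0/1 for reflexes and binary injuries, 0-3 for raw injuries) and
    covariates are float with NaN for missing.
    """

    df: pd.DataFrame
    provenance: str = ""
    validation: ValidationReport | None = None

    @property
    def n(self) -> int:
        return len(self.df)

    def attribute_matrix(self) -> np.ndarray:
        """(n, 10) float matrix of the binary attributes, canonical order."""
        return self.df[list(ATTRIBUTES)].to_numpy(dtype=float)

    def mortality(self) -> np.ndarray:
        return self.df["mortality"].to_numpy(dtype=float)

    def copy(self) -> "RecordSet":
        return RecordSet(self.df.copy(), self.provenance, self.validation)


def _coerce_binary(series: pd.Series, field: str, report: ValidationReport,
                   allowed: Sequence[int]) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() | ~numeric.isin(list(allowed))
    for idx in series.index[bad]:
        report.add(int(idx), field, "invalid_score",
                   f"{field}={series.loc[idx]!r} not in {set(allowed)}")
    return numeric


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    missing_sentinels: Iterable[str] = DEFAULT_MISSING_SENTINELS,
    flip_reflexes: bool = False,
    provenance: str | None = None,
) -> RecordSet:
    """Read a fish-record CSV into a validated :class:`RecordSet`.

    Parameters
    ----------
    path:
        CSV file with a header row, one row per fish.
    schema:
        Optional map from canonical column name to the column name used
        in the file.  Unmapped canonical names are looked up directly.
    missing_sentinels:
        Cell values treated as missing (in addition to empty cells).
    flip_reflexes:
        Set when the file codes reflexes as 1 = response present; scores
        are flipped so that stored 1 always means impaired.

    Rows violating hard invariants (attribute scores outside their
    domain, unknown vitality or gear level, non-binary mortality) are
    rejected; diagnostics are collected in ``RecordSet.validation``.
    Missing required columns raise :class:`SchemaError`.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(missing_sentinels),
        skipinitialspace=True,
    )
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    required = list(ID_COLUMNS) + list(REFLEXES) + ["vitality", "mortality"]
    # Injuries may arrive raw (0-3), binary, or both.
    has_raw = all(c in raw.columns for c in RAW_INJURY_COLUMNS)
    has_bin = all(c in raw.columns for c in INJURIES)
    if not (has_raw or has_bin):
        raise SchemaError(
            "injury columns missing: need either "
            f"{RAW_INJURY_COLUMNS} or {INJURIES}"
        )
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    report = ValidationReport(n_read=len(raw))
    df = pd.DataFrame(index=raw.index)
    for col in ("fish_id", "trip_id", "deployment_id"):
        df[col] = raw[col].astype(str)

    gear = raw["gear_type"].astype(str)
    for idx in gear.index[~gear.isin(GEAR_TYPES)]:
        report.add(int(idx), "gear_type", "invalid_level",
                   f"gear_type={gear.loc[idx]!r} not in {GEAR_TYPES}")
    df["gear_type"] = gear

    for col in CONTINUOUS_COVARIATES:
        if col in raw.columns:
            numeric = pd.to_numeric(raw[col], errors="coerce")
            unparsed = numeric.isna() & raw[col].notna()
            for idx in raw.index[unparsed]:
                report.add(int(idx), col, "unparseable",
                           f"{col}={raw[col].loc[idx]!r} is not numeric")
            df[col] = numeric
        else:
            df[col] = np.nan

    for col in REFLEXES:
        scores = _coerce_binary(raw[col], col, report, (0, 1))
        if flip_reflexes:
            scores = 1 - scores
        df[col] = scores
    if has_raw:
        for col in RAW_INJURY_COLUMNS:
            df[col] = _coerce_binary(raw[col], col, report, (0, 1, 2, 3))
    if has_bin:
        for col in INJURIES:
            df[col] = _coerce_binary(raw[col], col, report, (0, 1))

    vitality = raw["vitality"].astype(str).str.strip().str.upper()
    for idx in vitality.index[~vitality.isin(VITALITY_LEVELS)]:
        report.add(int(idx), "vitality", "invalid_level",
                   f"vitality={raw['vitality'].loc[idx]!r} not in A-D")
    df["vitality"] = vitality
    df["mortality"] = _coerce_binary(raw["mortality"], "mortality", report, (0, 1))

    bad_rows = set(report.rejected_rows)
    keep = [i for i in df.index if i not in bad_rows]
    df = df.loc[keep].reset_index(drop=True)

    dup = df["fish_id"].duplicated()
    if dup.any():
        raise SchemaError(f"duplicate fish_id values: "
                          f"{sorted(df['fish_id'][dup].unique())}")
    _check_nesting(df)

    for col in REFLEXES + (RAW_INJURY_COLUMNS if has_raw else ()) + \
            (INJURIES if has_bin else ()) + ("mortality",):
        df[col] = df[col].astype(int)
    report.n_valid = len(df)
    rs = RecordSet(_canonical_order(df), provenance or str(path), report)
    if has_raw and not has_bin:
        rs = derive_fields(rs)
    return rs


def _canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    known = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    return df[known + extra]


def _check_nesting(df: pd.DataFrame) -> None:
    """Deployment -> trip and trip -> gear maps must be functions."""
    dep = df.groupby("deployment_id")["trip_id"].nunique()
    if (dep > 1).any():
        raise SchemaError(
            f"deployment(s) mapped to multiple trips: "
            f"{sorted(dep.index[dep > 1])}")
    trip = df.groupby("trip_id")["gear_type"].nunique()
    if (trip > 1).any():
        raise SchemaError(
            f"trip(s) mapped to multiple gear types: "
            f"{sorted(trip.index[trip > 1])}")


def derive_fields(
    rs: RecordSet,
    deck_minutes: pd.Series | np.ndarray | None = None,
    handling_minutes: pd.Series | np.ndarray | None = None,
) -> RecordSet:
    """Compute derived columns: binary injuries and air exposure.

    Binary injury = 1 whenever the raw 0-3 severity score is >= 1.
    If per-fish deck time and handling time are supplied, air exposure
    is ``deck_minutes + handling_minutes / 3`` (one third of the reflex
    testing is performed in air); an existing air_exposure column is
    preserved otherwise.  Idempotent.
    """
    df = rs.df.copy()
    report = rs.validation or ValidationReport(n_read=len(df), n_valid=len(df))
    if all(c in df.columns for c in RAW_INJURY_COLUMNS):
        for inj, raw_col in zip(INJURIES, RAW_INJURY_COLUMNS):
            df[inj] = (df[raw_col] >= 1).astype(int)
    if deck_minutes is not None and handling_minutes is not None:
        deck = np.asarray(deck_minutes, dtype=float)
        handling = np.asarray(handling_minutes, dtype=float)
        if len(deck) != len(df) or len(handling) != len(df):
            raise ValueError("deck/handling time length does not match records")
        negative = (deck < 0) | (handling < 0)
        for idx in np.nonzero(negative)[0]:
            report.add(int(idx), "air_exposure", "negative_time",
                       f"deck={deck[idx]}, handling={handling[idx]}")
        df["air_exposure"] = deck + handling / 3.0
        df = df.loc[~negative].reset_index(drop=True)
        report.n_valid = len(df)
    return RecordSet(_canonical_order(df), rs.provenance, report)


def _required_columns(covariates: Iterable[str]) -> list[str]:
    cols: list[str] = []
    for cov in covariates:
        if cov not in COVARIATE_VOCABULARY:
            raise ValueError(
                f"unknown covariate {cov!r}; expected one of "
                f"{COVARIATE_VOCABULARY}")
        cols.append("gear_type" if cov == "gear" else cov)
    return cols


def complete_cases(rs: RecordSet, covariates: Iterable[str] = ()) -> RecordSet:
    """Keep only records complete for attributes, outcome and ``covariates``.

    Mirrors the complete-case filtering used before model fitting: every
    retained record has all ten attribute scores, mortality, and
    non-missing values for the requested covariates.  Adding covariates
    can only shrink the result.
    """
    cols = list(ATTRIBUTES) + ["mortality"] + _required_columns(covariates)
    mask = rs.df[cols].notna().all(axis=1)
    out = rs.df.loc[mask].reset_index(drop=True)
    return RecordSet(out, rs.provenance, rs.validation)


def write_records(rs: RecordSet, path: str | Path) -> Path:
    """Write the canonical CSV; round-trips through :func:`read_records`."""
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in rs.df.columns]
    rs.df[cols].to_csv(path, index=False)
    return path
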
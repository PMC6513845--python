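"""Core domain vocabulary: PAH congeners, seasons, population strata, and the
tidy congener-concentration table.

The 16 US-EPA priority PAHs are the fixed congener universe.  Concentrations
live in a tidy :class:`pandas.DataFrame` (one row per sample x congener) with
columns ``sample_id, city, date, season, congener, conc_ng_m3,
below_detection, lod_ng_m3`` — the canonical on-disk CSV layout of this
package.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable

import pandas as pd


class RingClass(str, enum.Enum):
    """Molecular-weight class: 2-3 aromatic rings (semi-volatile, mostly
    gas-phase) vs 4-6 rings (particle-bound, carrying the large TEFs)."""

    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class Congener:
    name: str
    ring_count: int

    def __post_init__(self) -> None:
        if not 2 <= self.ring_count <= 6:
            raise ValueError(f"ring_count must be in 2..6, got {self.ring_count}")

    @property
    def ring_class(self) -> RingClass:
        return RingClass.LOW if self.ring_count <= 3 else RingClass.HIGH


#: The 16 US-EPA priority PAHs, in elution order, with aromatic ring counts.
CONGENERS: tuple[Congener, ...] = (
    Congener("Nap", 2),    # naphthalene
    Congener("Acy", 3),    # acenaphthylene
    Congener("Flu", 3),    # fluorene
    Congener("Ace", 3),    # acenaphthene
    Congener("Phe", 3),    # phenanthrene
    Congener("Ant", 3),    # anthracene
    Congener("Fle", 4),    # fluoranthene
    Congener("Pyr", 4),    # pyrene
    Congener("Chr", 4),    # chrysene
    Congener("BaA", 4),    # benz(a)anthracene
    Congener("BbF", 5),    # benzo(b)fluoranthene
    Congener("BkF", 5),    # benzo(k)fluoranthene
    Congener("BaP", 5),    # benzo(a)pyrene
    Congener("DBA", 5),    # dibenz(a,h)anthracene
    Congener("BghiP", 6),  # benzo(g,h,i)perylene
    Congener("InP", 6),    # indeno(1,2,3-cd)pyrene
)

CONGENER_NAMES: tuple[str, ...] = tuple(c.name for c in CONGENERS)
CONGENER_BY_NAME: dict[str, Congener] = {c.name: c for c in CONGENERS}

#: Import-only synonym map for common alternative abbreviations.
CONGENER_SYNONYMS: dict[str, str] = {
    "Flt": "Fle",
    "Fla": "Fle",
    "Fluo": "Flu",
    "B[a]P": "BaP",
    "B[a]A": "BaA",
    "B[b]F": "BbF",
    "B[k]F": "BkF",
    "IcdP": "InP",
    "IND": "InP",
    "DahA": "DBA",
    "BgP": "BghiP",
}

HIGH_RING_NAMES: tuple[str, ...] = tuple(
    c.name for c in CONGENERS if c.ring_class is RingClass.HIGH
)
LOW_RING_NAMES: tuple[str, ...] = tuple(
    c.name for c in CONGENERS if c.ring_class is RingClass.LOW
)


def canonical_congener(name: str) -> str:
    """Resolve a congener name (canonical or synonym) to the canonical
    abbreviation, raising ``ValueError`` for unknown names."""
    if name in CONGENER_BY_NAME:
        return name
    if name in CONGENER_SYNONYMS:
        return CONGENER_SYNONYMS[name]
    raise ValueError(f"unknown PAH congener name: {name!r}")


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Season:
    label: str
    months: frozenset[int]


SEASONS: tuple[Season, ...] = (
    Season("spring", frozenset({3, 4, 5})),
    Season("summer", frozenset({6, 7, 8})),
    Season("autumn", frozenset({9, 10, 11})),
    Season("winter", frozenset({12, 1, 2})),
)

SEASON_LABELS: tuple[str, ...] = tuple(s.label for s in SEASONS)
_SEASON_OF_MONTH: dict[int, Season] = {
    m: s for s in SEASONS for m in s.months
}


def season_of(date: _dt.date | str) -> Season:
    """Calendar season of a date: MAM spring, JJA summer, SON autumn,
    DJF winter."""
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValueError(f"invalid ISO date: {date!r}") from exc
    if not isinstance(date, _dt.date):
        raise TypeError(f"expected a date or ISO string, got {type(date)}")
    return _SEASON_OF_MONTH[date.month]


# ---------------------------------------------------------------------------
# Population strata
# ---------------------------------------------------------------------------

AGE_GROUPS = ("adult", "child")
GENDERS = ("male", "female", "total")


@dataclass(frozen=True)
class PopulationStratum:
    """One city x age-group x gender population cell."""

    city: str
    age_group: str
    gender: str

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")

    @property
    def is_child(self) -> bool:
        return self.age_group == "child"


# ---------------------------------------------------------------------------
# Tidy congener table
# ---------------------------------------------------------------------------

TABLE_COLUMNS = (
    "sample_id",
    "city",
    "date",
    "season",
    "congener",
    "conc_ng_m3",
    "below_detection",
    "lod_ng_m3",
)

REQUIRED_COLUMNS = ("sample_id", "city", "date", "congener", "conc_ng_m3")

BELOW_DETECTION_POLICIES = ("half_lod", "zero", "lod_over_sqrt2")


class TableValidationError(ValueError):
    """Raised when a congener table violates its invariants; the message
    lists the offending rows."""


def validate_congener_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and normalize) a tidy congener table.

    Checks the required columns, congener-name dialect (synonyms are
    rewritten to canonical form), non-negative concentrations, uniqueness of
    (sample_id, congener), and consistency of the season column with the
    date's month; a missing/blank season column is derived from the date.
    Returns a normalized copy.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")

    out = df.copy()

    bad_name_rows = []
    canon = []
    for idx, name in out["congener"].items():
        try:
            canon.append(canonical_congener(str(name)))
        except ValueError:
            bad_name_rows.append((idx, name))
            canon.append(None)
    if bad_name_rows:
        raise TableValidationError(f"unknown congener names at rows: {bad_name_rows}")
    out["congener"] = canon

    out["conc_ng_m3"] = pd.to_numeric(out["conc_ng_m3"])
    neg = out.index[out["conc_ng_m3"] < 0].tolist()
    if neg:
        raise TableValidationError(f"negative concentrations at rows: {neg}")

    dup = out.duplicated(subset=["sample_id", "congener"], keep=False)
    if dup.any():
        raise TableValidationError(
            f"duplicate (sample_id, congener) pairs at rows: {out.index[dup].tolist()}"
        )

    derived = out["date"].map(lambda d: season_of(d).label)
    if "season" not in out.columns or out["season"].isna().all():
        out["season"] = derived
    else:
        season_col = out["season"].fillna(derived)
        mismatch = out.index[season_col != derived].tolist()
        if mismatch:
            raise TableValidationError(
                f"season inconsistent with date's month at rows: {mismatch}"
            )
        out["season"] = season_col

    if "below_detection" not in out.columns:
        out["below_detection"] = 0
    out["below_detection"] = pd.to_numeric(out["below_detection"]).astype(int)
    if "lod_ng_m3" not in out.columns:
        out["lod_ng_m3"] = float("nan")
    out["lod_ng_m3"] = pd.to_numeric(out["lod_ng_m3"])

    return out.loc[:, list(TABLE_COLUMNS)].reset_index(drop=True)


def read_congener_table(path: str | Path | StringIO) -> pd.DataFrame:
    """Read and validate a tidy congener-concentration CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "city": str, "date": str})
    return validate_congener_table(df)


def write_congener_table(df: pd.DataFrame, path: str | Path | StringIO) -> None:
    """Write a validated congener table as CSV (lossless round trip with
    :func:`read_congener_table`)."""
    validate_congener_table(df).to_csv(path, index=False)


def apply_detection_policy(df: pd.DataFrame, policy: str = "half_lod") -> pd.DataFrame:
    """Substitute concentrations of below-detection rows.

    half_lod: LOD/2 when a detection limit is supplied, else 0.
    zero: 0. lod_over_sqrt2: LOD/sqrt(2) when supplied, else 0.
    """
    if policy not in BELOW_DETECTION_POLICIES:
        raise ValueError(
            f"policy must be one of {BELOW_DETECTION_POLICIES}, got {policy!r}"
        )
    out = df.copy()
    mask = out["below_detection"].astype(bool)
    if not mask.any():
        return out
    lod = out.loc[mask, "lod_ng_m3"]
    if policy == "zero":
        sub = 0.0 * lod.fillna(0.0)
    elif policy == "half_lod":
        sub = (lod / 2.0).fillna(0.0)
    else:
        sub = (lod / 2.0**0.5).fillna(0.0)
    out.loc[mask, "conc_ng_m3"] = sub
    return out


def sum16(df: pd.DataFrame, by: Iterable[str] = ("sample_id",)) -> pd.Series:
    """Total concentration across the 16 congeners, grouped by ``by``."""
    return df.groupby(list(by), sort=True)["conc_ng_m3"].sum()
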
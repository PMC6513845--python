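"""BaP-equivalent toxicity (TEQ), composition summaries, and diagnostic-ratio
source screening.

TEQ = sum_i C_i * TEF_i over the 16 priority congeners, expressing a PAH
mixture as an equivalent benzo(a)pyrene concentration (TEF(BaP) = 1 by
definition).  Diagnostic ratios (Fle/Pyr, BaP/BghiP, BaP/(BaP+Chr)) computed
on group-mean concentrations flag the dominant emission source by interval
lookup against an editable threshold table.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .congeners import (
    CONGENER_BY_NAME,
    CONGENER_NAMES,
    HIGH_RING_NAMES,
    canonical_congener,
)

__all__ = [
    "TEFTable",
    "nisbet_lagoy_tefs",
    "RatioThresholds",
    "default_ratio_thresholds",
    "compute_teq",
    "summarize_teq",
    "ring_class_fractions",
    "diagnostic_ratios",
    "classify_source",
    "RATIO_NAMES",
]


@dataclass(frozen=True)
class TEFTable:
    """Toxic equivalency factors: congener -> potency relative to BaP."""

    tefs: dict[str, float]
    scheme: str = "custom"
    citation: str = ""

    def __post_init__(self) -> None:
        missing = [n for n in CONGENER_NAMES if n not in self.tefs]
        if missing:
            raise ValueError(f"TEF table missing congeners: {missing}")
        bad = {n: v for n, v in self.tefs.items() if v <= 0}
        if bad:
            raise ValueError(f"TEFs must be positive: {bad}")
        if self.tefs["BaP"] != 1.0:
            raise ValueError("TEF(BaP) must equal 1 by definition")

    def __getitem__(self, congener: str) -> float:
        return self.tefs[canonical_congener(congener)]

    @classmethod
    def from_csv(cls, path: str | Path, scheme: str = "file", citation: str = "") -> "TEFTable":
        df = pd.read_csv(path)
        tefs = {canonical_congener(r.congener): float(r.tef) for r in df.itertuples()}
        return cls(tefs, scheme=scheme, citation=citation)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"congener": list(CONGENER_NAMES), "tef": [self.tefs[n] for n in CONGENER_NAMES]}
        ).to_csv(path, index=False)


def nisbet_lagoy_tefs(dba_tef: float = 1.0) -> TEFTable:
    """The Nisbet & LaGoy (1992) relative-potency scheme.

    The dibenz(a,h)anthracene factor is scheme-ambiguous in the literature
    (1 in common regulatory use, 5 in the original proposal); it is exposed
    as ``dba_tef`` rather than hard-coded.
    """
    tefs = {
        "Nap": 0.001, "Acy": 0.001, "Flu": 0.001, "Ace": 0.001,
        "Phe": 0.001, "Ant": 0.01, "Fle": 0.001, "Pyr": 0.001,
        "Chr": 0.01, "BaA": 0.1, "BbF": 0.1, "BkF": 0.1,
        "BaP": 1.0, "DBA": float(dba_tef), "BghiP": 0.01, "InP": 0.1,
    }
    return TEFTable(tefs, scheme="Nisbet-LaGoy", citation="Nisbet & LaGoy (1992), Regul. Toxicol. Pharmacol. 16:290-300")


# ---------------------------------------------------------------------------
# TEQ
# ---------------------------------------------------------------------------

def compute_teq(table: pd.DataFrame, tefs: TEFTable) -> pd.DataFrame:
    """TEF-weighted BaP-equivalent concentration per sample.

    Returns one row per sample: sample_id, city, date, season, teq_ng_m3.
    Linear in concentrations; units follow the input concentration units.
    """
    missing = sorted(set(table["congener"]) - set(tefs.tefs))
    if missing:
        raise KeyError(f"no TEF for congener(s): {missing}")
    work = table.copy()
    work["_part"] = work["conc_ng_m3"] * work["congener"].map(tefs.tefs)
    out = (
        work.groupby(["sample_id", "city", "date", "season"], sort=True)["_part"]
        .sum()
        .rename("teq_ng_m3")
        .reset_index()
    )
    return out


def summarize_teq(series: pd.DataFrame, by=("city", "season")) -> pd.DataFrame:
    """Arithmetic mean +/- SD (n-1 convention) of TEQ per group.

    ``by`` may be a column tuple or the string 'annual' (group by city only,
    pooling all seasons)."""
    keys = ["city"] if by == "annual" else list(by)
    if series.empty:
        warnings.warn("empty TEQ series: no groups to summarize")
        return pd.DataFrame(columns=keys + ["mean", "sd", "n"])
    g = series.groupby(keys, sort=True)["teq_ng_m3"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    if by == "annual":
        out.insert(1, "season", "annual")
    return out


def ring_class_fractions(table: pd.DataFrame, by=("city", "season")) -> pd.DataFrame:
    """Share of total 16-congener mass carried by 4-6-ring vs 2-3-ring
    congeners, per group.  Shares sum to 1 within each group."""
    if table.empty:
        raise ValueError("empty congener table")
    work = table.copy()
    work["_high"] = work["congener"].isin(HIGH_RING_NAMES)
    g = work.groupby(list(by), sort=True)
    total = g["conc_ng_m3"].sum()
    high = work[work["_high"]].groupby(list(by), sort=True)["conc_ng_m3"].sum()
    high = high.reindex(total.index, fill_value=0.0)
    out = pd.DataFrame(
        {"high_ring_share": high / total, "low_ring_share": 1.0 - high / total}
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Diagnostic ratios
# ---------------------------------------------------------------------------

RATIO_NAMES = ("Fle/Pyr", "BaP/BghiP", "BaP/(BaP+Chr)")


def diagnostic_ratios(table: pd.DataFrame, by: str = "city") -> pd.DataFrame:
    """Source-diagnostic concentration ratios on group-mean concentrations.

    Computed on the mean concentration of each congener within the group
    (not as means of per-sample ratios).  A zero denominator yields NaN
    ('undefined'), never an exception.
    """
    means = (
        table.groupby([by, "congener"], sort=True)["conc_ng_m3"]
        .mean()
        .unstack("congener")
        .reindex(columns=CONGENER_NAMES)
        .fillna(0.0)
    )

    def safe_div(num, den):
        den = den.replace(0.0, np.nan)
        return num / den

    out = pd.DataFrame(
        {
            "Fle/Pyr": safe_div(means["Fle"], means["Pyr"]),
            "BaP/BghiP": safe_div(means["BaP"], means["BghiP"]),
            "BaP/(BaP+Chr)": safe_div(means["BaP"], means["BaP"] + means["Chr"]),
        }
    )
    out.index.name = by
    return out.reset_index()


@dataclass(frozen=True)
class RatioThresholds:
    """Labelled half-open intervals [lo, hi) -> source label, per ratio.

    Intervals within one ratio must not overlap.
    """

    intervals: dict[str, tuple[tuple[float, float, str], ...]]

    def __post_init__(self) -> None:
        for ratio, bands in self.intervals.items():
            ordered = sorted(bands, key=lambda b: b[0])
            for (lo1, hi1, _), (lo2, _, _) in zip(ordered, ordered[1:]):
                if lo2 < hi1:
                    raise ValueError(f"overlapping intervals for ratio {ratio!r}")
            for lo, hi, _ in bands:
                if not lo < hi:
                    raise ValueError(f"empty interval [{lo}, {hi}) for {ratio!r}")

    def lookup(self, ratio: str, value: float) -> str:
        if ratio not in self.intervals:
            raise KeyError(f"no thresholds for ratio {ratio!r}")
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return "undefined"
        for lo, hi, label in self.intervals[ratio]:
            if lo <= value < hi:
                return label
        return "unclassified"

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatioThresholds":
        df = pd.read_csv(path)
        d: dict[str, list] = {}
        for r in df.itertuples():
            d.setdefault(r.ratio, []).append((float(r.lo), float(r.hi), str(r.source_label)))
        return cls({k: tuple(v) for k, v in d.items()})

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"ratio": ratio, "lo": lo, "hi": hi, "source_label": label}
            for ratio, bands in self.intervals.items()
            for lo, hi, label in bands
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_ratio_thresholds() -> RatioThresholds:
    """Literature-style default intervals for the three diagnostic ratios.

    These are documented stand-ins assembled from the PAH source-diagnostic
    literature (e.g. Ravindra et al. 2008, Atmos. Environ. 42:2895); any
    site-specific analysis should supply its own table.
    """
    inf = float("inf")
    return RatioThresholds(
        {
            "Fle/Pyr": (
                (0.0, 1.0, "gasoline emission"),
                (1.0, inf, "coal combustion"),
            ),
            "BaP/BghiP": (
                (0.0, 0.6, "gasoline emission"),
                (0.6, inf, "coal combustion"),
            ),
            "BaP/(BaP+Chr)": (
                (0.0, 0.5, "gasoline emission"),
                (0.5, 1.0 + 1e-12, "coal combustion"),
            ),
        }
    )


def classify_source(
    ratios: pd.DataFrame, thresholds: RatioThresholds
) -> pd.DataFrame:
    """Per-ratio source labels plus a majority-vote consensus per group.

    Undefined / unclassified ratios do not vote; a tie yields 'mixed'; no
    votes yields 'unclassified'.
    """
    key = ratios.columns[0]
    out = ratios[[key]].copy()
    for ratio in RATIO_NAMES:
        out[f"source[{ratio}]"] = [
            thresholds.lookup(ratio, v) for v in ratios[ratio]
        ]

    def consensus(row) -> str:
        votes = [
            row[f"source[{r}]"]
            for r in RATIO_NAMES
            if row[f"source[{r}]"] not in ("undefined", "unclassified")
        ]
        if not votes:
            return "unclassified"
        counts = Counter(votes).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            return "mixed"
        return counts[0][0]

    out["consensus"] = out.apply(consensus, axis=1)
    return out
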
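"""Pittsburgh Sleep Quality Index (PSQI) component scoring.

The PSQI summarizes self-reported sleep over the past month as seven
component scores, each on a 0-3 scale: subjective sleep quality, sleep
latency, sleep duration, habitual sleep efficiency, sleep disturbances,
use of sleeping medication and daytime dysfunction.  Their sum is the
global score (0-21); a global score above 5 is the conventional marker
of poor sleep quality.

This module computes the component scores from raw quantities, the global
score and label, and the analysis transform (``log(x + 1)``) applied to
right-skewed components before continuous twin modelling.  The raw-item to
0-3 cut-points follow the standard published instrument but are exposed as
configurable tables, since scoring dialects differ slightly between
translations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PsqiComponents",
    "sleep_efficiency_percent",
    "efficiency_component",
    "duration_component",
    "global_score",
    "log1_transform",
    "score_component",
    "ScoreBands",
    "read_components_csv",
    "write_components_csv",
]


@dataclass(frozen=True)
class PsqiComponents:
    """The seven 0-3 component scores of one respondent."""

    subjective_quality: int
    latency: int
    duration: int
    efficiency: int
    disturbances: int
    medication: int
    daytime_dysfunction: int

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value not in (0, 1, 2, 3):
                raise ValueError(f"component {name!r} = {value!r} outside 0-3")

    def as_dict(self) -> dict[str, int]:
        return {
            "subjective_quality": self.subjective_quality,
            "latency": self.latency,
            "duration": self.duration,
            "efficiency": self.efficiency,
            "disturbances": self.disturbances,
            "medication": self.medication,
            "daytime_dysfunction": self.daytime_dysfunction,
        }


def sleep_efficiency_percent(hours_slept: float, hours_in_bed: float) -> float:
    """Habitual sleep efficiency: hours asleep / hours in bed x 100.

    Self-reports occasionally claim more sleep than time in bed; the ratio
    is capped at 100 rather than rejected, because only the banded 0-3
    score matters downstream.
    """
    if hours_in_bed <= 0:
        raise ValueError("hours_in_bed must be positive")
    if hours_slept < 0:
        raise ValueError("hours_slept must be nonnegative")
    return min(100.0, 100.0 * hours_slept / hours_in_bed)


@dataclass(frozen=True)
class ScoreBands:
    """Monotone banding of a raw quantity into the 0-3 component scale.

    ``cuts`` are the three boundaries between scores; ``ascending`` means
    larger raw values score *higher* (worse).  A value exactly on a cut
    falls in the worse band for ascending quantities and in the better band
    for descending ones, matching the instrument's ">=" conventions.
    """

    cuts: tuple[float, float, float]
    ascending: bool = True

    def score(self, value: float) -> int:
        if self.ascending:
            return sum(value > c for c in self.cuts)
        return sum(value < c for c in self.cuts)


#: Standard instrument cut-points for the derived components.
DEFAULT_BANDS: dict[str, ScoreBands] = {
    # efficiency %: >=85 -> 0, 75-84 -> 1, 65-74 -> 2, <65 -> 3
    "efficiency": ScoreBands((85.0, 75.0, 65.0), ascending=False),
    # sleep duration hours: >7 -> 0, 6-7 -> 1, 5-6 -> 2, <5 -> 3
    "duration": ScoreBands((7.0, 6.0, 5.0), ascending=False),
    # latency score from minutes-to-sleep item: <=15 -> 0, 16-30 -> 1, 31-60 -> 2, >60 -> 3
    "latency_minutes": ScoreBands((15.0, 30.0, 60.0), ascending=True),
}


def score_component(value: float, bands: ScoreBands) -> int:
    """Band a raw quantity into 0-3 with a configurable cut-point table."""
    return bands.score(value)


def efficiency_component(hours_slept: float, hours_in_bed: float,
                         bands: ScoreBands | None = None) -> int:
    pct = sleep_efficiency_percent(hours_slept, hours_in_bed)
    return (bands or DEFAULT_BANDS["efficiency"]).score(pct)


def duration_component(hours_slept: float, bands: ScoreBands | None = None) -> int:
    if hours_slept < 0:
        raise ValueError("hours_slept must be nonnegative")
    return (bands or DEFAULT_BANDS["duration"]).score(hours_slept)


def global_score(components: PsqiComponents) -> tuple[int, str]:
    """Global PSQI score (0-21) with the adequate/poor label at the >5 cutoff."""
    total = sum(components.as_dict().values())
    return total, ("good" if total <= 5 else "poor")


def log1_transform(x):
    """Natural ``log(x + 1)``, the skew-reducing transform for latency and
    disturbances scores before continuous modelling.

    Monotone, maps 0 to 0.  Accepts scalars or arrays; negative input is an
    error (scores are nonnegative by construction).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("log1_transform requires nonnegative input")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


# -- component-level CSV dialect ------------------------------------------

LONG_COLUMNS = ["family_id", "twin", "zygosity", "sex", "age"]


def write_components_csv(df: pd.DataFrame, path,
                         traits: Sequence[str] | None = None) -> None:
    """Write a long-format component table (one row per individual)."""
    from .datatypes import TRAITS

    traits = list(traits) if traits is not None else [t for t in TRAITS if t in df.columns]
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = df[LONG_COLUMNS + traits].copy()
    if all(np.isin(out[t].dropna(), [0, 1, 2, 3]).all() for t in traits) and len(traits) == 7:
        out["global"] = out[traits].sum(axis=1)
    out.to_csv(path, index=False)


def read_components_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return df
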
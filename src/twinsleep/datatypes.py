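"""Shared containers for twin-pair phenotype data.

The canonical in-memory layout is *wide*: one row per twin pair (family),
with each trait stored once per twin (``<trait>_t1`` / ``<trait>_t2``).
The canonical on-disk layout is *long* (one row per individual), which is
what the scoring module reads and writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Component order used throughout the package (matches the reporting order
#: of the multivariate analyses: latency first, daytime dysfunction last).
TRAITS: tuple[str, ...] = (
    "latency",
    "duration",
    "efficiency",
    "disturbances",
    "sleep_quality",
    "medication",
    "daytime_dysfunction",
)

#: The five zygosity-by-sex groups of the classical twin design.
ZYGOSITY_GROUPS: tuple[str, ...] = ("MZm", "DZm", "MZf", "DZf", "DZo")

MZ_GROUPS = frozenset({"MZm", "MZf"})
DZ_GROUPS = frozenset({"DZm", "DZf", "DZo"})


def is_mz(group: str) -> bool:
    if group not in ZYGOSITY_GROUPS:
        raise ValueError(f"unknown zygosity group {group!r}; expected one of {ZYGOSITY_GROUPS}")
    return group in MZ_GROUPS


@dataclass(frozen=True)
class ComponentSpec:
    """Measurement model of one trait: continuous, or ordinal with k categories."""

    kind: str  # "continuous" | "ordinal"
    n_categories: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if self.kind == "ordinal" and self.n_categories < 2:
            raise ValueError("ordinal traits need at least 2 categories")


#: Default measurement treatment: four components continuous, three
#: (single-item 0-3 ratings) ordinal on a latent liability.
DEFAULT_SPECS: dict[str, ComponentSpec] = {
    "latency": ComponentSpec("continuous"),
    "duration": ComponentSpec("continuous"),
    "efficiency": ComponentSpec("continuous"),
    "disturbances": ComponentSpec("continuous"),
    "sleep_quality": ComponentSpec("ordinal", 4),
    "medication": ComponentSpec("ordinal", 4),
    "daytime_dysfunction": ComponentSpec("ordinal", 4),
}


@dataclass
class TwinPairRecord:
    """One family: phenotypes and covariates for both twins.

    Missing phenotypes (or a fully absent co-twin) are ``nan``.
    """

    family_id: int
    zygosity: str
    sex: tuple[float, float]  # 0 = female, 1 = male; per twin
    age: float
    values: np.ndarray  # shape (2, p) — row 0 twin 1, row 1 twin 2

    def twin_observed(self, twin: int) -> bool:
        return bool(np.any(np.isfinite(self.values[twin])))


class TwinDataset:
    """A cohort of twin pairs with a per-trait measurement specification.

    Parameters
    ----------
    wide
        One row per pair with columns ``family_id``, ``zygosity``,
        ``sex_t1``, ``sex_t2``, ``age`` and ``<trait>_t1``/``<trait>_t2``
        for every trait.
    specs
        Mapping trait name -> :class:`ComponentSpec`.
    """

    def __init__(self, wide: pd.DataFrame, specs: Mapping[str, ComponentSpec],
                 traits: Sequence[str] | None = None):
        self.traits = tuple(traits) if traits is not None else tuple(
            t for t in TRAITS if f"{t}_t1" in wide.columns)
        if not self.traits:
            raise ValueError("no trait columns found")
        missing = [c for c in ("family_id", "zygosity", "age") if c not in wide.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        bad = set(wide["zygosity"]) - set(ZYGOSITY_GROUPS)
        if bad:
            raise ValueError(f"unknown zygosity labels {sorted(bad)}")
        self.specs = {t: specs[t] for t in self.traits}
        for t, s in self.specs.items():
            if s.kind == "ordinal":
                col = pd.concat([wide[f"{t}_t1"], wide[f"{t}_t2"]]).dropna()
                if len(col) and ((col < 0) | (col > s.n_categories - 1)).any():
                    raise ValueError(f"ordinal trait {t!r} has values outside its category range")
        self.wide = wide.reset_index(drop=True)

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.wide)

    @property
    def n_pairs(self) -> int:
        return len(self.wide)

    def iter_records(self) -> Iterator[TwinPairRecord]:
        p = len(self.traits)
        for row in self.wide.itertuples(index=False):
            d = row._asdict()
            vals = np.empty((2, p))
            for j, t in enumerate(self.traits):
                vals[0, j] = d[f"{t}_t1"]
                vals[1, j] = d[f"{t}_t2"]
            yield TwinPairRecord(
                family_id=d["family_id"], zygosity=d["zygosity"],
                sex=(d.get("sex_t1", np.nan), d.get("sex_t2", np.nan)),
                age=d["age"], values=vals)

    def subset_groups(self, groups: Sequence[str]) -> "TwinDataset":
        sub = self.wide[self.wide["zygosity"].isin(groups)]
        return TwinDataset(sub.copy(), self.specs, self.traits)

    def values_matrix(self, zygosity_groups: Sequence[str] | None = None) -> np.ndarray:
        """Stacked (n, 2p) matrix of trait values, twin 1 block then twin 2."""
        df = self.wide if zygosity_groups is None else \
            self.wide[self.wide["zygosity"].isin(zygosity_groups)]
        cols = [f"{t}_t1" for t in self.traits] + [f"{t}_t2" for t in self.traits]
        return df[cols].to_numpy(float)

    # -- serialization ----------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long layout: one row per individual (the on-disk CSV dialect)."""
        rows = []
        for twin in (1, 2):
            cols = {f"{t}_t{twin}": t for t in self.traits}
            part = self.wide[["family_id", "zygosity", "age"] + list(cols)].rename(columns=cols)
            part.insert(1, "twin", twin)
            sex_col = f"sex_t{twin}"
            part.insert(4, "sex", self.wide[sex_col] if sex_col in self.wide else np.nan)
            rows.append(part)
        long = pd.concat(rows, ignore_index=True)
        long = long[long[list(self.traits)].notna().any(axis=1) | (long["twin"] == 1)]
        return long.sort_values(["family_id", "twin"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, long: pd.DataFrame, specs: Mapping[str, ComponentSpec] | None = None,
                  traits: Sequence[str] | None = None) -> "TwinDataset":
        if traits is not None:
            traits = tuple(traits)
        else:
            traits = tuple(t for t in TRAITS if t in long.columns)
            if not traits:  # non-standard trait names: take the leftover columns
                reserved = {"family_id", "twin", "zygosity", "sex", "age", "global"}
                traits = tuple(c for c in long.columns if c not in reserved)
        if specs is not None:
            specs = dict(specs)
        else:
            # infer per trait: integer-valued 0-3 columns are ordinal scores,
            # anything else (e.g. liability-scale output) is continuous
            specs = {}
            for t in traits:
                vals = long[t].dropna().to_numpy(float)
                integral = len(vals) > 0 and np.allclose(vals, np.round(vals))
                if integral and vals.min() >= 0 and vals.max() <= 3:
                    specs[t] = ComponentSpec("ordinal", 4)
                else:
                    specs[t] = ComponentSpec("continuous")
        parts = []
        for twin in (1, 2):
            sub = long[long["twin"] == twin].set_index("family_id")
            ren = {t: f"{t}_t{twin}" for t in traits}
            ren["sex"] = f"sex_t{twin}"
            parts.append(sub[["zygosity", "age", "sex", *traits]].rename(columns=ren))
        wide = parts[0].join(parts[1][[f"{t}_t2" for t in traits] + ["sex_t2"]], how="left")
        wide["zygosity"] = wide["zygosity"].astype(str)
        return cls(wide.reset_index(), specs, traits)

    @classmethod
    def from_csv(cls, path, specs: Mapping[str, ComponentSpec] | None = None) -> "TwinDataset":
        return cls.from_long(pd.read_csv(path), specs)
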
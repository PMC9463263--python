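"""Covariance algebra of the classical twin design.

A phenotype vector observed on both members of a twin pair has expected
covariance built from additive-genetic (A), shared-environment (C) or
dominance (D), and non-shared environment (E) components.  MZ co-twins
share all additive and dominance effects; DZ co-twins share them with
coefficients 1/2 and 1/4.  C is shared fully by both zygosities; E is
never shared.

Components here follow the *direct symmetric* parameterization: each
component is a free symmetric matrix (not a Cholesky product), so an
individual component may be indefinite during estimation — only the total
phenotypic covariance is required positive (semi)definite.  This avoids
the boundary bias and distorted type-I error of constrained
parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import is_mz

__all__ = [
    "VarianceComponents",
    "expected_covariance",
    "standardize",
    "etiological_correlations",
    "decompose_phenotypic_correlation",
    "decomposition_table",
    "components_from_standardized",
]

#: cross-twin sharing coefficients (additive, dominance) by zygosity class
_ADDITIVE_SHARE = {"MZ": 1.0, "DZ": 0.5}
_DOMINANCE_SHARE = {"MZ": 1.0, "DZ": 0.25}

KINDS = ("ACE", "ADE", "AE", "CE", "E")


def _sym(name: str, m: np.ndarray, p: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (p, p):
        raise ValueError(f"{name} must be {p}x{p}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (m + m.T)


@dataclass
class VarianceComponents:
    """A/C-or-D/E covariance matrices over p traits.

    ``kind`` determines which components exist and how the middle one is
    shared across co-twins (C: fully in both zygosities; D: fully in MZ,
    one quarter in DZ).
    """

    kind: str
    A: np.ndarray | None
    CorD: np.ndarray | None
    E: np.ndarray
    trait_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {KINDS}")
        p = np.asarray(self.E).shape[0]
        self.E = _sym("E", self.E, p)
        if self.kind in ("ACE", "ADE", "AE"):
            if self.A is None:
                raise ValueError(f"kind {self.kind} requires an A matrix")
            self.A = _sym("A", self.A, p)
        elif self.A is not None:
            raise ValueError(f"kind {self.kind} admits no A matrix")
        if self.kind in ("ACE", "ADE", "CE"):
            if self.CorD is None:
                raise ValueError(f"kind {self.kind} requires a C/D matrix")
            self.CorD = _sym("CorD", self.CorD, p)
        elif self.CorD is not None:
            raise ValueError(f"kind {self.kind} admits no C/D matrix")
        if not self.trait_names:
            self.trait_names = tuple(f"trait{i + 1}" for i in range(p))
        if len(self.trait_names) != p:
            raise ValueError("trait_names length mismatch")

    # -- conveniences -----------------------------------------------------
    @property
    def p(self) -> int:
        return self.E.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Phenotypic covariance Sigma = A + C/D + E."""
        sigma = self.E.copy()
        if self.A is not None:
            sigma += self.A
        if self.CorD is not None:
            sigma += self.CorD
        return sigma

    def component(self, which: str) -> np.ndarray | None:
        return {"A": self.A, "CorD": self.CorD, "E": self.E}[which]

    @property
    def uses_dominance(self) -> bool:
        return self.kind == "ADE"


def expected_covariance(vc: VarianceComponents, zygosity: str) -> np.ndarray:
    """Expected 2p x 2p covariance of a twin pair's stacked phenotypes.

    Within-twin blocks are the full phenotypic covariance; the cross-twin
    block carries A with coefficient 1 (MZ) or 1/2 (DZ), C with 1, and D
    with 1 (MZ) or 1/4 (DZ).
    """
    zclass = "MZ" if is_mz(zygosity) else "DZ"
    within = vc.total
    cross = np.zeros_like(within)
    if vc.A is not None:
        cross = cross + _ADDITIVE_SHARE[zclass] * vc.A
    if vc.CorD is not None:
        share = _DOMINANCE_SHARE[zclass] if vc.uses_dominance else 1.0
        cross = cross + share * vc.CorD
    return np.block([[within, cross], [cross, within]])


def standardize(vc: VarianceComponents) -> pd.DataFrame:
    """Per-trait standardized variance shares h2, c2/d2, e2 (rows sum to 1)."""
    sigma = vc.total
    diag = np.diag(sigma)
    if np.any(diag <= 0):
        bad = [vc.trait_names[i] for i in np.flatnonzero(diag <= 0)]
        raise ValueError(f"degenerate traits with non-positive total variance: {bad}")
    out = {"h2": (np.diag(vc.A) / diag) if vc.A is not None else np.zeros(vc.p)}
    mid = "d2" if vc.uses_dominance else "c2"
    out[mid] = (np.diag(vc.CorD) / diag) if vc.CorD is not None else np.zeros(vc.p)
    out["e2"] = np.diag(vc.E) / diag
    return pd.DataFrame(out, index=list(vc.trait_names))


@dataclass
class CorrelationMatrices:
    """Etiological correlation matrices; entries undefined when a trait has
    zero variance in that component are flagged rather than silently NaN."""

    rA: np.ndarray | None
    rCorD: np.ndarray | None
    rE: np.ndarray
    undefined: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _component_correlation(mat: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    d = np.diag(mat).copy()
    if np.any(d < -1e-12):
        raise ValueError("negative component variance: correlation undefined")
    bad_traits = np.flatnonzero(d <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(d, d))
        r = np.where(denom > 0, mat / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(r, 1.0)
    undefined = [(int(i), int(j)) for i in bad_traits for j in range(len(d)) if i != j]
    return r, undefined


def etiological_correlations(vc: VarianceComponents) -> CorrelationMatrices:
    """Correlations of the latent A, C/D and E influences across traits.

    rA_ij = A_ij / sqrt(A_ii A_jj) and analogously for the other
    components; values of +-1 mean the influences on the two traits
    overlap completely, 0 means no overlap.
    """
    undefined: dict[str, list[tuple[int, int]]] = {}
    rA = rC = None
    if vc.A is not None:
        rA, undefined["rA"] = _component_correlation(vc.A)
    if vc.CorD is not None:
        rC, undefined["rCorD"] = _component_correlation(vc.CorD)
    rE, undefined["rE"] = _component_correlation(vc.E)
    return CorrelationMatrices(rA=rA, rCorD=rC, rE=rE,
                               undefined={k: v for k, v in undefined.items() if v})


@dataclass(frozen=True)
class BivariateDecomposition:
    """Decomposition of one phenotypic correlation into A and E parts."""

    contribA: float
    contribE: float
    rPH: float
    propA: float | None
    propE: float | None
    signed_only: bool  # True when shares are not reportable as proportions


def decompose_phenotypic_correlation(h2_i: float, h2_j: float, e2_i: float, e2_j: float,
                                     rA_ij: float, rE_ij: float) -> BivariateDecomposition:
    """Split a phenotypic correlation into genetic and environmental parts.

    contribA = rA * sqrt(h2_i h2_j) is the standardized genetic covariance
    (the "bivariate heritability" numerator); rPH = contribA + contribE.
    When both contributions share rPH's sign they are also reported as
    proportions of rPH.  When they have opposite signs a proportion would
    exceed 1 or change sign, so only the signed contributions are reported.
    """
    for name, v in (("h2_i", h2_i), ("h2_j", h2_j), ("e2_i", e2_i), ("e2_j", e2_j)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    for name, v in (("rA_ij", rA_ij), ("rE_ij", rE_ij)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    contribA = rA_ij * np.sqrt(h2_i * h2_j)
    contribE = rE_ij * np.sqrt(e2_i * e2_j)
    rph = contribA + contribE
    opposite = contribA * contribE < 0
    if rph == 0 or opposite:
        return BivariateDecomposition(contribA, contribE, rph, None, None,
                                      signed_only=bool(opposite or contribA != 0))
    return BivariateDecomposition(contribA, contribE, rph,
                                  propA=contribA / rph, propE=contribE / rph,
                                  signed_only=False)


def decomposition_table(vc: VarianceComponents) -> pd.DataFrame:
    """Full pairwise decomposition over an AE-family model.

    One row per unordered trait pair with the etiological correlations,
    model-implied phenotypic correlation, signed contributions and (when
    well defined) the A/E shares.  Per-trait h2/e2 are read off
    :func:`standardize`.
    """
    if vc.CorD is not None:
        raise ValueError("decomposition_table covers A/E decompositions; drop C/D first")
    std = standardize(vc)
    corr = etiological_correlations(vc)
    rows = []
    for i in range(vc.p):
        for j in range(i):
            dec = decompose_phenotypic_correlation(
                std["h2"].iloc[i], std["h2"].iloc[j],
                std["e2"].iloc[i], std["e2"].iloc[j],
                corr.rA[i, j] if corr.rA is not None else 0.0, corr.rE[i, j])
            rows.append({
                "trait_i": vc.trait_names[i], "trait_j": vc.trait_names[j],
                "rA": corr.rA[i, j] if corr.rA is not None else np.nan,
                "rE": corr.rE[i, j], "rPH": dec.rPH,
                "contribA": dec.contribA, "contribE": dec.contribE,
                "propA": np.nan if dec.propA is None else dec.propA,
                "propE": np.nan if dec.propE is None else dec.propE,
                "signed_only": dec.signed_only,
            })
    return pd.DataFrame(rows)


def components_from_standardized(h2: Sequence[float], rA: np.ndarray, rE: np.ndarray,
                                 trait_names: Sequence[str] = ()) -> VarianceComponents:
    """Build unit-variance AE components from heritabilities and etiological
    correlations (the algebraic inverse of standardize + correlations)."""
    h2 = np.asarray(h2, dtype=float)
    e2 = 1.0 - h2
    if np.any(h2 < 0) or np.any(h2 > 1):
        raise ValueError("h2 outside [0, 1]")
    A = np.asarray(rA, float) * np.sqrt(np.outer(h2, h2))
    E = np.asarray(rE, float) * np.sqrt(np.outer(e2, e2))
    return VarianceComponents("AE", A=A, CorD=None, E=E,
                              trait_names=tuple(trait_names) or ())
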
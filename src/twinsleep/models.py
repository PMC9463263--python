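"""Builders for the fitted model family.

* free multivariate ACE / ADE / AE / CE / E models in the direct
  symmetric parameterization;
* the common pathway model (one latent phenotype, or the three-factor
  efficiency / perceived-quality / daily-disturbances clustering, with
  its own A and E transmitted to the traits through loadings, plus
  trait-specific residual A and E);
* the independent pathway model (one common A and one common E factor
  loading directly on the traits, plus trait-specific residuals);
* a selection driver that fits a model set and tabulates -2LL, AIC and
  likelihood-ratio tests.

Every specification exposes the same surface consumed by
:func:`twinsleep.likelihood.fit`: ``param_names`` / ``bounds`` /
``start`` / ``unpack`` and, where analytic gradients are available,
``backward``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .biometric import VarianceComponents
from .datatypes import ComponentSpec, TwinDataset, TRAITS
from .likelihood import FitResult, MeanThresholdModel, compare, fit

__all__ = [
    "build_multivariate",
    "build_common_pathway",
    "build_independent_pathway",
    "build_univariate_standardized",
    "COLE_FACTORS",
    "selection_driver",
]

#: Cole's three-factor clustering of the seven components.
COLE_FACTORS: dict[str, tuple[str, ...]] = {
    "sleep_efficiency": ("duration", "efficiency"),
    "perceived_quality": ("sleep_quality", "latency", "medication"),
    "daily_disturbances": ("disturbances", "daytime_dysfunction"),
}

_COMPONENTS_BY_KIND = {
    "ACE": ("A", "CorD"), "ADE": ("A", "CorD"), "AE": ("A",), "CE": ("CorD",), "E": (),
}

_BOUND_OFFDIAG = (-10.0, 10.0)
_BOUND_DIAG = (-10.0, 10.0)
_BOUND_EDIAG = (1e-4, 50.0)
_BOUND_MEAN = (-50.0, 50.0)
_BOUND_TAU1 = (-6.0, 6.0)
_BOUND_DTAU = (1e-3, 6.0)
_BOUND_BETA = (-10.0, 10.0)
_BOUND_SPEC = (0.0, 10.0)
_BOUND_ESPEC = (1e-6, 50.0)
_BOUND_LOAD = (-10.0, 10.0)
_BOUND_LOAD_POS = (0.0, 10.0)
_BOUND_UNIT = (0.0, 1.0)
_BOUND_FCORR = (-0.95, 0.95)


class _ParamTable:
    """Ordered parameter bookkeeping: names, bounds, index lookup."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.bounds: list[tuple[float, float]] = []

    def add(self, name: str, bound: tuple[float, float]) -> int:
        self.names.append(name)
        self.bounds.append(bound)
        return len(self.names) - 1

    def index(self, name: str) -> int:
        return self.names.index(name)


def _pooled_start_cov(data: TwinDataset, traits: Sequence[str],
                      specs: Mapping[str, ComponentSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-twin covariance and means used for starting values.

    Ordinal columns are rescaled to unit variance (their liability scale).
    """
    frames = []
    for twin in (1, 2):
        frames.append(data.wide[[f"{t}_t{twin}" for t in traits]]
                      .set_axis(list(traits), axis=1))
    pooled = pd.concat(frames, ignore_index=True)
    s = pooled.cov().to_numpy()
    s = np.where(np.isfinite(s), s, 0.0)
    means = pooled.mean().to_numpy()
    scale = np.ones(len(traits))
    for i, t in enumerate(traits):
        if specs[t].kind == "ordinal" and s[i, i] > 0:
            scale[i] = 1.0 / np.sqrt(s[i, i])
    s = s * np.outer(scale, scale)
    d = np.diag(s).copy()
    d[d <= 1e-6] = 1.0
    np.fill_diagonal(s, d)
    return s, means


def _threshold_starts(data: TwinDataset, trait: str, n_cat: int) -> np.ndarray:
    both = pd.concat([data.wide[f"{trait}_t1"], data.wide[f"{trait}_t2"]]).dropna()
    cum = np.array([(both <= k).mean() for k in range(n_cat - 1)])
    tau = ndtri(np.clip(cum, 0.01, 0.99))
    for i in range(1, len(tau)):
        tau[i] = max(tau[i], tau[i - 1] + 0.05)
    return tau


@dataclass
class _MeasurementLayout:
    """Mean / threshold / covariate parameter block shared by all specs."""

    traits: tuple[str, ...]
    specs: dict[str, ComponentSpec]
    include_covariates: bool
    mean_idx: dict[str, int] = field(default_factory=dict)
    tau_idx: dict[str, list[int]] = field(default_factory=dict)
    beta_idx: dict[str, tuple[int, int]] = field(default_factory=dict)

    def register(self, table: _ParamTable) -> None:
        for t in self.traits:
            if self.specs[t].kind == "continuous":
                self.mean_idx[t] = table.add(f"mean_{t}", _BOUND_MEAN)
        for t in self.traits:
            if self.specs[t].kind == "ordinal":
                idx = [table.add(f"tau1_{t}", _BOUND_TAU1)]
                for k in range(2, self.specs[t].n_categories):
                    idx.append(table.add(f"dtau{k}_{t}", _BOUND_DTAU))
                self.tau_idx[t] = idx
        if self.include_covariates:
            for t in self.traits:
                self.beta_idx[t] = (table.add(f"bage_{t}", _BOUND_BETA),
                                    table.add(f"bsex_{t}", _BOUND_BETA))

    def unpack(self, theta: np.ndarray) -> MeanThresholdModel:
        p = len(self.traits)
        mu = np.zeros(p)
        for t, k in self.mean_idx.items():
            mu[self.traits.index(t)] = theta[k]
        thresholds = {}
        for t, idx in self.tau_idx.items():
            raw = theta[idx]
            thresholds[t] = np.concatenate([[raw[0]], raw[0] + np.cumsum(raw[1:])]) \
                if len(raw) > 1 else raw.copy()
        ba = np.zeros(p)
        bs = np.zeros(p)
        for t, (ia, isx) in self.beta_idx.items():
            j = self.traits.index(t)
            ba[j], bs[j] = theta[ia], theta[isx]
        return MeanThresholdModel(mu, ba, bs, thresholds)

    def fill_start(self, theta: np.ndarray, data: TwinDataset, means: np.ndarray) -> None:
        for t, k in self.mean_idx.items():
            theta[k] = means[self.traits.index(t)]
        for t, idx in self.tau_idx.items():
            tau = _threshold_starts(data, t, self.specs[t].n_categories)
            theta[idx[0]] = tau[0]
            for j in range(1, len(idx)):
                theta[idx[j]] = max(tau[j] - tau[j - 1], 0.05)


class _BaseSpec:
    """Common plumbing for model specifications."""

    name: str
    kind: str
    traits: tuple[str, ...]
    specs: dict[str, ComponentSpec]
    include_covariates: bool

    def __init__(self, traits, specs, include_covariates):
        self.traits = tuple(traits)
        self.specs = {t: (specs[t] if specs else ComponentSpec("continuous"))
                      for t in self.traits} if specs is not None else \
            {t: ComponentSpec("continuous") for t in self.traits}
        self.include_covariates = bool(include_covariates)
        self.table = _ParamTable()
        self.layout = _MeasurementLayout(self.traits, self.specs, self.include_covariates)

    @property
    def p(self) -> int:
        return len(self.traits)

    @property
    def has_ordinal(self) -> bool:
        return any(s.kind == "ordinal" for s in self.specs.values())

    @property
    def param_names(self) -> list[str]:
        return self.table.names

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return self.table.bounds

    def is_ordinal(self, t: str) -> bool:
        return self.specs[t].kind == "ordinal"

    backward = None  # analytic gradient hook; set by subclasses where available


class MultivariateSpec(_BaseSpec):
    """Free symmetric A / C-or-D / E matrices over p traits.

    For ordinal traits the liability variance is identified at one: the E
    diagonal entry is substituted as 1 minus the other components'
    diagonals rather than estimated.
    """

    def __init__(self, kind: str, traits=TRAITS, specs=None, include_covariates=False,
                 name: str | None = None):
        if kind not in _COMPONENTS_BY_KIND:
            raise ValueError(f"unknown model kind {kind!r}")
        super().__init__(traits, specs, include_covariates)
        self.kind = kind
        self.name = name or f"multivariate_{kind}"
        self.comp_idx: dict[str, dict[tuple[int, int], int]] = {}
        for comp in (*_COMPONENTS_BY_KIND[kind], "E"):
            idx = {}
            for i in range(self.p):
                for j in range(i, self.p):
                    if comp == "E" and i == j and self.is_ordinal(self.traits[i]):
                        continue  # substituted for unit liability variance
                    bound = _BOUND_EDIAG if (comp == "E" and i == j) else (
                        _BOUND_DIAG if i == j else _BOUND_OFFDIAG)
                    idx[(i, j)] = self.table.add(f"{comp}_{self.traits[i]}_{self.traits[j]}",
                                                 bound)
            self.comp_idx[comp] = idx
        self.layout.register(self.table)

    def _matrices(self, theta: np.ndarray) -> dict[str, np.ndarray | None]:
        mats: dict[str, np.ndarray | None] = {"A": None, "CorD": None}
        for comp, idx in self.comp_idx.items():
            m = np.zeros((self.p, self.p))
            for (i, j), k in idx.items():
                m[i, j] = m[j, i] = theta[k]
            mats[comp] = m
        for i, t in enumerate(self.traits):
            if self.is_ordinal(t):
                other = sum(mats[c][i, i] for c in _COMPONENTS_BY_KIND[self.kind])
                mats["E"][i, i] = 1.0 - other
        return mats

    def unpack(self, theta: np.ndarray):
        mats = self._matrices(theta)
        vc = VarianceComponents(self.kind, A=mats["A"], CorD=mats["CorD"], E=mats["E"],
                                trait_names=self.traits)
        return vc, self.layout.unpack(theta)

    def backward(self, theta, w_a, w_c, w_e, grad_mu):
        g = np.zeros(len(self.table.names))
        wmap = {"A": w_a, "CorD": w_c, "E": w_e}
        for comp, idx in self.comp_idx.items():
            w = wmap[comp]
            for (i, j), k in idx.items():
                g[k] = w[i, i] if i == j else w[i, j] + w[j, i]
        for t, k in self.layout.mean_idx.items():
            g[k] = grad_mu[self.traits.index(t)]
        return g

    def start(self, data: TwinDataset) -> np.ndarray:
        s, means = _pooled_start_cov(data, self.traits, self.specs)
        frac = {"ACE": {"A": 0.3, "CorD": 0.2, "E": 0.5},
                "ADE": {"A": 0.3, "CorD": 0.2, "E": 0.5},
                "AE": {"A": 0.4, "E": 0.6},
                "CE": {"CorD": 0.3, "E": 0.7},
                "E": {"E": 1.0}}[self.kind]
        theta = np.zeros(len(self.table.names))
        for comp, idx in self.comp_idx.items():
            for (i, j), k in idx.items():
                theta[k] = frac[comp] * s[i, j]
        self.layout.fill_start(theta, data, means)
        return theta


class IndependentPathwaySpec(_BaseSpec):
    """One common A and one common E factor loading directly on the traits,
    plus trait-specific residual A and E variances.

    Sign indeterminacy is resolved by forcing the first loading of each
    common factor nonnegative.  For ordinal traits the specific E variance
    is substituted for unit liability variance.
    """

    kind = "AE"

    def __init__(self, traits=TRAITS, specs=None, include_covariates=False):
        super().__init__(traits, specs, include_covariates)
        self.name = "independent_pathway_AE"
        self.a_idx = [self.table.add(f"a_load_{t}", _BOUND_LOAD_POS if i == 0 else _BOUND_LOAD)
                      for i, t in enumerate(self.traits)]
        self.e_idx = [self.table.add(f"e_load_{t}", _BOUND_LOAD_POS if i == 0 else _BOUND_LOAD)
                      for i, t in enumerate(self.traits)]
        self.as_idx = [self.table.add(f"a_spec_{t}", _BOUND_SPEC) for t in self.traits]
        self.es_idx = [self.table.add(f"e_spec_{t}", _BOUND_ESPEC)
                       for t in self.traits if not self.is_ordinal(t)]
        self._es_map = {t: i for i, t in enumerate(t for t in self.traits
                                                   if not self.is_ordinal(t))}
        self.layout.register(self.table)

    def _parts(self, theta):
        a = theta[self.a_idx]
        e = theta[self.e_idx]
        a_s = theta[self.as_idx]
        e_s = np.empty(self.p)
        for i, t in enumerate(self.traits):
            if self.is_ordinal(t):
                e_s[i] = 1.0 - a[i] ** 2 - e[i] ** 2 - a_s[i]
            else:
                e_s[i] = theta[self.es_idx[self._es_map[t]]]
        return a, e, a_s, e_s

    def unpack(self, theta: np.ndarray):
        a, e, a_s, e_s = self._parts(theta)
        A = np.outer(a, a) + np.diag(a_s)
        E = np.outer(e, e) + np.diag(e_s)
        vc = VarianceComponents("AE", A=A, CorD=None, E=E, trait_names=self.traits)
        return vc, self.layout.unpack(theta)

    def backward(self, theta, w_a, w_c, w_e, grad_mu):
        a, e, _, _ = self._parts(theta)
        g = np.zeros(len(self.table.names))
        g[self.a_idx] = (w_a + w_a.T) @ a
        g[self.e_idx] = (w_e + w_e.T) @ e
        g[self.as_idx] = np.diag(w_a)
        for t, j in self._es_map.items():
            g[self.es_idx[j]] = w_e[self.traits.index(t), self.traits.index(t)]
        for t, k in self.layout.mean_idx.items():
            g[k] = grad_mu[self.traits.index(t)]
        return g

    def start(self, data: TwinDataset) -> np.ndarray:
        s, means = _pooled_start_cov(data, self.traits, self.specs)
        vals, vecs = np.linalg.eigh(s)
        common = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-3))
        if common[0] < 0:
            common = -common
        resid = np.clip(np.diag(s) - common ** 2, 0.05, None)
        theta = np.zeros(len(self.table.names))
        theta[self.a_idx] = common * np.sqrt(0.4)
        theta[self.e_idx] = common * np.sqrt(0.6)
        theta[self.as_idx] = 0.4 * resid
        for t, j in self._es_map.items():
            theta[self.es_idx[j]] = 0.6 * resid[self.traits.index(t)]
        self.layout.fill_start(theta, data, means)
        return theta


class CommonPathwaySpec(_BaseSpec):
    """Latent-phenotype (common pathway) model.

    Each latent factor has unit variance split into additive-genetic and
    non-shared-environment parts (``latent_a2`` and its complement), and
    transmits to its assigned traits through free loadings; each trait
    keeps specific A and E residual variances.  The three-factor variant
    optionally correlates the factors' A parts and E parts.
    """

    kind = "AE"

    def __init__(self, factors: Mapping[str, Sequence[str]], traits=TRAITS, specs=None,
                 include_covariates=False, factor_correlations=True, name=None):
        super().__init__(traits, specs, include_covariates)
        self.factors = {f: tuple(ts) for f, ts in factors.items()}
        assigned = [t for ts in self.factors.values() for t in ts]
        if sorted(assigned) != sorted(self.traits):
            missing = set(self.traits) - set(assigned)
            extra = set(assigned) - set(self.traits)
            raise ValueError(f"factor assignment mismatch: missing={sorted(missing)}, "
                             f"unknown={sorted(extra)}")
        self.n_factors = len(self.factors)
        self.name = name or ("common_pathway_1f" if self.n_factors == 1
                             else f"common_pathway_{self.n_factors}f")
        self.factor_of = {t: fi for fi, ts in enumerate(self.factors.values()) for t in ts}
        self.first_of_factor = {fi: ts[0] for fi, ts in enumerate(self.factors.values())}

        self.a2_idx = [self.table.add(f"latent_a2_{f}", _BOUND_UNIT) for f in self.factors]
        self.lam_idx = []
        for t in self.traits:
            first = self.first_of_factor[self.factor_of[t]] == t
            self.lam_idx.append(self.table.add(f"lambda_{t}",
                                               _BOUND_LOAD_POS if first else _BOUND_LOAD))
        self.fcorr_a_idx: dict[tuple[int, int], int] = {}
        self.fcorr_e_idx: dict[tuple[int, int], int] = {}
        if self.n_factors > 1 and factor_correlations:
            fnames = list(self.factors)
            for i in range(self.n_factors):
                for j in range(i + 1, self.n_factors):
                    self.fcorr_a_idx[(i, j)] = self.table.add(
                        f"ra_{fnames[i]}_{fnames[j]}", _BOUND_FCORR)
                    self.fcorr_e_idx[(i, j)] = self.table.add(
                        f"re_{fnames[i]}_{fnames[j]}", _BOUND_FCORR)
        self.as_idx = [self.table.add(f"a_spec_{t}", _BOUND_SPEC) for t in self.traits]
        self.es_idx = [self.table.add(f"e_spec_{t}", _BOUND_ESPEC)
                       for t in self.traits if not self.is_ordinal(t)]
        self._es_map = {t: i for i, t in enumerate(t for t in self.traits
                                                   if not self.is_ordinal(t))}
        self.layout.register(self.table)
        if self.n_factors == 1:
            self.backward = self._backward_1f  # type: ignore[assignment]

    def _lambda_matrix(self, theta) -> np.ndarray:
        lam = np.zeros((self.p, self.n_factors))
        for i, t in enumerate(self.traits):
            lam[i, self.factor_of[t]] = theta[self.lam_idx[i]]
        return lam

    def _factor_cov(self, theta) -> tuple[np.ndarray, np.ndarray]:
        a2 = np.clip(theta[self.a2_idx], 0.0, 1.0)
        e2 = 1.0 - a2
        ra = np.eye(self.n_factors)
        re = np.eye(self.n_factors)
        for (i, j), k in self.fcorr_a_idx.items():
            ra[i, j] = ra[j, i] = theta[k]
        for (i, j), k in self.fcorr_e_idx.items():
            re[i, j] = re[j, i] = theta[k]
        b_a = np.sqrt(np.outer(a2, a2)) * ra
        b_e = np.sqrt(np.outer(e2, e2)) * re
        return b_a, b_e

    def _parts(self, theta):
        lam = self._lambda_matrix(theta)
        b_a, b_e = self._factor_cov(theta)
        a_s = theta[self.as_idx]
        common_var = np.einsum("if,fg,ig->i", lam, b_a + b_e, lam)
        e_s = np.empty(self.p)
        for i, t in enumerate(self.traits):
            if self.is_ordinal(t):
                e_s[i] = 1.0 - common_var[i] - a_s[i]
            else:
                e_s[i] = theta[self.es_idx[self._es_map[t]]]
        return lam, b_a, b_e, a_s, e_s

    def unpack(self, theta: np.ndarray):
        lam, b_a, b_e, a_s, e_s = self._parts(theta)
        A = lam @ b_a @ lam.T + np.diag(a_s)
        E = lam @ b_e @ lam.T + np.diag(e_s)
        vc = VarianceComponents("AE", A=A, CorD=None, E=E, trait_names=self.traits)
        return vc, self.layout.unpack(theta)

    def _backward_1f(self, theta, w_a, w_c, w_e, grad_mu):
        lam = theta[self.lam_idx]
        a2 = float(np.clip(theta[self.a2_idx[0]], 0.0, 1.0))
        g = np.zeros(len(self.table.names))
        wa_s = w_a + w_a.T
        we_s = w_e + w_e.T
        g[self.a2_idx[0]] = float(lam @ w_a @ lam) - float(lam @ w_e @ lam)
        g[self.lam_idx] = a2 * (wa_s @ lam) + (1.0 - a2) * (we_s @ lam)
        g[self.as_idx] = np.diag(w_a)
        for t, j in self._es_map.items():
            g[self.es_idx[j]] = w_e[self.traits.index(t), self.traits.index(t)]
        for t, k in self.layout.mean_idx.items():
            g[k] = grad_mu[self.traits.index(t)]
        return g

    def start(self, data: TwinDataset) -> np.ndarray:
        s, means = _pooled_start_cov(data, self.traits, self.specs)
        theta = np.zeros(len(self.table.names))
        theta[self.a2_idx] = 0.3
        vals, vecs = np.linalg.eigh(s)
        common = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-3))
        for fi, first_trait in self.first_of_factor.items():
            sign = np.sign(common[self.traits.index(first_trait)]) or 1.0
            for i, t in enumerate(self.traits):
                if self.factor_of[t] == fi:
                    theta[self.lam_idx[i]] = sign * common[i]
        for k in (*self.fcorr_a_idx.values(), *self.fcorr_e_idx.values()):
            theta[k] = 0.3
        resid = np.clip(np.diag(s) - common ** 2, 0.05, None)
        theta[self.as_idx] = 0.4 * resid
        for t, j in self._es_map.items():
            theta[self.es_idx[j]] = 0.6 * resid[self.traits.index(t)]
        self.layout.fill_start(theta, data, means)
        return theta


class UnivariateStandardizedSpec(_BaseSpec):
    """Univariate AE model with (h2, total variance, mean) as parameters.

    A reparameterization of the univariate model in which the
    heritability is itself a free parameter, so that profile-likelihood
    intervals for h2 come straight from the generic profiler.
    """

    kind = "AE"

    def __init__(self, trait: str = "trait", spec: ComponentSpec | None = None,
                 include_covariates=False):
        super().__init__((trait,), {trait: spec or ComponentSpec("continuous")},
                         include_covariates)
        self.name = "univariate_AE_standardized"
        self.h2_idx = self.table.add("h2", _BOUND_UNIT)
        self.var_idx = None
        if not self.is_ordinal(trait):
            self.var_idx = self.table.add("total_var", (1e-4, 50.0))
        self.layout.register(self.table)

    def unpack(self, theta: np.ndarray):
        h2 = float(np.clip(theta[self.h2_idx], 0.0, 1.0))
        v = float(theta[self.var_idx]) if self.var_idx is not None else 1.0
        vc = VarianceComponents("AE", A=np.array([[h2 * v]]), CorD=None,
                                E=np.array([[(1.0 - h2) * v]]), trait_names=self.traits)
        return vc, self.layout.unpack(theta)

    def backward(self, theta, w_a, w_c, w_e, grad_mu):
        h2 = float(theta[self.h2_idx])
        v = float(theta[self.var_idx]) if self.var_idx is not None else 1.0
        g = np.zeros(len(self.table.names))
        g[self.h2_idx] = v * (w_a[0, 0] - w_e[0, 0])
        if self.var_idx is not None:
            g[self.var_idx] = h2 * w_a[0, 0] + (1.0 - h2) * w_e[0, 0]
        for t, k in self.layout.mean_idx.items():
            g[k] = grad_mu[0]
        return g

    def start(self, data: TwinDataset) -> np.ndarray:
        s, means = _pooled_start_cov(data, self.traits, self.specs)
        theta = np.zeros(len(self.table.names))
        theta[self.h2_idx] = 0.4
        if self.var_idx is not None:
            theta[self.var_idx] = max(s[0, 0], 1e-3)
        self.layout.fill_start(theta, data, means)
        return theta


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def build_multivariate(kind: str, traits: Sequence[str] = TRAITS,
                       specs: Mapping[str, ComponentSpec] | None = None,
                       include_covariates: bool = False) -> MultivariateSpec:
    """Free multivariate model of the given kind (ACE, ADE, AE, CE or E)."""
    return MultivariateSpec(kind, traits, specs, include_covariates)


def build_common_pathway(structure: str | Mapping[str, Sequence[str]] = "one_factor",
                         traits: Sequence[str] = TRAITS,
                         specs: Mapping[str, ComponentSpec] | None = None,
                         include_covariates: bool = False,
                         factor_correlations: bool = True) -> CommonPathwaySpec:
    """Common pathway model: ``"one_factor"``, ``"cole"`` (the three-factor
    efficiency / perceived-quality / daily-disturbances clustering), or an
    explicit factor -> traits mapping."""
    if structure == "one_factor":
        factors = {"sleep_quality_factor": tuple(traits)}
    elif structure == "cole":
        factors = COLE_FACTORS
    else:
        factors = structure
    return CommonPathwaySpec(factors, traits, specs, include_covariates, factor_correlations)


def build_independent_pathway(traits: Sequence[str] = TRAITS,
                              specs: Mapping[str, ComponentSpec] | None = None,
                              include_covariates: bool = False) -> IndependentPathwaySpec:
    if len(traits) < 2:
        raise ValueError("independent pathway model needs at least 2 traits")
    return IndependentPathwaySpec(traits, specs, include_covariates)


def build_univariate_standardized(trait: str = "trait",
                                  spec: ComponentSpec | None = None) -> UnivariateStandardizedSpec:
    return UnivariateStandardizedSpec(trait, spec)


# ---------------------------------------------------------------------------
# warm starts along the nesting chain
# ---------------------------------------------------------------------------

def _copy_measurement(src_spec, src_theta, dst_spec, dst_theta) -> None:
    for t, k in dst_spec.layout.mean_idx.items():
        dst_theta[k] = src_theta[src_spec.layout.mean_idx[t]]
    for t, idx in dst_spec.layout.tau_idx.items():
        for a, b in zip(idx, src_spec.layout.tau_idx[t]):
            dst_theta[a] = src_theta[b]
    for t, (ia, isx) in dst_spec.layout.beta_idx.items():
        ja, js = src_spec.layout.beta_idx[t]
        dst_theta[ia], dst_theta[isx] = src_theta[ja], src_theta[js]


def ip_start_from_cp(cp_fit: FitResult, ip_spec: IndependentPathwaySpec) -> np.ndarray:
    """Map a fitted one-factor common-pathway optimum into the independent-
    pathway parameterization (the common-pathway covariance is exactly
    representable there, so the -2LL carries over)."""
    cp: CommonPathwaySpec = cp_fit.model
    if cp.n_factors != 1:
        raise ValueError("warm start mapping is defined for the one-factor model")
    lam = cp_fit.theta[cp.lam_idx]
    a2 = float(np.clip(cp_fit.theta[cp.a2_idx[0]], 0.0, 1.0))
    theta = np.zeros(len(ip_spec.param_names))
    a = np.sqrt(a2) * lam
    e = np.sqrt(1.0 - a2) * lam
    if a[0] < 0:
        a = -a
    if e[0] < 0:
        e = -e
    theta[ip_spec.a_idx] = a
    theta[ip_spec.e_idx] = e
    theta[ip_spec.as_idx] = cp_fit.theta[cp.as_idx]
    for t, j in ip_spec._es_map.items():
        theta[ip_spec.es_idx[j]] = cp_fit.theta[cp.es_idx[cp._es_map[t]]]
    _copy_measurement(cp, cp_fit.theta, ip_spec, theta)
    return theta


def mv_start_from_ip(ip_fit: FitResult, mv_spec: MultivariateSpec) -> np.ndarray:
    """Map a fitted independent-pathway optimum into the free multivariate
    AE parameterization (again an exact embedding)."""
    ip: IndependentPathwaySpec = ip_fit.model
    a, e, a_s, e_s = ip._parts(ip_fit.theta)
    A = np.outer(a, a) + np.diag(a_s)
    E = np.outer(e, e) + np.diag(e_s)
    theta = np.zeros(len(mv_spec.param_names))
    for (i, j), k in mv_spec.comp_idx["A"].items():
        theta[k] = A[i, j]
    for (i, j), k in mv_spec.comp_idx["E"].items():
        theta[k] = E[i, j]
    _copy_measurement(ip, ip_fit.theta, mv_spec, theta)
    return theta


# ---------------------------------------------------------------------------
# selection driver
# ---------------------------------------------------------------------------

#: parent model used for the likelihood-ratio test of each member
_LRT_PARENT = {
    "multivariate_AE": ("multivariate_ACE", "multivariate_ADE"),
    "multivariate_CE": ("multivariate_ACE",),
    "multivariate_E": ("multivariate_AE", "multivariate_CE"),
    "independent_pathway_AE": ("multivariate_AE",),
    "common_pathway_1f": ("independent_pathway_AE",),
    "common_pathway_3f": ("multivariate_AE",),
}


def selection_driver(data: TwinDataset, models: Sequence[str] | None = None,
                     seed: int = 0, include_covariates: bool = False,
                     n_restarts: int = 1) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit a model set and tabulate -2LL, AIC, and LRTs along the nesting
    chain.

    The default set follows the study design: the ACE-or-ADE screen from
    the cross-twin correlations picks the three-component model, then AE,
    CE, E submodels and the AE pathway models.  Pathway fits are chained:
    the common-pathway optimum warm-starts the independent-pathway fit,
    which warm-starts the free multivariate fit, so the -2LL ordering
    multivariate <= independent <= common is honoured by construction.
    """
    from .simulate import cross_twin_correlations

    if models is None:
        ctc = cross_twin_correlations(data)
        prefer_ace = (ctc["rDZ"] > 0.5 * ctc["rMZ"]).mean() >= 0.5
        three = "ACE" if prefer_ace else "ADE"
        models = [f"multivariate_{three}", "multivariate_AE", "multivariate_CE",
                  "multivariate_E"]
        if len(data.traits) >= 2:
            models += ["common_pathway_1f", "independent_pathway_AE"]

    traits, specs = data.traits, data.specs
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}

    def _fit(name: str, spec, **kw):
        try:
            fits[name] = fit(spec, data, seed=seed, n_restarts=n_restarts, **kw)
        except RuntimeError as exc:  # pragma: no cover - defensive
            failures[name] = str(exc)

    for name in models:
        if name.startswith("multivariate_") and name != "multivariate_AE":
            _fit(name, build_multivariate(name.split("_")[1], traits, specs,
                                          include_covariates))
    if "common_pathway_1f" in models:
        _fit("common_pathway_1f",
             build_common_pathway("one_factor", traits, specs, include_covariates))
    if "common_pathway_3f" in models:
        _fit("common_pathway_3f",
             build_common_pathway("cole", traits, specs, include_covariates))
    if "independent_pathway_AE" in models:
        ip_spec = build_independent_pathway(traits, specs, include_covariates)
        _fit("independent_pathway_AE", ip_spec)
        cp = fits.get("common_pathway_1f")
        if cp is not None and "independent_pathway_AE" in fits:
            warm = fit(ip_spec, data, seed=seed, n_restarts=0,
                       start=ip_start_from_cp(cp, ip_spec))
            if warm.minus2ll < fits["independent_pathway_AE"].minus2ll:
                fits["independent_pathway_AE"] = warm
    if "multivariate_AE" in models:
        mv_spec = build_multivariate("AE", traits, specs, include_covariates)
        _fit("multivariate_AE", mv_spec)
        ip = fits.get("independent_pathway_AE")
        if ip is not None and "multivariate_AE" in fits:
            warm = fit(mv_spec, data, seed=seed, n_restarts=0,
                       start=mv_start_from_ip(ip, mv_spec))
            if warm.minus2ll < fits["multivariate_AE"].minus2ll:
                fits["multivariate_AE"] = warm

    rows = []
    aic_min = min((f.aic for f in fits.values()), default=np.nan)
    for name in models:
        if name in failures:
            rows.append({"model": name, "failed": True, "error": failures[name]})
            continue
        f = fits[name]
        row = {"model": name, "failed": False, "minus2ll": f.minus2ll,
               "n_params": f.n_params, "aic": f.aic, "delta_aic": f.aic - aic_min,
               "lrt_vs": "", "chi2": np.nan, "df": np.nan, "p": np.nan}
        for parent in _LRT_PARENT.get(name, ()):
            if parent in fits:
                try:
                    cmp_res = compare(fits[parent], f)
                except RuntimeError:
                    continue
                row.update({"lrt_vs": parent, "chi2": cmp_res.chi2,
                            "df": cmp_res.df, "p": cmp_res.p_value})
                break
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    return table, fits
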
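"""Full-information maximum likelihood for twin-pair data.

Each pair contributes the likelihood of its *observed* phenotypes under
the expected twin covariance for its zygosity: continuous traits enter
through the multivariate-normal density, ordinal traits through the
probability of the liability rectangle between their thresholds,
conditional on the observed continuous traits.  A pair with a missing
co-twin contributes the marginal single-twin likelihood, so incomplete
pairs need no imputation.

Two evaluation paths exist:

* a general per-pair path handling any mix of continuous and ordinal
  traits, covariates and missingness (deterministic rectangle
  probabilities from :mod:`twinsleep.mvnorm`);
* a fast sufficient-statistic path for all-continuous models without
  covariates, which groups pairs by zygosity class and missingness
  pattern and supplies analytic gradients.

Optimization is bounded quasi-Newton (L-BFGS-B) with seed-controlled
jittered restarts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.stats import chi2 as chi2_dist

from .biometric import VarianceComponents, expected_covariance
from .datatypes import ComponentSpec, TwinDataset, TwinPairRecord, is_mz
from .mvnorm import rect_prob, DEFAULT_LATTICE_SIZE

__all__ = [
    "MeanThresholdModel",
    "FitResult",
    "pair_loglik",
    "dataset_minus2ll",
    "fit",
    "compare",
    "confidence_intervals",
    "profile_interval",
]

#: log-likelihood assigned to a pair when Sigma is not PSD at the tested
#: parameters: large, finite, optimizer-safe.
PAIR_PENALTY = -1.0e8

#: -2LL returned by the fast path on a non-PSD Sigma.
OBJECTIVE_PENALTY = 1.0e12

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MeanThresholdModel:
    """Mean and threshold structure over p traits.

    Continuous traits have a free intercept; ordinal traits have liability
    mean fixed at zero (identification) with covariates shifting the mean,
    and strictly increasing thresholds.  ``beta_age`` expects the age
    covariate already rescaled to [0, 1].
    """

    intercepts: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, float)
        self.beta_age = np.asarray(self.beta_age, float)
        self.beta_sex = np.asarray(self.beta_sex, float)
        for t, tau in self.thresholds.items():
            tau = np.asarray(tau, float)
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"thresholds for {t!r} must be strictly increasing")
            self.thresholds[t] = tau

    def pair_means(self, record: TwinPairRecord, p: int) -> np.ndarray:
        """Stacked 2p mean vector for one pair (twin 1 block then twin 2)."""
        mu = np.empty(2 * p)
        for twin in (0, 1):
            sex = record.sex[twin]
            sex = 0.0 if sex is None or not np.isfinite(sex) else float(sex)
            mu[twin * p:(twin + 1) * p] = (
                self.intercepts + self.beta_age * record.age + self.beta_sex * sex)
        return mu


def _category_limits(tau: np.ndarray, category: int) -> tuple[float, float]:
    k = int(category)
    lo = -np.inf if k == 0 else tau[k - 1]
    hi = np.inf if k >= len(tau) else tau[k]
    return lo, hi


def pair_loglik(record: TwinPairRecord, vc: VarianceComponents, mt: MeanThresholdModel,
                specs: Mapping[str, ComponentSpec], n_points: int = DEFAULT_LATTICE_SIZE,
                flags: list | None = None) -> float:
    """Log-likelihood contribution of one twin pair.

    Continuous observed values contribute a multivariate-normal log
    density; ordinal values contribute the log rectangle probability of
    the liability distribution conditional on the continuous values.
    Missing entries (NaN) are marginalized out.  A non-PSD covariance at
    the evaluated parameters yields a large finite penalty (recorded in
    ``flags`` when provided).
    """
    p = vc.p
    sigma = expected_covariance(vc, record.zygosity)
    mu = mt.pair_means(record, p)
    x = record.values.reshape(-1)  # stacked twin1, twin2

    observed = np.isfinite(x)
    if not observed.any():
        return 0.0
    kinds = [specs[t].kind for t in vc.trait_names]
    cont = observed & np.array([kinds[i % p] == "continuous" for i in range(2 * p)])
    ordn = observed & ~cont
    ci = np.flatnonzero(cont)
    oi = np.flatnonzero(ordn)

    ll = 0.0
    if len(ci):
        s_cc = sigma[np.ix_(ci, ci)]
        try:
            chol = cho_factor(s_cc, lower=True)
        except LinAlgError:
            if flags is not None:
                flags.append(("non_psd", record.family_id))
            return PAIR_PENALTY
        dev = x[ci] - mu[ci]
        quad = float(dev @ cho_solve(chol, dev))
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        ll += -0.5 * (len(ci) * _LOG_2PI + logdet + quad)

    if len(oi):
        if len(ci):
            s_cc_inv_soc = cho_solve(chol, sigma[np.ix_(ci, oi)])
            mean_o = mu[oi] + (x[ci] - mu[ci]) @ s_cc_inv_soc
            cov_o = sigma[np.ix_(oi, oi)] - sigma[np.ix_(oi, ci)] @ s_cc_inv_soc
        else:
            mean_o = mu[oi]
            cov_o = sigma[np.ix_(oi, oi)]
        if np.any(np.diag(cov_o) <= 0):
            if flags is not None:
                flags.append(("non_psd_conditional", record.family_id))
            return PAIR_PENALTY
        lower = np.empty(len(oi))
        upper = np.empty(len(oi))
        for k, idx in enumerate(oi):
            trait = vc.trait_names[idx % p]
            lower[k], upper[k] = _category_limits(mt.thresholds[trait], x[idx])
        prob = rect_prob(lower, upper, mean_o, cov_o, n_points=n_points)
        if not prob > 0:
            prob = 1e-300
        ll += float(np.log(prob))
    return ll


def dataset_minus2ll(model, data: TwinDataset, theta: np.ndarray,
                     n_points: int = DEFAULT_LATTICE_SIZE) -> float:
    """-2 log-likelihood of ``data`` at parameter vector ``theta``."""
    vc, mt = model.unpack(np.asarray(theta, float))
    records = _prepare_records(model, data)
    total = 0.0
    for rec in records:
        total += pair_loglik(rec, vc, mt, model.specs, n_points=n_points)
    return -2.0 * total


# ---------------------------------------------------------------------------
# fast path: sufficient statistics per (zygosity class, missingness pattern)
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    zclass: str                 # "MZ" | "DZ"
    idx: np.ndarray             # observed positions in the stacked 2p vector
    n: int
    xbar: np.ndarray
    scatter: np.ndarray         # sum (x - xbar)(x - xbar)^T


def _build_patterns(data: TwinDataset) -> list[_Pattern]:
    x = data.values_matrix()
    zclass = np.where(data.wide["zygosity"].map(is_mz), "MZ", "DZ")
    patterns: list[_Pattern] = []
    masks = np.isfinite(x)
    keys = [(z, m.tobytes()) for z, m in zip(zclass, masks)]
    order = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)
    for (z, _), rows in order.items():
        mask = masks[rows[0]]
        if not mask.any():
            continue
        sub = x[np.ix_(rows, np.flatnonzero(mask))]
        xbar = sub.mean(axis=0)
        dev = sub - xbar
        patterns.append(_Pattern(z, np.flatnonzero(mask), len(rows), xbar, dev.T @ dev))
    return patterns


def _fast_objective(model, data: TwinDataset):
    """-2LL and analytic gradient via per-pattern sufficient statistics."""
    patterns = _build_patterns(data)
    p = len(model.traits)

    def value_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        vc, mt = model.unpack(theta)
        sig = {z: expected_covariance(vc, "MZm" if z == "MZ" else "DZm") for z in ("MZ", "DZ")}
        mu_full = np.concatenate([mt.intercepts, mt.intercepts])
        f = 0.0
        # dF/dSigma_full accumulated per zygosity class, and dF/dmu (stacked)
        g_sigma = {z: np.zeros((2 * p, 2 * p)) for z in ("MZ", "DZ")}
        g_mu = np.zeros(2 * p)
        for pat in patterns:
            s = sig[pat.zclass][np.ix_(pat.idx, pat.idx)]
            try:
                chol = cho_factor(s, lower=True)
            except LinAlgError:
                return OBJECTIVE_PENALTY, np.zeros_like(theta)
            d = len(pat.idx)
            dev = pat.xbar - mu_full[pat.idx]
            s_inv = cho_solve(chol, np.eye(d))
            m_mat = pat.scatter + pat.n * np.outer(dev, dev)
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            f += pat.n * (d * _LOG_2PI + logdet) + float(np.sum(s_inv * m_mat))
            g_small = pat.n * s_inv - s_inv @ m_mat @ s_inv
            g_sigma[pat.zclass][np.ix_(pat.idx, pat.idx)] += g_small
            g_mu[pat.idx] += -2.0 * pat.n * (s_inv @ dev)

        # contract dF/dSigma into per-component W matrices:
        # Sigma = [[T, cX],[cX, T]] with T = A + CorD + E and component-
        # specific cross coefficients c per zygosity class.
        w = {"A": np.zeros((p, p)), "CorD": np.zeros((p, p)), "E": np.zeros((p, p))}
        for z in ("MZ", "DZ"):
            gz = g_sigma[z]
            within = gz[:p, :p] + gz[p:, p:]
            cross = gz[:p, p:] + gz[p:, :p].T
            w["E"] += within
            if vc.A is not None:
                w["A"] += within + (1.0 if z == "MZ" else 0.5) * cross
            if vc.CorD is not None:
                share = (1.0 if z == "MZ" else 0.25) if vc.uses_dominance else 1.0
                w["CorD"] += within + share * cross
        grad_mu_trait = g_mu[:p] + g_mu[p:]
        grad = model.backward(theta, w["A"], w["CorD"], w["E"], grad_mu_trait)
        return f, grad

    return value_and_grad


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one dataset."""

    model_name: str
    param_names: tuple[str, ...]
    theta: np.ndarray
    minus2ll: float
    n_params: int
    aic: float
    converged: bool
    n_pairs_used: int
    message: str = ""
    n_penalized: int = 0
    confidence_intervals: dict[str, tuple[float, float]] | None = None
    # non-serialized handles used for profiling / derived statistics
    model: object | None = field(default=None, repr=False)
    _objective: Callable | None = field(default=None, repr=False)
    _bounds: list | None = field(default=None, repr=False)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.theta)))

    def components(self) -> VarianceComponents:
        return self.model.unpack(self.theta)[0]

    def mean_thresholds(self) -> MeanThresholdModel:
        return self.model.unpack(self.theta)[1]

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model_name,
            "minus2ll": self.minus2ll,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_pairs_used": self.n_pairs_used,
            "message": self.message,
            "estimates": self.estimates,
            "confidence_intervals": self.confidence_intervals,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _prepare_records(model, data: TwinDataset) -> list[TwinPairRecord]:
    records = list(data.iter_records())
    if getattr(model, "include_covariates", False):
        ages = np.array([r.age for r in records], float)
        lo, hi = np.nanmin(ages), np.nanmax(ages)
        span = (hi - lo) if hi > lo else 1.0
        for r in records:
            r.age = (r.age - lo) / span
    else:
        for r in records:
            r.age = 0.0
    return records


def fit(model, data: TwinDataset, seed: int = 0, n_restarts: int = 2,
        start: np.ndarray | None = None, n_points: int = DEFAULT_LATTICE_SIZE,
        maxiter: int = 3000) -> FitResult:
    """Fit a model specification by FIML.

    Multi-start: the model's data-driven start plus ``n_restarts`` jittered
    copies (seed-controlled); the best converged optimum is returned.  The
    result carries an internal handle for profile-likelihood intervals.
    """
    rng = np.random.default_rng(seed)
    use_fast = (not model.has_ordinal) and (not model.include_covariates)
    if use_fast:
        vg = _fast_objective(model, data)
        func = lambda th: vg(th)  # noqa: E731
        jac = True
    else:
        records = _prepare_records(model, data)

        def func(th):
            vc, mt = model.unpack(th)
            flags: list = []
            ll = sum(pair_loglik(r, vc, mt, model.specs, n_points=n_points, flags=flags)
                     for r in records)
            return -2.0 * ll

        jac = None

    starts = [model.start(data) if start is None else np.asarray(start, float)]
    lo = np.array([b[0] for b in model.bounds], float)
    hi = np.array([b[1] for b in model.bounds], float)
    for _ in range(n_restarts):
        jit = starts[0] + rng.normal(scale=0.05, size=len(starts[0])) * (
            1.0 + np.abs(starts[0]))
        starts.append(np.clip(jit, lo + 1e-9, hi - 1e-9))

    best = None
    for th0 in starts:
        res = optimize.minimize(
            func, th0, jac=jac, method="L-BFGS-B", bounds=model.bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{model.name}: optimization failed from all starts")

    n_pairs = int(np.isfinite(data.values_matrix()).any(axis=1).sum())
    k = len(model.param_names)
    minus2ll = float(best.fun)
    result = FitResult(
        model_name=model.name, param_names=tuple(model.param_names),
        theta=np.asarray(best.x, float), minus2ll=minus2ll, n_params=k,
        aic=minus2ll + 2.0 * k, converged=bool(best.success),
        n_pairs_used=n_pairs, message=str(best.message), model=model,
        _objective=func if not use_fast else (lambda th: vg(th)[0]),
        _bounds=list(model.bounds))
    if use_fast:
        result._objective_grad = vg  # type: ignore[attr-defined]
    return result


@dataclass(frozen=True)
class ComparisonResult:
    chi2: float
    df: int
    p_value: float
    delta_aic: float


def compare(full: FitResult, nested: FitResult, tol: float = 1e-6) -> ComparisonResult:
    """Likelihood-ratio test of a nested model against a fuller one.

    ``chi2`` = -2LL(nested) - (-2LL(full)); a materially negative value
    means the fuller model's optimizer stopped short and a refit is needed.
    """
    if nested.n_params > full.n_params:
        raise ValueError("nested model must not have more parameters than the full model")
    chi2 = nested.minus2ll - full.minus2ll
    df = full.n_params - nested.n_params
    if chi2 < -tol * (1.0 + abs(full.minus2ll)):
        raise RuntimeError(
            f"LRT chi2 = {chi2:.3g} < 0: the full model ({full.model_name}) is "
            f"under-optimized relative to {nested.model_name}; refit needed")
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(chi2_dist.sf(chi2, df))
    if df == 0 and chi2 <= tol:
        p = 1.0
    return ComparisonResult(chi2, df, p, nested.aic - full.aic)


# ---------------------------------------------------------------------------
# profile-likelihood intervals
# ---------------------------------------------------------------------------

def profile_interval(profile_fn: Callable[[float], float], mle: float, m2ll_min: float,
                     level: float = 0.95, lower_bound: float = -np.inf,
                     upper_bound: float = np.inf,
                     max_expand: int = 40) -> tuple[float, float, dict[str, bool]]:
    """Invert a profile -2LL curve around the MLE at the given level.

    Searches outward on each side for the value where the profile rises by
    the chi-square(1) quantile, then refines by root bracketing.  A side
    that hits its box bound below the cutoff is reported at the bound with
    a boundary flag; an unbracketed side on an open box is flagged open.
    """
    target = m2ll_min + float(chi2_dist.ppf(level, 1))
    flags = {"lower_at_boundary": False, "upper_at_boundary": False, "open": False}
    out = []
    for side, bound, key in ((-1.0, lower_bound, "lower_at_boundary"),
                             (+1.0, upper_bound, "upper_at_boundary")):
        step = max(0.05 * (1.0 + abs(mle)), 1e-3)
        inside = mle
        found = None
        for _ in range(max_expand):
            candidate = inside + side * step
            hit_bound = (side < 0 and candidate <= bound) or (side > 0 and candidate >= bound)
            if hit_bound:
                candidate = bound
            val = profile_fn(candidate)
            if val >= target:
                found = optimize.brentq(lambda v: profile_fn(v) - target, inside, candidate,
                                        xtol=1e-6) if candidate != inside else candidate
                break
            if hit_bound:
                flags[key] = True
                found = bound
                break
            inside = candidate
            step *= 1.7
        if found is None:
            flags["open"] = True
            found = inside
        out.append(found)
    lo, hi = sorted(out)
    return float(lo), float(hi), flags


def _profiled_m2ll(fit_result: FitResult, k: int) -> Callable[[float], float]:
    """Profile -2LL over parameter k, re-optimizing all others."""
    model = fit_result.model
    obj = fit_result._objective
    grad_obj = getattr(fit_result, "_objective_grad", None)
    free = [i for i in range(len(fit_result.theta)) if i != k]
    bounds = [fit_result._bounds[i] for i in free]

    def prof(value: float) -> float:
        if not free:
            return obj(np.array([value]))

        def sub(th_free):
            th = fit_result.theta.copy()
            th[free] = th_free
            th[k] = value
            if grad_obj is not None:
                f, g = grad_obj(th)
                return f, g[free]
            return obj(th)

        res = optimize.minimize(sub, fit_result.theta[free],
                                jac=True if grad_obj is not None else None,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-11})
        return float(res.fun)

    return prof


def confidence_intervals(fit_result: FitResult, names: Sequence[str],
                         level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Profile-likelihood confidence bounds for named free parameters.

    Derived quantities (h2 of a standardized univariate model, etc.) are
    profiled by fitting a reparameterized model in which they are free
    parameters; see :func:`twinsleep.models.build_univariate_standardized`.
    """
    if not fit_result.converged:
        raise ValueError("confidence intervals require a converged fit")
    out: dict[str, tuple[float, float]] = {}
    for name in names:
        k = fit_result.param_names.index(name)
        lo_b, hi_b = fit_result._bounds[k]
        lo_b = -np.inf if lo_b is None else lo_b
        hi_b = np.inf if hi_b is None else hi_b
        lo, hi, flags = profile_interval(
            _profiled_m2ll(fit_result, k), float(fit_result.theta[k]),
            fit_result.minus2ll, level, lo_b, hi_b)
        out[name] = (lo, hi)
    if fit_result.confidence_intervals is None:
        fit_result.confidence_intervals = {}
    fit_result.confidence_intervals.update(out)
    return out
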
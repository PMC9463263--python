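"""Phenotypic confirmatory factor analysis of the seven components.

Fitted on one randomly selected twin per pair (complete cases), treating
the component scores as continuous and maximizing the Wishart likelihood
of the sample covariance matrix.  Competing structures: the original
single factor, the single factor with correlated residuals between
duration/efficiency and latency/efficiency, and the three-factor
clustering (sleep efficiency, perceived sleep quality, daily
disturbances).  All fit indices are computed from first principles so
their conventions are explicit: RMSEA uses n - 1, the BIC is on the
chi-square deviance scale, SRMR covers off-diagonal residual
correlations only, and the CFI/TLI baseline is the independence model
with free variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import ncx2

from .datatypes import TwinDataset

__all__ = [
    "CfaSpec",
    "FitIndices",
    "CfaResult",
    "ONE_FACTOR",
    "ONE_FACTOR_RESIDUALS",
    "COLE_THREE_FACTOR",
    "select_one_twin_per_pair",
    "fit_cfa",
    "fit_indices",
    "srmr",
]


@dataclass(frozen=True)
class CfaSpec:
    """A confirmatory factor structure.

    ``loading_pattern`` maps each trait to its factor; ``residual_pairs``
    lists trait pairs given a free residual covariance;
    ``factor_correlations`` frees the factor correlation matrix (always
    true for multi-factor structures unless explicitly fixed).
    """

    name: str
    loading_pattern: Mapping[str, str]
    residual_pairs: tuple[tuple[str, str], ...] = ()
    factor_correlations: bool = True

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.residual_pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) in residual_pairs")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate residual pair ({a}, {b})")
            seen.add(key)

    @property
    def factors(self) -> tuple[str, ...]:
        out: list[str] = []
        for f in self.loading_pattern.values():
            if f not in out:
                out.append(f)
        return tuple(out)


def _one_factor(traits: Sequence[str]) -> dict[str, str]:
    return {t: "sleep_quality_factor" for t in traits}


ONE_FACTOR = CfaSpec("one_factor", _one_factor(
    ("latency", "duration", "efficiency", "disturbances", "sleep_quality",
     "medication", "daytime_dysfunction")))

#: single factor plus residual covariances for the structurally linked
#: pairs (duration feeds the efficiency ratio; latency eats into duration)
ONE_FACTOR_RESIDUALS = CfaSpec(
    "one_factor_residual_corr", ONE_FACTOR.loading_pattern,
    residual_pairs=(("duration", "efficiency"), ("latency", "efficiency")))

COLE_THREE_FACTOR = CfaSpec("cole_three_factor", {
    "duration": "sleep_efficiency", "efficiency": "sleep_efficiency",
    "sleep_quality": "perceived_quality", "latency": "perceived_quality",
    "medication": "perceived_quality",
    "disturbances": "daily_disturbances", "daytime_dysfunction": "daily_disturbances",
})


def select_one_twin_per_pair(data: TwinDataset, seed: int) -> pd.DataFrame:
    """One randomly selected twin per family, complete cases only.

    Families where only one twin responded contribute that twin
    deterministically; the coin flip (reproducible from ``seed``) applies
    to complete pairs.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    traits = list(data.traits)
    pick = rng.integers(1, 3, size=len(data))  # 1 or 2 per family
    rows = []
    for i, row in enumerate(data.wide.itertuples(index=False)):
        d = row._asdict()
        have = [tw for tw in (1, 2)
                if all(np.isfinite(d[f"{t}_t{tw}"]) for t in traits)]
        if not have:
            continue
        tw = pick[i] if pick[i] in have else have[0]
        rows.append({"family_id": d["family_id"], "twin": tw,
                     "zygosity": d["zygosity"], "age": d["age"],
                     "sex": d.get(f"sex_t{tw}", np.nan),
                     **{t: d[f"{t}_t{tw}"] for t in traits}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    n_obs: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    cfi: float
    tli: float
    bic: float


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """RMSEA confidence bounds by inverting the noncentral chi-square."""
    alpha = (1.0 - level) / 2.0

    def solve(prob: float) -> float:
        # find noncentrality with ncx2.cdf(chi2; df, nc) == prob
        if ncx2.cdf(chi2, df, 0.0) < prob:
            return 0.0
        hi = max(chi2, 1.0)
        while ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2.0
            if hi > 1e7:
                break
        return float(optimize.brentq(lambda nc: ncx2.cdf(chi2, df, nc) - prob, 0.0, hi))

    lam_lo = solve(1.0 - alpha)
    lam_hi = solve(alpha)
    denom = df * (n - 1)
    return (float(np.sqrt(max(lam_lo, 0.0) / denom)),
            float(np.sqrt(max(lam_hi, 0.0) / denom)))


def fit_indices(chi2: float, df: int, chi2_baseline: float, df_baseline: int,
                n_obs: int, n_params: int, srmr_value: float = np.nan) -> FitIndices:
    """Approximate-fit indices from the test statistics.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))); CFI compares the
    excess chi-square with the baseline's; TLI rescales by degrees of
    freedom (truncated at 1); BIC = chi2 + n_params ln(n) on the deviance
    scale.  SRMR is computed from residual correlations by :func:`srmr`
    and passed through here.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    if df_baseline < df:
        raise ValueError("baseline model cannot have fewer df than the target model")
    if n_obs <= 1:
        raise ValueError("need n_obs > 1")
    excess = max(chi2 - df, 0.0)
    excess_b = max(chi2_baseline - df_baseline, 0.0)
    rmsea = float(np.sqrt(excess / (df * (n_obs - 1))))
    cfi = 1.0 - excess / max(excess_b, excess, np.finfo(float).tiny)
    ratio_b = chi2_baseline / df_baseline
    tli = ((ratio_b - chi2 / df) / (ratio_b - 1.0)) if ratio_b > 1.0 else 1.0
    tli = min(tli, 1.0)
    bic = chi2 + n_params * np.log(n_obs)
    return FitIndices(chi2=float(chi2), df=int(df), chi2_baseline=float(chi2_baseline),
                      df_baseline=int(df_baseline), n_obs=int(n_obs),
                      rmsea=rmsea, rmsea_ci=_rmsea_ci(chi2, df, n_obs),
                      srmr=float(srmr_value), cfi=float(cfi), tli=float(tli),
                      bic=float(bic))


def srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Root-mean-square of the off-diagonal residual correlations."""
    d_s = np.sqrt(np.diag(sample_cov))
    d_i = np.sqrt(np.diag(implied_cov))
    r_s = sample_cov / np.outer(d_s, d_s)
    r_i = implied_cov / np.outer(d_i, d_i)
    iu = np.triu_indices_from(r_s, k=1)
    resid = r_s[iu] - r_i[iu]
    return float(np.sqrt(np.mean(resid ** 2)))


# ---------------------------------------------------------------------------
# maximum-likelihood CFA
# ---------------------------------------------------------------------------

@dataclass
class CfaResult:
    spec: CfaSpec
    loadings: pd.DataFrame          # trait x factor
    factor_corr: pd.DataFrame
    residual_cov: np.ndarray
    implied_cov: np.ndarray
    sample_cov: np.ndarray
    indices: FitIndices
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return self.loadings


def _fml(sample_cov: np.ndarray, implied: np.ndarray) -> float:
    """ML discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - p."""
    p = sample_cov.shape[0]
    sign_i, logdet_i = np.linalg.slogdet(implied)
    sign_s, logdet_s = np.linalg.slogdet(sample_cov)
    if sign_i <= 0:
        return 1e10
    return float(logdet_i + np.trace(sample_cov @ np.linalg.inv(implied))
                 - logdet_s - p)


def fit_cfa(spec: CfaSpec, table: pd.DataFrame | None = None, *,
            sample_cov: np.ndarray | None = None, n_obs: int | None = None,
            traits: Sequence[str] | None = None) -> CfaResult:
    """Maximum-likelihood CFA of the component covariance matrix.

    Accepts either a single-respondent table (complete cases, one row per
    person) or a precomputed covariance matrix with its sample size.
    Factors are identified by unit variance; the chi-square statistic is
    (n - 1) times the minimized ML discrepancy.
    """
    if table is not None:
        traits = list(traits) if traits is not None else \
            [t for t in spec.loading_pattern if t in table.columns]
        sub = table[traits].dropna()
        n_obs = len(sub)
        sample_cov = np.cov(sub.to_numpy(float), rowvar=False, ddof=1)
    elif sample_cov is None or n_obs is None or traits is None:
        raise ValueError("pass either a table or (sample_cov, n_obs, traits)")
    traits = list(traits)
    p = len(traits)
    sample_cov = np.asarray(sample_cov, float)
    if np.linalg.eigvalsh(sample_cov).min() <= 0:
        raise ValueError("sample covariance is not positive definite")
    factors = spec.factors
    q = len(factors)
    f_idx = {f: k for k, f in enumerate(factors)}
    t_idx = {t: i for i, t in enumerate(traits)}
    for f in factors:
        if sum(1 for t in traits if spec.loading_pattern[t] == f) < 2:
            raise ValueError(f"factor {f!r} reaches fewer than 2 traits")

    # parameter layout: loadings (p), residual variances (p),
    # factor correlations (free), residual covariances (listed pairs)
    n_fc = q * (q - 1) // 2 if spec.factor_correlations else 0
    fc_pairs = [(i, j) for i in range(q) for j in range(i + 1, q)]
    rp = [(t_idx[a], t_idx[b]) for a, b in spec.residual_pairs]
    n_params = 2 * p + n_fc + len(rp)
    if n_obs <= n_params:
        raise ValueError("sample size must exceed the parameter count")

    diag_s = np.diag(sample_cov)

    def implied(theta: np.ndarray) -> np.ndarray:
        lam_v = theta[:p]
        resid = theta[p:2 * p]
        phi = np.eye(q)
        for k, (i, j) in enumerate(fc_pairs[:n_fc]):
            phi[i, j] = phi[j, i] = theta[2 * p + k]
        lam = np.zeros((p, q))
        for t in traits:
            lam[t_idx[t], f_idx[spec.loading_pattern[t]]] = lam_v[t_idx[t]]
        theta_mat = np.diag(resid)
        for k, (i, j) in enumerate(rp):
            theta_mat[i, j] = theta_mat[j, i] = theta[2 * p + n_fc + k]
        return lam @ phi @ lam.T + theta_mat

    def objective(theta: np.ndarray) -> float:
        return _fml(sample_cov, implied(theta))

    theta0 = np.concatenate([
        np.sqrt(np.clip(0.5 * diag_s, 1e-3, None)),
        np.clip(0.5 * diag_s, 1e-3, None),
        np.full(n_fc, 0.4), np.zeros(len(rp))])
    bounds = ([(-10 * np.sqrt(diag_s.max()), 10 * np.sqrt(diag_s.max()))] * p
              + [(1e-6, 10 * diag_s.max())] * p
              + [(-1.0, 1.0)] * n_fc
              + [(-5 * diag_s.max(), 5 * diag_s.max())] * len(rp))
    best = None
    for scale in (1.0, 0.6):
        res = optimize.minimize(objective, theta0 * scale, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": 2000, "ftol": 1e-13})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    sigma_hat = implied(theta)
    chi2 = max((n_obs - 1) * best.fun, 0.0)
    df = p * (p + 1) // 2 - n_params
    # baseline: independence with free variances
    sign_s, logdet_s = np.linalg.slogdet(sample_cov)
    f_base = float(np.sum(np.log(diag_s)) - logdet_s)
    chi2_b = max((n_obs - 1) * f_base, 0.0)
    df_b = p * (p - 1) // 2
    idx = fit_indices(chi2, df, chi2_b, df_b, n_obs, n_params,
                      srmr_value=srmr(sample_cov, sigma_hat))

    lam_tab = pd.DataFrame(0.0, index=traits, columns=list(factors))
    for t in traits:
        lam_tab.loc[t, spec.loading_pattern[t]] = theta[t_idx[t]]
    phi = np.eye(q)
    for k, (i, j) in enumerate(fc_pairs[:n_fc]):
        phi[i, j] = phi[j, i] = theta[2 * p + k]
    resid_mat = np.diag(theta[p:2 * p])
    for k, (i, j) in enumerate(rp):
        resid_mat[i, j] = resid_mat[j, i] = theta[2 * p + n_fc + k]
    return CfaResult(spec=spec, loadings=lam_tab,
                     factor_corr=pd.DataFrame(phi, index=list(factors),
                                              columns=list(factors)),
                     residual_cov=resid_mat, implied_cov=sigma_hat,
                     sample_cov=sample_cov, indices=idx,
                     converged=bool(best.success))
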
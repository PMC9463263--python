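"""End-to-end orchestration: descriptives, model fits, decomposition
tables, pathway summaries and CFA, written out as CSV/JSON bundles.

Every number in the emitted tables is re-derivable from the serialized
fit results; the report step does no computation of its own beyond
layout.  All randomness flows from a single master seed, split per
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biometric import decomposition_table, etiological_correlations, standardize
from .cfa import (COLE_THREE_FACTOR, ONE_FACTOR, ONE_FACTOR_RESIDUALS, fit_cfa,
                  select_one_twin_per_pair)
from .datatypes import DZ_GROUPS, MZ_GROUPS, TwinDataset
from .likelihood import FitResult
from .models import selection_driver
from .simulate import SimulationConfig, cross_twin_correlations, generate

__all__ = ["RunConfig", "run_pipeline", "describe_dataset"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    models: Sequence[str] | None = None
    traits: Sequence[str] | None = None
    seed: int = 0
    output_dir: str = "twinsleep_output"
    run_cfa: bool = True
    include_covariates: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**{
                k: (tuple(v) if k in ("skew_traits", "age_range") else
                    {g: tuple(s) for g, s in v.items()} if k in ("group_sizes",) else
                    {t: tuple(s) for t, s in v.items()} if k == "thresholds_true" else v)
                for k, v in sim.items()})
        return cfg


def describe_dataset(data: TwinDataset) -> dict:
    """Counts by zygosity group, completeness, sex and age summaries."""
    if len(data) == 0:
        return {"n_families": 0, "warning": "empty dataset", "groups": {},
                "pct_male": 0.0, "pct_mz": 0.0, "age": {}}
    w = data.wide
    x = data.values_matrix()
    p = len(data.traits)
    t1 = np.isfinite(x[:, :p]).any(axis=1)
    t2 = np.isfinite(x[:, p:]).any(axis=1)
    complete = t1 & t2
    groups = {}
    for g, sub in w.groupby("zygosity"):
        idx = sub.index.to_numpy()
        groups[g] = {"pairs": int(len(sub)), "complete": int(complete[idx].sum())}
    sexes = np.concatenate([w.loc[t1, "sex_t1"].to_numpy(float),
                            w.loc[t2, "sex_t2"].to_numpy(float)])
    n_ind = int(t1.sum() + t2.sum())
    n_mz_ind = int(t1[w["zygosity"].isin(MZ_GROUPS)].sum()
                   + t2[w["zygosity"].isin(MZ_GROUPS)].sum())
    return {
        "n_families": int(len(w)),
        "n_individuals": n_ind,
        "groups": groups,
        "pct_male": float(100.0 * np.nanmean(sexes)) if len(sexes) else 0.0,
        "pct_mz": float(100.0 * n_mz_ind / n_ind) if n_ind else 0.0,
        "age": {"mean": float(w["age"].mean()), "sd": float(w["age"].std()),
                "min": float(w["age"].min()), "max": float(w["age"].max())},
    }


def _check_schema(data: TwinDataset, requested: Sequence[str] | None) -> None:
    # every referenced trait must exist in the input schema
    missing = [t for t in (requested or ()) if t not in data.traits]
    if missing:
        raise ValueError(f"requested traits not in input schema: {missing}; "
                         f"available: {list(data.traits)}")


def _pathway_shares(fit: FitResult) -> pd.DataFrame | None:
    """Standardized common/specific variance shares of a pathway fit.

    Each trait's variance splits into the part transmitted by the common
    factor(s) (A and E separately) and the trait-specific residual parts;
    the four shares sum to one.
    """
    model = fit.model
    if not hasattr(model, "_parts"):
        return None
    vc = fit.components()
    total = np.diag(vc.total)
    parts = model._parts(fit.theta)
    a_spec, e_spec = np.asarray(parts[-2], float), np.asarray(parts[-1], float)
    df = pd.DataFrame({
        "common_A": (np.diag(vc.A) - a_spec) / total,
        "common_E": (np.diag(vc.E) - e_spec) / total,
        "specific_A": a_spec / total,
        "specific_E": e_spec / total,
    }, index=list(model.traits))
    df.index.name = "trait"
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run descriptives -> model fits -> decomposition -> pathway -> CFA.

    Returns a manifest dict of the written artifacts; rerunning with the
    same configuration and seed is bit-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2 ** 31 - 1))
                   for name in ("simulate", "fits", "cfa")}

    if config.simulation is not None:
        sim = config.simulation
        sim.seed = stage_seeds["simulate"] if config.input_csv is None else sim.seed
        data = generate(sim)
    elif config.input_csv is not None:
        data = TwinDataset.from_csv(config.input_csv)
    else:
        raise ValueError("RunConfig needs either input_csv or simulation")
    _check_schema(data, config.traits)
    if config.traits:
        keep = tuple(config.traits)
        data = TwinDataset(data.wide, {t: data.specs[t] for t in keep}, keep)

    manifest: dict = {"seed": config.seed, "stage_seeds": stage_seeds,
                      "software": {"twinsleep": __version__},
                      "artifacts": {}}

    def save(name: str, obj) -> None:
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, default=float)
        manifest["artifacts"][name] = name  # relative to output_dir

    save("descriptives.json", describe_dataset(data))
    save("cross_twin_correlations.csv", cross_twin_correlations(data))

    table, fits = selection_driver(data, models=config.models,
                                   seed=stage_seeds["fits"],
                                   include_covariates=config.include_covariates)
    save("model_comparison.csv", table.set_index("model"))
    for name, f in fits.items():
        f.to_json(out / f"fit_{name}.json")
        manifest["artifacts"][f"fit_{name}.json"] = f"fit_{name}.json"

    best_ae = fits.get("multivariate_AE")
    if best_ae is not None:
        vc = best_ae.components()
        save("standardized_components.csv", standardize(vc))
        save("decomposition_table.csv", decomposition_table(vc).set_index(
            ["trait_i", "trait_j"]))
        corr = etiological_correlations(vc)
        save("etiological_correlations.csv", pd.DataFrame(
            corr.rA, index=vc.trait_names, columns=vc.trait_names))
    for name in ("common_pathway_1f", "independent_pathway_AE"):
        if name in fits:
            shares = _pathway_shares(fits[name])
            if shares is not None:
                save(f"pathway_shares_{name}.csv", shares)

    if config.run_cfa and len(data.traits) >= 3:
        table1 = select_one_twin_per_pair(data, seed=stage_seeds["cfa"])
        cfa_rows = []
        for spec in (ONE_FACTOR, ONE_FACTOR_RESIDUALS, COLE_THREE_FACTOR):
            if not all(t in data.traits for t in spec.loading_pattern):
                continue
            res = fit_cfa(spec, table1)
            cfa_rows.append({"structure": spec.name, "chi2": res.indices.chi2,
                             "df": res.indices.df, "rmsea": res.indices.rmsea,
                             "rmsea_lo": res.indices.rmsea_ci[0],
                             "rmsea_hi": res.indices.rmsea_ci[1],
                             "srmr": res.indices.srmr, "cfi": res.indices.cfi,
                             "tli": res.indices.tli, "bic": res.indices.bic})
        if cfa_rows:
            save("cfa_indices.csv", pd.DataFrame(cfa_rows).set_index("structure"))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
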
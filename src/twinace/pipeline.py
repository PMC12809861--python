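"""End-to-end analysis pipeline: filters -> correlations -> gate -> ACE ->
decomposition -> criteria, with CSV/JSON report bundles.

Each measure x phenotype cell is processed independently; a failure in
one cell is recorded in the run log and the pipeline continues.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import core_data
from .correlation_models import fit_constrained_correlations
from .decomposition import decompose_fit, evaluate_endophenotype, genetic_sharing
from .estimation import fit_bivariate_ace
from .liability_model import get_disease_model

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_PROFILE_MAPS"]

DEFAULT_PROFILE_MAPS: dict[str, dict[str, str]] = {
    "main": {"SZ": "maudsley_sz", "BD1": "maudsley_bd1", "BROAD": "maudsley_broad"},
    "sensitivity": {"SZ": "polderman_sz", "BD1": "polderman_bd1"},
}


@dataclass
class PipelineConfig:
    input_path: str
    measures: Sequence[str]
    phenotypes: Sequence[str]
    out_dir: str
    seed: int
    profile_set: str = "main"
    profile_map: Mapping[str, str] | None = None
    apply_filters: bool = True
    min_iq: float = 70.0
    age_range: tuple[float, float] = (16.0, 65.0)
    iq_measure: str = "iq"
    use_covariates: bool = True
    reference_centre: str | None = None
    n_starts: int = 3
    ci_params: Sequence[str] = (
        "h2", "c2", "e2", "rg", "rc", "re", "rph_a", "rph_e"
    )

    def resolved_profile_map(self) -> dict[str, str]:
        if self.profile_map:
            return dict(self.profile_map)
        try:
            base = DEFAULT_PROFILE_MAPS[self.profile_set]
        except KeyError:
            raise ValueError(
                f"unknown profile set {self.profile_set!r}; "
                f"expected one of {sorted(DEFAULT_PROFILE_MAPS)}"
            ) from None
        return dict(base)


def _fmt(x) -> str:
    return "" if x is None else f"{x:.6g}"


def _ci_cols(prefix: str, ci: tuple[float, float] | None, flags: dict | None):
    if ci is None:
        return {f"{prefix}_lo": None, f"{prefix}_hi": None, f"{prefix}_flag": ""}
    flag_bits = []
    for key, mark in (("lo_at_bound", "lo@bound"), ("hi_at_bound", "hi@bound"),
                      ("unreliable", "unreliable"), ("fixed_structural", "fixed")):
        if flags and flags.get(key):
            flag_bits.append(mark)
    return {
        f"{prefix}_lo": ci[0],
        f"{prefix}_hi": ci[1],
        f"{prefix}_flag": "|".join(flag_bits),
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "profile_set": cfg.profile_set, "cells": {}}

    ds = core_data.read_dataset(cfg.input_path)
    if cfg.apply_filters:
        ds, excl = core_data.apply_inclusion_filters(
            ds, min_iq=cfg.min_iq, age_range=cfg.age_range, iq_measure=cfg.iq_measure
        )
        log["exclusions"] = excl
    design = None
    if cfg.use_covariates:
        enc, design = core_data.encode_covariates(ds, cfg.reference_centre)
        log["covariates"] = list(enc.names)

    profile_map = cfg.resolved_profile_map()
    corr_rows, vc_rows, dec_rows, endo_rows = [], [], [], []

    for phenotype in cfg.phenotypes:
        profile_name = profile_map.get(phenotype)
        if profile_name is None:
            log["cells"][phenotype] = f"no disease profile for {phenotype!r} in set {cfg.profile_set!r}"
            continue
        disease = get_disease_model(profile_name)
        for measure in cfg.measures:
            cell = f"{measure}|{phenotype}"
            try:
                corr = fit_constrained_correlations(
                    ds, measure, phenotype, disease, design=design,
                    n_starts=cfg.n_starts, seed=cfg.seed,
                )
                corr_rows.append({
                    "measure": measure, "phenotype": phenotype,
                    "profile": profile_name,
                    "r_wtct": corr.r_wtct,
                    **_ci_cols("r_wtct", corr.ci.get("r_wtct"),
                               corr.ci_flags.get("r_wtct")),
                    "r_ctct_mz": corr.r_ctct_mz, "r_ctct_dz": corr.r_ctct_dz,
                    "r_ctwt_mz": corr.r_ctwt_mz, "r_ctwt_dz": corr.r_ctwt_dz,
                    "fixed_disease_mz": corr.fixed_disease_mz,
                    "fixed_disease_dz": corr.fixed_disease_dz,
                })
                cell_log = {
                    "profile": profile_name,
                    "corr_loglik": corr.loglik,
                    "corr_grad_norm": corr.convergence.get("grad_norm"),
                }

                gate = corr.significant("r_wtct")
                if gate is not True:
                    marker = "excluded: within-twin cross-trait correlation not significant"
                    vc_rows.append({"measure": measure, "phenotype": phenotype,
                                    "status": marker})
                    dec_rows.append({"measure": measure, "phenotype": phenotype,
                                     "status": marker})
                    crit = evaluate_endophenotype(corr, None, None)
                else:
                    fit = fit_bivariate_ace(
                        ds, measure, phenotype, disease, design=design,
                        n_starts=cfg.n_starts, seed=cfg.seed,
                        ci_params=tuple(cfg.ci_params),
                    )
                    dec = decompose_fit(fit)
                    crit = evaluate_endophenotype(corr, fit, dec)
                    est = fit.estimates
                    vc_rows.append({
                        "measure": measure, "phenotype": phenotype, "status": "ok",
                        **{k: est[k] for k in ("h2", "c2", "e2")},
                        **_ci_cols("h2", fit.ci.get("h2"), fit.ci_flags.get("h2")),
                        **_ci_cols("c2", fit.ci.get("c2"), fit.ci_flags.get("c2")),
                        **_ci_cols("e2", fit.ci.get("e2"), fit.ci_flags.get("e2")),
                    })
                    dec_rows.append({
                        "measure": measure, "phenotype": phenotype, "status": "ok",
                        "rph_a": dec.rph_a, "rph_c": dec.rph_c,
                        "rph_e": dec.rph_e, "rph": dec.rph,
                        **_ci_cols("rph_a", dec.ci.get("rph_a"),
                                   dec.ci_flags.get("rph_a")),
                        **_ci_cols("rph_e", dec.ci.get("rph_e"),
                                   dec.ci_flags.get("rph_e")),
                        "rg": est["rg"], "rc": est["rc"], "re": est["re"],
                        **_ci_cols("rg", fit.ci.get("rg"), fit.ci_flags.get("rg")),
                        **_ci_cols("rc", fit.ci.get("rc"), fit.ci_flags.get("rc")),
                        **_ci_cols("re", fit.ci.get("re"), fit.ci_flags.get("re")),
                        "genetic_sharing_pct": genetic_sharing(est["rg"]),
                    })
                    cell_log.update(
                        ace_loglik=fit.loglik,
                        ace_grad_norm=fit.convergence.get("grad_norm"),
                        ace_converged=fit.converged,
                        n_pairs_used=fit.n_pairs_used,
                    )
                endo_rows.append({
                    "measure": measure, "phenotype": phenotype,
                    "c1_phenotypic": crit.c1_phenotypic,
                    "c2_heritability": crit.c2_heritability,
                    "c3_rg": crit.c3_rg,
                    "c4_rph_a": crit.c4_rph_a,
                    "is_endophenotype": crit.is_endophenotype,
                    "excluded_at_c1": crit.excluded_at_c1,
                })
                log["cells"][cell] = cell_log
            except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
                log["cells"][cell] = {
                    "error": f"{type(exc).__name__}: {exc}",
                    "traceback": traceback.format_exc(limit=5),
                }
                endo_rows.append({
                    "measure": measure, "phenotype": phenotype,
                    "c1_phenotypic": None, "c2_heritability": None,
                    "c3_rg": None, "c4_rph_a": None,
                    "is_endophenotype": False, "excluded_at_c1": False,
                })

    tables = {
        "correlations": pd.DataFrame(corr_rows),
        "variance_components": pd.DataFrame(vc_rows),
        "decomposition": pd.DataFrame(dec_rows),
        "endophenotypes": pd.DataFrame(endo_rows),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return tables
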
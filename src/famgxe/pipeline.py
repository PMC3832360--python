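"""End-to-end per-trait analysis: prep -> polygenic -> GxEE -> LRTs -> reports.

For each trait the pipeline adjusts covariates, applies the inverse normal
transformation, fits the polygenic and GxEE models (full and constrained),
runs the boundary-corrected likelihood-ratio tests and writes:

- ``heritability.tsv``: trait, h2, SE, p, 95% CI (heritability table shape)
- ``gxee_lrt.tsv``: trait, polygenic LnL, GxEE LnL, LRT, p (interaction table)
- ``functions_<trait>.csv``: fitted variance/correlation/covariance grids
- ``report.json``: full machine-readable study report
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from famgxe.activity import read_diaries, standardize_tdee, tdee_from_diary, EnergyCostTable
from famgxe.gxee import evaluate_functions, fit_gxee
from famgxe.lrt import LRTResult, lrt_statistic, mixture_sf, standard_contrasts
from famgxe.pedigree import Pedigree, kinship2, family_summary, read_pedigree
from famgxe.phenotype import FULL_DESIGN, adjust_and_normalize
from famgxe.polygenic import fit_polygenic, h2_test

logger = logging.getLogger("famgxe")

_PKG_VERSION = "0.1.0"

DEFAULT_TRAITS = ("WC", "SBP", "GLU", "HDL", "TC", "TG")


@dataclass
class RunConfig:
    """Configuration of one study run."""

    pedigree: str
    phenotypes: str
    diaries: str | None = None
    traits: tuple[str, ...] = DEFAULT_TRAITS
    pedigree_dialect: str = "linkage"
    covariate_terms: tuple[str, ...] = FULL_DESIGN
    inverse_normal_offset: float = 0.375
    standardize_tdee: bool = True
    energy_costs: tuple[float, ...] | None = None
    outdir: str = "famgxe_out"
    seed: int = 0
    log_level: str = "INFO"


def validate_inputs(config: RunConfig) -> dict:
    """Cross-check pedigree, phenotype and diary consistency.

    Reports findings without raising; ``run_study`` treats findings with
    severity 'fatal' as blocking.  Also tabulates phenotyped role counts in
    the descriptive-table layout.
    """
    findings: list[dict] = []

    def fatal(msg):
        findings.append({"severity": "fatal", "message": msg})

    def warn(msg):
        findings.append({"severity": "warning", "message": msg})

    ped = read_pedigree(config.pedigree, dialect=config.pedigree_dialect)
    phen = pd.read_csv(config.phenotypes, dtype={"individual_id": str})
    if "individual_id" not in phen.columns:
        fatal("phenotype table lacks an individual_id column")
        return {"findings": findings, "n_fatal": 1}
    missing_ped = [i for i in phen["individual_id"] if i not in ped]
    if missing_ped:
        fatal(
            f"{len(missing_ped)} phenotyped ids absent from pedigree "
            f"(first: {missing_ped[:5]})"
        )
    for trait in config.traits:
        if trait not in phen.columns:
            fatal(f"trait column {trait!r} missing from phenotype table")
    for col in ("age", "sex"):
        if col not in phen.columns:
            fatal(f"covariate column {col!r} missing from phenotype table")
    has_tdee = "tdee" in phen.columns
    if config.diaries:
        try:
            diaries = read_diaries(config.diaries)
        except ValueError as exc:
            fatal(f"diary file invalid: {exc}")
            diaries = []
        known = set(phen["individual_id"])
        for rec in diaries:
            if rec.individual_id not in known:
                warn(f"diary for unknown individual {rec.individual_id!r}")
    elif not has_tdee:
        fatal("no tdee column and no diary file: TDEE unavailable")
    miss = {
        c: int(phen[c].isna().sum())
        for c in phen.columns
        if phen[c].isna().any()
    }
    summary = None
    if not missing_ped:
        ok_ids = [i for i in phen["individual_id"] if i in ped]
        summary = family_summary(ped, ok_ids)
    n_fatal = sum(f["severity"] == "fatal" for f in findings)
    return {
        "findings": findings,
        "n_fatal": n_fatal,
        "missingness": miss,
        "family_summary": summary,
    }


def _tdee_vector(config: RunConfig, phen: pd.DataFrame) -> pd.Series:
    if config.diaries:
        costs = (
            EnergyCostTable(tuple(config.energy_costs))
            if config.energy_costs
            else EnergyCostTable()
        )
        weights = phen.set_index("individual_id")["weight"]
        values = {}
        for rec in read_diaries(config.diaries):
            if rec.individual_id in weights.index:
                ee = tdee_from_diary(rec, float(weights[rec.individual_id]), costs)
                values[rec.individual_id] = ee.tdee
        return pd.Series(values, name="tdee")
    return phen.set_index("individual_id")["tdee"].astype(float)


def _analyze_trait(trait, phen, rel, config, tdee):
    t0 = time.time()
    adj = adjust_and_normalize(
        phen, trait,
        terms=config.covariate_terms,
        offset=config.inverse_normal_offset,
    )
    ids = [i for i in adj.ids if i in tdee.index and np.isfinite(tdee[i])]
    scores = adj.scores.loc[ids]
    tvals = tdee.loc[ids]
    if config.standardize_tdee:
        q, transform = standardize_tdee(tvals.to_numpy())
    else:
        q = tvals.to_numpy(dtype=float)
        transform = None

    poly = fit_polygenic(scores, rel)
    logger.info("%s: polygenic loglik=%.3f h2=%.3f", trait, poly.loglik, poly.h2)
    h2_lrt = h2_test(poly, scores, rel)

    full = fit_gxee(scores, q, rel, anchor=poly)
    no_gg = fit_gxee(scores, q, rel, constraints={"gamma_g"}, anchor=poly)
    no_lam = fit_gxee(scores, q, rel, constraints={"lam"}, anchor=poly)
    logger.info("%s: gxee loglik=%.3f params=%s", trait, full.loglik, full.params)

    contrasts = standard_contrasts()
    lrts = {}
    for name, loglik_reduced in (
        ("full_vs_polygenic", poly.loglik),
        ("variance_homogeneity", no_gg.loglik),
        ("genetic_correlation_one", no_lam.loglik),
    ):
        T = lrt_statistic(full.loglik, loglik_reduced)
        null = contrasts[name]
        lrts[name] = LRTResult(
            contrast=name, T=T, null=null, p=mixture_sf(T, null),
            loglik_full=full.loglik, loglik_reduced=loglik_reduced,
        )
    lrts["h2_zero"] = h2_lrt

    q_arr = np.asarray(q, dtype=float)
    q_grid = np.linspace(q_arr.min(), q_arr.max(), 41)
    dq_grid = np.linspace(0.0, float(np.ptp(q_arr)), 41)
    functions = evaluate_functions(full, q_grid, dq_grid)
    logger.info("%s: done in %.1fs", trait, time.time() - t0)
    return {
        "adjusted": adj,
        "polygenic": poly,
        "gxee_full": full,
        "gxee_no_gamma_g": no_gg,
        "gxee_no_lambda": no_lam,
        "lrts": lrts,
        "functions": functions,
        "tdee_transform": transform,
        "n": len(ids),
    }


def run_study(config: RunConfig) -> dict:
    """Run the full per-trait analysis and write report files.

    Per-trait failures are isolated: remaining traits still run and the
    report records the error; callers should treat any failed trait as a
    non-zero exit condition.  Deterministic given inputs and config.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    validation = validate_inputs(config)
    if validation["n_fatal"]:
        raise ValueError(
            "fatal input problems: "
            + "; ".join(
                f["message"] for f in validation["findings"]
                if f["severity"] == "fatal"
            )
        )

    ped = read_pedigree(config.pedigree, dialect=config.pedigree_dialect)
    rel = kinship2(ped)
    phen = pd.read_csv(config.phenotypes, dtype={"individual_id": str})
    tdee = _tdee_vector(config, phen)

    results, errors = {}, {}
    for trait in config.traits:
        try:
            results[trait] = _analyze_trait(trait, phen, rel, config, tdee)
        except Exception as exc:  # noqa: BLE001 - per-trait isolation
            logger.error("trait %s failed: %s", trait, exc)
            errors[trait] = str(exc)

    herit_rows, lrt_rows, report_traits = [], [], {}
    for trait, res in results.items():
        poly = res["polygenic"]
        full = res["gxee_full"]
        lrts = res["lrts"]
        ci = poly.ci95
        herit_rows.append({
            "trait": trait,
            "h2": round(poly.h2, 4),
            "se": round(poly.se_h2, 4) if np.isfinite(poly.se_h2) else "",
            "p": f"{lrts['h2_zero'].p:.4g}",
            "ci95_low": round(ci[0], 4) if np.isfinite(ci[0]) else "",
            "ci95_high": round(ci[1], 4) if np.isfinite(ci[1]) else "",
            "n": res["n"],
        })
        fvp = lrts["full_vs_polygenic"]
        lrt_rows.append({
            "trait": trait,
            "polygenic_lnl": round(poly.loglik, 3),
            "gxee_lnl": round(full.loglik, 3),
            "lrt": round(fvp.T, 3),
            "p": f"{fvp.p:.4f}",
        })
        fn = res["functions"]
        grid = fn["variance"].merge(fn["correlation"], left_index=True,
                                    right_index=True)
        grid.to_csv(outdir / f"functions_{trait}.csv", index=False)
        transform = res["tdee_transform"]
        report_traits[trait] = {
            "n": res["n"],
            "polygenic": {
                "sigma2_g": poly.sigma2_g, "sigma2_e": poly.sigma2_e,
                "h2": poly.h2, "se_h2": poly.se_h2, "loglik": poly.loglik,
                "mu": poly.mu, "converged": poly.converged,
            },
            "gxee_full": {
                "params": asdict(full.params),
                "params_kcal_scale": (
                    full.params_on_kcal_scale(transform) if transform else None
                ),
                "loglik": full.loglik,
                "converged": full.converged,
            },
            "gxee_constrained": {
                "gamma_g=0": res["gxee_no_gamma_g"].loglik,
                "lambda=0": res["gxee_no_lambda"].loglik,
            },
            "lrts": {
                name: {
                    "T": r.T, "p": r.p, "null": str(r.null),
                    "loglik_full": r.loglik_full,
                    "loglik_reduced": r.loglik_reduced,
                }
                for name, r in lrts.items()
            },
            "covariate_model": res["adjusted"].model,
        }

    pd.DataFrame(herit_rows).to_csv(outdir / "heritability.tsv", sep="\t", index=False)
    pd.DataFrame(lrt_rows).to_csv(outdir / "gxee_lrt.tsv", sep="\t", index=False)

    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = {
        "provenance": {
            "famgxe_version": _PKG_VERSION,
            "config": asdict(config),
            "config_hash": config_hash,
        },
        "validation": validation,
        "traits": report_traits,
        "errors": errors,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
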
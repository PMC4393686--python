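"""End-to-end study pipeline for a twin cohort table.

Stages, in order: load or generate a cohort; preprocess (optional square-root
transform, then sex/age residualization); descriptives (scale moments,
phenotypic correlations on one random member per pair, twin ICC/CTCT);
phenotypic-correlation gate; univariate model suite per trait; bivariate
model suite for each outcome passing the gate; optional covariate-adjusted
bivariate refits; a single JSON/TSV report.

Covariate adjustment is implemented as phenotype residualization: both
analysis traits are residualized on the covariate(s) with the same OLS
machinery used for sex and age, re-standardized, and the bivariate suite is
refit on the residuals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ace import (BivariateACE, ComparisonRow, FitResult, ModelSpec, UnivariateACE,
                  compare_models, derived_bivariate, fit_model, select_best)
from .datasets import (BivariateGenSpec, UnivariateGenSpec, read_cohort,
                       simulate_bivariate, simulate_univariate, write_cohort)
from .descriptives import (correlation_gate, describe_scale, pearson_ci,
                           twin_correlations)
from .preprocessing import (residualize, residualize_pairs, select_random_member,
                            sqrt_transform)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConvergenceError", "run_pipeline",
           "adjust_for_covariate", "default_generation_spec"]

UNIVARIATE_SUITE = ("ACE", "AE", "CE")
BIVARIATE_SUITE = ("ACE", "CE", "AE", "ACE_drop_ra", "ACE_drop_rc")


class ConvergenceError(RuntimeError):
    """A required model fit failed to converge."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: data source, traits, gate, seeds, output."""

    exposure: str = "bullying"
    outcomes: tuple[str, ...] = ("paranoia",)
    input_path: str | None = None
    generate: bool = True
    covariates: tuple[str, ...] = ()
    gate_threshold: float = 0.25
    sqrt_transform: bool = False
    seed: int = 0
    out_dir: str | None = None
    n_starts: int = 8
    noise_outcomes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.outcomes:
            raise ValueError("config must name at least one outcome")
        if not (0.0 < self.gate_threshold < 1.0):
            raise ValueError(f"gate threshold must lie in (0, 1), got {self.gate_threshold}")


def default_generation_spec(seed: int = 0, missing_rate: float = 0.15) -> BivariateGenSpec:
    """Default synthetic cohort: an exposure-outcome pair with strong genetic
    overlap (heritable exposure with shared-environment variance, heritable
    outcome, genetic factor correlation .55, tiny unique-environment
    overlap, no shared-environment overlap)."""
    return BivariateGenSpec(
        a2_x=0.35, c2_x=0.26, e2_x=0.39,
        a2_y=0.52, c2_y=0.0, e2_y=0.48,
        r_a=0.55, r_c=0.0, r_e=0.04,
        n_mz=1418, n_dz=1258, missing_rate=missing_rate, seed=seed,
        trait_x="bullying", trait_y="paranoia")


def _attach_noise_outcome(pairs: pd.DataFrame, name: str, seed: int) -> pd.DataFrame:
    """Add an ACE-structured trait independent of the existing traits."""
    n_mz = int((pairs["zygosity"] == "MZ").sum())
    n_dz = int((pairs["zygosity"] == "DZ").sum())
    spec = UnivariateGenSpec(a2=0.3, c2=0.1, e2=0.6, n_mz=n_mz, n_dz=n_dz,
                             seed=seed, trait=name, beta_sex=0.0, beta_age=0.0)
    noise = simulate_univariate(spec)
    out = pairs.copy()
    out[f"{name}_1"] = noise[f"{name}_1"].to_numpy()
    out[f"{name}_2"] = noise[f"{name}_2"].to_numpy()
    return out


def adjust_for_covariate(pairs: pd.DataFrame, traits, covariates) -> pd.DataFrame:
    """Residualize traits on covariate(s) per person and re-standardize.

    Covariates live in per-twin columns ``<cov>_1``/``<cov>_2`` (or a single
    shared column ``<cov>``).  Aborts if any covariate is missing for more
    than half of the persons.
    """
    if isinstance(traits, str):
        traits = [traits]
    if isinstance(covariates, str):
        covariates = [covariates]
    n = len(pairs)
    cov_cols = []
    for cov in covariates:
        if f"{cov}_1" in pairs.columns:
            col = np.concatenate([pairs[f"{cov}_1"].to_numpy(float),
                                  pairs[f"{cov}_2"].to_numpy(float)])
        elif cov in pairs.columns:
            col = np.concatenate([pairs[cov].to_numpy(float)] * 2)
        else:
            raise ValueError(f"covariate {cov!r} not found in pair table")
        frac_missing = np.mean(~np.isfinite(col))
        if frac_missing > 0.5:
            raise ValueError(
                f"covariate {cov!r} missing for {frac_missing:.0%} of persons (> 50%)")
        cov_cols.append(col)
    X = np.column_stack(cov_cols)
    out = pairs.copy()
    for trait in traits:
        y = np.concatenate([pairs[f"{trait}_1"].to_numpy(float),
                            pairs[f"{trait}_2"].to_numpy(float)])
        ok_design = np.isfinite(X).all(axis=1)
        yy = np.where(ok_design, y, np.nan)
        design = np.column_stack([np.ones(2 * n), X])
        okk = np.isfinite(yy) & ok_design
        beta, *_ = np.linalg.lstsq(design[okk], yy[okk], rcond=None)
        res = np.full(2 * n, np.nan)
        res[okk] = yy[okk] - design[okk] @ beta
        res = (res - np.nanmean(res)) / np.nanstd(res, ddof=1)
        out[f"{trait}_1"] = res[:n]
        out[f"{trait}_2"] = res[n:]
    return out


def _row_dict(row: ComparisonRow) -> dict:
    return dataclasses.asdict(row)


def _fit_dict(fit: FitResult) -> dict:
    d = {k: v for k, v in dataclasses.asdict(fit).items() if k != "params"}
    d["ci"] = {k: list(v) for k, v in fit.ci.items()}
    return d


def _fit_suite(pairs, traits, families, seed, n_starts) -> tuple[dict, list]:
    """Fit saturated + the requested families; return fits and comparison."""
    sat = fit_model(pairs, ModelSpec("saturated", tuple(traits),
                                     n_starts=n_starts, seed=seed))
    fits = {"saturated": sat}
    for fam in families:
        fit = fit_model(pairs, ModelSpec(fam, tuple(traits),
                                         n_starts=n_starts, seed=seed))
        if not fit.converged:
            raise ConvergenceError(f"model {fam} on {traits} did not converge")
        fits[fam] = fit
    rows = compare_models([fits[f] for f in families], sat)
    return fits, rows


def _bivariate_block(pairs, exposure, outcome, seed, n_starts) -> dict:
    fits, rows = _fit_suite(pairs, [exposure, outcome], BIVARIATE_SUITE,
                            seed, n_starts)
    best = select_best(rows)
    block = {
        "traits": [exposure, outcome],
        "comparison": [_row_dict(r) for r in rows],
        "best_model": best,
        "fits": {name: _fit_dict(f) for name, f in fits.items()},
    }
    best_fit = fits[best]
    if best_fit.params is not None:
        block["derived"] = derived_bivariate(best_fit.params, strict=False)
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    traits = [config.exposure, *config.outcomes]

    # ---- stage 1: data -------------------------------------------------
    if config.input_path is not None:
        pairs = read_cohort(config.input_path)
        gen_spec = None
        logger.info("loaded %d pairs from %s", len(pairs), config.input_path)
    elif config.generate:
        gen_spec = default_generation_spec(seed=config.seed)
        pairs = simulate_bivariate(gen_spec)
        for i, name in enumerate(config.noise_outcomes):
            pairs = _attach_noise_outcome(pairs, name, seed=config.seed + 1000 + i)
        logger.info("generated %d pairs (synthetic default cohort)", len(pairs))
    else:
        raise ValueError("config must give input_path or set generate=True")
    traits = [t for t in traits if f"{t}_1" in pairs.columns]
    missing_traits = [t for t in [config.exposure, *config.outcomes]
                      if f"{t}_1" not in pairs.columns]
    if config.exposure in missing_traits:
        raise ValueError(f"exposure trait {config.exposure!r} not in table")
    n_families = len(pairs)

    # ---- stage 2: preprocessing ---------------------------------------
    processed = pairs.copy()
    if config.sqrt_transform:
        for t in traits:
            for i in (1, 2):
                processed[f"{t}_{i}"] = sqrt_transform(processed[f"{t}_{i}"])
    processed = residualize_pairs(processed, traits)
    logger.info("preprocessed %d traits over %d families", len(traits), n_families)

    # ---- stage 3: descriptives ----------------------------------------
    descriptives = {}
    for t in traits:
        row = describe_scale(pairs, t, transform=config.sqrt_transform,
                             seed=config.seed)
        descriptives[t] = dataclasses.asdict(row)

    one = select_random_member(processed, seed=config.seed, traits=traits)
    phenotypic = {}
    for outcome in traits[1:]:
        res = pearson_ci(one[config.exposure], one[outcome])
        phenotypic[outcome] = dataclasses.asdict(res)

    twin_corr = {}
    for t in traits:
        tc = twin_correlations(processed, t)
        twin_corr[t] = {"icc_mz": dataclasses.asdict(tc.icc_mz),
                        "icc_dz": dataclasses.asdict(tc.icc_dz)}
    for outcome in traits[1:]:
        tc = twin_correlations(processed, config.exposure, outcome)
        twin_corr[f"{config.exposure}~{outcome}"] = {
            "ctct_mz": dataclasses.asdict(tc.ctct_mz),
            "ctct_dz": dataclasses.asdict(tc.ctct_dz)}

    # ---- stage 4: gate -------------------------------------------------
    gate_input = {name: d["r"] for name, d in phenotypic.items()}
    passing = correlation_gate(gate_input, config.gate_threshold)
    logger.info("gate at %.2f: %d/%d outcomes pass (%s)",
                config.gate_threshold, len(passing), len(gate_input), passing)

    # ---- stage 5: univariate fits --------------------------------------
    univariate = {}
    for t in traits:
        fits, rows = _fit_suite(processed, [t], UNIVARIATE_SUITE,
                                config.seed, config.n_starts)
        univariate[t] = {
            "comparison": [_row_dict(r) for r in rows],
            "best_model": select_best(rows),
            "fits": {name: _fit_dict(f) for name, f in fits.items()},
        }

    # ---- stage 6: bivariate fits ---------------------------------------
    bivariate = {}
    if passing:
        for outcome in passing:
            bivariate[outcome] = _bivariate_block(
                processed, config.exposure, outcome, config.seed, config.n_starts)
    else:
        logger.info("no outcome passed the gate; bivariate stage skipped")

    # ---- stage 7: covariate-adjusted refits -----------------------------
    adjusted = {}
    for cov in config.covariates:
        for outcome in passing:
            adj = adjust_for_covariate(processed, [config.exposure, outcome], cov)
            adjusted[f"{outcome}|{cov}"] = _bivariate_block(
                adj, config.exposure, outcome, config.seed, config.n_starts)

    report = {
        "provenance": {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "generation_spec": dataclasses.asdict(gen_spec) if gen_spec else None,
            "n_families": n_families,
        },
        "descriptives": descriptives,
        "phenotypic_correlations": phenotypic,
        "twin_correlations": twin_corr,
        "gate": {"threshold": config.gate_threshold, "passing": passing,
                 "skipped_bivariate": not passing},
        "univariate": univariate,
        "bivariate": bivariate,
        "adjusted": adjusted,
    }

    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    text = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    tmp = out_dir / "report.json.tmp"
    tmp.write_text(text)
    tmp.replace(out_dir / "report.json")

    # TSV mirrors of the main comparison tables
    rows = []
    for trait, block in report["univariate"].items():
        for row in block["comparison"]:
            rows.append({"trait": trait, **row})
    for outcome, block in report.get("bivariate", {}).items():
        for row in block["comparison"]:
            rows.append({"trait": f"{block['traits'][0]}~{outcome}", **row})
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "model_comparison.tsv",
                                  sep="\t", index=False)
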
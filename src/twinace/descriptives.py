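"""Descriptive statistics for twin cohorts.

Covers the standard descriptive surfaces of a twin analysis: per-scale
moments and internal consistency with a sex-by-zygosity ANOVA on one random
member per pair; phenotypic Pearson correlations with Fisher-z confidence
intervals; intraclass (ICC) and cross-twin cross-trait (CTCT) correlations
by zygosity via double entry; and the phenotypic-correlation gate that
decides which trait pairs warrant bivariate twin modeling.

Conventions: skewness and kurtosis are moment-based with the non-excess
kurtosis convention (a Gaussian has kurtosis 3); ICCs use the double-entry
Pearson estimator with Fisher-z CIs on an effective n equal to the number of
pairs (double entry counts each pair twice, so the naive n would be
anti-conservative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import select_random_member, sqrt_transform

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptivesRow",
    "CorrelationResult",
    "TwinCorrelations",
    "describe_scale",
    "cronbach_alpha",
    "pearson_ci",
    "twin_correlations",
    "correlation_gate",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its 95% CI and the n it used."""

    r: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self):
        if not (-1 - 1e-9 <= self.ci_low <= self.r + 1e-9
                and self.r - 1e-9 <= self.ci_high <= 1 + 1e-9):
            raise ValueError(f"inconsistent correlation result {self!r}")


@dataclass
class DescriptivesRow:
    """Scale-level descriptives: moments, alpha, and sex x zygosity ANOVA."""

    trait: str
    mean: float
    sd: float
    mean_by_sex: dict[str, float]
    sd_by_sex: dict[str, float]
    mean_by_zyg: dict[str, float]
    sd_by_zyg: dict[str, float]
    score_range: tuple[float, float]
    skew: float
    kurtosis: float
    alpha: float | None
    p_sex: float | None
    p_zyg: float | None
    p_interaction: float | None
    r_squared: float | None
    n: int


@dataclass
class TwinCorrelations:
    """ICC per zygosity, plus CTCT per zygosity for a trait pair."""

    icc_mz: CorrelationResult
    icc_dz: CorrelationResult
    ctct_mz: CorrelationResult | None = None
    ctct_dz: CorrelationResult | None = None


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of an item table (complete rows only)."""
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha, _ = pg.cronbach_alpha(data=items.dropna(), ci=0.95)
    return float(alpha)


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1:
        return -1.0, 1.0
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def pearson_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson correlation with Fisher-z CI on pairwise-complete rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        raise ValueError(f"pearson_ci: need >= 4 complete rows, got {n}")
    for name, v in (("x", x[ok]), ("y", y[ok])):
        if np.ptp(v) == 0:
            raise ValueError(f"pearson_ci: variable {name} has zero variance")
    res = stats.pearsonr(x[ok], y[ok])
    ci = res.confidence_interval(confidence_level=level)
    return CorrelationResult(r=float(res.statistic), ci_low=float(ci.low),
                             ci_high=float(ci.high), n=n)


def _double_entry(u1, u2, v1, v2) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack both orderings of (u, v) across twins; drop incomplete rows."""
    a = np.concatenate([u1, u2])
    b = np.concatenate([v2, v1])
    ok = np.isfinite(a) & np.isfinite(b)
    n_pairs = int((np.isfinite(u1) & np.isfinite(v2)).sum()
                  + (np.isfinite(u2) & np.isfinite(v1)).sum()) // 2
    return a[ok], b[ok], n_pairs


def _double_entry_corr(u1, u2, v1, v2) -> CorrelationResult:
    a, b, n_pairs = _double_entry(u1, u2, v1, v2)
    if len(a) < 4:
        raise ValueError(f"too few complete double-entered rows ({len(a)})")
    r = float(np.corrcoef(a, b)[0, 1])
    lo, hi = _fisher_ci(r, n_pairs)
    return CorrelationResult(r=r, ci_low=min(lo, r), ci_high=max(hi, r), n=n_pairs)


def twin_correlations(pairs: pd.DataFrame, trait_x: str,
                      trait_y: str | None = None,
                      min_pairs: int = 10) -> TwinCorrelations:
    """Double-entry ICCs per zygosity, plus CTCT when a second trait is given.

    The ICC enters each pair in both twin orders, which makes the estimate
    invariant to the arbitrary within-pair labeling.  The CTCT pools the
    (X1, Y2) and (X2, Y1) orderings the same way.
    """
    res: dict[str, CorrelationResult] = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs["zygosity"] == zyg]
        x1 = sub[f"{trait_x}_1"].to_numpy(float)
        x2 = sub[f"{trait_x}_2"].to_numpy(float)
        complete = int((np.isfinite(x1) & np.isfinite(x2)).sum())
        if complete < min_pairs:
            raise ValueError(
                f"twin_correlations: only {complete} complete {zyg} pairs for "
                f"{trait_x!r} (need >= {min_pairs})")
        res[f"icc_{zyg.lower()}"] = _double_entry_corr(x1, x2, x1, x2)
        if trait_y is not None:
            y1 = sub[f"{trait_y}_1"].to_numpy(float)
            y2 = sub[f"{trait_y}_2"].to_numpy(float)
            res[f"ctct_{zyg.lower()}"] = _double_entry_corr(x1, x2, y1, y2)
    return TwinCorrelations(**res)


def describe_scale(pairs: pd.DataFrame, trait: str,
                   items: pd.DataFrame | None = None,
                   transform: bool = True, seed: int = 0) -> DescriptivesRow:
    """Scale descriptives with a sex-by-zygosity ANOVA on one random member.

    Means and SDs are reported on the raw scores; skewness and (non-excess)
    kurtosis on the transformed scores, since the transform is what the
    modeling sees.  The two-way fixed-effects ANOVA (type-II sums of
    squares) uses one randomly selected member of each pair.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    from .preprocessing import pairs_to_persons

    persons = pairs_to_persons(pairs, trait)
    vals = persons[trait].to_numpy(float)
    obs = vals[np.isfinite(vals)]
    if len(obs) < 2:
        raise ValueError(f"describe_scale: trait {trait!r} has < 2 observations")

    def _cell(series) -> tuple[float, float]:
        v = series.to_numpy(float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            logger.warning("describe_scale: empty cell for %r", trait)
            return math_nan, math_nan
        return float(v.mean()), float(v.std(ddof=1))

    math_nan = float("nan")
    mean_by_sex, sd_by_sex, mean_by_zyg, sd_by_zyg = {}, {}, {}, {}
    for sex, label in ((1, "male"), (0, "female")):
        m, s = _cell(persons.loc[persons["sex"] == sex, trait])
        mean_by_sex[label], sd_by_sex[label] = m, s
    for zyg in ("MZ", "DZ"):
        m, s = _cell(persons.loc[persons["zygosity"] == zyg, trait])
        mean_by_zyg[zyg], sd_by_zyg[zyg] = m, s

    transformed = sqrt_transform(obs) if (transform and obs.min() >= 0) else obs
    skew = float(stats.skew(transformed))
    kurt = float(stats.kurtosis(transformed, fisher=False))

    alpha = cronbach_alpha(items) if items is not None else None

    one = select_random_member(pairs, seed=seed, traits=[trait], require_trait=trait)
    p_sex = p_zyg = p_int = r2 = None
    if one["sex"].nunique() > 1 and one["zygosity"].nunique() > 1:
        model = smf.ols(f"Q('{trait}') ~ C(sex) * C(zygosity)", data=one).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        p_sex = float(anova.loc["C(sex)", "PR(>F)"])
        p_zyg = float(anova.loc["C(zygosity)", "PR(>F)"])
        p_int = float(anova.loc["C(sex):C(zygosity)", "PR(>F)"])
        r2 = float(model.rsquared)

    return DescriptivesRow(
        trait=trait, mean=float(obs.mean()), sd=float(obs.std(ddof=1)),
        mean_by_sex=mean_by_sex, sd_by_sex=sd_by_sex,
        mean_by_zyg=mean_by_zyg, sd_by_zyg=sd_by_zyg,
        score_range=(float(obs.min()), float(obs.max())),
        skew=skew, kurtosis=kurt, alpha=alpha,
        p_sex=p_sex, p_zyg=p_zyg, p_interaction=p_int,
        r_squared=r2, n=len(one))


def correlation_gate(correlations: dict[str, float],
                     threshold: float = 0.25) -> list[str]:
    """Trait (pair) names whose correlation strictly exceeds the threshold.

    The gate decides which outcomes carry enough phenotypic covariation with
    the exposure to warrant bivariate twin modeling.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return [name for name, r in correlations.items() if r > threshold]
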
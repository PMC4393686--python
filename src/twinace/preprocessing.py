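"""Scale scoring, normalization, and sex/age adjustment for twin pair tables.

Standard behavioral-genetic preprocessing: item totals, square-root transform
of positively skewed scales, OLS residualization on sex and age with
standardization, and one-random-member selection for person-level analyses.

The square-root transform is applied before residualization: residuals can be
negative, so the reverse order is not well defined for a square root.
Residualization fits a single regression over all persons (both twins
stacked); pair clustering affects standard errors, not the residuals
themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleDefinition",
    "score_scale",
    "sqrt_transform",
    "residualize",
    "Residualizer",
    "residualize_pairs",
    "select_random_member",
    "pairs_to_persons",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A summed composite scale: item names plus the legal response range."""

    name: str
    items: tuple[str, ...]
    response_range: tuple[float, float] = (0, 2)

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError(f"scale {self.name!r} must declare at least one item")
        lo, hi = self.response_range
        if lo >= hi:
            raise ValueError(f"scale {self.name!r} has empty response range {self.response_range}")


def score_scale(items: pd.DataFrame, scale: ScaleDefinition,
                missing_policy: str = "complete") -> pd.Series:
    """Sum item responses into a total composite score per person.

    missing_policy
        ``"complete"`` (default): the total is missing if any item is
        missing.  ``"prorate"``: mean of observed items times the item
        count, missing only when every item is missing.
    """
    missing_cols = [c for c in scale.items if c not in items.columns]
    if missing_cols:
        raise ValueError(f"scale {scale.name!r}: item columns not found: {missing_cols}")
    block = items[list(scale.items)].astype(float)
    lo, hi = scale.response_range
    for col in scale.items:
        vals = block[col]
        bad = vals[(vals.notna()) & ((vals < lo) | (vals > hi))]
        if len(bad):
            raise ValueError(
                f"item {col!r} has responses outside [{lo}, {hi}]: "
                f"e.g. {bad.iloc[0]!r} at row {bad.index[0]!r}"
            )
    if missing_policy == "complete":
        total = block.sum(axis=1, min_count=len(scale.items))
    elif missing_policy == "prorate":
        total = block.mean(axis=1) * len(scale.items)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    total.name = scale.name
    return total


def sqrt_transform(scores):
    """Element-wise square root; missing propagates; input must be >= 0."""
    arr = np.asarray(scores, dtype=float)
    if np.nanmin(arr, initial=np.inf) < 0:
        raise ValueError("sqrt_transform requires non-negative scores")
    out = np.sqrt(arr)
    if isinstance(scores, pd.Series):
        return pd.Series(out, index=scores.index, name=scores.name)
    return out


class Residualizer(BaseEstimator, TransformerMixin):
    """OLS residualization of a trait on sex and age, then standardization.

    Fits ``score ~ 1 + sex + age`` by ordinary least squares on complete
    rows, and transforms scores to residuals rescaled to mean 0, variance 1
    over non-missing entries.  Constant predictor columns are dropped with a
    logged warning.  Follows the scikit-learn transformer protocol so it can
    sit in a pipeline ahead of the twin-model estimators.
    """

    def __init__(self, with_sex: bool = True, with_age: bool = True):
        self.with_sex = with_sex
        self.with_age = with_age

    def _design(self, sex, age, n):
        cols = [np.ones(n)]
        names = ["intercept"]
        for use, vals, name in ((self.with_sex, sex, "sex"), (self.with_age, age, "age")):
            if not use:
                continue
            v = np.asarray(vals, dtype=float)
            cols.append(v)
            names.append(name)
        return np.column_stack(cols), names

    def fit(self, scores, sex=None, age=None):
        y = np.asarray(scores, dtype=float)
        X, names = self._design(sex, age, len(y))
        ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
        if ok.sum() == 0:
            raise ValueError("residualize: trait is entirely missing")
        if ok.sum() < 3:
            raise ValueError(f"residualize: need >= 3 complete rows, got {ok.sum()}")
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.ptp(X[ok, j]) == 0:
                logger.warning("residualize: dropping constant predictor %r", names[j])
            else:
                keep.append(j)
        self.columns_ = [names[j] for j in keep]
        Xk = X[:, keep]
        beta, *_ = np.linalg.lstsq(Xk[ok], y[ok], rcond=None)
        self.coef_ = beta
        resid = y[ok] - Xk[ok] @ beta
        self.resid_mean_ = resid.mean()
        self.resid_sd_ = resid.std(ddof=1)
        if self.resid_sd_ == 0:
            raise ValueError("residualize: residuals have zero variance")
        self._keep = keep
        return self

    def transform(self, scores, sex=None, age=None):
        y = np.asarray(scores, dtype=float)
        X, _ = self._design(sex, age, len(y))
        Xk = X[:, self._keep]
        out = np.full(len(y), np.nan)
        ok = np.isfinite(y) & np.isfinite(Xk).all(axis=1)
        out[ok] = (y[ok] - Xk[ok] @ self.coef_ - self.resid_mean_) / self.resid_sd_
        if isinstance(scores, pd.Series):
            return pd.Series(out, index=scores.index, name=scores.name)
        return out


def residualize(scores, sex=None, age=None):
    """Functional wrapper: standardized OLS residuals of score on sex and age."""
    r = Residualizer(with_sex=sex is not None, with_age=age is not None)
    return r.fit(scores, sex=sex, age=age).transform(scores, sex=sex, age=age)


def residualize_pairs(pairs: pd.DataFrame, traits) -> pd.DataFrame:
    """Residualize pair-table traits on sex and age over stacked persons.

    One regression is fit per trait over all persons (twin 1 and twin 2
    stacked), and the standardized residuals are written back to the
    ``<trait>_1`` / ``<trait>_2`` columns.  Family count is unchanged.
    """
    if isinstance(traits, str):
        traits = [traits]
    out = pairs.copy()
    for trait in traits:
        y = np.concatenate([pairs[f"{trait}_1"].to_numpy(float),
                            pairs[f"{trait}_2"].to_numpy(float)])
        sex = np.concatenate([pairs["sex_1"].to_numpy(float),
                              pairs["sex_2"].to_numpy(float)])
        age = np.concatenate([pairs["age"].to_numpy(float)] * 2)
        res = residualize(y, sex=sex, age=age)
        n = len(pairs)
        out[f"{trait}_1"] = res[:n]
        out[f"{trait}_2"] = res[n:]
    return out


def pairs_to_persons(pairs: pd.DataFrame, traits) -> pd.DataFrame:
    """Stack a pair table into one row per person (twin order column kept)."""
    if isinstance(traits, str):
        traits = [traits]
    rows = []
    for twin in (1, 2):
        cols = {
            "family_id": pairs["family_id"],
            "zygosity": pairs["zygosity"],
            "twin": twin,
            "sex": pairs[f"sex_{twin}"],
            "age": pairs["age"],
        }
        for t in traits:
            cols[t] = pairs[f"{t}_{twin}"]
        rows.append(pd.DataFrame(cols))
    return pd.concat(rows, ignore_index=True)


def select_random_member(pairs: pd.DataFrame, seed: int = 0,
                         traits=None, require_trait: str | None = None) -> pd.DataFrame:
    """Pick one twin per family uniformly at random, reproducibly.

    If ``require_trait`` is given, pairs whose selected member is missing
    that trait are dropped (not swapped, which would bias toward complete
    observations).
    """
    if len(pairs) == 0:
        raise ValueError("select_random_member: empty pair table")
    if traits is None:
        traits = sorted({c[:-2] for c in pairs.columns if c.endswith(("_1", "_2"))
                         and not c.startswith("sex")})
    elif isinstance(traits, str):
        traits = [traits]
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=len(pairs))
    cols = {
        "family_id": pairs["family_id"].to_numpy(),
        "zygosity": pairs["zygosity"].to_numpy(),
        "twin": pick,
        "age": pairs["age"].to_numpy(),
        "sex": np.where(pick == 1, pairs["sex_1"], pairs["sex_2"]),
    }
    for t in traits:
        cols[t] = np.where(pick == 1, pairs[f"{t}_1"], pairs[f"{t}_2"])
    out = pd.DataFrame(cols)
    if require_trait is not None:
        out = out[out[require_trait].notna()].reset_index(drop=True)
    return out
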
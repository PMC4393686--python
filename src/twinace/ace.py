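"""Maximum-likelihood ACE variance-component models for twin pair data.

The classical twin design decomposes phenotypic variance into additive
genetic (A), common-environment (C) and unique-environment (E) components
from the expected covariance structure of MZ and DZ pairs:

    Var(y)            = a^2 + c^2 + e^2
    Cov(y1, y2 | MZ)  = a^2 + c^2
    Cov(y1, y2 | DZ)  = 0.5 a^2 + c^2

The bivariate correlated-factors model adds per-trait paths plus factor
correlations r_a, r_c, r_e between the two traits; the cross-twin
cross-trait covariance is alpha * a_X a_Y r_a + c_X c_Y r_c with alpha = 1
(MZ) or 0.5 (DZ), which is what identifies the genetic and environmental
sources of trait covariation.

Likelihoods are full-information maximum likelihood (FIML): every pair
contributes the multivariate-normal density of its observed subvector, so
partially missing pairs are retained.  Pairs are grouped by missingness
pattern and the likelihood is evaluated from per-pattern sufficient
statistics (count, mean, scatter), which makes repeated evaluations cheap.

Models are exposed as scikit-learn style estimators (:class:`UnivariateACE`,
:class:`BivariateACE`) with ``fit``, ``get_params``/``set_params``, and
fitted attributes carrying a trailing underscore; module-level functions are
thin wrappers.  Path coefficients are estimated unconstrained in sign and
reported as squared, standardized components, which avoids boundary
pathologies at zero; factor correlations are optimized through a tanh
transform to stay inside (-1, 1).

Confidence intervals are profile-likelihood intervals: the bound is where
the -2 log-likelihood, re-optimized over all other parameters, rises by the
chi-square(1) quantile (3.841 at 95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "UnivariateACEParams",
    "BivariateACEParams",
    "ModelSpec",
    "FitResult",
    "ComparisonRow",
    "expected_cov_univariate",
    "expected_cov_bivariate",
    "fiml_neg2ll",
    "UnivariateACE",
    "BivariateACE",
    "fit_model",
    "profile_ci",
    "compare_models",
    "select_best",
    "falconer_univariate",
    "falconer_bivariate",
    "derived_bivariate",
]

ZYGOSITIES = ("MZ", "DZ")
_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12

UNIVARIATE_FAMILIES = ("saturated", "ACE", "AE", "CE", "E")
BIVARIATE_FAMILIES = ("saturated", "ACE", "ACE_drop_ra", "ACE_drop_rc", "AE", "CE")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class UnivariateACEParams:
    """Path coefficients (a, c, e) and mean for one trait.

    Standardized variance components are the squared paths divided by the
    total; they always sum to 1.
    """

    a: float
    c: float
    e: float
    mu: float = 0.0

    def __post_init__(self):
        if self.a ** 2 + self.c ** 2 + self.e ** 2 <= 0:
            raise ValueError("total variance a^2+c^2+e^2 must be positive")

    @property
    def total_var(self) -> float:
        return self.a ** 2 + self.c ** 2 + self.e ** 2

    @property
    def a2(self) -> float:
        return self.a ** 2 / self.total_var

    @property
    def c2(self) -> float:
        return self.c ** 2 / self.total_var

    @property
    def e2(self) -> float:
        return self.e ** 2 / self.total_var

    def standardized(self) -> dict[str, float]:
        return {"a2": self.a2, "c2": self.c2, "e2": self.e2}


@dataclass(frozen=True)
class BivariateACEParams:
    """Correlated-factors parameterization for a pair of traits.

    Per-trait paths plus factor correlations r_a, r_c, r_e linking the
    latent factors of trait X with those of trait Y.
    """

    a_x: float
    c_x: float
    e_x: float
    a_y: float
    c_y: float
    e_y: float
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0
    mu_x: float = 0.0
    mu_y: float = 0.0

    def __post_init__(self):
        for name in ("r_a", "r_c", "r_e"):
            r = getattr(self, name)
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1], got {r}")

    def trait(self, which: str) -> UnivariateACEParams:
        if which == "x":
            return UnivariateACEParams(self.a_x, self.c_x, self.e_x, self.mu_x)
        return UnivariateACEParams(self.a_y, self.c_y, self.e_y, self.mu_y)


@dataclass(frozen=True)
class ModelSpec:
    """Which model family to fit, plus optimizer settings."""

    family: str
    traits: tuple[str, ...] = ()
    n_starts: int = 8
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.family not in set(UNIVARIATE_FAMILIES) | set(BIVARIATE_FAMILIES):
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class FitResult:
    """Outcome of one FIML fit."""

    model: str
    minus2ll: float
    df: int
    n_free: int
    n_obs: int
    estimates: dict[str, float]
    params: object | None
    n_used: dict[str, int]
    converged: bool
    boundary: bool
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class ComparisonRow:
    """One model's fit relative to the saturated reference (LRT, BIC)."""

    model: str
    minus2ll: float
    df: int
    lrt: float | None
    delta_df: int | None
    p: float | None
    bic: float | None


# ---------------------------------------------------------------------------
# expected covariance algebra


def expected_cov_univariate(params: UnivariateACEParams, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 twin covariance for one trait."""
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    alpha = 1.0 if zygosity == "MZ" else 0.5
    a2, c2, e2 = params.a ** 2, params.c ** 2, params.e ** 2
    diag = a2 + c2 + e2
    off = alpha * a2 + c2
    return np.array([[diag, off], [off, diag]])


def expected_cov_bivariate(params: BivariateACEParams, zygosity: str) -> np.ndarray:
    """Model-implied 4x4 pair covariance, ordering (X1, Y1, X2, Y2)."""
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    alpha = 1.0 if zygosity == "MZ" else 0.5
    p = params
    var_x = p.a_x ** 2 + p.c_x ** 2 + p.e_x ** 2
    var_y = p.a_y ** 2 + p.c_y ** 2 + p.e_y ** 2
    within = p.a_x * p.a_y * p.r_a + p.c_x * p.c_y * p.r_c + p.e_x * p.e_y * p.r_e
    ct_x = alpha * p.a_x ** 2 + p.c_x ** 2
    ct_y = alpha * p.a_y ** 2 + p.c_y ** 2
    ctct = alpha * p.a_x * p.a_y * p.r_a + p.c_x * p.c_y * p.r_c
    sigma = np.array([
        [var_x, within, ct_x, ctct],
        [within, var_y, ctct, ct_y],
        [ct_x, ctct, var_x, within],
        [ctct, ct_y, within, var_y],
    ])
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-10:
        raise ValueError(
            f"implied {zygosity} covariance is not positive semidefinite; "
            f"eigenvalues {np.round(w, 6).tolist()}"
        )
    return sigma


# ---------------------------------------------------------------------------
# FIML likelihood from per-pattern sufficient statistics


class _PatternStats:
    """Sufficient statistics of one missingness pattern within a group."""

    __slots__ = ("idx", "n", "mean", "scatter")

    def __init__(self, idx: np.ndarray, y: np.ndarray):
        self.idx = idx
        self.n = y.shape[0]
        self.mean = y.mean(axis=0)
        d = y - self.mean
        self.scatter = d.T @ d


def _pattern_stats(Y: np.ndarray) -> list[_PatternStats]:
    """Group rows of Y (NaN = missing) by missingness pattern."""
    obs = ~np.isnan(Y)
    keep = obs.any(axis=1)
    if not keep.all():
        Y, obs = Y[keep], obs[keep]
    if Y.shape[0] == 0:
        return []
    codes = obs @ (1 << np.arange(Y.shape[1]))
    out = []
    for code in np.unique(codes):
        rows = codes == code
        idx = np.flatnonzero(obs[np.flatnonzero(rows)[0]])
        out.append(_PatternStats(idx, Y[np.ix_(rows, idx)]))
    return out


def _neg2ll_patterns(patterns: list[_PatternStats], mu: np.ndarray,
                     sigma: np.ndarray) -> float:
    """-2 log-likelihood of a multivariate-normal group from pattern stats."""
    total = 0.0
    for p in patterns:
        sub = sigma[np.ix_(p.idx, p.idx)]
        try:
            L = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return _BIG
        logdet = 2.0 * np.log(np.diag(L)).sum()
        diff = p.mean - mu[p.idx]
        z = np.linalg.solve(L, diff)
        tr = np.trace(np.linalg.solve(sub, p.scatter))
        total += p.n * (len(p.idx) * _LOG2PI + logdet + z @ z) + tr
    return total


def fiml_neg2ll(pairs: pd.DataFrame, traits, means: dict[str, np.ndarray],
                covs: dict[str, np.ndarray]) -> float:
    """FIML -2 log-likelihood of a pair table under given per-zygosity moments.

    ``means[z]`` and ``covs[z]`` are the model-implied mean vector and
    covariance for zygosity ``z``, over the column ordering
    (trait1_1, trait2_1, ..., trait1_2, trait2_2, ...) for the listed traits
    (univariate: (y1, y2); bivariate: (X1, Y1, X2, Y2)).
    """
    if isinstance(traits, str):
        traits = [traits]
    total = 0.0
    for zyg in ZYGOSITIES:
        sub = pairs[pairs["zygosity"] == zyg]
        if len(sub) == 0:
            continue
        Y = _pair_matrix(sub, traits)
        total += _neg2ll_patterns(_pattern_stats(Y), np.asarray(means[zyg], float),
                                  np.asarray(covs[zyg], float))
    return total


def _pair_matrix(pairs: pd.DataFrame, traits) -> np.ndarray:
    cols = [f"{t}_{i}" for i in (1, 2) for t in traits]
    return pairs[cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# model families: theta <-> implied moments


def _chol_unpack(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = theta
    return L


def _chol_pack(sigma: np.ndarray) -> np.ndarray:
    k = sigma.shape[0]
    w, v = np.linalg.eigh(sigma)
    sigma = (v * np.clip(w, 1e-6, None)) @ v.T
    return np.linalg.cholesky(sigma)[np.tril_indices(k)]


class _Family:
    """Maps a free-parameter vector to per-zygosity implied moments."""

    name: str
    k: int  # variables per pair
    free_names: list[str]

    def moments(self, theta):  # -> (means, covs) dicts
        raise NotImplementedError

    def params_object(self, theta):
        return None

    def estimates(self, theta) -> dict[str, float]:
        return {}

    def reportable(self, theta) -> dict[str, float]:
        """Values on the reporting scale, profiled for CIs."""
        return self.estimates(theta)


class _SaturatedFamily(_Family):
    """Free means and covariances per zygosity (Cholesky parameterized)."""

    def __init__(self, k: int):
        self.k = k
        self.name = "saturated"
        m = k * (k + 1) // 2
        self._m = m
        self.free_names = [f"{z}_{w}" for z in ZYGOSITIES
                           for w in [f"mu{i}" for i in range(k)] + [f"L{j}" for j in range(m)]]

    def moments(self, theta):
        k, m = self.k, self._m
        means, covs = {}, {}
        off = 0
        for z in ZYGOSITIES:
            means[z] = theta[off:off + k]
            L = _chol_unpack(theta[off + k:off + k + m], k)
            covs[z] = L @ L.T
            off += k + m
        return means, covs

    def estimates(self, theta):
        means, covs = self.moments(theta)
        out = {}
        for z in ZYGOSITIES:
            for i in range(self.k):
                out[f"{z}_mu{i + 1}"] = means[z][i]
            for i in range(self.k):
                for j in range(i + 1):
                    out[f"{z}_cov{i + 1}{j + 1}"] = covs[z][i, j]
        return out


class _UnivariateFamily(_Family):
    """ACE / AE / CE / E path model, means equated across twins and zygosity."""

    k = 2
    _paths = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}

    def __init__(self, family: str):
        self.name = family
        self.free_names = list(self._paths[family]) + ["mu"]

    def params_object(self, theta) -> UnivariateACEParams:
        vals = dict(zip(self.free_names, theta))
        return UnivariateACEParams(
            a=vals.get("a", 0.0), c=vals.get("c", 0.0), e=vals["e"], mu=vals["mu"])

    def moments(self, theta):
        p = self.params_object(theta)
        means = {z: np.full(2, p.mu) for z in ZYGOSITIES}
        covs = {z: expected_cov_univariate(p, z) for z in ZYGOSITIES}
        return means, covs

    def estimates(self, theta):
        p = self.params_object(theta)
        out = {"mu": p.mu, "total_var": p.total_var}
        out.update(p.standardized())
        return out

    def reportable(self, theta):
        p = self.params_object(theta)
        return {"a2": p.a2, "c2": p.c2, "e2": p.e2, "mu": p.mu}


class _BivariateFamily(_Family):
    """Correlated-factors model; factor correlations via tanh."""

    k = 4
    _spec = {
        "ACE": (("a_x", "c_x", "e_x", "a_y", "c_y", "e_y"), ("r_a", "r_c", "r_e")),
        "ACE_drop_ra": (("a_x", "c_x", "e_x", "a_y", "c_y", "e_y"), ("r_c", "r_e")),
        "ACE_drop_rc": (("a_x", "c_x", "e_x", "a_y", "c_y", "e_y"), ("r_a", "r_e")),
        "AE": (("a_x", "e_x", "a_y", "e_y"), ("r_a", "r_e")),
        "CE": (("c_x", "e_x", "c_y", "e_y"), ("r_c", "r_e")),
    }

    def __init__(self, family: str):
        self.name = family
        paths, rs = self._spec[family]
        self._path_names, self._r_names = paths, rs
        self.free_names = list(paths) + [f"z_{r}" for r in rs] + ["mu_x", "mu_y"]

    def params_object(self, theta) -> BivariateACEParams:
        vals = dict(zip(self.free_names, theta))
        kw = {p: vals.get(p, 0.0) for p in ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")}
        for r in ("r_a", "r_c", "r_e"):
            kw[r] = math.tanh(vals[f"z_{r}"]) if f"z_{r}" in vals else 0.0
        kw["mu_x"], kw["mu_y"] = vals["mu_x"], vals["mu_y"]
        return BivariateACEParams(**kw)

    def moments(self, theta):
        p = self.params_object(theta)
        means = {z: np.array([p.mu_x, p.mu_y, p.mu_x, p.mu_y]) for z in ZYGOSITIES}
        covs = {}
        for z in ZYGOSITIES:
            try:
                covs[z] = expected_cov_bivariate(p, z)
            except ValueError:
                return means, None
        return means, covs

    def estimates(self, theta):
        p = self.params_object(theta)
        out = {}
        for which, suffix in (("x", "_x"), ("y", "_y")):
            tp = p.trait(which)
            out.update({f"a2{suffix}": tp.a2, f"c2{suffix}": tp.c2,
                        f"e2{suffix}": tp.e2, f"mu{suffix}": tp.mu})
        out.update({"r_a": p.r_a, "r_c": p.r_c, "r_e": p.r_e})
        out.update(derived_bivariate(p, strict=False))
        return out

    def reportable(self, theta):
        est = self.estimates(theta)
        keys = ["a2_x", "c2_x", "e2_x", "a2_y", "c2_y", "e2_y",
                "biva2", "bivc2", "bive2"]
        out = {k: est[k] for k in keys if k in est}
        for r in self._r_names:
            out[r] = est[r]
        return out


def _make_family(family: str, k: int) -> _Family:
    if family == "saturated":
        return _SaturatedFamily(k)
    if k == 2:
        return _UnivariateFamily(family)
    return _BivariateFamily(family)


# ---------------------------------------------------------------------------
# fitting


def _group_patterns(pairs: pd.DataFrame, traits) -> tuple[dict, dict, int]:
    patterns, n_pairs, n_obs = {}, {}, 0
    for zyg in ZYGOSITIES:
        sub = pairs[pairs["zygosity"] == zyg]
        Y = _pair_matrix(sub, traits)
        keep = (~np.isnan(Y)).any(axis=1)
        patterns[zyg] = _pattern_stats(Y)
        n_pairs[zyg] = int(keep.sum())
        n_obs += int((~np.isnan(Y)).sum())
    return patterns, n_pairs, n_obs


def _objective(family: _Family, patterns: dict):
    def fun(theta):
        means, covs = family.moments(theta)
        if covs is None:
            return _BIG
        total = 0.0
        for z in ZYGOSITIES:
            total += _neg2ll_patterns(patterns[z], np.asarray(means[z], float), covs[z])
            if total >= _BIG:
                return _BIG
        return total
    return fun


def _sample_moments(pairs: pd.DataFrame, traits) -> tuple[dict, dict]:
    """Pairwise-complete per-zygosity moments, for starting values."""
    means, covs = {}, {}
    for zyg in ZYGOSITIES:
        sub = pairs[pairs["zygosity"] == zyg]
        Y = _pair_matrix(sub, traits)
        df = pd.DataFrame(Y)
        means[zyg] = df.mean().to_numpy()
        cov = df.cov(ddof=0).to_numpy()
        if np.isnan(cov).any():
            cov = np.eye(Y.shape[1])
        covs[zyg] = cov
    return means, covs


def _start_values(family: _Family, pairs: pd.DataFrame, traits) -> np.ndarray:
    means, covs = _sample_moments(pairs, traits)
    if isinstance(family, _SaturatedFamily):
        parts = []
        for z in ZYGOSITIES:
            parts.append(means[z])
            parts.append(_chol_pack(covs[z]))
        return np.concatenate(parts)
    if isinstance(family, _UnivariateFamily):
        var = np.mean([covs[z].diagonal().mean() for z in ZYGOSITIES])
        var = max(var, 1e-3)
        r_mz = covs["MZ"][0, 1] / max(covs["MZ"].diagonal().mean(), 1e-9)
        r_dz = covs["DZ"][0, 1] / max(covs["DZ"].diagonal().mean(), 1e-9)
        a2, c2, e2 = falconer_univariate(r_mz, r_dz)
        shares = np.clip([a2, c2, e2], 0.05, 0.9)
        shares = shares / shares.sum()
        vals = {"a": math.sqrt(shares[0] * var), "c": math.sqrt(shares[1] * var),
                "e": math.sqrt(shares[2] * var),
                "mu": float(np.mean([means[z].mean() for z in ZYGOSITIES]))}
        return np.array([vals[n] for n in family.free_names])
    # bivariate: start each trait from its own Falconer solution, r's from CTCT
    start = {}
    for i, suffix in ((0, "_x"), (1, "_y")):
        var = np.mean([covs[z][i, i] for z in ZYGOSITIES])
        var = max(var, 1e-3)
        r_mz = covs["MZ"][i, i + 2] / max(covs["MZ"][i, i], 1e-9)
        r_dz = covs["DZ"][i, i + 2] / max(covs["DZ"][i, i], 1e-9)
        a2, c2, e2 = falconer_univariate(r_mz, r_dz)
        shares = np.clip([a2, c2, e2], 0.05, 0.9)
        shares = shares / shares.sum()
        start[f"a{suffix}"] = math.sqrt(shares[0] * var)
        start[f"c{suffix}"] = math.sqrt(shares[1] * var)
        start[f"e{suffix}"] = math.sqrt(shares[2] * var)
        start[f"mu{suffix}"] = float(np.mean([means[z][i] for z in ZYGOSITIES]))
    for r in ("r_a", "r_c", "r_e"):
        start[f"z_{r}"] = 0.2
    return np.array([start[n] for n in family.free_names])


def _minimize(fun, x0, tol, max_iter=2000):
    return optimize.minimize(fun, x0, method="L-BFGS-B",
                             options={"ftol": tol, "gtol": 1e-7, "maxiter": max_iter})


def _fit_family(family: _Family, patterns: dict, pairs, traits,
                n_starts: int, tol: float, seed: int):
    fun = _objective(family, patterns)
    x0 = _start_values(family, pairs, traits)
    best = _minimize(fun, x0, tol)
    rng = np.random.default_rng(seed)
    extra = 0 if isinstance(family, _SaturatedFamily) else max(n_starts - 1, 0)
    for _ in range(extra):
        xs = x0 * (1.0 + 0.3 * rng.standard_normal(x0.size)) + 0.05 * rng.standard_normal(x0.size)
        res = _minimize(fun, xs, tol)
        if res.fun < best.fun - 1e-9:
            best = res
    return best


def _boundary_flag(family: _Family, theta: np.ndarray) -> bool:
    if isinstance(family, _SaturatedFamily):
        return False
    est = family.estimates(theta)
    for k, v in est.items():
        if k.startswith(("a2", "c2", "e2")) and (v < 1e-4 or v > 1 - 1e-4):
            return True
        if k in ("r_a", "r_c", "r_e") and abs(v) > 0.999 and k in "".join(family.free_names):
            return True
    return False


class _BaseACEEstimator(BaseEstimator):
    """Shared FIML fitting logic behind the univariate/bivariate estimators."""

    def _traits(self, X) -> list[str]:
        raise NotImplementedError

    def _family(self) -> _Family:
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model to a twin pair table by FIML."""
        traits = self._traits(X)
        family = self._family()
        patterns, n_pairs, n_obs = _group_patterns(X, traits)
        if min(n_pairs.values()) < 2:
            raise ValueError(f"too few pairs per zygosity: {n_pairs}")
        res = _fit_family(family, patterns, X, traits,
                          self.n_starts, self.tol, self.seed)
        self._family_obj = family
        self._patterns = patterns
        self.theta_ = res.x
        self.minus2ll_ = float(res.fun)
        self.n_free_ = len(family.free_names)
        self.n_obs_ = n_obs
        self.df_ = n_obs - self.n_free_
        self.n_pairs_ = n_pairs
        self.converged_ = bool(res.success) and res.fun < _BIG
        self.boundary_ = _boundary_flag(family, res.x)
        self.params_ = family.params_object(res.x)
        self.estimates_ = family.estimates(res.x)
        return self

    # -- reporting -----------------------------------------------------

    def result(self, ci: dict | None = None) -> FitResult:
        return FitResult(
            model=self.model, minus2ll=self.minus2ll_, df=self.df_,
            n_free=self.n_free_, n_obs=self.n_obs_,
            estimates=dict(self.estimates_), params=self.params_,
            n_used=dict(self.n_pairs_), converged=self.converged_,
            boundary=self.boundary_, ci=ci or {})

    def implied_moments(self):
        """Model-implied (means, covariances) per zygosity at the optimum."""
        return self._family_obj.moments(self.theta_)

    # -- profile confidence intervals ----------------------------------

    def profile_ci(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood CI for a reported parameter.

        The bound is where -2LL, re-optimized over all other parameters
        subject to the reported quantity being fixed, exceeds the optimum by
        the chi-square(1) quantile.  Bounds are clipped to the parameter
        domain (variance shares to [0, 1], correlations to [-1, 1]); a bound
        at the domain edge is reported as the edge.
        """
        family = self._family_obj
        reportable = family.reportable(self.theta_)
        if param not in reportable:
            raise ValueError(f"{param!r} is not a free parameter of model {self.model!r}")
        crit = stats.chi2.ppf(level, 1)
        target = self.minus2ll_ + crit
        fun = _objective(family, self._patterns)
        hat = reportable[param]

        if param.startswith(("a2", "c2", "e2")):
            lo_dom, hi_dom = 0.0, 1.0
        elif param.startswith("r_") or param.startswith("biv"):
            lo_dom, hi_dom = -1.0, 1.0
        else:
            lo_dom, hi_dom = -np.inf, np.inf

        def constrained(v: float) -> float:
            cons = {"type": "eq",
                    "fun": lambda th: family.reportable(th)[param] - v}
            res = optimize.minimize(fun, self.theta_, method="SLSQP",
                                    constraints=[cons],
                                    options={"ftol": 1e-10, "maxiter": 400})
            return float(res.fun)

        def bound(direction: int) -> float:
            step = max(0.02, abs(hat) * 0.1)
            v_in, f_in = hat, self.minus2ll_
            v = hat
            for _ in range(60):
                v = v + direction * step
                edge = hi_dom if direction > 0 else lo_dom
                hit_edge = (direction > 0 and v >= hi_dom) or (direction < 0 and v <= lo_dom)
                if hit_edge:
                    v = edge
                f = constrained(v)
                if f >= target:
                    lo, hi = (v_in, v) if direction > 0 else (v, v_in)
                    g = lambda u: constrained(u) - target
                    try:
                        return float(optimize.brentq(g, lo, hi, xtol=1e-4))
                    except ValueError:
                        return v
                if hit_edge:
                    return edge  # likelihood never rises enough inside domain
                v_in, f_in = v, f
                step *= 1.6
            return v

        return bound(-1), bound(+1)


class UnivariateACE(_BaseACEEstimator):
    """Univariate twin ACE model fit by FIML.

    Parameters
    ----------
    model : {"saturated", "ACE", "AE", "CE", "E"}
        Which family to fit.  Path models equate the trait mean across twins
        and zygosity groups; the saturated model frees means, variances and
        the within-pair covariance separately per zygosity group.
    trait : str, optional
        Trait name (columns ``<trait>_1``/``<trait>_2``); auto-detected when
        the table carries a single trait.
    n_starts : int
        Seeded multi-start count for the path models.
    """

    def __init__(self, model: str = "ACE", trait: str | None = None,
                 n_starts: int = 8, tol: float = 1e-8, seed: int = 0):
        self.model = model
        self.trait = trait
        self.n_starts = n_starts
        self.tol = tol
        self.seed = seed

    def _traits(self, X):
        if self.trait is not None:
            return [self.trait]
        traits = sorted({c[:-2] for c in X.columns
                         if c.endswith(("_1", "_2")) and not c.startswith("sex")})
        if len(traits) != 1:
            raise ValueError(f"specify trait=; table carries {traits}")
        return traits

    def _family(self):
        if self.model not in UNIVARIATE_FAMILIES:
            raise ValueError(f"unknown univariate family {self.model!r}")
        return _make_family(self.model, 2)


class BivariateACE(_BaseACEEstimator):
    """Bivariate correlated-factors twin model fit by FIML.

    ``model`` is one of ``saturated``, ``ACE``, ``ACE_drop_ra``,
    ``ACE_drop_rc``, ``AE``, ``CE``; the ``drop`` variants fix the named
    factor correlation to zero.  Column ordering within a pair is
    (X1, Y1, X2, Y2) with X = ``trait_x``.
    """

    def __init__(self, model: str = "ACE", trait_x: str | None = None,
                 trait_y: str | None = None, n_starts: int = 8,
                 tol: float = 1e-8, seed: int = 0):
        self.model = model
        self.trait_x = trait_x
        self.trait_y = trait_y
        self.n_starts = n_starts
        self.tol = tol
        self.seed = seed

    def _traits(self, X):
        if self.trait_x is None or self.trait_y is None:
            raise ValueError("trait_x and trait_y must be given")
        return [self.trait_x, self.trait_y]

    def _family(self):
        if self.model not in BIVARIATE_FAMILIES:
            raise ValueError(f"unknown bivariate family {self.model!r}")
        return _make_family(self.model, 4)


def fit_model(pairs: pd.DataFrame, spec: ModelSpec,
              ci_params: tuple[str, ...] = ()) -> FitResult:
    """Fit one model family per a :class:`ModelSpec` and return a FitResult."""
    if len(spec.traits) == 1 or (len(spec.traits) == 0):
        trait = spec.traits[0] if spec.traits else None
        est = UnivariateACE(model=spec.family, trait=trait, n_starts=spec.n_starts,
                            tol=spec.tol, seed=spec.seed)
    elif len(spec.traits) == 2:
        est = BivariateACE(model=spec.family, trait_x=spec.traits[0],
                           trait_y=spec.traits[1], n_starts=spec.n_starts,
                           tol=spec.tol, seed=spec.seed)
    else:
        raise ValueError("ModelSpec.traits must name one or two traits")
    est.fit(pairs)
    ci = {p: est.profile_ci(p) for p in ci_params}
    return est.result(ci=ci)


def profile_ci(estimator: _BaseACEEstimator, param: str,
               level: float = 0.95) -> tuple[float, float]:
    """Module-level wrapper over the estimator's profile CI."""
    return estimator.profile_ci(param, level=level)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fits, saturated: FitResult,
                   n_for_bic: int | None = None) -> list[ComparisonRow]:
    """LRT against the saturated model plus Mx-convention BIC per fit.

    LRT = -2LL(model) - (-2LL(saturated)); p from chi-square with the df
    difference; BIC = -2LL - df * ln(N) with N the number of pairs
    contributing data (lower / more negative is better).  Absolute BIC
    depends on the N convention; comparisons should use differences only.
    """
    rows = [ComparisonRow(model=saturated.model, minus2ll=saturated.minus2ll,
                          df=saturated.df, lrt=None, delta_df=None, p=None, bic=None)]
    for fit in fits:
        lrt = fit.minus2ll - saturated.minus2ll
        if lrt < -1e-6:
            raise ValueError(
                f"negative LRT ({lrt:.3g}) for {fit.model}: submodel fits better "
                "than the saturated model, optimizer failure")
        lrt = max(lrt, 0.0)
        ddf = fit.df - saturated.df
        p = float(stats.chi2.sf(lrt, ddf)) if ddf > 0 else (1.0 if lrt <= 1e-6 else 0.0)
        n = n_for_bic if n_for_bic is not None else sum(fit.n_used.values())
        bic = fit.minus2ll - fit.df * math.log(n)
        rows.append(ComparisonRow(model=fit.model, minus2ll=fit.minus2ll, df=fit.df,
                                  lrt=lrt, delta_df=ddf, p=p, bic=bic))
    return rows


def select_best(rows: list[ComparisonRow], alpha: float = 0.05) -> str:
    """Best model: lowest BIC among models not rejected by LRT vs saturated.

    Falls back to the lowest-BIC model overall if every model is rejected;
    ties broken toward fewer free parameters (larger df).
    """
    candidates = [r for r in rows if r.p is not None and r.p > alpha]
    if not candidates:
        candidates = [r for r in rows if r.bic is not None]
    if not candidates:
        raise ValueError("no comparable models")
    best = min(candidates, key=lambda r: (r.bic, -r.df))
    return best.model


# ---------------------------------------------------------------------------
# closed-form oracles and derived quantities


def falconer_univariate(icc_mz: float, icc_dz: float) -> tuple[float, float, float]:
    """Falconer's moment estimators: a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ,
    e2 = 1 - rMZ.  No truncation; values may exit [0, 1]."""
    a2 = 2.0 * (icc_mz - icc_dz)
    c2 = 2.0 * icc_dz - icc_mz
    e2 = 1.0 - icc_mz
    return a2, c2, e2


def falconer_bivariate(ctct_mz: float, ctct_dz: float,
                       r_phenotypic: float) -> tuple[float, float, float]:
    """Moment decomposition of a phenotypic correlation from CTCT contrasts.

    a_cov = 2(CTCT_MZ - CTCT_DZ); c_cov = 2 CTCT_DZ - CTCT_MZ;
    e_cov = r_ph - a_cov - c_cov.  Components sum to the phenotypic r.
    """
    a_cov = 2.0 * (ctct_mz - ctct_dz)
    c_cov = 2.0 * ctct_dz - ctct_mz
    e_cov = r_phenotypic - a_cov - c_cov
    return a_cov, c_cov, e_cov


def derived_bivariate(params: BivariateACEParams, strict: bool = True) -> dict[str, float]:
    """Bivariate shares and implied correlations from a correlated-factors fit.

    The cross-trait covariance splits into A = a_X a_Y r_a, C = c_X c_Y r_c,
    E = e_X e_Y r_e (on the standardized scale).  ``biva2`` etc. are each
    component's share of the implied phenotypic correlation -- the
    proportion of the trait association carried by genes / shared
    environment / unique environment.
    """
    p = params
    sd_x = math.sqrt(p.a_x ** 2 + p.c_x ** 2 + p.e_x ** 2)
    sd_y = math.sqrt(p.a_y ** 2 + p.c_y ** 2 + p.e_y ** 2)
    A = p.a_x * p.a_y * p.r_a / (sd_x * sd_y)
    C = p.c_x * p.c_y * p.r_c / (sd_x * sd_y)
    E = p.e_x * p.e_y * p.r_e / (sd_x * sd_y)
    r_implied = A + C + E
    out = {"r_implied": r_implied}
    for z in ZYGOSITIES:
        alpha = 1.0 if z == "MZ" else 0.5
        out[f"icc_x_{z.lower()}"] = (alpha * p.a_x ** 2 + p.c_x ** 2) / sd_x ** 2
        out[f"icc_y_{z.lower()}"] = (alpha * p.a_y ** 2 + p.c_y ** 2) / sd_y ** 2
        out[f"ctct_{z.lower()}"] = (alpha * p.a_x * p.a_y * p.r_a
                                    + p.c_x * p.c_y * p.r_c) / (sd_x * sd_y)
    if abs(r_implied) < 1e-12:
        if strict:
            raise ValueError("implied phenotypic correlation is zero; "
                             "bivariate shares are undefined")
        out.update({"biva2": math.nan, "bivc2": math.nan, "bive2": math.nan})
        return out
    out.update({"biva2": A / r_implied, "bivc2": C / r_implied, "bive2": E / r_implied})
    return out
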
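"""Synthetic twin-cohort generation with known ACE structure.

The classical twin design identifies additive-genetic (A), common-environment
(C) and unique-environment (E) variance from the contrast between monozygotic
(MZ) pairs, who share all segregating variants, and dizygotic (DZ) pairs, who
share on average half.  The generators here draw pair tables directly from the
ACE generative model so that every downstream stage (preprocessing,
descriptives, maximum-likelihood fitting) can be exercised and validated
without any real cohort data.

Latent construction
-------------------
For a trait with standardized components ``a2 + c2 + e2 = 1`` and paths
``a = sqrt(a2)`` etc., each twin's latent value is

    y_i = mu + a*A_i + c*C + e*E_i

with C shared within the pair, E_i independent, and the additive factor built
as ``A_i = A_family`` for MZ twins and ``A_i = sqrt(.5)*A_family +
sqrt(.5)*A_individual_i`` for DZ twins, which yields an exact cross-twin
additive correlation of 0.5 without rejection sampling.  In the bivariate
case the factor vectors across traits and twins have Kronecker-structured
correlation (twin-sharing pattern x trait factor correlation), drawn via a
Cholesky factor.

Small linear sex and age shifts are added by default so the residualization
stage has real signal to remove; both are removed exactly by OLS.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UnivariateGenSpec",
    "BivariateGenSpec",
    "simulate_univariate",
    "simulate_bivariate",
    "simulate_items",
    "apply_raw_scale",
    "write_cohort",
    "read_cohort",
]

#: default pair counts for paranoia-like and bullying-like runs
N_PAIRS_PARANOIA = (1719, 1551)
N_PAIRS_BULLYING = (1418, 1258)


def _check_proportions(a2: float, c2: float, e2: float) -> None:
    for name, v in (("a2", a2), ("c2", c2), ("e2", e2)):
        if v < 0:
            raise ValueError(f"variance proportion {name} must be >= 0, got {v}")
    total = a2 + c2 + e2
    if abs(total - 1.0) > 1e-12:
        raise ValueError(
            f"variance proportions a2+c2+e2 must sum to 1 (got {total!r})"
        )


@dataclass(frozen=True)
class UnivariateGenSpec:
    """Generating values for a single-trait twin cohort.

    ``a2``, ``c2``, ``e2`` are standardized variance proportions (must sum
    to 1); ``mean`` is the latent trait mean; ``n_mz``/``n_dz`` are pair
    counts; ``missing_rate`` is the element-wise MCAR probability.
    """

    a2: float
    c2: float
    e2: float
    mean: float = 0.0
    n_mz: int = N_PAIRS_PARANOIA[0]
    n_dz: int = N_PAIRS_PARANOIA[1]
    missing_rate: float = 0.0
    seed: int = 0
    trait: str = "trait"
    beta_sex: float = 0.1
    beta_age: float = 0.05
    age_range: tuple[float, float] = (15.8, 16.8)

    def __post_init__(self) -> None:
        _check_proportions(self.a2, self.c2, self.e2)
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("n_mz and n_dz must each be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")


@dataclass(frozen=True)
class BivariateGenSpec:
    """Generating values for a two-trait (X = exposure, Y = outcome) cohort.

    Per-trait proportions as in :class:`UnivariateGenSpec`; ``r_a``, ``r_c``,
    ``r_e`` are the additive-genetic, common-environment and
    unique-environment factor correlations between the traits.
    """

    a2_x: float
    c2_x: float
    e2_x: float
    a2_y: float
    c2_y: float
    e2_y: float
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0
    mean_x: float = 0.0
    mean_y: float = 0.0
    n_mz: int = N_PAIRS_BULLYING[0]
    n_dz: int = N_PAIRS_BULLYING[1]
    missing_rate: float = 0.0
    seed: int = 0
    trait_x: str = "bullying"
    trait_y: str = "paranoia"
    beta_sex: float = 0.1
    beta_age: float = 0.05
    age_range: tuple[float, float] = (15.8, 16.8)

    def __post_init__(self) -> None:
        _check_proportions(self.a2_x, self.c2_x, self.e2_x)
        _check_proportions(self.a2_y, self.c2_y, self.e2_y)
        for name in ("r_a", "r_c", "r_e"):
            r = getattr(self, name)
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"factor correlation {name} must lie in [-1, 1], got {r}")


def _ages_and_sexes(rng: np.random.Generator, n: int,
                    age_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    age = rng.uniform(age_range[0], age_range[1], size=n)
    # same-sex pairs only for MZ; DZ pairs drawn independently per twin.
    sex1 = rng.integers(0, 2, size=n)
    sex2 = rng.integers(0, 2, size=n)
    return age, sex1, sex2


def _latent_univariate(rng: np.random.Generator, n: int, zyg: str,
                       a: float, c: float, e: float) -> np.ndarray:
    """(n, 2) latent values with exact ACE cross-twin structure."""
    a_fam = rng.standard_normal(n)
    c_fam = rng.standard_normal(n)
    e_ind = rng.standard_normal((n, 2))
    if zyg == "MZ":
        a_twin = np.column_stack([a_fam, a_fam])
    else:
        a_ind = rng.standard_normal((n, 2))
        a_twin = np.sqrt(0.5) * a_fam[:, None] + np.sqrt(0.5) * a_ind
    return a * a_twin + c * c_fam[:, None] + e * e_ind


def _apply_missing(rng: np.random.Generator, y: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return y
    y = y.copy()
    mask = rng.random(y.shape) < rate
    # never blank an entire pair: keep one random element of fully-masked rows
    full = np.flatnonzero(mask.all(axis=1))
    if full.size:
        keep = rng.integers(0, y.shape[1], size=full.size)
        mask[full, keep] = False
    y[mask] = np.nan
    return y


def _assemble(zygosity: np.ndarray, age: np.ndarray, sex1: np.ndarray,
              sex2: np.ndarray, traits: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(zygosity)
    cols: dict[str, object] = {
        "family_id": [f"F{i:05d}" for i in range(n)],
        "zygosity": zygosity,
        "sex_1": sex1,
        "sex_2": sex2,
        "age": age,
    }
    for name, y in traits.items():
        cols[f"{name}_1"] = y[:, 0]
        cols[f"{name}_2"] = y[:, 1]
    return pd.DataFrame(cols)


def simulate_univariate(spec: UnivariateGenSpec) -> pd.DataFrame:
    """Draw a twin-pair table under the univariate ACE generative model.

    Returns a DataFrame with one row per pair: ``family_id``, ``zygosity``,
    ``sex_1``, ``sex_2``, ``age`` and ``<trait>_1``/``<trait>_2`` columns.
    Latent marginal variance is 1 before the (small) sex/age shifts.
    """
    rng = np.random.default_rng(spec.seed)
    a, c, e = np.sqrt([spec.a2, spec.c2, spec.e2])
    blocks = []
    for zyg, n in (("MZ", spec.n_mz), ("DZ", spec.n_dz)):
        y = _latent_univariate(rng, n, zyg, a, c, e) + spec.mean
        age, sex1, sex2 = _ages_and_sexes(rng, n, spec.age_range)
        if zyg == "MZ":
            sex2 = sex1
        mean_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
        y[:, 0] += spec.beta_sex * sex1 + spec.beta_age * (age - mean_age)
        y[:, 1] += spec.beta_sex * sex2 + spec.beta_age * (age - mean_age)
        y = _apply_missing(rng, y, spec.missing_rate)
        blocks.append(_assemble(np.repeat(zyg, n), age, sex1, sex2, {spec.trait: y}))
    df = pd.concat(blocks, ignore_index=True)
    df["family_id"] = [f"F{i:05d}" for i in range(len(df))]
    return df


def _factor_chol(r_trait: float, twin_r: float) -> np.ndarray:
    """Cholesky of the Kronecker-structured 4x4 factor correlation.

    Ordering (X1, Y1, X2, Y2): correlation ``r_trait`` within person,
    ``twin_r`` across twins same trait, ``twin_r * r_trait`` across twins
    cross trait.
    """
    r_twin = np.array([[1.0, twin_r], [twin_r, 1.0]])
    r_tr = np.array([[1.0, r_trait], [r_trait, 1.0]])
    corr = np.kron(r_twin, r_tr)
    w, _ = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError(
            f"implied factor covariance is not positive semidefinite "
            f"(minimum eigenvalue {w.min():.3e})"
        )
    # tiny jitter keeps the Cholesky defined at exact PSD boundaries
    return np.linalg.cholesky(corr + 1e-12 * np.eye(4))


def simulate_bivariate(spec: BivariateGenSpec) -> pd.DataFrame:
    """Draw a two-trait twin-pair table under the correlated-factors model.

    Sample moments converge to
    :func:`twinace.ace.expected_cov_bivariate` evaluated at the generating
    parameters.
    """
    rng = np.random.default_rng(spec.seed)
    paths_x = np.sqrt([spec.a2_x, spec.c2_x, spec.e2_x])
    paths_y = np.sqrt([spec.a2_y, spec.c2_y, spec.e2_y])
    blocks = []
    for zyg, n in (("MZ", spec.n_mz), ("DZ", spec.n_dz)):
        alpha = 1.0 if zyg == "MZ" else 0.5
        # ordering (X1, Y1, X2, Y2) per factor
        y = np.zeros((n, 4))
        for (r_f, twin_r), (px, py) in zip(
            [(spec.r_a, alpha), (spec.r_c, 1.0), (spec.r_e, 0.0)],
            [(paths_x[0], paths_y[0]), (paths_x[1], paths_y[1]), (paths_x[2], paths_y[2])],
        ):
            L = _factor_chol(r_f, twin_r)
            f = rng.standard_normal((n, 4)) @ L.T
            y += f * np.array([px, py, px, py])
        y[:, [0, 2]] += spec.mean_x
        y[:, [1, 3]] += spec.mean_y
        age, sex1, sex2 = _ages_and_sexes(rng, n, spec.age_range)
        if zyg == "MZ":
            sex2 = sex1
        mean_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
        shift1 = spec.beta_sex * sex1 + spec.beta_age * (age - mean_age)
        shift2 = spec.beta_sex * sex2 + spec.beta_age * (age - mean_age)
        y[:, 0] += shift1
        y[:, 1] += shift1
        y[:, 2] += shift2
        y[:, 3] += shift2
        y = _apply_missing(rng, y, spec.missing_rate)
        blocks.append(_assemble(
            np.repeat(zyg, n), age, sex1, sex2,
            {spec.trait_x: y[:, [0, 2]], spec.trait_y: y[:, [1, 3]]},
        ))
    df = pd.concat(blocks, ignore_index=True)
    df["family_id"] = [f"F{i:05d}" for i in range(len(df))]
    return df


def simulate_items(k: int, rho: float, n: int, seed: int = 0,
                   prefix: str = "item") -> pd.DataFrame:
    """Parallel item responses: equal variance, common inter-item correlation.

    Useful as a fixture for internal-consistency (Cronbach alpha) checks,
    where the Spearman-Brown closed form k*rho / (1 + (k-1)*rho) gives the
    population alpha.
    """
    if k < 2:
        raise ValueError(f"need at least 2 items, got k={k}")
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"inter-item correlation rho must lie in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    if rho == 1.0:
        # degenerate: identical items
        common = rng.standard_normal((n, 1))
        items = np.repeat(common, k, axis=1)
    else:
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError(
                f"item correlation matrix is not positive semidefinite "
                f"(minimum eigenvalue {w.min():.3e})"
            )
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        items = rng.standard_normal((n, k)) @ L.T
    return pd.DataFrame(items, columns=[f"{prefix}_{i + 1}" for i in range(k)])


def apply_raw_scale(latent, target_min: float = 0, target_max: float = 32,
                    skew_power: float = 2.0, rounding: bool = True):
    """Map latent values monotonically onto a bounded, positively skewed scale.

    The latent values are pushed through the normal CDF, raised to
    ``skew_power`` (>1 concentrates mass near the bottom of the range, which
    is how raw victimization/experience scales look), and rescaled to
    ``[target_min, target_max]``.  Monotone, so rank order is preserved;
    missing values propagate.
    """
    from scipy.stats import norm

    if target_min >= target_max:
        raise ValueError(f"target_min ({target_min}) must be < target_max ({target_max})")
    if skew_power <= 0:
        raise ValueError(f"skew_power must be > 0, got {skew_power}")
    arr = np.asarray(latent, dtype=float)
    x = np.asarray(arr, dtype=float)
    finite = np.isfinite(x)
    u = np.full_like(x, np.nan)
    std = np.nanstd(x)
    center = np.nanmean(x)
    if std == 0 or not np.isfinite(std):
        # constant input maps to a constant raw score
        u[finite] = 0.5
    else:
        u[finite] = norm.cdf((x[finite] - center) / std)
    raw = target_min + (target_max - target_min) * u ** skew_power
    raw = np.clip(raw, target_min, target_max)
    if rounding:
        raw = np.round(raw)
    if isinstance(latent, pd.Series):
        return pd.Series(raw, index=latent.index, name=latent.name)
    return raw


def write_cohort(df: pd.DataFrame, path, spec=None) -> None:
    """Write a pair table as CSV plus a JSON sidecar with the generating spec."""
    path = Path(path)
    df.to_csv(path, index=False)
    if spec is not None:
        meta = asdict(spec)
        meta["__spec_type__"] = type(spec).__name__
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_cohort(path) -> pd.DataFrame:
    """Read a pair-table CSV (empty cells are missing values)."""
    df = pd.read_csv(path)
    required = {"family_id", "zygosity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair table is missing required columns: {sorted(missing)}")
    bad = set(df["zygosity"].unique()) - {"MZ", "DZ"}
    if bad:
        raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
    return df
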
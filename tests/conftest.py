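import numpy as np
import pandas as pd
import pytest

import twinace as ta


@pytest.fixture(scope="session")
def bullying_cohort():
    """Cohort simulated at the bullying-like ACE solution (a2/c2/e2 = .35/.26/.39)."""
    spec = ta.UnivariateGenSpec(a2=0.35, c2=0.26, e2=0.39,
                                n_mz=1418, n_dz=1258, seed=11, trait="bullying")
    return ta.simulate_univariate(spec)


@pytest.fixture(scope="session")
def bullying_residualized(bullying_cohort):
    return ta.residualize_pairs(bullying_cohort, "bullying")


@pytest.fixture(scope="session")
def bivariate_cohort():
    """Cohort at the best-fitting bivariate solution (r_a=.55, r_c dropped)."""
    spec = ta.default_generation_spec(seed=7, missing_rate=0.0)
    return ta.simulate_bivariate(spec)


@pytest.fixture(scope="session")
def bivariate_residualized(bivariate_cohort):
    return ta.residualize_pairs(bivariate_cohort, ["bullying", "paranoia"])


@pytest.fixture(scope="session")
def moment_matched_pairs():
    """Complete balanced data whose per-zygosity sample moments are exact.

    Each zygosity group has sample mean exactly 0, variances exactly 1 and
    within-pair correlation exactly (0.6 MZ, 0.4 DZ) under the ML (ddof=0)
    convention, making the ACE model just-identified on the sample moments.
    """
    rng = np.random.default_rng(5)
    blocks = []
    for zyg, r, n in (("MZ", 0.6, 400), ("DZ", 0.4, 400)):
        X = rng.standard_normal((n, 2))
        X -= X.mean(axis=0)
        # whiten exactly, then recolor to the target correlation
        cov = (X.T @ X) / n
        L = np.linalg.cholesky(cov)
        Z = X @ np.linalg.inv(L).T
        target = np.array([[1.0, r], [r, 1.0]])
        Y = Z @ np.linalg.cholesky(target).T
        blocks.append(pd.DataFrame({
            "family_id": [f"{zyg}{i}" for i in range(n)],
            "zygosity": zyg, "sex_1": 0, "sex_2": 0, "age": 16.0,
            "y_1": Y[:, 0], "y_2": Y[:, 1]}))
    return pd.concat(blocks, ignore_index=True)
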
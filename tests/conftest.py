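import numpy as np
import pandas as pd
import pytest

import twinpath as tp


@pytest.fixture(scope="session")
def plain_model():
    """Reference AE generating model without items/covariates/missingness."""
    return tp.reference_generating_model(
        items=False, covariates=False, single_responder_rate=0.0
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """Full-size canonical cohort with items, covariates and missingness."""
    return tp.make_reference_cohort(seed=11)


@pytest.fixture(scope="session")
def bivariate_model():
    rg = np.array([[1.0, 0.6], [0.6, 1.0]])
    re = np.array([[1.0, 0.1], [0.1, 1.0]])
    return tp.build_generating_model(
        [0.45, 0.49], [0.55, 0.51], rg, re, phenotypes=("anxdep", "mspain")
    )


def gee_bruteforce(y, X, groups, tol=1e-12, max_iter=500):
    """Independent fixed-point GEE (Gaussian, exchangeable): Liang-Zeger
    moment estimator for the working correlation, GLS update for beta."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    ids = pd.unique(groups)
    idx = [np.flatnonzero(groups == g) for g in ids]
    p = X.shape[1]
    N = len(y)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    alpha = 0.0
    for _ in range(max_iter):
        resid = y - X @ beta
        phi = resid @ resid / (N - p)
        num = 0.0
        npairs = 0
        for ii in idx:
            r = resid[ii]
            for a in range(len(ii)):
                for b in range(a + 1, len(ii)):
                    num += r[a] * r[b]
                    npairs += 1
        alpha_new = num / ((npairs - p) * phi)
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        for ii in idx:
            R = np.full((len(ii), len(ii)), alpha_new)
            np.fill_diagonal(R, 1.0)
            Ri = np.linalg.inv(R)
            Xi = X[ii]
            A += Xi.T @ Ri @ Xi
            bvec += Xi.T @ Ri @ y[ii]
        beta_new = np.linalg.solve(A, bvec)
        done = np.max(np.abs(beta_new - beta)) < tol and abs(alpha_new - alpha) < tol
        beta, alpha = beta_new, alpha_new
        if done:
            break
    return beta, alpha


def fiml_bruteforce(dataset, spec):
    """Direct per-pair multivariate-normal density evaluation (oracle for
    the grouped sufficient-statistic FIML implementation)."""
    from scipy.stats import multivariate_normal

    from twinpath.cholesky import expected_pair_covariance

    X, zyg, sex = dataset.phenotype_pair_matrix(spec.phenotypes)
    total = 0.0
    for i in range(len(X)):
        sigma, mu = expected_pair_covariance(spec, zyg[i], sex[i])
        obs = ~np.isnan(X[i])
        sub = X[i][obs]
        total += -2.0 * multivariate_normal.logpdf(
            sub, mean=mu[obs], cov=sigma[np.ix_(obs, obs)]
        )
    return total
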
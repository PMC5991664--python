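"""Item-level descriptives, reliability and dimensionality of symptom scales.

Operations take an item matrix (subjects x items, Likert-coded 1..K) —
typically one twin-subsample of a cohort, since twin pairs are not
independent observations.  Factor extraction treats items as continuous and
uses maximum-likelihood factor analysis on the product-moment correlation
matrix; factor retention is assessed by the eigenvalue > 1 rule, the scree
curve (exposed as data) and Horn's parallel analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

__all__ = [
    "symptom_distribution",
    "cronbach_alpha",
    "efa_ml",
    "parallel_analysis",
    "EFAResult",
    "SymptomDistributionTable",
]


def _item_frame(items) -> pd.DataFrame:
    df = pd.DataFrame(items)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty item matrix")
    return df


@dataclass
class SymptomDistributionTable:
    """Per-item response-category percentages and symptomatic prevalence."""

    percentages: pd.DataFrame  # items x categories, rows sum to 100
    percent_symptomatic: pd.Series
    symptomatic_cutoff: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        out = self.percentages.copy()
        out["% symptomatic"] = self.percent_symptomatic
        return out


def symptom_distribution(items, symptomatic_cutoff: int = 2, levels=None) -> SymptomDistributionTable:
    """Score distribution (percentages) per item and percent symptomatic.

    ``symptomatic_cutoff`` is the lowest category counted as symptomatic
    (default 2, i.e. any response above the lowest level).
    """
    df = _item_frame(items).dropna(how="all")
    if levels is None:
        levels = np.arange(1, int(np.nanmax(df.to_numpy())) + 1)
    pct = {}
    sympt = {}
    for col in df.columns:
        x = df[col].dropna().to_numpy()
        if x.size == 0:
            raise ValueError(f"item {col!r} has no observations")
        counts = np.array([(x == lv).sum() for lv in levels], dtype=float)
        pct[col] = 100.0 * counts / x.size
        sympt[col] = 100.0 * (x >= symptomatic_cutoff).mean()
    table = pd.DataFrame(pct, index=[str(lv) for lv in levels]).T
    return SymptomDistributionTable(
        percentages=table,
        percent_symptomatic=pd.Series(sympt),
        symptomatic_cutoff=symptomatic_cutoff,
        n=len(df),
    )


def cronbach_alpha(items, listwise: bool = True) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum(item variances)/var(total)).

    May be negative for scales with no shared variance.  ``listwise`` drops
    subjects with any missing item; otherwise a pairwise-complete covariance
    matrix is used.
    """
    df = _item_frame(items)
    k = df.shape[1]
    if k < 2:
        raise ValueError("at least 2 items required")
    if listwise:
        df = df.dropna()
    if len(df) < 3:
        raise ValueError("at least 3 subjects required")
    cov = df.cov().to_numpy()  # pandas cov is pairwise-complete
    if np.any(np.diag(cov) == 0):
        raise ValueError("an item has zero variance")
    total_var = cov.sum()
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - np.trace(cov) / total_var)


@dataclass
class EFAResult:
    """Maximum-likelihood exploratory factor analysis summary."""

    eigenvalues: np.ndarray        # of the input correlation matrix, descending
    loadings: np.ndarray           # items x factors
    uniquenesses: np.ndarray
    variance_explained: np.ndarray  # sum(loadings_f^2) / n_items per factor
    n_factors: int
    n_obs: int | None
    heywood: bool
    retained_by_rule: dict = field(default_factory=dict)

    @property
    def scree(self) -> np.ndarray:
        """Eigenvalue curve for scree-plot inspection (no automatic elbow)."""
        return self.eigenvalues

    def implied_correlation(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.uniquenesses)


def efa_ml(
    data=None,
    corr=None,
    n_obs: int | None = None,
    n_factors: int = 1,
    max_iter: int = 200,
    tol: float = 1e-8,
    uniqueness_floor: float = 5e-3,
) -> EFAResult:
    """ML factor extraction from raw data or a correlation matrix.

    Heywood cases (uniqueness collapsing to zero) are flagged and floored at
    ``uniqueness_floor`` with a warning.
    """
    if (data is None) == (corr is None):
        raise ValueError("pass exactly one of data or corr")
    if data is not None:
        X = _item_frame(data).dropna()
        n_obs = len(X)
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n_factors >= p:
        raise ValueError("n_factors must be smaller than the number of items")
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(corr=R, n_factor=n_factors, method="ml", nobs=n_obs)
        res = fa.fit(maxiter=max_iter, opt={"gtol": tol})
    load = np.asarray(res.loadings)[:, :n_factors]
    # sign convention: dominant loading direction positive per factor
    sign = np.sign(load.sum(axis=0))
    sign[sign == 0] = 1.0
    load = load * sign
    uniq = np.asarray(res.uniqueness, dtype=float)
    heywood = bool(np.any(uniq < uniqueness_floor))
    if heywood:
        warnings.warn("Heywood case: uniqueness bounded at floor", stacklevel=2)
        uniq = np.maximum(uniq, uniqueness_floor)
    return EFAResult(
        eigenvalues=eig,
        loadings=load,
        uniquenesses=uniq,
        variance_explained=(load**2).sum(axis=0) / p,
        n_factors=n_factors,
        n_obs=n_obs,
        heywood=heywood,
        retained_by_rule={"eigenvalue_gt1": int((eig > 1.0).sum())},
    )


def parallel_analysis(
    observed_eigenvalues,
    n_obs: int,
    n_items: int,
    n_reps: int = 1000,
    percentile: float = 95.0,
    seed=None,
):
    """Horn's parallel analysis factor-retention count.

    Simulates ``n_reps`` standard-normal datasets of shape (n_obs, n_items),
    takes the given percentile of each ordered eigenvalue across replicates,
    and retains the longest initial run of observed eigenvalues exceeding
    their simulated counterpart.  Returns ``(retained, threshold_curve)``.
    """
    if n_obs <= n_items:
        raise ValueError("parallel analysis requires n_obs > n_items")
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    if not 50 < percentile <= 100:
        raise ValueError("percentile must lie in (50, 100]")
    obs = np.asarray(observed_eigenvalues, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sims = np.empty((n_reps, n_items))
    for r in range(n_reps):
        X = rng.standard_normal((n_obs, n_items))
        R = np.corrcoef(X, rowvar=False)
        sims[r] = np.sort(np.linalg.eigvalsh(R))[::-1]
    curve = np.percentile(sims, percentile, axis=0)
    retained = 0
    for j in range(min(obs.size, n_items)):
        if obs[j] > curve[j]:
            retained += 1
        else:
            break
    return retained, curve
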
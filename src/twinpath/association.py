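"""Phenotypic association analyses for twin-pair cohorts.

Pearson correlations with Fisher-z confidence intervals, marginal
regression by generalized estimating equations (GEE) with the twin pair as
the cluster, hierarchical variance blocks in independent twin subsamples,
and the extreme-scorer sensitivity filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence

from .dataset import TwinDataset, _twin_cols

__all__ = [
    "pearson_corr_ci",
    "gee_exchangeable",
    "hierarchical_blocks_r2",
    "exclude_extreme_scorers",
    "CorrelationWithCI",
    "GEEResult",
]


@dataclass(frozen=True)
class CorrelationWithCI:
    r: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95


def pearson_corr_ci(x, y, level: float = 0.95) -> CorrelationWithCI:
    """Pearson product-moment correlation with a Fisher-z interval.

    Missing values are removed pairwise; requires at least 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    from scipy.stats import norm

    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return CorrelationWithCI(
        r=r,
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        n=n,
        level=level,
    )


@dataclass
class GEEResult:
    coefficients: pd.Series
    robust_se: pd.Series
    working_corr: float
    n_clusters: int
    converged: bool
    results: object = None  # underlying statsmodels results

    def summary_frame(self) -> pd.DataFrame:
        z = self.coefficients / self.robust_se
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "robust_se": self.robust_se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        cols: list[int] = []
        for j in range(arr.shape[1]):
            trial = cols + [j]
            if np.linalg.matrix_rank(arr[:, trial]) < len(trial):
                bad.append(X.columns[j])
            else:
                cols.append(j)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def gee_exchangeable(
    data: pd.DataFrame,
    outcome: str,
    predictors,
    cluster: str = "pair_id",
    working: str = "exchangeable",
    robust: bool = True,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> GEEResult:
    """Gaussian identity-link GEE with the twin pair as the cluster.

    Returns coefficients with sandwich (robust) standard errors by default;
    ``robust=False`` reports model-based (naive) SEs.  ``working`` may be
    ``"exchangeable"`` or ``"independence"`` (the latter reproduces OLS
    point estimates exactly).
    """
    cols = [outcome, *predictors, cluster]
    df = data[cols].dropna()
    X = sm.add_constant(df[list(predictors)])
    _check_design(X)
    cov = {"exchangeable": Exchangeable, "independence": Independence}[working]()
    model = sm.GEE(
        df[outcome],
        X,
        groups=df[cluster],
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    res = model.fit(
        maxiter=max_iter,
        ctol=tol,
        cov_type="robust" if robust else "naive",
    )
    converged = bool(getattr(res, "converged", True))
    alpha = cov.dep_params if working == "exchangeable" else 0.0
    return GEEResult(
        coefficients=res.params,
        robust_se=res.bse,
        working_corr=float(alpha),
        n_clusters=df[cluster].nunique(),
        converged=converged,
        results=res,
    )


def hierarchical_blocks_r2(
    data,
    outcome: str,
    block1,
    block2,
    subsample: str | None = None,
) -> dict:
    """Least-squares R2 for block 1 and the increment after adding block 2.

    ``data`` may be a :class:`TwinDataset` (then ``subsample`` of
    ``"twin1"``/``"twin2"`` must break the pair clustering) or an
    individual-level DataFrame of independent subjects.
    """
    block1, block2 = list(block1), list(block2)
    overlap = set(block1) & set(block2)
    if overlap:
        raise ValueError(f"blocks must not overlap; shared: {sorted(overlap)}")
    if isinstance(data, TwinDataset):
        if subsample not in ("twin1", "twin2"):
            raise ValueError("a twin1/twin2 subsample is required for a TwinDataset")
        df = data.individuals(subsample=subsample)
    else:
        df = data
    df = df[[outcome] + block1 + block2].dropna()
    r2 = {}
    for label, cols in (("block1", block1), ("block1+2", block1 + block2)):
        X = sm.add_constant(df[cols])
        r2[label] = float(sm.OLS(df[outcome], X).fit().rsquared)
    return {
        "r2_block1": r2["block1"],
        "r2_full": r2["block1+2"],
        "delta_r2": r2["block1+2"] - r2["block1"],
        "n": len(df),
    }


def exclude_extreme_scorers(
    dataset: TwinDataset,
    scale: str,
    threshold: float = 3.0,
):
    """Remove subjects whose mean item score on ``scale`` is >= threshold.

    The subject's whole block is set missing; pairs with one remaining twin
    are retained as single responders, pairs losing both twins are dropped.
    Returns ``(filtered_dataset, summary)`` where summary reports the count
    and fraction of excluded subjects.
    """
    if scale not in dataset.item_columns:
        raise ValueError(f"unknown scale {scale!r}")
    items = dataset.item_columns[scale]
    df = dataset.pairs.copy()
    per_twin = (
        list(dataset.phenotypes)
        + [c for cols in dataset.item_columns.values() for c in cols]
        + list(dataset.covariates)
    )
    n_subjects = 0
    n_excluded = 0
    removed = {}
    for twin in (1, 2):
        means = df[_twin_cols(items, twin)].mean(axis=1)
        responding = df[_twin_cols(dataset.phenotypes, twin)].notna().any(axis=1)
        n_subjects += int(responding.sum())
        hit = responding & (means >= threshold)
        n_excluded += int(hit.sum())
        removed[twin] = hit
        cols = [c for c in _twin_cols(per_twin, twin) if c in df.columns]
        df.loc[hit, cols] = np.nan
    t1 = df[_twin_cols(dataset.phenotypes, 1)].notna().any(axis=1)
    t2 = df[_twin_cols(dataset.phenotypes, 2)].notna().any(axis=1)
    df = df[(t1 | t2)].reset_index(drop=True)
    filtered = TwinDataset(
        pairs=df,
        phenotypes=dataset.phenotypes,
        item_columns=dataset.item_columns,
        covariates=dataset.covariates,
        truth=dataset.truth,
    )
    summary = {
        "n_subjects": n_subjects,
        "n_excluded": n_excluded,
        "fraction_excluded": n_excluded / n_subjects if n_subjects else 0.0,
        "threshold": threshold,
    }
    return filtered, summary
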
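"""Simulation of twin-pair cohorts from a known generating model.

Pairs are drawn from the 2p-dimensional multivariate normal implied by the
model's path matrices: within-twin covariance A + C + E, cross-twin
covariance A + C for MZ pairs and 0.5*A + C for DZ pairs.  Female pairs have
each phenotype scaled by the model's per-phenotype SD scalars.  Ordinal item
batteries are produced by thresholding loading-weighted latents, and
covariates / single-responder missingness are attached afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import TwinDataset, _twin_cols
from .model import CovariateSpec, GeneratingModel, lower_cholesky_psd

__all__ = [
    "simulate_twin_pairs",
    "generate_likert_items",
    "attach_covariates_and_missingness",
]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_likert_items(
    latent_scores,
    loadings,
    thresholds,
    seed=None,
    return_underlying: bool = False,
):
    """Ordinal responses from a one-factor threshold model.

    For each subject with latent f and item i the underlying continuous
    response is ``y* = loading_i * f + sqrt(1 - loading_i^2) * z`` with
    standard-normal noise z; the recorded category is ``1 + #{thresholds
    below y*}``.  With standard-normal latents the marginal category
    probabilities are exactly the normal probabilities the thresholds cut.
    """
    rng = _as_rng(seed)
    f = np.asarray(latent_scores, dtype=float)
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) > 1):
        raise ValueError("|loading| must be <= 1")
    thresholds = [np.asarray(t, dtype=float) for t in thresholds]
    if len(thresholds) != lam.size:
        raise ValueError("one threshold vector required per item")
    for t in thresholds:
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got {t}")
    n = f.size
    noise = rng.standard_normal((n, lam.size))
    ystar = f[:, None] * lam + noise * np.sqrt(1.0 - lam**2)
    items = np.empty((n, lam.size), dtype=int)
    for i, t in enumerate(thresholds):
        items[:, i] = 1 + np.searchsorted(t, ystar[:, i], side="left")
    if return_underlying:
        return items, ystar
    return items


def simulate_twin_pairs(
    model: GeneratingModel,
    n_mz: int,
    n_dz: int,
    female_fraction: float = 0.5,
    seed=None,
) -> TwinDataset:
    """Draw a same-sex twin cohort of ``n_mz`` MZ and ``n_dz`` DZ pairs.

    The sex of each pair is Bernoulli(female_fraction); twin-1/twin-2
    assignment is exchangeable by construction (the pair distribution is
    symmetric in the two twins).  Reproducible given ``seed``.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be non-negative")
    if not 0 <= female_fraction <= 1:
        raise ValueError("female_fraction must be in [0, 1]")
    rng = _as_rng(seed)
    p = model.n_phenotypes
    rows = []
    pair_id = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        sexes = np.where(rng.random(n) < female_fraction, "F", "M")
        # draw per sex group from the group's 2p-normal
        scores = np.empty((n, 2 * p))
        for sex in ("M", "F"):
            idx = np.flatnonzero(sexes == sex)
            if idx.size == 0:
                continue
            sigma = model.pair_covariance(zyg, sex)
            L = lower_cholesky_psd(sigma)
            z = rng.standard_normal((idx.size, 2 * p))
            scores[idx] = model.pair_mean(sex) + z @ L.T
        for i in range(n):
            pair_id += 1
            rows.append((f"P{pair_id:05d}", zyg, sexes[i], scores[i]))
    phen = model.phenotypes
    cols = _twin_cols(phen, 1) + _twin_cols(phen, 2)
    df = pd.DataFrame(
        [r[3] for r in rows], columns=cols, dtype=float
    )
    df.insert(0, "pair_id", [r[0] for r in rows])
    df.insert(1, "zygosity", [r[1] for r in rows])
    df.insert(2, "sex", [r[2] for r in rows])

    item_columns: dict[str, list[str]] = {}
    if model.item_spec:
        female = (df["sex"] == "F").to_numpy()
        for scale, spec in model.item_spec.items():
            j = phen.index(scale)
            item_columns[scale] = [f"{scale}{i + 1}" for i in range(spec.n_items)]
            for twin in (1, 2):
                score = df[f"{scale}_t{twin}"].to_numpy()
                mu = np.where(
                    female, model.means["F"][j], model.means["M"][j]
                )
                sd = np.where(female, model.female_scalars[j], 1.0)
                latent = (score - mu) / sd
                items = generate_likert_items(
                    latent, spec.loadings, spec.thresholds, seed=rng
                )
                for i, base in enumerate(item_columns[scale]):
                    df[f"{base}_t{twin}"] = items[:, i]
    ds = TwinDataset(
        pairs=df,
        phenotypes=phen,
        item_columns=item_columns,
        truth=model,
    )
    if model.covariate_spec is not None or model.single_responder_rate > 0:
        ds = attach_covariates_and_missingness(
            ds,
            model.covariate_spec,
            model.single_responder_rate,
            seed=rng,
        )
    return ds


def attach_covariates_and_missingness(
    dataset: TwinDataset,
    covariate_spec: CovariateSpec | None = None,
    single_responder_rate: float = 0.0,
    seed=None,
) -> TwinDataset:
    """Draw per-twin covariates and impose MCAR single-responder missingness.

    Covariate linear effects are added to the named phenotype scores.  For a
    random fraction ``single_responder_rate`` of pairs one twin's entire
    block (phenotypes, items, covariates) is set missing.
    """
    if not 0 <= single_responder_rate < 1:
        raise ValueError("single_responder_rate must be in [0, 1)")
    rng = _as_rng(seed)
    df = dataset.pairs.copy()
    n = len(df)
    covariates: tuple[str, ...] = dataset.covariates
    if covariate_spec is not None:
        for phen_effects in covariate_spec.effects.values():
            for phen in phen_effects:
                if phen not in dataset.phenotypes:
                    raise ValueError(f"effect on unknown phenotype {phen!r}")
        for twin in (1, 2):
            for name, probs in covariate_spec.ordinal.items():
                probs = np.asarray(probs, float)
                probs = probs / probs.sum()
                df[f"{name}_t{twin}"] = rng.choice(
                    np.arange(1, probs.size + 1), size=n, p=probs
                ).astype(float)
            for name, prev in covariate_spec.binary.items():
                df[f"{name}_t{twin}"] = (rng.random(n) < prev).astype(float)
            for cov, phen_effects in covariate_spec.effects.items():
                x = df[f"{cov}_t{twin}"].to_numpy()
                for phen, beta in phen_effects.items():
                    df[f"{phen}_t{twin}"] = df[f"{phen}_t{twin}"] + beta * x
        covariates = tuple(dict.fromkeys(list(covariates) + covariate_spec.names))
    if single_responder_rate > 0 and n > 0:
        drop = rng.random(n) < single_responder_rate
        which_twin = rng.integers(1, 3, size=n)
        per_twin = (
            list(dataset.phenotypes)
            + [c for scale in dataset.item_columns.values() for c in scale]
            + list(covariates)
        )
        for twin in (1, 2):
            mask = drop & (which_twin == twin)
            cols = [c for c in _twin_cols(per_twin, twin) if c in df.columns]
            df.loc[mask, cols] = np.nan
    out = TwinDataset(
        pairs=df,
        phenotypes=dataset.phenotypes,
        item_columns=dataset.item_columns,
        covariates=covariates,
        truth=dataset.truth,
    )
    return out
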
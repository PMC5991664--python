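"""Generating models for same-sex twin cohorts.

A :class:`GeneratingModel` holds the lower-triangular genetic (a), shared
environmental (c, optional) and individual-specific environmental (e) path
matrices of a multivariate Cholesky variance decomposition, together with
per-phenotype female SD scalars, per-sex means, and optional ordinal-item and
covariate specifications.  The implied covariance algebra is the classical
twin-design one: latent additive-genetic factors correlate 1 within MZ pairs
and 0.5 within DZ pairs, shared-environment factors correlate 1 in both
groups, and individual-specific factors never correlate across twins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeneratingModel",
    "LikertScaleSpec",
    "CovariateSpec",
    "build_generating_model",
    "lower_cholesky_psd",
    "pair_covariance_blocks",
]

ZYGOSITIES = ("MZ", "DZ")
SEXES = ("M", "F")

#: genetic cross-twin correlation per zygosity
KAPPA = {"MZ": 1.0, "DZ": 0.5}


def _check_correlation_matrix(R: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {R.shape}")
    if not np.allclose(R, R.T, atol=tol):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(R).min() < -tol:
        raise ValueError(f"{name} is not positive semidefinite")
    return R


def lower_cholesky_psd(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Lower-triangular factor L with ``L @ L.T == M`` for PSD ``M``.

    Unlike :func:`numpy.linalg.cholesky` this accepts singular matrices
    (zero variance components yield zero rows/columns in L).
    """
    M = np.asarray(M, dtype=float)
    p = M.shape[0]
    L = np.zeros((p, p))
    for j in range(p):
        d = M[j, j] - L[j, :j] @ L[j, :j]
        if d > tol:
            L[j, j] = np.sqrt(d)
            for i in range(j + 1, p):
                L[i, j] = (M[i, j] - L[i, :j] @ L[j, :j]) / L[j, j]
        # d <= tol: pivot treated as exactly zero; column stays zero
    return L


def pair_covariance_blocks(
    A: np.ndarray,
    C: np.ndarray | None,
    E: np.ndarray,
    zygosity: str,
) -> np.ndarray:
    """2p x 2p expected twin-pair covariance from component matrices.

    Within-twin block A + C + E on the diagonal; cross-twin block
    ``kappa * A + C`` with kappa = 1 (MZ) or 0.5 (DZ).
    """
    if zygosity not in KAPPA:
        raise ValueError(f"zygosity must be one of {ZYGOSITIES}, got {zygosity!r}")
    C_ = np.zeros_like(A) if C is None else C
    within = A + C_ + E
    cross = KAPPA[zygosity] * A + C_
    return np.block([[within, cross], [cross, within]])


@dataclass(frozen=True)
class LikertScaleSpec:
    """Ordinal item battery tied to one phenotype.

    ``thresholds[i]`` are strictly increasing standard-normal cutpoints for
    item i; responses are coded 1..(len(thresholds[i]) + 1).
    """

    loadings: tuple[float, ...]
    thresholds: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        if len(self.loadings) != len(self.thresholds):
            raise ValueError("one threshold vector required per item loading")
        for lam in self.loadings:
            if abs(lam) > 1:
                raise ValueError(f"|loading| must be <= 1, got {lam}")
        for t in self.thresholds:
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds must be strictly increasing, got {t}")

    @property
    def n_items(self) -> int:
        return len(self.loadings)

    @property
    def n_levels(self) -> int:
        return len(self.thresholds[0]) + 1


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions and (optional) linear effects of cohort covariates.

    ``ordinal`` maps a covariate name to category probabilities on levels
    1..K; ``binary`` maps a name to a prevalence; ``effects`` maps a
    covariate name to ``{phenotype: slope}`` added to phenotype scores.
    """

    ordinal: dict[str, tuple[float, ...]] = field(default_factory=dict)
    binary: dict[str, float] = field(default_factory=dict)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.ordinal) + list(self.binary)


@dataclass(frozen=True)
class GeneratingModel:
    """Known-truth generating model for a same-sex twin cohort."""

    phenotypes: tuple[str, ...]
    a_paths: np.ndarray
    e_paths: np.ndarray
    c_paths: np.ndarray | None = None
    female_scalars: np.ndarray | None = None
    means: dict[str, np.ndarray] | None = None
    item_spec: dict[str, LikertScaleSpec] | None = None
    covariate_spec: CovariateSpec | None = None
    single_responder_rate: float = 0.0

    def __post_init__(self):
        p = len(self.phenotypes)
        a = np.asarray(self.a_paths, dtype=float)
        e = np.asarray(self.e_paths, dtype=float)
        object.__setattr__(self, "a_paths", a)
        object.__setattr__(self, "e_paths", e)
        for name, m in (("a_paths", a), ("e_paths", e)):
            if m.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
            if not np.allclose(m, np.tril(m)):
                raise ValueError(f"{name} must be lower-triangular")
        if self.c_paths is not None:
            c = np.asarray(self.c_paths, dtype=float)
            if c.shape != (p, p) or not np.allclose(c, np.tril(c)):
                raise ValueError(f"c_paths must be lower-triangular {p}x{p}")
            object.__setattr__(self, "c_paths", c)
        k = np.ones(p) if self.female_scalars is None else np.asarray(self.female_scalars, float)
        if k.shape != (p,) or np.any(k <= 0):
            raise ValueError("female_scalars must be positive, one per phenotype")
        object.__setattr__(self, "female_scalars", k)
        mu = self.means or {}
        mu = {s: np.asarray(mu.get(s, np.zeros(p)), dtype=float) for s in SEXES}
        for s, v in mu.items():
            if v.shape != (p,):
                raise ValueError(f"means[{s!r}] must have length {p}")
        object.__setattr__(self, "means", mu)
        if not 0 <= self.single_responder_rate < 1:
            raise ValueError("single_responder_rate must be in [0, 1)")
        if self.item_spec is not None:
            for scale in self.item_spec:
                if scale not in self.phenotypes:
                    raise ValueError(f"item_spec scale {scale!r} is not a phenotype")
        if self.covariate_spec is not None:
            for cov, eff in self.covariate_spec.effects.items():
                if cov not in self.covariate_spec.names:
                    raise ValueError(f"effect refers to unknown covariate {cov!r}")
                for phen in eff:
                    if phen not in self.phenotypes:
                        raise ValueError(f"effect on unknown phenotype {phen!r}")

    # -- covariance algebra -------------------------------------------------

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    @property
    def A(self) -> np.ndarray:
        return self.a_paths @ self.a_paths.T

    @property
    def C(self) -> np.ndarray | None:
        return None if self.c_paths is None else self.c_paths @ self.c_paths.T

    @property
    def E(self) -> np.ndarray:
        return self.e_paths @ self.e_paths.T

    def sex_scale(self, sex: str) -> np.ndarray:
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
        return self.female_scalars if sex == "F" else np.ones(self.n_phenotypes)

    def phenotypic_cov(self, sex: str = "M") -> np.ndarray:
        k = self.sex_scale(sex)
        C = self.C
        total = self.A + self.E + (0 if C is None else C)
        return total * np.outer(k, k)

    def pair_covariance(self, zygosity: str, sex: str = "M") -> np.ndarray:
        sigma = pair_covariance_blocks(self.A, self.C, self.E, zygosity)
        k2 = np.concatenate([self.sex_scale(sex)] * 2)
        return sigma * np.outer(k2, k2)

    def pair_mean(self, sex: str = "M") -> np.ndarray:
        mu = self.means[sex]
        return np.concatenate([mu, mu])

    def with_(self, **changes) -> "GeneratingModel":
        return replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_manifest(self) -> dict:
        """JSON-serializable truth record (paths, implied shares, Rg/Re)."""
        A, E = self.A, self.E
        C = self.C
        total = np.diag(A + E + (0 if C is None else C))
        d = {
            "phenotypes": list(self.phenotypes),
            "a_paths": self.a_paths.tolist(),
            "e_paths": self.e_paths.tolist(),
            "c_paths": None if self.c_paths is None else self.c_paths.tolist(),
            "female_scalars": self.female_scalars.tolist(),
            "means": {s: v.tolist() for s, v in self.means.items()},
            "single_responder_rate": self.single_responder_rate,
            "h2": (np.diag(A) / total).tolist(),
            "e2": (np.diag(E) / total).tolist(),
        }
        sd_a = np.sqrt(np.diag(A))
        sd_e = np.sqrt(np.diag(E))
        with np.errstate(divide="ignore", invalid="ignore"):
            d["rg"] = (A / np.outer(sd_a, sd_a)).tolist()
            d["re"] = (E / np.outer(sd_e, sd_e)).tolist()
        if C is not None:
            d["c2"] = (np.diag(C) / total).tolist()
        return d


def build_generating_model(
    h2,
    e2,
    rg,
    re,
    female_scalars=None,
    normalize: bool = False,
    phenotypes: tuple[str, ...] | None = None,
    **extra,
) -> GeneratingModel:
    """Build an AE generating model from variance shares and correlations.

    ``A = D_a^{1/2} Rg D_a^{1/2}`` and ``E = D_e^{1/2} Re D_e^{1/2}`` with
    ``D_a = diag(h2)``, ``D_e = diag(e2)``; each converted to lower-triangular
    paths by Cholesky factorization.  With ``normalize=True`` shares that do
    not sum to one (rounded published values) are rescaled proportionally.

    Extra keyword arguments (``means``, ``item_spec``, ``covariate_spec``,
    ``single_responder_rate``) are forwarded to :class:`GeneratingModel`.
    """
    h2 = np.asarray(h2, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    p = h2.size
    if e2.size != p:
        raise ValueError("h2 and e2 must have the same length")
    if np.any((h2 < 0) | (h2 > 1)) or np.any((e2 < 0) | (e2 > 1)):
        raise ValueError("h2 and e2 entries must lie in [0, 1]")
    Rg = _check_correlation_matrix(rg, "Rg")
    Re = _check_correlation_matrix(re, "Re")
    if Rg.shape[0] != p or Re.shape[0] != p:
        raise ValueError("correlation matrices must match the number of phenotypes")
    total = h2 + e2
    if not np.allclose(total, 1.0, atol=1e-9):
        if not normalize:
            raise ValueError(
                "h2 + e2 must sum to 1 per phenotype (pass normalize=True to "
                f"rescale rounded shares); got sums {total}"
            )
        h2 = h2 / total
        e2 = e2 / total
    sa = np.sqrt(h2)
    se = np.sqrt(e2)
    A = np.outer(sa, sa) * Rg
    E = np.outer(se, se) * Re
    if phenotypes is None:
        phenotypes = tuple(f"p{i + 1}" for i in range(p))
    return GeneratingModel(
        phenotypes=tuple(phenotypes),
        a_paths=lower_cholesky_psd(A),
        e_paths=lower_cholesky_psd(E),
        female_scalars=female_scalars,
        **extra,
    )
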
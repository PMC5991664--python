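"""Maximum-likelihood multivariate twin Cholesky ACE/AE models.

The model decomposes the covariance of p phenotypes measured on same-sex
twin pairs into additive-genetic (A), shared-environment (C, optional) and
individual-specific environment (E) components, each parameterized by a
lower-triangular path matrix (as many latent factors as phenotypes).  The
expected 2p x 2p pair covariance has within-twin block A + C + E and
cross-twin block A + C for MZ pairs or 0.5*A + C for DZ pairs; E never
crosses twins.

Sex limitation variants for same-sex pair designs:

``none``
    all structural parameters equal across sex;
``scalar``
    female phenotype SDs are free positive multiples of the male ones, so
    standardized components are sex-equal by construction;
``common_effects``
    per-component female variance scalings (shared A/C/E correlation
    structure, sex-specific magnitudes);
``free``
    fully separate path matrices per sex (diagnostic variant).

Estimation is full-information maximum likelihood: every pair contributes
the multivariate-normal density of its observed entries, so single
responders enter through the p-dimensional marginal.  The objective and its
analytic gradient are minimized by L-BFGS-B over raw paths with
log-parameterized diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .dataset import TwinDataset
from .model import KAPPA, lower_cholesky_psd, pair_covariance_blocks

__all__ = [
    "CholeskyModelSpec",
    "FittedBiometricModel",
    "FitConfig",
    "VarianceDecomposition",
    "CorrelationDecomposition",
    "expected_pair_covariance",
    "minus2_loglik_fiml",
    "fit_model",
    "standardized_decomposition",
    "correlation_decomposition",
    "compare_models",
    "confidence_intervals",
    "model_df",
]

LOG2PI = np.log(2.0 * np.pi)
FAMILIES = ("ACE", "AE")
SEX_LIMITATIONS = ("none", "scalar", "common_effects", "free")


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class CholeskyModelSpec:
    """Path matrices, sex scalars and means of a (fitted) Cholesky model."""

    phenotypes: tuple[str, ...]
    family: str
    sex_limitation: str
    a_paths: np.ndarray
    e_paths: np.ndarray
    c_paths: np.ndarray | None = None
    af_paths: np.ndarray | None = None
    cf_paths: np.ndarray | None = None
    ef_paths: np.ndarray | None = None
    scalars: dict[str, np.ndarray] | None = None
    means: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.sex_limitation not in SEX_LIMITATIONS:
            raise ValueError(f"sex_limitation must be one of {SEX_LIMITATIONS}")
        if self.family == "ACE" and self.c_paths is None:
            raise ValueError("ACE family requires c_paths")

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    def component_matrices(self, sex: str = "M"):
        """(A, C_or_None, E) covariance components on the given sex's scale."""
        if self.sex_limitation == "free" and sex == "F":
            a, c, e = self.af_paths, self.cf_paths, self.ef_paths
        else:
            a, c, e = self.a_paths, self.c_paths, self.e_paths
        A = a @ a.T
        C = None if c is None else c @ c.T
        E = e @ e.T
        if sex == "F" and self.sex_limitation == "scalar":
            K = np.outer(self.scalars["k"], self.scalars["k"])
            A, E = A * K, E * K
            C = None if C is None else C * K
        elif sex == "F" and self.sex_limitation == "common_effects":
            A = A * np.outer(self.scalars["ka"], self.scalars["ka"])
            E = E * np.outer(self.scalars["ke"], self.scalars["ke"])
            if C is not None:
                C = C * np.outer(self.scalars["kc"], self.scalars["kc"])
        return A, C, E

    def mean_vector(self, sex: str = "M") -> np.ndarray:
        mu = self.means.get(sex)
        return np.zeros(self.n_phenotypes) if mu is None else np.asarray(mu)


def expected_pair_covariance(spec, zygosity: str, sex: str = "M"):
    """Expected 2p x 2p pair covariance and 2p mean vector."""
    A, C, E = spec.component_matrices(sex)
    sigma = pair_covariance_blocks(A, C, E, zygosity)
    mu = spec.mean_vector(sex)
    return sigma, np.concatenate([mu, mu])


# ---------------------------------------------------------------------------
# parameter layout


def _tri_count(p: int) -> int:
    return p * (p + 1) // 2


class _Layout:
    """Flat-vector packing of free parameters for one model variant."""

    def __init__(self, p: int, family: str, sexlim: str, sexes: tuple[str, ...]):
        self.p = p
        self.family = family
        self.sexlim = sexlim
        self.sexes = tuple(sexes)
        self.has_c = family == "ACE"
        self.tril = np.tril_indices(p)
        self.diag_pos = np.flatnonzero(self.tril[0] == self.tril[1])
        nt = _tri_count(p)
        names = ["a"] + (["c"] if self.has_c else []) + ["e"]
        if sexlim == "free":
            names += ["af"] + (["cf"] if self.has_c else []) + ["ef"]
        sizes = {n: nt for n in names}
        if sexlim == "scalar":
            names.append("logk")
            sizes["logk"] = p
        elif sexlim == "common_effects":
            names.append("logka")
            sizes["logka"] = p
            if self.has_c:
                names.append("logkc")
                sizes["logkc"] = p
            names.append("logke")
            sizes["logke"] = p
        for s in self.sexes:
            names.append(f"mu_{s}")
            sizes[f"mu_{s}"] = p
        self.slices: dict[str, slice] = {}
        start = 0
        for n in names:
            self.slices[n] = slice(start, start + sizes[n])
            start += sizes[n]
        self.n_params = start

    # -- path matrix transforms ---------------------------------------------

    def tri_matrix(self, vec: np.ndarray) -> np.ndarray:
        L = np.zeros((self.p, self.p))
        L[self.tril] = vec
        np.fill_diagonal(L, np.exp(np.clip(np.diag(L), -30, 30)))
        return L

    def tri_vector(self, L: np.ndarray) -> np.ndarray:
        v = L[self.tril].copy()
        v[self.diag_pos] = np.log(np.clip(np.diag(L), 1e-10, None))
        return v

    def tri_grad(self, gmat: np.ndarray, L: np.ndarray) -> np.ndarray:
        v = gmat[self.tril].copy()
        v[self.diag_pos] *= np.diag(L)  # chain rule for log-parameterized diagonal
        return v

    def bounds(self):
        b = [(None, None)] * self.n_params
        for name, sl in self.slices.items():
            if name in ("a", "c", "e", "af", "cf", "ef"):
                for k in range(sl.start, sl.stop):
                    local = k - sl.start
                    b[k] = (-15.0, 8.0) if local in self.diag_pos else (-40.0, 40.0)
            elif name.startswith("logk"):
                for k in range(sl.start, sl.stop):
                    b[k] = (-3.0, 3.0)
        return b

    # -- structured unpack ---------------------------------------------------

    def unpack(self, theta: np.ndarray) -> SimpleNamespace:
        g = lambda n: theta[self.slices[n]]
        a = self.tri_matrix(g("a"))
        e = self.tri_matrix(g("e"))
        c = self.tri_matrix(g("c")) if self.has_c else None
        out = SimpleNamespace(a=a, c=c, e=e, af=None, cf=None, ef=None,
                              k=None, ka=None, kc=None, ke=None, means={})
        if self.sexlim == "free":
            out.af = self.tri_matrix(g("af"))
            out.ef = self.tri_matrix(g("ef"))
            out.cf = self.tri_matrix(g("cf")) if self.has_c else None
        elif self.sexlim == "scalar":
            out.k = np.exp(g("logk"))
        elif self.sexlim == "common_effects":
            out.ka = np.exp(g("logka"))
            out.ke = np.exp(g("logke"))
            out.kc = np.exp(g("logkc")) if self.has_c else None
        for s in self.sexes:
            out.means[s] = g(f"mu_{s}")
        return out

    def components(self, u: SimpleNamespace, sex: str):
        """(A, C|None, E) on the given sex's scale from unpacked params."""
        if self.sexlim == "free" and sex == "F":
            A = u.af @ u.af.T
            C = None if u.cf is None else u.cf @ u.cf.T
            E = u.ef @ u.ef.T
            return A, C, E
        A = u.a @ u.a.T
        C = None if u.c is None else u.c @ u.c.T
        E = u.e @ u.e.T
        if sex == "F" and self.sexlim == "scalar":
            K = np.outer(u.k, u.k)
            A, E = A * K, E * K
            C = None if C is None else C * K
        elif sex == "F" and self.sexlim == "common_effects":
            A = A * np.outer(u.ka, u.ka)
            E = E * np.outer(u.ke, u.ke)
            if C is not None:
                C = C * np.outer(u.kc, u.kc)
        return A, C, E

    def to_spec(self, theta: np.ndarray, phenotypes) -> CholeskyModelSpec:
        u = self.unpack(theta)
        scalars = None
        if self.sexlim == "scalar":
            scalars = {"k": u.k}
        elif self.sexlim == "common_effects":
            scalars = {"ka": u.ka, "ke": u.ke}
            if u.kc is not None:
                scalars["kc"] = u.kc
        return CholeskyModelSpec(
            phenotypes=tuple(phenotypes),
            family=self.family,
            sex_limitation=self.sexlim,
            a_paths=u.a,
            e_paths=u.e,
            c_paths=u.c,
            af_paths=u.af,
            cf_paths=u.cf,
            ef_paths=u.ef,
            scalars=scalars,
            means={s: u.means[s].copy() for s in self.sexes},
        )

    def from_spec(self, spec: CholeskyModelSpec) -> np.ndarray:
        theta = np.zeros(self.n_params)
        theta[self.slices["a"]] = self.tri_vector(spec.a_paths)
        theta[self.slices["e"]] = self.tri_vector(spec.e_paths)
        if self.has_c:
            theta[self.slices["c"]] = self.tri_vector(spec.c_paths)
        if self.sexlim == "free":
            theta[self.slices["af"]] = self.tri_vector(spec.af_paths)
            theta[self.slices["ef"]] = self.tri_vector(spec.ef_paths)
            if self.has_c:
                theta[self.slices["cf"]] = self.tri_vector(spec.cf_paths)
        elif self.sexlim == "scalar":
            theta[self.slices["logk"]] = np.log(spec.scalars["k"])
        elif self.sexlim == "common_effects":
            theta[self.slices["logka"]] = np.log(spec.scalars["ka"])
            theta[self.slices["logke"]] = np.log(spec.scalars["ke"])
            if self.has_c:
                theta[self.slices["logkc"]] = np.log(spec.scalars["kc"])
        for s in self.sexes:
            theta[self.slices[f"mu_{s}"]] = spec.means[s]
        return theta


# ---------------------------------------------------------------------------
# FIML objective


class _FIMLProblem:
    """Sufficient statistics of a twin dataset grouped by zygosity, sex and
    missingness pattern; evaluates the FIML -2 log likelihood."""

    def __init__(self, X: np.ndarray, zygosity, sex, p: int):
        X = np.asarray(X, dtype=float)
        self.p = p
        obs = ~np.isnan(X)
        keep = obs.any(axis=1)
        X, obs = X[keep], obs[keep]
        zygosity = np.asarray(zygosity)[keep]
        sex = np.asarray(sex)[keep]
        buckets: dict[tuple, list[int]] = {}
        for i in range(len(X)):
            key = (zygosity[i], sex[i], obs[i].tobytes())
            buckets.setdefault(key, []).append(i)
        self.groups = []
        self.n_obs_values = int(obs.sum())
        self.n_pairs = len(X)
        self.sexes = tuple(sorted(set(sex.tolist())))
        self.zygosities = tuple(sorted(set(zygosity.tolist())))
        for (zyg, sx, _), rows in sorted(buckets.items()):
            idx = np.flatnonzero(obs[rows[0]])
            sub = X[np.asarray(rows)][:, idx]
            n = len(rows)
            xbar = sub.mean(axis=0)
            dev = sub - xbar
            S = dev.T @ dev
            self.groups.append(
                SimpleNamespace(
                    kappa=KAPPA[zyg], sex=sx, idx=idx, n=n, xbar=xbar, S=S
                )
            )

    # value-only path, accepts arbitrary (possibly singular) matrices --------

    def neg2ll_from_matrices(self, mats: dict) -> float:
        p = self.p
        total = 0.0
        for g in self.groups:
            A, C, E, mu = mats[g.sex]
            sigma = pair_covariance_blocks(A, C, E, "MZ" if g.kappa == 1 else "DZ")
            mu2 = np.concatenate([mu, mu])
            so = sigma[np.ix_(g.idx, g.idx)]
            try:
                L = np.linalg.cholesky(so)
            except np.linalg.LinAlgError:
                return np.inf
            d = g.idx.size
            logdet = 2.0 * np.log(np.diag(L)).sum()
            Si = np.linalg.inv(so)
            delta = g.xbar - mu2[g.idx]
            total += g.n * (d * LOG2PI + logdet)
            total += (Si * g.S).sum() + g.n * delta @ Si @ delta
        return float(total)

    # value + analytic gradient over a layout's parameter vector -------------

    def neg2ll_and_grad(self, theta: np.ndarray, layout: _Layout):
        p = layout.p
        u = layout.unpack(theta)
        comp = {s: layout.components(u, s) for s in layout.sexes}
        dA = {s: np.zeros((p, p)) for s in layout.sexes}
        dC = {s: np.zeros((p, p)) for s in layout.sexes}
        dE = {s: np.zeros((p, p)) for s in layout.sexes}
        dmu = {s: np.zeros(p) for s in layout.sexes}
        total = 0.0
        for g in self.groups:
            A, C, E = comp[g.sex]
            C_ = 0.0 if C is None else C
            within = A + C_ + E
            cross = g.kappa * A + C_
            sigma = np.block([[within, cross], [cross, within]])
            mu = u.means[g.sex]
            mu2 = np.concatenate([mu, mu])
            so = sigma[np.ix_(g.idx, g.idx)]
            try:
                L = np.linalg.cholesky(so)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros(layout.n_params)
            d = g.idx.size
            logdet = 2.0 * np.log(np.diag(L)).sum()
            Si = np.linalg.inv(so)
            delta = g.xbar - mu2[g.idx]
            Sid = Si @ delta
            total += g.n * (d * LOG2PI + logdet)
            total += (Si * g.S).sum() + g.n * delta @ Sid
            M = g.S + g.n * np.outer(delta, delta)
            F = g.n * Si - Si @ M @ Si
            Ffull = np.zeros((2 * p, 2 * p))
            Ffull[np.ix_(g.idx, g.idx)] = F
            F11 = Ffull[:p, :p]
            F22 = Ffull[p:, p:]
            FX = Ffull[:p, p:] + Ffull[p:, :p]
            GT = F11 + F22
            dA[g.sex] += GT + g.kappa * FX
            dC[g.sex] += GT + FX
            dE[g.sex] += GT
            gmu_full = np.zeros(2 * p)
            gmu_full[g.idx] = -2.0 * g.n * Sid
            dmu[g.sex] += gmu_full[:p] + gmu_full[p:]

        grad = np.zeros(layout.n_params)

        def put_tri(name, gmat, L):
            grad[layout.slices[name]] = layout.tri_grad(2.0 * gmat @ L, L)

        if layout.sexlim == "free":
            put_tri("a", dA["M"], u.a)
            put_tri("e", dE["M"], u.e)
            if layout.has_c:
                put_tri("c", dC["M"], u.c)
            if "F" in layout.sexes:
                put_tri("af", dA["F"], u.af)
                put_tri("ef", dE["F"], u.ef)
                if layout.has_c:
                    put_tri("cf", dC["F"], u.cf)
        else:
            Am = u.a @ u.a.T
            Em = u.e @ u.e.T
            Cm = None if u.c is None else u.c @ u.c.T
            if layout.sexlim == "scalar":
                ka = ke = kc = u.k
            elif layout.sexlim == "common_effects":
                ka, ke, kc = u.ka, u.ke, u.kc
            else:
                ka = ke = kc = np.ones(p)
            gAf = dA.get("F", np.zeros((p, p)))
            gEf = dE.get("F", np.zeros((p, p)))
            gCf = dC.get("F", np.zeros((p, p)))
            dA_sh = dA["M"] + np.outer(ka, ka) * gAf
            dE_sh = dE["M"] + np.outer(ke, ke) * gEf
            put_tri("a", dA_sh, u.a)
            put_tri("e", dE_sh, u.e)
            if layout.has_c:
                dC_sh = dC["M"] + np.outer(kc, kc) * gCf
                put_tri("c", dC_sh, u.c)

            def scalar_grad(Mmale, k, G):
                # d/dk_j of tr(G * (K M K)) = 2 (M K G)_jj, chained to log k
                return 2.0 * np.diag(Mmale @ (k[:, None] * G)) * k

            if layout.sexlim == "scalar":
                gk = scalar_grad(Am, u.k, gAf) + scalar_grad(Em, u.k, gEf)
                if Cm is not None:
                    gk = gk + scalar_grad(Cm, u.k, gCf)
                grad[layout.slices["logk"]] = gk
            elif layout.sexlim == "common_effects":
                grad[layout.slices["logka"]] = scalar_grad(Am, u.ka, gAf)
                grad[layout.slices["logke"]] = scalar_grad(Em, u.ke, gEf)
                if layout.has_c:
                    grad[layout.slices["logkc"]] = scalar_grad(Cm, u.kc, gCf)
        for s in layout.sexes:
            grad[layout.slices[f"mu_{s}"]] = dmu[s]
        return float(total), grad


def _problem_for(dataset: TwinDataset, phenotypes) -> _FIMLProblem:
    X, zyg, sex = dataset.phenotype_pair_matrix(phenotypes)
    return _FIMLProblem(X, zyg, sex, len(phenotypes))


def minus2_loglik_fiml(dataset: TwinDataset, spec: CholeskyModelSpec) -> float:
    """FIML -2 log likelihood of the dataset under a fully specified model.

    Each pair contributes the multivariate-normal density of its observed
    entries; a non-positive-definite restricted covariance yields +inf.
    """
    prob = _problem_for(dataset, spec.phenotypes)
    mats = {}
    for s in prob.sexes:
        A, C, E = spec.component_matrices(s)
        mats[s] = (A, C, E, spec.mean_vector(s))
    return prob.neg2ll_from_matrices(mats)


def model_df(dataset: TwinDataset, n_params: int, phenotypes=None) -> int:
    """Degrees of freedom: non-missing phenotype values minus parameters."""
    phen = tuple(phenotypes or dataset.phenotypes)
    X, _, _ = dataset.phenotype_pair_matrix(phen)
    n_obs = int((~np.isnan(X)).sum())
    if n_params > n_obs:
        raise ValueError(f"{n_params} parameters exceed {n_obs} data points")
    return n_obs - n_params


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    n_starts: int = 1
    max_iter: int = 2000
    gtol: float = 1e-6
    seed: int | None = None
    aic_convention: str = "mx"  # "mx": -2LL - 2*df; "conventional": -2LL + 2*k
    restart_scale: float = 0.3


@dataclass
class FittedBiometricModel:
    spec: CholeskyModelSpec
    minus2ll: float
    n_params: int
    n_obs_values: int
    df: int
    converged: bool
    n_iter: int
    grad_norm: float
    aic_convention: str = "mx"
    theta: np.ndarray | None = None
    _layout: _Layout | None = None

    @property
    def aic(self) -> float:
        if self.aic_convention == "mx":
            return self.minus2ll - 2.0 * self.df
        return self.minus2ll + 2.0 * self.n_params

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return self.spec.phenotypes


def _clip_psd(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.clip(w, floor, None)) @ V.T


def _smart_start(problem: _FIMLProblem, layout: _Layout, X, zyg, sex):
    """Moment-based initialization from MZ/DZ cross-covariances."""
    p = layout.p
    df = pd.DataFrame(X)
    W = np.zeros((p, p))
    cross = {}
    for z in ("MZ", "DZ"):
        rows = df[np.asarray(zyg) == z]
        if len(rows) < 3:
            cross[z] = None
            continue
        cov = rows.cov(min_periods=2).to_numpy()
        cov = np.nan_to_num(cov, nan=0.0)
        Wz = 0.5 * (cov[:p, :p] + cov[p:, p:])
        B = cov[:p, p:]
        cross[z] = 0.5 * (B + B.T)
        W += 0.5 * Wz
    if cross.get("MZ") is None or cross.get("DZ") is None:
        A0 = 0.4 * W
        C0 = np.zeros((p, p))
    elif layout.has_c:
        A0 = _clip_psd(2.0 * (cross["MZ"] - cross["DZ"]))
        C0 = _clip_psd(2.0 * cross["DZ"] - cross["MZ"])
    else:
        A0 = _clip_psd(0.5 * (cross["MZ"] + 2.0 * cross["DZ"]))
        C0 = np.zeros((p, p))
    E0 = _clip_psd(W - A0 - C0)
    floor = 0.05 * np.clip(np.diag(W), 1e-4, None)
    A0 = A0 + np.diag(floor)
    E0 = E0 + np.diag(floor)
    theta = np.zeros(layout.n_params)
    theta[layout.slices["a"]] = layout.tri_vector(lower_cholesky_psd(A0))
    theta[layout.slices["e"]] = layout.tri_vector(lower_cholesky_psd(E0))
    if layout.has_c:
        C0 = C0 + np.diag(0.5 * floor)
        theta[layout.slices["c"]] = layout.tri_vector(lower_cholesky_psd(C0))
    if layout.sexlim == "free":
        theta[layout.slices["af"]] = theta[layout.slices["a"]]
        theta[layout.slices["ef"]] = theta[layout.slices["e"]]
        if layout.has_c:
            theta[layout.slices["cf"]] = theta[layout.slices["c"]]
    # log-scalars start at 0 (scalars at 1)
    sexarr = np.asarray(sex)
    for s in layout.sexes:
        rows = df[sexarr == s]
        if len(rows):
            m = rows.mean().to_numpy()
            theta[layout.slices[f"mu_{s}"]] = 0.5 * (
                np.nan_to_num(m[:p]) + np.nan_to_num(m[p:])
            )
    return theta


def fit_model(
    dataset: TwinDataset,
    phenotypes=None,
    family: str = "AE",
    sex_limitation: str = "none",
    config: FitConfig | None = None,
    start: np.ndarray | None = None,
) -> FittedBiometricModel:
    """Fit a Cholesky twin model by FIML.

    Minimizes the -2 log likelihood over free paths, means and (where
    applicable) female scalars.  ``config.n_starts > 1`` adds randomly
    perturbed restarts of the moment-based warm start and keeps the best
    optimum; non-convergence is flagged on the returned fit.
    """
    config = config or FitConfig()
    phen = tuple(phenotypes or dataset.phenotypes)
    X, zyg, sex = dataset.phenotype_pair_matrix(phen)
    zyg_present = set(np.asarray(zyg).tolist())
    if not {"MZ", "DZ"} <= zyg_present:
        raise ValueError("dataset must contain both MZ and DZ pairs")
    sexes_present = tuple(sorted(set(np.asarray(sex).tolist())))
    if sex_limitation != "none" and len(sexes_present) < 2:
        raise ValueError("sex-limited variants require both sexes in the data")
    layout = _Layout(len(phen), family, sex_limitation, sexes_present)
    problem = _FIMLProblem(X, zyg, sex, len(phen))

    x0 = start if start is not None else _smart_start(problem, layout, X, zyg, sex)
    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(max(0, config.n_starts - 1)):
        starts.append(x0 + config.restart_scale * rng.standard_normal(x0.size))

    best = None
    for s0 in starts:
        res = optimize.minimize(
            problem.neg2ll_and_grad,
            s0,
            args=(layout,),
            jac=True,
            method="L-BFGS-B",
            bounds=layout.bounds(),
            options={
                "maxiter": config.max_iter,
                "maxfun": 10 * config.max_iter,
                "ftol": 1e-13,
                "gtol": config.gtol,
                "maxcor": 25,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    gnorm = float(np.max(np.abs(best.jac)))
    spec = layout.to_spec(best.x, phen)
    n_params = layout.n_params
    return FittedBiometricModel(
        spec=spec,
        minus2ll=float(best.fun),
        n_params=n_params,
        n_obs_values=problem.n_obs_values,
        df=problem.n_obs_values - n_params,
        converged=bool(best.success or gnorm < 1e-3),
        n_iter=int(best.nit),
        grad_norm=gnorm,
        aic_convention=config.aic_convention,
        theta=best.x,
        _layout=layout,
    )


# ---------------------------------------------------------------------------
# decompositions


def _paths_of(obj):
    """(a, c, e, phenotypes) from a fit, spec or generating model."""
    spec = obj.spec if isinstance(obj, FittedBiometricModel) else obj
    return spec.a_paths, getattr(spec, "c_paths", None), spec.e_paths, tuple(spec.phenotypes)


@dataclass
class VarianceDecomposition:
    """Standardized per-factor variance shares on the common (male) scale.

    ``shares_a[j, k]`` is the fraction of phenotype j's total variance due
    to genetic factor A(k+1); rows of the combined shares sum to one.
    """

    phenotypes: tuple[str, ...]
    shares_a: np.ndarray
    shares_e: np.ndarray
    shares_c: np.ndarray | None
    h2: np.ndarray
    e2: np.ndarray
    c2: np.ndarray | None

    def to_frame(self) -> pd.DataFrame:
        p = len(self.phenotypes)
        cols = {}
        for k in range(p):
            cols[f"A{k + 1}"] = self.shares_a[:, k]
        if self.shares_c is not None:
            for k in range(p):
                cols[f"C{k + 1}"] = self.shares_c[:, k]
        for k in range(p):
            cols[f"E{k + 1}"] = self.shares_e[:, k]
        cols["h2"] = self.h2
        if self.c2 is not None:
            cols["c2"] = self.c2
        cols["e2"] = self.e2
        return pd.DataFrame(cols, index=list(self.phenotypes))


def standardized_decomposition(obj) -> VarianceDecomposition:
    """Per-factor standardized variance contributions of a (fitted) model."""
    a, c, e, phen = _paths_of(obj)
    A = a @ a.T
    E = e @ e.T
    C = None if c is None else c @ c.T
    total = np.diag(A + E + (0 if C is None else C))
    if np.any(total <= 0):
        raise ValueError("zero total variance for a phenotype")
    shares_a = a**2 / total[:, None]
    shares_e = e**2 / total[:, None]
    shares_c = None if c is None else c**2 / total[:, None]
    return VarianceDecomposition(
        phenotypes=phen,
        shares_a=shares_a,
        shares_e=shares_e,
        shares_c=shares_c,
        h2=shares_a.sum(axis=1),
        e2=shares_e.sum(axis=1),
        c2=None if shares_c is None else shares_c.sum(axis=1),
    )


@dataclass
class CorrelationDecomposition:
    phenotypes: tuple[str, ...]
    rg: np.ndarray
    re: np.ndarray
    rc: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Rg above the diagonal, Re below (the conventional display)."""
        p = len(self.phenotypes)
        out = np.full((p, p), np.nan)
        iu = np.triu_indices(p, 1)
        il = np.tril_indices(p, -1)
        out[iu] = self.rg[iu]
        out[il] = self.re[il]
        return pd.DataFrame(out, index=list(self.phenotypes), columns=list(self.phenotypes))


def correlation_decomposition(obj) -> CorrelationDecomposition:
    """Genetic and environmental correlation matrices of a (fitted) model.

    ``rg[i, j] = A[i, j] / sqrt(A[i, i] * A[j, j])`` and analogously for E
    (and C when present).  Phenotypes with (numerically) zero variance in a
    component get NaN rows/columns for that component.
    """
    a, c, e, phen = _paths_of(obj)

    def corr(M):
        d = np.sqrt(np.clip(np.diag(M), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = M / np.outer(d, d)
        R[~np.isfinite(R)] = np.nan
        return R

    A = a @ a.T
    E = e @ e.T
    return CorrelationDecomposition(
        phenotypes=phen,
        rg=corr(A),
        re=corr(E),
        rc=None if c is None else corr(c @ c.T),
    )


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fits: dict, baseline: str | None = None) -> pd.DataFrame:
    """Model-comparison ladder: -2LL, df, deltas vs the baseline, AIC.

    AIC follows each fit's convention (default ``-2LL - 2*df``).  The
    chi-square p-value is reported for models nested under the baseline
    (positive delta -2LL and delta df).
    """
    names = list(fits)
    base = baseline or names[0]
    ref = fits[base]
    n_obs = {f.n_obs_values for f in fits.values()}
    if len(n_obs) != 1:
        raise ValueError("fits were not computed on the same dataset")
    phens = {f.spec.phenotypes for f in fits.values()}
    if len(phens) != 1:
        raise ValueError("fits do not share a phenotype set")
    rows = []
    for name in names:
        f = fits[name]
        d_m2ll = f.minus2ll - ref.minus2ll
        d_df = f.df - ref.df
        pval = np.nan
        if name != base and d_df > 0:
            pval = float(chi2.sf(max(d_m2ll, 0.0), d_df))
        rows.append(
            {
                "model": name,
                "minus2LL": f.minus2ll,
                "df": f.df,
                "delta_minus2LL": d_m2ll if name != base else np.nan,
                "delta_df": d_df if name != base else np.nan,
                "p_value": pval,
                "AIC": f.aic,
                "n_params": f.n_params,
            }
        )
    return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# confidence intervals


@dataclass
class ConfidenceInterval:
    target: tuple
    estimate: float
    low: float
    high: float
    level: float
    method: str
    boundary: bool = False


def _target_fun(target: tuple, phen: tuple[str, ...]):
    kind = target[0]
    idx = [phen.index(t) for t in target[1:]]

    def value(spec: CholeskyModelSpec) -> float:
        dec = standardized_decomposition(spec)
        if kind == "h2":
            return float(dec.h2[idx[0]])
        if kind == "e2":
            return float(dec.e2[idx[0]])
        if kind == "c2":
            return float(dec.c2[idx[0]])
        cor = correlation_decomposition(spec)
        mat = {"rg": cor.rg, "re": cor.re, "rc": cor.rc}[kind]
        return float(mat[idx[0], idx[1]])

    return value


def confidence_intervals(
    fit: FittedBiometricModel,
    dataset: TwinDataset,
    targets,
    method: str = "bootstrap",
    level: float = 0.95,
    n_boot: int = 200,
    seed=None,
    config: FitConfig | None = None,
) -> dict:
    """CIs for standardized shares and genetic/environmental correlations.

    Targets are tuples such as ``("h2", "fatigue")`` or ``("rg", "mspain",
    "fatigue")``.  ``bootstrap`` resamples pairs with replacement within
    zygosity-by-sex strata and refits (warm-started at the original
    optimum), reporting percentile intervals; ``profile`` inverts the
    likelihood-ratio test by constrained refitting.  Estimates within 0.02
    of a boundary (0/1 for shares, +/-1 for correlations) are flagged as
    effectively one-sided.
    """
    if method not in ("bootstrap", "profile"):
        raise ValueError("method must be 'bootstrap' or 'profile'")
    phen = fit.spec.phenotypes
    funs = {tuple(t): _target_fun(tuple(t), phen) for t in targets}
    out = {}
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        X, zyg, sex = dataset.phenotype_pair_matrix(phen)
        strata = [
            np.flatnonzero((zyg == z) & (sex == s))
            for z in sorted(set(zyg))
            for s in sorted(set(sex))
        ]
        strata = [s for s in strata if s.size]
        draws = {t: [] for t in funs}
        cfg = config or FitConfig(max_iter=400, gtol=1e-5)
        for _ in range(n_boot):
            idx = np.concatenate([rng.choice(s, size=s.size, replace=True) for s in strata])
            prob = _FIMLProblem(X[idx], zyg[idx], sex[idx], len(phen))
            res = optimize.minimize(
                prob.neg2ll_and_grad,
                fit.theta,
                args=(fit._layout,),
                jac=True,
                method="L-BFGS-B",
                bounds=fit._layout.bounds(),
                options={"maxiter": cfg.max_iter, "ftol": 1e-12, "gtol": cfg.gtol},
            )
            bspec = fit._layout.to_spec(res.x, phen)
            for t, f in funs.items():
                draws[t].append(f(bspec))
        alpha = 100 * (1 - level) / 2
        for t, f in funs.items():
            est = f(fit.spec)
            lo, hi = np.percentile(draws[t], [alpha, 100 - alpha])
            out[t] = ConfidenceInterval(
                target=t,
                estimate=est,
                low=float(lo),
                high=float(hi),
                level=level,
                method=method,
                boundary=_near_boundary(t[0], est),
            )
        return out
    # profile likelihood
    prob = _problem_for(dataset, phen)
    crit = chi2.ppf(level, 1)
    for t, f in funs.items():
        est = f(fit.spec)
        lo = _profile_bound(fit, prob, f, est, crit, kind=t[0], direction=-1)
        hi = _profile_bound(fit, prob, f, est, crit, kind=t[0], direction=+1)
        out[t] = ConfidenceInterval(
            target=t,
            estimate=est,
            low=lo,
            high=hi,
            level=level,
            method=method,
            boundary=_near_boundary(t[0], est),
        )
    return out


def _near_boundary(kind: str, est: float, tol: float = 0.02) -> bool:
    if kind in ("h2", "c2", "e2"):
        return est < tol or est > 1 - tol
    return abs(est) > 1 - tol


def _hard_limits(kind: str):
    if kind in ("h2", "c2", "e2"):
        return 1e-4, 1 - 1e-4
    return -1 + 1e-4, 1 - 1e-4


def _profile_bound(fit, prob, target_fun, est, crit, kind, direction, step0=0.03, tol=2e-3):
    """One profile-likelihood bound: smallest objective subject to
    target = t exceeds the optimum by the chi-square critical value."""
    layout = fit._layout
    phen = fit.spec.phenotypes

    def profiled(t, x_start):
        cons = {
            "type": "eq",
            "fun": lambda th: target_fun(layout.to_spec(th, phen)) - t,
        }
        res = optimize.minimize(
            lambda th: prob.neg2ll_and_grad(th, layout)[0],
            x_start,
            method="SLSQP",
            constraints=[cons],
            options={"maxiter": 300, "ftol": 1e-10},
        )
        return res.fun, res.x

    limits = _hard_limits(kind)
    x_prev = fit.theta.copy()
    t = est
    step = step0
    t_in = est
    while True:
        t_try = t + direction * step
        if direction < 0 and t_try <= limits[0]:
            return limits[0]
        if direction > 0 and t_try >= limits[1]:
            return limits[1]
        fval, x_prev = profiled(t_try, x_prev)
        excess = fval - fit.minus2ll
        if excess >= crit:
            t_out = t_try
            break
        t_in, excess_prev = t_try, excess
        t = t_try
        step *= 1.6
    # bisect between t_in (inside) and t_out (outside)
    for _ in range(40):
        if abs(t_out - t_in) < tol:
            break
        mid = 0.5 * (t_in + t_out)
        fval, x_prev = profiled(mid, x_prev)
        if fval - fit.minus2ll >= crit:
            t_out = mid
        else:
            t_in = mid
    return float(0.5 * (t_in + t_out))
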
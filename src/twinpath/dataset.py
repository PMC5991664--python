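"""Wide-format twin-pair dataset container and CSV round-trip.

One row per pair: ``pair_id, zygosity, sex`` followed by per-twin phenotype
columns ``<phen>_t1 / <phen>_t2``, item columns ``<scale><k>_t1 / _t2`` and
per-twin covariates.  Missing co-twins (single responders) are empty cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import GeneratingModel, SEXES, ZYGOSITIES

__all__ = ["TwinDataset", "read_twin_csv", "write_twin_csv"]

SCHEMA_VERSION = "1"
ID_COLUMNS = ("pair_id", "zygosity", "sex")

#: canonical column names used by the bundled cohort emulation
DEFAULT_PHENOTYPES = ("epq_neuro", "neo_neuro", "anxdep", "mspain", "fatigue")
DEFAULT_COVARIATES = ("education", "medical_condition", "impairment", "reduced_activity")


def _twin_cols(names, twin: int) -> list[str]:
    return [f"{n}_t{twin}" for n in names]


@dataclass
class TwinDataset:
    """Collection of same-sex twin pairs in wide format."""

    pairs: pd.DataFrame
    phenotypes: tuple[str, ...]
    item_columns: dict[str, list[str]] = field(default_factory=dict)
    covariates: tuple[str, ...] = ()
    truth: GeneratingModel | None = None
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        df = self.pairs
        for col in ID_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        bad_z = ~df["zygosity"].isin(ZYGOSITIES)
        if bad_z.any():
            row = int(np.flatnonzero(bad_z.to_numpy())[0])
            raise ValueError(
                f"invalid zygosity {df['zygosity'].iloc[row]!r} on row {row + 1}"
            )
        bad_s = ~df["sex"].isin(SEXES)
        if bad_s.any():
            row = int(np.flatnonzero(bad_s.to_numpy())[0])
            raise ValueError(f"invalid sex {df['sex'].iloc[row]!r} on row {row + 1}")
        # same-sex design: each pair has exactly one sex; at least one twin observed
        t1 = df[_twin_cols(self.phenotypes, 1)].notna().any(axis=1)
        t2 = df[_twin_cols(self.phenotypes, 2)].notna().any(axis=1)
        if len(df) and not (t1 | t2).all():
            raise ValueError("each pair must have at least one non-missing twin")

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_individuals(self) -> int:
        t1 = self.pairs[_twin_cols(self.phenotypes, 1)].notna().any(axis=1)
        t2 = self.pairs[_twin_cols(self.phenotypes, 2)].notna().any(axis=1)
        return int(t1.sum() + t2.sum())

    @property
    def n_single_responders(self) -> int:
        t1 = self.pairs[_twin_cols(self.phenotypes, 1)].notna().any(axis=1)
        t2 = self.pairs[_twin_cols(self.phenotypes, 2)].notna().any(axis=1)
        return int((t1 ^ t2).sum())

    def individuals(self, subsample: str | None = None) -> pd.DataFrame:
        """Long format, one row per responding twin.

        ``subsample`` of ``"twin1"`` / ``"twin2"`` selects a single twin per
        pair, breaking the pair clustering (for analyses that assume
        independent observations).
        """
        if subsample not in (None, "twin1", "twin2"):
            raise ValueError("subsample must be None, 'twin1' or 'twin2'")
        base = [n for scale in self.item_columns.values() for n in scale]
        per_twin = list(self.phenotypes) + base + list(self.covariates)
        frames = []
        for twin in (1, 2):
            if subsample == f"twin{3 - twin}":
                continue
            cols = _twin_cols(per_twin, twin)
            sub = self.pairs[list(ID_COLUMNS)].copy()
            sub["twin"] = twin
            sub[per_twin] = self.pairs[cols].to_numpy()
            keep = self.pairs[_twin_cols(self.phenotypes, twin)].notna().any(axis=1)
            frames.append(sub[keep.to_numpy()])
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["pair_id", "twin"], ignore_index=True)

    def phenotype_pair_matrix(self, phenotypes=None):
        """(X, zygosity, sex) with X of shape (n_pairs, 2p): twin-1 block
        then twin-2 block, NaN where missing."""
        phen = tuple(phenotypes or self.phenotypes)
        X = self.pairs[_twin_cols(phen, 1) + _twin_cols(phen, 2)].to_numpy(float)
        return X, self.pairs["zygosity"].to_numpy(), self.pairs["sex"].to_numpy()

    def with_pairs(self, pairs: pd.DataFrame) -> "TwinDataset":
        return replace(self, pairs=pairs.reset_index(drop=True))

    # -- I/O -----------------------------------------------------------------

    def write_csv(self, path) -> None:
        write_twin_csv(self, path)


def write_twin_csv(dataset: TwinDataset, path) -> None:
    dataset.pairs.to_csv(path, index=False, float_format="%.10g")


def read_twin_csv(
    path,
    phenotypes=None,
    covariates=None,
    item_scales=None,
) -> TwinDataset:
    """Read a wide-format twin CSV written by :func:`write_twin_csv`.

    Columns are classified by the documented header convention: phenotype
    and covariate base names default to the canonical cohort schema; item
    columns are ``<scale><k>_t1/_t2`` with a trailing item index.  Unknown
    columns trigger a warning and are carried along untouched.  Empty
    co-twin phenotype cells are parsed as single responders.
    """
    df = pd.read_csv(path)
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    bases = set()
    for c in df.columns:
        if c.endswith(("_t1", "_t2")):
            bases.add(c[:-3])
    phen = tuple(p for p in (phenotypes or DEFAULT_PHENOTYPES) if p in bases)
    if not phen:
        raise ValueError("no phenotype columns found")
    covs = tuple(c for c in (covariates or DEFAULT_COVARIATES) if c in bases)
    known = set(phen) | set(covs)
    items: dict[str, list[str]] = {}
    scales = item_scales or phen
    for b in sorted(bases - known):
        stem = b.rstrip("0123456789")
        if stem != b and stem in scales:
            items.setdefault(stem, []).append(b)
        else:
            warnings.warn(f"unknown column {b!r} in {path}", stacklevel=2)
    for scale in items:
        items[scale].sort(key=lambda s: int(s[len(scale):]))
    return TwinDataset(
        pairs=df,
        phenotypes=phen,
        item_columns=items,
        covariates=covs,
    )
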
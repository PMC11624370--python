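"""Methane efficiency (MEF): the reversed residual-CH4 breeding value.

MEF is genetic residual CH4 production: the part of an animal's CH4 breeding
value that is genetically independent of milk, fat and protein yield.  With
genetic covariance matrix G (trait order CH4, MY, FY, PY), the conditional
genetic regression of CH4 on the production traits is

    b = G_pp^-1 g_p,              (G_pp the 3x3 production block,
                                   g_p the production-CH4 covariances)

and the raw residual breeding value of animal i is

    raw_i = EBV_CH4,i - b' (EBV_MY,i, EBV_FY,i, EBV_PY,i).

Because lower CH4 is better, the published index reverses the sign and is
expressed as a relative breeding value (RBV) with mean 100 and SD 5 in the
base-bull cohort.  Reliability of the linear index uses the selection-index
approximation with per-trait EBV reliabilities; official status for a sire
requires 20 daughters in 5 herds and 70% reliability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

PRODUCTION = slice(1, 4)   # MY, FY, PY in the canonical trait order
CH4 = 0


def structural_coefficients(genetic: np.ndarray) -> np.ndarray:
    """Regression of genetic CH4 on genetic MY, FY, PY: b = G_pp^-1 g_p."""
    g = np.asarray(genetic, dtype=float)
    gpp = g[PRODUCTION, PRODUCTION]
    gp = g[PRODUCTION, CH4]
    if np.linalg.cond(gpp) > 1e12:
        raise ValueError("production-trait genetic covariance block is singular")
    return np.linalg.solve(gpp, gp)


def residual_breeding_value(gebv: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw residual-genetic CH4 (g/d, lower = better) and the reversed index.

    ``gebv`` is (animals x 4) in canonical trait order.  Animals with any
    missing (NaN) trait EBV get NaN results.
    """
    g = np.asarray(gebv, dtype=float)
    if g.ndim != 2 or g.shape[1] != 4:
        raise ValueError("gebv must be animals x 4 (CH4, MY, FY, PY)")
    raw = g[:, CH4] - g[:, PRODUCTION] @ np.asarray(b, float)
    return raw, -raw


def rbv_standardize(
    values: np.ndarray,
    base_mask: np.ndarray,
    mean: float = 100.0,
    sd: float = 5.0,
) -> np.ndarray:
    """Express an index as an RBV: base group gets mean 100, SD 5 exactly."""
    x = np.asarray(values, dtype=float)
    m = np.asarray(base_mask, dtype=bool)
    base = x[m]
    base = base[np.isfinite(base)]
    if base.size < 2 or base.std() == 0:
        raise ValueError("degenerate base set: need >= 2 animals with variation")
    return mean + sd * (x - base.mean()) / base.std()


def base_bull_mask(
    pedigree_df: pd.DataFrame,
    official: np.ndarray,
    birth_window: tuple = (2008, 2017),
) -> np.ndarray:
    """Base cohort: bulls born in the window with an official evaluation."""
    y = pedigree_df["birth_year"].to_numpy()
    male = (pedigree_df["sex"] == "M").to_numpy()
    return male & (y >= birth_window[0]) & (y <= birth_window[1]) & np.asarray(official, bool)


def mef_reliability(
    trait_reliabilities: np.ndarray,
    genetic: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """Selection-index reliability of the MEF linear combination.

    With index weights w = (1, -b) on the trait EBVs and the approximation
    cov(EBV_i, EBV_j) ~= sqrt(rel_i rel_j) G_ij per animal,

        rel_MEF = (w' [sqrt(r) sqrt(r)' o G] w) / (w' G w),

    which is 1 when every trait reliability is 1, 0 when all are 0, and
    collapses to the CH4 reliability when b = 0.
    """
    rel = np.atleast_2d(np.asarray(trait_reliabilities, dtype=float))
    if rel.shape[1] != 4:
        raise ValueError("need 4 per-trait reliabilities (CH4, MY, FY, PY)")
    g = np.asarray(genetic, dtype=float)
    w = np.concatenate([[1.0], -np.asarray(b, float)])
    denom = w @ g @ w
    sq = np.sqrt(np.clip(rel, 0.0, 1.0))
    outer = sq[:, :, None] * sq[:, None, :]
    num = np.einsum("i,nij,j->n", w, outer * g[None], w)
    return np.clip(num / denom, 0.0, 1.0)


def official_status(
    n_daughters: np.ndarray,
    n_daughter_herds: np.ndarray,
    reliability: np.ndarray,
    min_daughters: int = 20,
    min_herds: int = 5,
    min_reliability: float = 0.70,
) -> np.ndarray:
    """Official-evaluation flag (all thresholds inclusive)."""
    return (
        (np.asarray(n_daughters) >= min_daughters)
        & (np.asarray(n_daughter_herds) >= min_herds)
        & (np.asarray(reliability) >= min_reliability)
    )


def sire_daughter_summary(records: pd.DataFrame, pedigree_df: pd.DataFrame) -> pd.DataFrame:
    """Daughter and daughter-herd counts per sire from phenotype records."""
    ped = pedigree_df.set_index("animal")
    rec = records.copy()
    rec["sire"] = ped.loc[rec["animal"], "sire"].to_numpy()
    rec = rec[rec["sire"] != 0]
    out = rec.groupby("sire").agg(
        n_daughters=("animal", "nunique"),
        n_daughter_herds=("herd", "nunique"),
    )
    return out.reset_index()


@dataclass
class MEFEvaluation:
    """Per-animal MEF results."""

    table: pd.DataFrame    # animal, raw_mef, index, rbv, reliability, official,
                           # n_daughters, n_daughter_herds

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MEFEvaluation":
        return cls(pd.read_csv(path))


def evaluate_mef(
    animal_ids: np.ndarray,
    gebv: np.ndarray,
    trait_reliabilities: np.ndarray,
    genetic: np.ndarray,
    pedigree_df: pd.DataFrame,
    records: Optional[pd.DataFrame] = None,
    birth_window: tuple = (2008, 2017),
) -> MEFEvaluation:
    """Full MEF evaluation: coefficients, raw values, reliabilities,
    official status, and RBV standardized on the base bulls."""
    b = structural_coefficients(genetic)
    raw, rev = residual_breeding_value(gebv, b)
    rel = mef_reliability(trait_reliabilities, genetic, b)

    ped = pedigree_df.set_index("animal").loc[animal_ids].reset_index()
    nd = np.zeros(len(animal_ids), dtype=int)
    nh = np.zeros(len(animal_ids), dtype=int)
    if records is not None:
        summ = sire_daughter_summary(records, pedigree_df).set_index("sire")
        for j, a in enumerate(animal_ids):
            if a in summ.index:
                nd[j] = summ.loc[a, "n_daughters"]
                nh[j] = summ.loc[a, "n_daughter_herds"]
    official = official_status(nd, nh, rel)
    base = base_bull_mask(ped, official, birth_window)
    if base.sum() < 2:
        # fall back to all bulls in the window so small simulations still scale
        base = (ped["sex"] == "M").to_numpy() & (
            (ped["birth_year"] >= birth_window[0]) & (ped["birth_year"] <= birth_window[1])
        )
    rbv = rbv_standardize(rev, base)
    table = pd.DataFrame(
        {
            "animal": animal_ids,
            "raw_mef": raw,
            "index": rev,
            "rbv": rbv,
            "reliability": rel,
            "official": official,
            "n_daughters": nd,
            "n_daughter_herds": nh,
            "base": base,
        }
    )
    return MEFEvaluation(table)
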
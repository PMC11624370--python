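"""Multi-trait herd-test-day animal model: design, MME, solvers, reliability.

The model for each record (all four traits observed together) is

    y = Xb + Z1 htd + Z2 a + Z3 p + e,

with fixed effects b (age-at-calving class, DIM class, year-season of
calving) and random herd-test-day, additive-genetic and permanent-
environment effects.  Equations are ordered level-major (the four trait
equations of one effect level are contiguous), so Henderson's mixed-model
equations take the Kronecker form

    [ W'W (x) R^-1  +  blockdiag(0, I (x) HTD^-1, K^-1 (x) G^-1, I (x) P^-1) ] s
        = (W' Y R^-1)vec ,

where W = [X Z1 Z2 Z3] and K^-1 is the pedigree (A^-1) or single-step
(H^-1) relationship inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .covariance import CovarianceComponents, TRAITS
from .pedigree import PedigreeTable
from .relationship import SparseSymmetric


@dataclass
class ModelSpec:
    """Trait list, fixed-effect class definitions and the DIM window."""

    traits: tuple = TRAITS
    dim_window: tuple = (120, 185)
    dim_class_width: int = 5
    age_class_width: int = 2   # months
    age_base: int = 18         # youngest age-at-calving class boundary
    lactation: int = 1

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def filter_records(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Restrict to first lactation and the DIM analysis window."""
    lo, hi = spec.dim_window
    m = (records["dim"] >= lo) & (records["dim"] <= hi)
    if "lactation" in records:
        m &= records["lactation"] == spec.lactation
    return records.loc[m].reset_index(drop=True)


def fixed_effect_codes(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Class codes for the three fixed effects."""
    out = pd.DataFrame(index=records.index)
    out["dim_class"] = (records["dim"] - spec.dim_window[0]) // spec.dim_class_width
    out["age_class"] = (records["age_calving"] - spec.age_base) // spec.age_class_width
    out["year_season"] = records["year_season"]
    return out


@dataclass
class Design:
    """Incidence structures of the model on a record set."""

    w: sp.csr_matrix                     # n_records x n_levels
    y: np.ndarray                        # n_records x n_traits
    blocks: dict                         # effect -> (offset, size, ids)
    records: pd.DataFrame
    spec: ModelSpec
    act_idx: np.ndarray                  # n_records x L padded active columns
    act_coef: np.ndarray                 # matching coefficients (0 = padding)

    @property
    def n_levels(self) -> int:
        return self.w.shape[1]

    def effect_slice(self, name: str) -> slice:
        off, size, _ = self.blocks[name]
        return slice(off, off + size)


def _fixed_columns(codes: pd.DataFrame):
    """Full-rank fixed-effect coding: all levels of the first factor,
    drop-first for the remaining factors."""
    cols = []          # per factor: (record -> column or -1)
    names = []
    offset = 0
    for k, fac in enumerate(codes.columns):
        levels = np.sort(codes[fac].unique())
        keep = levels if k == 0 else levels[1:]
        lookup = {lv: offset + j for j, lv in enumerate(keep)}
        cols.append(codes[fac].map(lambda v: lookup.get(v, -1)).to_numpy())
        names += [f"{fac}:{lv}" for lv in keep]
        offset += len(keep)
    return cols, names


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: PedigreeTable,
    random_effects: tuple = ("htd", "animal", "pe"),
) -> Design:
    """One-hot incidence for fixed and random effects.

    All pedigree animals receive animal-effect levels (animals without
    records are carried by the relationship matrix); PE levels exist only
    for recorded animals.
    """
    rec = records.reset_index(drop=True)
    ped_ids = set(pedigree.animals.tolist())
    offenders = sorted(set(rec["animal"]) - ped_ids)
    if offenders:
        raise ValueError(f"records reference animals missing from pedigree: {offenders[:10]}")

    n = len(rec)
    codes = fixed_effect_codes(rec, spec)
    fix_cols, fix_names = _fixed_columns(codes)
    n_fix = len(fix_names)

    blocks = {}
    offset = 0
    blocks["fixed"] = (0, n_fix, np.array(fix_names, dtype=object))
    offset += n_fix

    rows, cols, vals = [], [], []
    act = [[] for _ in range(n)]
    for fc in fix_cols:
        for r in range(n):
            if fc[r] >= 0:
                rows.append(r)
                cols.append(fc[r])
                vals.append(1.0)
                act[r].append((fc[r], 1.0))

    entries = {}
    if "htd" in random_effects:
        htd_ids = np.sort(rec["htd"].unique())
        lookup = {h: offset + j for j, h in enumerate(htd_ids)}
        blocks["htd"] = (offset, len(htd_ids), htd_ids)
        for r, h in enumerate(rec["htd"]):
            c = lookup[h]
            rows.append(r)
            cols.append(c)
            vals.append(1.0)
            act[r].append((c, 1.0))
        offset += len(htd_ids)
    if "animal" in random_effects:
        ani_ids = pedigree.animals
        lookup = {a: offset + j for j, a in enumerate(ani_ids)}
        blocks["animal"] = (offset, len(ani_ids), ani_ids)
        for r, a in enumerate(rec["animal"]):
            c = lookup[a]
            rows.append(r)
            cols.append(c)
            vals.append(1.0)
            act[r].append((c, 1.0))
        offset += len(ani_ids)
    if "pe" in random_effects:
        pe_ids = np.sort(rec["animal"].unique())
        lookup = {a: offset + j for j, a in enumerate(pe_ids)}
        blocks["pe"] = (offset, len(pe_ids), pe_ids)
        for r, a in enumerate(rec["animal"]):
            c = lookup[a]
            rows.append(r)
            cols.append(c)
            vals.append(1.0)
            act[r].append((c, 1.0))
        offset += len(pe_ids)

    w = sp.coo_matrix((vals, (rows, cols)), shape=(n, offset)).tocsr()
    L = max(len(a) for a in act)
    act_idx = np.zeros((n, L), dtype=np.int64)
    act_coef = np.zeros((n, L))
    for r, a in enumerate(act):
        for j, (c, v) in enumerate(a):
            act_idx[r, j] = c
            act_coef[r, j] = v
    y = rec[list(spec.traits)].to_numpy(dtype=float)
    return Design(w=w, y=y, blocks=blocks, records=rec, spec=spec,
                  act_idx=act_idx, act_coef=act_coef)


@dataclass
class MMESystem:
    """Assembled sparse mixed-model equations."""

    lhs: sp.csr_matrix
    rhs: np.ndarray
    design: Design
    components: CovarianceComponents
    rel_inverse_kind: str = "A"
    _factor: object = field(default=None, repr=False)

    @property
    def n_equations(self) -> int:
        return self.lhs.shape[0]

    def equation_index(self, effect: str, level_pos: int, trait: int) -> int:
        off, size, _ = self.design.blocks[effect]
        t = self.design.spec.n_traits
        return (off + level_pos) * t + trait

    def factorize(self):
        if self._factor is None:
            self._factor = spla.splu(self.lhs.tocsc())
        return self._factor


def _pad_block(kinv: sp.spmatrix, m: int, offset: int) -> sp.coo_matrix:
    k = kinv.tocoo()
    return sp.coo_matrix((k.data, (k.row + offset, k.col + offset)), shape=(m, m))


def assemble_mme(
    design: Design,
    components: CovarianceComponents,
    rel_inverse: Optional[SparseSymmetric] = None,
) -> MMESystem:
    """Henderson MME for the multi-trait model with complete-trait records.

    ``rel_inverse`` is A^-1 or H^-1 over exactly the animal-effect levels of
    the design (same id order); None means unrelated animals (identity).
    """
    t = design.spec.n_traits
    m = design.n_levels
    for name, mat in (("residual", components.residual),):
        if np.linalg.cond(mat) > 1e12:
            raise ValueError(f"singular component matrix: {name}")
    rinv = np.linalg.inv(components.residual)
    rinv = 0.5 * (rinv + rinv.T)
    wtw = (design.w.T @ design.w).tocsr()
    lhs = sp.kron(wtw, sp.csr_matrix(rinv), format="csr")

    priors = {
        "htd": components.htd,
        "animal": components.genetic,
        "pe": components.pe,
    }
    for eff, sigma in priors.items():
        if eff not in design.blocks:
            continue
        off, size, ids = design.blocks[eff]
        if np.linalg.cond(sigma) > 1e12:
            raise ValueError(f"singular component matrix: {eff}")
        sinv = np.linalg.inv(sigma)
        sinv = 0.5 * (sinv + sinv.T)
        if eff == "animal" and rel_inverse is not None:
            if rel_inverse.dim != size or not np.array_equal(rel_inverse.ids, ids):
                raise ValueError("rel_inverse ids do not match the animal levels")
            kinv = rel_inverse.matrix
        else:
            kinv = sp.eye(size, format="csr")
        lhs = lhs + sp.kron(_pad_block(kinv, m, off), sp.csr_matrix(sinv), format="csr")

    lhs = (0.5 * (lhs + lhs.T)).tocsr()  # exact symmetry
    rhs = (design.w.T @ (design.y @ rinv)).ravel()
    kind = "A" if rel_inverse is None else "custom"
    return MMESystem(lhs=lhs.tocsr(), rhs=rhs, design=design,
                     components=components, rel_inverse_kind=kind)


@dataclass
class SolutionSet:
    """Per-level, per-trait solutions of the MME."""

    theta: np.ndarray           # n_levels x n_traits
    design: Design
    method: str
    residual_norm: float
    iterations: int = 0

    def effect(self, name: str) -> np.ndarray:
        off, size, _ = self.design.blocks[name]
        return self.theta[off:off + size]

    def effect_frame(self, name: str) -> pd.DataFrame:
        off, size, ids = self.design.blocks[name]
        df = pd.DataFrame(self.effect(name), columns=list(self.design.spec.traits))
        df.insert(0, "id", ids)
        return df


def solve_mme(system: MMESystem, method: str = "direct", tol: float = 1e-10) -> SolutionSet:
    """Solve the MME by sparse LU or preconditioned conjugate gradients."""
    t = system.design.spec.n_traits
    if method == "direct":
        x = system.factorize().solve(system.rhs)
        iters = 0
    elif method == "cg":
        d = system.lhs.diagonal()
        d[d <= 0] = 1.0
        pre = sp.diags(1.0 / d)
        count = {"n": 0}

        def cb(_):
            count["n"] += 1

        x, info = spla.cg(system.lhs, system.rhs, rtol=tol, maxiter=20000, M=pre, callback=cb)
        if info != 0:
            raise RuntimeError(f"conjugate gradients did not converge (info={info}, iters={count['n']})")
        iters = count["n"]
    else:
        raise ValueError(f"unknown method {method!r}")
    res = np.linalg.norm(system.lhs @ x - system.rhs) / max(1.0, np.linalg.norm(system.rhs))
    return SolutionSet(theta=x.reshape(-1, t), design=system.design,
                       method=method, residual_norm=float(res), iterations=iters)


def prediction_error_variance(
    system: MMESystem, effect: str = "animal", level_positions: Optional[np.ndarray] = None
) -> np.ndarray:
    """Exact PEV blocks (n_levels x T x T) from columns of the MME inverse."""
    t = system.design.spec.n_traits
    off, size, _ = system.design.blocks[effect]
    if level_positions is None:
        level_positions = np.arange(size)
    lu = system.factorize()
    n = system.n_equations
    pev = np.zeros((len(level_positions), t, t))
    for j, lp in enumerate(level_positions):
        eqs = (off + lp) * t + np.arange(t)
        e = np.zeros((n, t))
        e[eqs, np.arange(t)] = 1.0
        sol = lu.solve(e)
        pev[j] = sol[eqs]
    return pev


def pev_reliability(
    system: MMESystem,
    f: Optional[np.ndarray] = None,
    effect: str = "animal",
    level_positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Reliability rel = 1 - PEV / ((1+F) * sigma2_a) per animal and trait,
    clipped to [0, 1]."""
    off, size, _ = system.design.blocks[effect]
    if level_positions is None:
        level_positions = np.arange(size)
    if f is None:
        f = np.zeros(size)
    pev = prediction_error_variance(system, effect, level_positions)
    g_diag = np.diag(system.components.genetic)
    denom = (1.0 + np.asarray(f)[level_positions])[:, None] * g_diag[None, :]
    rel = 1.0 - np.diagonal(pev, axis1=1, axis2=2) / denom
    if np.any(rel < -1e-8):
        import warnings

        warnings.warn("PEV exceeded (1+F) * sigma2_a for some animals; "
                      "reliabilities clipped to 0")
    return np.clip(rel, 0.0, 1.0)


def blend_reliability(dgv_rel, animal_model_rel, weight: float = 0.8):
    """GEBV reliability as the weighted (80:20) average of direct genomic
    value and animal-model reliabilities."""
    d = np.asarray(dgv_rel, dtype=float)
    a = np.asarray(animal_model_rel, dtype=float)
    if np.any((d < 0) | (d > 1)) or np.any((a < 0) | (a > 1)):
        raise ValueError("reliabilities must be in [0, 1]")
    return weight * d + (1.0 - weight) * a
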
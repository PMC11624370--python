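"""Multi-trait REML estimation of (HTD, G, P, R).

Two exact engines estimate the same animal model:

``reml_em_full``
    EM-REML on the complete mixed-model equations (every animal and PE level
    gets an equation; dense inverse of the coefficient matrix per
    iteration).  Works for any pedigree/design; intended for small data and
    used as the reference in tests.

``AbsorbedREML`` / ``reml_absorbed``
    The scalable path for repeatability data on non-parent cows whose
    parents are founders (e.g. nested half-sib/full-sib designs): only
    fixed, herd-test-day and parent-animal equations are retained, while
    each cow's Mendelian-sampling plus permanent-environment effect is
    absorbed into a per-cow residual covariance

        V_cow = J_k (x) Sigma_c + I_k (x) R ,   Sigma_c = 0.5 G + P .

    This is the classical reduced animal model combined with the free
    reparameterization (HTD, G, Sigma_c, R) <-> (HTD, G, P, R), so its REML
    optimum is the animal-model optimum.  EM steps (monotone in the
    restricted likelihood) are accelerated with average-information (AI)
    Newton steps guarded by step halving and EM fallback.

Both engines standardize traits internally and report components on the
original scale.  Heritability uses the full denominator (HTD + G + P + R).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .covariance import CovarianceComponents, nearest_psd
from .mixed_model import Design, ModelSpec, build_design, filter_records, fixed_effect_codes, _fixed_columns
from .pedigree import UNKNOWN, PedigreeTable

COMPONENT_NAMES = ("htd", "genetic", "pe", "residual")


def _vech_basis(t: int) -> list[np.ndarray]:
    basis = []
    for a in range(t):
        for b in range(a, t):
            e = np.zeros((t, t))
            e[a, b] = 1.0
            e[b, a] = 1.0
            basis.append(e)
    return basis


def _score_from_stat(stat: np.ndarray, sigma: np.ndarray, q: float, basis) -> np.ndarray:
    """Score of the restricted likelihood wrt vech(Sigma):
    dl/dSigma = 0.5 Sigma^-1 (S - q Sigma) Sigma^-1 with S the EM statistic."""
    sinv = np.linalg.inv(sigma)
    smat = 0.5 * sinv @ (stat - q * sigma) @ sinv
    return np.array([np.sum(smat * e) for e in basis])


def _chol_inverse(cf) -> np.ndarray:
    """Inverse of a matrix from its (lower) Cholesky factor via LAPACK dpotri."""
    c, lower = cf
    inv, info = sla.lapack.dpotri(c, lower=lower)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    # dpotri fills only the factor's triangle; mirror it
    if lower:
        tri = np.tril(inv)
        return tri + np.tril(inv, -1).T
    tri = np.triu(inv)
    return tri + np.triu(inv, 1).T


def _is_pd(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


@dataclass
class REMLResult:
    components: CovarianceComponents
    loglik_path: list
    converged: bool
    n_iter: int
    engine: str
    se: Optional[dict] = None
    param_cov: Optional[np.ndarray] = None  # over vech(htd,genetic,pe,residual)

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1]

    def heritability(self) -> np.ndarray:
        return self.components.heritability()

    def genetic_correlations(self) -> np.ndarray:
        return self.components.genetic_correlations()


def default_start(y: np.ndarray) -> dict:
    """Neutral start: split the empirical covariance of the observations."""
    c = np.cov(y, rowvar=False)
    c = np.atleast_2d(c)
    return {"htd": 0.10 * c, "genetic": 0.30 * c, "pe": 0.20 * c, "residual": 0.40 * c}


# ---------------------------------------------------------------------------
# full-MME EM engine
# ---------------------------------------------------------------------------

def reml_em_full(
    design: Design,
    start: Optional[dict] = None,
    ainv: Optional[sp.spmatrix] = None,
    max_iter: int = 2000,
    tol: float = 1e-7,
    check_monotone: bool = True,
) -> REMLResult:
    """EM-REML on the complete MME (dense); small-scale reference engine."""
    y = design.y
    n, t = y.shape
    scale = y.std(axis=0)
    scale[scale == 0] = 1.0
    ys = y / scale
    d = np.diag(1.0 / scale)

    if start is None:
        start = default_start(y)
    params = {k: d @ np.asarray(start[k], float) @ d for k in COMPONENT_NAMES}

    effects = [e for e in ("htd", "animal", "pe") if e in design.blocks]
    m = design.n_levels
    wtw = (design.w.T @ design.w).toarray()
    wty = design.w.T @ ys

    kinvs = {}
    logdet_k = 0.0
    for eff in effects:
        off, size, _ = design.blocks[eff]
        if eff == "animal" and ainv is not None:
            kinvs[eff] = sp.csr_matrix(ainv)
            sign, ld = np.linalg.slogdet(kinvs[eff].toarray())
            logdet_k += -ld * t  # log|A (x) G| = T log|A| + q log|G|
        else:
            kinvs[eff] = sp.eye(size, format="csr")

    comp_of = {"htd": "htd", "animal": "genetic", "pe": "pe"}
    basis = _vech_basis(t)
    arange_t = np.arange(t)
    llpath = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rinv = np.linalg.inv(params["residual"])
        c = np.kron(wtw, rinv)
        for eff in effects:
            off, size, _ = design.blocks[eff]
            sinv = np.linalg.inv(params[comp_of[eff]])
            sl = slice(off * t, (off + size) * t)
            c[sl, sl] += np.kron(kinvs[eff].toarray(), sinv)
        rhs = (wty @ rinv).ravel()
        cf = sla.cho_factor(c, lower=True, check_finite=False)
        theta = sla.cho_solve(cf, rhs, check_finite=False)
        cinv = _chol_inverse(cf)
        logdet_c = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = np.sum((ys @ rinv) * ys) - theta @ rhs
        m2ll = (
            n * np.linalg.slogdet(params["residual"])[1]
            + sum(
                design.blocks[e][1] * np.linalg.slogdet(params[comp_of[e]])[1]
                for e in effects
            )
            + logdet_k + logdet_c + quad
        )
        llpath.append(-0.5 * m2ll)
        if check_monotone and len(llpath) > 1 and llpath[-1] < llpath[-2] - 1e-6:
            raise RuntimeError("EM-REML restricted likelihood decreased")

        th = theta.reshape(m, t)
        new = {}
        # random-effect statistics
        for eff in effects:
            off, size, _ = design.blocks[eff]
            k = kinvs[eff].tocoo()
            u = th[off:off + size]
            ui, uj = u[k.row], u[k.col]
            stat = np.einsum("n,ni,nj->ij", k.data, ui, uj)
            ei = (off + k.row)[:, None] * t + arange_t
            ej = (off + k.col)[:, None] * t + arange_t
            blocks = cinv[ei[:, :, None], ej[:, None, :]]
            stat = stat + np.einsum("n,nij->ij", k.data, blocks)
            new[comp_of[eff]] = 0.5 * (stat + stat.T) / size
        # residual
        fitted = design.w @ th
        e_hat = ys - fitted
        stat = e_hat.T @ e_hat
        li = design.act_idx
        lc = design.act_coef
        for a in range(li.shape[1]):
            for b in range(li.shape[1]):
                wgt = lc[:, a] * lc[:, b]
                if not np.any(wgt):
                    continue
                ea = li[:, a][:, None] * t + arange_t
                eb = li[:, b][:, None] * t + arange_t
                blocks = cinv[ea[:, :, None], eb[:, None, :]]
                stat += np.einsum("n,nij->ij", wgt, blocks)
        new["residual"] = 0.5 * (stat + stat.T) / n

        delta = max(
            np.max(np.abs(new[k2] - params[k2]) / (np.abs(params[k2]) + 1e-2))
            for k2 in new
        )
        params.update(new)
        if delta < tol:
            converged = True
            break

    ds = np.diag(scale)
    comps = CovarianceComponents(
        *[ds @ params[k] @ ds for k in COMPONENT_NAMES],
        traits=tuple(design.spec.traits),
    )
    return REMLResult(components=comps, loglik_path=llpath, converged=converged,
                      n_iter=it, engine="full")


# ---------------------------------------------------------------------------
# absorbed engine with AI acceleration
# ---------------------------------------------------------------------------

class AbsorbedREML:
    """REML for repeatability data on non-parent cows with founder parents.

    See the module docstring for the model equivalence argument.  The free
    parameters during iteration are (HTD, G, Sigma_c, R); the reported PE
    matrix is Sigma_c - 0.5 G.
    """

    def __init__(self, records: pd.DataFrame, spec: ModelSpec, pedigree: PedigreeTable):
        self.spec = spec
        self.t = spec.n_traits
        rec = records.sort_values(["animal", "test_day"] if "test_day" in records
                                  else ["animal"]).reset_index(drop=True)
        ped = pedigree.sorted()
        pdf = ped.df.set_index("animal")

        counts = rec.groupby("animal").size()
        ks = counts.unique()
        if len(ks) != 1 or ks[0] < 2:
            raise ValueError("absorbed engine needs a uniform record count >= 2 per cow")
        self.k = int(ks[0])
        cows = counts.index.to_numpy()
        sire_of = pdf.loc[cows, "sire"].to_numpy()
        dam_of = pdf.loc[cows, "dam"].to_numpy()
        if np.any(sire_of == UNKNOWN) or np.any(dam_of == UNKNOWN):
            raise ValueError("absorbed engine requires both parents known for every cow")
        par_ids = np.unique(np.concatenate([sire_of, dam_of]))
        if np.intersect1d(par_ids, cows).size:
            raise ValueError("recorded animals may not be parents (use the full engine)")
        ps = pdf.loc[par_ids]
        if np.any(ps["sire"] != UNKNOWN) or np.any(ps["dam"] != UNKNOWN):
            raise ValueError("parents must be founders (use the full engine)")

        self.cows = cows
        self.nc = len(cows)
        t, k = self.t, self.k
        self.kt = k * t

        codes = fixed_effect_codes(rec, spec)
        fix_cols, fix_names = _fixed_columns(codes)
        n_fix = len(fix_names)
        htd_ids = np.sort(rec["htd"].unique())
        q1 = len(htd_ids)
        q2 = len(par_ids)
        htd_lookup = {h: n_fix + j for j, h in enumerate(htd_ids)}
        par_lookup = {p: n_fix + q1 + j for j, p in enumerate(par_ids)}
        self.m = n_fix + q1 + q2
        self.n_fix, self.q1, self.q2 = n_fix, q1, q2
        self.htd_ids, self.par_ids = htd_ids, par_ids
        self.blocks = {
            "fixed": (0, n_fix, np.array(fix_names, dtype=object)),
            "htd": (n_fix, q1, htd_ids),
            "parent": (n_fix + q1, q2, par_ids),
        }

        n = len(rec)
        if n != self.nc * k:
            raise AssertionError
        L = len(fix_cols) + 3  # fixed factors + htd + sire + dam
        ent_col = np.zeros((self.nc, k, L), dtype=np.int64)
        ent_coef = np.zeros((self.nc, k, L))
        htd_lev = np.zeros(n, dtype=np.int64)
        sire_lev = np.zeros(n, dtype=np.int64)
        dam_lev = np.zeros(n, dtype=np.int64)
        sire_rec = pdf.loc[rec["animal"], "sire"].to_numpy()
        dam_rec = pdf.loc[rec["animal"], "dam"].to_numpy()
        for r in range(n):
            c, rr = divmod(r, k)
            j = 0
            for fc in fix_cols:
                if fc[r] >= 0:
                    ent_col[c, rr, j] = fc[r]
                    ent_coef[c, rr, j] = 1.0
                j += 1
            ent_col[c, rr, j] = htd_lookup[rec["htd"].iloc[r]]
            ent_coef[c, rr, j] = 1.0
            htd_lev[r] = ent_col[c, rr, j] - n_fix
            j += 1
            ent_col[c, rr, j] = par_lookup[sire_rec[r]]
            ent_coef[c, rr, j] = 0.5
            sire_lev[r] = ent_col[c, rr, j] - n_fix - q1
            j += 1
            ent_col[c, rr, j] = par_lookup[dam_rec[r]]
            ent_coef[c, rr, j] = 0.5
            dam_lev[r] = ent_col[c, rr, j] - n_fix - q1
        self.L = L
        self.ent_col = ent_col
        self.ent_coef = ent_coef
        self.htd_lev, self.sire_lev, self.dam_lev = htd_lev, sire_lev, dam_lev

        y = rec[list(spec.traits)].to_numpy(dtype=float)
        self.scale = y.std(axis=0)
        self.scale[self.scale == 0] = 1.0
        self.yc = (y / self.scale).reshape(self.nc, self.kt)
        self.records = rec

        # precomputed assembly / gather indices
        kl = k * L
        colf = ent_col.reshape(self.nc, kl)
        coeff = ent_coef.reshape(self.nc, kl)
        recf = np.repeat(np.arange(k), L)[None, :].repeat(self.nc, axis=0)
        meq = self.m * t
        at = np.arange(t)
        # pair arrays for the data part of C
        ce = colf[:, :, None]
        cf_ = colf[:, None, :]
        re_ = recf[:, :, None]
        rf = recf[:, None, :]
        rows = (ce * t)[:, :, :, None, None] + at[None, None, None, :, None]
        cols = (cf_ * t)[:, :, :, None, None] + at[None, None, None, None, :]
        self._pair_pos = (rows * meq + cols).ravel()
        self._pair_factor = (coeff[:, :, None] * coeff[:, None, :])[
            :, :, :, None, None
        ].repeat(t, axis=3).repeat(t, axis=4).ravel()
        vrow = (re_ * t)[:, :, :, None, None] + at[None, None, None, :, None]
        vcol = (rf * t)[:, :, :, None, None] + at[None, None, None, None, :]
        self._pair_vidx = (vrow * self.kt + vcol).ravel()
        # rhs scatter positions
        self._rhs_pos = ((colf * t)[:, :, None] + at[None, None, :]).ravel()
        self._rhs_vpos = ((recf * t)[:, :, None] + at[None, None, :])
        self._eq48 = ((colf * t)[:, :, None] + at[None, None, :]).reshape(self.nc, kl * t)
        self._meq = meq
        self._basis = _vech_basis(t)

    # -- parameter helpers -------------------------------------------------
    def _free_from_components(self, comps: dict) -> dict:
        return {
            "htd": comps["htd"].copy(),
            "genetic": comps["genetic"].copy(),
            "cow": 0.5 * comps["genetic"] + comps["pe"],
            "residual": comps["residual"].copy(),
        }

    def _components_from_free(self, free: dict) -> dict:
        return {
            "htd": free["htd"],
            "genetic": free["genetic"],
            "pe": free["cow"] - 0.5 * free["genetic"],
            "residual": free["residual"],
        }

    # -- core linear algebra ----------------------------------------------
    def _system(self, free: dict):
        """Assemble and factorize the retained MME at the given parameters."""
        t, k, kt = self.t, self.k, self.kt
        v = np.kron(np.ones((k, k)), free["cow"]) + np.kron(np.eye(k), free["residual"])
        vinv = np.linalg.inv(v)
        sign, logdet_v = np.linalg.slogdet(v)
        data = self._pair_factor * vinv.ravel()[self._pair_vidx]
        c = np.bincount(self._pair_pos, weights=data, minlength=self._meq**2).reshape(
            self._meq, self._meq
        )
        hinv = np.linalg.inv(free["htd"])
        ginv = np.linalg.inv(free["genetic"])
        off, q1, _ = self.blocks["htd"]
        for j in range(q1):
            sl = slice((off + j) * t, (off + j + 1) * t)
            c[sl, sl] += hinv
        off, q2, _ = self.blocks["parent"]
        for j in range(q2):
            sl = slice((off + j) * t, (off + j + 1) * t)
            c[sl, sl] += ginv

        tvy = self.yc @ vinv  # nc x kt
        rhs = np.bincount(
            self._rhs_pos,
            weights=(self.ent_coef.reshape(self.nc, -1)[:, :, None]
                     * np.take_along_axis(tvy[:, None, :].repeat(self._rhs_vpos.shape[1], 1),
                                          self._rhs_vpos, axis=2)).ravel(),
            minlength=self._meq,
        )
        cf = sla.cho_factor(c, lower=True, check_finite=False)
        theta = sla.cho_solve(cf, rhs, check_finite=False)
        logdet_c = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = np.sum(tvy * self.yc) - theta @ rhs
        m2ll = (
            self.nc * logdet_v
            + self.q1 * np.linalg.slogdet(free["htd"])[1]
            + self.q2 * np.linalg.slogdet(free["genetic"])[1]
            + logdet_c + quad
        )
        return {
            "vinv": vinv, "cf": cf, "theta": theta, "rhs": rhs,
            "loglik": -0.5 * m2ll, "tvy": tvy,
        }

    def _estep(self, free: dict, sysd: dict):
        """EM sufficient statistics for all four free components."""
        t, k, kt, nc = self.t, self.k, self.kt, self.nc
        vinv, cf, theta = sysd["vinv"], sysd["cf"], sysd["theta"]
        cinv = _chol_inverse(cf)
        th = theta.reshape(self.m, t)
        at = np.arange(t)

        # fitted values per record slot via the entry structure
        thg = th.ravel()[self._eq48].reshape(nc, k, self.L, t)
        fitted = np.einsum("ckl,cklt->ckt", self.ent_coef, thg).reshape(nc, kt)
        estar = self.yc - fitted
        rw = estar @ vinv                      # P y, cow-major (nc x kt)
        rrec = rw.reshape(nc, k, t)
        sr = rrec.sum(axis=1)                  # Z' r per cow
        s_c = free["cow"]
        uhat = sr @ s_c

        q_all = vinv.reshape(k, t, k, t).sum(axis=(0, 2))
        cov0_u = s_c - s_c @ q_all @ s_c
        zv = vinv.reshape(k, t, kt).sum(axis=0)      # Z'Vinv, t x kt
        szv = (s_c @ zv).reshape(t, k, t)
        bsel = szv[:, np.repeat(np.arange(k), self.L), :]         # t x kL x t
        b = bsel[None, :, :, :] * self.ent_coef.reshape(nc, -1)[:, None, :, None]
        b48 = b.reshape(nc, t, -1)
        g48 = cinv[self._eq48[:, :, None], self._eq48[:, None, :]]
        corr_u = np.matmul(np.matmul(b48, g48), b48.transpose(0, 2, 1)).sum(axis=0)
        stat_c = uhat.T @ uhat + nc * cov0_u + corr_u
        stat_c = 0.5 * (stat_c + stat_c.T)

        # residual statistic
        r_mat = free["residual"]
        e8 = estar.reshape(nc, k, t) - uhat[:, None, :]
        stat_e = np.einsum("ckt,cku->tu", e8, e8)
        rv = np.kron(np.eye(k), r_mat) @ vinv
        rv4 = rv.reshape(k, t, k, t)
        cov0_e = k * r_mat
        for r in range(k):
            cov0_e = cov0_e - r_mat @ vinv[r * t:(r + 1) * t, r * t:(r + 1) * t] @ r_mat
        corr_e = np.zeros((t, t))
        recidx = np.repeat(np.arange(k), self.L)
        for r in range(k):
            sel = rv4[r][:, recidx, :]                 # t x kL x t
            be = sel[None] * self.ent_coef.reshape(nc, -1)[:, None, :, None]
            be48 = be.reshape(nc, t, -1)
            corr_e += np.matmul(np.matmul(be48, g48), be48.transpose(0, 2, 1)).sum(axis=0)
        stat_e = stat_e + nc * cov0_e + corr_e
        stat_e = 0.5 * (stat_e + stat_e.T)

        # retained random effects
        stats = {}
        for eff, comp in (("htd", "htd"), ("parent", "genetic")):
            off, q, _ = self.blocks[eff]
            u = th[off:off + q]
            eqs = (off + np.arange(q))[:, None] * t + at
            blocks = cinv[eqs[:, :, None], eqs[:, None, :]]
            s = u.T @ u + blocks.sum(axis=0)
            stats[comp] = 0.5 * (s + s.T)
        stats["cow"] = stat_c
        stats["residual"] = stat_e
        return stats, rw, sr

    def _ai_matrix(self, free: dict, sysd: dict, rw: np.ndarray, sr: np.ndarray):
        """Average-information matrix over vech(HTD, G, Sigma_c, R)."""
        t, k, kt, nc = self.t, self.k, self.kt, self.nc
        basis = self._basis
        nb = len(basis)
        p_tot = 4 * nb
        rrec = rw.reshape(nc * k, t)

        hagg = np.zeros((self.q1, t))
        np.add.at(hagg, self.htd_lev, rrec)
        pagg = np.zeros((self.q2, t))
        np.add.at(pagg, self.sire_lev, 0.5 * rrec)
        np.add.at(pagg, self.dam_lev, 0.5 * rrec)

        eb = np.stack(basis)                                # nb x t x t
        f = np.zeros((nc * k, t, p_tot))
        f[:, :, 0:nb] = np.einsum("ptu,nu->ntp", eb, hagg[self.htd_lev])
        agg_par = 0.5 * (pagg[self.sire_lev] + pagg[self.dam_lev])
        f[:, :, nb:2 * nb] = np.einsum("ptu,nu->ntp", eb, agg_par)
        sr_rec = np.repeat(sr, k, axis=0)
        f[:, :, 2 * nb:3 * nb] = np.einsum("ptu,nu->ntp", eb, sr_rec)
        f[:, :, 3 * nb:] = np.einsum("ptu,nu->ntp", eb, rrec)
        fc = f.reshape(nc, kt, p_tot)

        vinv, cf = sysd["vinv"], sysd["cf"]
        vf = np.einsum("ij,njp->nip", vinv, fc)
        # retained-equation RHS for every f, then MME solve
        coefe = self.ent_coef.reshape(nc, -1)
        kl = k * self.L
        ent_rec_t = self._rhs_vpos.reshape(nc, kl, t)
        rhsf = np.zeros((self._meq, p_tot))
        for p in range(p_tot):
            vals = coefe[:, :, None] * np.take_along_axis(vf[:, :, p][:, None, :]
                                                          .repeat(kl, 1), ent_rec_t, axis=2)
            rhsf[:, p] = np.bincount(self._rhs_pos, weights=vals.ravel(),
                                     minlength=self._meq)
        thf = sla.cho_solve(cf, rhsf, check_finite=False)
        thg = thf[self._eq48].reshape(nc, k, self.L, t, p_tot)
        fittedf = np.einsum("ckl,ckltp->cktp", self.ent_coef, thg).reshape(nc, kt, p_tot)
        pf = np.einsum("ij,njp->nip", vinv, fc - fittedf)
        ai = 0.5 * np.einsum("nip,niq->pq", fc, pf)
        return 0.5 * (ai + ai.T)

    # -- main loop ----------------------------------------------------------
    def fit(
        self,
        start: Optional[dict] = None,
        max_iter: int = 100,
        tol: float = 1e-5,
        n_em_start: int = 3,
        use_ai: bool = True,
        verbose: bool = False,
    ) -> REMLResult:
        t = self.t
        d = np.diag(1.0 / self.scale)
        y = self.yc.reshape(-1, t)
        if start is None:
            startd = default_start(y)
        else:
            startd = {k2: d @ np.asarray(start[k2], float) @ d for k2 in COMPONENT_NAMES}
        free = self._free_from_components(startd)

        basis = self._basis
        nb = len(basis)
        qs = {"htd": self.q1, "genetic": self.q2, "cow": self.nc,
              "residual": self.nc * self.k}
        order = ("htd", "genetic", "cow", "residual")

        llpath = []
        converged = False
        sysd = self._system(free)
        ai = None
        it = 0
        flat_count = 0
        for it in range(1, max_iter + 1):
            llpath.append(sysd["loglik"])
            stats, rw, sr = self._estep(free, sysd)
            em_update = {k2: stats[k2] / qs[k2] for k2 in order}

            proposal = None
            if use_ai and it > n_em_start:
                score = np.concatenate(
                    [_score_from_stat(stats[k2], free[k2], qs[k2], basis) for k2 in order]
                )
                ai = self._ai_matrix(free, sysd, rw, sr)
                try:
                    delta = np.linalg.solve(ai + 1e-8 * np.eye(len(ai)), score)
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None:
                    step = 1.0
                    for _ in range(15):
                        cand = {}
                        ok = True
                        for j, k2 in enumerate(order):
                            mnew = free[k2].copy()
                            for b, e in enumerate(basis):
                                mnew = mnew + step * delta[j * nb + b] * e
                            if not _is_pd(mnew):
                                # project back into the PD cone; components
                                # near the boundary otherwise reject every step
                                mnew = nearest_psd(mnew, 1e-8 * max(np.trace(mnew), 1e-8))
                                if not _is_pd(mnew):
                                    ok = False
                                    break
                            cand[k2] = mnew
                        if ok:
                            try:
                                sys_new = self._system(cand)
                            except np.linalg.LinAlgError:
                                ok = False
                            else:
                                if sys_new["loglik"] >= sysd["loglik"] - 1e-8:
                                    proposal = (cand, sys_new)
                                    break
                        step *= 0.5
            if proposal is None:
                cand = em_update
                if not all(_is_pd(cand[k2]) for k2 in order):
                    cand = {k2: nearest_psd(cand[k2], 1e-10) for k2 in order}
                try:
                    sys_new = self._system(cand)
                except np.linalg.LinAlgError:
                    # badly conditioned update near a boundary: lift the
                    # smallest eigenvalues and retry once
                    cand = {k2: nearest_psd(cand[k2], 1e-6 * max(np.trace(cand[k2]), 1e-8))
                            for k2 in order}
                    try:
                        sys_new = self._system(cand)
                    except np.linalg.LinAlgError:
                        break  # keep the last accepted state
                proposal = (cand, sys_new)

            new_free, sys_new = proposal
            change = max(
                np.max(np.abs(new_free[k2] - free[k2]) / (np.abs(free[k2]) + 1e-2))
                for k2 in order
            )
            ll_gain = sys_new["loglik"] - sysd["loglik"]
            free, sysd = new_free, sys_new
            if verbose:
                print(f"iter {it}: loglik {sysd['loglik']:.6f} change {change:.2e}")
            # converge on parameter stability, or on a flat likelihood
            # (small datasets can leave weakly identified directions)
            flat_count = flat_count + 1 if abs(ll_gain) < 1e-8 * (1 + abs(sysd["loglik"])) else 0
            if change < tol or (it > n_em_start + 2 and flat_count >= 3):
                converged = True
                llpath.append(sysd["loglik"])
                break

        # parameter covariance from the AI matrix at the optimum
        param_cov = None
        se = None
        if use_ai:
            stats, rw, sr = self._estep(free, sysd)
            ai = self._ai_matrix(free, sysd, rw, sr)
            try:
                cov_free = np.linalg.inv(ai)
                lmap = self._free_to_component_jacobian()
                cov_out = lmap @ cov_free @ lmap.T
                sc = self._vech_scale_vector()
                param_cov = cov_out * np.outer(sc, sc)
                se = self._se_matrices(param_cov)
            except np.linalg.LinAlgError:
                pass

        comps_scaled = self._components_from_free(free)
        ds = np.diag(self.scale)
        comps = CovarianceComponents(
            *[ds @ comps_scaled[k2] @ ds for k2 in COMPONENT_NAMES],
            traits=tuple(self.spec.traits),
        )
        return REMLResult(components=comps, loglik_path=llpath, converged=converged,
                          n_iter=it, engine="absorbed", se=se, param_cov=param_cov)

    # -- reporting helpers ---------------------------------------------------
    def _free_to_component_jacobian(self) -> np.ndarray:
        """(htd, G, pe, R) = L (htd, G, Sigma_c, R) with pe = Sigma_c - G/2."""
        nb = len(self._basis)
        lmap = np.eye(4 * nb)
        lmap[2 * nb:3 * nb, nb:2 * nb] = -0.5 * np.eye(nb)
        return lmap

    def _vech_scale_vector(self) -> np.ndarray:
        t = self.t
        pairs = [(a, b) for a in range(t) for b in range(a, t)]
        s = np.array([self.scale[a] * self.scale[b] for a, b in pairs])
        return np.tile(s, 4)

    def _se_matrices(self, param_cov: np.ndarray) -> dict:
        t = self.t
        nb = len(self._basis)
        pairs = [(a, b) for a in range(t) for b in range(a, t)]
        out = {}
        sd = np.sqrt(np.clip(np.diag(param_cov), 0, None))
        for j, name in enumerate(COMPONENT_NAMES):
            m = np.zeros((t, t))
            for b, (a, c) in enumerate(pairs):
                m[a, c] = m[c, a] = sd[j * nb + b]
            out[name] = m
        return out


def reml_absorbed(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: PedigreeTable,
    start: Optional[dict] = None,
    **kwargs,
) -> REMLResult:
    return AbsorbedREML(records, spec, pedigree).fit(start=start, **kwargs)


# ---------------------------------------------------------------------------
# front end
# ---------------------------------------------------------------------------

def reml_estimate(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: PedigreeTable,
    start: Optional[CovarianceComponents] = None,
    engine: str = "auto",
    **kwargs,
) -> REMLResult:
    """Estimate (HTD, G, P, R) by REML for the 4-trait animal model.

    ``engine='absorbed'`` uses the scalable reduced representation (requires
    a design with non-parent recorded cows and founder parents),
    ``engine='full'`` the complete-MME EM engine; ``'auto'`` tries the
    absorbed engine first and falls back to the full one.
    """
    rec = filter_records(records, spec)
    startd = None
    if start is not None:
        startd = {
            "htd": start.htd, "genetic": start.genetic,
            "pe": start.pe, "residual": start.residual,
        }
    if engine in ("auto", "absorbed"):
        try:
            return reml_absorbed(rec, spec, pedigree, start=startd, **kwargs)
        except ValueError:
            if engine == "absorbed":
                raise
    design = build_design(rec, spec, pedigree)
    from .relationship import numerator_relationship_inverse

    ainv = numerator_relationship_inverse(pedigree).matrix
    full_kw = {k: v for k, v in kwargs.items()
               if k in ("max_iter", "tol", "check_monotone")}
    return reml_em_full(design, start=startd, ainv=ainv, **full_kw)


def reml_by_herd_subsets(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: PedigreeTable,
    n_subsets: int = 5,
    herd_fraction: float = 0.1,
    seed: int = 0,
    **kwargs,
):
    """Estimate components on disjoint random herd subsets and report the
    per-subset results (mirrors production practice of estimating on herd
    samples and averaging)."""
    rng = np.random.default_rng(seed)
    herds = records["herd"].unique()
    n_take = max(1, int(round(herd_fraction * len(herds))))
    perm = rng.permutation(herds)
    results = []
    for s in range(n_subsets):
        chosen = perm[s * n_take:(s + 1) * n_take]
        if len(chosen) == 0:
            break
        sub = records[records["herd"].isin(chosen)]
        results.append(reml_estimate(sub, spec, pedigree, **kwargs))
    return results
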
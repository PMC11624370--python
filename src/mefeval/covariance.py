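"""(Co)variance components of the 4-trait herd-test-day animal model.

The evaluation model for CH4_MIR, milk, fat and protein yield partitions each
trait's phenotypic variance into herd-test-day (HTD), additive genetic (G),
permanent environment (P) and residual (R) components, each a 4x4 matrix
across traits.  Heritability is defined here as

    h2_t = G_tt / (G_tt + HTD_tt + P_tt + R_tt),

i.e. the contemporary-group variance is part of the phenotypic denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRAITS = ("ch4", "my", "fy", "py")
N_TRAITS = len(TRAITS)


def _as_sym(m, name: str, n: int = N_TRAITS) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {a.shape}")
    if not np.allclose(a, a.T, rtol=0, atol=1e-8 * (1 + np.abs(a).max())):
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (a + a.T)


def is_psd(m: np.ndarray, tol: float = 1e-8) -> bool:
    w = np.linalg.eigvalsh(np.asarray(m, dtype=float))
    return bool(w.min() >= -tol * max(1.0, w.max()))


def nearest_psd(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    return (v * np.maximum(w, floor)) @ v.T


def cov_to_corr(m: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(m))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = m / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class CovarianceComponents:
    """The four 4x4 matrices of the multi-trait model: HTD, G, P, R."""

    htd: np.ndarray
    genetic: np.ndarray
    pe: np.ndarray
    residual: np.ndarray
    traits: tuple = field(default=TRAITS)

    def __post_init__(self):
        n = len(self.traits)
        self.htd = _as_sym(self.htd, "htd", n)
        self.genetic = _as_sym(self.genetic, "genetic", n)
        self.pe = _as_sym(self.pe, "pe", n)
        self.residual = _as_sym(self.residual, "residual", n)

    def validate_psd(self) -> None:
        for name in ("htd", "genetic", "pe", "residual"):
            if not is_psd(getattr(self, name)):
                raise ValueError(f"component matrix {name!r} is not PSD")

    @property
    def phenotypic(self) -> np.ndarray:
        return self.htd + self.genetic + self.pe + self.residual

    def heritability(self, include_htd: bool = True) -> np.ndarray:
        denom = np.diag(self.genetic + self.pe + self.residual).copy()
        if include_htd:
            denom += np.diag(self.htd)
        return np.diag(self.genetic) / denom

    def genetic_correlations(self) -> np.ndarray:
        return cov_to_corr(self.genetic)

    def phenotypic_correlations(self) -> np.ndarray:
        return cov_to_corr(self.phenotypic)

    def scaled(self, scale: np.ndarray) -> "CovarianceComponents":
        """Rescale traits: component matrices become D S D with D=diag(scale)."""
        d = np.asarray(scale, dtype=float)
        out = np.outer(d, d)
        return CovarianceComponents(
            self.htd * out, self.genetic * out, self.pe * out,
            self.residual * out, self.traits,
        )

    def copy(self) -> "CovarianceComponents":
        return CovarianceComponents(
            self.htd.copy(), self.genetic.copy(), self.pe.copy(),
            self.residual.copy(), self.traits,
        )

    def as_dict(self) -> dict:
        return {
            "htd": self.htd.tolist(),
            "genetic": self.genetic.tolist(),
            "pe": self.pe.tolist(),
            "residual": self.residual.tolist(),
            "traits": list(self.traits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovarianceComponents":
        return cls(
            np.array(d["htd"]), np.array(d["genetic"]), np.array(d["pe"]),
            np.array(d["residual"]), tuple(d.get("traits", TRAITS)),
        )


# Summary statistics typical of first-lactation Canadian Holstein test-day
# data (CH4_MIR g/d, MY kg/d, FY kg/d, PY kg/d): trait means, phenotypic SD,
# heritabilities and genetic / phenotypic correlations.
HOLSTEIN_MEANS = np.array([490.4, 33.3, 1.3, 1.1])
HOLSTEIN_PHENOTYPIC_SD = np.array([81.2, 5.0, 0.2, 0.2])
HOLSTEIN_HERITABILITY = np.array([0.23, 0.38, 0.27, 0.28])
HOLSTEIN_GENETIC_CORR = np.array(
    [
        [1.00, -0.13, 0.38, -0.11],
        [-0.13, 1.00, 0.48, 0.83],
        [0.38, 0.48, 1.00, 0.71],
        [-0.11, 0.83, 0.71, 1.00],
    ]
)
HOLSTEIN_PHENOTYPIC_CORR = np.array(
    [
        [1.00, -0.06, -0.18, 0.01],
        [-0.06, 1.00, 0.66, 0.90],
        [-0.18, 0.66, 1.00, 0.74],
        [0.01, 0.90, 0.74, 1.00],
    ]
)


def components_from_summary(
    phenotypic_sd=HOLSTEIN_PHENOTYPIC_SD,
    heritability=HOLSTEIN_HERITABILITY,
    genetic_corr=HOLSTEIN_GENETIC_CORR,
    phenotypic_corr=HOLSTEIN_PHENOTYPIC_CORR,
    htd_share: float = 0.15,
    pe_share: float = 0.15,
) -> CovarianceComponents:
    """Build truth (HTD, G, P, R) from summary statistics.

    Per-trait variances: G_tt = h2 * var_p, HTD_tt = htd_share * var_p,
    P_tt = pe_share * var_p, R_tt the remainder.  Off-diagonals: genetic
    covariances follow ``genetic_corr``; the remaining (phenotypic minus
    genetic) covariance is split across HTD, P and R assuming the three
    non-genetic components share one correlation matrix.  That shared
    correlation is solved for so the total phenotypic correlations equal
    ``phenotypic_corr`` exactly.
    """
    sd = np.asarray(phenotypic_sd, float)
    h2 = np.asarray(heritability, float)
    var_p = sd**2
    resid_share = 1.0 - h2 - htd_share - pe_share
    if np.any(resid_share <= 0):
        raise ValueError("htd/pe shares leave a non-positive residual share")

    g_sd = np.sqrt(h2 * var_p)
    gmat = np.asarray(genetic_corr, float) * np.outer(g_sd, g_sd)
    cov_p = np.asarray(phenotypic_corr, float) * np.outer(sd, sd)
    cov_ng = cov_p - gmat  # non-genetic covariance to distribute

    htd_v = htd_share * var_p
    pe_v = pe_share * var_p
    r_v = resid_share * var_p
    denom = (
        np.sqrt(np.outer(htd_v, htd_v))
        + np.sqrt(np.outer(pe_v, pe_v))
        + np.sqrt(np.outer(r_v, r_v))
    )
    ng_corr = cov_ng / denom
    np.fill_diagonal(ng_corr, 1.0)
    if np.abs(ng_corr).max() > 1.0:
        raise ValueError("implied non-genetic correlation exceeds 1 in magnitude")

    htd = ng_corr * np.sqrt(np.outer(htd_v, htd_v))
    pe = ng_corr * np.sqrt(np.outer(pe_v, pe_v))
    resid = ng_corr * np.sqrt(np.outer(r_v, r_v))
    np.fill_diagonal(htd, htd_v)
    np.fill_diagonal(pe, pe_v)
    np.fill_diagonal(resid, r_v)

    comps = CovarianceComponents(htd, gmat, pe, resid)
    comps.validate_psd()
    return comps


def holstein_defaults() -> CovarianceComponents:
    """Default truth components on the Holstein test-day scale."""
    return components_from_summary()
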
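"""End-to-end genomic/pedigree evaluation runs.

Convenience layer tying the pieces together: filter records, build the
design, construct A^-1 (pedigree BLUP) or H^-1 (single-step GBLUP), solve
the multi-trait MME and attach PEV reliabilities.  The single-step H^-1
uses VanRaden method-1 G tuned and blended to A22.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .covariance import CovarianceComponents
from .mixed_model import (
    Design, ModelSpec, SolutionSet, assemble_mme, blend_reliability,
    build_design, filter_records, pev_reliability, solve_mme,
)
from .pedigree import PedigreeTable
from .relationship import (
    SparseSymmetric, a22_block, genomic_relationship, h_inverse,
    inbreeding_coefficients, numerator_relationship_inverse,
)


@dataclass
class EvaluationResult:
    solutions: SolutionSet
    design: Design
    system: object
    method: str
    rel_inverse: SparseSymmetric
    inbreeding: np.ndarray

    def ebv_frame(self) -> pd.DataFrame:
        return self.solutions.effect_frame("animal")

    def ebv(self) -> np.ndarray:
        return self.solutions.effect("animal")

    def reliabilities(self, level_positions: Optional[np.ndarray] = None) -> np.ndarray:
        return pev_reliability(self.system, f=self.inbreeding,
                               level_positions=level_positions)


def run_evaluation(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: PedigreeTable,
    components: CovarianceComponents,
    method: str = "pedigree",
    genotypes: Optional[np.ndarray] = None,
    allele_freqs: Optional[np.ndarray] = None,
    blend_weight: float = 0.05,
    tune: bool = True,
    solver: str = "direct",
) -> EvaluationResult:
    """Solve the 4-trait animal model by pedigree BLUP or ssGBLUP.

    For ``method='ssgblup'``, ``genotypes`` holds one row per genotyped
    animal in the order of ``pedigree.genotyped_ids``.
    """
    rec = filter_records(records, spec)
    ped = pedigree.sorted()
    design = build_design(rec, spec, ped)
    f = inbreeding_coefficients(ped)
    a_inv = numerator_relationship_inverse(ped, f)

    if method == "pedigree":
        rel_inv = a_inv
    elif method == "ssgblup":
        gids = ped.genotyped_ids
        if genotypes is None or len(genotypes) != len(gids):
            raise ValueError("ssGBLUP needs genotypes for every genotyped animal")
        a22 = a22_block(ped, gids)
        g_star = genomic_relationship(
            genotypes, allele_freqs=allele_freqs, a22=a22,
            blend_weight=blend_weight, tune=tune,
        )
        rel_inv = h_inverse(a_inv, a22, g_star, gids)
    else:
        raise ValueError(f"unknown evaluation method {method!r}")

    system = assemble_mme(design, components, rel_inverse=rel_inv)
    solutions = solve_mme(system, method=solver)
    return EvaluationResult(
        solutions=solutions, design=design, system=system, method=method,
        rel_inverse=rel_inv, inbreeding=f,
    )


def blended_reliability_frame(
    ss_result: EvaluationResult,
    pedigree_result: EvaluationResult,
    genotyped_ids,
    weight: float = 0.8,
) -> pd.DataFrame:
    """Per-animal reliabilities: blended for genotyped animals, animal-model
    otherwise."""
    design = ss_result.design
    _, size, ids = design.blocks["animal"]
    am_rel = pedigree_result.reliabilities()
    ss_rel = ss_result.reliabilities()
    gmask = np.isin(ids, np.asarray(genotyped_ids))
    out = am_rel.copy()
    out[gmask] = blend_reliability(ss_rel[gmask], am_rel[gmask], weight)
    df = pd.DataFrame(out, columns=list(design.spec.traits))
    df.insert(0, "animal", ids)
    df["genotyped"] = gmask
    return df
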
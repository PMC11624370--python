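import numpy as np
import pandas as pd
import pytest

from mefeval.covariance import CovarianceComponents, holstein_defaults
from mefeval.mixed_model import (
    ModelSpec,
    assemble_mme,
    blend_reliability,
    build_design,
    filter_records,
    pev_reliability,
    solve_mme,
)
from mefeval.pedigree import PedigreeTable
from mefeval.relationship import numerator_relationship_inverse
from mefeval.simulate import SimConfig, simulate_population, simulate_reml_dataset


def _single_trait_records(y, animals, htd=None):
    n = len(y)
    return pd.DataFrame({
        "animal": animals,
        "herd": 0,
        "test_day": np.arange(n),
        "htd": htd if htd is not None else ["h0"] * n,
        "dim": 150,
        "age_calving": 24,
        "year_season": 0,
        "lactation": 1,
        "ch4": y,
    })


def _founder_pedigree(ids):
    return PedigreeTable(pd.DataFrame({
        "animal": ids, "sire": 0, "dam": 0, "birth_year": 2000,
        "sex": "F", "genotyped": False,
    }))


ONE = CovarianceComponents(np.eye(1), np.eye(1), np.eye(1), np.eye(1),
                           traits=("ch4",))


class TestBuildDesign:
    def test_single_record_single_fixed_level(self):
        rec = _single_trait_records([5.0], [1])
        ped = _founder_pedigree([1])
        d = build_design(rec, ModelSpec(traits=("ch4",)), ped,
                         random_effects=("animal",))
        off, size, _ = d.blocks["fixed"]
        assert size == 1
        assert d.w[0, off] == 1.0

    def test_htd_column_sums_to_group_size(self):
        rec = _single_trait_records(np.zeros(6), [1, 1, 2, 2, 3, 3],
                                    htd=["a"] * 4 + ["b"] * 2)
        ped = _founder_pedigree([1, 2, 3])
        d = build_design(rec, ModelSpec(traits=("ch4",)), ped)
        off, size, ids = d.blocks["htd"]
        col_sums = np.asarray(d.w.sum(axis=0)).ravel()
        assert col_sums[off] == 4 and col_sums[off + 1] == 2

    def test_level_counts_match_distinct_levels(self, truth):
        pop = simulate_reml_dataset(seed=3, n_sires=5, dams_per_sire=2,
                                    daughters_per_dam=2, n_herds=3)
        rec = filter_records(pop.records, ModelSpec())
        d = build_design(rec, ModelSpec(), pop.pedigree)
        assert d.blocks["htd"][1] == rec["htd"].nunique()
        assert d.blocks["animal"][1] == len(pop.pedigree)
        assert d.blocks["pe"][1] == rec["animal"].nunique()

    def test_unknown_animal_listed(self):
        rec = _single_trait_records([1.0], [99])
        ped = _founder_pedigree([1])
        with pytest.raises(ValueError, match="99"):
            build_design(rec, ModelSpec(traits=("ch4",)), ped)


class TestAssembleAndSolve:
    def test_two_equation_hand_solution(self):
        """One record y on one founder, single trait, unit variances:
        C = [[1, 1], [1, 2]], rhs = [y, y]  =>  (mu, a) = (y, 0)."""
        y = 3.7
        rec = _single_trait_records([y], [1])
        ped = _founder_pedigree([1])
        d = build_design(rec, ModelSpec(traits=("ch4",)), ped,
                         random_effects=("animal",))
        sys_ = assemble_mme(d, ONE)
        assert np.allclose(sys_.lhs.toarray(), [[1, 1], [1, 2]])
        sol = solve_mme(sys_)
        assert sol.theta[0, 0] == pytest.approx(y)
        assert sol.theta[1, 0] == pytest.approx(0.0)

    def test_lhs_exactly_symmetric(self, truth):
        pop = simulate_reml_dataset(seed=5, n_sires=4, dams_per_sire=2,
                                    daughters_per_dam=2, n_herds=2)
        rec = filter_records(pop.records, ModelSpec())
        d = build_design(rec, ModelSpec(), pop.pedigree)
        ainv = numerator_relationship_inverse(pop.pedigree)
        sys_ = assemble_mme(d, truth, rel_inverse=ainv)
        asym = abs(sys_.lhs - sys_.lhs.T)
        assert asym.nnz == 0 or asym.max() == 0.0

    def test_diagonal_pe_has_no_cross_trait_coupling(self, truth):
        comps = CovarianceComponents(truth.htd, truth.genetic,
                                     np.diag(np.diag(truth.pe)), truth.residual)
        pop = simulate_reml_dataset(seed=5, n_sires=3, dams_per_sire=1,
                                    daughters_per_dam=2, n_herds=2)
        rec = filter_records(pop.records, ModelSpec())
        d = build_design(rec, ModelSpec(), pop.pedigree)
        sys_ = assemble_mme(d, comps)
        off, size, _ = d.blocks["pe"]
        t = 4
        lhs = sys_.lhs.toarray()
        # prior contribution on the PE block is R^-1-coupled only through
        # the data part; subtracting it leaves a diagonal prior
        rinv = np.linalg.inv(comps.residual)
        for lp in range(size):
            sl = slice((off + lp) * t, (off + lp + 1) * t)
            prior = lhs[sl, sl] - 2 * rinv  # two records per cow
            assert np.allclose(prior - np.diag(np.diag(prior)), 0.0, atol=1e-10)

    def test_zero_rhs_zero_solution(self, truth):
        pop = simulate_reml_dataset(seed=2, n_sires=3, dams_per_sire=1,
                                    daughters_per_dam=2, n_herds=2)
        rec = filter_records(pop.records, ModelSpec())
        for tr in ("ch4", "my", "fy", "py"):
            rec[tr] = 0.0
        d = build_design(rec, ModelSpec(), pop.pedigree)
        sol = solve_mme(assemble_mme(d, truth))
        assert np.allclose(sol.theta, 0.0)

    def test_direct_and_cg_agree(self, truth):
        pop = simulate_reml_dataset(seed=9, n_sires=6, dams_per_sire=2,
                                    daughters_per_dam=2, n_herds=4)
        rec = filter_records(pop.records, ModelSpec())
        d = build_design(rec, ModelSpec(), pop.pedigree)
        ainv = numerator_relationship_inverse(pop.pedigree)
        sys_ = assemble_mme(d, truth, rel_inverse=ainv)
        a = solve_mme(sys_, method="direct")
        b = solve_mme(sys_, method="cg", tol=1e-12)
        assert np.abs(a.theta - b.theta).max() < 1e-6

    def test_solutions_invariant_to_record_order(self, truth):
        pop = simulate_reml_dataset(seed=4, n_sires=4, dams_per_sire=2,
                                    daughters_per_dam=2, n_herds=3)
        rec = filter_records(pop.records, ModelSpec())
        d1 = build_design(rec, ModelSpec(), pop.pedigree)
        rng = np.random.default_rng(0)
        shuffled = rec.sample(frac=1.0, random_state=7).reset_index(drop=True)
        d2 = build_design(shuffled, ModelSpec(), pop.pedigree)
        ainv = numerator_relationship_inverse(pop.pedigree)
        s1 = solve_mme(assemble_mme(d1, truth, rel_inverse=ainv))
        s2 = solve_mme(assemble_mme(d2, truth, rel_inverse=ainv))
        assert np.abs(s1.effect("animal") - s2.effect("animal")).max() < 1e-8

    def test_singular_component_named(self, truth):
        bad = CovarianceComponents(truth.htd * 0, truth.genetic, truth.pe,
                                   truth.residual)
        pop = simulate_reml_dataset(seed=2, n_sires=3, dams_per_sire=1,
                                    daughters_per_dam=2, n_herds=2)
        rec = filter_records(pop.records, ModelSpec())
        d = build_design(rec, ModelSpec(), pop.pedigree)
        with pytest.raises(ValueError, match="htd"):
            assemble_mme(d, bad)


class TestReliability:
    def _system(self, truth, n_daughters=4, r_scale=1.0, pe_scale=1.0,
                htd_scale=1.0, with_isolated=False):
        ped_rows = [(1, 0, 0, 2000, "M", False)]
        nid = 2
        dams = []
        for _ in range(n_daughters):
            ped_rows.append((nid, 0, 0, 2000, "F", False))
            dams.append(nid)
            nid += 1
        cows = []
        for d_ in dams:
            ped_rows.append((nid, 1, d_, 2005, "F", False))
            cows.append(nid)
            nid += 1
        if with_isolated:
            ped_rows.append((nid, 0, 0, 2000, "M", False))
        ped = PedigreeTable(pd.DataFrame(
            ped_rows, columns=["animal", "sire", "dam", "birth_year", "sex",
                               "genotyped"]))
        rng = np.random.default_rng(1)
        recs = []
        for c in cows:
            for r in range(2):
                recs.append((c, 0, r, f"0:{r}", 150 + r, 24, 0, 1,
                             *rng.standard_normal(4)))
        rec = pd.DataFrame(recs, columns=[
            "animal", "herd", "test_day", "htd", "dim", "age_calving",
            "year_season", "lactation", "ch4", "my", "fy", "py"])
        comps = CovarianceComponents(truth.htd * htd_scale, truth.genetic,
                                     truth.pe * pe_scale,
                                     truth.residual * r_scale)
        d = build_design(rec, ModelSpec(), ped)
        ainv = numerator_relationship_inverse(ped)
        return assemble_mme(d, comps, rel_inverse=ainv), ped

    def test_isolated_animal_reliability_zero(self, truth):
        sys_, ped = self._system(truth, with_isolated=True)
        rel = pev_reliability(sys_)
        # last animal: no records, no relatives -> PEV equals sigma2_a
        assert np.allclose(rel[-1], 0.0, atol=1e-8)

    def test_more_daughters_never_decrease_sire_reliability(self, truth):
        r_small = pev_reliability(self._system(truth, n_daughters=2)[0])[0]
        r_large = pev_reliability(self._system(truth, n_daughters=8)[0])[0]
        assert np.all(r_large >= r_small - 1e-9)

    def test_vanishing_noise_reliability_to_one(self, truth):
        # with the non-genetic variances vanishing and many unrelated
        # recorded cows (so the fixed mean costs almost nothing), records
        # pin down the breeding values
        n = 40
        ped = _founder_pedigree(np.arange(1, n + 1))
        rng = np.random.default_rng(2)
        rec = pd.concat([
            _single_trait_records(rng.standard_normal(n), np.arange(1, n + 1)),
            _single_trait_records(rng.standard_normal(n), np.arange(1, n + 1)),
        ], ignore_index=True)
        comps = CovarianceComponents(np.eye(1) * 1e-8, np.eye(1),
                                     np.eye(1) * 1e-8, np.eye(1) * 1e-8,
                                     traits=("ch4",))
        d = build_design(rec, ModelSpec(traits=("ch4",)), ped)
        rel = pev_reliability(assemble_mme(d, comps))
        assert rel.min() > 0.95

    def test_reliability_clipped_to_unit_interval(self, truth):
        rel = pev_reliability(self._system(truth)[0])
        assert rel.min() >= 0.0 and rel.max() <= 1.0


class TestBlendReliability:
    def test_printed_weighting(self):
        assert blend_reliability(0.9, 0.5) == pytest.approx(0.82)

    def test_equal_inputs_unchanged(self):
        assert blend_reliability(0.66, 0.66) == pytest.approx(0.66)

    def test_extremes(self):
        assert blend_reliability(1.0, 0.0) == pytest.approx(0.8)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            blend_reliability(1.2, 0.5)
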
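"""Mixed-model equations, BLUP solutions and REML variance components."""

import numpy as np
import pytest

import ssgblup as sg
from ssgblup.evaluation import SingularSystemError
from ssgblup.pedigree import build_A

from conftest import dense_reml_oracle, gls_solutions, random_pedigree


def sim_bundle(seed=2, **kw):
    cfg = dict(
        n_founders=60,
        families_per_generation=25,
        offspring_per_family=8,
        snps_per_chromosome=12,
        n_chromosomes=10,
        chromosome_length_morgan=1.0,
    )
    cfg.update(kw)
    sim = sg.simulate_population(sg.SimConfig(seed=seed, **cfg))
    return sim, sg.EvalData(sim.pedigree, sim.phenotypes, sim.genotypes, sim.marker_map)


class TestHeritability:
    @pytest.mark.parametrize(
        "comps,expected",
        [((1.0, 0.0, 3.0), 0.25), ((0.38, 0.12, 0.50), 0.38), ((0.0, 1.0, 1.0), 0.0)],
    )
    def test_quoted_ratio(self, comps, expected):
        vc = sg.VarianceComponents(*comps)
        assert sg.heritability(vc) == pytest.approx(expected)

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            sg.VarianceComponents(-0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            sg.VarianceComponents(0.1, 0.0, 0.0)


class TestAssembleAndSolve:
    def test_single_animal_matches_gls(self):
        # 1 founder, 1 record, mean-only X, lambda = 1 -> 2x2 system
        ped = sg.Pedigree.from_records([("1", "0", "0")])
        import pandas as pd

        tab = sg.PhenotypeTable(
            data=pd.DataFrame(
                {
                    "animal_id": ["1"],
                    "t": [3.0],
                    "hatch_year": ["y"],
                    "harvest_group": ["h"],
                    "family": ["f"],
                }
            )
        )
        spec = sg.build_model_spec(tab, ped, "t", use_common_env=False)
        vc = sg.VarianceComponents(1.0, 0.0, 1.0)
        system = sg.assemble_mme(spec, vc, sg.build_A_inverse(ped))
        np.testing.assert_allclose(system.C.toarray(), [[1, 1], [1, 2]])
        fit = sg.solve_mme(system)
        b, a, _ = gls_solutions(spec, vc, build_A(ped))
        assert fit.fixed_solutions.iloc[0] == pytest.approx(b[0])
        assert fit.ebv.iloc[0] == pytest.approx(a[0])

    def test_hand_eliminated_three_by_three(self):
        # two founders, one record each, mean + two animal effects, lambda = 2:
        #   [2 1 1][mu]   [y1+y2]
        #   [1 3 0][a1] = [y1  ]   (founder A^-1 = I, so diag 1 + 2)
        #   [1 0 3][a2]   [y2  ]
        import pandas as pd

        ped = sg.Pedigree.from_records([("1", "0", "0"), ("2", "0", "0")])
        tab = sg.PhenotypeTable(
            data=pd.DataFrame(
                {
                    "animal_id": ["1", "2"],
                    "t": [4.0, 6.0],
                    "hatch_year": ["y", "y"],
                    "harvest_group": ["h", "h"],
                    "family": ["f1", "f2"],
                }
            )
        )
        spec = sg.build_model_spec(tab, ped, "t", use_common_env=False)
        vc = sg.VarianceComponents(0.5, 0.0, 1.0)
        fit = sg.solve_mme(sg.assemble_mme(spec, vc, sg.build_A_inverse(ped)))
        expected = np.linalg.solve(
            np.array([[2.0, 1, 1], [1, 3, 0], [1, 0, 3]]), np.array([10.0, 4, 6])
        )
        assert fit.fixed_solutions.iloc[0] == pytest.approx(expected[0])
        np.testing.assert_allclose(fit.ebv.to_numpy(), expected[1:], atol=1e-10)

    def test_mme_equals_dense_V_gls(self):
        sim, data = sim_bundle(seed=3, n_founders=20, families_per_generation=8)
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        vc = sg.VarianceComponents(0.25, 0.10, 0.65)
        fit = sg.solve_mme(sg.assemble_mme(spec, vc, sg.build_A_inverse(data.pedigree)))
        b, a, c = gls_solutions(spec, vc, build_A(data.pedigree))
        np.testing.assert_allclose(fit.fixed_solutions.to_numpy(), b, atol=1e-8)
        np.testing.assert_allclose(fit.ebv.to_numpy(), a, atol=1e-8)
        np.testing.assert_allclose(
            fit.common_env_solutions.to_numpy(), c, atol=1e-8
        )

    def test_direct_and_cg_solvers_agree(self):
        sim, data = sim_bundle(seed=4)
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        vc = sg.VarianceComponents(0.25, 0.10, 0.65)
        system = sg.assemble_mme(spec, vc, sg.build_A_inverse(data.pedigree))
        direct = sg.solve_mme(system, method="direct")
        iterative = sg.solve_mme(system, method="cg")
        np.testing.assert_allclose(
            direct.ebv.to_numpy(), iterative.ebv.to_numpy(), atol=1e-6
        )
        assert direct.relative_residual < 1e-8

    def test_rank_deficient_design_constrained(self):
        # a single hatch-year level makes harvest-group dummies + intercept
        # collinear only if a group is empty; force duplicate column instead
        sim, data = sim_bundle(seed=5)
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        X_dup = np.hstack([spec.X, spec.X[:, -1:]])
        from ssgblup.evaluation import _drop_collinear_columns

        with pytest.warns(UserWarning, match="rank-deficient"):
            X_fixed, names = _drop_collinear_columns(
                X_dup, spec.x_names + ["dup"]
            )
        assert X_fixed.shape[1] == spec.X.shape[1]
        # estimable functions (fitted values) are invariant
        beta_full, *_ = np.linalg.lstsq(spec.X, spec.y, rcond=None)
        beta_fix, *_ = np.linalg.lstsq(X_fixed, spec.y, rcond=None)
        np.testing.assert_allclose(spec.X @ beta_full, X_fixed @ beta_fix, atol=1e-8)

    def test_sigma_a_zero_rejected(self):
        sim, data = sim_bundle(seed=6, n_founders=12, families_per_generation=5)
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        with pytest.raises(ValueError, match="sigma2_a"):
            sg.assemble_mme(
                spec,
                sg.VarianceComponents(0.0, 0.1, 0.9),
                sg.build_A_inverse(data.pedigree),
            )


class TestSingleStepIdentities:
    def test_pblup_equals_ssgblup_without_genotypes(self):
        sim, data = sim_bundle(seed=7)
        nogeno = sg.EvalData(data.pedigree, data.phenotypes, None, None)
        vc = sg.VarianceComponents(0.25, 0.10, 0.65)
        fit_p = sg.run_evaluation(nogeno, "fillet_yield", vc, model="pblup")
        fit_g = sg.run_evaluation(nogeno, "fillet_yield", vc, model="ssgblup")
        np.testing.assert_allclose(fit_p.ebv.to_numpy(), fit_g.ebv.to_numpy())

    def test_G_equal_A22_reproduces_pblup(self):
        sim, data = sim_bundle(seed=8)
        vc = sg.VarianceComponents(0.25, 0.10, 0.65)
        A22, A22i = sg.build_A22_and_inverse(data.pedigree, data.genotypes.animal_ids)
        H_inv = sg.build_H_inverse(
            sg.build_A_inverse(data.pedigree),
            A22i,
            np.linalg.inv(A22),
            data.pedigree.index_of(data.genotypes.animal_ids),
        )
        fit_h = sg.run_evaluation(
            data, "fillet_yield", vc, model="ssgblup", K_inv=H_inv
        )
        fit_p = sg.run_evaluation(data, "fillet_yield", vc, model="pblup")
        np.testing.assert_allclose(
            fit_h.ebv.to_numpy(), fit_p.ebv.to_numpy(), atol=1e-6
        )


class TestREML:
    def test_em_and_ai_match_dense_likelihood_oracle(self):
        sim, data = sim_bundle(
            seed=9, n_founders=30, families_per_generation=12, offspring_per_family=6
        )
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        A_inv = sg.build_A_inverse(data.pedigree)
        oracle = dense_reml_oracle(spec, build_A(data.pedigree))
        ai = sg.reml_estimate(spec, A_inv, method="ai", tol=1e-8)
        np.testing.assert_allclose(
            [ai.sigma2_a, ai.sigma2_c, ai.sigma2_e], oracle, rtol=1e-3
        )
        em = sg.reml_estimate(spec, A_inv, method="em", tol=1e-7, max_iter=5000)
        np.testing.assert_allclose(
            [em.sigma2_a, em.sigma2_c, em.sigma2_e], oracle, rtol=5e-3
        )

    def test_null_additive_variance_recovered(self):
        sim = sg.simulate_population(
            sg.SimConfig(
                seed=10,
                n_founders=200,
                n_generations=2,
                families_per_generation=100,
                offspring_per_family=10,
                n_chromosomes=5,
                snps_per_chromosome=10,
                chromosome_length_morgan=1.0,
                h2_per_trait=(0.0, 0.0),
                c2_per_trait=(0.15, 0.15),
                n_qtl_per_trait=0,
            )
        )
        data = sg.EvalData(sim.pedigree, sim.phenotypes, sim.genotypes, sim.marker_map)
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        vc = sg.reml_estimate(
            spec, sg.build_A_inverse(data.pedigree), method="ai", tol=1e-5
        )
        total = vc.sigma2_a + vc.sigma2_c + vc.sigma2_e
        assert vc.sigma2_a <= 0.05 * total

    def test_h2_recovery_within_tolerance(self, reml_recovery_n2000):
        sim, out = reml_recovery_n2000
        assert out["fillet_yield"].h2 == pytest.approx(0.25, abs=0.07)
        assert out["fillet_firmness"].h2 == pytest.approx(0.38, abs=0.07)

    def test_non_convergence_carries_trajectory(self):
        sim, data = sim_bundle(seed=11, n_founders=20, families_per_generation=8)
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, "fillet_yield")
        from ssgblup.evaluation import REMLError

        with pytest.raises(REMLError) as err:
            sg.reml_estimate(
                spec, sg.build_A_inverse(data.pedigree), method="em",
                max_iter=3, tol=1e-12,
            )
        assert len(err.value.trajectory) == 4
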
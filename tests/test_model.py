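"""Animal-model design matrices, REML estimation and mixed-model equations."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import optimize
from scipy.linalg import null_space

from kradom.model import (
    AdditiveDominanceModel,
    ModelSpec,
    VarianceComponents,
    build_design_matrices,
    fit_report,
    genetic_parameters,
    reml_estimate,
    restricted_loglik,
    solve_mme,
)
from kradom.pedigree import (
    Pedigree,
    PedigreeRecord,
    additive_relationship_matrix,
    dominance_relationship_matrix,
)


def _pheno(animals, y, sex=None, hatch=None, age=6):
    n = len(animals)
    return pd.DataFrame(
        {
            "animal": animals,
            "age_wk": age,
            "bw_g": y,
            "sex": sex if sex is not None else ["M"] * n,
            "hatch": hatch if hatch is not None else ["H1"] * n,
        }
    )


@pytest.fixture(scope="module")
def family_fit_inputs(family_dataset):
    ped = family_dataset.pedigree
    A = additive_relationship_matrix(ped)
    D = dominance_relationship_matrix(ped, A)
    dm = build_design_matrices(family_dataset.phenotypes, ped, ModelSpec(age=6))
    return ped, A, D, dm


class TestDesignMatrices:
    def test_shapes_and_incidence(self):
        ped = Pedigree([PedigreeRecord(f"a{i}") for i in range(10)])
        pheno = _pheno([f"a{i}" for i in range(10)], np.arange(10.0),
                       sex=["M", "F"] * 5)
        dm = build_design_matrices(pheno, ped, ModelSpec(age=6))
        assert dm.X.shape == (10, 2)  # intercept + one sex column
        assert dm.x_names == ("intercept", "sex[F]")
        assert np.all(dm.Z.sum(axis=1) == 1.0)

    def test_recordless_animals_get_zero_columns(self):
        ped = Pedigree([PedigreeRecord(f"a{i}") for i in range(12)])
        pheno = _pheno([f"a{i}" for i in range(8)], np.arange(8.0))
        dm = build_design_matrices(pheno, ped, ModelSpec(age=6))
        assert dm.Z.shape == (8, 12)
        assert int((dm.Z.sum(axis=0) == 0).sum()) == 4

    def test_confounded_factors_rejected(self):
        ped = Pedigree([PedigreeRecord(f"a{i}") for i in range(8)])
        # each hatch single-sex: sex is a linear function of hatch dummies
        pheno = _pheno([f"a{i}" for i in range(8)], np.arange(8.0),
                       sex=["M"] * 4 + ["F"] * 4,
                       hatch=["H1"] * 4 + ["H2"] * 4)
        with pytest.raises(ValueError, match="confounded"):
            build_design_matrices(pheno, ped, ModelSpec(age=6))

    def test_unknown_animal_rejected(self):
        ped = Pedigree([PedigreeRecord("a")])
        with pytest.raises(ValueError, match="absent"):
            build_design_matrices(_pheno(["b"], [1.0]), ped, ModelSpec(age=6))


class TestRestrictedLoglik:
    def test_matches_error_contrast_formula(self, family_fit_inputs):
        """Differences of the restricted log-likelihood equal those of an
        independent evaluation on an orthonormal error-contrast basis."""
        ped, A, D, dm = family_fit_inputs
        K = null_space(dm.X.T)
        z = K.T @ dm.y

        def ll_contrast(theta):
            V = theta[0] * A.values + theta[1] * D.values + theta[2] * np.eye(len(ped))
            M = K.T @ V @ K
            _, ld = np.linalg.slogdet(M)
            return -0.5 * (len(z) * np.log(2 * np.pi) + ld
                           + z @ np.linalg.solve(M, z))

        thetas = [(100, 40, 60), (50, 10, 120), (200, 1, 30)]
        ours = [restricted_loglik(t, dm, A, D) for t in thetas]
        oracle = [ll_contrast(t) for t in thetas]
        for i in range(1, len(thetas)):
            assert ours[i] - ours[0] == pytest.approx(oracle[i] - oracle[0], abs=1e-7)


class TestREML:
    def test_reduces_to_independent_additive_fit(self, family_fit_inputs):
        """With the dominance component pinned at zero the fit must match a
        purely additive animal model optimized by an independent method."""
        ped, A, D, dm = family_fit_inputs
        vc = reml_estimate(dm, A, D, fix_zero=("sigma2_d",))
        assert vc.sigma2_d == 0.0

        K = null_space(dm.X.T)
        z = K.T @ dm.y

        def neg_ll(log_theta):
            sa, se = np.exp(log_theta)
            M = K.T @ (sa * A.values + se * np.eye(len(ped))) @ K
            _, ld = np.linalg.slogdet(M)
            return 0.5 * (ld + z @ np.linalg.solve(M, z))

        opt = optimize.minimize(neg_ll, np.log([50.0, 50.0]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        sa_o, se_o = np.exp(opt.x)
        assert vc.sigma2_a == pytest.approx(sa_o, rel=1e-4)
        assert vc.sigma2_e == pytest.approx(se_o, rel=1e-4)

        # BLUPs agree with the closed-form GLS predictor of the additive model
        sol = solve_mme(dm, A, D, vc)
        V = vc.sigma2_a * A.values + vc.sigma2_e * np.eye(len(ped))
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(dm.X.T @ Vinv @ dm.X, dm.X.T @ Vinv @ dm.y)
        a_oracle = vc.sigma2_a * A.values @ Vinv @ (dm.y - dm.X @ beta)
        assert np.allclose(sol.a_hat, a_oracle, atol=1e-6)
        assert np.allclose(sol.d_hat, 0.0)

    def test_scale_equivariance(self, family_fit_inputs):
        ped, A, D, dm = family_fit_inputs
        vc1 = reml_estimate(dm, A, D)
        dm_scaled = replace(dm, y=10.0 * dm.y)
        vc2 = reml_estimate(dm_scaled, A, D)
        for f in ("sigma2_a", "sigma2_d", "sigma2_e"):
            assert getattr(vc2, f) == pytest.approx(100.0 * getattr(vc1, f),
                                                    rel=1e-6, abs=1e-8)
        if vc1.sigma2_p > 0:
            assert vc2.h2 == pytest.approx(vc1.h2, rel=1e-6)
            assert vc2.d_ratio == pytest.approx(vc1.d_ratio, rel=1e-6, abs=1e-9)

    def test_noise_only_pins_genetic_components_at_zero(self, family_fit_inputs):
        """i.i.d. phenotypes with no pedigree signal drive both genetic
        variances to the boundary and heritability to zero."""
        ped, A, D, dm = family_fit_inputs
        rng = np.random.default_rng(7)
        dm_noise = replace(dm, y=rng.normal(0.0, 1.0, dm.n_records))
        vc = reml_estimate(dm_noise, A, D)
        assert vc.sigma2_a == 0.0
        assert vc.sigma2_d == 0.0
        assert vc.h2 == 0.0
        assert vc.sigma2_e > 0

    def test_likelihood_ascent(self, family_fit_inputs):
        ped, A, D, dm = family_fit_inputs
        vc = reml_estimate(dm, A, D)
        assert np.all(np.diff(vc.loglik_trace) >= -1e-10)

    def test_nonconvergence_reported_not_raised(self, family_fit_inputs):
        ped, A, D, dm = family_fit_inputs
        vc = reml_estimate(dm, A, D, max_iter=2)
        assert vc.converged is False
        assert vc.n_iter == 2


class TestSolveMME:
    def test_zero_dominance_variance_gives_zero_blups(self, family_fit_inputs):
        ped, A, D, dm = family_fit_inputs
        vc = _vc(100.0, 0.0, 60.0)
        sol = solve_mme(dm, A, D, vc)
        assert np.array_equal(sol.d_hat, np.zeros(len(ped)))
        assert sol.solution_residual_norm < 1e-8

    def test_tiny_variances_recover_ols_fixed_effects(self, family_fit_inputs):
        """Vanishing genetic variances shrink the BLUPs to zero, so the
        fixed-effect solution approaches the plain OLS fit."""
        ped, A, D, dm = family_fit_inputs
        sol = solve_mme(dm, A, D, _vc(1e-8, 1e-8, 1.0))
        beta_ols = np.linalg.lstsq(dm.X, dm.y, rcond=None)[0]
        assert np.allclose(sol.beta_hat, beta_ols, atol=1e-5)

    def test_self_consistency_residual(self, family_fit_inputs):
        ped, A, D, dm = family_fit_inputs
        vc = reml_estimate(dm, A, D)
        if vc.sigma2_e == 0:
            vc = replace(vc, sigma2_e=1.0)
        sol = solve_mme(dm, A, D, vc)
        assert sol.solution_residual_norm < 1e-8

    def test_requires_positive_residual_variance(self, family_fit_inputs):
        ped, A, D, dm = family_fit_inputs
        with pytest.raises(ValueError, match="residual"):
            solve_mme(dm, A, D, _vc(1.0, 1.0, 0.0))


def _vc(sa, sd, se):
    return VarianceComponents(sa, sd, se, 0, 0, 0, 0, 0.0, True, 1, (0.0,))


class TestGeneticParameters:
    def test_week4_heritability_rounds_to_084(self):
        gp = genetic_parameters(3721.66, 0.00, 702.17).round(2)
        assert gp.h2 == 0.84
        assert gp.d_ratio == 0.0

    def test_week6_total_variance_and_dominance_ratio(self):
        gp = genetic_parameters(14250.04, 3314.70, 712.57)
        assert gp.sigma2_p == pytest.approx(18277.31, abs=1e-9)
        assert gp.round(2).d_ratio == 0.18

    def test_equal_components_symmetric_thirds(self):
        gp = genetic_parameters(5.0, 5.0, 5.0)
        assert gp.h2 == pytest.approx(1 / 3)
        assert gp.d_ratio == pytest.approx(1 / 3)

    def test_zero_total_variance_is_missing(self):
        gp = genetic_parameters(0.0, 0.0, 0.0)
        assert np.isnan(gp.h2) and np.isnan(gp.d_ratio)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            genetic_parameters(-1.0, 0.0, 1.0)


class TestModelResultsAPI:
    def test_fit_summary_and_blups(self, family_dataset):
        model = AdditiveDominanceModel.from_tables(
            family_dataset.phenotypes, family_dataset.pedigree, age=6
        )
        res = model.fit()
        assert list(res.params.index) == ["sigma2_a", "sigma2_d", "sigma2_e"]
        assert len(res.a_hat) == len(family_dataset.pedigree)
        assert res.beta.index[0] == "intercept"
        text = res.summary()
        assert "sigma2_a" in text and "h2" in text
        report = fit_report({6: res.vc})
        assert report.shape == (7, 1)
        assert report.loc["sigma2_p", 6] == pytest.approx(
            round(res.vc.sigma2_p, 2), abs=0.011
        )
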
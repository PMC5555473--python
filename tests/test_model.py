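"""Single-step regression engine: oracles, invariances, Gibbs agreement."""

import dataclasses

import numpy as np
import pytest

from ssgp.model import (
    ModelSpec,
    SingularModelError,
    apply_centering,
    build_design,
    compute_gebv,
    compute_J_covariate,
    fit_single_step,
    gibbs_bayesc0,
    impute_marker_covariates,
    solve_mme,
)
from ssgp.pedigree import RelationshipOperator, build_A_tabular
from ssgp.simulation import StudyDataset


def shifted_design(design, v):
    """Recode genotype covariates by a constant shift v (per locus).

    Observed rows move by -v; imputed rows move by +Jn v, the image of the
    shift under best-linear-prediction imputation.
    """
    M = design.M.copy()
    geno = design.geno_mask
    M[geno] -= v
    M[~geno] += np.outer(design.J[~geno], v)
    return dataclasses.replace(design, M=M)


def all_genotyped_copy(dataset: StudyDataset) -> StudyDataset:
    return dataclasses.replace(dataset, genotyped=np.ones(dataset.pedigree.n, bool))


class TestJCovariate:
    def test_all_genotyped_is_minus_ones(self, six_id_pedigree):
        op = RelationshipOperator(six_id_pedigree, six_id_pedigree.ids)
        Jg, Jn = compute_J_covariate(op)
        np.testing.assert_array_equal(Jg, -1.0)
        assert Jn.size == 0

    def test_fully_determined_entry_is_minus_one(self, founder_pair_offspring):
        op = RelationshipOperator(founder_pair_offspring, ["S", "D"])
        _, Jn = compute_J_covariate(op)
        np.testing.assert_allclose(Jn, [-1.0])

    def test_matches_dense_block_oracle(self, six_id_pedigree):
        gids = [1, 2, 4, 6]
        op = RelationshipOperator(six_id_pedigree, gids)
        _, Jn = compute_J_covariate(op)
        A = build_A_tabular(six_id_pedigree)
        g = six_id_pedigree.positions(gids)
        n = np.setdiff1d(np.arange(6), g)
        dense = A[np.ix_(n, g)] @ np.linalg.solve(A[np.ix_(g, g)], -np.ones(g.size))
        np.testing.assert_allclose(Jn, dense, atol=1e-8)


class TestImputation:
    def test_midparent(self, founder_pair_offspring):
        op = RelationshipOperator(founder_pair_offspring, ["S", "D"])
        Mg = np.array([[2.0, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(
            impute_marker_covariates(op, Mg), [[1.0, 0.0]]
        )

    def test_constant_column_scales_like_minus_J(self, six_id_pedigree):
        op = RelationshipOperator(six_id_pedigree, [1, 2, 4])
        _, Jn = compute_J_covariate(op)
        c = 1.7
        Mhat = impute_marker_covariates(op, np.full((3, 1), c))
        np.testing.assert_allclose(Mhat[:, 0], c * (-Jn), atol=1e-10)

    def test_matches_dense_block_oracle(self, six_id_pedigree):
        rng = np.random.default_rng(0)
        gids = [1, 3, 5]
        Mg = rng.integers(0, 3, size=(3, 4)).astype(float)
        op = RelationshipOperator(six_id_pedigree, gids)
        A = build_A_tabular(six_id_pedigree)
        g = six_id_pedigree.positions(gids)
        n = np.setdiff1d(np.arange(6), g)
        dense = A[np.ix_(n, g)] @ np.linalg.solve(A[np.ix_(g, g)], Mg)
        np.testing.assert_allclose(impute_marker_covariates(op, Mg), dense, atol=1e-8)


class TestCentering:
    def test_mean_one_column_becomes_symmetric(self, six_id_pedigree):
        op = RelationshipOperator(six_id_pedigree, [1, 2, 4])
        Mg = np.array([[0.0], [1.0], [2.0]])
        Mg_c, _, v = apply_centering(Mg, op, "observed_only")
        np.testing.assert_allclose(Mg_c[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(v, [1.0])

    def test_none_is_identity(self, six_id_pedigree):
        op = RelationshipOperator(six_id_pedigree, [1, 2, 4])
        Mg = np.array([[0.0], [1.0], [2.0]])
        Mg_c, Mn_c, v = apply_centering(Mg, op, "none")
        np.testing.assert_array_equal(Mg_c, Mg)
        np.testing.assert_allclose(v, 0.0)

    def test_whole_matrix_columns_sum_to_zero(self, six_id_pedigree):
        op = RelationshipOperator(six_id_pedigree, [1, 2, 4])
        rng = np.random.default_rng(1)
        Mg = rng.integers(0, 3, size=(3, 5)).astype(float)
        Mg_c, Mn_c, _ = apply_centering(Mg, op, "all_covariates")
        total = np.vstack([Mg_c, Mn_c])
        np.testing.assert_allclose(total.sum(axis=0), 0.0, atol=1e-10)

    def test_observed_only_imputes_from_centered(self, six_id_pedigree):
        # imputing the explicitly centered Mg must equal the linearity shortcut
        op = RelationshipOperator(six_id_pedigree, [1, 2, 4])
        rng = np.random.default_rng(2)
        Mg = rng.integers(0, 3, size=(3, 4)).astype(float)
        _, Mn_c, v = apply_centering(Mg, op, "observed_only")
        direct = impute_marker_covariates(op, Mg - v)
        np.testing.assert_allclose(Mn_c, direct, atol=1e-10)


class TestSolveMme:
    def test_tiny_system_matches_dense_oracle(self):
        # 1 marker; genotyped parents S, D; their nongenotyped child X; an
        # unrelated nongenotyped founder E (J_E = 0 keeps mu_g identifiable).
        # Unknowns (mu, mu_g, alpha, eps_X, eps_E): hand-built 5x5 system.
        from ssgp.pedigree import Pedigree

        ped = Pedigree(
            ids=np.array(["S", "D", "X", "E"]),
            sire=np.array([-1, -1, 0, -1]),
            dam=np.array([-1, -1, 1, -1]),
            generation=np.array([0, 0, 1, 0]),
            sex=np.array(["M", "F", "F", "M"]),
        )
        y = np.array([1.0, 3.0, 2.5, 0.5])
        genotyped = np.array([True, True, False, False])
        op = RelationshipOperator(ped, ["S", "D"])
        Mg = np.array([[2.0], [0.0]])
        Mn = impute_marker_covariates(op, Mg)
        Jg, Jn = compute_J_covariate(op)
        s2g, s2e, s2a = 1.0, 1.0, 0.5
        import ssgp.model as mdl

        design = mdl.DesignSystem(
            y=y,
            train_idx=np.arange(4),
            J=np.array([Jg[0], Jg[1], Jn[0], Jn[1]]),
            M=np.vstack([Mg, Mn]),
            geno_mask=genotyped,
            eps_index=np.array([-1, -1, 0, 1]),
            A_inv_nn=op.A_inv_nn,
            sigma2_g=s2g,
            sigma2_e=s2e,
            sigma2_alpha=s2a,
            centering_vector=np.zeros(1),
            panel="qtl_plus_markers",
            operator=op,
        )
        spec = ModelSpec(fit_J=True)
        fit = solve_mme(design, spec)
        # dense oracle: W = [1, J, M, U], penalty diag(0, 0, lam_a, lam_g*Ann)
        W = np.zeros((4, 5))
        W[:, 0] = 1.0
        W[:, 1] = design.J
        W[:, 2] = design.M[:, 0]
        W[2, 3] = 1.0
        W[3, 4] = 1.0
        pen = np.zeros((5, 5))
        pen[2, 2] = s2e / s2a
        pen[3:, 3:] = (s2e / s2g) * op.A_inv_nn.toarray()
        sol = np.linalg.solve(W.T @ W + pen, W.T @ y)
        assert fit.mu_hat == pytest.approx(sol[0], abs=1e-8)
        assert fit.mu_g_hat == pytest.approx(sol[1], abs=1e-8)
        assert fit.alpha_hat[0] == pytest.approx(sol[2], abs=1e-8)
        np.testing.assert_allclose(fit.epsilon_hat, sol[3:], atol=1e-8)

    def test_residuals_orthogonal_to_unpenalized_columns(self, tiny_dataset):
        spec = ModelSpec.from_variant("J")
        design = build_design(tiny_dataset, spec)
        fit = solve_mme(design, spec)
        rows = design.train_idx
        eps = np.zeros(rows.size)
        has = design.eps_index[rows] >= 0
        eps[has] = fit.epsilon_hat[design.eps_index[rows][has]]
        fitted = (
            fit.mu_hat
            + design.J[rows] * fit.mu_g_hat
            + design.M[rows] @ fit.alpha_hat
            + eps
        )
        resid = design.y - fitted
        assert abs(resid.sum()) < 1e-6  # intercept normal equation
        assert abs(design.J[rows] @ resid) < 1e-6  # J normal equation

    def test_empty_phenotypes_give_prior_means(self, tiny_dataset):
        ds = dataclasses.replace(
            tiny_dataset, phenotype=np.full(tiny_dataset.pedigree.n, np.nan)
        )
        spec = ModelSpec.from_variant("J")
        fit = solve_mme(build_design(ds, spec), spec)
        np.testing.assert_array_equal(fit.alpha_hat, 0.0)
        np.testing.assert_array_equal(fit.epsilon_hat, 0.0)

    def test_all_genotyped_with_J_is_singular(self, tiny_dataset):
        ds = all_genotyped_copy(tiny_dataset)
        spec = ModelSpec.from_variant("J")
        with pytest.raises(SingularModelError, match="collinear"):
            solve_mme(build_design(ds, spec), spec)

    def test_all_genotyped_reduces_to_ridge(self, tiny_dataset):
        # no-J model with everyone genotyped == standalone ridge regression
        ds = all_genotyped_copy(tiny_dataset)
        spec = ModelSpec.from_variant("N")
        design = build_design(ds, spec)
        fit = solve_mme(design, spec)
        rows = design.train_idx
        X = np.hstack([np.ones((rows.size, 1)), design.M[rows]])
        pen = np.eye(X.shape[1]) * (design.sigma2_e / design.sigma2_alpha)
        pen[0, 0] = 0.0
        sol = np.linalg.solve(X.T @ X + pen, X.T @ design.y)
        np.testing.assert_allclose(fit.alpha_hat, sol[1:], atol=1e-8)
        np.testing.assert_allclose(fit.gebv, design.M @ sol[1:], atol=1e-6)


class TestCodingInvariance:
    def test_alpha_and_accuracy_invariant_under_recoding(self, tiny_dataset):
        spec = ModelSpec.from_variant("J")
        design = build_design(tiny_dataset, spec)
        fit = solve_mme(design, spec)
        rng = np.random.default_rng(4)
        v = rng.normal(scale=0.7, size=design.n_markers)
        fit2 = solve_mme(shifted_design(design, v), spec)
        np.testing.assert_allclose(fit2.alpha_hat, fit.alpha_hat, atol=1e-6)
        val = tiny_dataset.validation_mask
        tbv = tiny_dataset.tbv[val]
        c1 = np.corrcoef(tbv, fit.gebv[val])[0, 1]
        c2 = np.corrcoef(tbv, fit2.gebv[val])[0, 1]
        assert c1 == pytest.approx(c2, abs=1e-9)

    def test_mu_g_star_reparameterization(self, tiny_dataset):
        # centering observed covariates by their means shifts mu_g by -v'alpha
        spec_u = ModelSpec.from_variant("J")
        spec_c = ModelSpec.from_variant("JCstar")
        design_u = build_design(tiny_dataset, spec_u)
        design_c = build_design(tiny_dataset, spec_c)
        fit_u = solve_mme(design_u, spec_u)
        fit_c = solve_mme(design_c, spec_c)
        v = design_c.centering_vector
        np.testing.assert_allclose(fit_c.alpha_hat, fit_u.alpha_hat, atol=1e-6)
        assert fit_c.mu_g_hat == pytest.approx(
            fit_u.mu_g_hat - float(v @ fit_u.alpha_hat), abs=1e-6
        )


class TestGibbs:
    def test_agrees_with_mme_within_monte_carlo_error(self, tiny_dataset):
        spec = ModelSpec.from_variant("J", chain_length=4000, burn_in=1000, seed=5)
        design = build_design(tiny_dataset, spec)
        mme = solve_mme(design, spec)
        gib = gibbs_bayesc0(design, spec)
        assert abs(gib.mu_g_hat - mme.mu_g_hat) < 3 * max(gib.mcse["mu_g"], 1e-3)
        z = np.abs(gib.alpha_hat - mme.alpha_hat) / np.maximum(
            gib.mcse["alpha"], 1e-4
        )
        assert np.median(z) < 3
        assert z.max() < 6
        assert np.corrcoef(mme.gebv, gib.gebv)[0, 1] > 0.999

    def test_two_chains_agree(self, tiny_dataset):
        design = build_design(tiny_dataset, ModelSpec.from_variant("J"))
        fits = [
            gibbs_bayesc0(
                design,
                ModelSpec.from_variant("J", chain_length=6000, burn_in=1000, seed=s),
            )
            for s in (1, 2)
        ]
        assert np.corrcoef(fits[0].gebv, fits[1].gebv)[0, 1] > 0.999

    def test_vanishing_prior_variance_shrinks_alpha_to_zero(self, tiny_dataset):
        spec = ModelSpec.from_variant("J", chain_length=400, burn_in=100, seed=0)
        design = build_design(tiny_dataset, spec)
        design = dataclasses.replace(design, sigma2_alpha=1e-10)
        fit = gibbs_bayesc0(design, spec)
        assert np.abs(fit.alpha_hat).max() < 1e-3

    def test_chain_shorter_than_burnin_rejected(self, tiny_dataset):
        spec = ModelSpec.from_variant("J", chain_length=10, burn_in=10)
        design = build_design(tiny_dataset, spec)
        with pytest.raises(ValueError, match="burn_in"):
            gibbs_bayesc0(design, spec)


class TestGebv:
    def test_pure_mean_fit_gives_scaled_J(self, tiny_dataset):
        from ssgp.model import ModelFit

        design = build_design(tiny_dataset, ModelSpec.from_variant("J"))
        fit = ModelFit(
            mu_hat=0.0,
            mu_g_hat=2.5,
            alpha_hat=np.zeros(design.n_markers),
            epsilon_hat=np.zeros(design.n_eps),
            gebv=np.zeros(design.J.size),
            method="mme",
        )
        np.testing.assert_allclose(compute_gebv(fit, design), 2.5 * design.J)

    def test_whole_matrix_centering_shifts_gebv_by_constant(self, tiny_dataset):
        fit_j = fit_single_step(tiny_dataset, "J")
        fit_jc = fit_single_step(tiny_dataset, "JC")
        d = fit_jc.gebv - fit_j.gebv
        np.testing.assert_allclose(d, d[0], atol=1e-7)

    def test_validation_animals_have_no_epsilon_term(self, tiny_dataset):
        spec = ModelSpec.from_variant("J")
        design = build_design(tiny_dataset, spec)
        fit = solve_mme(design, spec)
        parts = fit.components(design)
        val = tiny_dataset.validation_mask  # G-final animals are genotyped
        np.testing.assert_array_equal(parts["epsilon_term"][val], 0.0)


class TestModelSpec:
    def test_variant_table(self):
        assert ModelSpec.from_variant("JC").fit_J is True
        assert ModelSpec.from_variant("JC").centering == "all_covariates"
        assert ModelSpec.from_variant("N").fit_J is False
        assert ModelSpec.from_variant("Cstar").centering == "observed_only"
        with pytest.raises(ValueError, match="variant"):
            ModelSpec.from_variant("Z")

    def test_nonzero_pi_rejected(self):
        with pytest.raises(NotImplementedError):
            ModelSpec(pi=0.5)
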
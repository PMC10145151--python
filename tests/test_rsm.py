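"""Response-surface fitting, transforms, diagnostics, and model selection."""

import numpy as np
import pytest

from chromodr import (
    QuadraticSurfaceRegressor,
    apply_transform,
    backward_eliminate,
    fit_rsm,
    full_quadratic_terms,
    inverse_transform,
    suggest_transform,
)
from chromodr.rsm import RankDeficiencyError, canonical_terms, term_matrix
from chromodr.reference import PUBLISHED_MODELS, printed_atol, printed_value


class TestTransforms:
    @pytest.mark.parametrize(
        "y, kind, expected",
        [
            (7.6, "log10", 0.8808),
            (3.87, "reciprocal", 0.2584),
            (5.0, "identity", 5.0),
        ],
    )
    def test_examples(self, y, kind, expected):
        assert apply_transform(y, kind) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("kind", ["identity", "reciprocal", "log10"])
    def test_inverse_round_trip(self, kind, rng):
        y = rng.uniform(0.1, 30.0, size=50)
        np.testing.assert_allclose(
            inverse_transform(apply_transform(y, kind), kind), y, atol=1e-12
        )

    @pytest.mark.parametrize("kind", ["reciprocal", "log10"])
    def test_nonpositive_rejected(self, kind):
        with pytest.raises(ValueError, match="positive"):
            apply_transform(np.array([1.0, -0.5]), kind)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="unknown transform"):
            apply_transform(1.0, "sqrt")


class TestFit:
    def test_noise_free_recovery(self, canonical_design, rng):
        """Exact polynomial data is recovered to numerical precision."""
        terms = ("1", "x1", "x2", "x3", "x1:x2", "x2^2")
        truth = rng.normal(size=len(terms))
        y = term_matrix(canonical_design.coded, terms) @ truth
        model = fit_rsm(canonical_design, y, terms=terms)
        np.testing.assert_allclose(model.coef_, truth, atol=1e-9)

    def test_normal_equations_oracle_on_small_systems(self, rng):
        """OLS agrees with an independent normal-equations solve on 5-run toys."""
        for _ in range(10):
            X = rng.uniform(-1, 1, size=(5, 3))
            y = rng.normal(size=5)
            terms = ("1", "x1", "x2", "x3")
            M = term_matrix(X, terms)
            brute = np.linalg.solve(M.T @ M, M.T @ y)
            model = fit_rsm(X, y, terms=terms)
            np.testing.assert_allclose(model.coef_, brute, atol=1e-10)

    def test_reproduces_published_k_last_coefficients(self, study_design, study_responses):
        pub = PUBLISHED_MODELS["k_last"]
        model = fit_rsm(
            study_design,
            study_responses["k_last"].to_numpy(),
            terms=list(pub["coefficients"]),
            transform="identity",
        )
        for term, printed in pub["coefficients"].items():
            i = model.terms_.index(term)
            assert model.coef_[i] == pytest.approx(
                printed_value(printed), abs=printed_atol(printed)
            ), term

    def test_reproduces_published_reciprocal_flow_coefficient(
        self, study_design, study_responses
    ):
        pub = PUBLISHED_MODELS["t_end_peak1"]
        model = fit_rsm(
            study_design,
            study_responses["t_end_peak1"].to_numpy(),
            terms=list(pub["coefficients"]),
            transform="reciprocal",
        )
        i = model.terms_.index("x1")
        assert model.coef_[i] == pytest.approx(0.041, abs=5e-4)

    def test_rank_deficiency_reported(self):
        X = np.zeros((8, 3))
        X[:, 0] = np.repeat([-1.0, 1.0], 4)  # x2, x3 constant -> collinear with intercept
        with pytest.raises(RankDeficiencyError, match="rank deficient"):
            fit_rsm(X, np.arange(8.0), terms=("1", "x1", "x2"))

    def test_too_few_runs_rejected(self, rng):
        X = rng.uniform(-1, 1, size=(3, 3))
        with pytest.raises(ValueError, match="at least"):
            fit_rsm(X, rng.normal(size=3), terms=("1", "x1", "x2", "x3"))

    def test_serialization_round_trip(self, study_models):
        for name, model in study_models.items():
            back = QuadraticSurfaceRegressor.from_dict(model.to_dict())
            np.testing.assert_allclose(back.coef_, model.coef_)
            np.testing.assert_allclose(back.cov_, model.cov_)
            assert back.transform == model.transform
            x = np.array([[0.3, -0.2, 0.8]])
            assert back.predict(x) == pytest.approx(model.predict(x))

    def test_coefficient_sampling_distribution(self, canonical_design, rng):
        """±3·(estimated SE) covers the truth at the t-distribution rate.

        With 12 residual df the exact coverage of a ±3-standardized-error
        interval is 1 − 2·P(t₁₂ > 3) ≈ 98.9 %; the empirical rate over 200
        seeded simulations must agree within 3 binomial standard errors.
        """
        from scipy import stats

        terms = ("1", "x1", "x2", "x3", "x2:x3", "x2^2")
        truth = np.array([16.89, 0.48, 1.24, -1.36, -0.22, -0.33])
        sd = 0.13  # residual scale of the retention-factor fit
        M = term_matrix(canonical_design.coded, terms)
        inside = 0
        total = 0
        df = None
        for _ in range(200):
            y = M @ truth + rng.normal(0, sd, size=len(M))
            model = fit_rsm(canonical_design, y, terms=terms)
            inside += int(np.sum(np.abs(model.coef_ - truth) <= 3 * model.se_))
            total += len(terms)
            df = model.df_resid_
        expected = 1 - 2 * stats.t.sf(3, df)
        tol = 3 * np.sqrt(expected * (1 - expected) / total)
        assert inside / total >= expected - tol


class TestDiagnostics:
    def test_residuals_orthogonal_to_model_columns(self, study_models, study_design):
        for model in study_models.values():
            M = term_matrix(study_design.coded, model.terms_)
            dots = M.T @ model._resid_
            assert np.max(np.abs(dots)) < 1e-8 * max(1.0, np.abs(M).max())

    def test_r2_orderings(self, study_models):
        for model in study_models.values():
            d = model.diagnostics_
            assert d.adj_r2 <= d.r2
            assert d.pred_r2 <= d.r2
            assert d.press >= 0

    def test_published_k_last_diagnostics(self, study_models):
        """Refit diagnostics agree with the published table to the precision
        the 2-decimal response data supports."""
        d = study_models["k_last"].diagnostics_
        assert d.r2 == pytest.approx(0.9902, abs=2e-3)
        assert d.adj_r2 == pytest.approx(0.9861, abs=2e-3)
        assert d.pred_r2 == pytest.approx(0.9805, abs=2e-3)
        assert d.lof_pvalue == pytest.approx(0.9718, abs=2e-3)

    def test_published_boundary_model_diagnostics_at_printed_precision(self, study_models):
        from chromodr.reference import PUBLISHED_DIAGNOSTICS

        for name in ("t_end_peak1", "t_start_peak2", "t_end_peak6", "t_start_peak7"):
            d = study_models[name].diagnostics_
            pub = PUBLISHED_DIAGNOSTICS[name]
            assert d.r2 == pytest.approx(float(pub["r2"]), abs=5e-5)
            assert d.adj_r2 == pytest.approx(float(pub["adj_r2"]), abs=5e-5)
            assert d.pred_r2 == pytest.approx(float(pub["pred_r2"]), abs=5e-5)
            assert d.lof_pvalue == pytest.approx(float(pub["lof_pvalue"]), abs=5e-5)

    def test_saturated_model_interpolates(self, rng):
        X = np.array([[-1, -1, -1], [1, -1, 0], [0, 1, 1], [1, 1, -1]], dtype=float)
        y = rng.normal(size=4)
        model = fit_rsm(X, y, terms=("1", "x1", "x2", "x3"))
        assert model.diagnostics_.r2 == pytest.approx(1.0, abs=1e-10)
        assert np.isnan(model.diagnostics_.pred_r2)  # LOO undefined when n = p
        assert model.df_resid_ == 0

    def test_intercept_only_model_explains_nothing(self, rng):
        X = rng.uniform(-1, 1, size=(10, 3))
        y = rng.normal(size=10)
        model = fit_rsm(X, y, terms=("1",))
        assert model.diagnostics_.r2 == pytest.approx(0.0, abs=1e-10)

    def test_lack_of_fit_undefined_without_replicates(self, rng):
        X = rng.uniform(-1, 1, size=(10, 3))  # all settings distinct
        model = fit_rsm(X, rng.normal(size=10), terms=("1", "x1"))
        assert model.diagnostics_.lof_pvalue is None


class TestSuggestTransform:
    def test_reciprocal_truth_detected(self, canonical_design, rng):
        # wide relative range so the Box-Cox profile pins λ near −1
        z = term_matrix(canonical_design.coded, ("1", "x1", "x2")) @ np.array([0.5, 0.3, 0.1])
        y = 1.0 / (z + rng.normal(0, 0.002, size=len(z)))
        assert suggest_transform(canonical_design, y) == "reciprocal"

    def test_linear_truth_keeps_identity(self, canonical_design, rng):
        z = term_matrix(canonical_design.coded, ("1", "x1", "x2")) @ np.array([16.9, 0.5, 1.2])
        y = z + rng.normal(0, 0.15, size=len(z))
        assert suggest_transform(canonical_design, y) == "identity"

    def test_constant_response_ties_to_identity(self, canonical_design):
        assert suggest_transform(canonical_design, np.full(18, 5.0)) == "identity"

    def test_nonpositive_rejected(self, canonical_design):
        with pytest.raises(ValueError, match="positive"):
            suggest_transform(canonical_design, np.linspace(-1, 1, 18))


class TestBackwardElimination:
    def test_study_retention_factor_term_set(self, study_design, study_responses):
        """The stated procedure retains the published reduced structure."""
        terms = backward_eliminate(
            study_design, study_responses["k_last"].to_numpy(), transform="identity", alpha=0.05
        )
        assert {"x1", "x2", "x3", "x2:x3", "x2^2"} <= set(terms)
        assert "x1:x2" not in terms and "x1^2" not in terms

    def test_noise_free_linear_truth_keeps_exactly_linear_terms(self, canonical_design):
        y = term_matrix(canonical_design.coded, ("1", "x1", "x3")) @ np.array([10.0, 1.0, -2.0])
        terms = backward_eliminate(canonical_design, y, alpha=0.05)
        assert set(terms) == {"1", "x1", "x3"}

    def test_pure_noise_reduces_to_intercept(self, rng):
        # large design so spurious terms are reliably non-significant
        X = rng.uniform(-1, 1, size=(400, 3))
        y = rng.normal(size=400)
        terms = backward_eliminate(X, y, alpha=0.01)
        assert terms == ("1",)

    def test_hierarchy_respected(self, canonical_design, rng):
        # strong interaction, weak mains: mains must survive alongside x1:x2
        y = (
            term_matrix(canonical_design.coded, ("1", "x1:x2")) @ np.array([5.0, 2.0])
            + rng.normal(0, 0.05, size=18)
        )
        terms = backward_eliminate(canonical_design, y, alpha=0.05)
        if "x1:x2" in terms:
            assert {"x1", "x2"} <= set(terms)


def test_canonical_terms_ordering_and_validation():
    assert canonical_terms(["x2^2", "x1"]) == ("1", "x1", "x2^2")
    assert full_quadratic_terms()[0] == "1"
    with pytest.raises(ValueError, match="unknown model terms"):
        canonical_terms(["x4"])
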
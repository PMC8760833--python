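"""Polynomial fitting, stepwise selection, hierarchy, ANOVA, and PRESS."""

import numpy as np
import pytest

import cocultrsm as crs
from cocultrsm.errors import (
    DegenerateAnovaError,
    LeverageError,
    SingularDesignError,
    UnsupportedDegreeError,
)
from cocultrsm.models import Term, estimable_subset, hierarchy_closure, is_hierarchical


def _simulate(design, model, sd, seed):
    rng = np.random.default_rng(seed)
    y = model.predict(design.coded_matrix())
    return y + rng.normal(0, sd, size=len(y))


class TestTerms:
    @pytest.mark.parametrize("deg,count", [(1, 4), (2, 10), (3, 20)])
    def test_basis_size(self, deg, count):
        assert len(crs.build_terms(3, deg)) == count

    def test_order_deterministic(self):
        labels = [t.label() for t in crs.build_terms(3, 2)]
        assert labels == ["1", "A", "B", "C", "A²", "AB", "AC", "B²", "BC", "C²"]

    def test_degree_cap(self):
        with pytest.raises(UnsupportedDegreeError):
            crs.build_terms(3, 4)

    def test_truth_model_is_cubic_subset(self, mbe_model, cubic_pool):
        assert len(mbe_model.terms) == 13
        assert set(mbe_model.terms) <= set(cubic_pool)
        assert is_hierarchical(mbe_model.terms)

    def test_hierarchy_closure_of_a2b(self):
        closed = hierarchy_closure([Term((2, 1, 0))])
        labels = {t.label() for t in closed}
        assert labels == {"1", "A", "B", "A²", "AB", "A²B"}


class TestFitOls:
    def test_noiseless_recovery_exact(self, design34, mbe_model):
        y = mbe_model.predict(design34.coded_matrix())
        fit = crs.fit_ols(design34, y, mbe_model.terms)
        assert np.allclose(fit.coefficients, mbe_model.coefficients, atol=1e-8)
        assert fit.fit_stats.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.fit_stats.df_model + fit.fit_stats.df_residual == len(design34) - 1

    def test_intercept_only_is_sample_mean(self, design34, rng):
        y = rng.normal(10, 2, size=len(design34))
        fit = crs.fit_ols(design34, y, [Term((0, 0, 0))])
        assert fit.coefficients[0] == pytest.approx(y.mean())

    def test_singular_basis_names_terms(self, design34):
        y = np.ones(len(design34))
        aliased = hierarchy_closure([Term((0, 1, 2)), Term((0, 3, 0))])  # BC², B³
        with pytest.raises(SingularDesignError, match="BC²"):
            crs.fit_ols(design34, y, aliased)

    def test_block_offsets_excluded_from_prediction(self, design34, mbe_model):
        y = mbe_model.predict(design34.coded_matrix())
        shift = np.array([2.0 if p.block == 1 else -1.0 for p in design34.points])
        fit = crs.fit_ols(design34, y + shift, mbe_model.terms, block_effect=True)
        # prediction at a new point ignores per-block offsets; the intercept
        # absorbs the mean block effect (here (2 - 1)/2 = 0.5)
        assert fit.predict(np.zeros(3)) == pytest.approx(23.91 + 0.5, abs=1e-6)
        # offsets themselves are estimated up to the overall mean
        est = fit.block_offsets
        assert est[1] - est[2] == pytest.approx(3.0, abs=1e-6)

    def test_confidence_interval_coverage(self, design34, mbe_model):
        """95% CIs cover each large true coefficient in >= 90% of 200 fits."""
        big = [
            i for i, (t, b) in enumerate(zip(mbe_model.terms, mbe_model.coefficients))
            if abs(b) >= 1
        ]
        hits = np.zeros(len(big))
        n_sim = 200
        for s in range(n_sim):
            y = _simulate(design34, mbe_model, sd=1.0, seed=1000 + s)
            fit = crs.fit_ols(design34, y, mbe_model.terms)
            ci = fit.conf_int(0.95)
            for j, i in enumerate(big):
                lo, hi = ci[i]
                hits[j] += lo <= mbe_model.coefficients[i] <= hi
        assert np.all(hits / n_sim >= 0.90)

    def test_constant_response_convention(self, design34):
        fit = crs.fit_ols(design34, np.full(len(design34), 7.0), [Term((0, 0, 0))])
        assert fit.fit_stats.r2 == 0.0


class TestForwardSelect:
    def test_single_active_linear_term(self, design34, cubic_pool):
        rng = np.random.default_rng(5)
        coded = design34.coded_matrix()
        y = 5 + 3 * coded[:, 0] + rng.normal(0, 1e-6, size=len(coded))
        fit = crs.forward_select(design34, y, cubic_pool, alpha_enter=0.10)
        labels = {t.label() for t in fit.terms}
        assert {"1", "A"} <= labels
        # anything else that slipped in on the 1e-6 jitter is negligible
        for t, b in zip(fit.terms, fit.coefficients):
            if t.label() not in {"1", "A"}:
                assert abs(b) < 1e-4
        assert fit.coefficients[fit.terms.index(Term((1, 0, 0)))] == pytest.approx(3.0, abs=1e-4)

    def test_hierarchy_enforced_after_selection(self, design34, mbe_model, cubic_pool):
        y = _simulate(design34, mbe_model, sd=1.0, seed=11)
        fit = crs.forward_select(design34, y, cubic_pool)
        assert is_hierarchical(fit.terms)

    def test_large_terms_selected_frequently(self, design34, mbe_model, cubic_pool):
        """Terms with |beta| >> sigma enter in >= 80% of 200 noisy fits."""
        want = [Term(e) for e in [(1, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2),
                                  (1, 1, 0), (1, 1, 1)]]
        counts = dict.fromkeys(want, 0)
        n_sim = 200
        for s in range(n_sim):
            y = _simulate(design34, mbe_model, sd=1.0, seed=2000 + s)
            fit = crs.forward_select(design34, y, cubic_pool)
            sel = set(fit.terms)
            for t in want:
                counts[t] += t in sel
        for t, n in counts.items():
            assert n / n_sim >= 0.80, f"{t.label()} selected in {n}/{n_sim} runs"

    def test_empty_pool(self, design34):
        with pytest.raises(crs.models.EmptyPoolError):
            crs.forward_select(design34, np.zeros(len(design34)), [])


class TestBackwardEliminate:
    def test_pure_quadratic_keeps_parent_by_hierarchy(self, design34):
        rng = np.random.default_rng(9)
        coded = design34.coded_matrix()
        y = 2 - 4 * coded[:, 0] ** 2 + rng.normal(0, 1e-6, size=len(coded))
        start = crs.build_terms(3, 2)
        fit = crs.backward_eliminate(design34, y, start, alpha_remove=0.10)
        labels = {t.label() for t in fit.terms}
        assert {"1", "A", "A²"} <= labels
        for t, b in zip(fit.terms, fit.coefficients):
            if t.label() not in {"1", "A", "A²"}:
                assert abs(b) < 1e-4

    def test_alpha_one_strips_to_intercept(self, design34, rng):
        y = rng.normal(0, 1, size=len(design34))
        fit = crs.backward_eliminate(design34, y, crs.build_terms(3, 2), alpha_remove=1.0)
        assert [t.label() for t in fit.terms] == ["1"]

    def test_concordance_with_forward_on_strong_signal(self, design34):
        """Both procedures recover the support when all true |beta| >= 5 sigma."""
        truth = crs.PolynomialModel(
            terms=[Term((0, 0, 0)), Term((1, 0, 0)), Term((0, 1, 0)), Term((2, 0, 0))],
            coefficients=np.array([20.0, 6.0, -5.0, -7.0]),
        )
        y = _simulate(design34, truth, sd=1.0, seed=21)
        pool = crs.build_terms(3, 2)
        fwd = crs.forward_select(design34, y, pool, alpha_enter=0.05)
        bwd = crs.backward_eliminate(design34, y, pool, alpha_remove=0.05)
        assert set(truth.terms) <= set(fwd.terms)
        assert set(truth.terms) <= set(bwd.terms)
        strong = lambda m: {t for t, b in zip(m.terms, m.coefficients) if abs(b) > 2}
        assert strong(fwd) == strong(bwd) == set(truth.terms)

    def test_estimable_subset_drops_aliased_cubics(self, design34, cubic_pool):
        kept = estimable_subset(design34, cubic_pool)
        assert len(kept) < len(cubic_pool)
        assert is_hierarchical(kept)
        X = np.column_stack(
            [t.evaluate(design34.coded_matrix()) for t in kept]
        )
        assert np.linalg.matrix_rank(X) == len(kept)


class TestAnova:
    def test_df_accounting_on_study_layout(self, design34, mbe_model):
        """15 distinct points, 34 runs, 13-parameter model -> pe 19, lof 2."""
        y = _simulate(design34, mbe_model, sd=1.0, seed=3)
        fit = crs.fit_ols(design34, y, mbe_model.terms)
        tab = crs.anova(fit, design34, y)
        assert tab["pure_error"].df == 19
        assert tab["residual"].df == 21
        assert tab["lack_of_fit"].df == 2

    def test_ss_and_df_additivity(self, design34, mbe_model):
        y = _simulate(design34, mbe_model, sd=2.3, seed=4)
        fit = crs.fit_ols(design34, y, mbe_model.terms)
        tab = crs.anova(fit, design34, y)
        rel = lambda a, b: abs(a - b) / max(abs(b), 1e-12)
        assert rel(tab["model"].ss + tab["residual"].ss, tab["total"].ss) < 1e-8
        assert rel(
            tab["lack_of_fit"].ss + tab["pure_error"].ss, tab["residual"].ss
        ) < 1e-8
        assert tab["model"].df + tab["residual"].df == tab["total"].df
        assert tab["lack_of_fit"].df + tab["pure_error"].df == tab["residual"].df

    def test_exact_fit_zero_residual(self, design34, mbe_model):
        y = mbe_model.predict(design34.coded_matrix())
        fit = crs.fit_ols(design34, y, mbe_model.terms)
        tab = crs.anova(fit, design34, y)
        assert tab["residual"].ss == pytest.approx(0.0, abs=1e-12)

    def test_no_replicates_warns(self, mbe_model):
        d = crs.generate_ccd(3, 1, 1, 1, seed=0)
        y = _simulate(d, mbe_model, sd=1.0, seed=5)
        fit = crs.fit_ols(d, y, crs.build_terms(3, 1))
        with pytest.warns(UserWarning, match="no replicated"):
            tab = crs.anova(fit, d, y)
        assert "pure_error" not in tab

    def test_zero_residual_df_raises(self):
        # saturated fit: 2² factorial, 4 runs, 4-term basis {1, A, B, AB}
        d = crs.generate_ccd(2, 1, 0, 0, seed=0)
        y = np.array([1.0, 2.0, 3.0, 5.0])
        fit = crs.fit_ols(d, y, crs.build_terms(2, 2)[:3] + [Term((1, 1))])
        with pytest.raises(DegenerateAnovaError):
            crs.anova(fit, d, y)


class TestPredictedR2:
    def test_press_matches_brute_force_loo(self, design15, design34, mbe_model):
        """Shortcut PRESS equals explicit leave-one-out refitting."""
        from cocultrsm.doe import DesignTable

        for design, sd in [(design15, 1.0), (design34, 2.3)]:
            y = _simulate(design, mbe_model, sd=sd, seed=8)
            terms = crs.build_terms(3, 2)
            fit = crs.fit_ols(design, y, terms)
            press = 0.0
            for i in range(len(design)):
                keep = [j for j in range(len(design)) if j != i]
                pts = [design.points[j] for j in keep]
                sub = DesignTable(
                    factors=design.factors,
                    points=[
                        crs.DesignPoint(
                            run_id=p.run_id, coded_levels=p.coded_levels,
                            point_type=p.point_type, block=p.block,
                            replicate=p.replicate, run_order=r + 1,
                        )
                        for r, p in enumerate(pts)
                    ],
                    seed=design.seed,
                )
                loo = crs.fit_ols(sub, y[keep], terms)
                press += (y[i] - loo.predict(np.asarray(design.points[i].coded_levels))) ** 2
            ss_tot = np.sum((y - y.mean()) ** 2)
            assert fit.fit_stats.press == pytest.approx(press, rel=1e-8)
            assert crs.predicted_r2(fit, design, y) == pytest.approx(
                1 - press / ss_tot, rel=1e-10
            )

    def test_exact_fit_gives_one(self, design34, mbe_model):
        y = mbe_model.predict(design34.coded_matrix())
        fit = crs.fit_ols(design34, y, mbe_model.terms)
        assert crs.predicted_r2(fit, design34, y) == pytest.approx(1.0, abs=1e-9)

    def test_r2_pred_below_r2(self, design34, mbe_model):
        for s in range(5):
            y = _simulate(design34, mbe_model, sd=2.3, seed=30 + s)
            fit = crs.fit_ols(design34, y, mbe_model.terms)
            assert fit.fit_stats.r2_pred <= fit.fit_stats.r2 <= 1.0

    def test_saturated_leverage_raises(self):
        d = crs.generate_ccd(2, 1, 0, 0, seed=0)
        y = np.array([1.0, 2.0, 3.0, 5.0])
        fit = crs.fit_ols(d, y, crs.build_terms(2, 2)[:3] + [Term((1, 1))])
        with pytest.raises(LeverageError):
            crs.predicted_r2(fit, d, y)
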
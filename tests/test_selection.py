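"""Logistic fitting, AIC bookkeeping, and the three greedy searches."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from pulseharm.errors import SeparationError, SingularDesignError
from pulseharm.selection import (
    EPVAdvisory,
    aic_of,
    backward_eliminate,
    epv_check,
    fit_logistic,
    forward_select,
    select_best,
    stepwise_select,
)


def direct_ml(X, y):
    """Independent oracle: numerically maximize the logistic log-likelihood."""

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(-(2 * y - 1) * eta))))

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x, -res.fun


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        model = fit_logistic(pd.DataFrame(index=range(4)), [1, 0, 1, 0], [])
        assert model.coefficients["(intercept)"] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_closed_form(self):
        model = fit_logistic(pd.DataFrame(index=range(4)), [1, 1, 1, 0], [])
        assert model.coefficients["(intercept)"] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_separating_predictor_raises(self):
        X = pd.DataFrame({"x": [0.0, 1, 2, 3, 4, 5]})
        with pytest.raises(SeparationError):
            fit_logistic(X, (X["x"] > 2.5).astype(float), ["x"])

    def test_singular_design_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2.0 * X["a"]
        y = (rng.random(30) < 0.5).astype(float)
        y[0], y[1] = 1.0, 0.0
        with pytest.raises(SingularDesignError) as exc:
            fit_logistic(X, y, ["a", "b"])
        assert "b" in exc.value.columns

    def test_matches_direct_likelihood_maximization(self, rng):
        """Fitted coefficients agree with BFGS on the written likelihood."""
        for _ in range(5):
            n = 80
            X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
            eta = -0.3 + 0.8 * X["a"] - 0.5 * X["b"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() in (0, n):
                continue
            model = fit_logistic(X, y, ["a", "b"])
            design = np.column_stack([np.ones(n), X["a"], X["b"]])
            beta_hat, ll = direct_ml(design, y.to_numpy())
            np.testing.assert_allclose(
                model.coefficients.to_numpy(), beta_hat, atol=1e-6
            )
            assert model.log_likelihood == pytest.approx(ll, abs=1e-6)


class TestAic:
    def test_closed_form_two_subjects(self):
        model = fit_logistic(pd.DataFrame(index=range(2)), [1, 0], [])
        assert aic_of(model) == pytest.approx(2 - 4 * np.log(0.5), abs=1e-8)

    def test_extra_parameter_at_fixed_likelihood_costs_two(self, rng):
        n = 60
        y = (rng.random(n) < 0.4).astype(float)
        base = fit_logistic(pd.DataFrame(index=range(n)), y, [])
        penalty = (2 * (base.k + 1) - 2 * base.log_likelihood) - base.aic
        assert penalty == pytest.approx(2.0, abs=1e-12)
        grown = fit_logistic(pd.DataFrame({"z": rng.normal(size=n)}), y, ["z"])
        assert grown.aic == pytest.approx(2 * 2 - 2 * grown.log_likelihood, abs=1e-10)

    def test_consistency_self_check(self):
        model = fit_logistic(pd.DataFrame(index=range(4)), [1, 0, 1, 0], [])
        model.log_likelihood += 0.1
        with pytest.raises(AssertionError):
            aic_of(model)


def _signal_fixture(rng, n=200, beta=1.5):
    X = pd.DataFrame(
        rng.normal(size=(n, 4)), columns=["aaa", "bbb", "true", "zzz"]
    )
    eta = -1.0 + beta * X["true"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestSearches:
    def test_all_methods_find_the_signal(self, rng):
        X, y = _signal_fixture(rng)
        for search in (forward_select, backward_eliminate, stepwise_select):
            result = search(X, y, list(X.columns))
            assert "true" in result.selected

    def test_empty_candidates_returns_intercept_only(self, rng):
        X, y = _signal_fixture(rng)
        result = forward_select(X, y, [])
        assert result.selected == []
        assert result.model.k == 1

    def test_aic_trajectory_strictly_decreasing(self, rng):
        X, y = _signal_fixture(rng)
        for search in (forward_select, backward_eliminate, stepwise_select):
            traj = search(X, y, list(X.columns)).aic_trajectory
            assert all(b < a for a, b in zip(traj, traj[1:]))

    def test_backward_falls_back_when_full_model_unfittable(self, rng):
        # more candidates than observations
        X = pd.DataFrame(rng.normal(size=(12, 15)),
                         columns=[f"c{i:02d}" for i in range(15)])
        y = np.array([1, 0] * 6, dtype=float)
        result = backward_eliminate(X, y, list(X.columns))
        assert result.method == "backward"
        assert any("fell back" in w for w in result.warnings)

    def test_stepwise_never_beats_exhaustive_best_subset(self, rng):
        X, y = _signal_fixture(rng, n=120)
        cols = list(X.columns)
        best_aic = np.inf
        for r in range(len(cols) + 1):
            for subset in itertools.combinations(cols, r):
                try:
                    best_aic = min(best_aic, fit_logistic(X, y, list(subset)).aic)
                except (SeparationError, SingularDesignError):
                    continue
        result = stepwise_select(X, y, cols)
        assert result.model.aic >= best_aic - 1e-8

    def test_significance_filter_keeps_only_significant_terms(self, rng):
        from pulseharm.selection import significance_filter

        X, y = _signal_fixture(rng, n=400, beta=2.0)
        full = fit_logistic(X, y, list(X.columns))
        filtered = significance_filter(X, y, full, alpha=0.05)
        assert "true" in filtered.variables
        p = filtered.p_values.drop("(intercept)")
        assert (p < 0.05).all()

    def test_degenerate_candidates_dropped(self, rng):
        X, y = _signal_fixture(rng)
        X["const"] = 1.7
        result = forward_select(X, y, list(X.columns))
        assert "const" not in result.selected


class TestSelectBest:
    def _dummy(self, aic, k, names, rng):
        X, y = _signal_fixture(rng)
        result = forward_select(X, y, [])
        result.model.aic = aic
        result.model.variables = names
        result.selected = names
        result.model.log_likelihood = (2 * (len(names) + 1) - aic) / 2.0
        return result

    def test_minimum_aic_wins(self, rng):
        fits = [self._dummy(a, 1, [f"v{i}"], rng) for i, a in enumerate([105.5, 110.2, 108.0])]
        assert select_best(fits) is fits[0]

    def test_tie_broken_toward_fewer_parameters(self, rng):
        small = self._dummy(100.0, 1, ["a"], rng)
        big = self._dummy(100.0, 2, ["a", "b"], rng)
        assert select_best([big, small]) is small

    def test_single_entry(self, rng):
        only = self._dummy(50.0, 1, ["a"], rng)
        assert select_best([only]) is only

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_best([])


class TestReportedVariableSets:
    """The clinically reported male/female predictor sets refit cleanly and
    emit the standard four-column coefficient table."""

    SETS = {
        "male": ["absdC10", "dD6", "absdD9", "absdD10", "absdP8", "absdP10",
                 "dP1CV", "dC9CV"],
        "female": ["absdD2", "absdD3", "absdD5", "absdD6", "absdD9",
                   "absdC2CV", "absdC4CV", "absdC5CV", "absdC6CV", "absdC9CV"],
    }

    @pytest.mark.parametrize("sex,n,n_events", [("male", 249, 32), ("female", 99, 13)])
    def test_refit_schema(self, sex, n, n_events, rng):
        variables = self.SETS[sex]
        X = pd.DataFrame(
            np.abs(rng.normal(0.0, 0.01, (n, len(variables)))), columns=variables
        )
        y = np.zeros(n)
        y[rng.choice(n, n_events, replace=False)] = 1.0
        model = fit_logistic(X, y, variables)
        table = model.coefficient_table()
        assert list(table.columns) == ["Coefficient", "SE", "tStat", "P Value"]
        assert len(table) == len(variables) + 1
        assert np.all((table["P Value"] >= 0) & (table["P Value"] <= 1))


class TestEpvCheck:
    def test_male_stratum_scale_warns(self):
        advisory = epv_check(32, 8)
        assert not advisory.ok
        assert "32" in advisory.message

    def test_boundary_passes(self):
        assert epv_check(100, 10).ok

    def test_no_events_warns(self):
        advisory = epv_check(0, 1)
        assert not advisory.ok and "no events" in advisory.message
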
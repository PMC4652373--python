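"""Transition regressions: transform, design sizes, agreement with a
reference GLM implementation, and degenerate-input behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ccistate as cs
from ccistate import fitting
from ccistate.fitting import CHANGE_TERMS, DEATH_TERMS, GE6_TERMS


class TestChangeSizeTransform:
    @pytest.mark.parametrize(
        "size,expected", [(1, (0, False)), (6, (0, True)), (3, (2, False)), (8, (2, True))]
    )
    def test_encode_examples(self, size, expected):
        assert cs.encode_change(size) == expected

    @pytest.mark.parametrize(
        "pair,expected", [((0, False), 1), ((0, True), 6), ((4, False), 5)]
    )
    def test_decode_examples(self, pair, expected):
        assert cs.decode_change(*pair) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            cs.encode_change(0)
        with pytest.raises(ValueError):
            cs.decode_change(-1, False)

    @given(st.integers(min_value=1, max_value=10**6))
    @settings(derandomize=True)
    def test_decode_inverts_encode(self, c):
        assert cs.decode_change(*cs.encode_change(c)) == c

    def test_encode_not_injective_on_pairs(self):
        # (5, False) decodes to 6, which re-encodes to (0, True): only the
        # decode(encode(.)) direction is an identity
        assert cs.encode_change(cs.decode_change(5, False)) == (0, True)


class TestDesignSizes:
    def test_coefficient_counts(self, fitted_small):
        p = fitted_small["params"]
        assert [m.n_coefficients for m in p.models] == [4, 19, 19, 10]
        assert all(m.dropped_terms == () for m in p.models)
        assert p.death.term_names == DEATH_TERMS
        assert p.change.term_names == CHANGE_TERMS
        assert p.size.term_names == CHANGE_TERMS
        assert p.ge6.term_names == GE6_TERMS

    def test_ge6_design_full_rank(self):
        # all clock categories, treatments, and >=3 distinct CCI values >= 2
        rows = []
        i = 0
        for trt in ("AS", "RP", "RT"):
            for clock in ("1", "2-3", "4-6", ">6/none"):
                for cci in (0, 1, 2, 3, 5):
                    i += 1
                    rows.append((trt, clock, cci, 55.0 + (i * 7) % 20))
        df = pd.DataFrame(rows, columns=["treatment", "t_since_change_cat", "cci", "age"])
        X = fitting.build_ge6_design(df)
        assert X.shape[1] == 10
        assert fitting.design_rank(X) == 10

    def test_empty_category_dropped_with_warning(self, fitted_small):
        steps = fitted_small["steps"]
        as_only = steps[steps["treatment"] == "AS"]
        with pytest.warns(UserWarning, match="dropping empty design columns"):
            m = cs.fit_change_model(as_only)
        # treatment dummies, both procedure clocks, and the age interactions vanish
        assert "treatment[RP]" in m.dropped_terms
        assert m.n_coefficients == 19 - len(m.dropped_terms)
        assert m.coef("treatment[RP]") == 0.0


class TestAgreementWithStatsmodels:
    """Our IRLS must agree with an independent GLM implementation."""

    def test_death_and_change_models(self, fitted_small):
        sm = pytest.importorskip("statsmodels.api")
        steps = fitted_small["steps"]
        ours = cs.fit_death_model(steps)
        X = fitting.build_death_design(steps)
        ref = sm.GLM(steps["died"].to_numpy(float), X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(
            np.sqrt(np.diag(ours.covariance)), ref.bse, rtol=1e-4
        )

        alive = steps[~steps["died"]]
        ours = cs.fit_change_model(steps)
        Xc = fitting.build_change_design(alive)
        ref = sm.GLM(alive["changed"].to_numpy(float), Xc, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(
            np.sqrt(np.diag(ours.covariance)), ref.bse, rtol=1e-4
        )

    def test_size_model_poisson(self, fitted_small):
        sm = pytest.importorskip("statsmodels.api")
        steps = fitted_small["steps"]
        changed = steps[steps["changed"]]
        ours = cs.fit_size_model(steps)
        X = fitting.build_change_design(changed)
        ref = sm.GLM(
            changed["transformed_size"].to_numpy(float), X, family=sm.families.Poisson()
        ).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-5, atol=1e-8)


class TestDegenerateInputs:
    def _steps(self, died, changed, sizes=None):
        n = len(died)
        sizes = sizes or [1] * n
        rows = []
        for i in range(n):
            ge6 = sizes[i] >= 6
            rows.append(
                {
                    "subject_id": f"s{i}", "step_index": 0, "age": 60.0 + i,
                    "cci": i % 3, "cci_cat": str(i % 3),
                    "t_since_change_cat": ">6/none", "t_since_rp_cat": ">6/none",
                    "t_since_rt_cat": ">6/none", "treatment": ("AS", "RP", "RT")[i % 3],
                    "died": died[i], "changed": changed[i],
                    "change_size": sizes[i] if changed[i] else pd.NA,
                    "transformed_size": (sizes[i] - (6 if ge6 else 1)) if changed[i] else pd.NA,
                    "ge6": ge6 if changed[i] else pd.NA,
                }
            )
        return pd.DataFrame(rows)

    def test_all_survivors_is_separation_error(self):
        df = self._steps(died=[False] * 6, changed=[False, True] * 3)
        with pytest.raises(cs.FitError, match="death model"):
            cs.fit_death_model(df)

    def test_no_changes_is_separation_error(self):
        df = self._steps(died=[False] * 6, changed=[False] * 6)
        with pytest.raises(cs.FitError, match="change model"):
            cs.fit_change_model(df)

    def test_all_size_one_changes_raise(self):
        # every transformed size is 0: the Poisson intercept is unbounded below
        df = self._steps(died=[False] * 6, changed=[True] * 6, sizes=[1] * 6)
        with pytest.raises(cs.FitError, match="size model"):
            cs.fit_size_model(df)

    def test_no_ge6_rows_raise_with_guidance(self):
        df = self._steps(died=[False] * 6, changed=[True] * 6, sizes=[2] * 6)
        with pytest.raises(cs.FitError, match="ge6 model"):
            cs.fit_ge6_model(df)


class TestParameterSet:
    def test_stacked_covariance_block_diagonal(self, fitted_small):
        p = fitted_small["params"]
        cov = p.stacked_covariance
        assert cov.shape == (52, 52)
        assert len(p.stacked_coefficients) == 52
        pos = 0
        blocks = []
        for m in p.models:
            k = m.n_coefficients
            blocks.append((pos, pos + k))
            np.testing.assert_array_equal(cov[pos : pos + k, pos : pos + k], m.covariance)
            pos += k
        for i, (a0, a1) in enumerate(blocks):
            for j, (b0, b1) in enumerate(blocks):
                if i != j:
                    assert not cov[a0:a1, b0:b1].any()

    def test_with_stacked_coefficients_roundtrip(self, fitted_small):
        p = fitted_small["params"]
        theta = p.stacked_coefficients + 0.5
        q = p.with_stacked_coefficients(theta)
        np.testing.assert_array_equal(q.stacked_coefficients, theta)
        np.testing.assert_array_equal(q.stacked_covariance, p.stacked_covariance)

    def test_yaml_roundtrip(self, tmp_path, fitted_small):
        p = fitted_small["params"]
        p.to_yaml(tmp_path / "params.yaml")
        q = cs.TransitionParameterSet.from_yaml(tmp_path / "params.yaml")
        np.testing.assert_array_equal(p.stacked_coefficients, q.stacked_coefficients)
        np.testing.assert_array_equal(p.stacked_covariance, q.stacked_covariance)
        assert q.change.term_names == p.change.term_names

    def test_covariance_symmetry_enforced(self):
        cov = np.zeros((4, 4))
        cov[0, 1] = 1e-6
        with pytest.raises(ValueError, match="symmetric"):
            cs.FittedModel("logistic", DEATH_TERMS, np.zeros(4), cov)


class TestChangeSizeHistogram:
    def test_degenerate_point_mass_at_one(self):
        params = cs.make_parameter_set(
            death={"intercept": -5}, change={"intercept": -3},
            size={"intercept": -30}, ge6={"intercept": -30},
        )
        df = pd.DataFrame(
            {
                "subject_id": ["a"], "step_index": [0], "age": [65.0], "cci": [0],
                "cci_cat": ["0"], "t_since_change_cat": [">6/none"],
                "t_since_rp_cat": [">6/none"], "t_since_rt_cat": [">6/none"],
                "treatment": ["AS"], "died": [False], "changed": [True],
                "change_size": [1], "transformed_size": [0], "ge6": [False],
            }
        )
        hist = cs.change_size_histogram(df, params.size, params.ge6)
        assert hist.loc[hist["size"] == 1, "implied_prob"].iloc[0] == pytest.approx(1.0)
        assert hist["implied_prob"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_model_matches_observed_on_self_generated_data(self, fitted_small):
        hist = cs.change_size_histogram(
            fitted_small["steps"], fitted_small["params"].size, fitted_small["params"].ge6
        )
        assert hist["implied_prob"].sum() == pytest.approx(1.0, abs=1e-9)
        tv = 0.5 * np.abs(hist["observed_freq"] - hist["implied_prob"]).sum()
        assert tv < 0.05
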
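"""Stepwise selection, chained-equations PMM, and Rubin's-rules pooling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialcea import impute


def _toy_table(n=500, seed=0, missing_frac=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
            "n3": rng.normal(size=n),
            "n4": rng.normal(size=n),
            "n5": rng.normal(size=n),
        }
    )
    df["y"] = 2.0 * df["x"] + rng.normal(scale=0.01, size=n)
    if missing_frac:
        miss = rng.random(n) < missing_frac
        df.loc[miss, "y"] = np.nan
    return df


class TestSelectCovariates:
    def test_true_signal_retained(self):
        """y = 2x + tiny noise among 5 noise candidates: x survives.

        Oracle: refitting y ~ x alone gives p far below 0.30."""
        df = _toy_table()
        sel = impute.select_covariates(df, "y", ["n1", "x", "n2", "n3", "n4", "n5"])
        assert "x" in sel
        import statsmodels.api as sm

        refit = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert refit.pvalues.iloc[1] < 1e-10

    def test_pure_noise_gives_empty_model(self):
        df = _toy_table(n=100, seed=1)
        df["y"] = np.random.default_rng(2).normal(size=100)
        sel = impute.select_covariates(df, "y", ["n1", "n2", "n3"], p_enter=1e-9)
        assert sel == []

    def test_collinear_duplicate_resolved_by_order(self):
        df = _toy_table(n=200, seed=3)
        df["x_copy"] = df["x"]
        sel = impute.select_covariates(df, "y", ["x", "x_copy"])
        assert sel == ["x"]
        sel2 = impute.select_covariates(df, "y", ["x_copy", "x"])
        assert sel2 == ["x_copy"]

    def test_forward_agrees_on_strong_signal(self):
        df = _toy_table(seed=4)
        sel = impute.select_covariates(df, "y", ["n1", "x", "n2"], direction="forward")
        assert "x" in sel

    def test_all_degenerate_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "c": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="degenerate"):
            impute.select_covariates(df, "y", ["c"])


def _trial_like(n=400, seed=0, missing_frac=0.15):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.normal(52, 2.5, n),
            "arm": rng.choice(["control", "social", "dvd"], n),
            "utility_0": np.clip(rng.normal(0.7, 0.1, n), 0, 1),
        }
    )
    df["utility_6"] = np.clip(df["utility_0"] + rng.normal(0, 0.08, n), 0, 1)
    df["cost_nhs_p1"] = rng.gamma(1.2, 40, n).round(2)
    miss = rng.random(n) < missing_frac  # MCAR
    df.loc[miss, ["utility_6", "cost_nhs_p1"]] = np.nan
    return df


def _cfg(**kw):
    base = impute.ImputationConfig(
        m=5,
        candidates=("age", "arm", "utility_0"),
        imputable=("cost_nhs_p1", "utility_6"),
        seed=7,
    )
    return dataclasses.replace(base, **kw)


class TestMicePmm:
    def test_no_missing_gives_identical_copies(self):
        df = _trial_like(missing_frac=0.0)
        out = impute.mice_pmm(df, _cfg())
        assert out.m == 5
        for d in out.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_donor_property_and_observed_immutability(self):
        df = _trial_like()
        out = impute.mice_pmm(df, _cfg())
        for v in ("utility_6", "cost_nhs_p1"):
            obs_mask = df[v].notna()
            support = set(df.loc[obs_mask, v])
            for d in out.datasets:
                # observed cells bit-identical
                assert (d.loc[obs_mask, v] == df.loc[obs_mask, v]).all()
                # every imputed cell is an observed donor value
                assert set(d.loc[~obs_mask, v]) <= support
                assert not d[v].isna().any()

    def test_reproducible_under_seed(self):
        df = _trial_like()
        a = impute.mice_pmm(df, _cfg())
        b = impute.mice_pmm(df, _cfg())
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)
        c = impute.mice_pmm(df, _cfg(seed=8))
        assert any(
            not da["utility_6"].equals(dc["utility_6"])
            for da, dc in zip(a.datasets, c.datasets)
        )

    def test_mcar_imputed_mean_matches_observed(self):
        """Under MCAR the imputed-cell mean agrees with the observed-cell
        mean to within 3 Monte-Carlo standard errors."""
        df = _trial_like(n=2000, seed=5)
        out = impute.mice_pmm(df, _cfg(m=10))
        obs = df["utility_6"].dropna()
        mis_mask = df["utility_6"].isna()
        imputed = np.concatenate([d.loc[mis_mask, "utility_6"] for d in out.datasets])
        se = obs.std(ddof=1) * np.sqrt(1 / mis_mask.sum() + 1 / len(obs))
        assert abs(imputed.mean() - obs.mean()) < 3 * se

    def test_error_paths(self):
        df = _trial_like(n=50)
        df["cost_nhs_p1"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            impute.mice_pmm(df, _cfg())
        df2 = _trial_like(n=30, seed=2)
        df2.loc[df2.index[:27], "utility_6"] = np.nan
        with pytest.raises(ValueError, match="fewer"):
            impute.mice_pmm(df2, _cfg(k=5))
        with pytest.raises(ValueError, match="2 imputations"):
            _cfg(m=1)

    def test_agrees_with_statsmodels_mice(self):
        """Independent route: statsmodels' chained-equations PMM yields a
        statistically indistinguishable imputed-cell mean on MCAR data."""
        from statsmodels.imputation.mice import MICEData

        df = _trial_like(n=1000, seed=6)
        num = df[["age", "utility_0", "utility_6", "cost_nhs_p1"]].copy()
        np.random.seed(3)
        md = MICEData(num)
        sm_means = []
        mis_mask = df["utility_6"].isna()
        for _ in range(5):
            md.update_all()
            sm_means.append(md.data.loc[mis_mask, "utility_6"].mean())
        ours = impute.mice_pmm(df, _cfg(m=5))
        our_means = [d.loc[mis_mask, "utility_6"].mean() for d in ours.datasets]
        se = df["utility_6"].std() / np.sqrt(mis_mask.sum())
        assert abs(np.mean(sm_means) - np.mean(our_means)) < 4 * se


class TestPoolRubin:
    def test_hand_arithmetic(self):
        pe = impute.pool_rubin([1, 2, 3], [1, 1, 1])
        assert pe.point == pytest.approx(2.0)
        assert pe.within == pytest.approx(1.0)
        assert pe.between == pytest.approx(1.0)
        assert pe.total == pytest.approx(7 / 3)

    def test_identical_estimates_have_no_between_variance(self):
        pe = impute.pool_rubin([1.5, 1.5, 1.5], [0.2, 0.3, 0.4])
        assert pe.between == 0.0
        assert pe.total == pe.within
        assert pe.df == np.inf

    def test_two_imputation_case(self):
        pe = impute.pool_rubin([0, 2], [0.5, 0.5])
        assert pe.point == pytest.approx(1.0)
        assert pe.between == pytest.approx(2.0)
        assert pe.total == pytest.approx(3.5)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            impute.pool_rubin([1.0], [1.0])

    @given(
        est=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20),
        data=st.data(),
    )
    def test_total_at_least_within(self, est, data):
        """T >= W always; strict whenever estimates differ."""
        var = data.draw(
            st.lists(st.floats(0, 1e6), min_size=len(est), max_size=len(est))
        )
        pe = impute.pool_rubin(est, var)
        assert pe.total >= pe.within
        if np.std(est) > 0:
            assert pe.total > pe.within
        assert pe.ci_low <= pe.point <= pe.ci_high
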
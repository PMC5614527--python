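"""Adjusted differences, bootstrap clouds, ICER logic, CEAC/CEAF, BCa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialcea import cea
from trialcea.cea import BootstrapCloud


def _two_arm(n=50, beta=2.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    arm = np.array(["control", "social"] * n)
    y = 5.0 + beta * (arm == "social") + rng.normal(0, noise, 2 * n)
    return pd.DataFrame({"arm": arm, "y": y, "x": rng.normal(size=2 * n)})


class TestAdjustedDifference:
    def test_exact_linear_structure(self):
        df = _two_arm(noise=0.0)
        ad = cea.adjusted_difference(df, "y", [], ("social", "control"))
        assert ad.estimate == pytest.approx(2.0)
        assert ad.se == pytest.approx(0.0, abs=1e-10)

    def test_sandwich_matches_explicit_matrix_formula(self):
        """HC1 SE on a 6-row fixture equals (X'X)^-1 X' diag(e^2) X (X'X)^-1
        scaled by n/(n-k), computed here with raw matrix arithmetic."""
        df = pd.DataFrame(
            {
                "arm": ["control", "control", "control", "social", "social", "social"],
                "y": [1.0, 2.0, 4.0, 3.0, 7.0, 8.0],
                "x": [0.5, -1.0, 0.2, 1.5, -0.3, 0.8],
            }
        )
        ad = cea.adjusted_difference(df, "y", ["x"], ("social", "control"))
        X = np.column_stack(
            [np.ones(6), (df["arm"] == "social").astype(float), df["x"]]
        )
        y = df["y"].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        e = y - X @ beta
        V = XtX_inv @ X.T @ np.diag(e**2) @ X @ XtX_inv * (6 / (6 - 3))
        assert ad.estimate == pytest.approx(beta[1])
        assert ad.se == pytest.approx(np.sqrt(V[1, 1]), rel=1e-10)

    def test_sandwich_near_classical_when_homoskedastic(self):
        """Asymptotic equivalence: HC1 within 5% of model-based OLS SE."""
        import statsmodels.api as sm

        df = _two_arm(n=2500, noise=1.0, seed=1)
        ad = cea.adjusted_difference(df, "y", ["x"], ("social", "control"))
        X = np.column_stack(
            [np.ones(len(df)), (df["arm"] == "social").astype(float), df["x"]]
        )
        classical = np.asarray(sm.OLS(df["y"], X).fit().bse)[1]
        assert ad.se == pytest.approx(classical, rel=0.05)

    def test_missing_arm_rejected(self):
        df = _two_arm()
        with pytest.raises(ValueError, match="dvd"):
            cea.adjusted_difference(df, "y", [], ("dvd", "control"))


class TestIcer:
    @pytest.mark.parametrize(
        "dc,de,expected_icer,label",
        [
            (52, 0.006, 8666.666666666666, "trade-off"),
            (61, -0.003, None, "dominated"),
            (-35, 0.013, None, "dominant"),
            (-10, -0.005, 2000.0, "southwest"),
            (52, 0.0, None, "undefined"),
        ],
    )
    def test_quadrants(self, dc, de, expected_icer, label):
        res = cea.icer(dc, de)
        assert res.label == label
        if expected_icer is None:
            assert res.icer is None
        else:
            assert res.icer == pytest.approx(expected_icer)


class TestNmb:
    def test_examples(self):
        assert cea.nmb(52, 0.006, 20000) == pytest.approx(68.0)
        assert cea.nmb(0, 0, 12345) == 0.0
        assert cea.nmb(52, 0.006, 52 / 0.006) == pytest.approx(0.0, abs=1e-9)


def _cloud(dc, de, seed=0):
    return BootstrapCloud(
        comparison=("social", "control"),
        delta_cost=np.asarray(dc, dtype=float),
        delta_effect=np.asarray(de, dtype=float),
        seed=seed,
    )


class TestCeac:
    def test_dominant_cloud_probability_one(self):
        c = _cloud([-5, -10, -1], [0.01, 0.02, 0.005])
        curve = cea.ceac(c, wtp_grid=(0, 10000, 30000))
        assert (curve["probability"] == 1.0).all()

    def test_toy_cloud_hand_counts(self):
        """5-pair cloud, lambda = 10,000: NMB = 10,000 dE - dC, positive for
        pairs (50,0.01), (-20,-0.001), (10,0.005) -> 3/5."""
        c = _cloud([50, 200, -20, 10, 100], [0.01, 0.01, -0.001, 0.005, 0.002])
        curve = cea.ceac(c, wtp_grid=(0.0, 10000.0))
        assert curve.loc[curve.wtp == 0, "probability"].item() == pytest.approx(1 / 5)
        assert curve.loc[curve.wtp == 10000, "probability"].item() == pytest.approx(3 / 5)

    def test_ceac_at_zero_is_probability_cost_saving(self, rng):
        dc = rng.normal(10, 40, 2000)
        c = _cloud(dc, rng.normal(0.01, 0.01, 2000))
        curve = cea.ceac(c, wtp_grid=(0.0, 100.0))
        assert curve["probability"].iloc[0] == pytest.approx((dc < 0).mean())

    @given(seed=st.integers(0, 50))
    def test_monotone_in_wtp_when_effect_positive(self, seed):
        r = np.random.default_rng(seed)
        c = _cloud(r.normal(50, 30, 200), np.abs(r.normal(0.01, 0.01, 200)) + 1e-6)
        curve = cea.ceac(c, wtp_grid=tuple(range(0, 50001, 5000)))
        assert (np.diff(curve["probability"]) >= -1e-12).all()


def _enumerate_ceaf(clouds, grid, comparator="control"):
    """Loop-based frontier oracle, kept independent of the implementation."""
    rows = []
    names = [comparator] + sorted(clouds)
    b = len(next(iter(clouds.values())).delta_cost)
    for lam in grid:
        means = {comparator: 0.0}
        for a, c in clouds.items():
            means[a] = np.mean(lam * c.delta_effect - c.delta_cost)
        opt = max(names, key=lambda a: (means[a], -names.index(a)))
        wins = 0
        for r in range(b):
            vals = {comparator: 0.0}
            for a, c in clouds.items():
                vals[a] = lam * c.delta_effect[r] - c.delta_cost[r]
            if vals[opt] >= max(vals.values()):
                wins += 1
        rows.append((lam, opt, wins / b))
    return rows


class TestCeaf:
    def test_single_strategy_always_positive(self):
        clouds = {"social": _cloud([-5, -2, -8, -1], [0.01, 0.02, 0.03, 0.005])}
        f = cea.ceaf(clouds, wtp_grid=(0, 20000))
        assert (f["optimal"] == "social").all()
        assert (f["probability"] == 1.0).all()

    def test_matches_enumeration_on_toy_clouds(self):
        clouds = {
            "social": _cloud([50, -10, 30, 20], [0.01, 0.004, -0.002, 0.008]),
            "dvd": _cloud([60, 40, -5, 90], [0.002, -0.01, 0.001, 0.02]),
        }
        grid = (0.0, 2000.0, 10000.0, 30000.0)
        f = cea.ceaf(clouds, wtp_grid=grid)
        for (lam, opt, prob), row in zip(_enumerate_ceaf(clouds, grid), f.itertuples()):
            assert row.optimal == opt
            assert row.probability == pytest.approx(prob)

    def test_at_zero_wtp_cheapest_strategy_optimal(self):
        clouds = {
            "social": _cloud([10, 12, 8], [0.1, 0.1, 0.1]),
            "dvd": _cloud([-4, -6, -2], [-0.5, -0.5, -0.5]),
        }
        f = cea.ceaf(clouds, wtp_grid=(0.0,))
        assert f["optimal"].iloc[0] == "dvd"  # cheapest in expectation at lambda=0

    def test_mismatched_replicates_rejected(self):
        clouds = {
            "social": _cloud([1, 2], [0.1, 0.1]),
            "dvd": _cloud([1, 2, 3], [0.1, 0.1, 0.1]),
        }
        with pytest.raises(ValueError, match="mismatched"):
            cea.ceaf(clouds, wtp_grid=(0.0,))


class TestBootstrapIncrements:
    def test_zero_noise_cloud_is_degenerate(self):
        df = _two_arm(n=30, noise=0.0)
        clouds = cea.bootstrap_increments(
            [df], "y", "y", [], [], b_main=100, seed=0, ref="control"
        )
        c = clouds["social"]
        assert np.allclose(c.delta_cost, 2.0)
        assert np.allclose(c.delta_effect, 2.0)

    def test_allocation_across_imputations(self):
        df = _two_arm(n=20, noise=1.0)
        clouds = cea.bootstrap_increments(
            [df.copy() for _ in range(10)], "y", "y", [], [], b_main=105, seed=0
        )
        assert clouds["social"].b == 105  # 10x10 + remainder 5 to first datasets

    def test_cloud_mean_near_point_estimate(self):
        df = _two_arm(n=200, noise=1.0, seed=5)
        ad = cea.adjusted_difference(df, "y", ["x"], ("social", "control"))
        clouds = cea.bootstrap_increments([df], "y", "y", ["x"], ["x"], b_main=2000, seed=1)
        c = clouds["social"]
        boot_se = c.delta_cost.std(ddof=1) / np.sqrt(c.b)
        assert abs(c.delta_cost.mean() - ad.estimate) < 3 * boot_se + 1e-9


class TestBcaCi:
    def test_symmetric_replicates_collapse_to_percentile(self):
        """z0 = 0 and a = 0 reduce BCa to plain percentile bounds."""
        theta = 0.0
        reps = np.concatenate([-np.linspace(0.01, 3, 500), np.linspace(0.01, 3, 500)])
        jack = np.zeros(10)  # constant jackknife -> zero acceleration
        lo, hi = cea._bca_interval(theta, reps, jack, alpha=0.05)
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-9)
        assert hi == pytest.approx(phi, abs=1e-9)

    def test_constant_data_zero_width(self):
        df = pd.DataFrame({"v": np.ones(30), "arm": ["a", "b"] * 15})
        point, lo, hi = cea.bca_ci(df, lambda d: d["v"].mean(), b=100, seed=0)
        assert point == lo == hi == 1.0

    def test_normal_mean_matches_t_interval(self, rng):
        """Mean of N(0,1), n=200, B=1000: BCa endpoints within Monte-Carlo
        tolerance of the classical t-interval."""
        from scipy import stats

        x = rng.normal(size=200)
        df = pd.DataFrame({"v": x})
        point, lo, hi = cea.bca_ci(df, lambda d: d["v"].mean(), b=1000, seed=3, strata=None)
        se = x.std(ddof=1) / np.sqrt(200)
        tlo, thi = stats.t.interval(0.95, 199, loc=x.mean(), scale=se)
        assert lo == pytest.approx(tlo, abs=3 * se / np.sqrt(10))
        assert hi == pytest.approx(thi, abs=3 * se / np.sqrt(10))

    def test_agrees_with_scipy_bca(self, rng):
        """Independent oracle: scipy.stats.bootstrap(method='BCa')."""
        from scipy import stats

        x = rng.gamma(2.0, 10.0, 150)
        df = pd.DataFrame({"v": x})
        point, lo, hi = cea.bca_ci(df, lambda d: d["v"].mean(), b=2000, seed=5, strata=None)
        res = stats.bootstrap(
            (x,),
            np.mean,
            n_resamples=2000,
            method="BCa",
            confidence_level=0.95,
            random_state=np.random.default_rng(5),
        )
        width = hi - lo
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.15 * width)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.15 * width)

    def test_fast_coefficient_path_matches_generic(self):
        df = _two_arm(n=60, noise=1.0, seed=9)
        X = np.column_stack([np.ones(len(df)), (df["arm"] == "social").astype(float)])
        y = df["y"].to_numpy()
        codes = (df["arm"] == "social").to_numpy().astype(int)
        p1, lo1, hi1 = cea.bca_ci_coefficient(X, y, 1, codes, b=500, seed=11)

        def stat(d):
            Xs = np.column_stack([np.ones(len(d)), (d["arm"] == "social").astype(float)])
            return np.linalg.lstsq(Xs, d["y"].to_numpy(), rcond=None)[0][1]

        p2, lo2, hi2 = cea.bca_ci(df, stat, b=500, seed=11)
        assert p1 == pytest.approx(p2)
        assert lo1 == pytest.approx(lo2, abs=0.3)
        assert hi1 == pytest.approx(hi2, abs=0.3)
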
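"""Incremental cost-utility analysis engine.

Arm differences in mean costs and QALYs are estimated by multiple linear
regression of the outcome on arm indicators plus baseline covariates, with
heteroskedasticity-consistent (Huber-White sandwich, HC1 by default)
standard errors — cost data are right-skewed, so model-based OLS variances
are not trusted.  Joint uncertainty in (incremental cost, incremental QALY)
comes from a nonparametric bootstrap stratified by arm: within each of the
M imputed datasets, B/M resamples are drawn and the adjusted differences
re-estimated, and the M clouds are stacked.

Decision outputs follow standard practice: the ICER dC/dE is reported only
in the trade-off quadrant (dearer and more effective); strategies that are
cheaper and more effective dominate, dearer and less effective are
dominated, and the rare cheaper-but-less-effective case is flagged as the
south-west quadrant where the ratio means willingness to accept, not pay.
Cost-effectiveness acceptability curves (CEAC) give, per willingness-to-pay
lambda, the fraction of bootstrap replicates with positive incremental net
monetary benefit lambda*dE - dC; the acceptability frontier (CEAF) tracks
the strategy with the highest *expected* net benefit and the probability
that it attains the per-replicate maximum.

Complete-case analyses use bias-corrected and accelerated (BCa) bootstrap
intervals, with the bias correction from the replicate distribution and the
acceleration from a jackknife.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._design import design_matrix
from .impute import ImputedDatasets, PooledEstimate, pool_rubin

__all__ = [
    "AnalysisConfig",
    "AdjustedDifference",
    "BootstrapCloud",
    "IncrementalResult",
    "adjusted_difference",
    "pooled_adjusted_difference",
    "bootstrap_increments",
    "icer",
    "nmb",
    "ceac",
    "ceaf",
    "bca_ci",
]

Z95 = 1.959963984540054

#: Default willingness-to-pay grid (GBP/QALY), bracketing the UK decision
#: band of 20,000-30,000 per QALY.
DEFAULT_WTP_GRID = tuple(range(0, 50_001, 500))


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the incremental analysis."""

    perspective: str = "nhs_pss"
    timepoint: str = "12m"
    cost_covariates: tuple[str, ...] = (
        "age",
        "bmi_class",
        "menopause_status",
        "symptom_freq_0",
    )
    qaly_covariates: tuple[str, ...] = (
        "age",
        "bmi_class",
        "menopause_status",
        "symptom_freq_0",
        "utility_0",
        "inpatient_stays",
        "employment",
        "antidep_change",
        "symptom_change",
    )
    b_main: int = 5000
    b_bca: int = 1000
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    hc_flavour: str = "HC1"
    stepwise_bootstrap: bool = True
    reselect_per_replicate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b_main < 100:
            raise ValueError("b_main must be >= 100")
        g = np.asarray(self.wtp_grid, dtype=float)
        if np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("WTP grid must be non-negative and strictly increasing")
        if self.hc_flavour not in ("HC0", "HC1", "HC2", "HC3"):
            raise ValueError(f"unknown sandwich flavour {self.hc_flavour!r}")


@dataclass(frozen=True)
class AdjustedDifference:
    """Covariate-adjusted arm difference with robust (sandwich) uncertainty."""

    comparison: tuple[str, str]
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class BootstrapCloud:
    """Paired (dC, dE) bootstrap draws for one comparison vs the comparator."""

    comparison: tuple[str, str]
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int
    stratified_by: str = "arm"

    @property
    def b(self) -> int:
        return len(self.delta_cost)


@dataclass(frozen=True)
class IncrementalResult:
    """Point decision summary for one comparison."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str  # trade-off | dominant | dominated | southwest | undefined


def _arm_design(
    df: pd.DataFrame,
    covariates,
    arm_col: str,
    ref: str,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with arm indicators (reference = ref) first."""
    arms = [a for a in pd.unique(df[arm_col]) if a != ref]
    arms.sort()
    blocks = [np.ones((len(df), 1))]
    names = ["const"]
    for a in arms:
        blocks.append((df[arm_col] == a).to_numpy(dtype=float)[:, None])
        names.append(f"{arm_col}[{a}]")
    Xc, cnames, _ = design_matrix(df, list(covariates))
    blocks.append(Xc[:, 1:])  # drop the duplicate intercept
    names.extend(cnames[1:])
    return np.hstack(blocks), names


def adjusted_difference(
    table: pd.DataFrame,
    outcome: str,
    covariates,
    comparison: tuple[str, str],
    arm_col: str = "arm",
    hc_flavour: str = "HC1",
) -> AdjustedDifference:
    """Adjusted mean difference (treatment - comparator) for one outcome.

    Fits outcome ~ arm + covariates on the two arms of ``comparison`` by
    OLS and reads the arm coefficient; the SE is the Huber-White sandwich
    of the requested flavour and the CI is estimate +/- 1.96 SE.
    """
    arm, ref = comparison
    present = set(table[arm_col])
    for a in comparison:
        if a not in present:
            raise ValueError(f"arm {a!r} absent from the table")
    sub = table.loc[table[arm_col].isin(comparison)].reset_index(drop=True)
    y = sub[outcome].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError(f"outcome {outcome!r} has missing values; impute or drop first")
    X, names = _arm_design(sub, covariates, arm_col, ref)
    res = sm.OLS(y, X).fit(cov_type=hc_flavour)
    j = names.index(f"{arm_col}[{arm}]")
    est = float(res.params[j])
    se = float(res.bse[j])
    return AdjustedDifference(
        comparison=comparison,
        outcome=outcome,
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
    )


def pooled_adjusted_difference(
    imputed: ImputedDatasets,
    outcome: str,
    covariates,
    comparison: tuple[str, str],
    arm_col: str = "arm",
    hc_flavour: str = "HC1",
) -> tuple[PooledEstimate, AdjustedDifference]:
    """Rubin-pooled adjusted difference across the M imputed datasets."""
    ests, variances = [], []
    for d in imputed.datasets:
        ad = adjusted_difference(d, outcome, covariates, comparison, arm_col, hc_flavour)
        ests.append(ad.estimate)
        variances.append(ad.se**2)
    pooled = pool_rubin(ests, variances)
    return pooled, AdjustedDifference(
        comparison=comparison,
        outcome=outcome,
        estimate=pooled.point,
        se=float(np.sqrt(pooled.total)),
        ci_low=pooled.ci_low,
        ci_high=pooled.ci_high,
    )


def _stratified_indices(arm_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample row indices within each arm, preserving arm sizes."""
    out = []
    for a in np.unique(arm_codes):
        rows = np.flatnonzero(arm_codes == a)
        out.append(rows[rng.integers(len(rows), size=len(rows))])
    return np.concatenate(out)


def bootstrap_increments(
    imputed: ImputedDatasets | list[pd.DataFrame],
    cost_col: str,
    effect_col: str,
    cost_covariates,
    effect_covariates,
    b_main: int = 5000,
    seed: int = 0,
    arm_col: str = "arm",
    ref: str = "control",
) -> dict[str, BootstrapCloud]:
    """Joint bootstrap distribution of adjusted (dC, dE) per strategy.

    Draws ``b_main`` arm-stratified resamples spread evenly over the M
    imputed datasets (any remainder goes to the first datasets) and refits
    both outcome regressions on each, so cost and QALY increments stay
    paired within a replicate.  All strategies share resamples, as the
    frontier construction requires.
    """
    datasets = imputed.datasets if isinstance(imputed, ImputedDatasets) else imputed
    m = len(datasets)
    per = [b_main // m + (1 if i < b_main % m else 0) for i in range(m)]
    if b_main % m:
        logging.getLogger(__name__).info(
            "b_main=%d not divisible by m=%d; %d extra replicates assigned to the first datasets",
            b_main,
            m,
            b_main % m,
        )
    arms = sorted(a for a in pd.unique(datasets[0][arm_col]) if a != ref)
    draws_c = {a: [] for a in arms}
    draws_e = {a: [] for a in arms}
    child_seeds = np.random.SeedSequence(seed).spawn(m)
    for d, b, seq in zip(datasets, per, child_seeds):
        rng = np.random.default_rng(seq)
        codes = pd.Categorical(d[arm_col]).codes
        Xc, names_c = _arm_design(d, cost_covariates, arm_col, ref)
        Xe, names_e = _arm_design(d, effect_covariates, arm_col, ref)
        yc = d[cost_col].to_numpy(dtype=float)
        ye = d[effect_col].to_numpy(dtype=float)
        jc = {a: names_c.index(f"{arm_col}[{a}]") for a in arms}
        je = {a: names_e.index(f"{arm_col}[{a}]") for a in arms}
        for _ in range(b):
            idx = _stratified_indices(codes, rng)
            bc = np.linalg.lstsq(Xc[idx], yc[idx], rcond=None)[0]
            be = np.linalg.lstsq(Xe[idx], ye[idx], rcond=None)[0]
            for a in arms:
                draws_c[a].append(bc[jc[a]])
                draws_e[a].append(be[je[a]])
    return {
        a: BootstrapCloud(
            comparison=(a, ref),
            delta_cost=np.asarray(draws_c[a]),
            delta_effect=np.asarray(draws_e[a]),
            seed=seed,
        )
        for a in arms
    }


def icer(delta_cost: float, delta_effect: float) -> IncrementalResult:
    """Classify an incremental (cost, effect) pair.

    Trade-off quadrant (dearer, more effective): ICER = dC/dE.  Cheaper and
    more effective: dominant (no ratio).  Dearer and less effective:
    dominated.  Cheaper and less effective: ratio reported with a
    south-west-quadrant flag.  dE = 0: undefined.
    """
    dc, de = float(delta_cost), float(delta_effect)
    if de == 0:
        return IncrementalResult(dc, de, None, "undefined")
    if de > 0:
        if dc > 0:
            return IncrementalResult(dc, de, dc / de, "trade-off")
        return IncrementalResult(dc, de, None, "dominant")
    if dc > 0:
        return IncrementalResult(dc, de, None, "dominated")
    return IncrementalResult(dc, de, dc / de, "southwest")


def nmb(delta_cost, delta_effect, wtp) -> np.ndarray | float:
    """Net monetary benefit wtp * dE - dC (vectorises over any argument)."""
    return np.asarray(wtp, dtype=float) * np.asarray(delta_effect, dtype=float) - np.asarray(
        delta_cost, dtype=float
    )


def ceac(cloud: BootstrapCloud, wtp_grid=DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for one comparison.

    Per lambda: fraction of bootstrap replicates with lambda*dE - dC > 0.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("WTP grid is empty")
    if cloud.b == 0:
        raise ValueError("empty bootstrap cloud")
    benefit = grid[:, None] * cloud.delta_effect[None, :] - cloud.delta_cost[None, :]
    return pd.DataFrame(
        {"wtp": grid, "probability": (benefit > 0).mean(axis=1)}
    )


def ceaf(
    clouds: dict[str, BootstrapCloud],
    wtp_grid=DEFAULT_WTP_GRID,
    comparator: str = "control",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier across all strategies.

    Replicate r of every cloud must come from the same resample (a common
    seed in :func:`bootstrap_increments` guarantees this).  At each lambda
    the optimal strategy maximises the *expected* NMB over replicates, the
    comparator sitting at NMB 0; the frontier probability is the fraction
    of replicates in which that strategy attains the per-replicate maximum.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    names = sorted(clouds)
    bs = {len(c.delta_cost) for c in clouds.values()}
    if len(bs) != 1:
        raise ValueError("strategies have mismatched replicate counts")
    b = bs.pop()
    # NMB matrix per strategy: (n_wtp, B); comparator contributes zeros.
    mats = [np.zeros((len(grid), b))]
    labels = [comparator]
    for a in names:
        c = clouds[a]
        mats.append(grid[:, None] * c.delta_effect[None, :] - c.delta_cost[None, :])
        labels.append(a)
    stack = np.stack(mats)  # (n_strat, n_wtp, B)
    mean_nmb = stack.mean(axis=2)  # (n_strat, n_wtp)
    opt = mean_nmb.argmax(axis=0)  # ties: lowest index = comparator first
    best = stack.max(axis=0)  # per-replicate max NMB
    prob = np.array(
        [(stack[opt[i], i] >= best[i]).mean() for i in range(len(grid))]
    )
    return pd.DataFrame(
        {"wtp": grid, "optimal": [labels[i] for i in opt], "probability": prob}
    )


def _bca_interval(
    theta_hat: float, reps: np.ndarray, jack: np.ndarray, alpha: float
) -> tuple[float, float]:
    """BCa percentile adjustment given replicates and jackknife values."""
    b = len(reps)
    prop = np.clip(np.mean(reps < theta_hat), 1 / (2 * b), 1 - 1 / (2 * b))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])

    def adj(z):
        return stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))

    lo, hi = np.quantile(reps, [adj(z_lo), adj(z_hi)])
    return float(lo), float(hi)


def bca_ci(
    table: pd.DataFrame,
    statistic,
    b: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    strata: str | None = "arm",
) -> tuple[float, float, float]:
    """Bias-corrected and accelerated bootstrap CI for a row-resampling
    statistic.

    ``statistic(df) -> float`` is evaluated on ``b`` resamples (stratified
    by ``strata`` when given), the bias correction z0 comes from the share
    of replicates below the point estimate, and the acceleration from the
    jackknife skewness.  Returns (point, low, high); a degenerate replicate
    distribution collapses to a point interval.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta_hat = float(statistic(table))
    n = len(table)
    codes = (
        pd.Categorical(table[strata]).codes
        if strata is not None and strata in table.columns
        else np.zeros(n, dtype=int)
    )
    reps = np.empty(b)
    for i in range(b):
        idx = _stratified_indices(codes, rng)
        reps[i] = statistic(table.iloc[idx].reset_index(drop=True))
    if np.allclose(reps, reps[0]):
        return theta_hat, theta_hat, theta_hat
    jack = np.empty(n)
    for i in range(n):
        jack[i] = statistic(table.drop(table.index[i]).reset_index(drop=True))
    lo, hi = _bca_interval(theta_hat, reps, jack, alpha)
    return theta_hat, lo, hi


def bca_ci_coefficient(
    X: np.ndarray,
    y: np.ndarray,
    j: int,
    codes: np.ndarray,
    b: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """BCa interval for coefficient ``j`` of the least-squares fit of y on X.

    Fast path used by the complete-case analysis: the statistic is the
    regression coefficient, resamples are stratified by the integer strata
    ``codes``, and the jackknife is leave-one-out.  Same adjustment as
    :func:`bca_ci`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta_hat = float(np.linalg.lstsq(X, y, rcond=None)[0][j])
    n = len(y)
    reps = np.empty(b)
    for i in range(b):
        idx = _stratified_indices(codes, rng)
        reps[i] = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0][j]
    if np.allclose(reps, reps[0]):
        return theta_hat, theta_hat, theta_hat
    mask = np.ones(n, dtype=bool)
    jack = np.empty(n)
    for i in range(n):
        mask[i] = False
        jack[i] = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0][j]
        mask[i] = True
    lo, hi = _bca_interval(theta_hat, reps, jack, alpha)
    return theta_hat, lo, hi
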
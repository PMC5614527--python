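"""Multiple imputation of costs and utilities, and Rubin's-rules pooling.

Follow-up questionnaire nonresponse leaves period costs and utility scores
missing.  Working at the level of period totals (not individual resource
items), missing values are multiply imputed by chained equations with
predictive mean matching (PMM): each incomplete variable is regressed on
baseline covariates chosen by stepwise selection (retention threshold
p <= 0.30) plus the other imputable variables, regression parameters are
drawn from their posterior (normal-inverse-chi-squared under the usual
noninformative prior), and every missing cell receives the *observed* value
of a donor whose predicted mean is among the k nearest.  PMM therefore never
fabricates values outside the observed support — imputed utilities stay in
[0, 1] and imputed costs stay non-negative automatically.

The M completed datasets are analysed individually downstream and combined
with Rubin's rules: total variance T = W + (1 + 1/M) B, where W is the mean
within-imputation variance and B the between-imputation variance of the
point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._design import design_matrix

__all__ = [
    "ImputationConfig",
    "ImputedDatasets",
    "PooledEstimate",
    "select_covariates",
    "mice_pmm",
    "pool_rubin",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the chained-equations run.

    m: number of completed datasets (default 10).
    k: PMM donor-pool size (default 5, the conventional choice).
    p_enter: stepwise retention threshold for imputation-model covariates.
    iterations: chained-equation cycles per dataset.
    candidates: baseline covariates offered to the stepwise selection.
    imputable: variables eligible for imputation (period costs, utilities).
    """

    m: int = 10
    k: int = 5
    p_enter: float = 0.30
    iterations: int = 10
    candidates: tuple[str, ...] = (
        "age",
        "bmi_class",
        "menopause_status",
        "antidep_hrt_use",
        "symptom_freq_0",
        "arm",
        "utility_0",
    )
    imputable: tuple[str, ...] = (
        "cost_nhs_p1",
        "cost_nhs_p2",
        "cost_soc_p1",
        "cost_soc_p2",
        "utility_6",
        "utility_12",
    )
    direction: str = "backward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("at least 2 imputations are required")
        if not 0 < self.p_enter < 1:
            raise ValueError("p_enter must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("donor pool k must be >= 1")
        if self.direction not in ("backward", "forward"):
            raise ValueError(f"unknown stepwise direction {self.direction!r}")


@dataclass
class ImputedDatasets:
    """M completed copies of the trial table plus provenance."""

    datasets: list[pd.DataFrame]
    models: dict[str, list[str]]
    config: ImputationConfig
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of M estimates."""

    point: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    m: int


def _fit_ss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares fit returning (beta, residual sum of squares, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def _term_f_pvalue(
    df: pd.DataFrame, y: np.ndarray, terms: list[str], drop: str
) -> float:
    """Partial F-test p-value for one term against the model with all terms."""
    X_full, _, _ = design_matrix(df, terms)
    X_red, _, _ = design_matrix(df, [t for t in terms if t != drop])
    _, ssr_full, rank_full = _fit_ss(X_full, y)
    _, ssr_red, rank_red = _fit_ss(X_red, y)
    q = rank_full - rank_red
    dfe = len(y) - rank_full
    if q <= 0 or dfe <= 0:
        return 1.0  # term adds nothing estimable
    if ssr_full <= 0:
        return 0.0  # perfect fit: term (with the rest) explains everything
    f = ((ssr_red - ssr_full) / q) / (ssr_full / dfe)
    return float(stats.f.sf(max(f, 0.0), q, dfe))


def _drop_collinear(
    df: pd.DataFrame, candidates: list[str], forced: list[str]
) -> list[str]:
    """Keep candidates, in order, that add rank to the (forced) design."""
    kept: list[str] = []
    X0, _, _ = design_matrix(df, forced)
    rank = np.linalg.matrix_rank(X0)
    for c in candidates:
        X, _, _ = design_matrix(df, forced + kept + [c])
        r = np.linalg.matrix_rank(X)
        if r > rank:
            kept.append(c)
            rank = r
    return kept


def select_covariates(
    table: pd.DataFrame,
    target: str,
    candidates: list[str] | tuple[str, ...],
    p_enter: float = 0.30,
    direction: str = "backward",
    forced: list[str] | tuple[str, ...] = (),
) -> list[str]:
    """Stepwise covariate selection for one regression target.

    Backward mode starts from all candidates and repeatedly removes the
    term with the largest partial-F p-value until every remaining term has
    p <= ``p_enter``.  Forward mode adds the best candidate while its entry
    p-value is <= ``p_enter``.  ``forced`` terms are always in the model
    and never dropped (e.g. the randomised-arm indicator).  Exactly
    collinear candidates are resolved before selection: the earlier
    candidate in the supplied order wins.  Rows with a missing target are
    ignored.  Returns the retained candidates in candidate order (possibly
    empty: model with only the intercept and any forced terms).
    """
    data = table.loc[table[target].notna()].reset_index(drop=True)
    if data.empty:
        raise ValueError(f"target {target!r} has no observed rows")
    forced = list(forced)
    usable = _drop_collinear(data, list(candidates), forced)
    if not usable:
        raise ValueError("all candidate covariates are degenerate (constant)")
    y = data[target].to_numpy(dtype=float)

    if direction == "backward":
        terms = list(usable)
        while terms:
            pvals = [
                (_term_f_pvalue(data, y, forced + terms, t), i)
                for i, t in enumerate(terms)
            ]
            # worst term = largest p; ties broken toward the later candidate
            worst_p, worst_i = max(pvals, key=lambda pi: (pi[0], pi[1]))
            if worst_p > p_enter:
                terms.pop(worst_i)
            else:
                break
        return terms
    if direction == "forward":
        terms: list[str] = []
        remaining = list(usable)
        while remaining:
            pvals = [
                (_term_f_pvalue(data, y, forced + terms + [c], c), i)
                for i, c in enumerate(remaining)
            ]
            best_p, best_i = min(pvals, key=lambda pi: (pi[0], pi[1]))
            if best_p <= p_enter:
                terms.append(remaining.pop(best_i))
            else:
                break
        return [t for t in usable if t in terms]
    raise ValueError(f"unknown stepwise direction {direction!r}")


def _pmm_draw(
    X: np.ndarray,
    y_obs: np.ndarray,
    obs: np.ndarray,
    mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Bayesian PMM draw: posterior parameter draw, then donor matching.

    Predicted means for observed rows use the posterior mode, those for
    missing rows use the parameter draw (type-1 matching); each missing row
    receives the observed y of one of its k nearest donors.
    """
    Xo, Xm = X[obs], X[mis]
    beta_hat, ssr, rank = _fit_ss(Xo, y_obs)
    dfe = max(len(y_obs) - rank, 1)
    sigma2 = ssr / stats.chi2.rvs(dfe, random_state=rng) if ssr > 0 else 0.0
    V = np.linalg.pinv(Xo.T @ Xo)
    w, Q = np.linalg.eigh(V)
    L = Q * np.sqrt(np.clip(w, 0.0, None))
    beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(len(beta_hat)))
    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_star
    out = np.empty(len(pred_mis))
    kk = min(k, len(y_obs))
    for i, p in enumerate(pred_mis):
        d = np.abs(pred_obs - p)
        donors = np.argpartition(d, kk - 1)[:kk]
        out[i] = y_obs[donors[rng.integers(kk)]]
    return out


def mice_pmm(table: pd.DataFrame, config: ImputationConfig) -> ImputedDatasets:
    """Chained-equations multiple imputation with predictive mean matching.

    Imputation models: each imputable variable on its stepwise-selected
    baseline covariates plus the other imputable variables (current filled
    values), cycling ``config.iterations`` times per dataset.  Observed
    cells are never modified; every imputed cell holds an observed donor
    value of the same variable.  Fully reproducible under ``config.seed``.
    """
    imputable = [v for v in config.imputable if v in table.columns]
    incomplete = [v for v in imputable if table[v].isna().any()]
    for v in incomplete:
        n_obs = int(table[v].notna().sum())
        if n_obs == 0:
            raise ValueError(f"variable {v!r} has no observed values to donate")
        if n_obs < config.k:
            raise ValueError(
                f"variable {v!r} has only {n_obs} observed donors, fewer than k={config.k}"
            )

    if not incomplete:
        return ImputedDatasets(
            datasets=[table.copy() for _ in range(config.m)],
            models={},
            config=config,
            seed=config.seed,
        )

    models = {
        v: select_covariates(
            table, v, config.candidates, config.p_enter, config.direction
        )
        for v in incomplete
    }
    obs_masks = {v: table[v].notna().to_numpy() for v in incomplete}
    y_obs_store = {v: table.loc[obs_masks[v], v].to_numpy(dtype=float) for v in incomplete}

    child_seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    datasets: list[pd.DataFrame] = []
    for seq in child_seeds:
        rng = np.random.default_rng(seq)
        work = table.copy()
        # initial fill: random observed donor per missing cell
        for v in incomplete:
            mis = ~obs_masks[v]
            work.loc[mis, v] = rng.choice(y_obs_store[v], size=int(mis.sum()))
        for _ in range(config.iterations):
            for v in incomplete:
                others = [u for u in imputable if u != v]
                Xbase, _, _ = design_matrix(work, models[v])
                Xoth = work[others].to_numpy(dtype=float) if others else np.empty((len(work), 0))
                X = np.hstack([Xbase, Xoth])
                work.loc[~obs_masks[v], v] = _pmm_draw(
                    X, y_obs_store[v], obs_masks[v], ~obs_masks[v], config.k, rng
                )
        datasets.append(work)
    return ImputedDatasets(datasets=datasets, models=models, config=config, seed=config.seed)


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine M point estimates and their variances by Rubin's rules.

    point = mean of estimates; W = mean variance; B = sample variance of
    estimates; T = W + (1 + 1/M) B.  Degrees of freedom follow the classic
    large-sample formula (M - 1)(1 + W / ((1 + 1/M) B))^2, infinite when
    B = 0.  The 95% CI uses normal quantiles on sqrt(T).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rules require at least 2 imputations")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1 + 1 / m) * between
    if between > 0:
        df = (m - 1) * (1 + within / ((1 + 1 / m) * between)) ** 2
    else:
        df = float("inf")
    half = 1.959963984540054 * np.sqrt(total)
    return PooledEstimate(
        point=point,
        within=within,
        between=between,
        total=total,
        df=df,
        ci_low=point - half,
        ci_high=point + half,
        m=m,
    )
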
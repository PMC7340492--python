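"""Trial-level statistics: factorial ANOVA, yield correlations, stepwise models.

Operates on a tidy trial table (one row per plot: plot_id, tillage,
density, hybrid, rep, grain_yield, plus any trait columns).  Three stages:

* two-way fixed-effects factorial ANOVA per trait (Type-II sums of squares
  via explicit model comparison, so balanced and mildly unbalanced tables
  are both handled), with cell means +/- standard errors and significance
  stars;
* Pearson correlations of traits against grain yield within treatment
  subsets (each tillage level, each density level, their four combinations,
  and the whole trial), pairwise-complete;
* forward stepwise multiple linear regression of grain yield on candidate
  traits with partial-F entry at alpha = 0.05 and a cap of four predictors,
  reporting R-squared, residual standard error and each predictor's
  incremental variance portion.

Missing values: pairwise deletion per correlation, listwise per regression.
No multiple-testing correction is applied by default (a Benjamini-Hochberg
option exists on the correlation table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "RegressionResult",
    "significance_stars",
    "factorial_anova",
    "yield_correlations",
    "stepwise_yield_model",
]

logger = logging.getLogger(__name__)

#: p-value thresholds for *, **, *** as used in agronomy trial tables
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    for thr, stars in STAR_LEVELS:
        if p < thr:
            return stars
    return ""


@dataclass(frozen=True)
class AnovaResult:
    """Factorial ANOVA output: per-effect table plus cell means."""

    trait: str
    effects: pd.DataFrame  # index: effect; columns: ss, df, F, p, stars
    cell_means: pd.DataFrame  # columns: effect, level, mean, sem, n
    residual_ss: float
    residual_df: int

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df


def _dummies(df: pd.DataFrame, factor: str) -> np.ndarray:
    """Treatment-coded dummies (first level dropped), levels sorted."""
    levels = sorted(df[factor].unique())
    return np.column_stack([(df[factor] == lv).to_numpy(float) for lv in levels[1:]])


def _rss(y: np.ndarray, x_blocks: list[np.ndarray]) -> tuple[float, int]:
    """Residual sum of squares and model rank of y ~ 1 + blocks."""
    x = np.column_stack([np.ones(len(y)), *[b for b in x_blocks if b.size]])
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def factorial_anova(
    table: pd.DataFrame,
    trait: str,
    factors: tuple[str, str] = ("tillage", "density"),
    interaction: bool = True,
) -> AnovaResult:
    """Two-way fixed-effects factorial ANOVA of one trait.

    Type-II sums of squares: each main effect is tested against the model
    with the other main effect (its SS is the RSS drop when it enters),
    the interaction against the additive model; F uses the full-model
    residual mean square.  Requires >= 2 levels per factor, every factor
    cell non-empty and >= 2 replicates per cell.
    """
    fa, fb = factors
    df = table.dropna(subset=[trait, fa, fb])
    if df.empty:
        raise ValueError(f"no complete observations for trait {trait!r}")
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    counts = df.groupby([fa, fb], observed=True).size()
    for a in sorted(df[fa].unique()):
        for b in sorted(df[fb].unique()):
            n_cell = counts.get((a, b), 0)
            if n_cell == 0:
                raise ValueError(f"empty design cell ({fa}={a}, {fb}={b})")
            if n_cell < 2:
                raise ValueError(f"cell ({fa}={a}, {fb}={b}) has fewer than 2 replicates")

    y = df[trait].to_numpy(float)
    da, db = _dummies(df, fa), _dummies(df, fb)
    dab = np.column_stack([da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])])

    rss_a_only, _ = _rss(y, [da])
    rss_b_only, _ = _rss(y, [db])
    rss_add, rank_add = _rss(y, [da, db])
    if interaction:
        rss_full, rank_full = _rss(y, [da, db, dab])
    else:
        rss_full, rank_full = rss_add, rank_add
    n = len(y)
    resid_df = n - rank_full
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / resid_df

    rows = {}
    rows[fa] = (rss_b_only - rss_add, da.shape[1])
    rows[fb] = (rss_a_only - rss_add, db.shape[1])
    if interaction:
        rows[f"{fa}:{fb}"] = (rss_add - rss_full, dab.shape[1])

    eff = []
    for name, (ss, dof) in rows.items():
        ss = max(ss, 0.0)
        f_stat = (ss / dof) / mse if mse > 0 else np.inf
        p = float(stats.f.sf(f_stat, dof, resid_df))
        eff.append((name, ss, dof, f_stat, p, significance_stars(p)))
    effects = pd.DataFrame(eff, columns=["effect", "ss", "df", "F", "p", "stars"]).set_index("effect")

    means = []
    groupings = [(fa, [fa]), (fb, [fb]), (f"{fa}:{fb}", [fa, fb])]
    for name, cols in groupings:
        g = df.groupby(cols, observed=True)[trait]
        for level, grp in g:
            level_str = level if isinstance(level, str) else ":".join(map(str, level))
            means.append((name, level_str, grp.mean(), grp.sem(), len(grp)))
    cell_means = pd.DataFrame(means, columns=["effect", "level", "mean", "sem", "n"])

    return AnovaResult(trait=trait, effects=effects, cell_means=cell_means, residual_ss=rss_full, residual_df=resid_df)


def default_subsets(table: pd.DataFrame) -> dict[str, pd.Series]:
    """Treatment subsets used throughout the trial reports.

    Whole trial, each tillage level, each density level, and the four
    tillage x density combinations.
    """
    subsets: dict[str, pd.Series] = {"all": pd.Series(True, index=table.index)}
    for t in sorted(table["tillage"].unique()):
        subsets[t] = table["tillage"] == t
    for d in sorted(table["density"].unique()):
        subsets[d] = table["density"] == d
    for t in sorted(table["tillage"].unique()):
        for d in sorted(table["density"].unique()):
            subsets[f"{t}*{d}"] = (table["tillage"] == t) & (table["density"] == d)
    return subsets


def yield_correlations(
    table: pd.DataFrame,
    traits: list[str],
    response: str = "grain_yield",
    subsets: dict[str, pd.Series] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Pearson correlations of traits against grain yield per subset.

    Returns a tidy frame (subset, trait, n, r, p, stars); pairwise-complete
    observations; a subset with fewer than 3 complete pairs or a constant
    trait yields a missing r (logged).  ``bh_adjust`` adds a
    Benjamini-Hochberg adjusted p column (off by default to match the
    conventional presentation of trial correlation tables).
    """
    if subsets is None:
        subsets = default_subsets(table)
    rows = []
    for name, mask in subsets.items():
        sub = table[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
        for trait in traits:
            pair = sub[[trait, response]].dropna()
            n = len(pair)
            if n < 3 or pair[trait].nunique() == 1 or pair[response].nunique() == 1:
                logger.warning("subset %s, trait %s: %d pairs or constant values; r omitted", name, trait, n)
                rows.append((name, trait, n, np.nan, np.nan, ""))
                continue
            r, p = stats.pearsonr(pair[trait], pair[response])
            rows.append((name, trait, n, float(r), float(p), significance_stars(p)))
    out = pd.DataFrame(rows, columns=["subset", "trait", "n", "r", "p", "stars"])
    if bh_adjust:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


@dataclass(frozen=True)
class RegressionResult:
    """Forward stepwise regression output."""

    selected_predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    rse: float
    p_value: float
    variance_portions: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        yhat = np.full(len(table), self.coefficients.get("intercept", np.nan))
        for name in self.selected_predictors:
            yhat = yhat + self.coefficients[name] * table[name].to_numpy(float)
        return yhat


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, int]:
    """beta, RSS, rank for y ~ x (x includes the intercept column)."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid), int(rank)


def stepwise_yield_model(
    table: pd.DataFrame,
    candidate_traits: list[str],
    response: str = "grain_yield",
    alpha_enter: float = 0.05,
    max_predictors: int = 4,
    cond_threshold: float = 1e8,
) -> RegressionResult:
    """Forward stepwise multiple linear regression of grain yield.

    Starting from the intercept-only model, each step adds the candidate
    that minimizes the residual sum of squares, provided its partial-F
    entry p-value is below ``alpha_enter``; selection stops when no
    candidate qualifies or ``max_predictors`` have entered.  Candidates
    whose entry makes the design matrix rank-deficient or ill-conditioned
    (condition number above ``cond_threshold``) are skipped with a warning.
    Raw (unstandardized) coefficients are reported; the variance portion of
    each predictor is its incremental R-squared at entry, so the portions
    sum to the final model R-squared.
    """
    cols = [response] + list(candidate_traits)
    df = table[cols].dropna()  # listwise deletion
    n = len(df)
    if n <= len(candidate_traits) + 1:
        logger.warning("only %d complete rows for %d candidates; selection may stop early", n, len(candidate_traits))
    y = df[response].to_numpy(float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("response is constant; no model can be fitted")

    selected: list[str] = []
    portions: dict[str, float] = {}
    rss_current = tss
    x_current = np.ones((n, 1))

    while len(selected) < max_predictors:
        if rss_current <= 1e-12 * tss:  # numerically perfect fit; nothing left to explain
            break
        best = None
        p_model = x_current.shape[1]
        df_resid_new = n - (p_model + 1)
        if df_resid_new <= 0:
            break
        for cand in candidate_traits:
            if cand in selected:
                continue
            xc = df[cand].to_numpy(float)
            x_new = np.column_stack([x_current, xc])
            # guard against collinearity on the standardized augmented matrix
            x_std = x_new.copy()
            sds = x_std[:, 1:].std(axis=0)
            if (sds == 0).any():
                logger.warning("candidate %s is constant; skipped", cand)
                continue
            x_std[:, 1:] = (x_std[:, 1:] - x_std[:, 1:].mean(axis=0)) / sds
            if np.linalg.cond(x_std) > cond_threshold:
                logger.warning("candidate %s is collinear with the current model; skipped", cand)
                continue
            _, rss_new, rank = _ols(y, x_new)
            if rank < x_new.shape[1]:
                logger.warning("candidate %s makes the model rank-deficient; skipped", cand)
                continue
            if best is None or rss_new < best[1]:
                best = (cand, rss_new)
        if best is None:
            break
        cand, rss_new = best
        f_stat = (rss_current - rss_new) / (rss_new / df_resid_new) if rss_new > 0 else np.inf
        p_enter = float(stats.f.sf(f_stat, 1, df_resid_new))
        if p_enter >= alpha_enter:
            break
        selected.append(cand)
        portions[cand] = (rss_current - rss_new) / tss
        rss_current = rss_new
        x_current = np.column_stack([x_current, df[cand].to_numpy(float)])

    if not selected:
        return RegressionResult([], {"intercept": float(y.mean())}, float("nan"), float("nan"), float("nan"), {}, n)

    beta, rss, _ = _ols(y, x_current)
    k = len(selected)
    r2 = 1.0 - rss / tss
    df_resid = n - k - 1
    rse = float(np.sqrt(rss / df_resid))
    f_overall = ((tss - rss) / k) / (rss / df_resid)
    p_overall = float(stats.f.sf(f_overall, k, df_resid))
    coefs = {"intercept": float(beta[0])}
    coefs.update({name: float(b) for name, b in zip(selected, beta[1:])})
    return RegressionResult(selected, coefs, float(r2), rse, p_overall, portions, n)
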
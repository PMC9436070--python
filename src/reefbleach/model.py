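"""Weighted drivers model of square-root percent bleached.

The response is sqrt(% bleached) per cluster x depth-bin cell; predictors
are the standardized drivers plus two families of candidate two-way
interactions — acute thermal stress x each other driver, and taxonomic
susceptibility x each other driver — reflecting the hypothesis that other
drivers modify the bleaching response to heat stress and to assemblage
susceptibility.  Cells are weighted by the inverse-SE analysis weights.

Model selection is greedy backward elimination under BIC with marginality
enforced: a main effect is never dropped while one of its interactions is
retained.  BIC here is the weighted-least-squares convention

    BIC = n * log(RSS_w / n) + k * log(n),   RSS_w = sum_i w_i e_i^2

with k the number of regression coefficients; conventions differ, so this
one is fixed and stated.

Also provides the weighted one-way ANOVA + Tukey HSD used for spatial
contrasts, the weighted random-intercept mixed model with likelihood-ratio
tests used for the MHI temporal comparison, and the weighted two-way ANOVA
used for the NWHI temporal comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

logger = logging.getLogger(__name__)

INTERCEPT = "Intercept"
#: drivers whose interactions with everything else are candidate terms
DEFAULT_INTERACTION_ANCHORS = ("acute_dhw", "bs_score")


def interaction_name(a: str, b: str) -> str:
    """Canonical (alphabetical) name for a two-way interaction term."""
    lo, hi = sorted((a, b))
    return f"{lo}:{hi}"


def term_parents(term: str) -> "tuple[str, ...]":
    return tuple(term.split(":")) if ":" in term else ()


def candidate_terms(
    drivers: "list[str]", anchors: "tuple[str, ...]" = DEFAULT_INTERACTION_ANCHORS
) -> "list[str]":
    """Full candidate term list: intercept, all mains, anchor interactions."""
    terms = [INTERCEPT] + sorted(drivers)
    inters = set()
    for a in anchors:
        if a not in drivers:
            continue
        for d in drivers:
            if d != a:
                inters.add(interaction_name(a, d))
    return terms + sorted(inters)


def build_design(data: pd.DataFrame, terms: "list[str]") -> pd.DataFrame:
    """Design matrix columns for a term list over standardized drivers."""
    cols = {}
    for t in terms:
        if t == INTERCEPT:
            cols[t] = np.ones(len(data))
        elif ":" in t:
            a, b = t.split(":")
            cols[t] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
        else:
            cols[t] = data[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class ModelSpec:
    """Candidate model: response column, drivers, interaction anchors, weights."""

    response: str = "sqrt_pct_bleached"
    drivers: "list[str]" = field(default_factory=list)
    anchors: "tuple[str, ...]" = DEFAULT_INTERACTION_ANCHORS
    weight_col: str = "weight"

    def terms(self) -> "list[str]":
        return candidate_terms(self.drivers, self.anchors)


@dataclass
class FittedModel:
    """A weighted linear fit with its term list and diagnostics."""

    terms: "list[str]"
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    bic: float
    adj_r2: float
    resid: np.ndarray
    fitted: np.ndarray
    weights: np.ndarray
    loglik: float
    registry: object = None  # optional TransformRegistry for back-mapping

    def predict_sqrt(self, rows: pd.DataFrame) -> np.ndarray:
        """Linear prediction on the sqrt-% scale for standardized rows."""
        needed = set(itertools.chain.from_iterable(
            term_parents(t) or ((t,) if t != INTERCEPT else ()) for t in self.terms
        ))
        missing = needed - set(rows.columns)
        if missing:
            raise KeyError(f"prediction rows lack driver columns: {sorted(missing)}")
        X = build_design(rows, self.terms)
        return X.to_numpy() @ self.params.to_numpy()

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params.values,
                "se": self.bse.values,
                "t": self.tvalues.values,
                "p": self.pvalues.values,
            }
        )


def wls_bic(n: int, weighted_rss: float, k: int) -> float:
    return n * np.log(weighted_rss / n) + k * np.log(n)


def wls_fit(
    design: pd.DataFrame,
    response: np.ndarray,
    weights: np.ndarray,
    registry: object = None,
) -> FittedModel:
    """Weighted least squares minimising sum_i w_i (y_i - x_i beta)^2.

    Rejects rank-deficient designs, naming the aliased columns found by
    pivoted QR.  BIC uses the weighted-RSS convention defined above with
    effective sample size = number of rows.
    """
    X = design.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    Xw = np.sqrt(w)[:, None] * X
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(Xw, pivoting=True)
        aliased = [design.columns[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; aliased terms: {sorted(aliased)}")
    res = sm.WLS(y, X, weights=w).fit()
    weighted_rss = float(np.sum(w * res.resid**2))
    k = X.shape[1]
    n = len(y)
    names = list(design.columns)
    return FittedModel(
        terms=names,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        n=n,
        bic=wls_bic(n, weighted_rss, k),
        adj_r2=float(res.rsquared_adj),
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        weights=w,
        loglik=float(res.llf),
        registry=registry,
    )


def fit_terms(
    data: pd.DataFrame,
    terms: "list[str]",
    response: str,
    weight_col: str = "weight",
    registry: object = None,
) -> FittedModel:
    design = build_design(data, terms)
    return wls_fit(design, data[response].to_numpy(), data[weight_col].to_numpy(), registry)


def _eligible_for_removal(terms: "list[str]") -> "list[str]":
    """Terms removable without violating marginality (intercept never leaves)."""
    protected = {INTERCEPT}
    for t in terms:
        protected.update(term_parents(t))
    return [t for t in terms if t not in protected]


def stepwise_bic(
    spec: ModelSpec,
    data: pd.DataFrame,
    registry: object = None,
) -> FittedModel:
    """Greedy backward elimination from the full candidate model under BIC.

    At each step the single eligible term whose removal most lowers BIC is
    dropped (eligible = not the intercept and not a parent of a retained
    interaction); elimination stops when no removal lowers BIC.  Ties break
    to the alphabetically first term, making the search deterministic.
    """
    terms = spec.terms()
    current = fit_terms(data, terms, spec.response, spec.weight_col, registry)
    while True:
        candidates = _eligible_for_removal(current.terms)
        if not candidates:
            break
        best_term = None
        best_fit = None
        for t in sorted(candidates):
            trial_terms = [x for x in current.terms if x != t]
            trial = fit_terms(data, trial_terms, spec.response, spec.weight_col, registry)
            if best_fit is None or trial.bic < best_fit.bic - 1e-12:
                best_fit = trial
                best_term = t
        if best_fit is not None and best_fit.bic < current.bic - 1e-12:
            logger.debug("dropping %s (BIC %.3f -> %.3f)", best_term, current.bic, best_fit.bic)
            current = best_fit
        else:
            break
    return current


# ---------------------------------------------------------------------------
# Weighted one-way ANOVA + Tukey HSD (spatial contrasts)
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # pairwise table: group_a, group_b, diff, se, q, p


def weighted_anova_oneway(
    values: np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray,
) -> AnovaResult:
    """Weighted one-way ANOVA with Tukey HSD on weighted group means.

    The F-test comes from the weighted linear model with group indicators.
    Tukey uses each group's effective sample size sum(w) and the pooled
    weighted error variance, with studentized-range critical values — an
    approximation appropriate for inverse-variance style weights.
    Groups with fewer than two cells are dropped with a warning.
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "w": np.asarray(weights, float),
                       "g": np.asarray(groups)})
    sizes = df.groupby("g")["y"].count()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        logger.warning("dropping singleton groups from ANOVA: %s", singletons)
        df = df[~df["g"].isin(singletons)]
    levels = sorted(df["g"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups with >= 2 cells")
    n, k = len(df), len(levels)
    y, w = df["y"].to_numpy(), df["w"].to_numpy()
    dummies = pd.get_dummies(df["g"]).astype(float)[levels]
    full = sm.WLS(y, dummies.to_numpy(), weights=w).fit()
    null = sm.WLS(y, np.ones((n, 1)), weights=w).fit()
    rss_full = float(np.sum(w * full.resid**2))
    rss_null = float(np.sum(w * null.resid**2))
    df_b, df_w = k - 1, n - k
    if rss_full == 0:
        f = 0.0 if rss_null == rss_full else np.inf
    else:
        f = ((rss_null - rss_full) / df_b) / (rss_full / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0

    s2 = rss_full / df_w if df_w > 0 else np.nan  # pooled weighted error variance
    gstats = df.groupby("g").apply(
        lambda g: pd.Series({
            "mean": np.average(g["y"], weights=g["w"]),
            "eff_n": g["w"].sum(),
        }),
        include_groups=False,
    )
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = float(gstats.loc[a, "mean"] - gstats.loc[b, "mean"])
        se = float(np.sqrt(s2 / 2.0 * (1.0 / gstats.loc[a, "eff_n"] + 1.0 / gstats.loc[b, "eff_n"])))
        q = abs(diff) / se if se > 0 else 0.0
        rows.append({
            "group_a": a, "group_b": b, "diff": diff, "se": se, "q": q,
            "p": float(stats.studentized_range.sf(q, k, df_w)) if se > 0 else 1.0,
        })
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=p,
                       tukey=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Weighted random-intercept mixed model (temporal, MHI) + two-way ANOVA (NWHI)
# ---------------------------------------------------------------------------

@dataclass
class WeightedLmmFit:
    """ML fit of y = X beta + b_group + eps, b ~ N(0, s2_b), eps_i ~ N(0, s2/w_i)."""

    params: pd.Series
    sigma2: float
    sigma2_b: float
    loglik: float
    n: int
    k: int


def fit_weighted_lmm(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    weights: np.ndarray,
) -> WeightedLmmFit:
    """Maximum-likelihood random-intercept model with known observation weights.

    The marginal covariance per group g is sigma2 * diag(1/w) + sigma2_b * J;
    beta is profiled out by GLS and (log sigma2, log sigma2_b) optimized
    numerically.  sigma2_b may go to (numerically) zero, in which case the
    fit coincides with WLS.
    """
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    Xm = X.to_numpy(dtype=float)
    n, k = Xm.shape
    codes, _ = pd.factorize(pd.Series(groups), sort=True)
    idx_by_group = [np.where(codes == g)[0] for g in range(codes.max() + 1)]

    def neg2ll(theta: np.ndarray) -> float:
        s2, s2b = np.exp(theta)
        xtvx = np.zeros((k, k))
        xtvy = np.zeros(k)
        logdet = 0.0
        quad_parts = []
        for idx in idx_by_group:
            Vi = s2 * np.diag(1.0 / w[idx]) + s2b * np.ones((len(idx), len(idx)))
            sign, ld = np.linalg.slogdet(Vi)
            if sign <= 0:
                return np.inf
            logdet += ld
            Vinv = np.linalg.inv(Vi)
            xtvx += Xm[idx].T @ Vinv @ Xm[idx]
            xtvy += Xm[idx].T @ Vinv @ y[idx]
            quad_parts.append((idx, Vinv))
        beta = np.linalg.solve(xtvx, xtvy)
        quad = 0.0
        for idx, Vinv in quad_parts:
            r = y[idx] - Xm[idx] @ beta
            quad += r @ Vinv @ r
        return logdet + quad + n * np.log(2 * np.pi)

    # WLS variance as the starting point; random-effect variance starts small
    wls = sm.WLS(y, Xm, weights=w).fit()
    s2_start = max(float(np.sum(w * wls.resid**2)) / n, 1e-8)
    best = None
    for s2b_start in (s2_start, s2_start * 0.1, 1e-8):
        res = optimize.minimize(
            neg2ll,
            x0=np.log([s2_start, s2b_start]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    s2, s2b = np.exp(best.x)
    # recover beta at the optimum
    xtvx = np.zeros((k, k))
    xtvy = np.zeros(k)
    for idx in idx_by_group:
        Vi = s2 * np.diag(1.0 / w[idx]) + s2b * np.ones((len(idx), len(idx)))
        Vinv = np.linalg.inv(Vi)
        xtvx += Xm[idx].T @ Vinv @ Xm[idx]
        xtvy += Xm[idx].T @ Vinv @ y[idx]
    beta = np.linalg.solve(xtvx, xtvy)
    return WeightedLmmFit(
        params=pd.Series(beta, index=list(X.columns)),
        sigma2=float(s2),
        sigma2_b=float(s2b),
        loglik=float(-0.5 * best.fun),
        n=n,
        k=k,
    )


def _two_way_design(data: pd.DataFrame, a: str, b: str, interaction: bool) -> pd.DataFrame:
    """Treatment-coded design for a two-factor model (optionally with a:b)."""
    cols = {INTERCEPT: np.ones(len(data))}
    da = pd.get_dummies(data[a].astype(str), prefix=a, drop_first=True).astype(float)
    db = pd.get_dummies(data[b].astype(str), prefix=b, drop_first=True).astype(float)
    for c in da.columns:
        cols[c] = da[c].to_numpy()
    for c in db.columns:
        cols[c] = db[c].to_numpy()
    if interaction:
        for ca in da.columns:
            for cb in db.columns:
                cols[f"{ca}:{cb}"] = da[ca].to_numpy() * db[cb].to_numpy()
    return pd.DataFrame(cols, index=data.index)


def retain_shared_strata(
    cells: pd.DataFrame, year_col: str = "year", strata: "tuple[str, ...]" = ("zone", "depth_bin")
) -> pd.DataFrame:
    """Keep only strata (e.g. zone x depth bin) observed in every year."""
    years = sorted(cells[year_col].unique())
    key = cells[list(strata)].astype(str).agg("|".join, axis=1)
    shared = None
    for yr in years:
        present = set(key[cells[year_col] == yr])
        shared = present if shared is None else (shared & present)
    kept = cells[key.isin(shared or set())].reset_index(drop=True)
    n_dropped = len(cells) - len(kept)
    if n_dropped:
        logger.info("temporal filter dropped %d cells absent in some year", n_dropped)
    return kept


def lmm_lrt_table(
    cells: pd.DataFrame,
    response: str = "sqrt_pct_bleached",
    year_col: str = "year",
    zone_col: str = "zone",
    island_col: str = "island",
    weight_col: str = "weight",
) -> pd.DataFrame:
    """MHI temporal test: weighted LMM of year x zone with island random intercept.

    Likelihood-ratio tests compare ML fits of nested fixed-effect models:
    the interaction against the additive model, and each main effect against
    the additive model without it.  Factor levels absent in one year were
    already removed by :func:`retain_shared_strata`.
    """
    data = cells.copy()
    y = data[response].to_numpy(float)
    w = data[weight_col].to_numpy(float)
    groups = data[island_col].to_numpy()

    def _fit(interaction: bool, drop: "str | None" = None) -> WeightedLmmFit:
        X = _two_way_design(data, year_col, zone_col, interaction)
        if drop is not None:
            X = X[[c for c in X.columns if not c.startswith(f"{drop}_")]]
        return fit_weighted_lmm(y, X, groups, w)

    full = _fit(interaction=True)
    additive = _fit(interaction=False)
    no_year = _fit(interaction=False, drop=year_col)
    no_zone = _fit(interaction=False, drop=zone_col)

    def _row(effect: str, big: WeightedLmmFit, small: WeightedLmmFit) -> dict:
        chi2 = max(0.0, 2.0 * (big.loglik - small.loglik))
        df = big.k - small.k
        return {
            "effect": effect,
            "chi2": chi2,
            "df": df,
            "p": float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan,
        }

    return pd.DataFrame([
        _row(f"{year_col}:{zone_col}", full, additive),
        _row(year_col, additive, no_year),
        _row(zone_col, additive, no_zone),
    ])


def weighted_anova_twoway(
    cells: pd.DataFrame,
    response: str = "sqrt_pct_bleached",
    factor_a: str = "year",
    factor_b: str = "island",
    weight_col: str = "weight",
) -> pd.DataFrame:
    """NWHI temporal test: weighted two-way ANOVA with interaction.

    Type-II style sequential comparisons via weighted RSS of nested models.
    """
    y = cells[response].to_numpy(float)
    w = cells[weight_col].to_numpy(float)

    def _rss(design: pd.DataFrame) -> "tuple[float, int]":
        res = sm.WLS(y, design.to_numpy(), weights=w).fit()
        return float(np.sum(w * res.resid**2)), design.shape[1]

    full_X = _two_way_design(cells, factor_a, factor_b, interaction=True)
    add_X = _two_way_design(cells, factor_a, factor_b, interaction=False)
    rss_full, k_full = _rss(full_X)
    rss_add, k_add = _rss(add_X)
    df_resid = len(y) - k_full
    s2 = rss_full / df_resid
    rows = []
    # main effects: additive model vs additive minus the factor (Type II)
    for factor in (factor_a, factor_b):
        other = factor_b if factor == factor_a else factor_a
        base_X = _two_way_design(cells, factor_a, factor_b, interaction=False)
        red_X = base_X[[c for c in base_X.columns if not c.startswith(f"{factor}_")]]
        rss_red, k_red = _rss(red_X)
        df_num = k_add - k_red
        f = ((rss_red - rss_add) / df_num) / s2
        rows.append({"effect": factor, "F": float(f), "df_num": df_num,
                     "df_den": df_resid, "p": float(stats.f.sf(f, df_num, df_resid))})
    df_num = k_full - k_add
    f = ((rss_add - rss_full) / df_num) / s2
    rows.append({"effect": f"{factor_a}:{factor_b}", "F": float(f), "df_num": df_num,
                 "df_den": df_resid, "p": float(stats.f.sf(f, df_num, df_resid))})
    return pd.DataFrame(rows)
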
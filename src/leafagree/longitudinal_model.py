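"""Longitudinal genotype x time inference on leaf counts.

The model is a mixed-effects repeated-measures ANOVA with time treated as a
continuous predictor:

    count ~ 1 + time + cultivar + time:cultivar
            + (1 | plant) + (0 + time | plant)

i.e. fixed effects for time, cultivar and their interaction, and independent
random intercept and random time-slope per plant (the replicate is the
subject).  The random slope matters: biological replicates differ in their
emergence *rate*, and omitting it makes the between-cultivar slope test
anticonservative.  The interaction term is the quantity of interest — it
tests whether the longitudinal count trends of the cultivars differ.

Two inference engines serve this model.  For *balanced* tables (every plant
observed at the same time points — the native shape of the study design and
of every subsampling consensus) the classical expected-mean-squares
decomposition applies: each plant's trajectory is reduced to its least-
squares intercept and slope, and each fixed term is tested against the
matching between-plant mean square (the interaction F is the one-way ANOVA
of per-plant slopes across cultivars, exact F(k-1, N-k) under the model).
For unbalanced tables the model is fit by REML and fixed-effect F tests use
Wald statistics with Satterthwaite denominator degrees of freedom computed
from the variance-component information matrix; when both random-effect
variances collapse to zero that path falls back to an ordinary
least-squares ANCOVA.  The exact decomposition is preferred wherever it
applies because small-sample REML-Wald tests are anticonservative when the
count quantization leaves autocorrelated within-plant residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .errors import MissingDataError, ModelError

__all__ = [
    "build_count_table",
    "fit_interaction_anova",
    "growth_curves",
    "AnovaResult",
]

_VAR_FLOOR = 1e-12  # variances below this (relative to scale) count as zero


@dataclass
class AnovaResult:
    """Fixed-term inference from the longitudinal model.

    ``terms`` has one row per fixed term (time, cultivar, time:cultivar)
    with columns term, df_num, df_den, sum_sq, f_value, p_value.  The sum of
    squares is the Wald statistic scaled by the residual variance (so that
    ``sum_sq / df_num / scale = F``).  For a two-cultivar design the
    interaction is a single coefficient — the slope difference, second
    cultivar minus reference — exposed with its standard error and
    denominator df for interval estimation.
    """

    terms: pd.DataFrame
    interaction_term: str
    method: str  # "mixed" or "ols"
    scale: float
    n_obs: int
    variance_components: dict = field(default_factory=dict)
    interaction_coef: Optional[float] = None
    interaction_se: Optional[float] = None
    interaction_df: Optional[float] = None

    def _interaction_row(self) -> pd.Series:
        return self.terms.set_index("term").loc[self.interaction_term]

    @property
    def interaction_f(self) -> float:
        return float(self._interaction_row()["f_value"])

    @property
    def interaction_p(self) -> float:
        return float(self._interaction_row()["p_value"])

    def interaction_ci(self, level: float = 0.95):
        """t-based confidence interval for the interaction coefficient."""
        if self.interaction_coef is None:
            raise ModelError("interaction coefficient undefined for >2 cultivars")
        half = stats.t.ppf(0.5 + level / 2, self.interaction_df) * self.interaction_se
        return (self.interaction_coef - half, self.interaction_coef + half)

    def to_frame(self) -> pd.DataFrame:
        return self.terms.copy()


# ---------------------------------------------------------------------------
# count table construction
# ---------------------------------------------------------------------------

def build_count_table(
    counts,
    design: pd.DataFrame,
    aggregation: str = "mean_over_observers",
) -> pd.DataFrame:
    """Assemble the per-plant-per-time count table feeding the ANOVA.

    ``counts`` is an annotation frame, a list of such frames, or a consensus
    result; ``design`` must contain exactly one image per (plant, time) —
    filter to a single resolution/transform variant first.  With
    ``aggregation="single"`` each image must carry exactly one count; with
    ``"mean_over_observers"`` counts are averaged per image (un-rounded).

    Returns a frame with columns plant_id, cultivar, time_days, count.
    """
    if aggregation not in ("single", "mean_over_observers"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if isinstance(counts, (list, tuple)):
        frame = pd.concat([getattr(c, "frame", c) for c in counts], ignore_index=True)
    else:
        frame = getattr(counts, "frame", counts)
    value_col = "value" if "value" in frame.columns else "count"

    if design.duplicated(subset=["plant_id", "time_days"]).any():
        raise ModelError(
            "design has multiple images per plant and time point; filter to a "
            "single resolution/transform variant before building the table"
        )
    sub = frame[frame["image_id"].isin(set(design["image_id"]))]
    missing = sorted(set(design["image_id"]) - set(sub["image_id"]))
    if missing:
        raise MissingDataError(
            f"{len(missing)} design images have no count (e.g. {missing[:5]})",
            image_ids=missing,
        )
    per_image = sub.groupby("image_id")[value_col]
    if aggregation == "single":
        sizes = per_image.size()
        if (sizes > 1).any():
            raise ModelError(
                "aggregation='single' but some images carry multiple counts; "
                "use mean_over_observers or filter to one observer"
            )
    values = per_image.mean().rename("count")
    table = design[["image_id", "plant_id", "cultivar", "time_days"]].merge(
        values, left_on="image_id", right_index=True
    )
    return table[["plant_id", "cultivar", "time_days", "count"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# REML machinery (random intercept + independent random time slope)
# ---------------------------------------------------------------------------

def _make_blocks(y, X, t, codes):
    blocks = []
    for g in np.unique(codes):
        m = codes == g
        Z = np.column_stack([np.ones(m.sum()), t[m]])
        blocks.append((X[m], y[m], Z))
    return blocks


def _gls(theta, blocks):
    """GLS quantities at variance components theta = (v_int, v_slope, s2).

    Returns (beta, C, logdet_V, logdet_XtViX, rss_quadform) where C is the
    fixed-effects covariance (X' V^-1 X)^-1.
    """
    v_int, v_slope, s2 = theta
    G = np.diag([max(v_int, 0.0), max(v_slope, 0.0)])
    p = blocks[0][0].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    logdet = 0.0
    solves = []
    for Xg, yg, Zg in blocks:
        V = s2 * np.eye(len(yg)) + Zg @ G @ Zg.T
        cf = cho_factor(V, lower=True)
        logdet += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ViX = cho_solve(cf, Xg)
        Viy = cho_solve(cf, yg)
        XtViX += Xg.T @ ViX
        XtViy += Xg.T @ Viy
        solves.append((cf, Xg, yg))
    C = np.linalg.inv(XtViX)
    beta = C @ XtViy
    quad = 0.0
    for cf, Xg, yg in solves:
        r = yg - Xg @ beta
        quad += float(r @ cho_solve(cf, r))
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    return beta, C, logdet, logdet_XtViX, quad


def _reml_nll(theta, blocks):
    """Restricted (REML) negative log-likelihood, up to an additive constant."""
    if theta[2] <= 0 or theta[0] < 0 or theta[1] < 0:
        return np.inf
    try:
        _, _, logdet, logdet_X, quad = _gls(theta, blocks)
    except np.linalg.LinAlgError:
        return np.inf
    return 0.5 * (logdet + logdet_X + quad)


def _contrast_var(theta, blocks, L):
    """f(theta) = L C(theta) L' for a single contrast row L."""
    _, C, _, _, _ = _gls(theta, blocks)
    return float(L @ C @ L)


def _numeric_grad(fun, theta, active, rel_step=1e-4):
    g = np.zeros(active.sum())
    for j, i in enumerate(np.where(active)[0]):
        h = max(abs(theta[i]), 1e-8) * rel_step
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0 if i < 2 else 1e-12)
        actual = tp[i] - tm[i]
        g[j] = (fun(tp) - fun(tm)) / actual
    return g


def _numeric_hessian(fun, theta, active, rel_step=1e-4):
    idx = np.where(active)[0]
    k = len(idx)
    H = np.zeros((k, k))
    h = np.array([max(abs(theta[i]), 1e-8) * rel_step * 10 for i in idx])
    f0 = fun(theta)
    for a in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[idx[a]] += h[a]
        tm[idx[a]] = theta[idx[a]] - h[a]
        if tm[idx[a]] < 0 and idx[a] < 2:
            # one-sided second difference at the boundary
            tpp = theta.copy()
            tpp[idx[a]] += 2 * h[a]
            H[a, a] = (fun(tpp) - 2 * fun(tp) + f0) / h[a] ** 2
        else:
            H[a, a] = (fun(tp) - 2 * f0 + fun(tm)) / h[a] ** 2
    for a in range(k):
        for b in range(a + 1, k):
            pts = []
            for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                tt = theta.copy()
                tt[idx[a]] = max(theta[idx[a]] + sa * h[a], 0.0 if idx[a] < 2 else 1e-12)
                tt[idx[b]] = max(theta[idx[b]] + sb * h[b], 0.0 if idx[b] < 2 else 1e-12)
                pts.append(fun(tt))
            H[a, b] = H[b, a] = (pts[0] - pts[1] - pts[2] + pts[3]) / (4 * h[a] * h[b])
    return H


def _satterthwaite_df(theta, blocks, L, resid_df):
    """Satterthwaite denominator df for the contrast L at the REML optimum."""
    active = np.array([theta[0] > _VAR_FLOOR * theta[2],
                       theta[1] > _VAR_FLOOR * theta[2],
                       True])
    f0 = _contrast_var(theta, blocks, L)
    try:
        g = _numeric_grad(lambda th: _contrast_var(th, blocks, L), theta, active)
        H = _numeric_hessian(lambda th: _reml_nll(th, blocks), theta, active)
        A = np.linalg.pinv(H)  # asymptotic covariance of the variance components
        denom = float(g @ A @ g)
    except np.linalg.LinAlgError:
        denom = np.nan
    if not np.isfinite(denom) or denom <= 0:
        return float(resid_df)
    df = 2.0 * f0**2 / denom
    return float(np.clip(df, 1.0, 1e7))


def _multi_df_satterthwaite(theta, blocks, L_rows, resid_df, beta, C):
    """lmerTest-style multi-df Satterthwaite F via eigen-contrasts."""
    L = np.atleast_2d(L_rows)
    q = L.shape[0]
    M = L @ C @ L.T
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        raise ModelError("singular contrast covariance")
    F = float((L @ beta) @ Minv @ (L @ beta)) / q
    evals, evecs = np.linalg.eigh(M)
    nus = []
    for i in range(q):
        row = evecs[:, i] @ L
        nus.append(_satterthwaite_df(theta, blocks, row, resid_df))
    nus = np.asarray(nus)
    good = nus > 2
    if good.sum() == 0:
        return F, float(resid_df)
    E = float(np.sum(nus[good] / (nus[good] - 2)))
    if E <= q:
        return F, float(resid_df)
    return F, 2.0 * E / (E - q)


def _design_matrix(table: pd.DataFrame):
    cultivars = sorted(table["cultivar"].unique())
    t = table["time_days"].to_numpy(dtype=float)
    cols = [np.ones(len(table)), t]
    names = ["Intercept", "time"]
    for c in cultivars[1:]:
        dummy = (table["cultivar"] == c).to_numpy(dtype=float)
        cols.append(dummy)
        names.append(f"cultivar[{c}]")
    for c in cultivars[1:]:
        dummy = (table["cultivar"] == c).to_numpy(dtype=float)
        cols.append(dummy * t)
        names.append(f"time:cultivar[{c}]")
    X = np.column_stack(cols)
    return X, names, t, cultivars


def _term_rows(names, cultivars):
    """Map each ANOVA term to the indices of its design-matrix columns."""
    others = cultivars[1:]
    return {
        "time": [names.index("time")],
        "cultivar": [names.index(f"cultivar[{c}]") for c in others],
        "time:cultivar": [names.index(f"time:cultivar[{c}]") for c in others],
    }


def fit_interaction_anova(table: pd.DataFrame, engine: str = "auto") -> AnovaResult:
    """Fit the mixed-effects repeated-measures model and test the fixed terms.

    Requires >= 2 cultivars, >= 2 plants per cultivar and >= 3 time points.

    ``engine`` selects the inference path: ``"auto"`` (default) uses the
    exact expected-mean-squares decomposition when the table is balanced and
    REML otherwise; ``"rm_anova"`` forces the exact decomposition (balanced
    tables only); ``"mixed"`` forces REML through :class:`statsmodels`
    MixedLM (diagonal random-effect covariance: independent intercept and
    time slope per plant, variance components polished on the closed-form
    REML objective) with Satterthwaite-df Wald F tests, falling back to an
    OLS ANCOVA if both random-effect variances are estimated at zero.
    """
    if engine not in ("auto", "rm_anova", "mixed"):
        raise ValueError(f"unknown engine {engine!r}")
    table = table.reset_index(drop=True)
    cultivar_per_plant = table.groupby("plant_id")["cultivar"].nunique()
    if (cultivar_per_plant > 1).any():
        raise ModelError("a plant_id maps to more than one cultivar")
    n_cult = table["cultivar"].nunique()
    if n_cult < 2:
        raise ModelError("need >= 2 cultivars for an interaction test")
    plants_per_cult = table.drop_duplicates("plant_id").groupby("cultivar").size()
    if (plants_per_cult < 2).any():
        raise ModelError("need >= 2 plants per cultivar")
    if table["time_days"].nunique() < 3:
        raise ModelError("need >= 3 time points")

    y = table["count"].to_numpy(dtype=float)
    X, names, t, cultivars = _design_matrix(table)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(
            f"rank-deficient fixed-effects design (rank {rank} < {X.shape[1]} "
            f"columns {names}); cultivar and time may be confounded"
        )

    pivot = table.pivot_table(index="plant_id", columns="time_days",
                              values="count", aggfunc="first")
    counts_per_plant = table.groupby("plant_id").size()
    balanced = (not pivot.isna().any().any()
                and counts_per_plant.nunique() == 1
                and counts_per_plant.iloc[0] == pivot.shape[1])
    if engine == "rm_anova" and not balanced:
        raise ModelError("engine='rm_anova' requires a balanced table")
    if engine in ("auto", "rm_anova") and balanced:
        return _fit_rm_anova(table, pivot, cultivars)

    codes = pd.factorize(table["plant_id"])[0]
    blocks = _make_blocks(y, X, t, codes)
    n, p = X.shape
    resid_df = n - p

    theta = _estimate_components(y, X, t, codes, blocks)
    if theta is None or (theta[0] <= _VAR_FLOOR * theta[2] and
                         theta[1] <= _VAR_FLOOR * theta[2]):
        return _fit_ols(table, y, X, names, cultivars)

    beta, C, *_ = _gls(theta, blocks)
    scale = theta[2]
    term_rows = _term_rows(names, cultivars)
    rows = []
    for term, cols in term_rows.items():
        if len(cols) == 1:
            L = np.zeros(p)
            L[cols[0]] = 1.0
            se2 = float(L @ C @ L)
            F = float(beta[cols[0]] ** 2 / se2)
            df_den = _satterthwaite_df(theta, blocks, L, resid_df)
            q = 1
        else:
            Lm = np.zeros((len(cols), p))
            for i, cix in enumerate(cols):
                Lm[i, cix] = 1.0
            F, df_den = _multi_df_satterthwaite(theta, blocks, Lm, resid_df, beta, C)
            q = len(cols)
        p_val = float(stats.f.sf(F, q, df_den))
        rows.append((term, q, df_den, F * q * scale, F, p_val))
    terms = pd.DataFrame(
        rows, columns=["term", "df_num", "df_den", "sum_sq", "f_value", "p_value"]
    )
    result = AnovaResult(
        terms=terms,
        interaction_term="time:cultivar",
        method="mixed",
        scale=scale,
        n_obs=n,
        variance_components={
            "plant_intercept": float(theta[0]),
            "plant_slope": float(theta[1]),
            "residual": float(theta[2]),
        },
    )
    if n_cult == 2:
        cix = term_rows["time:cultivar"][0]
        L = np.zeros(p)
        L[cix] = 1.0
        result.interaction_coef = float(beta[cix])
        result.interaction_se = float(np.sqrt(L @ C @ L))
        result.interaction_df = float(
            terms.set_index("term").loc["time:cultivar", "df_den"]
        )
    return result


def _oneway_ss(values, groups):
    """Between- and within-group sums of squares of a per-plant statistic."""
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in np.unique(groups):
        v = values[groups == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += float(((v - v.mean()) ** 2).sum())
    return ss_b, ss_w


def _ems_f(ss_b, ss_w, q, df_den):
    """F and p for an expected-mean-squares ratio with degenerate guards."""
    ms_b, ms_w = ss_b / q, ss_w / df_den
    if ms_w > 0:
        F = ms_b / ms_w
        return F, float(stats.f.sf(F, q, df_den))
    if ms_b <= 1e-300:
        return 0.0, 1.0  # total unanimity: no evidence either way
    return float("inf"), 0.0


def _fit_rm_anova(table, pivot, cultivars) -> AnovaResult:
    """Exact balanced-design decomposition via per-plant intercepts/slopes."""
    t = pivot.columns.to_numpy(dtype=float)
    tc = t - t.mean()
    sxx = float((tc**2).sum())
    Y = pivot.to_numpy(dtype=float)
    N, T = Y.shape
    groups = (
        table.drop_duplicates("plant_id")
        .set_index("plant_id")["cultivar"]
        .reindex(pivot.index)
        .to_numpy()
    )
    k = len(cultivars)
    df_den = N - k

    slopes = Y @ (tc / sxx)
    means = Y.mean(axis=1)
    fitted = means[:, None] + slopes[:, None] * tc[None, :]
    ss_res = float(((Y - fitted) ** 2).sum())
    df_res = N * (T - 2)
    scale = ss_res / df_res if df_res > 0 else float("nan")

    ssb_slope, ssw_slope = _oneway_ss(slopes, groups)
    ssb_mean, ssw_mean = _oneway_ss(means, groups)
    ms_slope_w = ssw_slope / df_den
    ms_mean_w = ssw_mean / df_den

    rows = []
    # time: mean slope against the between-plant slope mean square
    ss_time = sxx * N * slopes.mean() ** 2
    f_time, p_time = _ems_f(N * slopes.mean() ** 2, ssw_slope, 1, df_den)
    rows.append(("time", 1, float(df_den), ss_time, f_time, p_time))
    f_cult, p_cult = _ems_f(ssb_mean, ssw_mean, k - 1, df_den)
    rows.append(("cultivar", k - 1, float(df_den), T * ssb_mean, f_cult, p_cult))
    f_int, p_int = _ems_f(ssb_slope, ssw_slope, k - 1, df_den)
    rows.append(("time:cultivar", k - 1, float(df_den), sxx * ssb_slope,
                 f_int, p_int))
    terms = pd.DataFrame(
        rows, columns=["term", "df_num", "df_den", "sum_sq", "f_value", "p_value"]
    )
    result = AnovaResult(
        terms=terms,
        interaction_term="time:cultivar",
        method="rm_anova",
        scale=scale,
        n_obs=N * T,
        variance_components={
            "plant_intercept": max(0.0, ms_mean_w - scale / T),
            "plant_slope": max(0.0, ms_slope_w - scale / sxx),
            "residual": scale,
        },
    )
    if k == 2:
        ref, other = cultivars
        n_ref = int((groups == ref).sum())
        n_other = int((groups == other).sum())
        result.interaction_coef = float(
            slopes[groups == other].mean() - slopes[groups == ref].mean()
        )
        result.interaction_se = float(
            np.sqrt(ms_slope_w * (1.0 / n_ref + 1.0 / n_other))
        )
        result.interaction_df = float(df_den)
    return result


def _estimate_components(y, X, t, codes, blocks):
    """REML variance components: statsmodels MixedLM start + L-BFGS-B polish."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLMParams
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    theta0 = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = sm.MixedLM(y, X, groups=codes, exog_re=np.column_stack(
                [np.ones(len(t)), t]))
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
            )
            fit = model.fit(free=free, reml=True, method="lbfgs", maxiter=200)
        theta0 = np.array(
            [max(fit.cov_re.iloc[0, 0], 0.0), max(fit.cov_re.iloc[1, 1], 0.0),
             max(fit.scale, 1e-10)]
        )
    except Exception:
        theta0 = None
    if theta0 is None:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = float(np.var(resid, ddof=X.shape[1]))
        theta0 = np.array([0.1 * s2, 0.01 * s2 + 1e-8, max(s2, 1e-10)])

    res = optimize.minimize(
        _reml_nll,
        theta0,
        args=(blocks,),
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None), (1e-10, None)],
    )
    theta = res.x if res.success or np.isfinite(res.fun) else theta0
    return np.asarray(theta, dtype=float)


def _fit_ols(table, y, X, names, cultivars):
    """OLS ANCOVA fallback when random-effect variances vanish."""
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    scale = float(fit.mse_resid)
    term_rows = _term_rows(names, cultivars)
    p = X.shape[1]
    rows = []
    for term, cols in term_rows.items():
        Lm = np.zeros((len(cols), p))
        for i, cix in enumerate(cols):
            Lm[i, cix] = 1.0
        wt = fit.wald_test(Lm, use_f=True, scalar=True)
        F = float(wt.statistic)
        df_den = float(fit.df_resid)
        q = len(cols)
        rows.append((term, q, df_den, F * q * scale, F, float(wt.pvalue)))
    terms = pd.DataFrame(
        rows, columns=["term", "df_num", "df_den", "sum_sq", "f_value", "p_value"]
    )
    result = AnovaResult(
        terms=terms,
        interaction_term="time:cultivar",
        method="ols",
        scale=scale,
        n_obs=len(y),
        variance_components={"plant_intercept": 0.0, "plant_slope": 0.0,
                             "residual": scale},
    )
    if len(cultivars) == 2:
        cix = term_rows["time:cultivar"][0]
        result.interaction_coef = float(fit.params[cix])
        result.interaction_se = float(fit.bse[cix])
        result.interaction_df = float(fit.df_resid)
    return result


def growth_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Average growth curves: per (cultivar, time) mean, sample SD and n.

    With a single plant the SD is reported as 0.0 and n = 1 flags the
    degeneracy.
    """
    if len(table) == 0:
        raise ModelError("empty count table")
    g = table.groupby(["cultivar", "time_days"])["count"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                n="size").reset_index()
    out["sd"] = out["sd"].astype(float)
    return out
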
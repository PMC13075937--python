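"""Individuality statistics across environmental contexts.

The question throughout: does a fly's position within its group persist
when the environment changes?  Four complementary views:

* cross-context Pearson correlation of a trait (with the usual paired
  t-transform p-value);
* percentile ranks within a group and the absolute rank change between
  contexts;
* a ridge-regularised GLM predicting rank change from *which* factors
  changed (binary predictors: time, temperature, vision, arena, behavioral
  state), with five-fold cross-validated lambda on a log-spaced 1e-6..1e6
  grid and bootstrap coefficient inference (1000 resamples);
* a hierarchical linear mixed model per trait with context fixed effects
  and a fly random intercept, whose variance decomposition gives the
  intraclass correlation ICC = between-fly / (between-fly + within-fly) —
  the trait's repeatability — with a fly-resampling bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
import statsmodels.api as sm

#: binary change predictors of the rank-difference GLM
CHANGE_PREDICTORS = ("time", "temperature", "vision", "arena", "behavioral_state")
#: default lambda grid: log-spaced over 1e-6 .. 1e6
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-6, 6, 25))
DEFAULT_CV_FOLDS = 5
DEFAULT_BOOTSTRAP = 1000
#: between-fly variance below this fraction of the residual variance is
#: treated as a boundary (singular) fit
SINGULAR_RTOL = 1e-2


@dataclass
class CorrelationResult:
    r: float | None
    p: float | None
    n: int


@dataclass
class GroupComparison:
    shapiro_w: float | None
    shapiro_p: float | None
    t: float | None
    t_p: float | None
    mean_difference: float
    n: int
    note: str | None = None


@dataclass
class RidgeFit:
    lambda_star: float
    coefficients: dict[str, float]
    intercept: float
    cv_mse: dict[float, float]
    predictor_names: tuple[str, ...]
    x_mean: np.ndarray
    x_std: np.ndarray
    bootstrap_mean: dict[str, float] | None = None
    bootstrap_se: dict[str, float] | None = None
    p_values: dict[str, float] | None = None


@dataclass
class LMMFit:
    fixed_effects: dict[str, tuple[float, float, float]]  # estimate, ci_lo, ci_hi
    sigma2_between: float
    sigma2_within: float
    icc: float
    singular: bool = False
    icc_ci: tuple[float, float] | None = None
    icc_ci_unreliable: bool = False


# ---------------------------------------------------------------------------
# pairwise consistency


def _trait_pivot(table: pd.DataFrame, trait: str, contexts) -> pd.DataFrame:
    sub = table[(table["trait"] == trait) & (table["context"].isin(contexts))]
    return sub.pivot_table(index="fly", columns="context", values="value", aggfunc="first")


def pearson_across_contexts(
    table: pd.DataFrame, trait: str, context_a: str, context_b: str
) -> CorrelationResult:
    """Pearson r of a trait between two contexts over complete fly pairs."""
    wide = _trait_pivot(table, trait, [context_a, context_b])
    for c in (context_a, context_b):
        if c not in wide.columns:
            raise ValueError(f"context {c!r} absent for trait {trait!r}")
    wide = wide[[context_a, context_b]].dropna()
    n = len(wide)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, found {n}")
    a = wide[context_a].to_numpy()
    b = wide[context_b].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(r=None, p=None, n=n)
    r, p = sps.pearsonr(a, b)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def group_comparison(a, b) -> GroupComparison:
    """Shapiro–Wilk on the paired differences, then a paired two-sided t-test.

    The normality result is reported alongside the t-test, never used to
    silently switch tests.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = b - a
    if np.allclose(d, d[0]):
        sw = (None, None) if np.ptp(d) == 0 else sps.shapiro(d)
        return GroupComparison(
            shapiro_w=sw[0], shapiro_p=sw[1], t=None, t_p=None,
            mean_difference=float(d.mean()), n=len(a),
            note="all paired differences identical; t undefined",
        )
    w, wp = sps.shapiro(d)
    t, tp = sps.ttest_rel(b, a)
    return GroupComparison(
        shapiro_w=float(w), shapiro_p=float(wp), t=float(t), t_p=float(tp),
        mean_difference=float(d.mean()), n=len(a),
    )


# ---------------------------------------------------------------------------
# ranks


def to_percentile_ranks(values) -> np.ndarray:
    """Within-group percentile ranks on a 0-100 scale, average ranks for ties.

    Scaled as (rank - 1) / (n - 1) * 100, so the smallest value maps to 0
    and the largest to 100.  Invariant under any strictly monotone
    transform of the values.  NaNs stay NaN.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    out = np.full(v.shape, np.nan)
    ranks = sps.rankdata(v[ok], method="average")
    out[ok] = (ranks - 1.0) / (ok.sum() - 1.0) * 100.0
    return out


def rank_change(
    table: pd.DataFrame, trait: str, context_a: str, context_b: str
) -> pd.Series:
    """Per-fly absolute percentile-rank difference between two contexts.

    Ranks are computed within each context over the flies measured in both;
    flies missing in one context are omitted.  Symmetric in its contexts.
    """
    wide = _trait_pivot(table, trait, [context_a, context_b])
    wide = wide[[context_a, context_b]].dropna()
    if len(wide) < 2:
        raise ValueError("need >= 2 flies present in both contexts")
    ra = to_percentile_ranks(wide[context_a].to_numpy())
    rb = to_percentile_ranks(wide[context_b].to_numpy())
    return pd.Series(np.abs(ra - rb), index=wide.index, name="abs_rank_change")


def build_change_design(pairs: list[dict]) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack per-fly rank changes with binary which-factor-changed predictors.

    Each element of ``pairs`` is ``{"changed": iterable of predictor names,
    "rank_changes": per-fly values}``; a pair that claims no changed factor
    must be explicitly labeled a retest via ``"retest": True``.  Returns
    (X as DataFrame with CHANGE_PREDICTORS columns, y).
    """
    rows = []
    ys = []
    for pair in pairs:
        changed = set(pair.get("changed", ()))
        unknown = changed - set(CHANGE_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        if not changed and not pair.get("retest", False):
            raise ValueError(
                "context pair with no changed factor must be labeled retest=True"
            )
        indicator = {p: (1 if p in changed else 0) for p in CHANGE_PREDICTORS}
        for v in np.asarray(pair["rank_changes"], dtype=float):
            rows.append(indicator)
            ys.append(v)
    return pd.DataFrame(rows, columns=list(CHANGE_PREDICTORS)), np.asarray(ys)


# ---------------------------------------------------------------------------
# ridge GLM


def _zscore(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    return mean, std, keep


def fit_ridge_cv(
    X: pd.DataFrame | np.ndarray,
    y,
    grid=DEFAULT_LAMBDA_GRID,
    folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
) -> RidgeFit:
    """Ridge regression with k-fold cross-validated penalty.

    Predictors are z-scored once on the full data (constant columns are
    dropped with a warning); for each lambda on the grid the seeded k-fold
    CV mean squared error is computed, lambda* minimises it, and the final
    model is refit on all rows at lambda*.  The intercept is unpenalised.
    """
    names = (
        tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(f"x{i}" for i in range(np.asarray(X).shape[1]))
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    if X.shape[0] < folds:
        raise ValueError(f"{X.shape[0]} rows < {folds} folds")
    mean, std, keep = _zscore(X)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant predictor(s): {dropped}")
    names_kept = tuple(n for n, k in zip(names, keep) if k)
    Z = (X[:, keep] - mean[keep]) / std[keep]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Z))
    cv_mse = {}
    for lam in grid:
        errs = []
        for tr, te in splits:
            model = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
            model.fit(Z[tr], y[tr])
            resid = y[te] - model.predict(Z[te])
            errs.append(np.mean(resid**2))
        cv_mse[float(lam)] = float(np.mean(errs))
    lambda_star = min(cv_mse, key=cv_mse.get)
    final = Ridge(alpha=lambda_star, fit_intercept=True, solver="cholesky")
    final.fit(Z, y)
    return RidgeFit(
        lambda_star=lambda_star,
        coefficients=dict(zip(names_kept, map(float, final.coef_))),
        intercept=float(final.intercept_),
        cv_mse=cv_mse,
        predictor_names=names_kept,
        x_mean=mean[keep],
        x_std=std[keep],
    )


def bootstrap_ridge(
    X: pd.DataFrame | np.ndarray,
    y,
    fit: RidgeFit,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> RidgeFit:
    """Bootstrap coefficient inference at the cross-validated penalty.

    Rows of (X, y) are resampled jointly with replacement ``n_boot`` times
    and the ridge model refit at lambda*; the bootstrap SD of each
    coefficient is its SE, and the two-sided p-value comes from the normal
    tail of (full-data coefficient) / SE.  Resamples where a predictor
    collapses to a constant are redrawn (capped at 10x n_boot draws).
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    names = fit.predictor_names
    if isinstance(X, pd.DataFrame):
        X = X[list(names)]  # drop any columns pruned during fitting
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != len(names):
        raise ValueError("X must contain exactly the fitted predictors")
    Z = (X - fit.x_mean) / fit.x_std
    rng = np.random.default_rng(seed)
    n = len(y)
    coefs = np.empty((n_boot, len(names)))
    draws = 0
    done = 0
    while done < n_boot:
        if draws >= 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, n)
        draws += 1
        Zb = Z[idx]
        if np.any(Zb.std(axis=0) == 0):
            continue  # degenerate resample, redraw
        model = Ridge(alpha=fit.lambda_star, fit_intercept=True, solver="cholesky")
        model.fit(Zb, y[idx])
        coefs[done] = model.coef_
        done += 1
    se = coefs.std(axis=0, ddof=1)
    full = np.array([fit.coefficients[nm] for nm in names])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, full / se, np.inf * np.sign(full))
    pvals = 2.0 * sps.norm.sf(np.abs(tstat))
    fit.bootstrap_mean = dict(zip(names, map(float, coefs.mean(axis=0))))
    fit.bootstrap_se = dict(zip(names, map(float, se)))
    fit.p_values = dict(zip(names, map(float, pvals)))
    return fit


# ---------------------------------------------------------------------------
# hierarchical mixed model


def _context_design(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric context fixed-effect columns with more than one level.

    Columns that are linearly dependent on the intercept plus the columns
    already included (e.g. day and temperature varied in lockstep) are
    dropped, earlier factors taking precedence, so the fixed-effect design
    always has full rank.
    """
    cols = [np.ones(len(table))]
    names: list[str] = []
    for c in ("day", "temperature", "stripes", "light", "arena"):
        if c in table.columns and table[c].nunique() > 1:
            cand = table[c].to_numpy(dtype=float)
            trial = np.column_stack(cols + [cand])
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(cand)
                names.append(c)
    if names:
        return np.column_stack(cols[1:]), names
    return np.empty((len(table), 0)), names


def fit_trait_lmm(table: pd.DataFrame, trait: str) -> LMMFit:
    """Random-intercept mixed model for one trait, REML.

    value ~ 1 + numeric context factors, random intercept per fly.  The
    variance decomposition gives ICC = between / (between + within); a
    singular fit (between-fly variance estimated at zero) reports ICC 0
    with the ``singular`` flag instead of raising.
    """
    sub = table[table["trait"] == trait].copy()
    counts = sub.groupby("fly")["value"].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 flies with >= 2 observations each")
    X, names = _context_design(sub)
    exog = sm.add_constant(X) if X.size else np.ones((len(sub), 1))
    exog_names = ["const"] + names
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(sub["value"].to_numpy(), exog, groups=sub["fly"].to_numpy())
        res = model.fit(reml=True)
    sigma2_b = float(np.squeeze(res.cov_re))
    sigma2_w = float(res.scale)
    # REML optimizers stop slightly off the boundary; a between-fly variance
    # below 1% of the residual variance is indistinguishable from zero
    singular = sigma2_b <= SINGULAR_RTOL * sigma2_w
    icc = 0.0 if singular else sigma2_b / (sigma2_b + sigma2_w)
    fixed = {}
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    for i, nm in enumerate(exog_names):
        fixed[nm] = (float(res.fe_params[i]), float(ci[i, 0]), float(ci[i, 1]))
    return LMMFit(
        fixed_effects=fixed,
        sigma2_between=max(sigma2_b, 0.0),
        sigma2_within=sigma2_w,
        icc=float(icc),
        singular=bool(singular),
    )


def bootstrap_icc(
    table: pd.DataFrame,
    trait: str,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> tuple[LMMFit, tuple[float, float]]:
    """Fly-resampling bootstrap CI for the ICC.

    Flies are resampled with replacement, each resampled fly keeping its
    full set of context observations (duplicates relabeled as new flies),
    the model refit, and the 2.5/97.5 percentiles of the bootstrap ICCs
    taken as the 95% CI.  More than 10% failed refits flags the CI as
    unreliable.
    """
    fit = fit_trait_lmm(table, trait)
    sub = table[table["trait"] == trait]
    flies = sub["fly"].unique()
    rng = np.random.default_rng(seed)
    iccs = []
    failures = 0
    by_fly = {f: g for f, g in sub.groupby("fly")}
    for _ in range(n_boot):
        chosen = rng.choice(flies, size=len(flies), replace=True)
        parts = []
        for new_id, f in enumerate(chosen):
            g = by_fly[f].copy()
            g["fly"] = f"bs{new_id}"
            parts.append(g)
        bs = pd.concat(parts, ignore_index=True)
        try:
            bfit = fit_trait_lmm(bs, trait)
            iccs.append(bfit.icc)
        except Exception:
            failures += 1
    if not iccs:
        raise RuntimeError("all bootstrap refits failed")
    lo, hi = np.percentile(iccs, [2.5, 97.5])
    fit.icc_ci = (float(lo), float(hi))
    fit.icc_ci_unreliable = failures > 0.1 * n_boot
    return fit, fit.icc_ci
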
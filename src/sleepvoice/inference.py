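"""Association-modeling cascade for sleepiness.

The cascade mirrors the analysis sequence the pipeline reproduces:

1. random-forest screening of candidate predictors by node-purity
   importance (features below an absolute cutoff are dropped; race is
   manually excluded by default because of category imbalance),
2. ordinary least squares of sleepiness (numeric 1-4) on the retained
   predictors, with a forest-plot-ready term table,
3. a RESET misspecification test (powers of the fitted values), and
4. if the RESET rejects, a penalized-spline additive model with smooth
   terms for VRT, age, education, caffeine and test difficulty and linear
   terms for sex, BZRA use, mood and cognition, compared to the linear
   model by AIC and an approximate F-test.

Sleepiness is modeled as Gaussian on the numeric 1-4 scale throughout so
the two models' AIC values are comparable (computed by one shared
formula, :func:`sleepvoice.util.gaussian_aic`).

Importance scale note: node-purity totals are implementation-dependent.
The absolute cutoffs used by default (50 for screening, 20 for per-fold
selection) are meaningful for this implementation's scale — the total
impurity decrease summed over a tree's splits, averaged over trees — and a
quantile-based cutoff is available where an absolute one does not
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrices, dmatrix
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.diagnostic import linear_reset

from .util import gaussian_aic

DEFAULT_CANDIDATES = ("vrt_seconds", "cognition_scale", "mood", "age", "sex",
                      "caffeine", "bzra_use", "education", "difficulty",
                      "pass_fail", "alcohol", "race")
DEFAULT_LR_FEATURES = ("vrt_seconds", "cognition_scale", "mood", "age", "sex",
                       "caffeine", "bzra_use", "education", "difficulty")
DEFAULT_SMOOTH = ("vrt_seconds", "age", "education", "caffeine", "difficulty")
DEFAULT_LINEAR = ("sex", "bzra_use", "mood", "cognition_scale")


class ScreeningError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Random-forest screening


def _rf_design(table: pd.DataFrame, features: Sequence[str]
               ) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix for forests; returns (X, parent feature per column)."""
    cols, parents = [], []
    for f in features:
        s = table[f]
        if s.dtype == bool:
            cols.append(s.to_numpy(dtype=float))
            parents.append(f)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=f)
            for c in d.columns:
                cols.append(d[c].to_numpy(dtype=float))
                parents.append(f)
        else:
            cols.append(s.to_numpy(dtype=float))
            parents.append(f)
    return np.column_stack(cols), parents


def _node_purity(forest, parents: list[str]) -> dict[str, float]:
    """R-style node-purity importance: total impurity decrease per feature.

    Per tree, the unnormalized impurity decrease (per-sample scale) is
    rescaled by the tree's root sample weight to a total decrease, then
    averaged over trees and summed over a categorical feature's dummy
    columns.
    """
    total = np.zeros(len(parents))
    for est in forest.estimators_:
        t = est.tree_
        total += t.compute_feature_importances(normalize=False) \
            * t.weighted_n_node_samples[0]
    total /= len(forest.estimators_)
    out: dict[str, float] = {}
    for p, v in zip(parents, total):
        out[p] = out.get(p, 0.0) + float(v)
    return out


@dataclass(frozen=True)
class ImportanceTable:
    importances: dict[str, float]
    cutoff: float
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    manually_excluded: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(feature=f, importance=v,
                     status=("manually excluded" if f in self.manually_excluded
                             else "dropped" if f in self.dropped else "retained"))
                for f, v in sorted(self.importances.items(),
                                   key=lambda kv: -kv[1])]
        return pd.DataFrame(rows)


def classify_importances(importances: Mapping[str, float], cutoff: float,
                         manual_exclusions: Sequence[str] = ()
                         ) -> ImportanceTable:
    """Apply the cutoff rule: dropped iff importance < cutoff, minus manual
    exclusions; the three sets partition the candidates."""
    manual = tuple(f for f in importances if f in set(manual_exclusions))
    dropped = tuple(f for f, v in importances.items()
                    if v < cutoff and f not in manual)
    retained = tuple(f for f in importances
                     if f not in manual and f not in dropped)
    return ImportanceTable(dict(importances), cutoff, retained, dropped, manual)


def screen_features(table: pd.DataFrame, outcome: str = "sleepiness",
                    candidates: Sequence[str] = DEFAULT_CANDIDATES,
                    cutoff: float = 50.0, cutoff_quantile: float | None = None,
                    manual_exclusions: Sequence[str] = ("race",),
                    n_trees: int = 500, seed: int = 0,
                    classifier: bool = False) -> ImportanceTable:
    """Rank candidate predictors of the outcome by node-purity importance.

    ``cutoff_quantile`` (e.g. 0.25) replaces the absolute cutoff with a
    quantile of the observed importances.  ``classifier=True`` uses Gini
    impurity on the outcome as classes instead of variance reduction.
    """
    candidates = [c for c in candidates if c in table.columns]
    y = table[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ScreeningError("outcome is constant; no impurity to reduce")
    X, parents = _rf_design(table, candidates)
    cls = RandomForestClassifier if classifier else RandomForestRegressor
    forest = cls(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    imp = _node_purity(forest, parents)
    if cutoff_quantile is not None:
        cutoff = float(np.quantile(list(imp.values()), cutoff_quantile))
    return classify_importances(imp, cutoff, manual_exclusions)


# ---------------------------------------------------------------------------
# Linear model


_TERM_MAP = {
    "sex": "C(sex, Treatment('female'))",
    "mood": "C(mood, Treatment(1))",
    "race": "C(race)",
    "test_type": "C(test_type)",
}


def _formula(outcome: str, features: Sequence[str]) -> str:
    if not features:
        raise ValueError("no features to fit; screening may have dropped "
                         "everything (check the cutoff against the "
                         "importance scale)")
    terms = [_TERM_MAP.get(f, f) for f in features]
    return f"{outcome} ~ " + " + ".join(terms)


def _prep(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for c in ("bzra_use", "alcohol", "pass_fail", "tobacco"):
        if c in out.columns and out[c].dtype == bool:
            out[c] = out[c].astype(int)  # reference: non-use / False
    return out


def _check_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank == exog.shape[1]:
        return
    offenders = []
    base = np.empty((exog.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([base, exog[:, j]])
        if np.linalg.matrix_rank(cand) == base.shape[1]:
            offenders.append(name)
        else:
            base = cand
    raise RankDeficiencyError(f"design matrix is rank deficient; "
                              f"collinear columns: {offenders}")


@dataclass(frozen=True)
class LinearFit:
    terms: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p_value
    r_squared: float
    aic: float
    n: int
    rss: float
    edf: float
    formula: str
    _results: object = field(repr=False, default=None)
    _table: pd.DataFrame = field(repr=False, default=None)


def fit_linear(table: pd.DataFrame,
               features: Sequence[str] = DEFAULT_LR_FEATURES) -> LinearFit:
    """Ordinary least squares of numeric sleepiness on the given features.

    Categorical covariates are reference-coded (female, mood level 1, BZRA
    non-use).  95% CIs use estimate +/- 1.96*SE.  Raises on rank-deficient
    designs, naming the collinear columns.
    """
    data = _prep(table)
    formula = _formula("sleepiness", features)
    y, X = dmatrices(formula, data, return_type="dataframe")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"n={X.shape[0]} too small for {X.shape[1]} parameters")
    for name in X.columns[1:]:
        if np.ptp(X[name].to_numpy()) == 0:
            raise RankDeficiencyError(f"feature column {name!r} is constant")
    _check_rank(X.to_numpy(), list(X.columns))

    res = sm.OLS(y.to_numpy().ravel(), X).fit()
    est, se, p = res.params, res.bse, res.pvalues
    terms = pd.DataFrame({
        "term": X.columns, "estimate": est.to_numpy(), "se": se.to_numpy(),
        "ci_low": (est - 1.96 * se).to_numpy(),
        "ci_high": (est + 1.96 * se).to_numpy(),
        "p_value": p.to_numpy()})
    yv = y.to_numpy().ravel()
    rss = float(np.sum(res.resid ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    k = X.shape[1]
    return LinearFit(terms=terms, r_squared=r2,
                     aic=gaussian_aic(rss, len(yv), k), n=len(yv), rss=rss,
                     edf=float(k), formula=formula, _results=res, _table=data)


def reset_test(fit: LinearFit, powers: Sequence[int] = (2, 3),
               use_f: bool = True) -> float:
    """RESET misspecification p-value: does adding powers of the fitted
    values (squares and cubes by default) improve the linear model?"""
    res = linear_reset(fit._results, power=list(powers), use_f=use_f)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Generalized additive model


@dataclass(frozen=True)
class GamFit:
    smooth_terms: dict[str, dict]   # feature -> {edf, p_value, x, curve}
    linear_terms: dict[str, dict]   # term -> {estimate, se, p_value}
    aic: float
    deviance_explained: float
    n: int
    rss: float
    edf: float
    alpha: tuple[float, ...]
    _results: object = field(repr=False, default=None)


def _select_alpha_grid(model: GLMGam, n_smooths: int,
                       grid: np.ndarray | None = None,
                       sweeps: int = 2) -> np.ndarray:
    """Coordinate-wise GCV minimization over a log-spaced penalty grid.

    Deterministic and robust for a handful of smooths; each evaluation is
    one penalized IRLS fit.
    """
    if grid is None:
        grid = np.logspace(-3, 5, 9)
    alpha = np.ones(n_smooths)
    for _ in range(sweeps):
        for j in range(n_smooths):
            best, best_gcv = alpha[j], np.inf
            for a in grid:
                alpha[j] = a
                gcv = model._fit_pirls(alpha=list(alpha)).gcv
                if gcv < best_gcv:
                    best, best_gcv = a, gcv
            alpha[j] = best
    return alpha


def _smooth_f_test(y: np.ndarray, exog: np.ndarray, bases: Sequence[np.ndarray],
                   exclude: int) -> float:
    """Exact nested-OLS F-test for one smooth's basis block.

    Compares the unpenalized design with all spline bases against the one
    without the tested smooth's basis.  Exact under the Gaussian null (no
    dependence on the selected penalty weights), at the price of some
    power relative to a penalized test; preferred here because penalty
    selection makes penalized drop-term tests anti-conservative.
    """
    full = np.column_stack([exog, *bases])
    reduced = np.column_stack([exog]
                              + [b for i, b in enumerate(bases) if i != exclude])
    n = len(y)

    def rss_rank(X):
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        return rss, int(rank)

    rss1, rank1 = rss_rank(full)
    rss0, rank0 = rss_rank(reduced)
    q = rank1 - rank0
    if q <= 0 or n <= rank1:
        return 1.0
    f_stat = max(rss0 - rss1, 0.0) / q / (rss1 / (n - rank1))
    return float(stats.f.sf(f_stat, q, n - rank1))


def fit_gam(table: pd.DataFrame,
            smooth_features: Sequence[str] = DEFAULT_SMOOTH,
            linear_features: Sequence[str] = DEFAULT_LINEAR,
            k: int | Mapping[str, int] = 10,
            alpha: Sequence[float] | None = None) -> GamFit:
    """Penalized B-spline additive Gaussian model of sleepiness.

    Each smooth gets a cubic B-spline basis of size ``k`` (int, or a
    per-feature mapping) with its penalty weight chosen by coordinate-wise
    GCV unless ``alpha`` is given.  Linear terms use the same reference
    coding as :func:`fit_linear` so nested comparisons are exact.  Smooth
    p-values are approximate Wald tests on the penalized coefficients.
    With no smooth features the model collapses to the linear fit.
    """
    data = _prep(table)
    y = data["sleepiness"].to_numpy(dtype=float)
    n = len(y)

    if linear_features:
        lin_terms = [_TERM_MAP.get(f, f) for f in linear_features]
        X_lin = dmatrix(" + ".join(lin_terms), data, return_type="dataframe")
    else:
        X_lin = pd.DataFrame({"Intercept": np.ones(n)})

    if not smooth_features:
        res = sm.OLS(y, X_lin).fit()
        rss = float(np.sum(res.resid ** 2))
        kk = X_lin.shape[1]
        linear_terms = {t: dict(estimate=float(res.params[t]),
                                se=float(res.bse[t]),
                                p_value=float(res.pvalues[t]))
                        for t in X_lin.columns}
        tss = float(np.sum((y - y.mean()) ** 2))
        return GamFit(smooth_terms={}, linear_terms=linear_terms,
                      aic=gaussian_aic(rss, n, kk),
                      deviance_explained=0.0 if tss == 0 else 1 - rss / tss,
                      n=n, rss=rss, edf=float(kk), alpha=(), _results=res)

    ks = []
    for f in smooth_features:
        kf = k[f] if isinstance(k, Mapping) else int(k)
        n_unique = data[f].nunique()
        if kf > n_unique:
            raise ValueError(
                f"basis size {kf} for smooth {f!r} exceeds its {n_unique} "
                f"unique values; reduce k (e.g. k<={n_unique})")
        ks.append(kf)
    Xs = data[list(smooth_features)].to_numpy(dtype=float)
    bs = BSplines(Xs, df=ks, degree=[3] * len(ks),
                  variable_names=list(smooth_features))

    model = GLMGam(y, exog=X_lin.to_numpy(), smoother=bs,
                   alpha=[1.0] * len(ks))
    if alpha is None:
        alpha = _select_alpha_grid(model, len(ks))
    alpha = np.asarray(alpha, dtype=float)
    res = GLMGam(y, exog=X_lin.to_numpy(), smoother=bs,
                 alpha=list(alpha)).fit()

    k_exog = X_lin.shape[1]
    edf = np.asarray(res.edf)
    cov = np.asarray(res.cov_params())
    params = np.asarray(res.params)

    bases = [np.asarray(s.basis) for s in bs.smoothers]
    smooth_terms: dict[str, dict] = {}
    start = k_exog
    for j, f in enumerate(smooth_features):
        dim = bs.smoothers[j].dim_basis
        sl = slice(start, start + dim)
        start += dim
        edf_j = float(edf[sl].sum())
        p = _smooth_f_test(y, X_lin.to_numpy(), bases, exclude=j)
        yest, _ = res.partial_values(j)
        order = np.argsort(Xs[:, j])
        smooth_terms[f] = dict(edf=edf_j, p_value=p,
                               x=Xs[order, j], curve=np.asarray(yest)[order])

    linear_terms = {}
    for i, t in enumerate(X_lin.columns):
        se = float(np.sqrt(cov[i, i]))
        z = params[i] / se if se > 0 else 0.0
        linear_terms[t] = dict(estimate=float(params[i]), se=se,
                               p_value=float(2 * stats.norm.sf(abs(z))))

    fitted = np.asarray(res.fittedvalues)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    edf_total = float(edf.sum())
    return GamFit(smooth_terms=smooth_terms, linear_terms=linear_terms,
                  aic=gaussian_aic(rss, n, edf_total),
                  deviance_explained=0.0 if tss == 0 else 1 - rss / tss,
                  n=n, rss=rss, edf=edf_total, alpha=tuple(alpha),
                  _results=res)


@dataclass(frozen=True)
class ModelComparison:
    aic_linear: float
    aic_gam: float
    delta_aic: float
    anova_p: float
    winner: str

    def report_line(self) -> str:
        return (f"AIC linear {self.aic_linear:.2f} vs additive "
                f"{self.aic_gam:.2f} (delta {self.delta_aic:.2f}); "
                f"{self.winner} preferred; approx. ANOVA p={self.anova_p:.3g}")


def compare_models(lin: LinearFit, gam: GamFit) -> ModelComparison:
    """AIC difference and an approximate F-test between the two models.

    The F comparison treats the additive model's total effective df as its
    parameter count; it is approximate because penalized effective df are
    not integer model dimensions.
    """
    if lin.n != gam.n:
        raise ValueError(f"models fitted on different row counts "
                         f"({lin.n} vs {gam.n})")
    delta = lin.aic - gam.aic
    df_num = gam.edf - lin.edf
    if df_num <= 1e-8:
        p = 1.0
    elif gam.rss <= 0:
        p = 0.0
    else:
        f_stat = max(lin.rss - gam.rss, 0.0) / df_num \
            / (gam.rss / max(gam.n - gam.edf, 1.0))
        p = float(stats.f.sf(f_stat, df_num, max(gam.n - gam.edf, 1.0)))
    winner = "additive model" if gam.aic < lin.aic else "linear model"
    return ModelComparison(aic_linear=lin.aic, aic_gam=gam.aic,
                           delta_aic=delta, anova_p=p, winner=winner)


def plot_forest(fit: LinearFit, path: str | None = None):
    """Forest plot of the linear model's term estimates with 95% CIs.

    Requires matplotlib (optional dependency).  Returns the figure; writes
    it to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    terms = fit.terms[fit.terms["term"] != "Intercept"]
    y = np.arange(len(terms))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(terms) + 1.5))
    ax.errorbar(terms["estimate"], y,
                xerr=[terms["estimate"] - terms["ci_low"],
                      terms["ci_high"] - terms["estimate"]],
                fmt="o", color="black", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(terms["term"])
    ax.set_xlabel("estimate (95% CI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


# ---------------------------------------------------------------------------
# Cascade


@dataclass(frozen=True)
class CascadeResult:
    importance: ImportanceTable
    linear: LinearFit
    reset_p: float
    gam: GamFit | None
    comparison: ModelComparison | None


def association_cascade(table: pd.DataFrame, outcome: str = "sleepiness",
                        candidates: Sequence[str] = DEFAULT_CANDIDATES,
                        screening_cutoff: float = 50.0,
                        manual_exclusions: Sequence[str] = ("race",),
                        reset_alpha: float = 0.05,
                        smooth_features: Sequence[str] = DEFAULT_SMOOTH,
                        linear_features: Sequence[str] = DEFAULT_LINEAR,
                        gam_k: int | Mapping[str, int] = 10,
                        n_trees: int = 500, seed: int = 0) -> CascadeResult:
    """screen -> linear fit -> RESET -> (if rejected) GAM -> comparison.

    The additive model is only fitted when the RESET test finds evidence of
    unmodeled nonlinearity (p <= reset_alpha).  Basis sizes are capped at
    each smooth's number of unique values automatically.
    """
    imp = screen_features(table, outcome=outcome, candidates=candidates,
                          cutoff=screening_cutoff,
                          manual_exclusions=manual_exclusions,
                          n_trees=n_trees, seed=seed)
    lr_features = [f for f in candidates if f in imp.retained]
    lin = fit_linear(table, lr_features)
    reset_p = reset_test(lin)
    gam = comparison = None
    if reset_p <= reset_alpha:
        sf = [f for f in smooth_features if f in lr_features]
        lf = [f for f in linear_features if f in lr_features]
        kmap = {f: min(gam_k if not isinstance(gam_k, Mapping) else gam_k[f],
                       int(table[f].nunique())) for f in sf}
        gam = fit_gam(table, sf, lf, k=kmap)
        comparison = compare_models(lin, gam)
    return CascadeResult(importance=imp, linear=lin, reset_p=reset_p,
                         gam=gam, comparison=comparison)
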
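"""Distance-gradient model fitting with AIC selection, tissue ANOVA,
cohort ANCOVA, and metric-H correlation reports.

Five model families describe how a value (e.g. the homologous-H ratio)
varies with distance d from the tumor margin: polynomials of degree 1-3, a
pure exponential ``b * exp(c d)``, and an exponential with intercept
``a + b * exp(c d)``.  Families are compared by the Gaussian least-squares
AIC ``n ln(RSS/n) + 2 (k + 1)`` (the +1 counts the noise variance); the
best model is the minimum-AIC family, ties broken toward fewer parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

FAMILIES = ("linear", "quadratic", "cubic", "exponential", "exponential_intersect")
_N_PARAMS = {
    "linear": 2,
    "quadratic": 3,
    "cubic": 4,
    "exponential": 2,
    "exponential_intersect": 3,
}


def aic(rss: float, n: int, k_params: int) -> float:
    """Gaussian least-squares AIC: ``n ln(RSS/n) + 2 (k + 1)``.

    An exact fit (RSS = 0) returns -inf (the model cannot be beaten on AIC).
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n <= k_params + 1:
        raise ValueError("need n > k_params + 1")
    if rss == 0:
        warnings.warn("zero residual sum of squares: AIC is -inf", stacklevel=2)
        return -np.inf
    return n * np.log(rss / n) + 2.0 * (k_params + 1)


@dataclass
class ModelFit:
    """One fitted gradient-model family."""

    family: str
    coefficients: np.ndarray
    r_squared: float
    aic: float
    n_obs: int
    p_value: float = np.nan
    converged: bool = True

    def predict(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        c = self.coefficients
        if self.family in ("linear", "quadratic", "cubic"):
            return np.polyval(c[::-1], d)  # stored ascending (a, b, c, ...)
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * d)
        if self.family == "exponential_intersect":
            return c[0] + c[1] * np.exp(c[2] * d)
        raise ValueError(self.family)


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return max(0.0, min(1.0, 1.0 - float(resid @ resid) / tss))


def _regression_p(rss: float, tss: float, n: int, k_params: int) -> float:
    """Overall F-test of the fitted curve against the constant model."""
    df1 = k_params - 1
    df2 = n - k_params
    if df1 <= 0 or df2 <= 0 or rss <= 0 or tss <= rss:
        return np.nan if df1 <= 0 or df2 <= 0 else (1.0 if tss <= rss else 0.0)
    f = ((tss - rss) / df1) / (rss / df2)
    return float(stats.f.sf(f, df1, df2))


def _fit_polynomial(d, y, degree):
    coef = np.polynomial.polynomial.polyfit(d, y, degree)
    resid = y - np.polynomial.polynomial.polyval(d, coef)
    return coef, resid


def _fit_exponential(d, y, with_intercept, seed):
    """Variable-projection least squares: for a fixed rate c the model is
    linear in the remaining coefficients, so those are profiled out with a
    closed-form solve and only c is searched (coarse grid plus a bounded
    1-D polish).  c is bounded so exp never overflows on the observed range.
    Deterministic; ``seed`` is accepted for interface stability but unused.
    """
    del seed
    d_scale = max(np.max(np.abs(d)), 1.0)
    c_bound = 20.0 / d_scale

    def profiled(c):
        e = np.exp(np.clip(c * d, -50.0, 50.0))
        X = np.column_stack([np.ones_like(d), e]) if with_intercept else e[:, None]
        lin, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = X @ lin - y
        return float(resid @ resid), lin, resid

    grid = np.linspace(-c_bound, c_bound, 81)
    rss_grid = np.array([profiled(c)[0] for c in grid])
    i = int(np.argmin(rss_grid))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    sol = optimize.minimize_scalar(
        lambda c: profiled(c)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    c_best = float(sol.x) if sol.fun <= rss_grid[i] else float(grid[i])
    rss, lin, resid = profiled(c_best)
    coef = np.append(lin, c_best)
    if not np.all(np.isfinite(coef)):
        return None
    return coef, resid, True


def fit_gradient_models(
    distance: np.ndarray, value: np.ndarray, seed: int = 0
) -> list[ModelFit]:
    """Fit all five families of value-on-distance models.

    Pairs with non-finite entries are dropped; at least 6 complete pairs are
    required.  A non-converging nonlinear family is returned flagged
    (``converged=False``) rather than aborting the others.
    """
    d = np.asarray(distance, dtype=float)
    y = np.asarray(value, dtype=float)
    if d.shape != y.shape:
        raise ValueError("distance and value must have equal length")
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    n = d.size
    if n < 6:
        raise ValueError("need >= 6 finite observations")
    tss = float(np.sum((y - y.mean()) ** 2))

    fits = []
    for family in FAMILIES:
        k = _N_PARAMS[family]
        if family in ("linear", "quadratic", "cubic"):
            coef, resid = _fit_polynomial(d, y, k - 1)
            converged = True
        else:
            res = _fit_exponential(d, y, family == "exponential_intersect", seed)
            if res is None:
                fits.append(
                    ModelFit(family, np.full(k, np.nan), np.nan, np.inf, n, converged=False)
                )
                continue
            coef, resid, converged = res
        rss = float(resid @ resid)
        fits.append(
            ModelFit(
                family=family,
                coefficients=np.asarray(coef, dtype=float),
                r_squared=_r2(y, resid),
                aic=aic(rss, n, k),
                n_obs=n,
                p_value=_regression_p(rss, tss, n, k),
                converged=converged,
            )
        )
    return fits


def select_best(fits: list[ModelFit], parsimony_margin: float = 2.0) -> ModelFit:
    """Most parsimonious family within ``parsimony_margin`` of the minimum
    AIC, among converged fits.

    Models within ~2 AIC of the minimum are conventionally regarded as
    equivalently supported, so the fewest-parameter member of that set is
    selected (ties on parameter count go to the lower AIC).  Set
    ``parsimony_margin=0`` for strict minimum-AIC selection.
    """
    usable = [f for f in fits if f.converged and (np.isfinite(f.aic) or f.aic == -np.inf)]
    if not usable:
        raise ValueError("no converged fits to select from")
    best_aic = min(f.aic for f in usable)
    if best_aic == -np.inf:
        candidates = [f for f in usable if f.aic == -np.inf]
    else:
        candidates = [f for f in usable if f.aic <= best_aic + parsimony_margin]
    return min(candidates, key=lambda f: (_N_PARAMS[f.family], f.aic))


def fits_table(fits: list[ModelFit]) -> pd.DataFrame:
    """R^2 / AIC summary table, one row per family."""
    return pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "aic": [f.aic for f in fits],
            "p_value": [f.p_value for f in fits],
            "n_obs": [f.n_obs for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def tissue_anova(groups: dict[str, np.ndarray] | list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from the between/within sums-of-squares decomposition.

    Returns (F, p).  Zero within-group variance everywhere yields
    (inf or 0, nan) with a warning rather than an exception.
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0:
        warnings.warn("zero within-group variance in every group", stacklevel=2)
        return (np.inf if ss_between > 0 else 0.0), np.nan
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), float(stats.f.sf(f, df_between, df_within))


@dataclass
class AncovaResult:
    """Cohort-by-distance interaction test on log-H."""

    f_interaction: float
    p_interaction: float
    df: tuple[int, int]
    slopes: dict[str, float]
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def cohort_ancova(
    log_h: np.ndarray, distance: np.ndarray, cohort: np.ndarray
) -> AncovaResult:
    """Test whether the slope of log H on tumor distance differs between
    cohorts.

    The full design (intercept + cohort dummies + distance + cohort x
    distance) and the no-interaction design are fitted by least squares on
    explicitly built design matrices; the interaction F comes from the
    nested-model sums of squares.  Post-hoc pairwise slope contrasts use the
    full-model coefficient covariance with Bonferroni correction.
    """
    y = np.asarray(log_h, dtype=float)
    d = np.asarray(distance, dtype=float)
    g = np.asarray(cohort)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d, g = y[ok], d[ok], g[ok]
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("ANCOVA needs >= 2 cohorts")
    counts = {lv: int((g == lv).sum()) for lv in levels}
    if any(c < 3 for c in counts.values()):
        raise ValueError("each cohort needs >= 3 observations")

    n = y.size
    dummies = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
    X_full = np.column_stack([np.ones(n), dummies, d, dummies * d[:, None]])
    X_red = np.column_stack([np.ones(n), dummies, d])
    for X, name in ((X_red, "main-effect"),):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient {name} design (collinear cohort/distance terms)")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design: cohort x distance interaction is collinear")

    beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_f = float(np.sum((y - X_full @ beta_f) ** 2))
    rss_r = float(np.sum((y - X_red @ beta_r) ** 2))
    df1 = levels.size - 1
    df2 = n - X_full.shape[1]
    f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(f, df1, df2))

    # per-cohort slopes: reference slope is beta[d]; others add their interaction
    slope_idx = 1 + (levels.size - 1)
    slopes = {str(levels[0]): float(beta_f[slope_idx])}
    for i, lv in enumerate(levels[1:]):
        slopes[str(lv)] = float(beta_f[slope_idx] + beta_f[slope_idx + 1 + i])

    sigma2 = rss_f / df2
    cov = sigma2 * np.linalg.inv(X_full.T @ X_full)
    m = levels.size * (levels.size - 1) // 2
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(levels), 2):
        contrast = np.zeros(X_full.shape[1])
        if i > 0:
            contrast[slope_idx + i] = 1.0
        if j > 0:
            contrast[slope_idx + j] -= 1.0
        diff = float(contrast @ beta_f)
        se = float(np.sqrt(contrast @ cov @ contrast))
        t = diff / se if se > 0 else np.nan
        p_raw = float(2 * stats.t.sf(abs(t), df2)) if np.isfinite(t) else np.nan
        rows.append(
            {
                "cohort_a": str(a),
                "cohort_b": str(b),
                "slope_diff": diff,
                "t": t,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw) if np.isfinite(p_raw) else np.nan,
            }
        )
    return AncovaResult(
        f_interaction=float(f),
        p_interaction=p,
        df=(df1, df2),
        slopes=slopes,
        posthoc=pd.DataFrame(rows),
    )


def metric_hurst_correlations(
    h_per_node: np.ndarray, metrics: pd.DataFrame, columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Pearson r between node H and each network measure, Bonferroni-corrected
    over the number of measures tested."""
    h = np.asarray(h_per_node, dtype=float)
    if columns is None:
        columns = [
            c
            for c in metrics.columns
            if c != "id" and not c.endswith("_z") and not c.endswith("_ratio")
            and np.issubdtype(metrics[c].dtype, np.number)
        ]
    m = len(columns)
    rows = []
    for col in columns:
        x = metrics[col].to_numpy(dtype=float)
        ok = np.isfinite(h) & np.isfinite(x)
        n = int(ok.sum())
        if n < 4 or x[ok].std() == 0 or h[ok].std() == 0:
            rows.append({"metric": col, "r": np.nan, "p_raw": np.nan,
                         "p_bonferroni": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(h[ok], x[ok])
        rows.append(
            {
                "metric": col,
                "r": float(r),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
                "n": n,
            }
        )
    return pd.DataFrame(rows)
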
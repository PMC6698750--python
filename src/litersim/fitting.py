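"""Dose-response fits and the population-statistics tests.

This is the analysis layer applied to dose-response tables (simulated or
measured): ordinary least-squares fits of the low-dose linear range, Hill
fits of the full response with bootstrap confidence intervals, fold-change
with a two-sample significance test between the extreme conditions, and the
Kruskal-Wallis comparison of CV curves between circuits.

The Hill model is ``y(u) = y0 + ymax * u^n / (K^n + u^n)`` with an explicit
basal term y0: uninduced expression is leak-dominated and nonzero for these
circuits, so the classical two-parameter Hill form systematically misfits
the low-dose plateau.

Confidence intervals come from a nonparametric bootstrap over the (dose,
value) points (dose grids here are short, <= 12 points, which makes
asymptotic Jacobian intervals unreliable); the resampler is seeded and
reproducible.  Two-sample t-tests use Welch's unequal-variance form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class FitResult:
    """Estimated dose-response model with 95% CIs and goodness of fit."""

    model: str                               # "linear" | "hill"
    params: dict[str, float]
    ci: dict[str, tuple[float, float]]       # 95% intervals per parameter
    r2: float
    residuals: pd.DataFrame = field(repr=False)
    converged: bool = True
    diagnostics: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def covers(self, name: str, value: float) -> bool:
        lo, hi = self.ci[name]
        return lo <= value <= hi

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "r2": self.r2,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


def _as_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not {"dose", "value"} <= set(table.columns):
        # accept the deterministic engine's dose-response schema too
        if {"dose", "gfp"} <= set(table.columns):
            return table["dose"].to_numpy(float), table["gfp"].to_numpy(float)
        raise FitError("dose-response table needs columns 'dose' and 'value'")
    return table["dose"].to_numpy(float), table["value"].to_numpy(float)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_linear(table: pd.DataFrame, dose_max: float = np.inf) -> FitResult:
    """OLS line through the points with dose <= dose_max.

    Used for the low-dose linear range of the circuits (approximately linear
    up to 225 g.s.); restricting ``dose_max`` to that range and comparing R²
    against the full-range fit quantifies where the response bends.
    """
    u, y = _as_xy(table)
    keep = u <= dose_max
    u, y = u[keep], y[keep]
    if u.size < 3:
        raise FitError(f"need >= 3 points with dose <= {dose_max}, got {u.size}")
    res = stats.linregress(u, y)
    yhat = res.intercept + res.slope * u
    tcrit = stats.t.ppf(0.975, u.size - 2) if u.size > 2 else np.inf
    ci = {
        "slope": (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr),
        "intercept": (
            res.intercept - tcrit * res.intercept_stderr,
            res.intercept + tcrit * res.intercept_stderr,
        ),
    }
    return FitResult(
        model="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        ci=ci,
        r2=_r2(y, yhat),
        residuals=pd.DataFrame({"dose": u, "value": y, "fitted": yhat, "residual": y - yhat}),
    )


def hill(u, y0, ymax, K, n):
    u = np.asarray(u, dtype=float)
    out = np.full_like(u, y0, dtype=float)
    pos = u > 0
    out[pos] = y0 + ymax * u[pos] ** n / (K**n + u[pos] ** n)
    return out


def _hill_fit_once(u, y):
    y0_init = float(np.min(y))
    ymax_init = float(np.max(y) - np.min(y))
    half = y0_init + 0.5 * ymax_init
    order = np.argsort(u)
    K_init = float(np.interp(half, y[order], u[order]))
    if not np.isfinite(K_init) or K_init <= 0:
        K_init = float(np.median(u[u > 0]))
    p0 = [y0_init, ymax_init, K_init, 2.0]
    lo = [0.0, 1e-12, 1e-9, 1e-3]
    hi = [np.inf, np.inf, np.inf, 25.0]
    popt, _ = optimize.curve_fit(hill, u, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    return popt


def fit_hill(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> FitResult:
    """Nonlinear least squares of the 4-parameter Hill model.

    Requires >= 5 distinct doses.  95% CIs are percentile intervals from a
    seeded nonparametric bootstrap over points (``n_boot`` resamples);
    resamples whose fit fails to converge are dropped.  Flat data (all y
    equal) is an error; non-convergence of the primary fit is returned
    flagged rather than raised.
    """
    u, y = _as_xy(table)
    if np.unique(u).size < 5:
        raise FitError("Hill fit needs >= 5 distinct doses")
    if np.allclose(y, y[0]):
        raise FitError("degenerate flat data: all responses equal")
    names = ("y0", "ymax", "K", "n")
    try:
        popt = _hill_fit_once(u, y)
    except RuntimeError as e:
        nan = float("nan")
        return FitResult(
            "hill", dict.fromkeys(names, nan), {k: (nan, nan) for k in names},
            r2=nan, residuals=pd.DataFrame(), converged=False, diagnostics=str(e),
        )
    yhat = hill(u, *popt)

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, u.size, u.size)
        if np.unique(u[idx]).size < 5 or np.allclose(y[idx], y[idx][0]):
            continue
        try:
            boot.append(_hill_fit_once(u[idx], y[idx]))
        except RuntimeError:
            continue
    alpha = 100 * (1 - ci_level) / 2
    if boot:
        barr = np.asarray(boot)
        ci = {
            name: (float(np.percentile(barr[:, k], alpha)),
                   float(np.percentile(barr[:, k], 100 - alpha)))
            for k, name in enumerate(names)
        }
    else:
        ci = {name: (float(popt[k]), float(popt[k])) for k, name in enumerate(names)}
    return FitResult(
        model="hill",
        params=dict(zip(names, map(float, popt))),
        ci=ci,
        r2=_r2(y, yhat),
        residuals=pd.DataFrame({"dose": u, "value": y, "fitted": yhat, "residual": y - yhat}),
        diagnostics=f"bootstrap resamples used: {len(boot)}/{n_boot}",
    )


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    p_value: float
    max_dose: float
    min_dose: float
    mean_max: float
    mean_min: float
    defined: bool = True


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fold_change(table: pd.DataFrame) -> FoldChangeResult:
    """Max-mean / min-mean expression across conditions, with Welch's t-test.

    ``table`` holds replicate measurements per dose (columns ``dose`` and
    ``value``); the extreme conditions are the doses with maximal and minimal
    mean, each of which needs >= 2 replicates.  A zero minimum mean flags the
    ratio as undefined instead of dividing by zero.
    """
    u, y = _as_xy(table)
    df = pd.DataFrame({"dose": u, "value": y})
    means = df.groupby("dose")["value"].mean()
    if len(means) < 2:
        raise FitError("fold change needs >= 2 distinct conditions")
    dose_max, dose_min = means.idxmax(), means.idxmin()
    g_max = df.loc[df.dose == dose_max, "value"].to_numpy()
    g_min = df.loc[df.dose == dose_min, "value"].to_numpy()
    if len(g_max) < 2 or len(g_min) < 2:
        raise FitError("fold change needs >= 2 replicates at the extreme conditions")
    mean_max, mean_min = float(g_max.mean()), float(g_min.mean())
    p = _welch(g_max, g_min)
    if mean_min == 0:
        return FoldChangeResult(float("nan"), p, dose_max, dose_min, mean_max, mean_min, defined=False)
    return FoldChangeResult(mean_max / mean_min, p, dose_max, dose_min, mean_max, mean_min)


@dataclass(frozen=True)
class CVComparison:
    statistic: float          # Kruskal-Wallis H
    p_value: float
    max_fold_difference: float
    n_a: int
    n_b: int


def compare_cv_curves(cv_table_a: pd.DataFrame, cv_table_b: pd.DataFrame) -> CVComparison:
    """Kruskal-Wallis test between two circuits' CV-vs-dose curves.

    Both tables need columns ``dose`` and ``cv`` (replicates allowed) on the
    same dose grid.  All doses x replicates are pooled per circuit, and the
    maximal per-dose fold difference of mean CV is reported alongside H and p.
    """
    for name, t in (("A", cv_table_a), ("B", cv_table_b)):
        if not {"dose", "cv"} <= set(t.columns):
            raise FitError(f"CV table {name} needs columns 'dose' and 'cv'")
    grid_a = sorted(cv_table_a["dose"].unique())
    grid_b = sorted(cv_table_b["dose"].unique())
    if grid_a != grid_b:
        raise FitError(f"dose grids differ: {grid_a} vs {grid_b}")
    a = cv_table_a["cv"].to_numpy(float)
    b = cv_table_b["cv"].to_numpy(float)
    if np.allclose(np.concatenate([a, b]), a[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(a, b)
    mean_a = cv_table_a.groupby("dose")["cv"].mean()
    mean_b = cv_table_b.groupby("dose")["cv"].mean()
    per_dose = pd.concat([mean_a, mean_b], axis=1, keys=["a", "b"])
    folds = per_dose.max(axis=1) / per_dose.min(axis=1)
    return CVComparison(float(H), float(p), float(folds.max()), a.size, b.size)
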
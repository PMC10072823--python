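"""Gompertz growth-curve fitting and factorial mitonuclear ANOVA.

The growth model is the Zwietering modified Gompertz form
``y(t) = A * exp(-exp(mu*e/A * (lam - t) + 1))``; fitting is nonlinear
least squares with multi-start initialization. Factorial ANOVA uses Type II
sums of squares (statsmodels) because replicate structures are unbalanced.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from mitoevo.errors import ConfigurationError, DegenerateCurveError
from mitoevo.simulate import gompertz

N_STARTS = 10


@dataclass
class GompertzFit:
    """Fitted growth parameters for one colony curve."""

    A: float
    mu: float
    lam: float
    rss: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return gompertz(t, self.A, self.mu, self.lam)


def fit_gompertz(
    time_h: np.ndarray,
    size: np.ndarray,
    n_starts: int = N_STARTS,
    raise_on_degenerate: bool = True,
    seed: int = 0,
) -> GompertzFit:
    """Least-squares Gompertz fit with multi-start initialization.

    Starting points are data-driven (A ~ max size, mu ~ max finite-difference
    slope, lam ~ time of first rise) and jittered; the start with the lowest
    residual sum of squares wins. Flat or monotone-decreasing curves raise
    :class:`DegenerateCurveError` (or return ``converged=False`` when
    ``raise_on_degenerate`` is off).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(size, dtype=float)
    if t.size < 5:
        raise ConfigurationError("need >= 5 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("timepoints must be strictly increasing")
    if np.any(y < 0):
        raise ConfigurationError("sizes must be >= 0")

    y_span = y.max() - y.min()
    if y.max() <= 0 or y_span < 1e-12 * max(y.max(), 1.0) or y[-1] <= y[0]:
        if raise_on_degenerate:
            raise DegenerateCurveError("flat or non-increasing curve")
        return GompertzFit(np.nan, np.nan, np.nan, np.nan, converged=False)

    a0 = float(y.max())
    slopes = np.diff(y) / np.diff(t)
    mu0 = float(max(slopes.max(), 1e-6))
    risen = np.nonzero(y > y[0] + 0.1 * y_span)[0]
    lam0 = float(t[risen[0]]) if risen.size else float(t[0])

    rng = np.random.default_rng(seed)
    starts = [(a0, mu0, lam0)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                a0 * rng.uniform(0.7, 1.3),
                mu0 * rng.uniform(0.3, 2.0),
                max(0.0, lam0 + rng.uniform(-0.3, 0.3) * (t[-1] - t[0])),
            )
        )

    best: GompertzFit | None = None
    bounds = ([1e-9, 1e-9, 0.0], [np.inf, np.inf, float(t[-1])])
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    gompertz, t, y, p0=p0, bounds=bounds, maxfev=20_000
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((gompertz(t, *popt) - y) ** 2))
        if best is None or rss < best.rss:
            best = GompertzFit(float(popt[0]), float(popt[1]), float(popt[2]), rss, True)
    if best is None:
        if raise_on_degenerate:
            raise DegenerateCurveError("optimizer failed for all starts")
        return GompertzFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    return best


def fit_plate(
    curves: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    curve_to_clone: pd.DataFrame | None = None,
    n_starts: int = N_STARTS,
) -> pd.DataFrame:
    """Fit every curve on a plate and aggregate replicates per clone.

    ``curves`` is long format (curve_id, time_h, size) with an optional
    ``clone_id`` column (or supplied via ``curve_to_clone``). Returns one row
    per clone with the median ``mu`` and ``A`` over converged replicate fits,
    the replicate counts, and a ``missing`` flag when nothing converged.
    """
    df = curves.copy()
    if "clone_id" not in df.columns:
        if curve_to_clone is not None:
            df = df.merge(curve_to_clone, on="curve_id", how="left")
        else:
            df["clone_id"] = df["curve_id"]

    fit_rows = []
    for (clone, curve), sub in df.groupby(["clone_id", "curve_id"], sort=True):
        sub = sub.sort_values("time_h")
        fit = fit_gompertz(
            sub["time_h"].to_numpy(),
            sub["size"].to_numpy(),
            n_starts=n_starts,
            raise_on_degenerate=False,
        )
        fit_rows.append(
            {
                "clone_id": clone,
                "curve_id": curve,
                "A": fit.A,
                "mu": fit.mu,
                "lam": fit.lam,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    fits = pd.DataFrame(fit_rows)

    rows = []
    for clone, sub in fits.groupby("clone_id", sort=True):
        ok = sub[sub["converged"]]
        rows.append(
            {
                "clone_id": clone,
                "mu": float(ok["mu"].median()) if len(ok) else np.nan,
                "A": float(ok["A"].median()) if len(ok) else np.nan,
                "n_replicates": int(len(ok)),
                "n_failed": int(len(sub) - len(ok)),
                "missing": len(ok) == 0,
            }
        )
    per_clone = pd.DataFrame(rows)
    if metadata is not None:
        per_clone = per_clone.merge(metadata, on="clone_id", how="left")
    return per_clone


def factorial_anova(
    values: np.ndarray | pd.Series,
    factors: dict[str, np.ndarray | pd.Series],
    include_interactions: bool = True,
    ss_type: int = 2,
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA with Type II sums of squares.

    ``factors`` maps factor names to label vectors (2 or 3 factors). Returns
    the ANOVA table with one row per term (main effects, interactions,
    residual) and columns ``term, sum_sq, df, F, p``.
    """
    if not 2 <= len(factors) <= 3:
        raise ConfigurationError("factorial_anova supports 2 or 3 factors")
    data = pd.DataFrame({k: np.asarray(v) for k, v in factors.items()})
    data["_y"] = np.asarray(values, dtype=float)
    for name, col in factors.items():
        if len(pd.unique(np.asarray(col))) < 2:
            raise ConfigurationError(f"factor {name} needs >= 2 levels")
        if len(col) != len(data):
            raise ConfigurationError("factor vectors must match values in length")

    names = list(factors)
    terms = [(n,) for n in names]
    if include_interactions:
        for k in range(2, len(names) + 1):
            for combo in itertools.combinations(names, k):
                # an interaction with a structurally empty cell is inestimable
                cell_counts = data.groupby(list(combo), observed=False).size()
                n_levels = np.prod([data[c].nunique() for c in combo])
                if len(cell_counts) < n_levels or (cell_counts == 0).any():
                    warnings.warn(
                        f"term {':'.join(combo)} dropped: empty design cells"
                    )
                    continue
                terms.append(combo)
    formula = "_y ~ " + " + ".join(
        ":".join(f"C({n})" for n in combo) for combo in terms
    )
    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=ss_type)

    table = table.rename(
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    table.index = [_clean_term(ix) for ix in table.index]
    table.index.name = "term"
    return table.reset_index()[["term", "sum_sq", "df", "F", "p"]]


def _clean_term(term: str) -> str:
    return term.replace("C(", "").replace(")", "").strip()


def tukey_posthoc(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons with studentized-range adjustment.

    Returns ``group1, group2, mean_diff, p_adj, significant``; comparisons
    involving a singleton group get ``p_adj = NaN`` and are never flagged.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ConfigurationError("need >= 2 groups")
    sizes = {lv: int((g == lv).sum()) for lv in levels}
    singletons = {lv for lv, n in sizes.items() if n < 2}

    usable = ~np.isin(g, list(singletons))
    results: dict[tuple[str, str], tuple[float, float]] = {}
    if len(set(g[usable])) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_tukeyhsd(y[usable], g[usable], alpha=alpha)
        frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        for _, r in frame.iterrows():
            results[(str(r["group1"]), str(r["group2"]))] = (
                float(r["meandiff"]),
                float(r["p-adj"]),
            )

    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        key = (str(g1), str(g2))
        if g1 in singletons or g2 in singletons:
            md = float(np.mean(y[g == g2]) - np.mean(y[g == g1]))
            rows.append(
                {"group1": g1, "group2": g2, "mean_diff": md, "p_adj": np.nan,
                 "significant": False}
            )
            continue
        md, p = results[key]
        rows.append(
            {"group1": g1, "group2": g2, "mean_diff": md, "p_adj": p,
             "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)
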
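"""Group-level statistics over the feature table and per-participant
curves.

Two-group comparisons follow a gated decision tree: Shapiro-Wilk normality
per group (α = 0.05; if either group rejects and all values are positive,
both groups are log-transformed, otherwise the comparison proceeds
untransformed with a flag), then Levene's test for equal variances —
Student's t if variances look equal, Welch's t otherwise.  ANCOVA fits the
parallel-lines linear model ``value ~ group + age + sex + education``
(no group×covariate interactions); constant covariate columns are dropped.
Four-subgroup models add all six pairwise contrasts with Bonferroni
adjustment.  α = 0.05 throughout.  Pointwise time/frequency masks are
uncorrected and exploratory by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .io import MAIN_GROUP, SEVEN_BANDS

__all__ = ["ComparisonResult", "compare_two_groups", "ancova_groups",
           "grand_average_curves", "interval_comparison", "band_comparison"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    variable: str
    comparison: str              # e.g. "HC vs MCI" or "4 subgroups"
    test: str                    # "t" | "Welch-t" | "ANCOVA"
    statistic: float
    p: float
    adjusted_p: float | None = None
    transform: str = "none"      # "none" | "log" | "log-skipped"
    covariates: tuple = ()
    posthoc: dict = field(default_factory=dict)   # pair -> Bonferroni p

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _normality_gate(groups: list[np.ndarray]) -> str:
    """Shapiro-Wilk per group; returns the transform decision."""
    reject = False
    for g in groups:
        if len(g) >= 3 and np.ptp(g) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if sps.shapiro(g).pvalue < ALPHA:
                    reject = True
    if not reject:
        return "none"
    if all(np.all(g > 0) for g in groups):
        return "log"
    return "log-skipped"         # transform required but data not positive


def compare_two_groups(table: pd.DataFrame, variable: str,
                       group_col: str = "main_group",
                       groups: tuple = ("HC", "MCI")) -> ComparisonResult:
    """Normality/variance-gated independent-samples comparison."""
    vals = []
    for g in groups:
        v = table.loc[table[group_col] == g, variable].to_numpy(float)
        v = v[np.isfinite(v)]
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
        vals.append(v)
    transform = _normality_gate(vals)
    if transform == "log":
        vals = [np.log(v) for v in vals]
    equal_var = sps.levene(*vals).pvalue >= ALPHA
    res = sps.ttest_ind(*vals, equal_var=equal_var)
    return ComparisonResult(variable=variable,
                            comparison=f"{groups[0]} vs {groups[1]}",
                            test="t" if equal_var else "Welch-t",
                            statistic=float(res.statistic),
                            p=float(res.pvalue), transform=transform)


def _design(table: pd.DataFrame, variable: str, group_col: str,
            covariates: tuple) -> tuple:
    df = table.dropna(subset=[variable]).copy()
    y = df[variable].to_numpy(float)
    cols = {}
    levels = sorted(df[group_col].unique())
    for lev in levels[1:]:
        cols[f"g_{lev}"] = (df[group_col] == lev).astype(float).to_numpy()
    used = []
    for cov in covariates:
        v = df[cov]
        if v.dtype == object or str(v.dtype) == "category":
            codes = pd.Categorical(v).codes.astype(float)
        else:
            codes = v.to_numpy(float)
        if np.ptp(codes) > 0:                  # drop constant covariates
            cols[cov] = codes
            used.append(cov)
    X = pd.DataFrame(cols)
    X = sm.add_constant(X, has_constant="add")
    return y, X, levels, tuple(used)


def ancova_groups(table: pd.DataFrame, variable: str,
                  covariates: tuple = ("age", "sex", "education"),
                  group_col: str = "main_group") -> ComparisonResult:
    """Parallel-lines ANCOVA: omnibus group effect adjusted for covariates;
    for four subgroups, all six Bonferroni-adjusted pairwise contrasts."""
    df = table.dropna(subset=[variable]).copy()
    groups = [df.loc[df[group_col] == g, variable].to_numpy(float)
              for g in sorted(df[group_col].unique())]
    transform = _normality_gate(groups)
    if transform == "log":
        df[variable] = np.log(df[variable].to_numpy(float))
    y, X, levels, used = _design(df, variable, group_col, covariates)
    model = sm.OLS(y, X).fit()
    gcols = [c for c in X.columns if c.startswith("g_")]
    if not gcols:
        raise ValueError("only one group present")
    # omnibus F for the group term (restriction: all group coefs = 0)
    contrast = pd.DataFrame(0.0, index=gcols, columns=X.columns)
    for c in gcols:
        contrast.loc[c, c] = 1.0
    f = model.f_test(contrast.to_numpy())
    result = ComparisonResult(variable=variable,
                              comparison=" vs ".join(levels)
                              if len(levels) == 2 else f"{len(levels)} subgroups",
                              test="ANCOVA", statistic=float(f.fvalue),
                              p=float(f.pvalue), transform=transform,
                              covariates=used)
    if len(levels) > 2:
        n_pairs = len(levels) * (len(levels) - 1) // 2
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                vec = np.zeros(X.shape[1])
                if f"g_{a}" in X.columns:
                    vec[X.columns.get_loc(f"g_{a}")] = 1.0
                if f"g_{b}" in X.columns:
                    vec[X.columns.get_loc(f"g_{b}")] -= 1.0
                t = model.t_test(vec)
                result.posthoc[f"{a} vs {b}"] = min(1.0,
                                                    n_pairs * float(t.pvalue))
    return result


# --------------------------------------------------------------------------
# Curve-level comparisons
# --------------------------------------------------------------------------

def grand_average_curves(curves: np.ndarray, axis_vals: np.ndarray,
                         groups: np.ndarray) -> dict:
    """Pointwise group means of per-participant curves.

    ``curves``: [participant x axis]; ``groups``: label per participant.
    Returns ``{label: mean curve}``; the axis is echoed under ``"axis"``.
    """
    curves = np.asarray(curves, float)
    if curves.shape[1] != len(axis_vals):
        raise ValueError("curve/axis length mismatch")
    out = {"axis": np.asarray(axis_vals, float)}
    for g in pd.unique(np.asarray(groups)):
        out[g] = curves[np.asarray(groups) == g].mean(axis=0)
    return out


def _windowed_comparison(curves, axis_vals, groups, windows, unit,
                         group_pair=("HC", "MCI")):
    curves = np.asarray(curves, float)
    axis_vals = np.asarray(axis_vals, float)
    groups = np.asarray(groups)
    results = []
    for name, (lo, hi) in windows.items():
        m = (axis_vals >= lo) & (axis_vals < hi)
        if not m.any():
            raise ValueError(f"window {name} covers no axis points")
        table = pd.DataFrame({"value": curves[:, m].mean(axis=1),
                              "main_group": groups})
        res = compare_two_groups(table, "value", groups=group_pair)
        res.variable = f"{name} [{lo:g}-{hi:g} {unit})"
        results.append(res)
    # pointwise exploratory mask (uncorrected Welch t per axis point)
    a = curves[groups == group_pair[0]]
    b = curves[groups == group_pair[1]]
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    return results, p < ALPHA


def interval_comparison(plv_curves: np.ndarray, times_ms: np.ndarray,
                        groups: np.ndarray, n_intervals: int = 7,
                        span: tuple = (0.0, 700.0),
                        group_pair: tuple = ("HC", "MCI")):
    """Compare group means of PLV curves over consecutive 100 ms intervals
    (seven bins over 0–700 ms by default) plus a pointwise mask."""
    edges = np.linspace(span[0], span[1], n_intervals + 1)
    windows = {f"interval_{i+1}": (edges[i], edges[i + 1])
               for i in range(n_intervals)}
    return _windowed_comparison(plv_curves, times_ms, groups, windows,
                                "ms", group_pair)


def band_comparison(coh_curves: np.ndarray, freqs_hz: np.ndarray,
                    groups: np.ndarray, bands: dict | None = None,
                    group_pair: tuple = ("HC", "MCI")):
    """Compare group means of coherence spectra over the seven named
    frequency ranges plus a per-bin mask."""
    bands = dict(SEVEN_BANDS if bands is None else bands)
    return _windowed_comparison(coh_curves, freqs_hz, groups, bands,
                                "Hz", group_pair)


def add_main_group(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the HC/MCI main-group column from the subgroup labels."""
    out = table.copy()
    out["main_group"] = out["subgroup"].map(MAIN_GROUP)
    return out
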
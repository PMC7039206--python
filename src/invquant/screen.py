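"""Vesicle-capture screen statistics.

Per-cell mitochondrial intensity ratios (post/pre), mean-difference effect
sizes against a control construct with bias-corrected and accelerated
(BCa) bootstrap confidence intervals, family-wise many-to-one comparisons
per trial via a max-t permutation test, and co-rerouting correlation
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "CorrelationResult",
    "validate_screen_table",
    "mito_ratio",
    "effect_size_bca",
    "dunnett_vs_control",
    "rerouting_correlation",
    "screen_report",
]

CONTROL = "GFP"


@dataclass
class EffectSize:
    construct: str
    mean_diff: float
    ci_low: float
    ci_high: float
    n_cells: int
    alpha: float = 0.05
    method: str = "bca"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("CI must bracket the observed mean difference")

    @property
    def is_hit(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_value: float
    slope_se: float
    shape: str  # "rising" | "high-flat" | "low-flat"


def validate_screen_table(table: pd.DataFrame, control: str = CONTROL) -> pd.DataFrame:
    """Check required columns and invariants; add the ``ratio`` column."""
    required = {"construct", "trial", "F_pre", "F_post"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    if (table["F_pre"] <= 0).any():
        raise ValueError("F_pre must be positive for every cell")
    if control not in set(table["construct"]):
        raise ValueError(f"control construct {control!r} absent from table")
    control_trials = set(table.loc[table["construct"] == control, "trial"])
    all_trials = set(table["trial"])
    if control_trials != all_trials:
        raise ValueError(
            f"control {control!r} must be present in every trial "
            f"(has {sorted(control_trials)}, table has {sorted(all_trials)})"
        )
    out = table.copy()
    out["ratio"] = out["F_post"] / out["F_pre"]
    return out


def mito_ratio(f_pre: float, f_post: float) -> float:
    """Post/pre mitochondrial intensity ratio for one cell."""
    if f_pre <= 0:
        raise ValueError("F_pre must be positive")
    return f_post / f_pre


# ---------------------------------------------------------------------------
# BCa bootstrap effect sizes
# ---------------------------------------------------------------------------


def _bca_bounds(theta_hat, boot, jack, alpha):
    """BCa interval bounds from bootstrap and jackknife statistics.

    z0 from the fraction of resamples below the observed statistic;
    acceleration from the jackknife skewness.  Returns (lo, hi, flags).
    """
    flags = {}
    below = np.mean(boot < theta_hat)
    if below <= 0.0 or below >= 1.0:
        flags["degenerate"] = "all resamples on one side; percentile fallback"
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi), flags
    z0 = stats.norm.ppf(below)
    jmean = jack.mean()
    num = np.sum((jmean - jack) ** 3)
    den = 6.0 * np.sum((jmean - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0

    z_alpha = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi), flags


def effect_size_bca(
    table: pd.DataFrame,
    construct: str,
    control: str = CONTROL,
    n_boot: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EffectSize:
    """Mean ratio difference vs control with a BCa bootstrap interval.

    Both groups are resampled independently, stratified by trial when
    trial labels are present; the acceleration term comes from the pooled
    leave-one-out (jackknife) statistics.  Deterministic under ``seed``.
    """
    table = validate_screen_table(table, control=control)
    x = table.loc[table["construct"] == construct]
    y = table.loc[table["construct"] == control]
    if len(x) < 5 or len(y) < 5:
        raise ValueError("construct and control each need >= 5 cells")

    rng = np.random.default_rng(seed)

    def stratified_boot(group: pd.DataFrame) -> np.ndarray:
        """(n_boot,) bootstrap means, resampling within each trial."""
        parts = []
        for _, sub in group.groupby("trial"):
            # sorted so the interval is invariant to cell relabeling
            vals = np.sort(sub["ratio"].to_numpy())
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            parts.append(vals[idx])
        return np.concatenate(parts, axis=1).mean(axis=1)

    theta_hat = x["ratio"].mean() - y["ratio"].mean()
    boot = stratified_boot(x) - stratified_boot(y)

    # pooled leave-one-out statistics over both groups
    xv = x["ratio"].to_numpy()
    yv = y["ratio"].to_numpy()
    jack = np.empty(len(xv) + len(yv))
    sx, sy_ = xv.sum(), yv.sum()
    for i in range(len(xv)):
        jack[i] = (sx - xv[i]) / (len(xv) - 1) - sy_ / len(yv)
    for j in range(len(yv)):
        jack[len(xv) + j] = sx / len(xv) - (sy_ - yv[j]) / (len(yv) - 1)

    if np.std(xv) == 0 and np.std(yv) == 0:
        lo = hi = theta_hat
        flags = {"degenerate": "zero variance in both groups"}
    else:
        lo, hi, flags = _bca_bounds(theta_hat, boot, jack, alpha)
    lo = min(lo, theta_hat)
    hi = max(hi, theta_hat)
    return EffectSize(
        construct=construct,
        mean_diff=float(theta_hat),
        ci_low=lo,
        ci_high=hi,
        n_cells=len(x),
        alpha=alpha,
        method="bca" if "degenerate" not in flags else "percentile",
        flags=flags,
    )


# ---------------------------------------------------------------------------
# many-to-one permutation test (max-t)
# ---------------------------------------------------------------------------


def _t_stats(groups: list[np.ndarray], control: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistics of each group vs control."""
    out = np.empty(len(groups))
    nc = len(control)
    mc = control.mean()
    vc = control.var(ddof=1)
    for i, g in enumerate(groups):
        ng = len(g)
        sp2 = ((ng - 1) * g.var(ddof=1) + (nc - 1) * vc) / (ng + nc - 2)
        denom = np.sqrt(sp2 * (1.0 / ng + 1.0 / nc))
        out[i] = (g.mean() - mc) / denom if denom > 0 else 0.0
    return out


def dunnett_vs_control(
    table: pd.DataFrame,
    trial,
    control: str = CONTROL,
    n_perm: int = 10_000,
    seed: int = 0,
    min_cells: int = 3,
) -> dict[str, float]:
    """Family-wise p-values of each construct vs control within one trial.

    Many-to-one comparisons with family-wise error control via a max-|t|
    permutation test: construct labels are permuted over all cells in the
    trial and each observed |t| is compared with the permutation
    distribution of the maximum |t|.
    """
    table = validate_screen_table(table, control=control)
    sub = table.loc[table["trial"] == trial]
    if sub.empty:
        raise ValueError(f"no rows for trial {trial!r}")

    names = []
    groups = []
    for construct, grp in sub.groupby("construct", sort=False):
        if construct == control:
            continue
        if len(grp) < min_cells:
            warnings.warn(
                f"construct {construct!r} has < {min_cells} cells in trial "
                f"{trial!r}; excluded"
            )
            continue
        names.append(construct)
        groups.append(grp["ratio"].to_numpy())
    ctrl = sub.loc[sub["construct"] == control, "ratio"].to_numpy()
    if not names:
        raise ValueError("need >= 1 eligible construct besides the control")

    t_obs = np.abs(_t_stats(groups, ctrl))

    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups + [ctrl])
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(pooled)
        start = 0
        pg = []
        for s in sizes:
            pg.append(perm[start:start + s])
            start += s
        pc = perm[start:]
        max_t[p] = np.abs(_t_stats(pg, pc)).max()

    # tie tolerance: permutations reproducing the observed split must count
    pvals = {
        name: float((np.sum(max_t >= t - 1e-9 * max(1.0, t)) + 1)
                    / (n_perm + 1))
        for name, t in zip(names, t_obs)
    }
    return pvals


# ---------------------------------------------------------------------------
# co-rerouting correlation
# ---------------------------------------------------------------------------


def rerouting_correlation(
    anchor_ratio: np.ndarray,
    partner_ratio: np.ndarray,
    slope_flat: float = 0.25,
    intercept_high: float = 1.5,
) -> CorrelationResult:
    """OLS line of partner co-rerouting ratio on anchor rerouting ratio.

    Classifies the relationship shape against the y = x reference:
    ``rising`` (slope above ``slope_flat``), else ``high-flat`` or
    ``low-flat`` by whether the intercept exceeds ``intercept_high``.
    """
    x = np.asarray(anchor_ratio, dtype=float)
    y = np.asarray(partner_ratio, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired series must have equal length")
    if len(x) < 5:
        raise ValueError("need >= 5 paired cells")
    if np.std(x) == 0:
        raise ValueError("zero variance in the anchor ratios")
    res = stats.linregress(x, y)
    if res.slope > slope_flat:
        shape = "rising"
    elif res.intercept > intercept_high:
        shape = "high-flat"
    else:
        shape = "low-flat"
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        slope_se=float(res.stderr),
        shape=shape,
    )


def screen_report(
    table: pd.DataFrame,
    control: str = CONTROL,
    n_boot: int = 100_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled BCa effect sizes plus per-trial p-values, ranked by effect."""
    table = validate_screen_table(table, control=control)
    trials = sorted(set(table["trial"]))
    per_trial = {t: dunnett_vs_control(table, t, control=control,
                                       n_perm=n_perm, seed=seed)
                 for t in trials}
    rows = []
    for construct in table["construct"].unique():
        if construct == control:
            continue
        es = effect_size_bca(table, construct, control=control,
                             n_boot=n_boot, seed=seed)
        row = {
            "construct": construct,
            "mean_diff": es.mean_diff,
            "ci_low": es.ci_low,
            "ci_high": es.ci_high,
            "n_cells": es.n_cells,
            "hit_pooled": es.is_hit,
        }
        for t in trials:
            row[f"p_trial_{t}"] = per_trial[t].get(construct, np.nan)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("mean_diff", ascending=False)
    return out.reset_index(drop=True)
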
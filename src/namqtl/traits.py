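"""Trait derivation, spatial field adjustment, combined analysis, heritability.

Derived traits follow the standard plot-level formulas:

    GY (kg/ha)      = plot grain weight / plot area x 10,000
    TKW (g)         = weight of 200 kernels x 5
    GFP (days)      = days to maturity - days to heading
    GFR (g/day)     = TKW / GFP
    Spk.m2          = spikes per linear meter x 4
    Gr.m2           = (grain weight in g per m2) / (single kernel weight in g)
    Grn.Spk         = Gr.m2 / Spk.m2

Spatial adjustment fits additive entry + row + column effects per
environment by backfitting (the replicated checks connect the design),
and the combined analysis uses method-of-moments variance components on
the environment x entry mean table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

DERIVED_TRAITS = ("GY", "TKW", "GFP", "GFR", "Spk.m2", "Gr.m2", "Grn.Spk")


def derive_traits(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Append the derived trait columns; missing inputs yield NaN."""
    t = plot_table.copy()
    area = t["plot_area"] if "plot_area" in t else 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        t["GY"] = t["plot_grain_weight"] / area * 1e4
        t["TKW"] = t["kernel_sample_weight"] * 5.0
        gfp = t["DtM"] - t["DtH"]
        t["GFP"] = gfp.where(gfp > 0)
        t["GFR"] = t["TKW"] / t["GFP"]
        t["Spk.m2"] = t["spike_row_count"] * 4.0
        t["Gr.m2"] = (t["plot_grain_weight"] * 1000.0 / area) / (t["TKW"] / 1000.0)
        spk = t["Spk.m2"].where(t["Spk.m2"] > 0)
        t["Grn.Spk"] = t["Gr.m2"] / spk
    return t


def adjust_spatial(
    plot_table: pd.DataFrame,
    trait: str,
    model: str = "linear",
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> pd.DataFrame:
    """Per-environment entry means adjusted for additive row/column effects.

    model="linear" (default) fits a linear trend over row and column
    indices jointly with the entry effects; in an augmented design with
    mostly unreplicated entries this spends 2 degrees of freedom and
    leaves the entry-mean error essentially at the plot error.
    model="levels" backfits a free effect per row and per column, which
    removes arbitrary additive row/column patterns but is close to
    saturated when only the checks are replicated.  In both models the
    effects are centred, so the environment grand mean is untouched,
    and a purely additive linear trend is removed exactly in the
    noiseless case.  Returns long-format entry means (env_id, entry_id,
    trait, adjusted_value, n_plots).
    """
    if trait not in plot_table.columns:
        raise KeyError(f"trait {trait!r} not in plot table")
    if model not in ("linear", "levels"):
        raise ValueError("model must be 'linear' or 'levels'")
    out = []
    for env, sub in plot_table.groupby("env_id", sort=True):
        sub = sub.dropna(subset=[trait])
        if sub.empty:
            raise ValueError(f"trait {trait!r} entirely missing in {env}")
        if sub["row"].nunique() < 2 or sub["column"].nunique() < 2:
            raise ValueError(f"{env}: need >=2 rows and >=2 columns")
        y = sub[trait].to_numpy(dtype=float)
        entry_codes, entries = pd.factorize(sub["entry_id"])
        n_entry = np.bincount(entry_codes).astype(float)
        if model == "linear":
            spatial = _backfit_linear(y, entry_codes, n_entry,
                                      sub["row"].to_numpy(dtype=float),
                                      sub["column"].to_numpy(dtype=float),
                                      max_iter, tol)
        else:
            spatial = _backfit_levels(y, entry_codes, n_entry,
                                      sub["row"], sub["column"], max_iter, tol)
        adj = y - spatial
        means = pd.DataFrame({
            "env_id": env,
            "entry_id": entries,
            "trait": trait,
            "adjusted_value": np.bincount(entry_codes, adj) / n_entry,
            "n_plots": n_entry.astype(int),
        })
        out.append(means)
    return pd.concat(out, ignore_index=True)


def _backfit_linear(y, entry_codes, n_entry, row, col, max_iter, tol):
    """Alternate entry means with OLS on centred row/col indices."""
    r_c = row - row.mean()
    c_c = col - col.mean()
    X = np.column_stack([r_c, c_c])
    beta = np.zeros(2)
    g = np.zeros(len(n_entry))
    for _ in range(max_iter):
        g_new = np.bincount(entry_codes, y - X @ beta) / n_entry
        resid = y - g_new[entry_codes]
        beta_new, *_ = np.linalg.lstsq(X, resid - resid.mean(), rcond=None)
        delta = max(np.abs(g_new - g).max(), np.abs(beta_new - beta).max())
        g, beta = g_new, beta_new
        if delta < tol:
            break
    trend = X @ beta
    return trend - trend.mean()


def _backfit_levels(y, entry_codes, n_entry, row, col, max_iter, tol):
    row_codes, _ = pd.factorize(row)
    col_codes, _ = pd.factorize(col)
    g = np.zeros(len(n_entry))
    r = np.zeros(row_codes.max() + 1)
    c = np.zeros(col_codes.max() + 1)
    n_row = np.bincount(row_codes).astype(float)
    n_col = np.bincount(col_codes).astype(float)
    for _ in range(max_iter):
        g_new = np.bincount(entry_codes, y - r[row_codes] - c[col_codes]) / n_entry
        r_new = np.bincount(row_codes, y - g_new[entry_codes] - c[col_codes]) / n_row
        r_new -= np.average(r_new, weights=n_row)
        c_new = np.bincount(col_codes, y - g_new[entry_codes] - r_new[row_codes]) / n_col
        c_new -= np.average(c_new, weights=n_col)
        delta = max(np.abs(g_new - g).max(), np.abs(r_new - r).max(),
                    np.abs(c_new - c).max())
        g, r, c = g_new, r_new, c_new
        if delta < tol:
            break
    return r[row_codes] + c[col_codes]


def combine_environments(
    entry_means: pd.DataFrame,
    env_subset: Sequence[str] | None = None,
    sigma2_e: float = 0.0,
    n_rep: float = 1.0,
    value_col: str = "adjusted_value",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Random-effects combination of per-environment entry means.

    Method-of-moments on the env x entry table: the genotype mean
    square estimates n_env*sigma2_g above the interaction mean square,
    and the interaction mean square estimates sigma2_ge + sigma2_e /
    n_rep (a plot-level error variance, e.g. from check replicates,
    must be supplied to split the two).  Shrunk values are BLUP-style:
    grand + h * (entry mean - grand) with
    h = sigma2_g / (sigma2_g + (sigma2_ge + sigma2_e/n_rep) / n_env).
    """
    em = entry_means
    if env_subset is not None:
        em = em[em["env_id"].isin(env_subset)]
    wide = em.pivot_table(index="entry_id", columns="env_id", values=value_col)
    wide = wide.dropna(axis=0, how="all")
    if wide.shape[1] < 2:
        raise ValueError("combined analysis needs >= 2 environments")
    if wide.isna().any().any():
        # entries absent from some environments: centre within environment
        # then fill with the environment mean (neutral cell)
        wide = wide.apply(lambda col: col.fillna(col.mean()))
    n_env = wide.shape[1]
    n_g = wide.shape[0]
    grand = float(wide.to_numpy().mean())
    g_means = wide.mean(axis=1)
    e_means = wide.mean(axis=0)
    resid = wide.to_numpy() - g_means.to_numpy()[:, None] - e_means.to_numpy()[None, :] + grand
    ms_g = n_env * float(((g_means - grand) ** 2).sum()) / (n_g - 1)
    ms_ge = float((resid**2).sum()) / ((n_g - 1) * (n_env - 1))
    sigma2_ge = max(ms_ge - sigma2_e / n_rep, 0.0)
    sigma2_g = max((ms_g - ms_ge) / n_env, 0.0)
    denom = sigma2_g + (sigma2_ge + sigma2_e / n_rep) / n_env
    h = sigma2_g / denom if denom > 0 else 0.0
    shrunk = grand + h * (g_means - grand)
    table = pd.DataFrame({
        "entry_id": wide.index,
        "mean_value": g_means.to_numpy(),
        "shrunk_value": shrunk.to_numpy(),
    }).reset_index(drop=True)
    components = {
        "sigma2_g": sigma2_g, "sigma2_ge": sigma2_ge, "sigma2_e": sigma2_e,
        "n_env": float(n_env), "n_rep": float(n_rep), "grand_mean": grand,
        "shrinkage": h,
    }
    return table, components


def heritability(components: dict[str, float]) -> float:
    """Entry-mean broad-sense heritability, bounded to [0, 1].

    H2 = s2_g / (s2_g + s2_ge/n_env + s2_e/(n_env * n_rep)).
    """
    s2g = max(components["sigma2_g"], 0.0)
    s2ge = max(components["sigma2_ge"], 0.0)
    s2e = max(components["sigma2_e"], 0.0)
    n_env = components["n_env"]
    n_rep = components.get("n_rep", 1.0)
    denom = s2g + s2ge / n_env + s2e / (n_env * n_rep)
    if denom == 0:
        raise ValueError("zero total variance")
    return min(max(s2g / denom, 0.0), 1.0)


def ratio_to_best_combine(
    entry_means: pd.DataFrame,
    env_subset: Sequence[str] | None = None,
    value_col: str = "adjusted_value",
) -> pd.Series:
    """Per-entry mean of value / (best value in that environment)."""
    em = entry_means
    if env_subset is not None:
        em = em[em["env_id"].isin(env_subset)]
    wide = em.pivot_table(index="entry_id", columns="env_id", values=value_col)
    best = wide.max(axis=0)
    if (best <= 0).any():
        raise ValueError("ratio-to-best needs strictly positive environment maxima")
    return (wide / best).mean(axis=1).rename("ratio_to_best")
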
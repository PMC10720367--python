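"""Growth-stage climate matrices, factor screening and environment clustering.

Environments are characterised by temperature means and rainfall totals
over four growth-stage windows (pre-sowing month, sowing to end of
vegetative stage, flowering, grain filling).  Factors whose regression
on site trait means is significant are used to cluster environments
with Ward linkage on Euclidean distance, typically separating
moisture-stressed from non-stressed sites.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

STAGES = ("pre_sowing", "vegetative", "flowering", "grain_fill")


def build_climate_matrix(
    daily_weather: pd.DataFrame,
    stage_dates: pd.DataFrame,
    max_missing_frac: float = 0.10,
) -> pd.DataFrame:
    """Per-environment stage window summaries (wide, one row per env).

    daily_weather: site, date, tmin, tmax, rain.
    stage_dates: env_id, stage, start, end (end exclusive); windows must
    be chronologically ordered and non-overlapping.
    """
    rows = {}
    for env, st in stage_dates.groupby("env_id"):
        st = st.set_index("stage").loc[[s for s in STAGES if s in st["stage"].values]]
        starts = pd.to_datetime(st["start"])
        ends = pd.to_datetime(st["end"])
        if (ends <= starts).any():
            raise ValueError(f"{env}: empty or inverted stage window")
        if not (starts.to_numpy()[1:] >= ends.to_numpy()[:-1]).all():
            raise ValueError(f"{env}: stage windows overlap or out of order")
        daily = daily_weather[daily_weather["site"] == env].copy()
        daily["date"] = pd.to_datetime(daily["date"])
        rec: dict[str, float] = {}
        for stage in st.index:
            a, b = starts[stage], ends[stage]
            win = daily[(daily["date"] >= a) & (daily["date"] < b)]
            expected = (b - a).days
            if len(win) < (1 - max_missing_frac) * expected or win.empty:
                raise ValueError(f"{env}/{stage}: >{max_missing_frac:.0%} days missing")
            rec[f"{stage}_tmax_mean"] = float(win["tmax"].mean())
            rec[f"{stage}_tmin_mean"] = float(win["tmin"].mean())
            rec[f"{stage}_tavg_mean"] = float(((win["tmax"] + win["tmin"]) / 2).mean())
            rec[f"{stage}_rain_total"] = float(win["rain"].sum())
        rows[env] = rec
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("env_id")


def screen_factors(
    climate_matrix: pd.DataFrame,
    site_trait_means: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate regression of each climate factor on site trait means.

    Returns one row per factor with slope, p-value and a significance
    flag at `alpha`.  Zero-variance factors are skipped with a warning.
    """
    envs = climate_matrix.index.intersection(site_trait_means.index)
    if len(envs) < 4:
        raise ValueError("factor screening needs >= 4 environments")
    y = site_trait_means.loc[envs].to_numpy(dtype=float)
    recs = []
    for factor in climate_matrix.columns:
        x = climate_matrix.loc[envs, factor].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"factor {factor} has zero variance; skipped")
            continue
        res = stats.linregress(x, y)
        recs.append({"factor": factor, "slope": res.slope, "r": res.rvalue,
                     "p_value": res.pvalue, "significant": res.pvalue < alpha})
    return pd.DataFrame(recs)


def cluster_environments(
    selected_factors: pd.DataFrame,
    k: int = 2,
    standardize: bool = True,
) -> tuple[pd.Series, np.ndarray]:
    """Ward/Euclidean clustering of environments on (standardized) factors.

    Returns (labels indexed by env_id, scipy linkage matrix).  A
    degenerate cut (all points identical) is flagged with a warning.
    """
    if k > len(selected_factors):
        raise ValueError(f"k={k} exceeds {len(selected_factors)} environments")
    X = selected_factors.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    # stable ordering: sort rows by env label before linkage
    order = np.argsort(selected_factors.index.to_numpy())
    Z = hierarchy.linkage(pdist(X[order]), method="ward")
    if np.allclose(Z[:, 2], 0):
        warnings.warn("all environments identical: k-cluster cut is degenerate")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(index=selected_factors.index[order], dtype=int)
    labels[:] = raw
    return labels.reindex(selected_factors.index), Z


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string for inspection."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
                f":{length:.6g}")

    return walk(tree, tree.dist) + ";"
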
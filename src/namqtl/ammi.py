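"""AMMI decomposition, AWAI stability index and stable-performer selection.

The additive main effects and multiplicative interaction (AMMI) model
removes grand mean, genotype and environment main effects from a
complete genotype x environment table and decomposes the residual by
SVD.  Axis k has singular value lambda_k, genotype score
IPCA_k = u_k * sqrt(lambda_k) (symmetric scaling) and share
s_k = lambda_k^2 / sum_j lambda_j^2 of the interaction sum of squares.

The AMMI wide adaptation index per genotype is

    AWAI_g = sum over retained axes of s_k * |IPCA_k(g)|

so widely adapted genotypes score near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AmmiDecomposition:
    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray           # descending
    genotype_scores: pd.DataFrame         # entries x axes, u*sqrt(lambda)
    environment_loadings: pd.DataFrame    # envs x axes, v*sqrt(lambda)
    variance_share: np.ndarray            # s_k = lambda_k^2 / sum lambda^2

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    @property
    def interaction_ss(self) -> float:
        return float((self.singular_values**2).sum())

    def reconstruct(self) -> pd.DataFrame:
        """Grand + genotype + environment + sum_k score_k x loading_k."""
        inter = self.genotype_scores.to_numpy() @ self.environment_loadings.to_numpy().T
        table = (self.grand_mean
                 + self.genotype_effects.to_numpy()[:, None]
                 + self.environment_effects.to_numpy()[None, :]
                 + inter)
        return pd.DataFrame(table, index=self.genotype_effects.index,
                            columns=self.environment_effects.index)


def fit_ammi(ge_table: pd.DataFrame) -> AmmiDecomposition:
    """Fit AMMI to a complete genotype x environment mean table."""
    if ge_table.isna().any().any():
        raise ValueError("AMMI needs a complete table; impute missing cells upstream")
    g, e = ge_table.shape
    if g < 3 or e < 3:
        raise ValueError("AMMI needs >= 3 genotypes and >= 3 environments")
    X = ge_table.to_numpy(dtype=float)
    grand = X.mean()
    g_eff = X.mean(axis=1) - grand
    e_eff = X.mean(axis=0) - grand
    resid = X - grand - g_eff[:, None] - e_eff[None, :]
    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    k = min(g, e) - 1
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    ss = s**2
    total = ss.sum()
    share = ss / total if total > 0 else np.zeros_like(ss)
    scores = U * np.sqrt(s)
    loadings = Vt.T * np.sqrt(s)
    return AmmiDecomposition(
        grand_mean=float(grand),
        genotype_effects=pd.Series(g_eff, index=ge_table.index),
        environment_effects=pd.Series(e_eff, index=ge_table.columns),
        singular_values=s,
        genotype_scores=pd.DataFrame(scores, index=ge_table.index,
                                     columns=[f"IPCA{i+1}" for i in range(k)]),
        environment_loadings=pd.DataFrame(loadings, index=ge_table.columns,
                                          columns=[f"IPCA{i+1}" for i in range(k)]),
        variance_share=share,
    )


def significant_ipca(
    dec: AmmiDecomposition,
    error_ms: float | None = None,
    error_df: float = 1e6,
    alpha: float = 0.05,
    rel_tol: float = 1e-9,
    min_share: float = 0.005,
) -> int:
    """Number of interaction axes retained by a Gollob-style F test.

    Axis k has df_k = g + e - 1 - 2k and mean square lambda_k^2 / df_k.
    With an `error_ms` supplied (e.g. the plot-error mean square on the
    entry-mean scale) the classical Gollob F is used; otherwise each
    axis is tested against the pooled mean square of the axes after it.
    At least one axis is retained whenever the interaction sum of
    squares is non-negligible.
    """
    g = len(dec.genotype_effects)
    e = len(dec.environment_effects)
    ss = dec.singular_values**2
    total = ss.sum()
    if total <= rel_tol * max(abs(dec.grand_mean), 1.0) ** 2:
        return 0
    dfs = np.array([g + e - 1 - 2 * (k + 1) for k in range(dec.n_axes)], dtype=float)
    dfs = np.maximum(dfs, 1.0)
    retained = 0
    for k in range(dec.n_axes):
        if ss[k] <= rel_tol * total:
            break
        ms_k = ss[k] / dfs[k]
        if error_ms is not None:
            if error_ms <= 0:
                retained += 1
                continue
            p = stats.f.sf(ms_k / error_ms, dfs[k], error_df)
        else:
            # pooled-residual surrogate: guard against retaining the top
            # noise axis, whose eigenvalue exceeds the pooled mean by
            # construction, with a minimum interaction-share requirement
            if ss[k] < min_share * total:
                break
            rest_ss = ss[k + 1:].sum()
            rest_df = dfs[k + 1:].sum()
            if rest_df <= 0 or rest_ss <= rel_tol * total:
                retained += 1
                continue
            p = stats.f.sf(ms_k / (rest_ss / rest_df), dfs[k], rest_df)
        if p < alpha:
            retained += 1
        else:
            break
    return max(retained, 1)  # interaction exists, keep at least one axis


def awai(dec: AmmiDecomposition, retained_axes: int) -> pd.DataFrame:
    """AWAI per genotype over the retained axes (0 = widely adapted)."""
    if retained_axes < 1:
        vals = np.zeros(len(dec.genotype_scores))
    else:
        k = min(retained_axes, dec.n_axes)
        scores = np.abs(dec.genotype_scores.to_numpy()[:, :k])
        vals = scores @ dec.variance_share[:k]
    return pd.DataFrame({"entry_id": dec.genotype_scores.index,
                         "awai": vals}).reset_index(drop=True)


def select_stable(
    stability: pd.DataFrame,
    performance: pd.Series,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Rank entries by performance (desc) then AWAI (asc); flag the top slice.

    Ties break lexicographically on the entry label for determinism.
    Output also carries the biplot coordinates (performance, awai).
    """
    df = stability.set_index("entry_id").copy()
    common = df.index.intersection(performance.index)
    df = df.loc[common]
    df["performance"] = performance.loc[common]
    df.index.name = "entry_id"
    df = df.reset_index()
    df["entry_id"] = df["entry_id"].astype(str)
    df = df.sort_values(["performance", "awai", "entry_id"],
                        ascending=[False, True, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    n_sel = max(int(np.ceil(top_fraction * len(df))), 1)
    df["selected"] = df["rank"] <= n_sel
    return df
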
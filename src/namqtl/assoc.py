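"""Association scans, LD-protected thresholds, MTA merging and QTL calling.

Two complementary scans are provided, mirroring the combined
QTL-analysis + GWAS strategy used for NAM panels:

* ``glm_scan`` — general linear model over all lines with population
  structure (Q) and days-to-heading covariates; per-marker partial F
  test of the dosage term.
* ``interval_scan`` — composite interval mapping within a single
  biparental subfamily: stepwise forward-backward marker cofactor
  selection, then a Haley-Knott regression scan on a walking grid with
  cofactors excluded inside a window around the tested position.

Significance uses the LD-protected Bonferroni correction: the number of
effective tests is the map length divided by the LD decay distance, and
the genome-wide p threshold is alpha divided by that count.  Marker-
trait associations closer than twice the LD decay distance cannot be
distinguished and are merged into a single QTL.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._regress import residualise
from .simdata import GeneticMap, GenotypeMatrix

SINGLE_ENV_PREFIX = "env:"


# ---------------------------------------------------------------------------
# GLM scan


def _impute_marker_means(calls: np.ndarray) -> np.ndarray:
    X = calls.astype(float).copy()
    mu = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = mu[nan_c]
    return X


def glm_scan(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    q_covariates: pd.DataFrame | None = None,
    dth_covariate: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-marker GLM test: trait ~ intercept + Q + DtH + dosage.

    Missing dosages are mean-imputed per marker; lines with a missing
    phenotype or covariate are dropped.  Markers monomorphic (or
    collinear with the covariates) in the analysed subset are returned
    with NaN statistics and a skip reason.
    """
    pheno = phenotype.reindex(genotypes.line_ids)
    parts = [pheno.rename("_y")]
    if q_covariates is not None:
        parts.append(q_covariates.reindex(genotypes.line_ids))
    if dth_covariate is not None:
        parts.append(dth_covariate.reindex(genotypes.line_ids).rename("_dth"))
    design = pd.concat(parts, axis=1)
    keep = ~design.isna().any(axis=1)
    design = design[keep]
    n = len(design)
    y = design["_y"].to_numpy(dtype=float)
    C = np.column_stack([np.ones(n)] + [design[c].to_numpy(dtype=float)
                                        for c in design.columns if c != "_y"])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        # drop redundant covariate columns (e.g. complete Q dummies)
        q, r = np.linalg.qr(C)
        indep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1.0)
        C = C[:, indep]
    if n < C.shape[1] + 3:
        raise ValueError("too few lines for the covariate model")
    X = _impute_marker_means(genotypes.calls[keep.to_numpy()])
    mono = X.std(axis=0) == 0
    df = n - C.shape[1] - 1
    y_r = residualise(y, C)
    X_r = residualise(X, C)
    sse0 = float(y_r @ y_r)
    xtx = np.einsum("ij,ij->j", X_r, X_r)
    xty = X_r.T @ y_r
    safe = np.where(xtx > 1e-10, xtx, 1.0)
    gain = np.where(xtx > 1e-10, xty**2 / safe, 0.0)
    beta = np.where(xtx > 1e-10, xty / safe, np.nan)
    sse1 = np.maximum(sse0 - gain, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sse1 > 0, gain / (sse1 / df), np.inf)
        p = stats.f.sf(f, 1, df)
        lod = -np.log10(np.maximum(p, 1e-300))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = gain / sst if sst > 0 else np.zeros_like(gain)
    skip = np.where(mono, "monomorphic",
                    np.where(xtx <= 1e-10, "collinear_with_covariates", ""))
    bad = skip != ""
    if bad.any():
        warnings.warn(f"{int(bad.sum())} markers skipped "
                      f"({pd.Series(skip[bad]).value_counts().to_dict()})")
    out = pd.DataFrame({
        "marker_id": genotypes.marker_ids,
        "p_value": np.where(bad, np.nan, p),
        "lod": np.where(bad, np.nan, lod),
        "effect": np.where(bad, np.nan, beta),
        "r2": np.where(bad, np.nan, r2),
        "n": n,
        "skip_reason": skip,
    })
    return out


# ---------------------------------------------------------------------------
# composite interval scan


def stepwise_cofactors(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.001,
    max_cofactors: int | None = None,
) -> list[int]:
    """Forward-backward stepwise marker selection at the given p threshold."""
    n, m = X.shape
    if max_cofactors is None:
        max_cofactors = max(n // 10, 1)
    selected: list[int] = []
    while len(selected) < max_cofactors:
        C = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        df = n - C.shape[1] - 1
        if df < 2:
            break
        y_r = residualise(y, C)
        X_r = residualise(X, C)
        sse0 = float(y_r @ y_r)
        xtx = np.einsum("ij,ij->j", X_r, X_r)
        xty = X_r.T @ y_r
        safe = np.where(xtx > 1e-10, xtx, 1.0)
        gain = np.where(xtx > 1e-10, xty**2 / safe, 0.0)
        sse1 = np.maximum(sse0 - gain, 1e-300)
        f = gain / (sse1 / df)
        p = stats.f.sf(f, 1, df)
        p[selected] = 1.0
        j = int(np.nanargmin(p))
        if p[j] >= alpha:
            break
        selected.append(j)
        # backward pass: drop any cofactor no longer significant
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for drop in list(selected):
                others = [s for s in selected if s != drop]
                C0 = np.column_stack([np.ones(n)] + [X[:, s] for s in others])
                dfb = n - C0.shape[1] - 1
                y_rb = residualise(y, C0)
                x_rb = residualise(X[:, drop], C0)
                denom = float(x_rb @ x_rb)
                if denom <= 1e-10:
                    selected.remove(drop)
                    changed = True
                    continue
                gain_b = float(x_rb @ y_rb) ** 2 / denom
                sse_b = max(float(y_rb @ y_rb) - gain_b, 1e-300)
                p_b = stats.f.sf(gain_b / (sse_b / dfb), 1, dfb)
                if p_b >= alpha:
                    selected.remove(drop)
                    changed = True
    return sorted(selected)


def _haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _expected_hap(
    a: np.ndarray, b: np.ndarray | None, dl: float, dr: float | None
) -> np.ndarray:
    """P(haplotype allele = 1 at the test point | flanking hap probabilities).

    a, b are per-line probabilities that the left/right flanking
    haplotype carries allele 1; Haldane recombination, no interference.
    """
    rl = _haldane_r(dl)
    if b is None or dr is None:
        return a * (1 - rl) + (1 - a) * rl
    rr = _haldane_r(dr)
    w1 = (a * (1 - rl) + (1 - a) * rl) * (b * (1 - rr) + (1 - b) * rr)
    w0 = ((1 - a) * (1 - rl) + a * rl) * ((1 - b) * (1 - rr) + b * rr)
    with np.errstate(invalid="ignore"):
        p = np.where(w1 + w0 > 0, w1 / (w1 + w0), 0.5)
    return p


def interval_scan(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    phenotype: pd.Series,
    walk_cM: float = 4.0,
    cofactor_alpha: float = 0.001,
    window_cM: float = 10.0,
    max_cofactors: int | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Composite interval scan within one biparental subfamily.

    Returns the LOD profile (chromosome, position_cM, lod, p_value,
    effect, r2, nearest_marker) and the selected cofactor column
    indices.  LOD = (n/2) * log10(RSS0/RSS1) against the
    cofactors-only model at each grid position.
    """
    pheno = phenotype.reindex(genotypes.line_ids)
    keep = ~pheno.isna()
    y = pheno[keep].to_numpy(dtype=float)
    X = _impute_marker_means(genotypes.calls[keep.to_numpy()])
    n = len(y)
    if n < 10:
        raise ValueError("interval scan needs >= 10 lines")
    poly = X.std(axis=0) > 0
    marker_pos = gmap.table.set_index("marker_id").loc[genotypes.marker_ids]
    cof_candidates = np.flatnonzero(poly)
    cof = stepwise_cofactors(X[:, cof_candidates], y, alpha=cofactor_alpha,
                             max_cofactors=max_cofactors)
    cofactors = [int(cof_candidates[j]) for j in cof]
    cof_chrom = marker_pos["chromosome"].to_numpy()[cofactors]
    cof_pos = marker_pos["position_cM"].to_numpy()[cofactors]
    hap = X / 2.0  # probability scale for the recurrent-allele haplotype
    records = []
    for chrom in gmap.chromosomes:
        on_chrom = np.flatnonzero(
            (marker_pos["chromosome"].to_numpy() == chrom) & poly)
        if len(on_chrom) == 0:
            continue
        pos = marker_pos["position_cM"].to_numpy()[on_chrom]
        order = np.argsort(pos)
        on_chrom, pos = on_chrom[order], pos[order]
        mk_ids = marker_pos.index.to_numpy()[on_chrom]
        grid = np.arange(pos.min(), pos.max() + 1e-9, walk_cM)
        if grid[-1] < pos.max():
            grid = np.append(grid, pos.max())
        if len(on_chrom) < 2:
            grid = pos.copy()
        # expected dosage at each grid point
        Xq = np.empty((n, len(grid)))
        left = np.searchsorted(pos, grid, side="right") - 1
        for gi, q in enumerate(grid):
            li = left[gi]
            ri = li + 1
            a = hap[:, on_chrom[max(li, 0)]]
            if li < 0:
                Xq[:, gi] = 2 * _expected_hap(hap[:, on_chrom[0]], None,
                                              pos[0] - q, None)
            elif ri >= len(pos):
                Xq[:, gi] = 2 * _expected_hap(a, None, q - pos[li], None)
            else:
                Xq[:, gi] = 2 * _expected_hap(a, hap[:, on_chrom[ri]],
                                              q - pos[li], pos[ri] - q)
        # group grid points by the active cofactor set
        excl_keys = []
        for q in grid:
            excluded = tuple(j for j, (cc, cp) in enumerate(zip(cof_chrom, cof_pos))
                             if cc == chrom and abs(cp - q) < window_cM)
            excl_keys.append(excluded)
        sst = float(np.sum((y - y.mean()) ** 2))
        for key in sorted(set(excl_keys)):
            cols = [gi for gi, kk in enumerate(excl_keys) if kk == key]
            active = [c for j, c in enumerate(cofactors) if j not in key]
            C = np.column_stack([np.ones(n)] + [X[:, c] for c in active])
            df = n - C.shape[1] - 1
            y_r = residualise(y, C)
            Q_r = residualise(Xq[:, cols], C)
            sse0 = float(y_r @ y_r)
            xtx = np.einsum("ij,ij->j", Q_r, Q_r)
            xty = Q_r.T @ y_r
            safe = np.where(xtx > 1e-10, xtx, 1.0)
            gain = np.where(xtx > 1e-10, xty**2 / safe, 0.0)
            beta = np.where(xtx > 1e-10, xty / safe, np.nan)
            sse1 = np.maximum(sse0 - gain, 1e-300)
            with np.errstate(divide="ignore"):
                lod = (n / 2.0) * np.log10(sse0 / sse1)
                f = np.where(sse1 > 0, gain / (sse1 / df), np.inf)
            p = stats.f.sf(f, 1, df)
            for gi, l, pp, b, gn in zip(cols, lod, p, beta, gain):
                nearest = mk_ids[np.argmin(np.abs(pos - grid[gi]))]
                records.append((chrom, float(grid[gi]), float(l), float(pp),
                                float(b), float(gn / sst if sst > 0 else 0.0),
                                nearest))
    profile = pd.DataFrame(records, columns=[
        "chromosome", "position_cM", "lod", "p_value", "effect", "r2",
        "nearest_marker"]).sort_values(["chromosome", "position_cM"]
                                       ).reset_index(drop=True)
    return profile, cofactors


def profile_peaks(profile: pd.DataFrame, lod_threshold: float) -> pd.DataFrame:
    """Local maxima of a LOD profile above the threshold, one per excursion."""
    peaks = []
    for chrom, sub in profile.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_cM").reset_index(drop=True)
        above = sub["lod"].to_numpy() >= lod_threshold
        if not above.any():
            continue
        # split contiguous excursions above the threshold
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            best = seg[np.argmax(sub["lod"].to_numpy()[seg])]
            peaks.append(sub.iloc[best])
    if not peaks:
        return profile.iloc[0:0]
    return pd.DataFrame(peaks).reset_index(drop=True)


# ---------------------------------------------------------------------------
# thresholds and merging


def effective_tests(map_length_cM: float, ld_decay_cM: float) -> int:
    """LD-protected effective test count: round(map length / LD decay), >= 1."""
    if map_length_cM <= 0 or ld_decay_cM <= 0:
        raise ValueError("map length and LD decay must be positive")
    return max(int(round(map_length_cM / ld_decay_cM)), 1)


def significance_thresholds(
    m_effective: int,
    genomewide_alpha: float = 0.01,
    n_lines: int | None = None,
    r2_alpha: float = 0.05,
) -> dict[str, float]:
    """Bonferroni p/LOD thresholds plus the critical r2 from Pearson's r.

    p threshold = alpha / M; LOD threshold = -log10 of that.  The r2
    threshold squares the two-tailed Pearson critical value at
    `r2_alpha` for df = n_lines - 2.
    """
    if m_effective < 1 or not 0 < genomewide_alpha < 1:
        raise ValueError("need M >= 1 and alpha in (0,1)")
    p_thr = genomewide_alpha / m_effective
    out = {"p_threshold": p_thr, "lod_threshold": float(-np.log10(p_thr))}
    if n_lines is not None:
        if n_lines < 4:
            raise ValueError("critical r needs n_lines >= 4")
        df = n_lines - 2
        t = stats.t.ppf(1 - r2_alpha / 2, df)
        out["r2_threshold"] = float(t**2 / (df + t**2))
    return out


def merge_mtas(mta_table: pd.DataFrame, ld_decay_cM: float) -> pd.DataFrame:
    """Chain MTAs within a chromosome into QTLs (gap < 2 x LD decay).

    Input columns: trait, env_context, environments (iterable), marker_id,
    chromosome, position_cM, lod, method (plus anything else, carried on
    the peak row).  Output: one row per QTL with the interval, peak
    marker, and the unions of traits / environments / methods.
    """
    if mta_table.empty:
        return pd.DataFrame(columns=["qtl_id", "chromosome", "start_cM", "end_cM",
                                     "peak_marker", "peak_lod", "traits",
                                     "environments", "env_contexts", "methods",
                                     "n_mtas"])
    if mta_table["position_cM"].isna().any():
        raise ValueError("every MTA needs a map position")
    gap = 2.0 * ld_decay_cM
    mta = mta_table.sort_values(["chromosome", "position_cM"],
                                kind="mergesort").reset_index(drop=True)
    rows = []
    for chrom, sub in mta.groupby("chromosome", sort=True):
        pos = sub["position_cM"].to_numpy()
        new_group = np.concatenate([[True], np.diff(pos) >= gap])
        gid = np.cumsum(new_group)
        for _, grp in sub.groupby(gid):
            peak = grp.loc[grp["lod"].idxmax()]
            envs: set[str] = set()
            for e in grp["environments"]:
                envs.update(e)
            rows.append({
                "chromosome": chrom,
                "start_cM": float(grp["position_cM"].min()),
                "end_cM": float(grp["position_cM"].max()),
                "peak_marker": peak["marker_id"],
                "peak_lod": float(peak["lod"]),
                "traits": tuple(sorted(set(grp["trait"]))),
                "environments": tuple(sorted(envs)),
                "env_contexts": tuple(sorted(set(grp["env_context"]))),
                "methods": tuple(sorted(set(grp["method"]))),
                "n_mtas": len(grp),
            })
    out = pd.DataFrame(rows).sort_values(["chromosome", "start_cM"]
                                         ).reset_index(drop=True)
    out.insert(0, "qtl_id", [f"QTL-{i+1:02d}" for i in range(len(out))])
    return out


def classify_stable(
    qtl_table: pd.DataFrame,
    min_envs: int = 2,
    require_both_methods: bool = True,
) -> pd.DataFrame:
    """Stable QTLs: seen in >= min_envs environments and (optionally) by
    both the GLM and the interval-mapping route."""
    if qtl_table.empty:
        q = qtl_table.copy()
        q["stable"] = pd.Series(dtype=bool)
        return q
    q = qtl_table.copy()
    n_envs = q["environments"].map(len)
    ok_env = n_envs >= min_envs
    if require_both_methods:
        ok_m = q["methods"].map(lambda ms: {"glm", "interval"}.issubset(set(ms)))
    else:
        ok_m = pd.Series(True, index=q.index)
    q["stable"] = (ok_env & ok_m).to_numpy()
    return q


def scan_to_mtas(
    scan: pd.DataFrame,
    gmap: GeneticMap,
    trait: str,
    env_context: str,
    environments: Sequence[str],
    method: str,
    p_threshold: float,
    r2_threshold: float = 0.0,
) -> pd.DataFrame:
    """Filter a glm_scan table to significant MTAs with map positions."""
    pos = gmap.table.set_index("marker_id")
    sig = scan[(scan["p_value"] < p_threshold) & (scan["r2"] > r2_threshold)].copy()
    sig = sig[sig["marker_id"].isin(pos.index)]
    sig["chromosome"] = pos.loc[sig["marker_id"], "chromosome"].to_numpy()
    sig["position_cM"] = pos.loc[sig["marker_id"], "position_cM"].to_numpy()
    sig["trait"] = trait
    sig["env_context"] = env_context
    sig["environments"] = [tuple(environments)] * len(sig)
    sig["method"] = method
    return sig[["trait", "env_context", "environments", "marker_id", "chromosome",
                "position_cM", "lod", "p_value", "effect", "r2", "method"]]
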
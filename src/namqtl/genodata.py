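"""Genotype QC, kinship, subpopulation assignment, LD and map merging.

Conventions for inbred (RIL) panels: calls are recurrent-allele dosages
0/1/2 with NaN missing; kinship is identity-by-state similarity; LD is
the squared Pearson correlation of dosage vectors (haplotype-phase
estimation is unnecessary in near-homozygous material).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .simdata import GeneticMap, GenotypeMatrix


# ---------------------------------------------------------------------------
# QC


def snp_qc_report(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker missing rate and minor allele frequency."""
    calls = genotypes.calls
    miss = np.isnan(calls).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    return pd.DataFrame({"marker_id": genotypes.marker_ids,
                         "missing_rate": miss, "maf": maf})


def filter_snps(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.01,
    min_maf: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep markers with missing rate < max_missing and MAF > min_maf (strict)."""
    report = snp_qc_report(genotypes)
    keep = (report["missing_rate"] < max_missing) & (report["maf"] > min_maf)
    report["kept"] = keep
    if not keep.any():
        raise ValueError("QC removed every marker")
    idx = np.flatnonzero(keep.to_numpy())
    filtered = GenotypeMatrix(
        list(genotypes.line_ids),
        [genotypes.marker_ids[i] for i in idx],
        genotypes.calls[:, idx],
        genotypes.subfamily,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# kinship and structure


def kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """IBS similarity: mean of 1 - |d_i - d_j|/2 over shared non-missing markers."""
    calls = genotypes.calls
    obs = ~np.isnan(calls)
    filled = np.nan_to_num(calls, nan=0.0)
    n_shared = obs.astype(float) @ obs.T.astype(float)
    if (n_shared == 0).any():
        raise ValueError("a line pair shares no non-missing markers")
    # sum over shared markers of |d_i - d_j| via the identity
    # |a-b| for a,b in {0,1,2}: compute with three indicator expansions
    total = np.zeros_like(n_shared)
    for a in (0.0, 1.0, 2.0):
        Ia = (filled == a) & obs
        for b in (0.0, 1.0, 2.0):
            if abs(a - b) == 0:
                continue
            Ib = (filled == b) & obs
            total += abs(a - b) * (Ia.astype(float) @ Ib.T.astype(float))
    sim = 1.0 - total / (2.0 * n_shared)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=genotypes.line_ids, columns=genotypes.line_ids)


def assign_subpopulations(
    kin: pd.DataFrame,
    k: int = 3,
    pedigree_labels: pd.Series | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1 - kinship cut at k clusters.

    When pedigree subfamilies are known the numeric clusters are renamed
    to the subfamily holding their majority.
    """
    n = len(kin)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} lines")
    if k == 1:
        return pd.Series(["cluster1"] * n, index=kin.index, name="subpopulation")
    d = 1.0 - kin.to_numpy()
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        warnings.warn("degenerate split: fewer than k distinct clusters")
    labels = pd.Series([f"cluster{c}" for c in raw], index=kin.index,
                       name="subpopulation")
    if pedigree_labels is not None:
        ped = pedigree_labels.reindex(kin.index)
        mapping = {}
        for c in labels.unique():
            members = ped[labels == c].dropna()
            if len(members):
                mapping[c] = members.mode().iloc[0]
        labels = labels.map(lambda c: mapping.get(c, c))
    return labels


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(genotypes: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared dosage correlation over lines non-missing at both markers."""
    xa = genotypes.calls[:, genotypes.marker_index(marker_a)]
    xb = genotypes.calls[:, genotypes.marker_index(marker_b)]
    ok = ~np.isnan(xa) & ~np.isnan(xb)
    xa, xb = xa[ok], xb[ok]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("monomorphic marker after missing-call removal")
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r**2)


def pairwise_ld_points(
    genotypes: GenotypeMatrix, gmap: GeneticMap, max_pairs_per_chrom: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """All intrachromosomal (distance_cM, r2) pairs, mean-imputing missing."""
    frames = []
    gdf = gmap.table.set_index("marker_id")
    marker_pos = gdf.loc[[m for m in genotypes.marker_ids if m in gdf.index]]
    for chrom, sub in marker_pos.groupby("chromosome", sort=True):
        ids = list(sub.index)
        if len(ids) < 2:
            continue
        cols = [genotypes.marker_index(m) for m in ids]
        X = genotypes.calls[:, cols].copy()
        mu = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = mu[nan_c]
        sd = X.std(axis=0)
        keep = sd > 0
        X = X[:, keep]
        pos = sub["position_cM"].to_numpy()[keep]
        if X.shape[1] < 2:
            continue
        R = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices(len(pos), k=1)
        d = np.abs(pos[iu[0]] - pos[iu[1]])
        r2 = R[iu] ** 2
        frames.append(pd.DataFrame({"chromosome": chrom, "distance_cM": d, "r2": r2}))
    points = pd.concat(frames, ignore_index=True)
    if max_pairs_per_chrom is not None and rng is not None:
        points = points.groupby("chromosome", group_keys=False).apply(
            lambda g: g.sample(min(len(g), max_pairs_per_chrom), random_state=None)
            if len(g) > max_pairs_per_chrom else g)
    return points


@dataclass
class LdDecayFit:
    points: pd.DataFrame
    params: dict[str, float]
    threshold: float
    decay_distance_cM: float | None       # fitted-curve crossing
    decay_distance_ma_cM: float | None    # moving-average crossing (fallback)

    def expected_r2(self, d: np.ndarray) -> np.ndarray:
        return _hill_weir(np.asarray(d, dtype=float),
                          self.params["rho"], self.params["n"])


def _hill_weir(d: np.ndarray, rho: float, n: float) -> np.ndarray:
    """Hill-Weir expected r2 with finite-sample correction; C = rho * d."""
    C = rho * d
    term = ((10 + C) / ((2 + C) * (11 + C))) * (
        1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C)))
    return term


def _moving_average_crossing(
    points: pd.DataFrame, threshold: float, window_cM: float = 2.0
) -> float | None:
    d = points["distance_cM"].to_numpy()
    r2 = points["r2"].to_numpy()
    grid = np.arange(0.0, d.max(), window_cM / 2)
    means = []
    for g in grid:
        sel = (d >= g) & (d < g + window_cM)
        means.append(r2[sel].mean() if sel.any() else np.nan)
    means = np.asarray(means)
    below = np.flatnonzero(~np.isnan(means) & (means <= threshold))
    if len(below) == 0:
        return None
    return float(grid[below[0]] + window_cM / 2)


def ld_decay(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    threshold: float = 0.2,
) -> LdDecayFit:
    """Genome-wide LD decay distance at the r2 threshold.

    A Hill-Weir expected-r2 curve (nonlinear least squares over
    intrachromosomal pairs) gives the primary crossing; a nonparametric
    moving-average crossing is reported alongside.  The crossing is
    flagged undefined (None) when the curve never reaches the threshold.
    """
    points = pairwise_ld_points(genotypes, gmap)
    if len(points) < 100:
        raise ValueError("LD decay needs >= 100 intrachromosomal pairs")
    if threshold >= 1.0:
        return LdDecayFit(points, {"rho": np.nan, "n": genotypes.n_lines},
                          threshold, 0.0, 0.0)
    d = points["distance_cM"].to_numpy()
    r2 = points["r2"].to_numpy()
    n_lines = genotypes.n_lines
    try:
        popt, _ = optimize.curve_fit(
            lambda dd, rho: _hill_weir(dd, rho, n_lines), d, r2,
            p0=[0.1], bounds=(1e-6, 1e3), maxfev=2000)
        rho = float(popt[0])
    except RuntimeError:
        rho = np.nan
    params = {"rho": rho, "n": float(n_lines)}
    crossing: float | None = None
    if np.isfinite(rho):
        f = lambda dd: _hill_weir(np.array([dd]), rho, n_lines)[0] - threshold
        lo, hi = 1e-6, max(d.max(), 1.0)
        if f(lo) > 0 and f(hi) < 0:
            crossing = float(optimize.brentq(f, lo, hi))
        elif f(lo) <= 0:
            crossing = 0.0
    ma = _moving_average_crossing(points, threshold)
    return LdDecayFit(points, params, threshold, crossing, ma)


# ---------------------------------------------------------------------------
# consensus map


def consensus_map(
    per_population_maps: Sequence[GeneticMap],
    anchor_positions: pd.Series,
    group_gap_cM: float = 20.0,
) -> tuple[GeneticMap, list[str]]:
    """Merge per-population maps onto a shared anchor (physical) order.

    Marker order follows `anchor_positions` (marker_id -> physical
    coordinate).  Each map's positions are linearly rescaled onto the
    frame of the first map via shared markers, and the consensus
    position is the mean of the rescaled positions.  Within a
    chromosome, runs of markers separated by >= group_gap_cM are
    reported as split groups; order conflicts against the anchor frame
    are logged and anchor order wins.
    """
    logs: list[str] = []
    all_rows = []
    chroms: list[str] = []
    for m in per_population_maps:
        for c in m.chromosomes:
            if c not in chroms:
                chroms.append(c)
    for chrom in chroms:
        tables = []
        for i, m in enumerate(per_population_maps):
            if chrom in m.chromosomes:
                t = m.chrom_slice(chrom)[["marker_id", "position_cM"]].copy()
                t["map"] = i
                tables.append(t)
        ref = tables[0].set_index("marker_id")["position_cM"]
        rescaled = {0: ref}
        for t in tables[1:]:
            s = t.set_index("marker_id")["position_cM"]
            shared = ref.index.intersection(s.index)
            if len(shared) == 0:
                raise ValueError(f"{chrom}: no shared anchors between maps")
            if len(shared) >= 2 and s.loc[shared].std() > 0:
                slope, intercept = np.polyfit(s.loc[shared], ref.loc[shared], 1)
            else:
                slope, intercept = 1.0, float(ref.loc[shared].mean()
                                              - s.loc[shared].mean())
            rescaled[int(t["map"].iloc[0])] = s * slope + intercept
        merged = pd.concat(rescaled.values(), axis=1)
        cons = merged.mean(axis=1)
        markers = cons.index
        anchors = anchor_positions.reindex(markers)
        if anchors.isna().all():
            raise ValueError(f"{chrom}: no markers with anchor positions")
        order = anchors.fillna(anchors.max() + 1).argsort(kind="mergesort")
        ordered = markers[order]
        cons_sorted = cons.loc[ordered]
        if not cons_sorted.is_monotonic_increasing:
            logs.append(f"{chrom}: genetic order conflicts with anchor order; "
                        "anchor order imposed")
            cons_sorted = pd.Series(np.sort(cons.to_numpy()), index=ordered)
        # rescaling round-off can leave ~1e-15 negatives; clamp at zero
        cons_sorted = cons_sorted.clip(lower=0.0)
        gaps = np.diff(cons_sorted.to_numpy())
        n_groups = 1 + int((gaps >= group_gap_cM).sum())
        if n_groups > 1:
            logs.append(f"{chrom}: {n_groups} groups separated by >= "
                        f"{group_gap_cM} cM after merging")
        for mk, p in cons_sorted.items():
            all_rows.append((chrom, mk, float(p),
                             anchor_positions.get(mk, np.nan)))
    table = pd.DataFrame(all_rows, columns=["chromosome", "marker_id",
                                            "position_cM", "position_bp"])
    return GeneticMap(table), logs
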
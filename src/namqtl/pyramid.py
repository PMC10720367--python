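"""Multi-locus haplotype classes at QTL peak markers and pyramiding effects.

Lines are partitioned by their joint {+,-} allele pattern at the chosen
peak markers (+ = the designated favourable, recurrent-parent allele).
Class trait means are compared by one-way ANOVA with LSD letter
grouping, and the pyramiding advantage is the percent gap between the
best and worst class means relative to the best.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeMatrix


def build_haplotype_classes(
    genotypes: GenotypeMatrix,
    peak_markers: Sequence[str],
    positive_alleles: Sequence[float] | None = None,
    het_tolerance: float = 0.10,  # F5 RILs retain ~6% residual heterozygosity
) -> pd.DataFrame:
    """Assign each complete-call line to its joint +/- pattern.

    positive_alleles gives, per locus, the dosage value counted as "+"
    (default 2, the recurrent-parent homozygote).  Heterozygous calls
    are tolerated up to `het_tolerance` of calls (RILs should be nearly
    fixed); lines with a missing or heterozygous call at any locus are
    excluded and counted.  Classes are ordered by descending number of
    positive alleles, then by pattern.
    """
    if positive_alleles is None:
        positive_alleles = [2.0] * len(peak_markers)
    cols = [genotypes.marker_index(m) for m in peak_markers]
    calls = genotypes.calls[:, cols]
    het = calls == 1.0
    if het.mean() > het_tolerance:
        warnings.warn(f"heterozygous calls at {het.mean():.1%} of scored loci "
                      "exceed the RIL tolerance")
    complete = ~np.isnan(calls).any(axis=1) & ~het.any(axis=1)
    pattern = np.where(calls == np.asarray(positive_alleles)[None, :], "+", "-")
    rows = []
    for i, line in enumerate(genotypes.line_ids):
        if complete[i]:
            rows.append((line, "".join(pattern[i]), int((pattern[i] == "+").sum())))
    df = pd.DataFrame(rows, columns=["line_id", "pattern", "n_positive"])
    pats = (df.groupby("pattern")["n_positive"].first()
            .sort_values(ascending=False).index)
    order = {p: i for i, p in enumerate(
        sorted(pats, key=lambda p: (-p.count("+"), p)))}
    df["class_id"] = df["pattern"].map(lambda p: f"Hap{order[p]+1}")
    df.attrs["n_excluded"] = int((~complete).sum())
    return df.sort_values(["class_id", "line_id"]).reset_index(drop=True)


def class_anova_lsd(
    classes: pd.DataFrame,
    trait_values: pd.Series,
    alpha: float = 0.05,
    min_members: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA across haplotype classes with LSD letter groups.

    LSD between classes i,j = t(1-alpha/2, df_error) * sqrt(MSE * (1/n_i
    + 1/n_j)).  Letters are assigned by descending mean with the usual
    overlap rule (classes not significantly different share a letter).
    Classes with fewer than `min_members` scored lines are dropped.
    """
    df = classes.copy()
    df["value"] = trait_values.reindex(df["line_id"]).to_numpy()
    df = df.dropna(subset=["value"])
    sizes = df.groupby("class_id").size()
    small = sizes[sizes < min_members].index
    if len(small):
        warnings.warn(f"classes dropped with <{min_members} members: "
                      f"{sorted(small)}")
        df = df[~df["class_id"].isin(small)]
    groups = {c: g["value"].to_numpy() for c, g in df.groupby("class_id")}
    if len(groups) < 2:
        raise ValueError("LSD needs >= 2 classes with enough members")
    k = len(groups)
    n_total = len(df)
    grand = df["value"].mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_err = n_total - k
    mse = ss_within / df_err
    f = (ss_between / (k - 1)) / mse if mse > 0 else np.inf
    p_anova = stats.f.sf(f, k - 1, df_err)
    t_crit = stats.t.ppf(1 - alpha / 2, df_err)
    means = pd.Series({c: v.mean() for c, v in groups.items()}).sort_values(
        ascending=False)
    ns = {c: len(v) for c, v in groups.items()}

    def differ(a: str, b: str) -> bool:
        lsd = t_crit * np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        return abs(means[a] - means[b]) > lsd

    # insert-and-absorb letter assignment on the descending means
    letters: dict[str, str] = {c: "" for c in means.index}
    current = 0
    covered: set[str] = set()
    order = list(means.index)
    for i, c in enumerate(order):
        if c in covered:
            continue
        letter = chr(ord("a") + current)
        block = [c] + [d for d in order[i + 1:] if not differ(c, d)]
        for d in block:
            letters[d] += letter
        covered.update([c])
        current += 1
    out = pd.DataFrame({
        "class_id": means.index,
        "mean": means.to_numpy(),
        "n": [ns[c] for c in means.index],
        "letters": [letters[c] for c in means.index],
    }).reset_index(drop=True)
    out.attrs["anova_p"] = float(p_anova)
    out.attrs["mse"] = float(mse)
    out.attrs["t_crit"] = float(t_crit)
    return out


def pyramiding_advantage(best_class_mean: float, worst_class_mean: float) -> float:
    """Percent advantage of the best class: 100 * (best - worst) / best."""
    if best_class_mean <= 0:
        raise ValueError("best class mean must be positive")
    if best_class_mean < worst_class_mean:
        raise ValueError("best class mean must be >= worst class mean")
    return 100.0 * (best_class_mean - worst_class_mean) / best_class_mean
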
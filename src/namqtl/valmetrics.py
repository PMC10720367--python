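"""Marker validation metrics for an independent selection panel.

A converted single-SNP assay is judged by (i) the point-biserial
correlation of its +/- call with the trait and (ii) top/bottom
diagnostic metrics: the top-n and bottom-n lines by trait value are the
true positives and negatives; sensitivity is the share of "+" calls in
the top n, specificity the share of "-" calls in the bottom n, and
accuracy the share of correct calls over all scored lines (correct = +
above / - below the trait median by default, or restricted to the two
extreme groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MarkerValidation:
    marker_id: str
    polymorphic: bool
    r: float | None
    r_critical: float | None
    significant: bool | None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    n: int = 0


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed Pearson critical value at alpha for df = n - 2."""
    if n < 4:
        raise ValueError("critical r needs n >= 4")
    df = n - 2
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(df + t**2))


def marker_trait_correlation(
    allele_calls: pd.Series,
    trait_values: pd.Series,
    alpha: float = 0.05,
    r_threshold: float | None = None,
    marker_id: str = "",
) -> MarkerValidation:
    """Point-biserial correlation of 0/1 calls with the trait.

    Monomorphic markers are flagged and carry no r.  Significance uses
    |r| > critical r at alpha (df = n-2) unless an explicit
    `r_threshold` override is supplied.
    """
    both = pd.concat([allele_calls.rename("x"), trait_values.rename("y")],
                     axis=1).dropna()
    x = both["x"].to_numpy(dtype=float)
    y = both["y"].to_numpy(dtype=float)
    n = len(both)
    if n < 4 or np.ptp(x) == 0:
        return MarkerValidation(marker_id, polymorphic=bool(n >= 4 and np.ptp(x) > 0),
                                r=None, r_critical=None, significant=None, n=n)
    r = float(np.corrcoef(x, y)[0, 1])
    crit = r_threshold if r_threshold is not None else critical_r(n, alpha)
    return MarkerValidation(marker_id, True, r, float(crit),
                            bool(abs(r) > crit), n=n)


def top_bottom_metrics(
    allele_calls: pd.Series,
    trait_values: pd.Series,
    n: int = 20,
    accuracy_scope: str = "median_split",
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) against the trait ranking.

    Ranks break ties by line label for determinism.  accuracy_scope is
    "median_split" (correct = + in the top half, - in the bottom half,
    over all scored lines) or "extremes" (correct calls among the 2n
    extreme lines only).
    """
    both = pd.concat([allele_calls.rename("call"), trait_values.rename("y")],
                     axis=1).dropna()
    if len(both) < 2 * n:
        raise ValueError(f"panel of {len(both)} lines smaller than 2n = {2*n}")
    # descending trait value; boundary ties break by line label
    both = both.iloc[np.lexsort((both.index.astype(str),
                                 -both["y"].to_numpy()))]
    calls = both["call"].to_numpy(dtype=float)
    pos = calls == 1
    sensitivity = float(pos[:n].mean())
    specificity = float((~pos)[-n:].mean())
    if accuracy_scope == "median_split":
        half = len(both) // 2
        correct = np.concatenate([pos[:half], ~pos[half:]])
        accuracy = float(correct.mean())
    elif accuracy_scope == "extremes":
        correct = np.concatenate([pos[:n], ~pos[-n:]])
        accuracy = float(correct.mean())
    else:
        raise ValueError("accuracy_scope must be 'median_split' or 'extremes'")
    return accuracy, sensitivity, specificity


def validate_markers(
    calls_table: pd.DataFrame,
    trait_values: pd.Series,
    n: int = 20,
    alpha: float = 0.05,
    r_threshold: float | None = None,
) -> pd.DataFrame:
    """Validation table for a panel: one row per marker (0/1 calls)."""
    rows = []
    for marker in calls_table.columns:
        mv = marker_trait_correlation(calls_table[marker], trait_values,
                                      alpha=alpha, r_threshold=r_threshold,
                                      marker_id=marker)
        rec = {"marker_id": marker, "polymorphic": mv.polymorphic, "r": mv.r,
               "r_critical": mv.r_critical, "significant": mv.significant,
               "accuracy": None, "sensitivity": None, "specificity": None,
               "n": mv.n}
        if mv.polymorphic:
            acc, sen, spe = top_bottom_metrics(calls_table[marker], trait_values, n=n)
            rec.update(accuracy=acc, sensitivity=sen, specificity=spe)
        rows.append(rec)
    return pd.DataFrame(rows)
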
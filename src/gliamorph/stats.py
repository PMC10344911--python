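"""Nonparametric group comparison of morphometric features.

Per feature: an omnibus Kruskal–Wallis H-test across all treatment groups,
pairwise Mann–Whitney U post-hoc tests using the normal approximation with
continuity correction and tie-corrected variance (appropriate for group
sizes above ~20), Bonferroni adjustment over the pairwise family, and
mean ± SEM summaries.  A shift report classifies each feature's change
between a reference and a treated group as Up/Down with a significance
class.

Star conventions: the default three-level convention is
``*** p < 0.005, ** p < 0.01, * p < 0.05``; ``convention="two-level"``
collapses * and ** into a single ``**`` class (``** p < 0.05``), the
rendering used in summary tables of the underlying study design.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FEATURE_NAMES, CohortTable

__all__ = [
    "kruskal_wallis",
    "mann_whitney_u",
    "MannWhitneyResult",
    "bonferroni",
    "summarize_groups",
    "GroupComparisonResult",
    "compare_groups",
    "phenotype_shift_table",
    "significance_stars",
]


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p with k−1 df.

    Degenerate input where every value across all groups is identical
    returns ``(0.0, 1.0)``.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if sum(s.size for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    z: float
    p: float


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, continuity: bool = True
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test by normal approximation.

    Mid-ranks with tie-corrected variance; ``U`` is reported as
    ``min(U1, U2)`` and the z statistic uses a 0.5 continuity correction
    toward the mean.  The approximation is intended for both samples larger
    than 20; smaller samples trigger a warning but are still computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("samples must be non-empty")
    if min(n1, n2) <= 20:
        warnings.warn(
            "normal approximation is intended for n1, n2 > 20",
            stacklevel=2,
        )
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all values identical
        return MannWhitneyResult(U=float(u), z=0.0, p=1.0)
    cc = 0.5 * math.copysign(1.0, mu - u) if continuity and u != mu else 0.0
    z = (u - mu + cc) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(U=float(u), z=float(z), p=float(p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m·p)``, order preserved.

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def summarize_groups(cohort: CohortTable, features=None) -> pd.DataFrame:
    """Per-feature, per-group mean, SEM (sd/√n, n−1 denominator) and n.

    SEM is reported as missing (NaN) for singleton groups.
    """
    features = list(features or FEATURE_NAMES)
    rows = []
    for feat in features:
        for grp, vals in cohort.group_values(feat).items():
            n = vals.size
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {"feature": feat, "group": grp, "mean": float(vals.mean()),
                 "sem": sem, "n": n}
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonResult:
    """Omnibus and pairwise statistics for one feature."""

    feature: str
    H: float
    p_omnibus: float
    pairs: list[tuple[str, str]]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    U: np.ndarray
    group_summaries: pd.DataFrame

    def pairwise_p(self, a: str, b: str, adjusted: bool = True) -> float:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        i = self.pairs.index(key)
        return float(self.p_adjusted[i] if adjusted else self.p_raw[i])


def compare_groups(
    cohort: CohortTable,
    features=None,
    pairs: list[tuple[str, str]] | None = None,
    m: int | None = None,
) -> dict[str, GroupComparisonResult]:
    """Kruskal–Wallis omnibus plus Bonferroni-adjusted pairwise U tests.

    ``pairs`` defaults to all group pairs; the Bonferroni family size ``m``
    defaults to the number of pairs actually tested per feature.
    """
    features = list(features or FEATURE_NAMES)
    groups = cohort.groups
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    results: dict[str, GroupComparisonResult] = {}
    summaries = summarize_groups(cohort, features)
    for feat in features:
        values = cohort.group_values(feat)
        h, p_omni = kruskal_wallis([values[g] for g in groups])
        raw, us = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a, b in pairs:
                r = mann_whitney_u(values[a], values[b])
                raw.append(r.p)
                us.append(r.U)
        adj = bonferroni(raw, m)
        results[feat] = GroupComparisonResult(
            feature=feat,
            H=h,
            p_omnibus=p_omni,
            pairs=list(pairs),
            p_raw=np.asarray(raw),
            p_adjusted=adj,
            U=np.asarray(us),
            group_summaries=summaries[summaries["feature"] == feat].reset_index(drop=True),
        )
    return results


def significance_stars(p: float, convention: str = "three-level") -> str:
    """Map a p-value to a significance class.

    ``three-level``: ``***`` p<0.005, ``**`` p<0.01, ``*`` p<0.05, else N.S.
    ``two-level``: ``***`` p<0.005, ``**`` p<0.05, else N.S.
    """
    if convention == "three-level":
        levels = [(0.005, "***"), (0.01, "**"), (0.05, "*")]
    elif convention == "two-level":
        levels = [(0.005, "***"), (0.05, "**")]
    else:
        raise ValueError(f"unknown star convention {convention!r}")
    for thr, stars in levels:
        if p < thr:
            return stars
    return "N.S."


def phenotype_shift_table(
    results: dict[str, GroupComparisonResult],
    reference: str,
    treated: str,
    convention: str = "three-level",
) -> pd.DataFrame:
    """Per-feature Up/Down shift of ``treated`` vs ``reference`` with stars.

    Direction is the sign of the treated-minus-reference mean difference;
    significance uses the Bonferroni-adjusted pairwise p-value.
    """
    rows = []
    for feat, res in results.items():
        summ = res.group_summaries.set_index("group")
        for grp in (reference, treated):
            if grp not in summ.index:
                raise KeyError(f"group {grp!r} missing from comparison results")
        diff = summ.loc[treated, "mean"] - summ.loc[reference, "mean"]
        p_adj = res.pairwise_p(reference, treated)
        rows.append(
            {
                "feature": feat,
                "reference": reference,
                "treated": treated,
                "direction": "Up" if diff >= 0 else "Down",
                "mean_difference": float(diff),
                "p_adjusted": p_adj,
                "significance": significance_stars(p_adj, convention),
            }
        )
    return pd.DataFrame(rows)
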
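"""Paired agreement analysis between dosimetry methods.

Per-pair relative differences are signed percentages of the pair mean,
100*(x - y)/((x + y)/2), with the 3D method conventionally the reference y
(negative = underestimation versus 3D). Systematic differences are
summarised as median differences with a paired rank test (exact signed-rank
null by full enumeration for small n, normal approximation with tie and
continuity correction otherwise); random differences as Bland-Altman limits
of agreement, mean difference +/- 1.96 standard deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_N_MAX = 12


@dataclass(frozen=True)
class AgreementStats:
    median_diff_abs: float  # Gy/GBq
    median_diff_pct: float
    p_value: float
    mean_diff_pct: float
    loa_halfwidth_pct: float  # 1.96 * SD of the relative differences
    n: int

    def __post_init__(self) -> None:
        if self.loa_halfwidth_pct < 0:
            raise ValueError("LoA halfwidth must be non-negative")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value must lie in [0, 1]")


def relative_difference(x: float, y: float) -> float:
    """Signed percent difference of a pair relative to the pair mean."""
    m = 0.5 * (x + y)
    if m == 0:
        warnings.warn("pair with zero mean excluded from relative difference", stacklevel=2)
        return float("nan")
    return 100.0 * (x - y) / m


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by dynamic programming over all 2^n sign patterns.

    The distribution of W+ over equally likely sign assignments of the
    observed (possibly tied, midranked) absolute ranks is built by
    convolution on a half-rank integer grid to keep exactness with ties.
    """
    units = np.rint(ranks * 2).astype(int)  # midranks are multiples of 1/2
    total = units.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for u in units:
        new = dist.copy()
        new[u:] += dist[: total + 1 - u]
        dist = new
    dist /= dist.sum()
    w_units = int(round(w_plus * 2))
    p_low = dist[: w_units + 1].sum()
    p_high = dist[w_units:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _asymptotic_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def rank_test(differences, *, test: str = "signed_rank") -> float:
    """Two-sided p-value for a systematic paired difference.

    ``signed_rank`` (default, matching the paired structure of the data):
    exact enumeration for n <= 12 after zero removal, normal approximation
    with tie/continuity correction otherwise. ``ranksum`` exposes the
    unpaired Wilcoxon-Mann-Whitney variant on the signed differences versus
    their negation, for completeness.
    """
    d = np.asarray(differences, float)
    d = d[~np.isnan(d)]
    if test == "ranksum":
        if np.all(d == 0):
            warnings.warn("all differences zero: p = 1", stacklevel=2)
            return 1.0
        return float(stats.mannwhitneyu(d, -d, alternative="two-sided").pvalue)
    if test != "signed_rank":
        raise ValueError("test must be 'signed_rank' or 'ranksum'")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences zero: p = 1", stacklevel=2)
        return 1.0
    w_plus, ranks = _signed_rank_statistic(d)
    if d.size <= EXACT_N_MAX:
        return _exact_signed_rank_p(w_plus, ranks)
    return _asymptotic_signed_rank_p(w_plus, ranks)


def bland_altman(pairs) -> AgreementStats:
    """Bland-Altman agreement of paired doses (x = method, y = reference).

    Relative differences are taken against the pair mean; the limits of
    agreement are mean difference +/- 1.96 SD. Also reports the median
    absolute (Gy/GBq) and percent differences and the rank-test p-value.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    rel = np.array([relative_difference(a, b) for a, b in zip(x, y)])
    keep = ~np.isnan(rel)
    rel = rel[keep]
    if rel.size < 2:
        raise ValueError("fewer than 2 valid pairs after exclusions")
    diffs = (x - y)[keep]
    sd = float(np.std(rel, ddof=1))
    return AgreementStats(
        median_diff_abs=float(np.median(diffs)),
        median_diff_pct=float(np.median(rel)),
        p_value=rank_test(diffs),
        mean_diff_pct=float(np.mean(rel)),
        loa_halfwidth_pct=1.96 * sd,
        n=int(rel.size),
    )


def comparison_table(
    doses: pd.DataFrame,
    *,
    reference: str = "3D",
    methods: tuple[str, ...] = ("2D", "hybrid"),
    value: str = "dose_gy_per_gbq",
) -> pd.DataFrame:
    """Per region class: median differences and Bland-Altman stats vs 3D.

    ``doses`` must carry columns ``region_class``, ``method``, ``instance``
    and the dose column; instances missing in either method of a pair are
    dropped (count logged).
    """
    rows = []
    for region_class, grp in doses.groupby("region_class"):
        ref = grp[grp["method"] == reference].set_index("instance")[value]
        for method in methods:
            m = grp[grp["method"] == method].set_index("instance")[value]
            common = ref.index.intersection(m.index)
            dropped = len(ref.index.symmetric_difference(m.index))
            if dropped:
                logger.info(
                    "%s %s-vs-%s: dropped %d unmatched instances",
                    region_class, method, reference, dropped,
                )
            if len(common) == 0:
                continue
            if len(common) == 1:
                x, y = float(m[common].iloc[0]), float(ref[common].iloc[0])
                rows.append(
                    {
                        "region_class": region_class,
                        "comparison": f"{method} vs {reference}",
                        "n": 1,
                        "median_diff_gy_per_gbq": x - y,
                        "median_diff_pct": relative_difference(x, y),
                        "p_value": 1.0,
                        "mean_diff_pct": relative_difference(x, y),
                        "loa_halfwidth_pct": float("nan"),
                    }
                )
                continue
            ba = bland_altman(np.column_stack([m[common].values, ref[common].values]))
            rows.append(
                {
                    "region_class": region_class,
                    "comparison": f"{method} vs {reference}",
                    "n": ba.n,
                    "median_diff_gy_per_gbq": ba.median_diff_abs,
                    "median_diff_pct": ba.median_diff_pct,
                    "p_value": ba.p_value,
                    "mean_diff_pct": ba.mean_diff_pct,
                    "loa_halfwidth_pct": ba.loa_halfwidth_pct,
                }
            )
    return pd.DataFrame(rows)


def bland_altman_points(pairs) -> pd.DataFrame:
    """Per-pair (mean, relative difference) for Bland-Altman plotting."""
    arr = np.asarray(pairs, float)
    means = arr.mean(axis=1)
    rel = np.array([relative_difference(a, b) for a, b in arr])
    return pd.DataFrame({"pair_mean": means, "rel_diff_pct": rel})
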
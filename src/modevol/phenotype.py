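"""Phenotyping statistics: Kruskal-Wallis rank-sum test for weight-loss
comparisons and the chi-square goodness-of-fit test against an equal (0.5)
outcome for pairwise competition experiments."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability P(chi^2_df > x) via the regularized upper
    incomplete gamma function; accurate to well below 1e-10."""
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x}")
    return float(special.gammaincc(df / 2.0, x / 2.0))


@dataclass
class KruskalResult:
    H: float
    df: int
    p: float


def kruskal_wallis(groups: list[np.ndarray]) -> KruskalResult:
    """Kruskal-Wallis rank-sum test with midranks and tie correction.

    H = (12 / (n(n+1))) * sum R_i^2 / n_i - 3(n+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n^3 - n); df = k - 1, p from the
    chi-square upper tail.  All-tied data (correction divisor 0) is
    degenerate and reported as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need total n >= 3")
    ranks = stats.rankdata(pooled)  # midranks for ties

    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)

    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    df = len(groups) - 1
    if correction <= 0:  # every observation tied
        return KruskalResult(H=0.0, df=df, p=1.0)
    h /= correction
    h = max(h, 0.0)
    return KruskalResult(H=float(h), df=df, p=chi2_sf(float(h), df))


@dataclass
class CompetitionResult:
    chi2: float
    df: int
    p: float
    proportion_b: float


def chisq_gof_half(count_a: int, count_b: int,
                   continuity: bool = False) -> CompetitionResult:
    """Chi-square goodness-of-fit test of deviation from an equal (0.5)
    outcome between two competitors (df = 1).

    ``continuity`` applies the Yates correction (off by default, matching
    the plain test)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n < 1:
        raise ValueError("need at least one observation")
    expected = n / 2.0
    if continuity:
        stat = sum((abs(o - expected) - 0.5) ** 2 / expected
                   for o in (count_a, count_b))
    else:
        stat = ((count_a - expected) ** 2 + (count_b - expected) ** 2) / expected
    return CompetitionResult(chi2=float(stat), df=1, p=chi2_sf(float(stat), 1),
                             proportion_b=count_b / n)


# ---------------------------------------------------------------------------
# file-level runners for the CLI
# ---------------------------------------------------------------------------

def weight_loss_tests(table: pd.DataFrame, group_col: str = "strain",
                      value_col: str = "percent_weight_loss",
                      by: str = "wood_type") -> pd.DataFrame:
    """Kruskal-Wallis across groups, one test per wood type."""
    rows = []
    for wood, grp in table.groupby(by):
        samples = [g[value_col].to_numpy() for _, g in grp.groupby(group_col)]
        if len(samples) < 2:
            continue
        res = kruskal_wallis(samples)
        rows.append({by: wood, "test": "kruskal_wallis", "statistic": res.H,
                     "df": res.df, "p": res.p})
    return pd.DataFrame(rows)


def competition_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Chi-square vs 0.5 for each competition pair (columns pair_id,
    competitor_a, competitor_b, count_a, count_b)."""
    rows = []
    for _, rec in table.iterrows():
        res = chisq_gof_half(int(rec["count_a"]), int(rec["count_b"]))
        rows.append({"pair_id": rec["pair_id"],
                     "competitor_a": rec["competitor_a"],
                     "competitor_b": rec["competitor_b"],
                     "chi2": res.chi2, "df": res.df, "p": res.p,
                     "proportion_b": res.proportion_b})
    return pd.DataFrame(rows)
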
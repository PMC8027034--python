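"""Fisher-exact overlap and term-enrichment statistics with BH FDR control.

All tests are one-sided (enrichment direction): the p-value is the
hypergeometric upper tail P(X >= a) of the 2x2 table, evaluated in
log-space for numerical stability.  Cross-species module overlap is tested
on the universe of ortholog tuples complete in both species; BH is applied
across all cells of all species pairs in one family, and across all terms
of one enrichment run in one family.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import MODULES
from .orthology import OrthologySet
from .diffexpr import bh_adjust


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of a 2x2 table.

    Returns (p, odds ratio) where p = P(X >= a) for X hypergeometric with
    population N = a+b+c+d, K = a+b successes and n = a+c draws, and the
    odds ratio is ad/bc (inf when bc = 0).
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    N, K, n = a + b + c + d, a + b, a + c
    if N == 0:
        raise ValueError("empty table")
    p = float(stats.hypergeom.sf(a - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return p, odds


def module_overlap_matrix(assign1: pd.Series, assign2: pd.Series,
                          orthology: OrthologySet, sp1: str, sp2: str
                          ) -> pd.DataFrame:
    """3x3 grid of module-overlap tests between two species.

    ``assign1``/``assign2`` map gene_id -> module for each species.  The
    universe is the set of tuples complete in both species.  Adjusted
    p-values are NOT computed here; apply BH across all pairs with
    :func:`overlap_all_pairs`.
    """
    tuples = orthology.tuples
    both = tuples[[sp1, sp2]].notna().all(axis=1)
    universe = tuples.index[both]
    if len(universe) == 0:
        raise ValueError(f"no tuples complete in both {sp1} and {sp2}")
    m1 = pd.Series([assign1.get(g, "none") for g in tuples.loc[universe, sp1]],
                   index=universe)
    m2 = pd.Series([assign2.get(g, "none") for g in tuples.loc[universe, sp2]],
                   index=universe)
    rows = []
    for mod1 in MODULES:
        for mod2 in MODULES:
            in1, in2 = (m1 == mod1), (m2 == mod2)
            a = int((in1 & in2).sum())
            b = int((in1 & ~in2).sum())
            c = int((~in1 & in2).sum())
            d = int((~in1 & ~in2).sum())
            p, odds = fisher_exact_greater(a, b, c, d)
            rows.append({"sp1": sp1, "sp2": sp2, "module1": mod1,
                         "module2": mod2, "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)


def overlap_all_pairs(assignments: dict[str, pd.Series],
                      orthology: OrthologySet) -> pd.DataFrame:
    """Overlap grids for every unordered species pair, BH across all cells."""
    frames = [module_overlap_matrix(assignments[s1], assignments[s2],
                                    orthology, s1, s2)
              for s1, s2 in itertools.combinations(sorted(assignments), 2)]
    out = pd.concat(frames, ignore_index=True)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def term_enrichment(gene_set: set[str], universe: set[str],
                    annotations: pd.DataFrame, alpha: float = 0.05,
                    min_term_size: int = 3) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of ``gene_set`` within ``universe``.

    Terms with fewer than ``min_term_size`` universe genes are skipped; BH
    is applied across the tested terms and rows with fdr < alpha are
    flagged enriched.  Output columns follow the k/K/n/N convention:
    k = term genes in the set, K = term genes in the universe, n = set
    size, N = universe size.
    """
    gene_set, universe = set(gene_set), set(universe)
    if not gene_set <= universe:
        raise ValueError("gene set is not a subset of the universe")
    ann = annotations[annotations["gene_id"].isin(universe)]
    N, n = len(universe), len(gene_set)
    rows = []
    for term, grp in ann.groupby("term_id"):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & gene_set)
        p, _ = fisher_exact_greater(k, K - k, n - k, N - K - (n - k))
        fold = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p": p, "fold_enrichment": fold})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p",
                                      "fold_enrichment"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["enriched"] = out["fdr"] < alpha
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = []
        out["enriched"] = []
    return out
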
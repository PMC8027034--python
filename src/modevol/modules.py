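"""Assignment of genes to the core / spruce / pine expression modules.

A gene is "significantly up" in a contrast when its BH-adjusted p-value is
below ``fdr_alpha`` and its log2 fold change exceeds ``lfc_min``.  The
wood-type-specific modules additionally require a significant difference
between the two wood types, which makes the three modules disjoint:

* spruce: up on spruce vs SCD, and spruce-vs-pine significant with
  log2FC > lfc_min toward spruce;
* pine: the mirror image;
* core: up in the averaged (spruce+pine)/2 vs SCD contrast and not already
  wood-type specific.

Wood-specific labels take precedence over core so the reported counts are
exclusive sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MODULES

_CONTRASTS = ("core", "spruce_vs_SCD", "pine_vs_SCD", "spruce_vs_pine")


def assign_modules(de_results: pd.DataFrame, fdr_alpha: float = 0.05,
                   lfc_min: float = 1.0) -> pd.DataFrame:
    """Label every tested gene core / spruce / pine / none from its contrasts.

    ``de_results`` is the long DE table of one strain with all four
    contrasts on the same gene universe.  Returns one row per gene with the
    module label and the (log2FC, fdr) pair of each contrast.
    """
    have = set(de_results["contrast"])
    missing = [c for c in _CONTRASTS if c not in have]
    if missing:
        raise ValueError(f"missing contrast(s): {missing}")
    lfc = de_results.pivot(index="gene_id", columns="contrast", values="log2FC")
    fdr = de_results.pivot(index="gene_id", columns="contrast", values="fdr")
    if lfc.isna().any().any():
        raise ValueError("contrasts computed on mismatched gene universes")

    sig_up = lambda name: (fdr[name] < fdr_alpha) & (lfc[name] > lfc_min)
    sp_vs_pi_sig = fdr["spruce_vs_pine"] < fdr_alpha
    is_spruce = sig_up("spruce_vs_SCD") & sp_vs_pi_sig & (lfc["spruce_vs_pine"] > lfc_min)
    is_pine = sig_up("pine_vs_SCD") & sp_vs_pi_sig & (lfc["spruce_vs_pine"] < -lfc_min)
    is_core = sig_up("core") & ~is_spruce & ~is_pine

    module = pd.Series("none", index=lfc.index, name="module")
    module[is_core] = "core"
    module[is_spruce] = "spruce"
    module[is_pine] = "pine"

    out = pd.DataFrame({"gene_id": lfc.index, "module": module.to_numpy()})
    for c in _CONTRASTS:
        out[f"lfc_{c}"] = lfc[c].to_numpy()
        out[f"fdr_{c}"] = fdr[c].to_numpy()
    return out.reset_index(drop=True)


def module_summary(assignments: dict[str, pd.DataFrame],
                   truth: dict[str, pd.Series] | None = None) -> pd.DataFrame:
    """Per-strain gene counts per module; with a truth labeling, also
    per-module sensitivity and precision of the recovered sets."""
    rows = []
    for strain, assign in assignments.items():
        counts = assign["module"].value_counts()
        row: dict = {"strain": strain}
        for m in MODULES + ("none",):
            row[m] = int(counts.get(m, 0))
        if truth is not None and strain in truth:
            t = truth[strain]
            called = assign.set_index("gene_id")["module"]
            universe = called.index.union(t.index)
            called = called.reindex(universe, fill_value="none")
            t = t.reindex(universe, fill_value="none")
            for m in MODULES:
                tp = int(((called == m) & (t == m)).sum())
                fp = int(((called == m) & (t != m)).sum())
                fn = int(((called != m) & (t == m)).sum())
                row[f"sensitivity_{m}"] = tp / (tp + fn) if tp + fn else np.nan
                row[f"precision_{m}"] = tp / (tp + fp) if tp + fp else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
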
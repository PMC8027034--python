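"""Ancestral reconstruction of conserved expression modules on the species
tree, with gain / loss / duplication attribution per internal branch.

The logic is Dollo-style set algebra, not a probabilistic model: a module is
conserved at a branch when every leaf below carries its ortholog in that
module, a gain at a branch is a conserved tuple whose outgroup orthologs are
not in the module, and a loss is a tuple induced on wood in every outgroup
leaf but induced nowhere below the branch.  Gain provenance distinguishes
genes newly induced (outgroup "none"), recruited from another module, and
duplication-associated gains (multi-copy below the branch, single-copy
outside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MODULES, SpeciesTree
from .orthology import OrthologySet

GAIN_CATEGORIES = ("not_induced_in_outgroup", "recruited_from_core",
                   "recruited_from_spruce", "recruited_from_pine",
                   "duplicated_at_branch")

Assignments = dict[str, pd.Series]  # strain -> gene_id -> module label


def _module_of(assignments: Assignments, strain: str, gene) -> str | None:
    """Module of a tuple member; None when the gene is absent from the
    tuple, 'none' when present but untested/unassigned."""
    if gene is None or (isinstance(gene, float) and np.isnan(gene)):
        return None
    return str(assignments[strain].get(gene, "none"))


def conserved_at_branch(tree: SpeciesTree, assignments: Assignments,
                        orthology: OrthologySet, branch: str,
                        module: str) -> set[str]:
    """Tuple ids whose member is in ``module`` in every leaf under ``branch``.

    Tuples missing a member for any leaf under the branch are skipped (not
    counted as non-conserved).
    """
    leaves = tree.leaves_under(branch)
    out = set()
    for tid, row in orthology.tuples.iterrows():
        states = [_module_of(assignments, lf, row[lf]) for lf in leaves]
        if any(s is None for s in states):
            continue
        if all(s == module for s in states):
            out.add(tid)
    return out


def gains_at_branch(tree: SpeciesTree, assignments: Assignments,
                    orthology: OrthologySet, branch: str,
                    module: str) -> pd.DataFrame:
    """Gained tuples at ``branch`` for ``module``, with provenance category.

    A gain is conserved at the branch while not satisfying conservation via
    the outgroup: some outgroup ortholog is outside the module, or the
    tuple has no outgroup member at all.  Categories:

    * ``duplicated_at_branch``: >=2 copies in every leaf under the branch
      and <=1 in each outgroup leaf;
    * ``recruited_from_X``: all outgroup members share module X != module;
    * ``not_induced_in_outgroup``: all outgroup members unassigned
      ("none"); mixed outgroup states fall here with a "mixed" annotation,
      and outgroup-absent tuples with an "absent_in_outgroup" annotation.
    """
    outgroup = tree.outgroup_leaves(branch)
    conserved = conserved_at_branch(tree, assignments, orthology, branch, module)
    under = tree.leaves_under(branch)
    rows = []
    for tid in sorted(conserved):
        row = orthology.tuples.loc[tid]
        og_states = {lf: _module_of(assignments, lf, row[lf]) for lf in outgroup}
        present = {lf: s for lf, s in og_states.items() if s is not None}
        if not outgroup:
            continue  # root has no outgroup to compare against
        if len(present) == len(outgroup) and all(s == module
                                                 for s in present.values()):
            continue  # conserved via the outgroup too: not a gain here

        copies = orthology.copy_number(tid)
        annotation = ""
        if (all(copies.get(lf, 0) >= 2 for lf in under)
                and all(copies.get(lf, 0) <= 1 for lf in outgroup)):
            category = "duplicated_at_branch"
        elif not present:
            category = "not_induced_in_outgroup"
            annotation = "absent_in_outgroup"
        else:
            distinct = set(present.values())
            if distinct == {"none"}:
                category = "not_induced_in_outgroup"
            elif len(distinct) == 1:
                category = f"recruited_from_{distinct.pop()}"
            else:
                category = "not_induced_in_outgroup"
                annotation = "mixed"
        rows.append({"tuple_id": tid, "category": category,
                     "annotation": annotation})
    return pd.DataFrame(rows, columns=["tuple_id", "category", "annotation"])


def lost_induction(tree: SpeciesTree, assignments: Assignments,
                   orthology: OrthologySet, branch: str) -> set[str]:
    """Tuples wood-induced in every outgroup leaf but silent under ``branch``.

    "Induced" means assigned to any of the core/spruce/pine modules.  Every
    outgroup leaf must carry an induced member; under the branch every
    present member must be "none" (absent members count as not induced).
    """
    outgroup = tree.outgroup_leaves(branch)
    if not outgroup:
        return set()
    under = tree.leaves_under(branch)
    induced = set(MODULES)
    lost = set()
    for tid, row in orthology.tuples.iterrows():
        og = [_module_of(assignments, lf, row[lf]) for lf in outgroup]
        if any(s is None or s not in induced for s in og):
            continue
        below = [_module_of(assignments, lf, row[lf]) for lf in under]
        if all(s is None or s == "none" for s in below):
            lost.add(tid)
    return lost


def branch_report(tree: SpeciesTree, assignments: Assignments,
                  orthology: OrthologySet) -> pd.DataFrame:
    """Conserved / gained / lost tuples for every internal branch and module."""
    rows = []
    for branch in tree.internal_names:
        for module in MODULES:
            conserved = conserved_at_branch(tree, assignments, orthology,
                                            branch, module)
            gains = gains_at_branch(tree, assignments, orthology, branch, module)
            gained_ids = set(gains["tuple_id"])
            categories = dict(zip(gains["tuple_id"], gains["category"]))
            annotations = dict(zip(gains["tuple_id"], gains["annotation"]))
            for tid in sorted(conserved):
                status = "gained" if tid in gained_ids else "conserved"
                rows.append({"branch": branch, "module": module,
                             "tuple_id": tid, "status": status,
                             "category": categories.get(tid, ""),
                             "annotation": annotations.get(tid, "")})
        for tid in sorted(lost_induction(tree, assignments, orthology, branch)):
            rows.append({"branch": branch, "module": "any_wood",
                         "tuple_id": tid, "status": "lost",
                         "category": "", "annotation": ""})
    return pd.DataFrame(rows, columns=["branch", "module", "tuple_id",
                                       "status", "category", "annotation"])


def branch_counts(report: pd.DataFrame) -> pd.DataFrame:
    """Summarize a branch report into per-branch/module counts."""
    rows = []
    for (branch, module), grp in report.groupby(["branch", "module"]):
        rows.append({
            "branch": branch, "module": module,
            "conserved": int((grp["status"] != "lost").sum()),
            "gained": int((grp["status"] == "gained").sum()),
            "lost": int((grp["status"] == "lost").sum()),
        })
    return pd.DataFrame(rows)


def annotate_gene_classes(assignments: Assignments,
                          class_table: pd.DataFrame,
                          std_expr: dict[str, pd.DataFrame] | None = None
                          ) -> pd.DataFrame:
    """Per strain and functional class: module counts and mean standardized
    expression per condition (pure aggregation; unknown genes are counted
    and skipped)."""
    required = ("gene_id", "class")
    missing = [c for c in required if c not in class_table.columns]
    if missing:
        raise ValueError(f"class table missing columns: {missing}")
    rows = []
    for strain, assign in assignments.items():
        known = class_table[class_table["gene_id"].isin(assign.index)]
        for cls, grp in known.groupby("class"):
            genes = grp["gene_id"].tolist()
            labels = assign.loc[genes]
            row = {"strain": strain, "class": cls, "n_genes": len(genes),
                   "n_unknown": int((class_table["class"] == cls).sum()) - len(genes)}
            for m in MODULES + ("none",):
                row[f"count_{m}"] = int((labels == m).sum())
            if std_expr is not None and strain in std_expr:
                se = std_expr[strain]
                present = [g for g in genes if g in se.index]
                for cond in se.columns:
                    row[f"mean_std_{cond}"] = (
                        float(se.loc[present, cond].mean()) if present else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
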
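import numpy as np
import pandas as pd
import pytest

from modevol.evolution import (annotate_gene_classes, branch_counts,
                               branch_report, conserved_at_branch,
                               gains_at_branch, lost_induction)
from modevol.io import MODULES, read_newick
from modevol.orthology import OrthologySet

STRAINS = ["lacE", "lacJ", "shas", "shim"]


def make_orthoset(tuple_rows, copy_numbers=None):
    """tuple_rows: tuple_id -> {strain: gene or None};
    copy_numbers: tuple_id -> {strain: count} (default 1 per present gene)."""
    tuples = pd.DataFrame.from_dict(
        {tid: {s: (row.get(s) if row.get(s) is not None else np.nan)
               for s in STRAINS} for tid, row in tuple_rows.items()},
        orient="index", columns=STRAINS)
    tuples.index.name = "tuple_id"
    clusters = {}
    for tid, row in tuple_rows.items():
        members = []
        for s in STRAINS:
            g = row.get(s)
            if g is None:
                continue
            n = 1 if copy_numbers is None else copy_numbers.get(tid, {}).get(s, 1)
            members.append((s, g))
            for extra in range(1, n):
                members.append((s, f"{g}_copy{extra}"))
        clusters[tid] = members
    return OrthologySet(clusters=clusters, tuples=tuples, duplicated={},
                        strains=STRAINS)


def series_assignments(per_strain):
    """per_strain: strain -> {gene: module}"""
    return {s: pd.Series(d, dtype=object) for s, d in per_strain.items()}


def simple_case(modules_by_strain, tid="t0"):
    """One tuple with gene '<strain>_g' assigned per-strain modules."""
    rows = {tid: {s: f"{s}_g" for s in STRAINS}}
    assigns = series_assignments(
        {s: {f"{s}_g": m} for s, m in modules_by_strain.items()})
    return make_orthoset(rows), assigns


@pytest.fixture(scope="module")
def tree():
    return read_newick("(((lacE,lacJ),shas),shim);")


LCA = "lacElacJshas"
ROOT = "lacElacJshasshim"


class TestConserved:
    def test_conserved_everywhere(self, tree):
        oset, assigns = simple_case({s: "spruce" for s in STRAINS})
        for branch in (LCA, ROOT, "lacElacJ"):
            assert conserved_at_branch(tree, assigns, oset, branch,
                                       "spruce") == {"t0"}

    def test_conserved_in_ingroup_only(self, tree):
        oset, assigns = simple_case({"lacE": "spruce", "lacJ": "spruce",
                                     "shas": "spruce", "shim": "core"})
        assert conserved_at_branch(tree, assigns, oset, LCA, "spruce") == {"t0"}
        assert conserved_at_branch(tree, assigns, oset, ROOT, "spruce") == set()

    def test_incomplete_tuple_skipped(self, tree):
        rows = {"t0": {"lacE": "lacE_g", "lacJ": "lacJ_g", "shim": "shim_g"}}
        oset = make_orthoset(rows)
        assigns = series_assignments({s: {f"{s}_g": "core"} for s in STRAINS})
        assert conserved_at_branch(tree, assigns, oset, LCA, "core") == set()
        assert conserved_at_branch(tree, assigns, oset, "lacElacJ",
                                   "core") == {"t0"}

    def test_unknown_branch_rejected(self, tree):
        oset, assigns = simple_case({s: "core" for s in STRAINS})
        with pytest.raises(KeyError):
            conserved_at_branch(tree, assigns, oset, "nosuch", "core")


class TestGains:
    def test_recruited_from_core(self, tree):
        oset, assigns = simple_case({"lacE": "spruce", "lacJ": "spruce",
                                     "shas": "spruce", "shim": "core"})
        gains = gains_at_branch(tree, assigns, oset, LCA, "spruce")
        assert list(gains["category"]) == ["recruited_from_core"]

    def test_not_induced_in_outgroup(self, tree):
        oset, assigns = simple_case({"lacE": "spruce", "lacJ": "spruce",
                                     "shas": "spruce", "shim": "none"})
        gains = gains_at_branch(tree, assigns, oset, LCA, "spruce")
        assert list(gains["category"]) == ["not_induced_in_outgroup"]

    def test_duplicated_at_branch(self, tree):
        rows = {"t0": {s: f"{s}_g" for s in STRAINS}}
        copies = {"t0": {"lacE": 2, "lacJ": 2, "shas": 2, "shim": 1}}
        oset = make_orthoset(rows, copy_numbers=copies)
        assigns = series_assignments(
            {s: {f"{s}_g": "spruce"} for s in ("lacE", "lacJ", "shas")}
            | {"shim": {"shim_g": "none"}})
        gains = gains_at_branch(tree, assigns, oset, LCA, "spruce")
        assert list(gains["category"]) == ["duplicated_at_branch"]

    def test_no_gain_when_outgroup_also_in_module(self, tree):
        oset, assigns = simple_case({s: "pine" for s in STRAINS})
        assert gains_at_branch(tree, assigns, oset, LCA, "pine").empty

    def test_root_has_no_gains(self, tree):
        oset, assigns = simple_case({s: "core" for s in STRAINS})
        assert gains_at_branch(tree, assigns, oset, ROOT, "core").empty


class TestLoss:
    def test_loss_at_lca(self, tree):
        oset, assigns = simple_case({"lacE": "none", "lacJ": "none",
                                     "shas": "none", "shim": "core"})
        assert lost_induction(tree, assigns, oset, LCA) == {"t0"}

    def test_recruitment_is_not_loss(self, tree):
        oset, assigns = simple_case({"lacE": "spruce", "lacJ": "spruce",
                                     "shas": "spruce", "shim": "core"})
        assert lost_induction(tree, assigns, oset, LCA) == set()


# ---------------------------------------------------------------------------
# brute-force oracle over random toy tuples
# ---------------------------------------------------------------------------

def oracle_eval(tree, assigns, oset, branch, module):
    """Exhaustive re-evaluation of the conserved/gained/lost definitions,
    written directly from their set-logic wording."""
    under = tree.leaves_under(branch)
    outgroup = tree.outgroup_leaves(branch)

    def state(leaf, row):
        g = row[leaf]
        if not isinstance(g, str):
            return None
        return assigns[leaf].get(g, "none")

    conserved, gained, lost = set(), set(), set()
    for tid, row in oset.tuples.iterrows():
        below = [state(l, row) for l in under]
        if all(s is not None for s in below) and all(s == module for s in below):
            conserved.add(tid)
            og = [state(l, row) for l in outgroup]
            if outgroup and (any(s is None for s in og)
                             or any(s != module for s in og)):
                gained.add(tid)
        og = [state(l, row) for l in outgroup]
        if (outgroup and all(s in ("core", "spruce", "pine") for s in og)
                and all(s is None or s == "none"
                        for s in [state(l, row) for l in under])):
            lost.add(tid)
    return conserved, gained, lost


def random_toy(rng, n_tuples=60):
    rows, assigns = {}, {s: {} for s in STRAINS}
    levels = ["core", "spruce", "pine", "none"]
    for i in range(n_tuples):
        tid = f"t{i:03d}"
        row = {}
        for s in STRAINS:
            if rng.random() < 0.85:
                g = f"{s}_g{i:03d}"
                row[s] = g
                if rng.random() < 0.9:  # some genes left unassigned
                    assigns[s][g] = levels[rng.integers(4)]
        rows[tid] = row
    return make_orthoset(rows), series_assignments(assigns)


def test_random_tuples_match_oracle_on_all_branches(tree):
    rng = np.random.default_rng(11)
    for rep in range(4):
        oset, assigns = random_toy(rng)
        for branch in tree.internal_names:
            losses = lost_induction(tree, assigns, oset, branch)
            for module in MODULES:
                want_c, want_g, want_l = oracle_eval(tree, assigns, oset,
                                                     branch, module)
                got_c = conserved_at_branch(tree, assigns, oset, branch, module)
                got_g = set(gains_at_branch(tree, assigns, oset, branch,
                                            module)["tuple_id"])
                assert got_c == want_c
                assert got_g == want_g
                assert losses == want_l


class TestInvariants:
    def test_root_conservation_shrinks(self, tree, small_sim, small_result):
        assigns = {s: small_result.assignments[s].set_index("gene_id")["module"]
                   for s in STRAINS}
        oset = small_result.orthology
        for module in MODULES:
            root = conserved_at_branch(tree, assigns, oset, ROOT, module)
            for branch in (LCA, "lacElacJ"):
                below = conserved_at_branch(tree, assigns, oset, branch, module)
                # restrict to tuples complete at the root
                complete = set(oset.tuples.index[oset.complete])
                assert root & complete <= below

    def test_gained_subset_of_conserved_in_report(self, small_result):
        rep = small_result.report
        grouped = rep[rep["status"].isin(["conserved", "gained"])]
        for (_, _), grp in grouped.groupby(["branch", "module"]):
            assert set(grp.loc[grp["status"] == "gained", "tuple_id"]) <= \
                set(grp["tuple_id"])

    def test_gain_categories_partition(self, small_result):
        gained = small_result.report.query("status == 'gained'")
        allowed = {"not_induced_in_outgroup", "recruited_from_core",
                   "recruited_from_spruce", "recruited_from_pine",
                   "duplicated_at_branch"}
        assert set(gained["category"]) <= allowed


class TestAnnotateClasses:
    def test_counting(self):
        assigns = {"lacE": pd.Series({"a": "pine", "b": "pine", "c": "core"})}
        classes = pd.DataFrame({"gene_id": ["a", "b", "c", "zz"],
                                "class": ["GH5_5", "GH5_5", "GH5_5", "GH5_5"]})
        out = annotate_gene_classes(assigns, classes)
        row = out.iloc[0]
        assert row["count_pine"] == 2 and row["count_core"] == 1
        assert row["n_unknown"] == 1

    def test_empty_class_table(self):
        assigns = {"lacE": pd.Series({"a": "pine"})}
        out = annotate_gene_classes(
            assigns, pd.DataFrame(columns=["gene_id", "class"]))
        assert out.empty
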
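"""Synthetic dataset generator with planted module-evolution events.

The simulator emulates the study design: four strains on a rooted species
tree, three conditions (spruce, pine, SCD) with five replicates each, and
~2000 orthogroups whose expression-module membership evolves root-to-tip as
a state machine.  A gain turns a "none" group into a module member (or
recruits it from another module) at one branch; a loss silences a module
member; a duplication adds a second gene copy in every leaf below the
branch.  Planted states translate into condition effects on the NB count
means: core = induction on both woods vs the sugar control, spruce/pine =
induction on one wood only.

The generator also emits a BLAST-like similarity table that encodes the
true orthogroups as high-bitscore within-cluster edges plus low-score noise
edges between clusters (so Markov clustering must genuinely separate
groups), and an annotation table with one term planted among the
spruce-gain genes of the focal branch.

Everything is driven by one ``numpy`` Generator seeded from
``SimConfig.rng_seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITIONS, CountTable, MODULES, SampleDesign, SpeciesTree
from .orthology import OrthologySet

DEFAULT_TREE_NEWICK = "(((lacE,lacJ),shas),shim);"


@dataclass
class SimConfig:
    """Simulation parameters (defaults mirror the emulated study design)."""

    n_orthogroups: int = 2000
    n_replicates: int = 5
    baseline_log2_mean: float = 5.0     # log2 NB mean at unit library factor
    baseline_log2_sd: float = 2.0
    effect_size: float = 2.0            # planted induction, log2FC
    dispersion_shape: float = 2.0       # gamma prior on NB dispersion phi
    dispersion_scale: float = 0.05
    libsize_low: float = 0.8e6
    libsize_high: float = 1.2e6
    #: branch -> module -> fraction of orthogroups gaining that module there;
    #: None = study defaults (core 0.05 at the root; spruce/pine/core
    #: 0.05/0.03/0.04 at the largest child of the root, the focal LCA)
    gain_fractions: dict[str, dict[str, float]] | None = None
    duplication_fraction: float = 0.02  # of orthogroups, at the focal branch
    loss_fraction: float = 0.02         # of orthogroups, at the focal branch
    noise_edge_fraction: float = 0.10   # cross-cluster noise edges / group
    annotation_coverage: float = 0.80   # planted-term cover of spruce gains
    annotation_background: float = 0.05
    n_background_terms: int = 20
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_orthogroups < 1 or self.n_replicates < 2:
            raise ValueError("need >=1 orthogroup and >=2 replicates")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for frac in (self.duplication_fraction, self.loss_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.gain_fractions is not None:
            for branch, mods in self.gain_fractions.items():
                total = sum(mods.values())
                if total > 1 or any(f < 0 for f in mods.values()):
                    raise ValueError(
                        f"gain fractions at {branch} invalid (sum {total})")


@dataclass
class TruthTable:
    """Planted ground truth of one simulated dataset."""

    states: pd.DataFrame                 # orthogroup x tree node -> module
    events: pd.DataFrame                 # orthogroup, branch, event, module, category
    effects: dict[str, pd.DataFrame]     # strain -> gene x (spruce/pine effects)
    leaf_modules: dict[str, pd.Series]   # strain -> gene -> module
    gene_group: dict[str, int]           # gene id -> orthogroup index
    focal_branch: str

    def gains_at(self, branch: str, module: str) -> set[int]:
        ev = self.events
        sel = (ev["branch"] == branch) & (ev["module"] == module) \
            & (ev["event"] == "gain")
        return set(ev.loc[sel, "orthogroup"])

    def losses_at(self, branch: str) -> set[int]:
        ev = self.events
        sel = (ev["branch"] == branch) & (ev["event"] == "loss")
        return set(ev.loc[sel, "orthogroup"])

    def events_frame(self) -> pd.DataFrame:
        return self.events.copy()


@dataclass
class SimulatedDataset:
    tree: SpeciesTree
    config: SimConfig
    counts: dict[str, CountTable]
    design: SampleDesign
    orthology: OrthologySet
    similarity: pd.DataFrame
    annotations: pd.DataFrame
    truth: TruthTable


def nb_draw(mean, dispersion: float, rng: np.random.Generator):
    """NB draw(s) with variance = mean + dispersion * mean^2.

    ``dispersion`` 0 degenerates to Poisson; implemented as the
    gamma-Poisson mixture so any positive real dispersion is allowed.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _default_gain_fractions(tree: SpeciesTree) -> tuple[dict, str]:
    root = tree.root_name
    internal = [b for b in tree.internal_names if b != root]
    if internal:
        focal = max(internal, key=lambda b: (len(tree.leaves_under(b)), b))
    else:
        focal = root
    fractions = {root: {"core": 0.05}}
    fractions.setdefault(focal, {})
    fractions[focal].update({"spruce": 0.05, "pine": 0.03, "core": 0.04})
    return fractions, focal


def _evolve_states(cfg: SimConfig, tree: SpeciesTree,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame,
                                                      str, np.ndarray]:
    """Root-to-tip state machine over orthogroups.

    Returns (states per node, event list, focal branch, duplicated mask).
    """
    gain_fractions, focal = (
        (cfg.gain_fractions, None) if cfg.gain_fractions is not None
        else _default_gain_fractions(tree))
    if focal is None:
        non_root = [b for b in gain_fractions if b != tree.root_name]
        focal = non_root[0] if non_root else tree.root_name

    G = cfg.n_orthogroups
    nodes = list(tree.internal_names) + tree.leaf_names
    states = pd.DataFrame("none", index=range(G), columns=nodes)
    events: list[dict] = []
    duplicated = np.zeros(G, dtype=bool)

    for node in tree.tree.preorder_node_iter():
        name = node.label if not node.is_leaf() else node.taxon.label
        parent = node.parent_node
        current = (states[parent.label if not parent.is_leaf()
                          else parent.taxon.label].copy()
                   if parent is not None else pd.Series("none", index=range(G)))

        branch_gains = gain_fractions.get(name, {})
        is_focal = name == focal
        n_loss = round(cfg.loss_fraction * G) if is_focal else 0
        n_dup = round(cfg.duplication_fraction * G) if is_focal else 0

        order = rng.permutation(G)
        taken = np.zeros(G, dtype=bool)
        gained_here: list[int] = []
        for module in sorted(branch_gains):
            need = round(branch_gains[module] * G)
            for g in order:
                if need == 0:
                    break
                if taken[g] or current.iloc[g] == module:
                    continue
                prior = current.iloc[g]
                category = ("not_induced_in_outgroup" if prior == "none"
                            else f"recruited_from_{prior}")
                events.append({"orthogroup": int(g), "branch": name,
                               "event": "gain", "module": module,
                               "category": category})
                current.iloc[g] = module
                taken[g] = True
                gained_here.append(int(g))
                need -= 1
        if n_loss:
            eligible = [g for g in order
                        if not taken[g] and current.iloc[g] in MODULES]
            for g in eligible[:n_loss]:
                events.append({"orthogroup": int(g), "branch": name,
                               "event": "loss", "module": current.iloc[g],
                               "category": ""})
                current.iloc[g] = "none"
                taken[g] = True
        if n_dup and gained_here:
            chosen = rng.choice(gained_here,
                                size=min(n_dup, len(gained_here)),
                                replace=False)
            for g in chosen:
                duplicated[g] = True
                # the gain rides on a duplication: relabel its provenance
                for ev in reversed(events):
                    if ev["orthogroup"] == int(g) and ev["branch"] == name \
                            and ev["event"] == "gain":
                        ev["category"] = "duplicated"
                        break
                events.append({"orthogroup": int(g), "branch": name,
                               "event": "duplication",
                               "module": current.iloc[g], "category": ""})
        states[name] = current.to_numpy()

    ev = pd.DataFrame(events, columns=["orthogroup", "branch", "event",
                                       "module", "category"])
    return states, ev, focal, duplicated


def simulate_dataset(cfg: SimConfig, tree: SpeciesTree | None = None
                     ) -> SimulatedDataset:
    """Generate counts, orthology, similarity, annotations and truth."""
    from .io import read_newick

    if tree is None:
        tree = read_newick(DEFAULT_TREE_NEWICK)
    if len(tree.leaf_names) < 2:
        raise ValueError("tree must have >= 2 leaves")
    rng = np.random.default_rng(cfg.rng_seed)
    G = cfg.n_orthogroups
    strains = tree.leaf_names

    states, events, focal, dup_mask = _evolve_states(cfg, tree, rng)
    focal_under = set(tree.leaves_under(focal))

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=G)
    phi = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale, size=G)

    # gene inventory: one copy per strain per group; focal-branch duplications
    # add a "b" copy in every leaf below the focal branch
    gene_group: dict[str, int] = {}
    clusters: dict[str, list[tuple[str, str]]] = {}
    width = max(4, len(str(G)))
    genes_per_strain: dict[str, list[tuple[str, int, bool]]] = {s: [] for s in strains}
    for g in range(G):
        cid = f"OG{g:0{width}d}"
        members = []
        for s in strains:
            gid = f"{s}_g{g:0{width}d}"
            members.append((s, gid))
            gene_group[gid] = g
            genes_per_strain[s].append((gid, g, False))
            if dup_mask[g] and s in focal_under:
                gid2 = f"{s}_g{g:0{width}d}b"
                members.append((s, gid2))
                gene_group[gid2] = g
                genes_per_strain[s].append((gid2, g, True))
        clusters[cid] = members

    # sample design
    design_rows = []
    for s in strains:
        for cond in CONDITIONS:
            for rep in range(1, cfg.n_replicates + 1):
                design_rows.append({"sample_id": f"{s}_{cond}_{rep}",
                                    "strain": s, "condition": cond,
                                    "replicate": rep})
    design = SampleDesign(pd.DataFrame(design_rows))

    # condition effects and counts per strain
    effects: dict[str, pd.DataFrame] = {}
    leaf_modules: dict[str, pd.Series] = {}
    count_tables: dict[str, CountTable] = {}
    for s in strains:
        leaf_state = states[s]
        gene_rows = genes_per_strain[s]
        gids = [g for g, _, _ in gene_rows]
        grp = np.array([k for _, k, _ in gene_rows])
        is_dup = np.array([d for _, _, d in gene_rows])
        mod = leaf_state.to_numpy()[grp]
        eff_sp = np.where(np.isin(mod, ("core", "spruce")), cfg.effect_size, 0.0)
        eff_pi = np.where(np.isin(mod, ("core", "pine")), cfg.effect_size, 0.0)
        base = baseline[grp] + np.where(is_dup, rng.normal(0, 0.1, is_dup.size), 0.0)
        eff_sp = eff_sp + np.where(is_dup & (eff_sp > 0),
                                   rng.normal(0, 0.1, is_dup.size), 0.0)
        eff_pi = eff_pi + np.where(is_dup & (eff_pi > 0),
                                   rng.normal(0, 0.1, is_dup.size), 0.0)
        effects[s] = pd.DataFrame({"spruce_vs_SCD": eff_sp,
                                   "pine_vs_SCD": eff_pi}, index=gids)
        leaf_modules[s] = pd.Series(mod, index=gids, name="module")

        sdesign = design.for_strain(s)
        samples = sdesign.table["sample_id"].tolist()
        conds = sdesign.table["condition"].tolist()
        libs = rng.uniform(cfg.libsize_low, cfg.libsize_high, len(samples))
        counts = np.empty((len(gids), len(samples)), dtype=np.int64)
        gphi = phi[grp]
        for j, cond in enumerate(conds):
            effect = (eff_sp if cond == "spruce"
                      else eff_pi if cond == "pine" else 0.0)
            mean = (libs[j] / 1e6) * 2.0 ** (base + effect)
            mean = np.maximum(mean, 1e-8)
            lam = rng.gamma(shape=1.0 / gphi, scale=mean * gphi)
            counts[:, j] = rng.poisson(lam)
        count_tables[s] = CountTable(
            pd.DataFrame(counts, index=pd.Index(gids, name="gene_id"),
                         columns=samples), sdesign)

    # truth orthology (representatives = the primary, non-"b" copies)
    rows = {}
    dup_flags = {}
    for g in range(G):
        cid = f"OG{g:0{width}d}"
        rows[cid] = {s: f"{s}_g{g:0{width}d}" for s in strains}
        dup_flags[cid] = set(focal_under) if dup_mask[g] else set()
    tuples = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    tuples.index.name = "tuple_id"
    orthology = OrthologySet(clusters=clusters, tuples=tuples,
                             duplicated=dup_flags, strains=list(strains))

    similarity = _simulate_similarity(cfg, clusters, rng)
    annotations = _simulate_annotations(cfg, events, focal, gene_group,
                                        strains, rng)

    truth = TruthTable(states=states, events=events, effects=effects,
                       leaf_modules=leaf_modules, gene_group=gene_group,
                       focal_branch=focal)
    return SimulatedDataset(tree=tree, config=cfg, counts=count_tables,
                            design=design, orthology=orthology,
                            similarity=similarity, annotations=annotations,
                            truth=truth)


def _simulate_similarity(cfg: SimConfig, clusters: dict[str, list],
                         rng: np.random.Generator) -> pd.DataFrame:
    """Within-cluster high-bitscore hits (both directions) plus low-score
    cross-cluster noise edges that still pass the default filters."""
    rows = []
    all_genes = []
    for members in clusters.values():
        genes = [g for _, g in members]
        all_genes.append(genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                bs = rng.uniform(150.0, 400.0)
                pid = rng.uniform(60.0, 95.0)
                for q, t in ((genes[i], genes[j]), (genes[j], genes[i])):
                    rows.append({"query": q, "subject": t,
                                 "pident": round(pid, 1), "length": 300,
                                 "evalue": 1e-50, "bitscore": round(bs, 1)})
    n_noise = round(cfg.noise_edge_fraction * len(clusters))
    cluster_ids = list(range(len(all_genes)))
    for _ in range(n_noise):
        if len(cluster_ids) < 2:
            break
        c1, c2 = rng.choice(cluster_ids, size=2, replace=False)
        q = all_genes[c1][rng.integers(len(all_genes[c1]))]
        t = all_genes[c2][rng.integers(len(all_genes[c2]))]
        rows.append({"query": q, "subject": t,
                     "pident": round(rng.uniform(26.0, 35.0), 1),
                     "length": 120, "evalue": 1e-8,
                     "bitscore": round(rng.uniform(30.0, 60.0), 1)})
    return pd.DataFrame(rows, columns=["query", "subject", "pident",
                                       "length", "evalue", "bitscore"])


def _simulate_annotations(cfg: SimConfig, events: pd.DataFrame, focal: str,
                          gene_group: dict[str, int], strains: list[str],
                          rng: np.random.Generator) -> pd.DataFrame:
    """Annotation table planting one enriched term among the focal-branch
    spruce-gain genes, plus uninformative background terms."""
    spruce_gain = sorted(set(
        events.loc[(events["branch"] == focal) & (events["event"] == "gain")
                   & (events["module"] == "spruce"), "orthogroup"]))
    genes = sorted(gene_group)
    by_group: dict[int, list[str]] = {}
    for g, k in gene_group.items():
        by_group.setdefault(k, []).append(g)

    rows = []
    covered = [k for k in spruce_gain
               if rng.random() < cfg.annotation_coverage]
    planted = set()
    for k in covered:
        planted.update(by_group[k])
    n_bg = round(cfg.annotation_background * len(genes))
    background = rng.choice([g for g in genes if g not in planted],
                            size=n_bg, replace=False)
    for g in sorted(planted) + sorted(background):
        rows.append({"gene_id": g, "term_id": "TERM_PLANTED"})
    for t in range(cfg.n_background_terms):
        size = round(0.03 * len(genes))
        for g in rng.choice(genes, size=size, replace=False):
            rows.append({"gene_id": g, "term_id": f"TERM_BG{t:03d}"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------------------
# recovery scoring against the planted truth
# ---------------------------------------------------------------------------

def score_event_recovery(truth: TruthTable, report: pd.DataFrame,
                         orthology: OrthologySet, branch: str | None = None
                         ) -> pd.DataFrame:
    """Sensitivity and precision of recovered gains (per module) and losses
    at a branch against the planted events.

    Recovered tuples are mapped onto truth orthogroups through their member
    genes (majority vote), so the scoring is independent of cluster ids.
    """
    branch = branch or truth.focal_branch

    def tuple_to_group(tid) -> int | None:
        groups = [truth.gene_group[g] for g in orthology.tuples.loc[tid]
                  if isinstance(g, str) and g in truth.gene_group]
        if not groups:
            return None
        vals, counts = np.unique(groups, return_counts=True)
        return int(vals[np.argmax(counts)])

    rows = []
    at_branch = report[report["branch"] == branch]
    for module in MODULES:
        called = {tuple_to_group(t) for t in at_branch.loc[
            (at_branch["module"] == module) & (at_branch["status"] == "gained"),
            "tuple_id"]}
        called.discard(None)
        true = truth.gains_at(branch, module)
        tp = len(called & true)
        rows.append({"branch": branch, "event": f"gain_{module}",
                     "n_true": len(true), "n_called": len(called), "tp": tp,
                     "sensitivity": tp / len(true) if true else np.nan,
                     "precision": tp / len(called) if called else np.nan})
    called = {tuple_to_group(t) for t in at_branch.loc[
        at_branch["status"] == "lost", "tuple_id"]}
    called.discard(None)
    true = truth.losses_at(branch)
    tp = len(called & true)
    rows.append({"branch": branch, "event": "loss",
                 "n_true": len(true), "n_called": len(called), "tp": tp,
                 "sensitivity": tp / len(true) if true else np.nan,
                 "precision": tp / len(called) if called else np.nan})
    return pd.DataFrame(rows)
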
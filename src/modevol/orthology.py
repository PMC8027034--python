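"""Orthogroup inference: similarity graph filtering, Markov clustering, and
within-cluster one-to-one ortholog / duplication classification.

The all-vs-all protein similarity hits are filtered by e-value and percent
match, symmetrized by taking the maximum bitscore over hit directions, and
clustered by MCL (alternating expansion and inflation of the
column-stochastic weight matrix).  Within each cluster, strains with a
single member contribute it to the one-to-one ortholog tuple directly;
strains with several members are flagged as duplicated and contribute
their best-connected copy (highest within-cluster mean bitscore).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over gene ids (weight = max bitscore)."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # key sorted (u, v), u < v

    def weight(self, u: str, v: str) -> float:
        return self.edges.get((u, v) if u < v else (v, u), 0.0)

    def neighbors_weights(self, u: str) -> dict[str, float]:
        out = {}
        for (a, b), w in self.edges.items():
            if a == u:
                out[b] = w
            elif b == u:
                out[a] = w
        return out


def build_similarity_graph(hits: pd.DataFrame, evalue_max: float = 1e-5,
                           percent_match_min: float = 25.0) -> SimilarityGraph:
    """Filter hits and symmetrize into an undirected weighted graph.

    An edge is kept if at least one direction passes both the e-value and
    percent-match cutoffs; its weight is the maximum bitscore over all
    retained directions.  Self-hits are dropped.  All genes appearing in
    the table (as query or subject) become nodes, so genes whose every hit
    fails the filter still emerge as singletons.
    """
    required = ("query", "subject", "pident", "evalue", "bitscore")
    missing = [c for c in required if c not in hits.columns]
    if missing:
        raise ValueError(f"hits table missing columns: {missing}")
    nodes = sorted(set(hits["query"]).union(hits["subject"]))
    passing = hits[(hits["evalue"] <= evalue_max)
                   & (hits["pident"] >= percent_match_min)
                   & (hits["query"] != hits["subject"])]
    edges: dict[tuple[str, str], float] = {}
    for q, s, bs in zip(passing["query"], passing["subject"], passing["bitscore"]):
        key = (q, s) if q < s else (s, q)
        if bs > edges.get(key, 0.0):
            edges[key] = float(bs)
    return SimilarityGraph(nodes=nodes, edges=edges)


def mcl_cluster(graph: SimilarityGraph, inflation: float = 3.0,
                max_iter: int = 200, tol: float = 1e-8,
                prune: float = 1e-10) -> list[tuple[str, ...]]:
    """Markov clustering of the similarity graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1 for isolated nodes), columns are normalized to sum 1,
    and expansion (matrix square) alternates with inflation (elementwise
    power ``inflation`` followed by column renormalization) and pruning of
    entries below ``prune`` until the matrix changes by less than ``tol``.
    Clusters are the connected components of the converged matrix;
    singletons are retained.  The result is invariant to node relabeling
    and to scaling all weights by a positive constant.
    """
    if not graph.nodes:
        raise ValueError("empty similarity graph")
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)

    rows, cols, vals = [], [], []
    max_incident = np.zeros(n)
    for (u, v), w in graph.edges.items():
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_incident[i] = max(max_incident[i], w)
        max_incident[j] = max(max_incident[j], w)
    loop = np.where(max_incident > 0, max_incident, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)
    m = sparse.csc_array((vals, (rows, cols)), shape=(n, n), dtype=float)

    m = _normalize_columns(m)
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m                       # expansion
        m.data **= inflation            # inflation
        m = _normalize_columns(m)
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = _normalize_columns(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.data.max() < tol:
            break

    n_comp, labels = sparse.csgraph.connected_components(m, directed=False)
    clusters = [[] for _ in range(n_comp)]
    for v, lab in zip(nodes, labels):
        clusters[lab].append(v)
    out = [tuple(sorted(c)) for c in clusters]
    out.sort(key=lambda c: (-len(c), c[0]))
    return out


def _normalize_columns(m: "sparse.csc_array") -> "sparse.csc_array":
    col_sums = np.asarray(m.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    d = sparse.dia_array((1.0 / col_sums[None, :], [0]), shape=m.shape)
    return (m @ d).tocsc()


# ---------------------------------------------------------------------------
# within-cluster orthology
# ---------------------------------------------------------------------------

@dataclass
class OrthologySet:
    """Clusters, one-to-one ortholog tuples, and per-strain duplication flags.

    ``tuples`` has one row per cluster (indexed by cluster id) and one
    column per strain; a missing member is NaN.  ``complete`` marks tuples
    with a member for every strain.
    """

    clusters: dict[str, list[tuple[str, str]]]  # cluster_id -> [(strain, gene)]
    tuples: pd.DataFrame
    duplicated: dict[str, set[str]]             # cluster_id -> strains with >=2 copies
    strains: list[str]
    gene_cluster: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_cluster:
            self.gene_cluster = {g: cid for cid, mem in self.clusters.items()
                                 for _, g in mem}

    @property
    def complete(self) -> pd.Series:
        return self.tuples[self.strains].notna().all(axis=1)

    def copy_number(self, cluster_id: str) -> dict[str, int]:
        counts: dict[str, int] = {s: 0 for s in self.strains}
        for strain, _ in self.clusters[cluster_id]:
            counts[strain] = counts.get(strain, 0) + 1
        return counts

    def to_cluster_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.clusters):
            dup = self.duplicated.get(cid, set())
            for strain, gene in sorted(self.clusters[cid]):
                rows.append({"cluster_id": cid, "strain": strain,
                             "gene_id": gene, "duplicated_flag": strain in dup})
        return pd.DataFrame(rows)


def classify_orthologs(members: list[tuple[str, str]], strains: list[str],
                       graph: SimilarityGraph | None = None
                       ) -> tuple[dict[str, str], set[str], bool]:
    """One-to-one representatives and duplication flags for one cluster.

    Returns (strain -> representative gene, duplicated strains, complete).
    Multi-copy strains contribute the copy with the highest mean bitscore
    to the other cluster members (ties broken by gene id).
    """
    by_strain: dict[str, list[str]] = {}
    for strain, gene in members:
        by_strain.setdefault(strain, []).append(gene)
    genes_all = [g for _, g in members]

    rep: dict[str, str] = {}
    duplicated: set[str] = set()
    for strain, genes in by_strain.items():
        if len(genes) == 1:
            rep[strain] = genes[0]
            continue
        duplicated.add(strain)
        def mean_score(g: str) -> float:
            others = [x for x in genes_all if x != g]
            if not others or graph is None:
                return 0.0
            return float(np.mean([graph.weight(g, o) for o in others]))
        rep[strain] = max(sorted(genes), key=mean_score)
    complete = all(s in rep for s in strains)
    return rep, duplicated, complete


def build_orthology(clusters: list[tuple[str, ...]], gene_strain: dict[str, str],
                    strains: list[str], graph: SimilarityGraph | None = None,
                    ) -> OrthologySet:
    """Assemble an OrthologySet from MCL clusters and a gene->strain map."""
    width = max(4, len(str(len(clusters))))
    cluster_map: dict[str, list[tuple[str, str]]] = {}
    dup_map: dict[str, set[str]] = {}
    rows = {}
    for i, genes in enumerate(clusters):
        cid = f"OG{i:0{width}d}"
        members = [(gene_strain[g], g) for g in genes]
        cluster_map[cid] = members
        rep, dup, _ = classify_orthologs(members, strains, graph)
        dup_map[cid] = dup
        rows[cid] = {s: rep.get(s, np.nan) for s in strains}
    tuples = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    tuples.index.name = "tuple_id"
    return OrthologySet(clusters=cluster_map, tuples=tuples,
                        duplicated=dup_map, strains=list(strains))


def from_orthogroup_table(table: pd.DataFrame, strains: list[str]
                          ) -> OrthologySet:
    """Build an OrthologySet from a precomputed cluster_id/strain/gene table."""
    clusters: dict[str, list[tuple[str, str]]] = {}
    for cid, strain, gene in zip(table["cluster_id"], table["strain"],
                                 table["gene_id"]):
        clusters.setdefault(cid, []).append((strain, gene))
    dup_map, rows = {}, {}
    for cid, members in clusters.items():
        rep, dup, _ = classify_orthologs(members, strains, graph=None)
        dup_map[cid] = dup
        rows[cid] = {s: rep.get(s, np.nan) for s in strains}
    tuples = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    tuples = tuples.sort_index()
    tuples.index.name = "tuple_id"
    return OrthologySet(clusters=clusters, tuples=tuples,
                        duplicated=dup_map, strains=list(strains))


def nontrivial_clusters(orthology: OrthologySet) -> list[str]:
    """Cluster ids with more than 3 sequences and at least one strain with
    more than one gene (the duplication-aware subset)."""
    keep = []
    for cid, members in orthology.clusters.items():
        if len(members) <= 3:
            continue
        counts = orthology.copy_number(cid)
        if max(counts.values()) > 1:
            keep.append(cid)
    return sorted(keep)
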
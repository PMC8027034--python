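"""Readers and writers for the on-disk formats and the species tree.

Every table is TSV with a header row; gene and sample identifiers are
opaque strings.  The species tree is Newick; unnamed internal nodes get a
deterministic name (concatenation of their sorted descendant leaf names) so
that branch-level reports are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

CONDITIONS = ("spruce", "pine", "SCD")
MODULES = ("core", "spruce", "pine")
MODULE_LEVELS = ("core", "spruce", "pine", "none")


# ---------------------------------------------------------------------------
# sample design & count tables
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Per-sample metadata: strain, condition and replicate index."""

    table: pd.DataFrame  # columns: sample_id, strain, condition, replicate

    REQUIRED = ("sample_id", "strain", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        t = self.table
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if t.duplicated(["strain", "condition", "replicate"]).any():
            raise ValueError("duplicated (strain, condition, replicate) in design")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id in design")
        for (strain, cond), grp in t.groupby(["strain", "condition"]):
            if len(grp) < 2:
                raise ValueError(
                    f"strain {strain} has <2 replicates for condition {cond}"
                )

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())

    def for_strain(self, strain: str) -> "SampleDesign":
        sub = self.table[self.table["strain"] == strain].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no samples for strain {strain!r}")
        return SampleDesign(sub)

    def condition_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["condition"]


@dataclass
class CountTable:
    """Integer gene x sample counts for one strain, with its design."""

    counts: pd.DataFrame  # genes as rows, samples as columns
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        want = list(self.design.table["sample_id"])
        have = set(self.counts.columns)
        missing = [s for s in want if s not in have]
        if missing:
            raise ValueError(f"samples in design but not in counts: {missing}")
        # column order follows the design
        self.counts = self.counts[want]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.int64)

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(float)


def read_design(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str,
                                               "condition": str})
    return SampleDesign(table)


def read_count_table(path: str | Path, design_path: str | Path,
                     strain: str | None = None) -> CountTable:
    """Read a genes x samples TSV of counts plus its sample design.

    The first column holds gene ids; remaining column names must match
    sample ids in the design.  Non-integer or negative values are rejected
    with the offending row and column named.
    """
    design = read_design(design_path)
    if strain is not None:
        design = design.for_strain(strain)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.empty or raw.shape[0] == 0:
        raise ValueError(f"no genes in count table {path}")
    for col in raw.columns:
        vals = raw[col]
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = vals[vals != np.floor(pd.to_numeric(vals, errors="coerce"))]
            gene = frac.index[0] if len(frac) else vals.index[0]
            raise ValueError(
                f"non-integer count at gene {gene!r}, sample {col!r} in {path}"
            )
        if (arr < 0).any():
            gene = vals.index[arr < 0][0]
            raise ValueError(f"negative count at gene {gene!r}, sample {col!r}")
    raw.index = raw.index.astype(str)
    return CountTable(raw, design)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted species tree with uniquely named leaves and internal nodes.

    Internal nodes without a Newick label are named by concatenating their
    sorted descendant leaf names, which is deterministic for a fixed
    topology regardless of input rotation.
    """

    tree: dendropy.Tree
    _leaves_under: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        leaves = [l.taxon.label for l in self.tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf names are not unique")
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if len(node.child_nodes()) < 2:
                raise ValueError("internal node with <2 children")
            under = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            if not node.label:
                node.label = "".join(under)
            self._leaves_under[node.label] = under

    @property
    def leaf_names(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    @property
    def internal_names(self) -> list[str]:
        """Internal node names in preorder (root first)."""
        return [n.label for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    @property
    def root_name(self) -> str:
        return self.tree.seed_node.label

    def leaves_under(self, branch: str) -> tuple[str, ...]:
        if branch in self._leaves_under:
            return self._leaves_under[branch]
        if branch in self.leaf_names:
            return (branch,)
        raise KeyError(f"branch {branch!r} not in tree")

    def outgroup_leaves(self, branch: str) -> tuple[str, ...]:
        under = set(self.leaves_under(branch))
        return tuple(sorted(set(self.leaf_names) - under))


def read_newick(source: str | Path) -> SpeciesTree:
    """Parse a rooted Newick tree from a path or a literal Newick string."""
    text = str(source)
    if not text.strip().startswith("(") :
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True, rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# similarity hits, orthogroups, annotations
# ---------------------------------------------------------------------------

SIMILARITY_COLUMNS = ("query", "subject", "pident", "length", "evalue", "bitscore")


def read_similarity(path: str | Path) -> pd.DataFrame:
    """BLAST outfmt-6-like TSV; extra columns beyond the first six ignored."""
    hits = pd.read_csv(path, sep="\t")
    missing = [c for c in SIMILARITY_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"similarity table missing columns: {missing}")
    for i, (ev, bs) in enumerate(zip(hits["evalue"], hits["bitscore"])):
        if not np.isfinite(ev) or not np.isfinite(bs) or bs < 0 or ev < 0:
            raise ValueError(f"malformed similarity row at line {i + 2}")
    return hits[list(SIMILARITY_COLUMNS)]


def write_similarity(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_orthogroups(path: str | Path) -> pd.DataFrame:
    """Orthogroup membership TSV: cluster_id, strain, gene_id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("cluster_id", "strain", "gene_id") if c not in table.columns]
    if missing:
        raise ValueError(f"orthogroup table missing columns: {missing}")
    return table


def read_annotations(path: str | Path) -> pd.DataFrame:
    """gene -> term annotation TSV with columns gene_id, term_id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_id", "term_id") if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return table


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)
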
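"""Pathway priors: GMT / relation parsing, layered hierarchies and connectivity masks.

A curated pathway knowledgebase (Reactome-style) provides two priors:

* gene -> leaf-pathway membership (GMT file), and
* child-pathway -> parent-pathway relations (two-column TSV) forming a DAG.

These are compiled into a :class:`PathwayHierarchy` whose levels run from
leaf pathways up to top-level pathways, and then into a :class:`MaskStack`
of binary connectivity matrices that constrain the encoder weights: a unit
may only receive signal from prior-supported inputs.

Two encoder depths are supported: the shallow ``3F`` variant
(genes -> leaf pathways -> top pathways, intermediate levels collapsed by
reachability) and the full-depth ``5X`` variant that keeps every hierarchy
level as its own masked layer.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayHierarchy",
    "MaskStack",
    "parse_gmt",
    "parse_relations",
    "build_hierarchy",
    "build_masks",
]


class PathwayParseError(ValueError):
    """Raised for malformed prior files."""


# --------------------------------------------------------------------- parsing
def parse_gmt(path) -> set[tuple[str, str]]:
    """Parse a GMT gene-set file into deduplicated ``(gene, set)`` pairs.

    Each line must have at least three tab-separated fields:
    set name, description, then one or more member genes.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise PathwayParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3 "
                    "(name, description, genes...)"
                )
            name = fields[0].strip()
            for gene in fields[2:]:
                gene = gene.strip()
                if gene:
                    pairs.add((gene, name))
    if n_lines == 0:
        raise PathwayParseError(f"{path}: empty GMT file")
    return pairs


def parse_relations(path) -> set[tuple[str, str]]:
    """Parse a two-column child/parent TSV into deduplicated relation pairs.

    Self-loops and rows with a column count other than two are rejected.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise PathwayParseError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 2"
                )
            child, parent = (f.strip() for f in fields)
            if child == parent:
                raise PathwayParseError(
                    f"{path}: line {lineno} is a self-loop ({child} -> {parent})"
                )
            pairs.add((child, parent))
    return pairs


# ------------------------------------------------------------------- hierarchy
@dataclass(frozen=True)
class PathwayHierarchy:
    """Layered gene -> pathway -> super-pathway graph.

    ``levels`` is ordered from leaf pathways (index 0) up to top-level
    pathways (last index); every level list is lexicographically sorted.
    ``relations`` is the raw child->parent DAG (it may skip levels; mask
    construction composes reachability).
    """

    gene_ids: tuple[str, ...]
    levels: tuple[tuple[str, ...], ...]
    gene_membership: frozenset[tuple[str, str]]
    relations: frozenset[tuple[str, str]]
    orphan_nodes: tuple[str, ...] = ()

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def top_level(self) -> tuple[str, ...]:
        return self.levels[-1]

    def node_level(self, node: str) -> int:
        for k, level in enumerate(self.levels):
            if node in level:
                return k
        raise KeyError(node)

    def top_ancestors(self, node: str) -> tuple[str, ...]:
        """Top-level pathway(s) reachable from ``node`` via child->parent links."""
        top = set(self.top_level)
        if node in top:
            return (node,)
        graph = nx.DiGraph()
        graph.add_edges_from(self.relations)
        if node not in graph:
            raise KeyError(node)
        return tuple(sorted(nx.descendants(graph, node) & top))


def build_hierarchy(
    membership: set[tuple[str, str]],
    relations: set[tuple[str, str]],
    n_levels: int,
) -> PathwayHierarchy:
    """Assign pathway nodes to levels by longest path to a root.

    Roots (nodes with no parent) form the top level; a node whose longest
    child->parent path to any root has length ``d`` sits ``d`` levels below
    the top.  Nodes deeper than ``n_levels`` are dropped with a warning.
    Leaf-level nodes without member genes are flagged as orphans but kept.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")

    genes = sorted({g for g, _ in membership})
    member_sets = {p for _, p in membership}
    nodes = member_sets | {n for rel in relations for n in rel}

    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(relations)  # child -> parent
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"pathway relations contain a cycle: {cycle}")

    in_closure = member_sets | {
        p for g, leaf in membership if leaf in graph for p in nx.descendants(graph, leaf)
    }
    stray = sorted(nodes - in_closure)
    if stray:
        warnings.warn(
            f"{len(stray)} pathway node(s) have no gene membership below them "
            f"(kept): {stray[:5]}{'...' if len(stray) > 5 else ''}",
            stacklevel=2,
        )

    roots = [n for n in nodes if graph.out_degree(n) == 0]
    # depth = longest path (in edges) from node up to any root
    depth: dict[str, int] = {}
    for node in nx.topological_sort(graph.reverse(copy=True)):  # parents first
        parents = list(graph.successors(node))
        depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)

    dropped = sorted(n for n, d in depth.items() if d >= n_levels)
    if dropped:
        logger.warning(
            "dropping %d node(s) deeper than %d levels: %s",
            len(dropped), n_levels, dropped[:10],
        )
    levels: list[tuple[str, ...]] = []
    for k in range(n_levels):  # k=0 is the leaf level
        d = n_levels - 1 - k
        levels.append(tuple(sorted(n for n in nodes if depth[n] == d)))
    assert set(levels[-1]) == set(roots) - set(dropped) or set(levels[-1]) == set(roots)

    kept = {n for level in levels for n in level}
    kept_membership = frozenset((g, p) for g, p in membership if p in kept)
    kept_genes = tuple(sorted({g for g, _ in kept_membership}))
    orphans = tuple(sorted(
        n for n in levels[0] if n not in {p for _, p in kept_membership}
    ))
    return PathwayHierarchy(
        gene_ids=kept_genes,
        levels=tuple(levels),
        gene_membership=kept_membership,
        relations=frozenset((c, p) for c, p in relations if c in kept and p in kept),
        orphan_nodes=orphans,
    )


# ----------------------------------------------------------------------- masks
@dataclass
class MaskStack:
    """Ordered binary connectivity matrices for one encoder variant.

    ``masks[0]`` maps genes to the first pathway layer; the last mask's
    output dimension is the top-level pathway count.  ``layer_node_ids``
    holds the output node labels of each mask for traceability.
    """

    masks: list[np.ndarray]
    variant: str
    gene_ids: tuple[str, ...]
    layer_node_ids: list[tuple[str, ...]]
    zero_row_genes: tuple[str, ...] = ()
    pruned_nodes: tuple[str, ...] = ()

    def __post_init__(self):
        for ell, (a, b) in enumerate(zip(self.masks[:-1], self.masks[1:])):
            if a.shape[1] != b.shape[0]:
                raise ValueError(
                    f"mask {ell} output dim {a.shape[1]} != mask {ell + 1} input dim {b.shape[0]}"
                )
        for ell, m in enumerate(self.masks):
            if not np.isin(m, (0.0, 1.0)).all():
                raise ValueError(f"mask {ell} has non-binary entries")

    @property
    def pathway_dim(self) -> int:
        return self.masks[-1].shape[1]

    @property
    def top_node_ids(self) -> tuple[str, ...]:
        return self.layer_node_ids[-1]

    def gene_to_top(self) -> np.ndarray:
        """Boolean gene x top-pathway reachability matrix (membership A)."""
        reach = self.masks[0].astype(bool)
        for m in self.masks[1:]:
            reach = reach @ m.astype(bool)
        return reach.astype(np.float64) > 0

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.variant.encode())
        for m in self.masks:
            h.update(np.ascontiguousarray(m, dtype=np.uint8).tobytes())
            h.update(repr(m.shape).encode())
        return h.hexdigest()


def _reachability(graph: nx.DiGraph, sources, targets) -> np.ndarray:
    """Binary matrix: 1 iff any child->parent path links source to target."""
    t_index = {t: j for j, t in enumerate(targets)}
    out = np.zeros((len(sources), len(targets)))
    for i, s in enumerate(sources):
        reachable = nx.descendants(graph, s) | {s}
        for t in reachable:
            j = t_index.get(t)
            if j is not None:
                out[i, j] = 1.0
    return out


def build_masks(hierarchy: PathwayHierarchy, variant: str) -> MaskStack:
    """Build the binary mask stack for a depth variant.

    ``3F``: genes -> leaf level -> top level (two masks; skipped levels
    collapsed by reachability).  ``5X``: one mask per consecutive level
    pair of the full hierarchy, requiring at least three pathway levels.
    Nodes unreachable from any gene are pruned with a warning; genes not
    assignable to any retained leaf node get an all-zero mask row, which
    is reported via ``zero_row_genes``.
    """
    if variant not in ("3F", "5X"):
        raise ValueError(f"unknown variant {variant!r}, expected '3F' or '5X'")
    if variant == "5X" and hierarchy.n_levels < 3:
        raise ValueError(
            f"5X needs a hierarchy with >= 3 pathway levels, got {hierarchy.n_levels}; "
            "use 3F for shallow hierarchies"
        )

    graph = nx.DiGraph()
    for level in hierarchy.levels:
        graph.add_nodes_from(level)
    graph.add_edges_from(hierarchy.relations)

    genes = hierarchy.gene_ids
    leaf_of_gene: dict[str, set[str]] = {}
    for g, p in hierarchy.gene_membership:
        leaf_of_gene.setdefault(g, set()).add(p)

    if variant == "3F":
        level_ids = [hierarchy.levels[0], hierarchy.levels[-1]]
    else:
        level_ids = list(hierarchy.levels)

    # gene -> first pathway layer: direct membership into that layer, or
    # membership to a node below it with an upward path into the layer
    first = level_ids[0]
    first_index = {p: j for j, p in enumerate(first)}
    m0 = np.zeros((len(genes), len(first)))
    for i, g in enumerate(genes):
        for p in leaf_of_gene.get(g, ()):
            j = first_index.get(p)
            if j is not None:
                m0[i, j] = 1.0
            elif p in graph:
                for anc in nx.descendants(graph, p):
                    j = first_index.get(anc)
                    if j is not None:
                        m0[i, j] = 1.0
    masks = [m0]
    for lower, upper in zip(level_ids[:-1], level_ids[1:]):
        masks.append(_reachability(graph, lower, upper))

    # prune nodes with no path from any gene (dead, untrainable columns)
    pruned: list[str] = []
    kept_ids: list[tuple[str, ...]] = []
    support = None
    new_masks: list[np.ndarray] = []
    for ell, m in enumerate(masks):
        support = m.astype(bool) if support is None else support @ m.astype(bool)
        keep = support.any(axis=0)
        labels = level_ids[ell]
        pruned.extend(lab for lab, k in zip(labels, keep) if not k)
        kept_ids.append(tuple(lab for lab, k in zip(labels, keep) if k))
        new_masks.append(m[:, keep])
        support = support[:, keep]
        # restrict the next mask's input rows to kept columns
        if ell + 1 < len(masks):
            masks[ell + 1] = masks[ell + 1][keep, :]
    if pruned:
        warnings.warn(
            f"pruned {len(pruned)} pathway node(s) unreachable from any gene: "
            f"{sorted(pruned)[:5]}{'...' if len(pruned) > 5 else ''}",
            stacklevel=2,
        )
    if new_masks[-1].shape[1] == 0:
        raise ValueError("no top-level pathway is reachable from any gene")

    zero_rows = tuple(
        g for g, row in zip(genes, new_masks[0].sum(axis=1)) if row == 0
    )
    if zero_rows:
        logger.warning(
            "%d gene(s) have no prior-supported connection (all-zero mask row): %s",
            len(zero_rows), list(zero_rows)[:10],
        )
    return MaskStack(
        masks=new_masks,
        variant=variant,
        gene_ids=genes,
        layer_node_ids=kept_ids,
        zero_row_genes=zero_rows,
        pruned_nodes=tuple(sorted(pruned)),
    )
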
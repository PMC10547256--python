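"""Phylogenetically corrected copy-number correlation.

Family-representative subsampling, raw Spearman correlation of
log-transformed counts, and Felsenstein's independent contrasts with a
positivization convention for rank correlation on contrast pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .census import DomainCensusRow
from .stats import TestResult, spearman_rho

__all__ = [
    "ContrastSet",
    "select_family_representatives",
    "independent_contrasts",
    "correlate_traits",
]


@dataclass
class ContrastSet:
    contrasts: np.ndarray  # (n_tips-1,) standardized contrasts
    variances: np.ndarray  # the standardizing variances v_i + v_j
    node_ids: list  # stable internal-node identifiers (sorted tip labels)


def select_family_representatives(
    rows: Sequence[DomainCensusRow],
) -> list[DomainCensusRow]:
    """One row per taxonomic family: the largest scaffold N50 wins, ties go
    to the lexicographically smallest assembly id."""
    best: dict[str, DomainCensusRow] = {}
    for row in rows:
        cur = best.get(row.family)
        if (
            cur is None
            or row.scaffold_n50 > cur.scaffold_n50
            or (row.scaffold_n50 == cur.scaffold_n50 and row.assembly_id < cur.assembly_id)
        ):
            best[row.family] = row
    return [best[f] for f in sorted(best)]


def _resolve_polytomies(tree: dendropy.Tree, epsilon: float) -> None:
    # arbitrary but deterministic resolution: sorted-label order, zero-length
    # internal branches, then epsilon added to zero branches
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            children = sorted(
                node.child_nodes(), key=lambda c: min(_tip_labels(c))
            )
            a, b = children[0], children[1]
            for c in (a, b):
                node.remove_child(c)
            merged = dendropy.Node(edge_length=0.0)
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if not edge.length or edge.length <= 0:
            edge.length = epsilon


def _tip_labels(node) -> list[str]:
    return sorted(l.taxon.label for l in node.leaf_iter())


def independent_contrasts(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    pseudocount: float = 1.0,
    log_base: float = 10.0,
    log_transform: bool = True,
) -> ContrastSet:
    """Felsenstein's pruning contrasts of (optionally) log(count+pseudocount).

    At each internal node joining children with adjusted branch lengths
    v_i, v_j the standardized contrast is (x_i - x_j)/sqrt(v_i + v_j), the
    ancestral value the precision-weighted mean, and the parent branch is
    lengthened by v_i v_j / (v_i + v_j).
    """
    tree = tree.clone(depth=1)
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in trait]
    if missing:
        raise ValueError(f"tips without trait values: {sorted(missing)}")
    depth = max(tree.calc_node_root_distances(return_leaf_distances_only=True))
    epsilon = 1e-8 * (depth if depth > 0 else 1.0)
    _resolve_polytomies(tree, epsilon)

    def transform(v: float) -> float:
        if not log_transform:
            return float(v)
        return math.log(v + pseudocount) / math.log(log_base)

    xs: dict = {}
    vs: dict = {}
    contrasts: list[float] = []
    variances: list[float] = []
    node_ids: list = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            xs[node] = transform(trait[node.taxon.label])
            vs[node] = max(node.edge.length or 0.0, epsilon)
        else:
            ci, cj = node.child_nodes()
            vi, vj = vs[ci], vs[cj]
            # orient each contrast deterministically by sorted tip labels
            li, lj = _tip_labels(ci)[0], _tip_labels(cj)[0]
            if lj < li:
                ci, cj, vi, vj = cj, ci, vj, vi
            c = (xs[ci] - xs[cj]) / math.sqrt(vi + vj)
            contrasts.append(c)
            variances.append(vi + vj)
            node_ids.append((_tip_labels(ci)[0], _tip_labels(cj)[0]))
            xs[node] = (xs[ci] / vi + xs[cj] / vj) / (1.0 / vi + 1.0 / vj)
            base = node.edge.length or 0.0
            if node is tree.seed_node:
                base = 0.0
            vs[node] = max(base, 0.0 if node is tree.seed_node else epsilon) + (
                vi * vj / (vi + vj)
            )
    return ContrastSet(
        contrasts=np.array(contrasts),
        variances=np.array(variances),
        node_ids=node_ids,
    )


def correlate_traits(
    x: Mapping[str, float],
    y: Mapping[str, float],
    tree: dendropy.Tree | None = None,
    method: str = "raw",
    positivize: bool = True,
    log_transform: bool = True,
) -> tuple[TestResult, int]:
    """Spearman correlation of two traits, raw or on independent contrasts.

    Raw: rho of log10(value+1) across species.  PIC: contrasts of each trait
    on the same tree, each pair's sign flipped so the x-contrast is
    non-negative (positivization), then Spearman.  Returns (result, n_points).
    """
    if set(x) != set(y):
        raise ValueError("x and y must cover the same species")
    if method == "raw":
        species = sorted(x)
        if log_transform:
            xv = [math.log10(x[s] + 1.0) for s in species]
            yv = [math.log10(y[s] + 1.0) for s in species]
        else:
            xv = [x[s] for s in species]
            yv = [y[s] for s in species]
        return spearman_rho(xv, yv), len(species)
    if method != "pic":
        raise ValueError("method must be 'raw' or 'pic'")
    if tree is None:
        raise ValueError("method='pic' requires a tree")
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    if tips != set(x):
        diff = tips.symmetric_difference(set(x))
        raise ValueError(f"tree tips and trait species differ: {sorted(diff)}")
    cx = independent_contrasts(tree, x, log_transform=log_transform)
    cy = independent_contrasts(tree, y, log_transform=log_transform)
    a, b = cx.contrasts.copy(), cy.contrasts.copy()
    if positivize:
        flip = a < 0
        a[flip] *= -1
        b[flip] *= -1
    return spearman_rho(a, b), a.size
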
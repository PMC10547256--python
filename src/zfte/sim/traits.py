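"""Yule trees with bivariate Brownian traits at the tips.

Used to test phylogenetically independent contrasts: two traits (think
log ZNF count and log retroelement count) evolve by correlated Brownian
motion from the root to the tips of a random birth tree scaled to unit
depth.  A pectinate ("caterpillar") topology option provides the strongly
imbalanced case where naive cross-species correlation is anticonservative.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

__all__ = ["simulate_trait_tree"]


def _yule_newick(n_taxa: int, rng: np.random.Generator) -> str:
    # forward-time pure-birth process; node = [birth_time, children or label]
    next_tip = [1]

    class _N:
        __slots__ = ("birth", "death", "children", "label")

        def __init__(self, birth):
            self.birth = birth
            self.death = None
            self.children = []
            self.label = None

    root = _N(0.0)
    a, b = _N(0.0), _N(0.0)
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(0, len(active)))
        node = active.pop(idx)
        node.death = t
        c1, c2 = _N(t), _N(t)
        node.children = [c1, c2]
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / n_taxa)
    for leaf in active:
        leaf.death = t_end
        leaf.label = f"t{next_tip[0]}"
        next_tip[0] += 1
    scale = 1.0 / t_end

    def render(node) -> str:
        bl = (node.death - node.birth) * scale
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{bl:.10f}"
        return f"{node.label}:{bl:.10f}"

    inner = ",".join(render(c) for c in root.children)
    return f"({inner});"


def _caterpillar_newick(n_taxa: int) -> str:
    # pectinate tree with unit branches: deep shared history between
    # successive tips, the classic inflation case for raw correlations
    s = "(t1:1.0,t2:1.0)"
    for i in range(3, n_taxa + 1):
        s = f"({s}:1.0,t{i}:1.0)"
    return s + ";"


def simulate_trait_tree(
    n_taxa: int,
    rho: float,
    sigma2: float = 1.0,
    seed: int = 0,
    shape: str = "yule",
):
    """Simulate a tree and correlated Brownian tip traits.

    Returns ``(tree, traits)`` where ``tree`` is a rooted dendropy tree with
    branch lengths and ``traits`` maps each tip label to a pair
    ``(trait_x, trait_y)``; the traits are already on the (log) scale the
    contrasts operate on.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    if shape == "yule":
        newick = _yule_newick(n_taxa, rng)
    elif shape == "caterpillar":
        newick = _caterpillar_newick(n_taxa)
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    cross = rho
    ortho = math.sqrt(max(0.0, 1.0 - rho * rho))
    values: dict = {tree.seed_node: (0.0, 0.0)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        px, py = values[node.parent_node]
        bl = node.edge.length or 0.0
        sd = math.sqrt(sigma2 * bl)
        z1, z2 = rng.standard_normal(2)
        values[node] = (px + sd * z1, py + sd * (cross * z1 + ortho * z2))
    traits = {
        leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()
    }
    return tree, traits
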
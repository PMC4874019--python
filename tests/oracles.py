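"""Independent reference implementations used by the test suite only.

These deliberately avoid the package's tree structure: trees are re-read
with dendropy and walked with its own MRCA/patristic machinery, so any
agreement with the package is a genuine cross-check.
"""
from __future__ import annotations

import itertools

import dendropy
import numpy as np


def enumerate_reachable_pairsets(
    newick: str, temps: dict[str, float], threshold: float
) -> set[frozenset[frozenset[str]]]:
    """All pair sets the sampling rule can terminate with, by exhaustion.

    State space: (blocked tip set, accepted pairs). From each state every
    unblocked focal tip is tried; a focal with admissible partners
    branches over all minimal-distance partners (tie branches), a focal
    without any is blocked alone. Terminal states (no unblocked tips)
    contribute their accepted pairings.
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.suppress_unifurcations()
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lbl: lf.taxon for lbl, lf in leaves.items()}

    def clade_tips(node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def moves(focal: str, blocked: frozenset[str], used: frozenset[str]):
        parent = leaves[focal].parent_node
        if parent is None:
            return [], frozenset()
        clade = clade_tips(parent)
        if clade & used:
            # pairing here would nest around an earlier sampled clade
            return [], clade
        cands = [
            c
            for c in clade - {focal} - blocked
            if abs(temps[c] - temps[focal]) >= threshold
        ]
        if not cands:
            return [], clade
        dists = {
            c: pdm.patristic_distance(taxa[focal], taxa[c]) for c in cands
        }
        dmin = min(dists.values())
        return [c for c in cands if dists[c] == dmin], clade

    all_tips = frozenset(leaves)
    results: set[frozenset[frozenset[str]]] = set()
    seen: set[tuple] = set()

    def step(
        blocked: frozenset[str],
        used: frozenset[str],
        acc: frozenset[frozenset[str]],
    ):
        key = (blocked, acc)  # `used` is a function of acc
        if key in seen:
            return
        seen.add(key)
        open_tips = all_tips - blocked
        if not open_tips:
            results.add(acc)
            return
        for focal in open_tips:
            partners, clade = moves(focal, blocked, used)
            if not partners:
                step(blocked | {focal}, used, acc)
            else:
                for p in partners:
                    step(
                        blocked | clade,
                        used | clade,
                        acc | {frozenset((focal, p))},
                    )

    step(frozenset(), frozenset(), frozenset())
    return results


def all_binary_shapes(n: int):
    """All rooted binary tree shapes with n leaves, as nested tuples."""
    if n == 1:
        return [None]
    shapes = []
    seen = set()
    for i in range(1, n // 2 + 1):
        for left in all_binary_shapes(i):
            for right in all_binary_shapes(n - i):
                key = frozenset([(i, repr(left)), (n - i, repr(right))])
                tag = (i, repr(left), n - i, repr(right))
                mirror = (n - i, repr(right), i, repr(left))
                if mirror in seen:
                    continue
                seen.add(tag)
                shapes.append((left, right))
    return shapes


def shape_to_newick(shape, lengths) -> str:
    """Label leaves t1.. in traversal order; lengths drawn from an iterator."""
    counter = itertools.count(1)

    def rec(s) -> str:
        if s is None:
            return f"t{next(counter)}:{next(lengths)!r}"
        return f"({rec(s[0])},{rec(s[1])}):{next(lengths)!r}"

    left, right = shape
    return f"({rec(left)},{rec(right)});"


def max_pairs_by_enumeration(newick, temps, threshold) -> int:
    sets_ = enumerate_reachable_pairsets(newick, temps, threshold)
    return max((len(s) for s in sets_), default=0)
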
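"""Phylogenetic trees, trait tables, and the join between them.

Trees are read from Newick via dendropy and converted to a flat,
array-indexed structure (parent pointers, per-node edge lengths, cached
root-to-node depths and descendant-tip lists) so that the pair sampler can
ask for MRCAs, clade memberships and patristic distances many thousands of
times per analysis without touching object graphs.

Branch lengths are taken as given: substitutions per site for empirical
maximum-likelihood trees, arbitrary time units for simulated chronograms.
Unary (single-child) internal nodes are collapsed on construction, summing
their edge lengths, so every tip's parent is its smallest branching
ancestor.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "SpeciesPair",
    "JoinReport",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "read_traits",
    "validate_traits",
    "join_traits",
    "tip_paths_to_mrca",
    "normalize_name",
]


class NewickParseError(ValueError):
    """Raised when a Newick file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


def normalize_name(name: str) -> str:
    """Canonicalize a species name: trim and use ``_`` as the separator.

    Tree tip labels and trait-table species ids frequently differ only in
    whitespace-vs-underscore convention; both sides are normalized before
    matching and no further reconciliation (synonymy etc.) is attempted.
    """
    return re.sub(r"\s+", "_", name.strip())


@dataclass(frozen=True)
class SpeciesPair:
    """One sampled sister pair with its branch lengths and trait values.

    ``bl_a``/``bl_b`` are the tip-to-MRCA path lengths, i.e. the amount of
    molecular evolution accumulated by each species since their common
    ancestor (equal elapsed time on both sides, so no calibration needed).
    """

    tip_a: str
    tip_b: str
    mrca: int
    bl_a: float
    bl_b: float
    temp_a: float
    temp_b: float
    abslat_a: float
    abslat_b: float


@dataclass(frozen=True)
class JoinReport:
    """Bookkeeping from :func:`join_traits`."""

    n_shared: int
    dropped_tips: tuple[str, ...]
    dropped_species: tuple[str, ...]


class PhyloTree:
    """Rooted tree with array-indexed nodes.

    Nodes are integers ``0..n_nodes-1`` in preorder (root first). Tips are
    nodes without children and carry a label; internal labels are ignored.
    """

    __slots__ = (
        "parent",
        "edge_length",
        "labels",
        "children",
        "root",
        "tip_nodes",
        "_label_to_node",
        "_depth",
        "_nlevel",
        "_desc_tips",
    )

    def __init__(
        self,
        parent: np.ndarray,
        edge_length: np.ndarray,
        labels: list[str | None],
    ):
        parent = np.asarray(parent, dtype=np.int64)
        edge_length = np.asarray(edge_length, dtype=float)
        n = parent.size
        if edge_length.size != n or len(labels) != n:
            raise TreeValidationError("parent/edge_length/labels size mismatch")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(parent[i])
            if p >= 0:
                children[p].append(i)
        self.parent = parent
        self.edge_length = edge_length
        self.children = tuple(tuple(c) for c in children)
        self.labels = list(labels)
        tip_nodes = [i for i in range(n) if not children[i]]
        self.tip_nodes = np.asarray(tip_nodes, dtype=np.int64)
        self._validate()
        self._label_to_node = {self.labels[i]: i for i in tip_nodes}
        self._depth: np.ndarray | None = None
        self._nlevel: np.ndarray | None = None
        self._desc_tips: list[np.ndarray] | None = None

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_components(
        cls,
        parent: np.ndarray,
        edge_length: np.ndarray,
        labels: list[str | None],
    ) -> "PhyloTree":
        """Build a tree, collapsing unary internal nodes (lengths summed)."""
        parent, edge_length, labels = _collapse_unary(
            np.asarray(parent, dtype=np.int64),
            np.asarray(edge_length, dtype=float),
            list(labels),
        )
        return cls(parent, edge_length, labels)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        parent: list[int] = []
        lengths: list[float] = []
        labels: list[str | None] = []
        index: dict[int, int] = {}
        for node in dtree.preorder_node_iter():
            idx = len(parent)
            index[id(node)] = idx
            if node.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(node.parent_node)])
                if node.is_leaf() and node.edge.length is None:
                    raise TreeValidationError(
                        "tip without an edge length is not acceptable input"
                    )
                lengths.append(float(node.edge.length or 0.0))
            if node.is_leaf():
                if node.taxon is not None:
                    labels.append(normalize_name(node.taxon.label))
                elif node.label is not None:
                    labels.append(normalize_name(node.label))
                else:
                    raise TreeValidationError("unlabelled tip")
            else:
                labels.append(None)
        return cls.from_components(
            np.asarray(parent), np.asarray(lengths), labels
        )

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Read a single Newick tree from a file path."""
        try:
            dtree = dendropy.Tree.get(
                path=str(source),
                schema="newick",
                suppress_internal_node_taxa=True,
                suppress_leaf_node_taxa=True,
                preserve_underscores=True,
            )
        except (dendropy.utility.error.DataParseError, ValueError) as exc:
            raise NewickParseError(f"cannot parse {source}: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                suppress_leaf_node_taxa=True,
                preserve_underscores=True,
            )
        except (dendropy.utility.error.DataParseError, ValueError) as exc:
            raise NewickParseError(f"cannot parse newick string: {exc}") from exc
        return cls.from_dendropy(dtree)

    def _validate(self) -> None:
        if np.any(self.edge_length < 0):
            raise TreeValidationError("negative edge length")
        if not np.all(np.isfinite(self.edge_length)):
            raise TreeValidationError("non-finite edge length")
        tip_labels = [self.labels[i] for i in self.tip_nodes]
        if any(lbl is None for lbl in tip_labels):
            raise TreeValidationError("unlabelled tip")
        seen: set[str] = set()
        for lbl in tip_labels:
            if lbl in seen:
                raise TreeValidationError(f"duplicate tip label: {lbl!r}")
            seen.add(lbl)
        # reachability: every node must descend from the root
        order = self.preorder()
        if order.size != self.parent.size:
            raise TreeValidationError("nodes unreachable from the root")

    # ------------------------------------------------------------------ #
    # basic queries

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_nodes.size

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_nodes]

    def node_of(self, label: str) -> int:
        try:
            return self._label_to_node[normalize_name(label)]
        except KeyError:
            raise KeyError(f"tip label {label!r} not in tree") from None

    def preorder(self) -> np.ndarray:
        out = [self.root]
        stack = list(self.children[self.root])[::-1]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return np.asarray(out, dtype=np.int64)

    @property
    def depth(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        if self._depth is None:
            d = np.zeros(self.n_nodes)
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.edge_length[v]
            self._depth = d
        return self._depth

    @property
    def _level(self) -> np.ndarray:
        if self._nlevel is None:
            lv = np.zeros(self.n_nodes, dtype=np.int64)
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    lv[v] = lv[p] + 1
            self._nlevel = lv
        return self._nlevel

    def desc_tips(self, node: int) -> np.ndarray:
        """Tip nodes of the clade subtended by ``node`` (node itself if a tip)."""
        if self._desc_tips is None:
            acc: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for v in self.preorder()[::-1]:
                if not self.children[v]:
                    acc[v].append(v)
                p = self.parent[v]
                if p >= 0:
                    acc[p].extend(acc[v])
            self._desc_tips = [np.asarray(a, dtype=np.int64) for a in acc]
        return self._desc_tips[node]

    def mrca(self, u: int, v: int) -> int:
        lv = self._level
        while lv[u] > lv[v]:
            u = int(self.parent[u])
        while lv[v] > lv[u]:
            v = int(self.parent[v])
        while u != v:
            u = int(self.parent[u])
            v = int(self.parent[v])
        return u

    def patristic(self, u: int, v: int) -> float:
        d = self.depth
        a = self.mrca(u, v)
        return float(d[u] + d[v] - 2 * d[a])

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depth[self.tip_nodes]
        return bool(d.max() - d.min() <= tol)

    # ------------------------------------------------------------------ #
    # editing / IO

    def prune_to(self, keep_labels) -> "PhyloTree":
        """Restrict to the given tip labels, preserving path lengths.

        Collapsed unbranched internal nodes sum their edge lengths, so the
        patristic distance between any two retained tips is unchanged.
        """
        keep = {normalize_name(k) for k in keep_labels}
        keep_nodes = [self.node_of(k) for k in keep]
        if not keep_nodes:
            raise TreeValidationError("cannot prune to an empty tip set")
        keep_mask = np.zeros(self.n_nodes, dtype=bool)
        for t in keep_nodes:
            v = t
            while v >= 0 and not keep_mask[v]:
                keep_mask[v] = True
                v = int(self.parent[v])
        order = self.preorder()
        new_index = np.full(self.n_nodes, -1, dtype=np.int64)
        parent: list[int] = []
        lengths: list[float] = []
        labels: list[str | None] = []
        for v in order:
            if not keep_mask[v]:
                continue
            idx = len(parent)
            new_index[v] = idx
            p = int(self.parent[v])
            parent.append(int(new_index[p]) if p >= 0 else -1)
            lengths.append(float(self.edge_length[v]))
            labels.append(self.labels[v])
        return PhyloTree.from_components(
            np.asarray(parent), np.asarray(lengths), labels
        )

    def with_edge_lengths(self, edge_length: np.ndarray) -> "PhyloTree":
        """Same topology with replacement edge lengths (no unary collapse)."""
        return PhyloTree(self.parent.copy(), np.asarray(edge_length, float), list(self.labels))

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                body = self.labels[v]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return f"{body};"
            return f"{body}:{float(self.edge_length[v])!r}"

        return rec(self.root)

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


def _collapse_unary(
    parent: np.ndarray, edge_length: np.ndarray, labels: list[str | None]
):
    """Remove single-child internal nodes, summing edge lengths through them.

    A unary root is also removed (its surviving child becomes the root).
    """
    n = parent.size
    nchild = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if parent[i] >= 0:
            nchild[parent[i]] += 1
    is_tip = nchild == 0
    drop = (~is_tip) & (nchild == 1)
    if not drop.any():
        return parent, edge_length, labels
    new_parent = parent.copy()
    new_length = edge_length.copy()
    # preorder guarantees parents precede children in the original arrays
    # only when input is preordered; resolve chains iteratively instead.
    for i in range(n):
        if drop[i] or parent[i] < 0:
            continue
        p = int(new_parent[i])
        acc = float(new_length[i])
        while p >= 0 and drop[p]:
            acc += float(new_length[p])
            p = int(new_parent[p])
        new_parent[i] = p
        new_length[i] = acc
    keep = ~drop
    # a dropped unary root leaves its child with parent -1 via the loop above
    new_index = np.full(n, -1, dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))
    out_parent = np.asarray(
        [int(new_index[p]) if p >= 0 else -1 for p in new_parent[keep]],
        dtype=np.int64,
    )
    out_length = new_length[keep]
    out_length_root = out_parent < 0
    out_length = np.where(out_length_root, 0.0, out_length)
    out_labels = [labels[i] for i in range(n) if keep[i]]
    return out_parent, out_length, out_labels


# ---------------------------------------------------------------------- #
# module-level operations


def read_newick(path: str | Path) -> PhyloTree:
    """Read one Newick tree with branch lengths; see :class:`PhyloTree`."""
    return PhyloTree.from_newick(path)


def validate_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a trait table.

    Expects columns ``species_id``, ``temperature`` (°C mean annual) and
    ``latitude`` (signed decimal degrees); adds ``abs_latitude``. The
    returned frame is indexed by normalized species_id.
    """
    required = {"species_id", "temperature", "latitude"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    out = table.copy()
    out["species_id"] = out["species_id"].astype(str).map(normalize_name)
    if out["species_id"].duplicated().any():
        dups = out.loc[out["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species_id in trait table: {dups[:5]}")
    out["temperature"] = out["temperature"].astype(float)
    out["latitude"] = out["latitude"].astype(float)
    if not np.isfinite(out["temperature"]).all():
        raise ValueError("non-finite temperature in trait table")
    if (out["latitude"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    out["abs_latitude"] = out["latitude"].abs()
    return out.set_index("species_id")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a comma-separated trait table (species_id,temperature,latitude)."""
    return validate_traits(pd.read_csv(path))


def join_traits(
    tree: PhyloTree, traits: pd.DataFrame
) -> tuple[PhyloTree, pd.DataFrame, JoinReport]:
    """Intersect tree tips with trait species; prune both to the overlap."""
    tips = set(tree.tip_labels)
    species = set(traits.index)
    shared = tips & species
    if not shared:
        raise ValueError("no species shared between tree and trait table")
    dropped_tips = tuple(sorted(tips - species))
    dropped_species = tuple(sorted(species - tips))
    for name in dropped_tips:
        log.info("tip %s has no trait row; dropped", name)
    for name in dropped_species:
        log.info("species %s not in tree; dropped", name)
    pruned = tree.prune_to(shared) if dropped_tips else tree
    kept_traits = traits.loc[sorted(shared)]
    report = JoinReport(
        n_shared=len(shared),
        dropped_tips=dropped_tips,
        dropped_species=dropped_species,
    )
    return pruned, kept_traits, report


def tip_paths_to_mrca(
    tree: PhyloTree, tip_a: str, tip_b: str
) -> tuple[float, float, int]:
    """Path lengths from each tip to their MRCA, plus the MRCA node id."""
    u = tree.node_of(tip_a)
    v = tree.node_of(tip_b)
    a = tree.mrca(u, v)
    d = tree.depth
    return float(d[u] - d[a]), float(d[v] - d[a]), a
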
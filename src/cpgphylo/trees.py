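"""Distance matrices, UPGMA under a molecular clock, calibration, Newick I/O
and tree comparison.

Trees are rooted, binary, ultrametric: every node carries a height (leaves
at 0, root highest), so node heights read directly as relative divergence
times; :func:`calibrate` rescales them to absolute time (Ma) against a
species pair of known divergence. Branch lengths in Newick output are
parent height minus child height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .seqio import Msa
from .recode import RecodedMatrix


@dataclass
class Node:
    height: float
    label: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class ClockTree:
    """A rooted ultrametric tree with node heights; optionally calibrated
    (``time_scale`` = Ma per original height unit)."""

    root: Node
    time_scale: float | None = None

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def _find_path(self, label: str) -> list[Node]:
        def walk(node: Node, path: list[Node]) -> list[Node] | None:
            path = path + [node]
            if node.is_leaf:
                return path if node.label == label else None
            for c in node.children:
                got = walk(c, path)
                if got:
                    return got
            return None

        got = walk(self.root, [])
        if got is None:
            raise KeyError(f"leaf {label!r} not in tree")
        return got

    def mrca(self, a: str, b: str) -> Node:
        pa, pb = self._find_path(a), self._find_path(b)
        mrca = self.root
        for x, y in zip(pa, pb):
            if x is y:
                mrca = x
            else:
                break
        return mrca

    def max_height_spread(self) -> float:
        """Max difference between root-to-leaf path heights (0 if ultrametric)."""
        depths = []

        def walk(node: Node, d: float) -> None:
            if node.is_leaf:
                depths.append(d + node.height)
            for c in node.children:
                walk(c, d + (node.height - c.height))

        walk(self.root, 0.0)
        return max(depths) - min(depths)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    units: str = "substitutions-per-site"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for sid, row in zip(self.ids, self.d):
            lines.append(sid + "\t" + "\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class PercentIdentityMatrix:
    ids: list[str]
    pid: np.ndarray

    def __post_init__(self) -> None:
        self.pid = np.asarray(self.pid, dtype=float)
        if np.any(np.diag(self.pid) != 100.0):
            raise ValueError("diagonal must be exactly 100")

    def get(self, a: str, b: str) -> float:
        return float(self.pid[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for sid, row in zip(self.ids, self.pid):
            lines.append(sid + "\t" + "\t".join(f"{v:.2f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def percent_identity(msa: Msa) -> PercentIdentityMatrix:
    """Clustal-style percent identity: 100 × matches / co-ungapped columns;
    columns where either row has a gap are dropped from both numerator and
    denominator."""
    n = len(msa.ids)
    pid = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            comp = match = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                comp += 1
                match += x == y
            if comp == 0:
                raise ValueError(
                    f"no co-ungapped columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            pid[i, j] = pid[j, i] = 100.0 * match / comp
    return PercentIdentityMatrix(ids=list(msa.ids), pid=pid)


def p_distance(rows: Msa | RecodedMatrix, count_indels: bool = False) -> DistanceMatrix:
    """Pairwise p-distance: mismatches over comparable positions.

    Missing symbols ('-' and, for nucleotide alignments, 'N') are excluded.
    With ``count_indels`` a gap aligned to a base counts as one mismatch
    (gap-vs-gap still excluded) — the scoring used for the all-changes tree.
    """
    if isinstance(rows, Msa):
        ids, seqs, missing = rows.ids, rows.rows, set("-N")
        units = "substitutions-per-site"
    else:
        ids, seqs, missing = rows.ids, rows.characters, {"-"}
        units = "character-mismatch fraction"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = mism = 0
            for x, y in zip(seqs[i], seqs[j]):
                xm, ym = x in missing, y in missing
                if xm and ym:
                    continue
                if xm or ym:
                    if count_indels and "-" in (x, y):
                        comp += 1
                        mism += 1
                    continue
                comp += 1
                mism += x != y
            if comp == 0:
                raise ValueError(f"no comparable positions between {ids[i]!r} and {ids[j]!r}")
            d[i, j] = d[j, i] = mism / comp
    return DistanceMatrix(ids=list(ids), d=d, units=units)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> ClockTree:
    """Average-linkage (UPGMA) clustering of a distance matrix into an
    ultrametric tree; the node merging clusters at distance d sits at
    height d/2. Ties are broken by the lexicographically smallest member
    label of the candidate pair."""
    if np.any(~np.isfinite(dm.d)) or np.any(dm.d < 0):
        raise ValueError("distances must be finite and non-negative")
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 taxa")

    # cluster key: sorted tuple of member labels
    clusters: dict[tuple[str, ...], Node] = {
        (sid,): Node(height=0.0, label=sid) for sid in dm.ids
    }
    sizes = {k: 1 for k in clusters}
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            dist[frozenset([(a,), (dm.ids[j],)])] = float(dm.d[i, j])

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        best_d = math.inf
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                dv = dist[frozenset([a, b])]
                cand_key = tuple(sorted((min(a), min(b))))
                if dv < best_d or (dv == best_d and cand_key < best[2]):
                    best, best_d = (a, b, cand_key), dv
        a, b, _ = best
        na, nb = sizes[a], sizes[b]
        new_key = tuple(sorted(a + b))
        node = Node(height=best_d / 2.0,
                    children=sorted([clusters[a], clusters[b]],
                                    key=lambda n: min(l.label for l in n.leaves())))
        for other in list(clusters):
            if other in (a, b):
                continue
            dv = (na * dist[frozenset([a, other])] + nb * dist[frozenset([b, other])]) / (na + nb)
            dist[frozenset([new_key, other])] = dv
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new_key] = node
        sizes[new_key] = na + nb

    (root,) = clusters.values()
    return ClockTree(root=root)


def calibrate(tree: ClockTree, pair: tuple[str, str], time_ma: float) -> ClockTree:
    """Rescale node heights so the MRCA of ``pair`` sits at ``time_ma``."""
    mrca = tree.mrca(*pair)
    if mrca.height <= 0:
        raise ValueError(
            f"MRCA of {pair} has height 0 (identical sequences); cannot calibrate"
        )
    scale = time_ma / mrca.height

    def copy(node: Node) -> Node:
        return Node(height=node.height * scale, label=node.label,
                    children=[copy(c) for c in node.children])

    return ClockTree(root=copy(tree.root), time_scale=scale)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def to_newick(tree: ClockTree) -> str:
    def fmt(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return core
        return f"{core}:{parent_height - node.height:.12g}"

    return fmt(tree.root, None) + ";"


def write_newick(tree: ClockTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(source: str | Path) -> ClockTree:
    """Parse a rooted Newick tree with branch lengths into a ClockTree.

    Node heights are reconstructed as the distance to the deepest
    descendant leaf (identical to the original heights for ultrametric
    trees). ``source`` may be a path or a Newick string.
    """
    text = str(source)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        dt = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(height=0.0, label=dnode.taxon.label.replace(" ", "_")
                        if dnode.taxon else dnode.label)
        children = [convert(c) for c in dnode.child_nodes()]
        height = max(
            c.height + (c_edge.length or 0.0)
            for c, c_edge in zip(children, [cn.edge for cn in dnode.child_nodes()])
        )
        return Node(height=height, children=children)

    return ClockTree(root=convert(dt.seed_node))


# ---------------------------------------------------------------------------
# Tree comparison
# ---------------------------------------------------------------------------

def _bipartitions(tree: ClockTree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as frozensets of two label-frozensets."""
    all_leaves = frozenset(tree.leaf_labels())
    splits: set[frozenset] = set()

    def walk(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        clade = frozenset().union(*(walk(c) for c in node.children))
        rest = all_leaves - clade
        if len(clade) >= 2 and len(rest) >= 2:
            splits.add(frozenset([clade, rest]))
        return clade

    walk(tree.root)
    return splits


def rf_distance(t1: ClockTree, t2: ClockTree) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(_bipartitions(t1) ^ _bipartitions(t2))
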
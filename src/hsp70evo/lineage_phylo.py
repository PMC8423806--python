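"""Desk-scale distance trees and clade assignment.

Published HSP70 phylogenies come from heavyweight Bayesian/ML inference; this
module instead provides the minimum needed to run the pipeline end-to-end and
to test it: protein distance matrices (p-distance or Poisson-corrected),
neighbor joining — exact on additive distances — and seeded clade assignment
on any tree (an NJ tree or one supplied as newick, e.g. a published
consensus tree).

Trees are :class:`dendropy.Tree` objects throughout, so newick IO, midpoint
rooting and Robinson–Foulds comparisons come from dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .seqio import GAP, MultipleAlignment


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal.

    ``missing`` lists pairs whose distance is undefined (Poisson correction
    domain exceeded); the matrix holds NaN there.
    """

    ids: list[str]
    matrix: np.ndarray
    missing: list[tuple[str, str]]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T), atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def protein_distance_matrix(aln: MultipleAlignment, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise protein distances over columns where both rows are ungapped.

    p-distance is the mismatch fraction; the Poisson model corrects it to
    ``-ln(1 - p)``, undefined at p = 1 (reported as missing).  A pair with no
    shared ungapped column is an error.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 rows")
    n = len(aln.ids)
    mat = np.zeros((n, n))
    missing: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = aln.rows[i], aln.rows[j]
            compared = mismatch = 0
            for a, b in zip(ri, rj):
                if a == GAP or b == GAP:
                    continue
                compared += 1
                if a != b:
                    mismatch += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            p = mismatch / compared
            if model == "p-distance":
                d = p
            elif p >= 1.0:
                d = float("nan")
                missing.append((aln.ids[i], aln.ids[j]))
            else:
                d = -math.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(aln.ids), mat, missing)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining (Saitou–Nei with the Studier–Keppler Q matrix).

    Exact on additive matrices.  Ties in Q are broken by the lexicographically
    smallest id pair, so the result is deterministic.  Negative estimated
    branch lengths are clamped to zero with the deficit transferred to the
    sister branch.  The returned tree is unrooted (trifurcating seed node).
    """
    if dm.missing:
        raise ValueError(f"distance matrix has missing entries: {dm.missing}")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    # active nodes keyed by a label used only for deterministic tie-breaks
    nodes: dict[str, dendropy.Node] = {}
    for rid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(rid))
        nodes[rid] = node
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.matrix[i, j])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    active = sorted(nodes)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_q, best_pair = None, None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if best_q is None or q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and pair < best_pair
                ):
                    best_q, best_pair = q, pair
        a, b = best_pair
        ba = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        bb = d(a, b) - ba
        if ba < 0:
            bb, ba = bb + ba, 0.0
        if bb < 0:
            ba, bb = ba + bb, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = ba
        parent.add_child(nodes[b])
        nodes[b].edge.length = bb
        new_label = f"({a},{b})"
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = sorted(set(active) - {a, b} | {new_label})

    a, b, c = active
    # three-point formulas for the final star
    ba = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    bb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    bc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = tree.seed_node
    for label, length in ((a, ba), (b, bb), (c, bc)):
        root.add_child(nodes[label])
        nodes[label].edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a copy of *tree* (used before clade extraction).

    Implemented by an explicit longest-path walk so that a midpoint falling
    exactly on an internal node (common for ultrametric trees) is handled
    gracefully as a zero-length root branch.
    """
    rooted = tree.clone(depth=1)
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for node in rooted.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))
    leaves = list(rooted.leaf_node_iter())
    if len(leaves) < 2:
        return rooted

    def distances(src):
        dist, prev, stack = {src: 0.0}, {src: None}, [src]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = (-1.0, None, None, None)
    for a in leaves:
        dist, prev = distances(a)
        for b in leaves:
            if dist[b] > best[0]:
                best = (dist[b], a, b, prev)
    diameter, a, b, prev = best
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()  # a .. b
    half, cum = diameter / 2.0, 0.0
    for u, v in zip(path, path[1:]):
        w = next(wt for (x, wt) in adj[u] if x is v)
        if cum + w >= half:
            edge = v.edge if v.parent_node is u else u.edge
            d_tail = cum if edge.tail_node is u else cum + w
            length1 = abs(half - d_tail)
            rooted.reroot_at_edge(edge, length1=length1, length2=w - length1,
                                  update_bipartitions=True)
            return rooted
        cum += w
    return rooted


def outgroup_root(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    rooted = tree.clone(depth=1)
    og = rooted.find_node_with_taxon_label(outgroup_id)
    if og is None:
        raise KeyError(f"outgroup {outgroup_id!r} not in tree")
    rooted.to_outgroup_position(og, update_bipartitions=True)
    return rooted


def assign_clades(tree: dendropy.Tree, seeds: Mapping[str, str]) -> dict[str, str]:
    """Propagate seed labels to all leaves via smallest pure clades.

    Each unlabeled leaf receives the label of the smallest clade (leafset
    under a node of the rooted tree) that contains it together with seeds of
    exactly one class; leaves whose every seed-containing clade mixes classes
    stay unassigned (absent from the result).  Root unrooted trees first,
    e.g. with :func:`midpoint_root`.  Seed labels are never overwritten and
    the operation is idempotent.
    """
    if not seeds:
        raise ValueError("no seed labels given")
    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for sid in seeds:
        if sid not in leaf_ids:
            raise KeyError(f"seed id {sid!r} not a leaf of the tree")

    sides: list[frozenset[str]] = [
        frozenset(lf.taxon.label for lf in node.leaf_iter())
        for node in tree.preorder_node_iter()
    ]
    sides = sorted(set(sides), key=lambda s: (len(s), sorted(s)))

    out: dict[str, str] = dict(seeds)
    for leaf in leaf_ids:
        if leaf in out:
            continue
        for side in sides:
            if leaf not in side:
                continue
            classes = {seeds[s] for s in side if s in seeds}
            if len(classes) == 1:
                out[leaf] = next(iter(classes))
                break
    return out


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted RF distance between two trees over the same leaf set."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=tree_a.as_string(schema="newick", unquoted_underscores=True),
                           schema="newick", taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=tree_b.as_string(schema="newick", unquoted_underscores=True),
                           schema="newick", taxon_namespace=tns, preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)
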
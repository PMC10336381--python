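"""Phylogeny container: Newick I/O, pruning, distances, bipartitions.

Trees are held as dendropy objects (one taxon namespace per tree) with a
thin wrapper adding the operations the pipeline needs: unit-length and
patristic distance matrices, bipartition sets for monophyly / Robinson-Foulds
work, per-edge support values, and midpoint rooting.
"""

from __future__ import annotations

import io
from collections import deque

import dendropy
import numpy as np


class Phylogeny:
    """A (possibly unrooted) tree over uniquely labelled tips.

    Branch lengths, when present, are in expected substitutions per site.
    Support values live on internal edges, parsed from Newick internal node
    labels; bracketed comments are ignored by the parser.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool | None = None):
        self.tree = tree
        if rooted is None:
            rooted = bool(tree.is_rooted)
        self.rooted = rooted
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        for e in tree.edges():
            if e.length is not None and e.length < 0:
                raise ValueError(f"negative branch length {e.length}")

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        if newick.count("(") != newick.count(")"):
            raise ValueError("unbalanced parentheses in Newick string")
        ns = dendropy.TaxonNamespace()
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                taxon_namespace=ns,
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as e:  # dendropy raises its own hierarchy
            raise ValueError(f"failed to parse Newick: {e}") from e
        rooted = cls._looks_rooted(tree, newick)
        return cls(tree, rooted=rooted)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @staticmethod
    def _looks_rooted(tree: dendropy.Tree, newick: str) -> bool:
        if "[&R]" in newick:
            return True
        if "[&U]" in newick:
            return False
        root = tree.seed_node
        return len(root.child_nodes()) == 2

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=False,
        )
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ basics
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), rooted=self.rooted)

    def prune_to(self, labels) -> "Phylogeny":
        """New tree restricted to ``labels`` (degree-2 nodes suppressed)."""
        wanted = set(labels)
        keep = [t for t in self.tree.taxon_namespace if t.label in wanted]
        sub = self.tree.extract_tree_with_taxa(taxa=keep)
        # the extracted tree shares the source namespace: migrate to a fresh
        # one so neither tree can mutate the other's taxon bookkeeping
        sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
        return Phylogeny(sub, rooted=self.rooted)

    def unrooted(self) -> "Phylogeny":
        """Collapse a bifurcating root so the tree is stored unrooted."""
        t = self.tree.clone(depth=1)
        if len(t.seed_node.child_nodes()) == 2:
            t.deroot()
        t.is_rooted = False
        return Phylogeny(t, rooted=False)

    # --------------------------------------------------------- adjacency
    def _adjacency(self):
        """(nodes, adj) with adj[u] = [(v, branch_length), ...]."""
        nodes = list(self.tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        adj: list[list[tuple[int, float]]] = [[] for _ in nodes]
        for n in nodes:
            p = n.parent_node
            if p is None:
                continue
            ln = n.edge.length if n.edge.length is not None else 1.0
            i, j = index[id(p)], index[id(n)]
            adj[i].append((j, ln))
            adj[j].append((i, ln))
        return nodes, adj

    def _distance_matrix(self, labels: list[str], unit: bool) -> np.ndarray:
        nodes, adj = self._adjacency()
        tip_row = {}
        for i, n in enumerate(nodes):
            if n.is_leaf():
                tip_row[n.taxon.label] = i
        missing = [t for t in labels if t not in tip_row]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        D = np.zeros((len(labels), len(labels)))
        for a, la in enumerate(labels):
            dist = np.full(len(nodes), np.nan)
            src = tip_row[la]
            dist[src] = 0.0
            dq = deque([src])
            while dq:
                u = dq.popleft()
                for v, ln in adj[u]:
                    if np.isnan(dist[v]):
                        dist[v] = dist[u] + (1.0 if unit else ln)
                        dq.append(v)
            for b, lb in enumerate(labels):
                D[a, b] = dist[tip_row[lb]]
        return D

    def topological_distances(self, labels: list[str]) -> np.ndarray:
        """Unit-branch-length path distances between the given tips."""
        return self._distance_matrix(labels, unit=True)

    def patristic_distances(self, labels: list[str] | None = None) -> np.ndarray:
        if labels is None:
            labels = sorted(self.tip_labels())
        return self._distance_matrix(labels, unit=False)

    # ------------------------------------------------------ bipartitions
    def bipartitions(self, nontrivial_only: bool = False) -> set[frozenset]:
        """Bipartitions as frozensets of tip labels (smaller-or-canonical side).

        Each internal edge splits the tips in two; the split is stored as the
        canonical side: the lexicographically smaller frozenset of the two.
        """
        all_tips = frozenset(self.tip_labels())
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            if nontrivial_only and (
                len(below) < 2 or len(all_tips - below) < 2
            ):
                continue
            side = min(below, all_tips - below, key=lambda s: (len(s), sorted(s)))
            if side and side != all_tips:
                out.add(side)
        return out

    def has_clade(self, members: frozenset) -> bool:
        """True iff ``members`` forms one side of some bipartition."""
        tips = frozenset(self.tip_labels())
        if not members or members == tips:
            return False
        side = min(members, tips - members, key=lambda s: (len(s), sorted(s)))
        return side in self.bipartitions()

    # ---------------------------------------------------------- supports
    def edge_supports(self) -> list[float]:
        """Support values read from internal node labels (non-root)."""
        vals = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            if node.label is not None:
                try:
                    vals.append(float(node.label))
                except ValueError:
                    pass
        return vals

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges())

    def internal_length(self) -> float:
        tot = 0.0
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            tot += node.edge.length or 0.0
        return tot

    # ------------------------------------------------------ midpoint root
    def midpoint_root_to_tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths under midpoint rooting.

        The midpoint is located directly (the point halfway along the
        longest tip-to-tip path); depths are returned in ``tip_labels()``
        order without materializing a rerooted tree.
        """
        nodes, adj = self._adjacency()
        tip_idx = [i for i, n in enumerate(nodes) if n.is_leaf()]

        def dists_from(src):
            dist = np.full(len(nodes), np.nan)
            prev = np.full(len(nodes), -1, dtype=int)
            dist[src] = 0.0
            dq = deque([src])
            while dq:
                u = dq.popleft()
                for v, ln in adj[u]:
                    if np.isnan(dist[v]):
                        dist[v] = dist[u] + ln
                        prev[v] = u
                        dq.append(v)
            return dist, prev

        d0, _ = dists_from(tip_idx[0])
        a = tip_idx[int(np.argmax(d0[tip_idx]))]
        da, prev = dists_from(a)
        b = tip_idx[int(np.argmax(da[tip_idx]))]
        diameter = da[b]
        # walk the a->b path to find the edge containing the midpoint
        path = [b]
        while path[-1] != a:
            path.append(prev[path[-1]])
        path.reverse()  # a ... b
        half = diameter / 2.0
        u = a
        for v in path[1:]:
            edge_len = da[v] - da[u]
            if da[v] >= half or v == b:
                break
            u = v
        x = half - da[u]  # distance from u into edge (u, v)
        edge_len = da[v] - da[u]
        du, _ = dists_from(u)
        dv, _ = dists_from(v)
        depths = np.minimum(
            x + du[tip_idx], (edge_len - x) + dv[tip_idx]
        )
        return depths


def robinson_foulds_similarity(t1: Phylogeny, t2: Phylogeny) -> float:
    """1 - normalized RF distance on the shared taxon set.

    Normalization is by the maximum possible RF for that tip count,
    2*(s-3) non-trivial splits for a pair of binary unrooted trees.
    Returns NaN when fewer than 4 taxa are shared.
    """
    shared = set(t1.tip_labels()) & set(t2.tip_labels())
    if len(shared) < 4:
        return float("nan")
    p1 = t1.prune_to(shared).unrooted()
    p2 = t2.prune_to(shared).unrooted()
    b1 = p1.bipartitions(nontrivial_only=True)
    b2 = p2.bipartitions(nontrivial_only=True)
    rf = len(b1 ^ b2)
    max_rf = 2 * (len(shared) - 3)
    if max_rf == 0:
        return 1.0
    return 1.0 - rf / max_rf
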
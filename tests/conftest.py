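"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take different computational routes from the
implementation: likelihoods by explicit enumeration of internal-state
assignments, quartet dissimilarities from bipartition membership, so that
agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from topodissect.alignment import AMINO_ACIDS, LocusAlignment
from topodissect.likelihood import PruningEngine
from topodissect.models import TransitionKernel
from topodissect.trees import Phylogeny


# ------------------------------------------------------------------ helpers

def random_binary_newick(labels, rng, bl_mean=0.1, with_lengths=True):
    """Random unrooted binary tree by successive joins."""
    nodes = [
        f"{t}:{rng.exponential(bl_mean):.6f}" if with_lengths else t
        for t in labels
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        bl = f":{rng.exponential(bl_mean):.6f}" if with_lengths else ""
        nodes.append(f"({a},{b}){bl}")
    return "(" + ",".join(nodes) + ");"


def random_alignment(taxa, n_sites, rng, p_missing=0.05):
    seqs = []
    for _ in taxa:
        chars = [AMINO_ACIDS[rng.integers(20)] for _ in range(n_sites)]
        for j in range(n_sites):
            if rng.random() < p_missing:
                chars[j] = "-" if rng.random() < 0.5 else "X"
        seqs.append("".join(chars))
    return LocusAlignment("rand", list(taxa), seqs)


def simulate_on_tree(tree: Phylogeny, model, n_sites, rng):
    """Minimal independent sequence simulator (no gamma) for oracle use."""
    kern = TransitionKernel(model)
    t = tree.tree
    root = t.seed_node
    states = {id(root): rng.choice(20, size=n_sites, p=model.frequencies)}
    for node in t.preorder_node_iter():
        if node is root:
            continue
        P = kern.probs(node.edge.length or 0.0)
        ps = states[id(node.parent_node)]
        cum = P.cumsum(axis=1)
        u = rng.random(n_sites)
        states[id(node)] = (cum[ps] < u[:, None]).sum(axis=1)
    taxa = [l.taxon.label for l in t.leaf_node_iter()]
    seqs = [
        "".join(AMINO_ACIDS[s] for s in states[id(l)])
        for l in t.leaf_node_iter()
    ]
    return LocusAlignment("sim", taxa, seqs)


# ------------------------------------------------------------------ oracles

def brute_force_site_lnl(aln: LocusAlignment, tree: Phylogeny, model):
    """Site log-likelihoods by explicit summation over every assignment of
    states to internal nodes (20^n_internal terms per rate category)."""
    eng = PruningEngine(aln, tree, model)
    ix = eng.index
    rates = model.category_rates()
    pi = model.frequencies
    internal = [i for i in ix.postorder if ix.tip_row[i] < 0]
    S = aln.n_sites
    per_cat = np.zeros((len(rates), S))
    for k, r in enumerate(rates):
        P = {i: eng.kernel.probs(ix.lengths[i], r) for i in ix.edges}
        total = np.zeros(S)
        for assign in itertools.product(range(20), repeat=len(internal)):
            st = dict(zip(internal, assign))
            term = np.full(S, pi[st[ix.root]])
            for i in ix.edges:
                p = ix.parent[i]
                if ix.tip_row[i] >= 0:
                    term = term * (
                        eng._tip_partial[i] * P[i][st[p]][None, :]
                    ).sum(axis=1)
                else:
                    term = term * P[i][st[p], st[i]]
            total += term
        per_cat[k] = total
    return logsumexp(np.log(per_cat), axis=0) - np.log(len(rates))


def bipartition_quartet_dissimilarity(t1: Phylogeny, t2: Phylogeny):
    """Quartet dissimilarity via the bipartition definition.

    A quartet ab|cd is induced by a tree iff some bipartition separates
    {a,b} from {c,d}.  Enumerate all four-taxon subsets of the shared tips
    and compare the induced resolutions.
    """
    shared = sorted(set(t1.tip_labels()) & set(t2.tip_labels()))
    if len(shared) < 4:
        return None

    def resolution(tree, quartet):
        tips = frozenset(tree.tip_labels())
        splits = tree.unrooted().bipartitions()
        full_splits = [(s, tips - s) for s in splits]
        a, b, c, d = quartet
        for pair in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
            (x1, x2), (y1, y2) = pair
            for s1, s2 in full_splits:
                if {x1, x2} <= s1 and {y1, y2} <= s2:
                    return pair
                if {x1, x2} <= s2 and {y1, y2} <= s1:
                    return pair
        return None

    p1 = t1.prune_to(shared)
    p2 = t2.prune_to(shared)
    n_both = n_diff = 0
    for quartet in itertools.combinations(shared, 4):
        r1 = resolution(p1, quartet)
        r2 = resolution(p2, quartet)
        if r1 is None or r2 is None:
            continue
        n_both += 1
        if r1 != r2:
            n_diff += 1
    if n_both == 0:
        return 0.0
    return n_diff / n_both


# ----------------------------------------------------------------- fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(20230988)


@pytest.fixture
def quartet_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_taxon_alignment():
    return LocusAlignment(
        "L5", list("ABCDE"), ["ARX", "AR-", "CRN", "CWN", "AWN"]
    )


@pytest.fixture
def five_taxon_tree():
    return Phylogeny.from_newick(
        "((A:0.2,B:0.1):0.15,(C:0.3,D:0.25):0.05,E:0.4);"
    )
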
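"""Felsenstein pruning for amino-acid likelihoods and gene-wise scores.

Per-column log-likelihoods are computed by post-order pruning with per-node
scaling; discrete-gamma mixtures are averaged with equal category weights;
missing residues contribute partial-likelihood vectors of ones.  Branch
lengths are re-optimized per locus under each fixed candidate topology by
cycling bounded scalar searches over edges; each edge's one-dimensional
likelihood function is evaluated exactly from "above"/"below" conditional
vectors refreshed along the traversal, so every accepted move is a true
improvement.

The gene-wise log-likelihood score (GLS) of a locus under a topology is the
sum of its site log-likelihoods after branch-length optimization; the
pipeline compares GLS across a set of candidate topologies that differ in
the resolution of one contentious clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import LocusAlignment
from .models import SubstitutionModel, TransitionKernel, get_model
from .trees import Phylogeny

logger = logging.getLogger(__name__)

BL_MIN, BL_MAX = 1e-8, 10.0
DEFAULT_BL = 0.1


@dataclass
class SiteLikelihoodResult:
    """Site and gene log-likelihoods of one locus under one topology."""

    locus_id: str
    topology_id: str
    site_lnl: np.ndarray
    gene_lnl: float
    optimized_tree: Phylogeny | None = None
    converged: bool = True

    def __post_init__(self):
        s = float(np.sum(self.site_lnl))
        if not np.isclose(s, self.gene_lnl, rtol=1e-9, atol=1e-9):
            raise ValueError("gene_lnL does not equal the sum of site lnL")


class _IndexedTree:
    """Array-backed rooted view of an (unrooted) tree for the pruning engine.

    The tree is rooted at an internal node (a trifurcation for unrooted
    input); every other node carries the length of the edge to its parent.
    Node order is post-order, so children always precede parents.
    """

    def __init__(self, phylo: Phylogeny, taxa_order: list[str]):
        tree = phylo.unrooted().tree if phylo.n_tips > 2 else phylo.tree
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.lengths = np.zeros(self.n_nodes)
        self.tip_label: dict[int, str] = {}
        row = {t: i for i, t in enumerate(taxa_order)}
        self.tip_row = np.full(self.n_nodes, -1, dtype=int)
        for n in nodes:
            i = idx[id(n)]
            if n.parent_node is not None:
                p = idx[id(n.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                ln = n.edge.length
                self.lengths[i] = DEFAULT_BL if ln is None else max(ln, BL_MIN)
            if n.is_leaf():
                lab = n.taxon.label
                if lab not in row:
                    raise KeyError(f"tree tip {lab!r} absent from alignment")
                self.tip_label[i] = lab
                self.tip_row[i] = row[lab]
        self.root = idx[id(tree.seed_node)]
        self.postorder = list(range(self.n_nodes))  # nodes enumerated post-order
        self._phylo_template = phylo

    @property
    def edges(self) -> list[int]:
        """Edges identified by their child node; excludes the root."""
        return [i for i in self.postorder if self.parent[i] >= 0]

    def to_phylogeny(self) -> Phylogeny:
        """Write current lengths back onto a copy of the source tree."""
        out = self._phylo_template.unrooted() \
            if self._phylo_template.n_tips > 2 else self._phylo_template.clone()
        tree = out.tree
        nodes = list(tree.postorder_node_iter())
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                n.edge.length = float(self.lengths[i])
        return out


class PruningEngine:
    """Likelihood machinery bound to one (alignment, topology, model)."""

    def __init__(
        self,
        aln: LocusAlignment,
        phylo: Phylogeny,
        model: SubstitutionModel,
    ):
        tips = set(phylo.tip_labels())
        if not tips <= set(aln.taxa):
            missing = tips - set(aln.taxa)
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        if len(tips) != aln.n_taxa:
            aln = aln.restrict(sorted(tips))
        if aln.n_taxa < 2:
            raise ValueError(
                f"{aln.locus_id}: {aln.n_taxa} taxa after restriction; "
                "need at least 2"
            )
        if aln.n_taxa < 4:
            logger.warning(
                "%s: only %d taxa; likelihoods are computable but the locus "
                "is uninformative for topology comparison",
                aln.locus_id, aln.n_taxa,
            )
        self.aln = aln
        self.model = model
        self.kernel = TransitionKernel(model)
        self.rates = model.category_rates()
        self.n_cat = len(self.rates)
        self.index = _IndexedTree(phylo, aln.taxa)
        codes = aln.encode()
        self.n_sites = aln.n_sites
        # tip partials: one-hot, or ones where missing
        self._tip_partial = {}
        for i, lab in self.index.tip_label.items():
            c = codes[self.index.tip_row[i]]
            L = np.zeros((self.n_sites, 20))
            obs = c >= 0
            L[obs, c[obs]] = 1.0
            L[~obs, :] = 1.0
            self._tip_partial[i] = L

    # ------------------------------------------------------------- pruning
    def _down_pass(self, rate: float):
        """Post-order conditional likelihoods below each node, scaled.

        Returns (partials, logscale) where partials[i] is (n_sites, 20) for
        internal nodes (tips use their fixed one-hot arrays) and logscale[i]
        accumulates the subtree's per-site log scaling factors.
        """
        ix = self.index
        partials: list[np.ndarray | None] = [None] * ix.n_nodes
        logscale = np.zeros((ix.n_nodes, self.n_sites))
        for i in ix.postorder:
            if ix.tip_row[i] >= 0:
                partials[i] = self._tip_partial[i]
                continue
            M = np.ones((self.n_sites, 20))
            sc = np.zeros(self.n_sites)
            for c in ix.children[i]:
                P = self.kernel.probs(ix.lengths[c], rate)
                M = M * (partials[c] @ P.T)
                sc += logscale[c]
            smax = M.max(axis=1)
            bad = smax <= 0
            if np.any(bad):
                cols = np.nonzero(bad)[0]
                raise FloatingPointError(
                    f"{self.aln.locus_id}: non-finite/zero partial likelihood "
                    f"at column {cols[0]}"
                )
            M = M / smax[:, None]
            partials[i] = M
            logscale[i] = sc + np.log(smax)
        return partials, logscale

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-column log-likelihood, gamma categories averaged."""
        pi = self.model.frequencies
        per_cat = np.empty((self.n_cat, self.n_sites))
        for k, r in enumerate(self.rates):
            partials, logscale = self._down_pass(r)
            root = self.index.root
            L = partials[root] @ pi
            per_cat[k] = np.log(L) + logscale[root]
        site = logsumexp(per_cat, axis=0) - np.log(self.n_cat)
        if not np.all(np.isfinite(site)):
            col = int(np.nonzero(~np.isfinite(site))[0][0])
            raise FloatingPointError(
                f"{self.aln.locus_id}: non-finite site log-likelihood at "
                f"column {col}"
            )
        return site

    def gene_lnl(self) -> float:
        return float(self.site_log_likelihoods().sum())

    # ------------------------------------------------- branch optimization
    def _edge_arrays(self):
        """Down and above conditionals for every edge, all categories.

        For the edge above node v with parent u, ``above[v]`` holds the joint
        probability of all data outside v's subtree as a function of the
        state at u (stationary frequencies folded in at the root), and
        ``down[v]`` the data below v given the state at v.  The per-edge
        likelihood is then sum_i above_i * (P(t) down)_i per site.
        """
        ix = self.index
        down, dsc, above, asc = {}, {}, {}, {}
        for k, r in enumerate(self.rates):
            partials, logscale = self._down_pass(r)
            down[k], dsc[k] = partials, logscale
        return down, dsc

    def _edge_lnl_fn(self, v: int, down, dsc, above_v, asc_v):
        """Gene lnL as a function of the length of the edge above v."""
        ncat, pi = self.n_cat, self.model.frequencies

        def f(t: float) -> float:
            per_cat = np.empty((ncat, self.n_sites))
            for k, r in enumerate(self.rates):
                P = self.kernel.probs(t, r)
                L = np.einsum("si,si->s", above_v[k], down[k][v] @ P.T)
                per_cat[k] = np.log(np.maximum(L, 1e-300)) + dsc[k][v] + asc_v[k]
            return float((logsumexp(per_cat, axis=0) - np.log(ncat)).sum())

        return f

    def optimize_branch_lengths(
        self,
        tol: float = 1e-3,
        max_sweeps: int = 50,
    ) -> tuple[float, bool]:
        """Cycle bounded scalar searches over edges until lnL stabilizes.

        Returns (gene_lnL, converged).  Each sweep walks the tree
        depth-first: the "above" conditional of an edge is built from its
        parent's fresh "above" and its siblings' "down" conditionals, and a
        subtree's "down" arrays are refreshed bottom-up as soon as its
        branch lengths have been updated, so every per-edge objective is
        the exact gene-lnL profile under the current lengths.
        """
        ix = self.index
        pi = self.model.frequencies
        last = self.gene_lnl()
        converged = False

        for sweep in range(max_sweeps):
            down, dsc = self._edge_arrays()

            def refresh_down(v: int) -> None:
                for k, r in enumerate(self.rates):
                    M = np.ones((self.n_sites, 20))
                    sc = np.zeros(self.n_sites)
                    for c in ix.children[v]:
                        P = self.kernel.probs(ix.lengths[c], r)
                        M = M * (down[k][c] @ P.T)
                        sc += dsc[k][c]
                    smax = M.max(axis=1)
                    down[k][v] = M / smax[:, None]
                    dsc[k][v] = sc + np.log(smax)

            def process(u: int, above_u, asc_u) -> None:
                for v in ix.children[u]:
                    av, sv = {}, {}
                    for k, r in enumerate(self.rates):
                        sibs = [c for c in ix.children[u] if c != v]
                        if ix.parent[u] < 0:
                            M = np.broadcast_to(pi, (self.n_sites, 20)).copy()
                            sc = np.zeros(self.n_sites)
                        else:
                            Pu = self.kernel.probs(ix.lengths[u], r)
                            M = above_u[k] @ Pu
                            sc = asc_u[k].copy()
                        for c in sibs:
                            Pc = self.kernel.probs(ix.lengths[c], r)
                            M = M * (down[k][c] @ Pc.T)
                            sc += dsc[k][c]
                        smax = M.max(axis=1)
                        av[k] = M / smax[:, None]
                        sv[k] = sc + np.log(smax)
                    f = self._edge_lnl_fn(v, down, dsc, av, sv)
                    cur = ix.lengths[v]
                    res = minimize_scalar(
                        lambda t: -f(t),
                        bounds=(BL_MIN, BL_MAX),
                        method="bounded",
                        options={"xatol": 1e-7},
                    )
                    if -res.fun > f(cur):
                        ix.lengths[v] = float(res.x)
                    if ix.children[v]:
                        process(v, av, sv)
                        refresh_down(v)

            process(ix.root, None, None)
            cur_lnl = self.gene_lnl()
            if cur_lnl < last - 1e-6:
                logger.warning(
                    "%s: lnL decreased during sweep %d (%.6f -> %.6f)",
                    self.aln.locus_id, sweep, last, cur_lnl,
                )
            if cur_lnl - last < tol:
                last = max(cur_lnl, last)
                converged = True
                break
            last = cur_lnl
        if not converged:
            logger.warning(
                "%s: branch-length optimization hit %d sweeps without "
                "converging; best lnL so far returned",
                self.aln.locus_id, max_sweeps,
            )
        return last, converged


# ----------------------------------------------------------------- frontend

def site_log_likelihoods(
    aln: LocusAlignment,
    tree: Phylogeny,
    model: SubstitutionModel,
    locus_id: str | None = None,
    topology_id: str = "T",
) -> SiteLikelihoodResult:
    """Site lnL under a fixed tree with fixed branch lengths."""
    eng = PruningEngine(aln, tree, model)
    site = eng.site_log_likelihoods()
    return SiteLikelihoodResult(
        locus_id or aln.locus_id, topology_id, site, float(site.sum()),
        optimized_tree=tree,
    )


def optimize_branch_lengths(
    aln: LocusAlignment,
    topology: Phylogeny,
    model: SubstitutionModel,
    topology_id: str = "T",
    tol: float = 1e-3,
    max_sweeps: int = 50,
) -> SiteLikelihoodResult:
    """Refit branch lengths on a fixed topology; returns the fitted result."""
    eng = PruningEngine(aln, topology, model)
    _, converged = eng.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)
    site = eng.site_log_likelihoods()
    return SiteLikelihoodResult(
        aln.locus_id, topology_id, site, float(site.sum()),
        optimized_tree=eng.index.to_phylogeny(), converged=converged,
    )


def _optimize_gamma_shape(
    aln: LocusAlignment, tree: Phylogeny, model: SubstitutionModel
) -> tuple[SubstitutionModel, float]:
    """Fit the gamma shape on fixed branch lengths (everything else fixed)."""

    def neg(log_shape: float) -> float:
        m = model.with_gamma(float(np.exp(log_shape)), model.n_rate_categories)
        return -PruningEngine(aln, tree, m).gene_lnl()

    res = minimize_scalar(
        neg, bounds=(np.log(0.02), np.log(50.0)), method="bounded",
        options={"xatol": 1e-3},
    )
    shape = float(np.exp(res.x))
    return model.with_gamma(shape, model.n_rate_categories), -float(res.fun)


def select_model(
    aln: LocusAlignment,
    guide_tree: Phylogeny,
    candidates: list[str] | None = None,
) -> SubstitutionModel:
    """Pick the candidate minimizing BIC on the guide tree.

    BIC = -2 lnL + k ln(n_sites) with k counting only the gamma shape
    (empirical exchangeabilities and frequencies are fixed).  Gamma shapes
    are fitted on the guide tree's branch lengths.  Ties go to the candidate
    with fewest parameters, then to input order.
    """
    if candidates is None:
        candidates = ["POISSON", "POISSON+G4", "LG", "LG+G4",
                      "WAG", "WAG+G4", "JTT", "JTT+G4"]
    if not candidates:
        raise ValueError("empty model candidate list")
    best = None
    for pos, name in enumerate(candidates):
        model = get_model(name)
        if model.gamma_shape is not None:
            model, lnl = _optimize_gamma_shape(aln, guide_tree, model)
        else:
            lnl = PruningEngine(aln, guide_tree, model).gene_lnl()
        k = model.n_free_parameters
        bic = -2.0 * lnl + k * np.log(aln.n_sites)
        key = (round(bic, 9), k, pos)
        if best is None or key < best[0]:
            best = (key, model)
    return best[1]


@dataclass
class GLSRow:
    locus_id: str
    lnl: dict[str, float]
    model_name: str
    indistinguishable_pairs: list[tuple[str, str]] = field(default_factory=list)
    converged: bool = True
    n_taxa: int = 0


def _pairs_indistinguishable(
    pruned: dict[str, Phylogeny]
) -> list[tuple[str, str]]:
    """Topology pairs that coincide once pruned to the locus' taxa."""
    ids = list(pruned)
    splits = {
        t: pruned[t].unrooted().bipartitions(nontrivial_only=True) for t in ids
    }
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if splits[ids[i]] == splits[ids[j]]:
                out.append((ids[i], ids[j]))
    return out


def compute_gls(
    loci: list[LocusAlignment],
    topologies: dict[str, Phylogeny],
    model_candidates: list[str] | None = None,
    tol: float = 1e-3,
    max_sweeps: int = 50,
) -> list[GLSRow]:
    """Gene-wise log-likelihood scores for every locus under K topologies.

    Per locus: each candidate topology is pruned to the locus' taxa; branch
    lengths are optimized on the first topology under the first candidate
    model; the model is then selected once (BIC on that optimized tree) and
    reused for all topologies.  Topology pairs that become identical after
    pruning are flagged indistinguishable (their ΔGLS is forced to zero
    downstream).
    """
    if len(topologies) < 2:
        raise ValueError("need at least 2 candidate topologies")
    topo_ids = list(topologies)
    rows = []
    for aln in loci:
        taxa = set(aln.taxa)
        pruned = {}
        ok = True
        for tid in topo_ids:
            shared = taxa & set(topologies[tid].tip_labels())
            if len(shared) < 4:
                logger.warning(
                    "%s: fewer than 4 taxa shared with topology %s; skipped",
                    aln.locus_id, tid,
                )
                ok = False
                break
            pruned[tid] = topologies[tid].prune_to(shared)
        if not ok:
            continue
        indist = _pairs_indistinguishable(pruned)

        first = topo_ids[0]
        base_name = (model_candidates or ["LG"])[0]
        base_fit = optimize_branch_lengths(
            aln, pruned[first], get_model(base_name),
            topology_id=first, tol=tol, max_sweeps=max_sweeps,
        )
        if model_candidates and len(model_candidates) > 1:
            model = select_model(
                aln, base_fit.optimized_tree, candidates=model_candidates
            )
        else:
            model = get_model(base_name)

        lnl: dict[str, float] = {}
        converged = True
        for tid in topo_ids:
            if tid == first and model.name == base_name:
                fit = base_fit
            else:
                fit = optimize_branch_lengths(
                    aln, pruned[tid], model,
                    topology_id=tid, tol=tol, max_sweeps=max_sweeps,
                )
            lnl[tid] = fit.gene_lnl
            converged &= fit.converged
        rows.append(
            GLSRow(
                locus_id=aln.locus_id,
                lnl=lnl,
                model_name=model.name,
                indistinguishable_pairs=indist,
                converged=converged,
                n_taxa=aln.n_taxa,
            )
        )
    return rows


def gls_rows_to_frame(rows: list[GLSRow], topo_ids: list[str]) -> pd.DataFrame:
    data = {
        "locus_id": [r.locus_id for r in rows],
        **{
            f"lnl_{t}": [r.lnl[t] for r in rows] for t in topo_ids
        },
        "model": [r.model_name for r in rows],
        "n_taxa": [r.n_taxa for r in rows],
        "converged": [r.converged for r in rows],
        "indistinguishable_pairs": [
            ";".join(f"{a}|{b}" for a, b in r.indistinguishable_pairs)
            for r in rows
        ],
    }
    return pd.DataFrame(data)
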
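"""Synthetic phylogenomic scenarios.

Generates the inputs the dissection pipeline consumes — per-locus
amino-acid alignments, gene trees with supports, three candidate species
topologies differing only in the attachment of one movable clade, and
named clade definitions — with the statistical structure of a deep
phylogenomic dataset: ~39 taxa grouped in labelled order-level clades,
locus lengths lognormal around ~240 columns (range clipped to 100-650),
heterogeneous per-locus rates, per-locus missing taxa, optional
compositional bias, and gene-tree error modelled as NNI perturbations.

Every locus records its generating topology and tree in a truth table so
downstream recovery statistics are auditable; no analysis stage consumes
the truth fields.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, LocusAlignment
from .models import SubstitutionModel, TransitionKernel, get_model
from .trees import Phylogeny

CLADE_NAMES = ["Movable", "CladeB", "CladeC", "CladeD", "CladeE"]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named substream: one master seed fans out to per-stage generators."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class ScenarioConfig:
    """Shape of a synthetic study.

    Defaults emulate the scale of a deep-phylogenomics dataset: 39 taxa,
    lognormal locus lengths with mean ~240 columns in a 100-650 range, and
    a three-way mixture of generating topologies that differ only in where
    one clade attaches.
    """

    n_taxa: int = 39
    n_loci: int = 100
    mixture_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    length_mean: float = 240.0
    length_sigma: float = 0.45  # lognormal sigma on the log scale
    length_range: tuple[int, int] = (100, 650)
    fixed_length: int | None = None  # overrides the length distribution
    rate_sigma: float = 0.4  # lognormal sigma of per-locus rate multipliers
    missing_taxon_fraction: float = 0.2
    nni_probability: float = 0.0  # chance a gene tree is NNI-perturbed
    model_name: str = "LG"
    compositional_bias_taxa: int = 0
    compositional_bias_strength: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.mixture_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if self.length_range[0] < 50:
            raise ValueError("minimum locus length is 50")
        if self.n_taxa < 12:
            raise ValueError("need at least 12 taxa for 5 labelled clades")


@dataclass
class SyntheticLocus:
    alignment: LocusAlignment
    true_topology_id: str
    true_tree: Phylogeny
    gene_tree: Phylogeny
    rate_multiplier: float
    perturbed: bool


@dataclass
class Scenario:
    loci: list[SyntheticLocus]
    topologies: dict[str, Phylogeny]
    clades: dict[str, set[str]]
    truth: pd.DataFrame
    config: ScenarioConfig


# ------------------------------------------------------ candidate topologies

def _random_subtree(labels: list[str], rng: np.random.Generator,
                    bl_mean: float = 0.08) -> str:
    """Random binary Newick subtree over ``labels`` by successive joins."""
    nodes = [f"{t}:{rng.exponential(bl_mean):.6f}" for t in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.exponential(bl_mean):.6f}")
    return nodes[0]


def make_candidate_topologies(
    n_taxa: int = 39, seed: int = 0, backbone_length: float = 0.06
) -> tuple[dict[str, Phylogeny], dict[str, set[str]]]:
    """Three resolutions differing only in one clade's attachment.

    Taxa are split into five labelled clades (the first is the movable
    one).  The three candidates graft the movable clade onto three
    adjacent branches of the fixed backbone ((B,C),(D,E)):

      T1: sister to CladeB; T2: sister to CladeC; T3: sister to (B,C).

    Pruning the movable clade away makes all three identical.
    """
    if n_taxa < 12:
        raise ValueError("need at least 12 taxa")
    rng = rng_for(seed, "topologies")
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # movable clade gets >= 3 taxa so random missingness rarely removes it
    sizes = np.full(5, n_taxa // 5)
    sizes[: n_taxa % 5] += 1
    parts, start = [], 0
    for s in sizes:
        parts.append(labels[start : start + s])
        start += s
    clades = {nm: set(p) for nm, p in zip(CLADE_NAMES, parts)}
    sub = {nm: _random_subtree(p, rng) for nm, p in zip(CLADE_NAMES, parts)}
    bl = backbone_length

    def nw(m, b, c, d, e):
        return m.format(M=sub["Movable"], B=b, C=c, D=d, E=e, L=f"{bl:.6f}")

    b, c, d, e = sub["CladeB"], sub["CladeC"], sub["CladeD"], sub["CladeE"]
    t1 = f"((({sub['Movable']},{b}):{bl:.6f},{c}):{bl:.6f},{d},{e});"
    t2 = f"((({sub['Movable']},{c}):{bl:.6f},{b}):{bl:.6f},{d},{e});"
    t3 = f"((({b},{c}):{bl:.6f},{sub['Movable']}):{bl:.6f},{d},{e});"
    topos = {
        "T1": Phylogeny.from_newick(t1),
        "T2": Phylogeny.from_newick(t2),
        "T3": Phylogeny.from_newick(t3),
    }
    return topos, clades


# ----------------------------------------------------------- locus simulator

def simulate_locus(
    tree: Phylogeny,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator = 0,
    locus_id: str = "locus",
    biased_taxa: set[str] | None = None,
    bias_strength: float = 0.5,
) -> LocusAlignment:
    """Simulate one alignment along a tree under a reversible model.

    Root states are drawn from the stationary frequencies and evolved along
    each branch with the model's transition probabilities; per-site gamma
    rate multipliers apply when the model carries a gamma shape.  Taxa in
    ``biased_taxa`` evolve along their terminal branch under a model whose
    frequencies are pulled toward a perturbed profile, creating
    compositional heterogeneity.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    kernel = TransitionKernel(model)
    bias_kernel = None
    if biased_taxa:
        f = model.frequencies.copy()
        # up-weight half the residues; strictly positive for any strength
        s = min(float(bias_strength), 1.0)
        weights = np.ones_like(f)
        weights[: len(weights) // 2] = 1.0 + 2.0 * s
        fb = f * weights
        fb /= fb.sum()
        bias_kernel = TransitionKernel(
            SubstitutionModel(
                model.name + "+bias", model.exchangeabilities, fb,
                model.gamma_shape, model.n_rate_categories,
            )
        )
    rates = model.category_rates()
    site_rate = rates[rng.integers(0, len(rates), size=n_sites)]

    t = tree.tree
    root = t.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(20, size=n_sites, p=model.frequencies)
    }
    for node in t.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length or 0.0
        is_biased_tip = (
            bias_kernel is not None
            and node.is_leaf()
            and node.taxon.label in biased_taxa
        )
        kern = bias_kernel if is_biased_tip else kernel
        parent_states = states[id(node.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        for r in np.unique(site_rate):
            m = site_rate == r
            P = kern.probs(bl, float(r))
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(m.sum()))
            child[m] = (cum[parent_states[m]] < u[:, None]).sum(axis=1)
        states[id(node)] = child
    taxa, seqs = [], []
    for leaf in t.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seqs.append("".join(AMINO_ACIDS[s] for s in states[id(leaf)]))
    return LocusAlignment(locus_id, taxa, seqs)


# ---------------------------------------------------------- NNI + supports

def _nni_perturb(phylo: Phylogeny, rng: np.random.Generator) -> tuple[Phylogeny, bool]:
    """One random nearest-neighbour interchange on an internal edge."""
    tree = phylo.unrooted().tree.clone(depth=1)
    internal = [
        e for e in tree.preorder_edge_iter()
        if e.head_node.parent_node is not None
        and not e.head_node.is_leaf()
        and e.tail_node is not None
    ]
    candidates = []
    for e in internal:
        child = e.head_node
        parent = e.tail_node
        kids = child.child_nodes()
        sibs = [c for c in parent.child_nodes() if c is not child]
        if len(kids) >= 2 and len(sibs) >= 1:
            candidates.append((child, parent, kids, sibs))
    if not candidates:
        return phylo, False
    child, parent, kids, sibs = candidates[rng.integers(len(candidates))]
    a = kids[rng.integers(len(kids))]
    b = sibs[rng.integers(len(sibs))]
    # swap subtrees a (below the edge) and b (beside it)
    child.remove_child(a)
    parent.remove_child(b)
    child.add_child(b)
    parent.add_child(a)
    out = Phylogeny(tree, rooted=False)
    return out, True


def _attach_supports(
    phylo: Phylogeny, perturbed: bool, rng: np.random.Generator
) -> Phylogeny:
    """Pseudo-bootstrap supports: Beta draws stretched to [50,100] on clean
    trees and [20,90] on NNI-perturbed ones."""
    t = phylo.tree.clone(depth=1)
    lo, hi = (20.0, 90.0) if perturbed else (50.0, 100.0)
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        node.label = f"{lo + (hi - lo) * rng.beta(4, 1.5):.1f}"
    return Phylogeny(t, rooted=phylo.rooted)


# ------------------------------------------------------------- the scenario

def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Draw a full synthetic study from the scenario configuration."""
    topos, clades = make_candidate_topologies(
        config.n_taxa, seed=config.rng_seed
    )
    model = get_model(config.model_name)
    topo_ids = list(topos)
    w = np.asarray(config.mixture_weights, dtype=float)
    rng_mix = rng_for(config.rng_seed, "mixture")
    rng_len = rng_for(config.rng_seed, "lengths")
    rng_rate = rng_for(config.rng_seed, "rates")
    rng_miss = rng_for(config.rng_seed, "missing")
    rng_sim = rng_for(config.rng_seed, "sequences")
    rng_tree = rng_for(config.rng_seed, "gene_trees")
    rng_bias = rng_for(config.rng_seed, "bias")

    biased: set[str] = set()
    if config.compositional_bias_taxa > 0:
        labels = [f"t{i:02d}" for i in range(config.n_taxa)]
        biased = set(
            rng_bias.choice(labels, size=config.compositional_bias_taxa,
                            replace=False)
        )

    loci: list[SyntheticLocus] = []
    truth_rows = []
    lo, hi = config.length_range
    mu = math.log(config.length_mean) - 0.5 * config.length_sigma**2
    for i in range(config.n_loci):
        lid = f"locus{i:04d}"
        tid = topo_ids[rng_mix.choice(3, p=w)]
        if config.fixed_length is not None:
            n_sites = config.fixed_length
        else:
            n_sites = int(np.clip(rng_len.lognormal(mu, config.length_sigma),
                                  lo, hi))
        mult = float(rng_rate.lognormal(-0.5 * config.rate_sigma**2,
                                        config.rate_sigma))
        # scale branch lengths of this locus' generating tree
        gt = topos[tid].clone()
        for e in gt.tree.edges():
            if e.length is not None:
                e.length = e.length * mult
        # per-locus taxon dropout
        keep = [
            t for t in gt.tip_labels()
            if rng_miss.random() >= config.missing_taxon_fraction
        ]
        if len(keep) < 4:
            keep = list(gt.tip_labels())[:4]
        true_tree = gt.prune_to(keep)
        aln = simulate_locus(
            true_tree, model, n_sites, seed=rng_sim, locus_id=lid,
            biased_taxa=biased & set(keep),
            bias_strength=min(1.0, config.compositional_bias_strength
                              * min(2.0, mult)),
        )
        gene_tree = true_tree
        perturbed = False
        # fast-evolving loci get noisier gene trees (saturation erodes
        # gene-tree accuracy), coupling the panel's signal and bias metrics
        p_nni = min(1.0, config.nni_probability * mult)
        if p_nni > 0 and rng_tree.random() < p_nni:
            gene_tree, perturbed = _nni_perturb(true_tree, rng_tree)
        gene_tree = _attach_supports(gene_tree, perturbed, rng_tree)
        loci.append(
            SyntheticLocus(aln, tid, true_tree, gene_tree, mult, perturbed)
        )
        truth_rows.append(
            {
                "locus_id": lid,
                "true_topology": tid,
                "n_sites": n_sites,
                "n_taxa": len(keep),
                "rate_multiplier": mult,
                "perturbed": perturbed,
                "movable_taxa_sampled": len(clades["Movable"] & set(keep)),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return Scenario(loci, topos, clades, truth, config)


def write_scenario(scenario: Scenario, outdir) -> None:
    """Write per-locus FASTA, gene trees, candidate topologies, clade
    definitions and truth.tsv under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    aln_dir = os.path.join(outdir, "alignments")
    tree_dir = os.path.join(outdir, "gene_trees")
    os.makedirs(aln_dir, exist_ok=True)
    os.makedirs(tree_dir, exist_ok=True)
    for locus in scenario.loci:
        lid = locus.alignment.locus_id
        with open(os.path.join(aln_dir, f"{lid}.fasta"), "w") as fh:
            fh.write(locus.alignment.to_fasta())
        locus.gene_tree.write(os.path.join(tree_dir, f"{lid}.nwk"))
    for tid, topo in scenario.topologies.items():
        topo.write(os.path.join(outdir, f"{tid}.nwk"))
    with open(os.path.join(outdir, "clades.tsv"), "w") as fh:
        for name, members in scenario.clades.items():
            for t in sorted(members):
                fh.write(f"{name}\t{t}\n")
    scenario.truth.to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )
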
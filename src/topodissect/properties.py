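"""Per-locus gene properties and the phylogenetic-usefulness ranking.

The panel of fifteen per-locus metrics covers phylogenetic signal (average
bootstrap support, similarity to a reference topology), potential sources
of systematic bias (saturation, compositional heterogeneity, lack of
clocklikeness), and information content / evolutionary rate (variable and
parsimony-informative sites, tree length, site entropy, ...).  Loci are
ranked for usefulness by a PCA of the z-scored panel: the usefulness axis
is the component on which the signal metrics load together and opposite to
the bias metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .alignment import LocusAlignment
from .trees import Phylogeny, robinson_foulds_similarity

logger = logging.getLogger(__name__)

PROPERTY_NAMES = [
    "alignment_length",
    "pct_missing",
    "prop_variable_sites",
    "prop_parsimony_informative",
    "n_taxa",
    "avg_bootstrap",
    "rf_similarity",
    "root_to_tip_variance",
    "saturation",
    "rcfv",
    "total_tree_length",
    "avg_patristic_distance",
    "treeness",
    "treeness_over_rcfv",
    "mean_site_entropy",
]

#: loading-sign pattern defining the usefulness axis: signal metrics
#: positive together, bias metrics opposite.
_SIGNAL_METRICS = ("avg_bootstrap", "rf_similarity")
_BIAS_METRICS = ("root_to_tip_variance", "saturation", "rcfv")


@dataclass
class GenePropertyRecord:
    locus_id: str
    alignment_length: float = math.nan
    pct_missing: float = math.nan
    prop_variable_sites: float = math.nan
    prop_parsimony_informative: float = math.nan
    n_taxa: float = math.nan
    avg_bootstrap: float = math.nan
    rf_similarity: float = math.nan
    root_to_tip_variance: float = math.nan
    saturation: float = math.nan
    rcfv: float = math.nan
    total_tree_length: float = math.nan
    avg_patristic_distance: float = math.nan
    treeness: float = math.nan
    treeness_over_rcfv: float = math.nan
    mean_site_entropy: float = math.nan


# ------------------------------------------------------- alignment metrics

def _column_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column state counts (20, n_sites) and per-column coverage."""
    n_taxa, n_sites = codes.shape
    counts = np.zeros((20, n_sites), dtype=np.int32)
    for s in range(20):
        counts[s] = (codes == s).sum(axis=0)
    return counts, counts.sum(axis=0)


def proportion_variable_sites(aln: LocusAlignment) -> float:
    counts, cov = _column_counts(aln.encode())
    has_data = cov > 0
    n_states = (counts > 0).sum(axis=0)
    if not has_data.any():
        return 0.0
    return float((n_states[has_data] >= 2).mean())


def proportion_parsimony_informative(aln: LocusAlignment) -> float:
    """Columns with >=2 states each present in >=2 sequences."""
    counts, cov = _column_counts(aln.encode())
    has_data = cov > 0
    if not has_data.any():
        return 0.0
    informative = (counts >= 2).sum(axis=0) >= 2
    return float(informative[has_data].mean())


def pct_missing(aln: LocusAlignment) -> float:
    codes = aln.encode()
    return float(100.0 * (codes < 0).mean())


def mean_site_entropy(aln: LocusAlignment) -> float:
    """Mean Shannon entropy (bits) of residue composition per column."""
    counts, cov = _column_counts(aln.encode())
    has_data = cov > 0
    if not has_data.any():
        return 0.0
    p = counts[:, has_data] / cov[has_data]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=0)
    return float(h.mean())


def rcfv(aln: LocusAlignment) -> float:
    """Relative composition frequency variability.

    Mean (over taxa) total absolute deviation of each taxon's residue
    frequencies from the across-taxon mean frequency; frequencies are
    computed over non-missing cells per taxon.  Zero for compositionally
    homogeneous data.
    """
    if aln.n_taxa < 2:
        raise ValueError("RCFV needs at least 2 taxa")
    codes = aln.encode()
    freqs = []
    for row in codes:
        obs = row[row >= 0]
        if obs.size == 0:
            continue
        f = np.bincount(obs, minlength=20) / obs.size
        freqs.append(f)
    if len(freqs) < 2:
        return 0.0
    F = np.array(freqs)
    mean = F.mean(axis=0)
    return float(np.abs(F - mean).sum(axis=1).sum() / F.shape[0])


def p_distance_matrix(aln: LocusAlignment) -> np.ndarray:
    """Uncorrected pairwise distances ignoring pairwise-missing sites."""
    codes = aln.encode()
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            if both.sum() == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            d = float((codes[i][both] != codes[j][both]).mean())
            D[i, j] = D[j, i] = d
    return D


def saturation(aln: LocusAlignment, gene_tree: Phylogeny) -> float:
    """1 minus the origin-constrained slope of p-distance on patristic distance.

    Multiple substitutions flatten the relation between observed and
    inferred distance; near-zero divergence gives slope ~1, saturation ~0.
    """
    labels = [t for t in gene_tree.tip_labels() if t in set(aln.taxa)]
    if len(labels) < 4:
        return math.nan
    sub = aln.restrict(labels)
    # align matrix orders
    order = [sub.taxa.index(t) for t in labels]
    P = p_distance_matrix(sub)[np.ix_(order, order)]
    T = gene_tree.patristic_distances(labels)
    iu = np.triu_indices(len(labels), k=1)
    x, y = T[iu], P[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0 or np.allclose(x, 0):
        return math.nan
    slope = float(np.sum(x * y) / np.sum(x * x))
    return 1.0 - slope


# ------------------------------------------------------------ tree metrics

def treeness(tree: Phylogeny) -> float:
    total = tree.total_length()
    if total <= 0:
        return 0.0
    return tree.internal_length() / total


def root_to_tip_variance(tree: Phylogeny) -> float:
    """Variance of midpoint-rooted root-to-tip path lengths (clocklikeness)."""
    depths = tree.midpoint_root_to_tip_depths()
    return float(np.var(depths))


def avg_patristic_distance(tree: Phylogeny) -> float:
    D = tree.patristic_distances()
    iu = np.triu_indices(D.shape[0], k=1)
    return float(D[iu].mean())


def avg_bootstrap(tree: Phylogeny) -> float:
    """Mean internal-edge support, auto-rescaled to [0, 100]."""
    vals = tree.edge_supports()
    if not vals:
        return math.nan
    arr = np.asarray(vals, dtype=float)
    if arr.max() <= 1.0:
        arr = arr * 100.0
    return float(arr.mean())


# --------------------------------------------------------------- the panel

def compute_properties(
    aln: LocusAlignment,
    gene_tree: Phylogeny | None,
    reference: Phylogeny | None,
) -> GenePropertyRecord:
    """Populate the 15-metric panel for one locus.

    Alignment-level metrics are always computed; tree-dependent metrics are
    left missing when the gene tree is absent or has fewer than 4 tips.
    """
    rec = GenePropertyRecord(aln.locus_id)
    rec.alignment_length = float(aln.n_sites)
    rec.pct_missing = pct_missing(aln)
    rec.prop_variable_sites = proportion_variable_sites(aln)
    rec.prop_parsimony_informative = proportion_parsimony_informative(aln)
    rec.n_taxa = float(aln.n_taxa)
    rec.mean_site_entropy = mean_site_entropy(aln)
    if aln.n_taxa >= 2:
        rec.rcfv = rcfv(aln)
    if gene_tree is None or gene_tree.n_tips < 4:
        return rec
    rec.avg_bootstrap = avg_bootstrap(gene_tree)
    rec.root_to_tip_variance = root_to_tip_variance(gene_tree)
    rec.saturation = saturation(aln, gene_tree)
    rec.total_tree_length = gene_tree.total_length()
    rec.avg_patristic_distance = avg_patristic_distance(gene_tree)
    rec.treeness = treeness(gene_tree)
    if rec.rcfv and rec.rcfv > 0:
        rec.treeness_over_rcfv = rec.treeness / rec.rcfv
    if reference is not None:
        rec.rf_similarity = robinson_foulds_similarity(gene_tree, reference)
    return rec


def records_to_frame(records: list[GenePropertyRecord]) -> pd.DataFrame:
    rows = [
        {f.name: getattr(r, f.name) for f in fields(GenePropertyRecord)}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["locus_id"] + PROPERTY_NAMES)


# ---------------------------------------------------------- usefulness sort

@dataclass
class UsefulnessResult:
    ranked_ids: list[str]
    scores: pd.Series  # usefulness score per locus, descending-is-better
    axis: int  # which principal component was the usefulness axis (0/1)
    loadings: pd.DataFrame  # (2, properties)
    explained_variance_pct: np.ndarray


def usefulness_sort(frame: pd.DataFrame) -> UsefulnessResult:
    """Rank loci by phylogenetic usefulness.

    PCA on the z-scored (median-imputed) property panel; the usefulness
    axis is the first of the top two components where ``avg_bootstrap`` and
    ``rf_similarity`` load with a common sign and ``root_to_tip_variance``,
    ``saturation`` and ``rcfv`` all load with the opposite sign.  The axis
    is oriented so signal-rich loci score high; ties break on locus id.
    """
    if len(frame) < 10:
        raise ValueError("usefulness ranking needs at least 10 loci")
    X = frame[PROPERTY_NAMES].to_numpy(dtype=float).copy()
    med = np.nanmedian(X, axis=0)
    nan_cols = ~np.isfinite(med)
    med[nan_cols] = 0.0
    inds = np.where(~np.isfinite(X))
    X[inds] = np.take(med, inds[1])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    var = s**2
    pct = 100.0 * var / var.sum()
    loadings = Vt[:2]
    names = PROPERTY_NAMES
    sig_ix = [names.index(n) for n in _SIGNAL_METRICS]
    bias_ix = [names.index(n) for n in _BIAS_METRICS]
    axis = None
    for c in range(2):
        v = loadings[c]
        sig = np.sign(v[sig_ix])
        bias = np.sign(v[bias_ix])
        if 0 in sig or 0 in bias:
            continue
        if len(set(sig)) == 1 and len(set(bias)) == 1 and sig[0] == -bias[0]:
            axis = c
            break
    if axis is None:
        raise ValueError(
            "no principal component matches the usefulness loading pattern "
            "(signal metrics together, bias metrics opposite); inspect the "
            "loadings and choose an axis manually"
        )
    v = loadings[axis].copy()
    if v[names.index("avg_bootstrap")] < 0:
        v = -v
    scores = pd.Series((Z - Z.mean(axis=0)) @ v, index=frame["locus_id"].values)
    order = sorted(scores.index, key=lambda lid: (-scores[lid], lid))
    return UsefulnessResult(
        ranked_ids=list(order),
        scores=scores,
        axis=axis,
        loadings=pd.DataFrame(loadings, index=["PC1", "PC2"], columns=names),
        explained_variance_pct=pct[:2],
    )


def subset_by_usefulness(
    ranked_ids: list[str],
    fraction: float | None = None,
    count: int | None = None,
) -> list[str]:
    """Top-scoring loci: ceil(fraction * n) ids, or an explicit count."""
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    if count is None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        count = math.ceil(fraction * len(ranked_ids))
    return list(ranked_ids[:count])
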
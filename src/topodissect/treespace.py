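"""Gene-tree treespace: quartet dissimilarity, PCoA, disparity, clade recovery.

Topological conflict among gene trees is summarized by embedding the trees
in a treespace: pairwise quartet dissimilarities (fraction of mutually
resolved four-taxon subtrees resolved differently) are ordinated by
principal coordinate analysis, and the dispersion of a set of trees is the
mean Euclidean distance of its members to their centroid.  Subsets enriched
for phylogenetic usefulness are compared against null distributions of
randomly drawn subsets of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

from .trees import Phylogeny

logger = logging.getLogger(__name__)


# ------------------------------------------------------ quartet dissimilarity

@lru_cache(maxsize=64)
def _quartet_index(s: int) -> tuple[np.ndarray, ...]:
    q = np.array(list(combinations(range(s), 4)), dtype=np.int64)
    return q[:, 0], q[:, 1], q[:, 2], q[:, 3]


def _quartet_codes(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve every quartet from a tree's path-length matrix.

    Uses the four-point condition: for quartet {a,b,c,d} the pairing with
    the strictly smallest sum of within-pair distances is the induced
    topology; if no sum is strictly smallest the quartet is unresolved
    (polytomy).  Returns (codes in {0,1,2}, resolved mask).
    """
    s = D.shape[0]
    a, b, c, d = _quartet_index(s)
    s0 = D[a, b] + D[c, d]  # ab|cd
    s1 = D[a, c] + D[b, d]  # ac|bd
    s2 = D[a, d] + D[b, c]  # ad|bc
    sums = np.stack([s0, s1, s2])
    code = np.argmin(sums, axis=0)
    smin = sums.min(axis=0)
    resolved = (sums > smin + 1e-9).sum(axis=0) == 2
    return code, resolved


@dataclass
class QuartetResult:
    value: float
    n_shared: int
    n_mutually_resolved: int
    flag: str = ""


def quartet_dissimilarity(
    t1: Phylogeny, t2: Phylogeny, detailed: bool = False
):
    """Fraction of mutually resolved quartets resolved differently.

    Both trees are pruned to their shared tip set first.  Quartets
    unresolved in either tree are excluded from numerator and denominator;
    an empty denominator yields 0 with a flag.  Fewer than 4 shared tips
    makes the dissimilarity undefined (None / flagged).
    """
    shared = sorted(set(t1.tip_labels()) & set(t2.tip_labels()))
    if len(shared) < 4:
        res = QuartetResult(np.nan, len(shared), 0, flag="lt4_shared")
        return res if detailed else None
    p1 = t1.prune_to(shared)
    p2 = t2.prune_to(shared)
    c1, r1 = _quartet_codes(p1.topological_distances(shared))
    c2, r2 = _quartet_codes(p2.topological_distances(shared))
    both = r1 & r2
    n_both = int(both.sum())
    if n_both == 0:
        res = QuartetResult(0.0, len(shared), 0, flag="no_mutually_resolved")
        return res if detailed else 0.0
    val = float((c1[both] != c2[both]).sum() / n_both)
    res = QuartetResult(val, len(shared), n_both)
    return res if detailed else val


def dissimilarity_matrix(
    trees: dict[str, Phylogeny]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Pairwise quartet dissimilarities; undefined cells median-imputed.

    Returns (matrix, ids, imputed boolean mask).  Per-tree quartet codes
    are cached on the union taxon ordering of each pair.
    """
    ids = list(trees)
    n = len(ids)
    D = np.zeros((n, n))
    missing = np.zeros((n, n), dtype=bool)
    tips = {i: set(trees[i].tip_labels()) for i in ids}
    for i in range(n):
        for j in range(i + 1, n):
            v = quartet_dissimilarity(trees[ids[i]], trees[ids[j]])
            if v is None:
                missing[i, j] = missing[j, i] = True
            else:
                D[i, j] = D[j, i] = v
    if missing.any():
        med = float(np.median(D[~missing & ~np.eye(n, dtype=bool)]))
        D[missing] = med
        logger.warning(
            "%d tree pairs shared <4 taxa; dissimilarities median-imputed "
            "(%.3f)", int(missing.sum() // 2), med,
        )
    return D, ids, missing


# --------------------------------------------------------------------- PCoA

@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (n, m) on axes with positive eigenvalues
    eigenvalues: np.ndarray  # (m,) positive, descending
    cailliez_constant: float = 0.0


def _double_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D (off-diagonal) Euclidean."""
    n = D.shape[0]
    d1 = _double_center(D**2)
    d2 = _double_center(D)
    top = np.hstack([np.zeros((n, n)), 2.0 * d1])
    bot = np.hstack([-np.eye(n), -4.0 * d2])
    ev = np.linalg.eigvals(np.vstack([top, bot]))
    return float(np.max(ev.real))


def pcoa(D: np.ndarray, eig_tol: float = 1e-8) -> PCoAResult:
    """Classical scaling of a dissimilarity matrix.

    When the most negative eigenvalue of the centered matrix exceeds the
    tolerance in magnitude, the Cailliez correction (adding a constant to
    all off-diagonal dissimilarities) is applied so all retained axes are
    real.  Axes are ordered by decreasing eigenvalue.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    c = 0.0
    B = _double_center(D**2)
    lam = np.linalg.eigvalsh(B)
    if lam[0] < -eig_tol:
        c = _cailliez_constant(D)
        Dc = D + c
        np.fill_diagonal(Dc, 0.0)
        B = _double_center(Dc**2)
    lam, V = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    keep = lam > eig_tol
    coords = V[:, keep] * np.sqrt(lam[keep])[None, :]
    return PCoAResult(coords, lam[keep], cailliez_constant=c)


# ---------------------------------------------------------------- disparity

def disparity(coordinates: np.ndarray, subset: np.ndarray | list | None = None) -> float:
    """Mean Euclidean distance to the subset centroid, on all axes."""
    X = np.asarray(coordinates, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty subset")
        X = X[subset]
    if X.shape[0] == 0:
        raise ValueError("empty subset")
    centroid = X.mean(axis=0)
    return float(np.linalg.norm(X - centroid, axis=1).mean())


def subsample_null(
    coordinates: np.ndarray,
    k: int,
    observed: float,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Null disparity distribution for random k-subsets.

    Draws ``n_reps`` uniform subsets of size k without replacement (within
    each replicate), computes their disparities, and reports the percentile
    of the observed value: the proportion of null values ≤ observed.  A
    significant reduction in conflict is a percentile ≤ 0.05 (one-tailed).
    """
    n = coordinates.shape[0]
    if k > n:
        raise ValueError(f"subset size {k} exceeds number of trees {n}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(n, size=k, replace=False)
        null[r] = disparity(coordinates, idx)
    pct = float(np.mean(null <= observed))
    return {
        "null": null,
        "observed": observed,
        "percentile_p": pct,
        "significant_reduction": pct <= 0.05,
        "null_mean": float(null.mean()),
        "null_q05": float(np.quantile(null, 0.05)),
    }


@dataclass
class TreespaceResult:
    dissimilarity: np.ndarray
    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    disparity_full: float
    subset_disparities: dict[str, float] = field(default_factory=dict)
    subset_sizes: dict[str, int] = field(default_factory=dict)
    null_distributions: dict[str, np.ndarray] = field(default_factory=dict)
    percentile_p: dict[str, float] = field(default_factory=dict)
    imputed: np.ndarray | None = None


def build_treespace(
    trees: dict[str, Phylogeny],
    subsets: dict[str, list[str]] | None = None,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TreespaceResult:
    """Full treespace analysis: distances → PCoA → disparity + nulls."""
    D, ids, imputed = dissimilarity_matrix(trees)
    ord_res = pcoa(D)
    coords = ord_res.coordinates
    res = TreespaceResult(
        D, ids, coords, ord_res.eigenvalues,
        disparity_full=disparity(coords), imputed=imputed,
    )
    pos = {t: i for i, t in enumerate(ids)}
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for name, members in (subsets or {}).items():
        idx = np.array([pos[m] for m in members])
        obs = disparity(coords, idx)
        null = subsample_null(coords, len(idx), obs, n_reps=n_reps, seed=rng)
        res.subset_disparities[name] = obs
        res.subset_sizes[name] = len(idx)
        res.null_distributions[name] = null["null"]
        res.percentile_p[name] = null["percentile_p"]
    return res


# ----------------------------------------------------------- clade recovery

@dataclass
class CladeRecoveryRecord:
    locus_id: str
    status: dict[str, str]  # clade -> recovered / not_recovered / untestable
    proportion_recovered: float


def clade_recovery(
    gene_tree: Phylogeny,
    clades: dict[str, set[str]],
    locus_id: str | None = None,
) -> CladeRecoveryRecord:
    """Score recovery of named clades on one gene tree.

    A clade is testable when at least two of its members are sampled and at
    least one non-member tip exists; it is recovered when the sampled
    members form one side of a bipartition of the unrooted gene tree.  The
    summary proportion is over testable clades only.
    """
    tips = set(gene_tree.tip_labels())
    unrooted = gene_tree.unrooted()
    status = {}
    n_rec = n_test = 0
    for name, members in clades.items():
        sampled = frozenset(members & tips)
        if len(sampled) < 2 or len(tips - sampled) < 1:
            status[name] = "untestable"
            continue
        n_test += 1
        if len(sampled) == len(tips) - 1 or unrooted.has_clade(sampled):
            # n-1 tips always form a split side (the remaining tip's edge)
            status[name] = "recovered"
            n_rec += 1
        else:
            status[name] = "not_recovered"
    prop = n_rec / n_test if n_test else float("nan")
    return CladeRecoveryRecord(
        locus_id or "", status, prop
    )
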
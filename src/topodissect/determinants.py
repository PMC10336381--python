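"""Determinants of topological preference.

Two complementary scans ask whether any gene property predicts a locus'
topological preference: (i) vector fitting of each property onto the ΔGLS
ordination plane, with permutation p-values for the squared multiple
correlation; (ii) a conditional-inference-style classification tree on the
three-level category factor, where each split must first pass a
Bonferroni-corrected permutation/asymptotic association test, so the tree
cannot grow on noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# -------------------------------------------------------------- vector fit

@dataclass
class VectorFitResult:
    property_name: str
    direction: np.ndarray  # unit 2-vector in the ordination plane
    r_squared: float
    p_value: float
    n_permutations: int
    n_used: int


def vector_fit(
    scores: np.ndarray,
    prop: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    name: str = "",
) -> VectorFitResult:
    """Fit one property as a vector in the 2-D ordination.

    Direction and R² come from the least-squares regression of the
    (centered) property on the two score columns; R² is the squared
    multiple correlation.  The p-value is the permutation tail probability
    p = (1 + #{permuted R² ≥ observed}) / (1 + n_perm), permuting the
    property across loci.
    """
    scores = np.asarray(scores, dtype=float)
    prop = np.asarray(prop, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    ok = np.isfinite(prop) & np.isfinite(scores).all(axis=1)
    X, y = scores[ok], prop[ok]
    n = len(y)
    if n < 10:
        raise ValueError("vector fitting needs at least 10 loci")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if np.ptp(y) == 0 or ss_tot <= 0:
        return VectorFitResult(name, np.array([1.0, 0.0]), 0.0, 1.0, n_perm, n)
    Q, _ = np.linalg.qr(Xc)
    proj = Q.T @ yc
    r2 = float(proj @ proj / ss_tot)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    nrm = np.linalg.norm(beta)
    direction = beta / nrm if nrm > 0 else np.array([1.0, 0.0])

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # vectorized permutation null: R2 = ||Q^T y_perm||^2 / ||y_perm||^2
    perms = np.empty(n_perm)
    block = 500
    for start in range(0, n_perm, block):
        m = min(block, n_perm - start)
        Y = np.empty((n, m))
        for j in range(m):
            Y[:, j] = yc[rng.permutation(n)]
        num = np.sum((Q.T @ Y) ** 2, axis=0)
        perms[start : start + m] = num / ss_tot
    p = float((1 + np.sum(perms >= r2 - 1e-12)) / (1 + n_perm))
    return VectorFitResult(name, direction, r2, p, n_perm, n)


def determinant_scan(
    scores: np.ndarray,
    properties: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Vector-fit every property column; report raw and Bonferroni p."""
    rng = np.random.default_rng(seed)
    rows = []
    names = [c for c in properties.columns if c != "locus_id"]
    for name in names:
        res = vector_fit(
            scores, properties[name].to_numpy(dtype=float),
            n_perm=n_perm, seed=rng, name=name,
        )
        rows.append(
            {
                "property": name,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * len(names)),
                "dir_1": res.direction[0],
                "dir_2": res.direction[1],
                "n": res.n_used,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------ categorical factor

def categorize_factor(categorized: pd.DataFrame) -> pd.Series:
    """The 3-level A/B/C factor with fixed level order (A, B, C)."""
    factor = pd.Categorical(
        categorized["category"], categories=["A", "B", "C"], ordered=False
    )
    levels_present = pd.Series(factor).dropna().unique()
    if len(levels_present) < 2:
        logger.warning(
            "category factor has a single level (%s); degenerate for tree "
            "fitting", list(levels_present),
        )
    return pd.Series(factor, index=categorized.index, name="category")


# -------------------------------------------------------- classification tree

@dataclass
class TreeNode:
    n: int
    counts: dict[str, int]
    depth: int
    predictor: str | None = None
    cutpoint: float | None = None
    p_adjusted: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def n_splits(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + self.left.n_splits() + self.right.n_splits()

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf n={self.n} counts={self.counts}\n"
        out = (
            f"{pad}[{self.predictor} <= {self.cutpoint:.6g}] "
            f"p_adj={self.p_adjusted:.4g} n={self.n}\n"
        )
        out += self.left.to_text(indent + 1)
        out += self.right.to_text(indent + 1)
        return out

    def to_records(self, node_id: int = 0) -> list[dict]:
        rec = {
            "node": node_id,
            "n": self.n,
            "depth": self.depth,
            "predictor": self.predictor or "",
            "cutpoint": self.cutpoint if self.cutpoint is not None else np.nan,
            "p_adjusted": self.p_adjusted if self.p_adjusted is not None else np.nan,
            **{f"n_{k}": v for k, v in self.counts.items()},
        }
        out = [rec]
        if not self.is_leaf:
            out += self.left.to_records(2 * node_id + 1)
            out += self.right.to_records(2 * node_id + 2)
        return out


def _kruskal_pvalue(
    x: np.ndarray,
    groups: np.ndarray,
    method: str,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Kruskal-Wallis association p between a numeric predictor and a factor."""
    levels = np.unique(groups)
    samples = [x[groups == g] for g in levels]
    if len(samples) < 2 or np.all(x == x[0]):
        return 1.0
    try:
        h, p_asym = stats.kruskal(*samples)
    except ValueError:  # all values identical within the test
        return 1.0
    if method == "asymptotic":
        return float(p_asym)
    # permutation calibration of the same H statistic
    count = 0
    for _ in range(n_perm):
        g = rng.permutation(groups)
        hp, _ = stats.kruskal(*[x[g == lv] for lv in levels])
        if hp >= h - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def _best_cutpoint(
    x: np.ndarray, groups: np.ndarray, min_leaf: int
) -> tuple[float | None, float]:
    """Cut maximizing the chi-square association of the 2-way split with
    the factor; candidates are midpoints between consecutive unique values."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    uniq = np.unique(xs)
    if uniq.size < 2:
        return None, 0.0
    levels = np.unique(groups)
    best_cut, best_stat = None, -np.inf
    for i in range(uniq.size - 1):
        cut = 0.5 * (uniq[i] + uniq[i + 1])
        left = x <= cut
        nl, nr = int(left.sum()), int((~left).sum())
        if nl < min_leaf or nr < min_leaf:
            continue
        # 2 x k contingency chi-square statistic
        table = np.array(
            [
                [(groups[left] == lv).sum() for lv in levels],
                [(groups[~left] == lv).sum() for lv in levels],
            ],
            dtype=float,
        )
        exp = table.sum(1, keepdims=True) * table.sum(0, keepdims=True) / table.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(exp > 0, (table - exp) ** 2 / exp, 0.0).sum()
        if chi2 > best_stat:
            best_stat, best_cut = chi2, cut
    return best_cut, best_stat


def fit_classification_tree(
    properties: pd.DataFrame,
    factor: pd.Series | np.ndarray,
    alpha: float = 0.05,
    min_node: int = 20,
    min_leaf: int = 5,
    max_depth: int = 5,
    p_method: str = "asymptotic",
    n_perm: int = 9_999,
    seed: int = 0,
) -> TreeNode:
    """Recursive partitioning with multiplicity-corrected split tests.

    At each node, every numeric predictor is tested against the factor with
    a Kruskal-Wallis statistic (asymptotic chi-square p by default,
    permutation p optionally); p-values are Bonferroni-adjusted across the
    predictors.  The node splits on the most significant predictor only
    when its adjusted p ≤ alpha; the cutpoint maximizes the two-sample
    chi-square association.  Recursion stops at depth ``max_depth`` or when
    a node holds fewer than ``min_node`` loci.
    """
    names = [c for c in properties.columns if c != "locus_id"]
    X = properties[names].to_numpy(dtype=float)
    y = np.asarray(pd.Categorical(factor).astype(str))
    if len(y) != X.shape[0]:
        raise ValueError("factor length does not match properties")
    if len(y) < min_node:
        raise ValueError(f"need at least {min_node} loci")
    rng = np.random.default_rng(seed)

    def counts(idx):
        vals, cnt = np.unique(y[idx], return_counts=True)
        base = {lv: 0 for lv in ("A", "B", "C")}
        base.update(dict(zip(vals.tolist(), cnt.tolist())))
        return base

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(n=len(idx), counts=counts(idx), depth=depth)
        if (
            len(idx) < min_node
            or depth >= max_depth
            or len(np.unique(y[idx])) < 2
        ):
            return node
        pvals = np.ones(len(names))
        for j in range(len(names)):
            xj = X[idx, j]
            ok = np.isfinite(xj)
            if ok.sum() < min_node:
                continue
            pvals[j] = _kruskal_pvalue(
                xj[ok], y[idx][ok], p_method, n_perm, rng
            )
        adj = np.minimum(1.0, pvals * len(names))
        j = int(np.argmin(adj))
        if adj[j] > alpha:
            return node
        xj = X[idx, j]
        ok = np.isfinite(xj)
        cut, _ = _best_cutpoint(xj[ok], y[idx][ok], min_leaf)
        if cut is None:
            return node
        left_mask = np.zeros(len(idx), dtype=bool)
        left_mask[ok] = xj[ok] <= cut
        right_mask = np.zeros(len(idx), dtype=bool)
        right_mask[ok] = xj[ok] > cut
        if left_mask.sum() < min_leaf or right_mask.sum() < min_leaf:
            return node
        node.predictor = names[j]
        node.cutpoint = float(cut)
        node.p_adjusted = float(adj[j])
        node.left = grow(idx[left_mask], depth + 1)
        node.right = grow(idx[right_mask], depth + 1)
        return node

    return grow(np.arange(len(y)), 0)
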
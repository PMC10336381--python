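"""ΔGLS signal dissection: pairwise differences, PCA, categorization.

For three candidate topologies the per-locus ΔGLS values are linearly
dependent (Δ12 = Δ13 − Δ23), so the three differences live on a plane; PCA
rotates that plane so the dominant axis of topological preference can be
read off directly.  Loci are then categorized against a focal topology
using a nominal ±2 log-likelihood-unit threshold: (A) uninformative,
(B) supporting the focal resolution, (C) rejecting it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORY_LEVELS = ("A", "B", "C")  # uninformative / supports focal / rejects


@dataclass
class PCASummary:
    loadings: np.ndarray  # (2, 3) rows = components
    explained_variance_pct: np.ndarray  # (2,)
    scores: np.ndarray  # (n_loci, 2)


def delta_gls(
    gls: pd.DataFrame, topo_ids: list[str]
) -> pd.DataFrame:
    """Append ordered-pair ΔGLS columns to a GLS table.

    Expects columns ``lnl_<tid>`` for each topology; emits
    ``dgls_<x>_<y>`` = lnL(x) − lnL(y) for the ordered pairs (1,2), (1,3),
    (2,3).  Loci with non-finite lnL are dropped with a warning; pairs
    flagged indistinguishable have their ΔGLS forced to zero.
    """
    if len(topo_ids) != 3:
        raise ValueError("delta_gls expects exactly 3 topologies")
    cols = [f"lnl_{t}" for t in topo_ids]
    out = gls.copy()
    finite = np.isfinite(out[cols]).all(axis=1)
    if not finite.all():
        bad = out.loc[~finite, "locus_id"].tolist()
        logger.warning("dropping loci with non-finite lnL: %s", bad)
        out = out[finite].reset_index(drop=True)
    for x, y in combinations(topo_ids, 2):
        out[f"dgls_{x}_{y}"] = out[f"lnl_{x}"] - out[f"lnl_{y}"]
    if "indistinguishable_pairs" in out.columns:
        for i, flags in enumerate(out["indistinguishable_pairs"]):
            if not flags:
                continue
            for pair in str(flags).split(";"):
                if not pair:
                    continue
                a, b = pair.split("|")
                col = (
                    f"dgls_{a}_{b}"
                    if f"dgls_{a}_{b}" in out.columns
                    else f"dgls_{b}_{a}"
                )
                out.iloc[i, out.columns.get_loc(col)] = 0.0
    return out


def _delta_matrix(table: pd.DataFrame, topo_ids: list[str]) -> np.ndarray:
    pairs = list(combinations(topo_ids, 2))
    return table[[f"dgls_{x}_{y}" for x, y in pairs]].to_numpy(dtype=float)


def pca_rotate(
    table: pd.DataFrame, topo_ids: list[str], focal: str | None = None
) -> PCASummary:
    """PCA of the centered, unscaled ΔGLS triplets.

    The triplets are rank-2 by the linear dependency, so two components
    carry all the variance and the explained percentages sum to 100.  PC1
    is oriented so positive scores go with net support for the focal
    topology (mean of the focal-involving ΔGLS, signed focal-minus-other).
    """
    X = _delta_matrix(table, topo_ids)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 loci")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        logger.warning("zero-variance ΔGLS table; degenerate PCA")
        return PCASummary(
            np.zeros((2, 3)), np.array([100.0, 0.0]), np.zeros((X.shape[0], 2))
        )
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()  # rank <= 2: third singular value is ~0
    loadings = Vt[:2]
    scores = Xc @ loadings.T
    pct = 100.0 * var[:2] / total

    focal = focal or topo_ids[0]
    signed = _focal_deltas(table, topo_ids, focal)
    target = signed.mean(axis=1)
    for c in range(2):
        ref = target if c == 0 else loadings[c]
        if c == 0:
            if np.corrcoef(scores[:, 0], target)[0, 1] < 0:
                loadings[0] *= -1
                scores[:, 0] *= -1
        else:
            # deterministic sign: largest-magnitude loading positive
            j = int(np.argmax(np.abs(loadings[1])))
            if loadings[1, j] < 0:
                loadings[1] *= -1
                scores[:, 1] *= -1
    return PCASummary(loadings, pct, scores)


def _focal_deltas(
    table: pd.DataFrame, topo_ids: list[str], focal: str
) -> np.ndarray:
    """Focal-involving ΔGLS signed as focal − other; (n_loci, 2)."""
    others = [t for t in topo_ids if t != focal]
    if len(others) != 2:
        raise ValueError(f"focal topology {focal!r} not among {topo_ids}")
    cols = []
    for o in others:
        if f"dgls_{focal}_{o}" in table.columns:
            cols.append(table[f"dgls_{focal}_{o}"].to_numpy(dtype=float))
        else:
            cols.append(-table[f"dgls_{o}_{focal}"].to_numpy(dtype=float))
    return np.column_stack(cols)


def categorize(
    table: pd.DataFrame,
    topo_ids: list[str],
    focal: str,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Assign each locus to A (uninformative), B (supports focal) or
    C (rejects focal).

    A locus is A when all three |ΔGLS| ≤ threshold ("within ±2" inclusive).
    Otherwise only the two focal-involving comparisons decide: B if at
    least one favours the focal topology by more than the threshold and
    none disfavours it; C in the mirror case.  Loci with evidence in both
    directions go with the larger |Δ| (tie → C) and carry a conflict flag;
    loci where only the non-focal pair exceeds the threshold remain A with
    an 'alternative-discriminating only' flag.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    X = _delta_matrix(table, topo_ids)
    signed = _focal_deltas(table, topo_ids, focal)
    cats, flags = [], []
    for i in range(X.shape[0]):
        flag = ""
        if np.all(np.abs(X[i]) <= threshold):
            cat = "A"
        else:
            favour = signed[i] > threshold
            disfavour = signed[i] < -threshold
            if favour.any() and not disfavour.any():
                cat = "B"
            elif disfavour.any() and not favour.any():
                cat = "C"
            elif favour.any() and disfavour.any():
                fmax = signed[i][favour].max()
                dmax = -signed[i][disfavour].min()
                cat = "B" if fmax > dmax else "C"
                flag = "conflict"
            else:
                cat = "A"
                flag = "alternative_discriminating_only"
        if cat == "B" and flag != "conflict":
            flag = (flag + ";" if flag else "") + (
                "supports_both" if (signed[i] > threshold).all() else "supports_one"
            )
        if cat == "C" and flag != "conflict":
            flag = (flag + ";" if flag else "") + (
                "rejects_both" if (signed[i] < -threshold).all() else "rejects_one"
            )
        cats.append(cat)
        flags.append(flag)
    out = table.copy()
    out["category"] = pd.Categorical(cats, categories=list(CATEGORY_LEVELS))
    out["category_flag"] = flags
    return out


def category_summary(
    categorized: pd.DataFrame,
    subsets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Counts and percentages of A/B/C per named subset (plus 'all')."""
    known = set(categorized["locus_id"])
    groups = {"all": list(categorized["locus_id"])}
    if subsets:
        for name, ids in subsets.items():
            unknown = [i for i in ids if i not in known]
            if unknown:
                raise KeyError(f"subset {name!r}: unknown locus ids {unknown[:5]}")
            groups[name] = list(ids)
    rows = []
    by_id = categorized.set_index("locus_id")["category"]
    for name, ids in groups.items():
        cats = by_id.loc[ids]
        n = len(ids)
        row = {"subset": name, "n": n}
        for lvl in CATEGORY_LEVELS:
            cnt = int((cats == lvl).sum())
            row[f"n_{lvl}"] = cnt
            row[f"pct_{lvl}"] = 100.0 * cnt / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
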
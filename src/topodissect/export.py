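"""Tabular result export: deterministic tab-separated files."""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_tsv(frame: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    """Write a TSV with headers; column order as given, rows as given.

    Re-exporting the same frame yields a byte-identical file.
    """
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def gls_table(
    categorized: pd.DataFrame, scores: np.ndarray | None = None
) -> pd.DataFrame:
    """One row per locus: lnL per topology, ΔGLS per pair, PC scores,
    category (the ordination-plot table)."""
    out = categorized.copy()
    if scores is not None:
        out["PC1"] = scores[:, 0]
        out["PC2"] = scores[:, 1]
    lead = ["locus_id"]
    lnl = sorted(c for c in out.columns if c.startswith("lnl_"))
    dgls = sorted(c for c in out.columns if c.startswith("dgls_"))
    tail = [c for c in ("PC1", "PC2", "category", "category_flag") if c in out.columns]
    rest = [c for c in out.columns if c not in lead + lnl + dgls + tail]
    return out[lead + lnl + dgls + tail + rest]


def category_breakdown(categorized: pd.DataFrame) -> pd.DataFrame:
    """Category x support-pattern counts (the wheel-chart table).

    Splits supporting/rejecting loci into those whose preference holds
    against both alternatives versus only one.
    """
    rows = []
    for cat in ("A", "B", "C"):
        sub = categorized[categorized["category"] == cat]
        n = len(sub)
        both = int(sub["category_flag"].str.contains("both", na=False).sum())
        one = int(sub["category_flag"].str.contains("one", na=False).sum())
        conflict = int((sub["category_flag"] == "conflict").sum())
        rows.append(
            {
                "category": cat,
                "n": n,
                "pct": 100.0 * n / max(len(categorized), 1),
                "n_vs_both": both,
                "n_vs_one": one,
                "n_conflict": conflict,
            }
        )
    return pd.DataFrame(rows)


def distance_matrix_frame(D: np.ndarray, ids: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(D, columns=ids)
    out.insert(0, "tree_id", ids)
    return out


def disparity_report(result) -> pd.DataFrame:
    """Observed vs null disparity per subset (TreespaceResult)."""
    rows = [
        {
            "subset": "all",
            "n": len(result.ids),
            "n_null_reps": 0,
            "disparity": result.disparity_full,
            "null_mean": np.nan,
            "null_q05": np.nan,
            "percentile_p": np.nan,
        }
    ]
    for name, obs in result.subset_disparities.items():
        null = result.null_distributions[name]
        rows.append(
            {
                "subset": name,
                "n": int(result.subset_sizes.get(name, 0)),
                "n_null_reps": len(null),
                "disparity": obs,
                "null_mean": float(null.mean()),
                "null_q05": float(np.quantile(null, 0.05)),
                "percentile_p": result.percentile_p[name],
            }
        )
    return pd.DataFrame(rows)
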
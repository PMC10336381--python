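"""End-to-end orchestration of the dissection stages.

Thin glue shared by the command-line interface and the scripts: load
inputs from a directory layout (per-locus FASTA, Newick gene trees, K
candidate topologies, clade definitions), run the requested stages, and
write the tabular reports.
"""

from __future__ import annotations

import glob
import logging
import os

import numpy as np
import pandas as pd

from . import export
from .alignment import LocusAlignment, read_alignment
from .config import PipelineConfig, read_clade_file
from .determinants import (
    categorize_factor,
    determinant_scan,
    fit_classification_tree,
)
from .likelihood import compute_gls, gls_rows_to_frame
from .properties import (
    compute_properties,
    records_to_frame,
    subset_by_usefulness,
    usefulness_sort,
)
from .signal import categorize, category_summary, delta_gls, pca_rotate
from .simulate import rng_for
from .treespace import build_treespace, clade_recovery
from .trees import Phylogeny

logger = logging.getLogger(__name__)


def load_inputs(base_dir: str, cfg: PipelineConfig):
    """Read alignments, gene trees, candidate topologies and clades."""
    aln_dir = os.path.join(base_dir, cfg.alignment_dir)
    tree_dir = os.path.join(base_dir, cfg.gene_tree_dir)
    loci = {}
    for path in sorted(glob.glob(os.path.join(aln_dir, "*.fa*"))):
        aln = read_alignment(path, "fasta")
        loci[aln.locus_id] = aln
    gene_trees = {}
    for path in sorted(glob.glob(os.path.join(tree_dir, "*.nwk"))):
        lid = os.path.splitext(os.path.basename(path))[0]
        gene_trees[lid] = Phylogeny.from_file(path)
    if cfg.topology_paths:
        topologies = {
            tid: Phylogeny.from_file(os.path.join(base_dir, p))
            for tid, p in cfg.topology_paths.items()
        }
    else:
        topologies = {
            os.path.splitext(os.path.basename(p))[0]: Phylogeny.from_file(p)
            for p in sorted(glob.glob(os.path.join(base_dir, "T*.nwk")))
        }
    clade_path = os.path.join(base_dir, cfg.clade_file)
    clades = read_clade_file(clade_path) if os.path.exists(clade_path) else {}
    return loci, gene_trees, topologies, clades


def run_gls_stage(
    loci: dict[str, LocusAlignment],
    topologies: dict[str, Phylogeny],
    cfg: PipelineConfig,
):
    """GLS -> ΔGLS -> PCA -> categories; returns (table, pca_summary)."""
    topo_ids = list(topologies)
    rows = compute_gls(
        list(loci.values()), topologies, model_candidates=cfg.model_choices
    )
    table = gls_rows_to_frame(rows, topo_ids)
    table = delta_gls(table, topo_ids)
    pca = pca_rotate(table, topo_ids, focal=cfg.focal_topology_id)
    table = categorize(
        table, topo_ids, focal=cfg.focal_topology_id, threshold=cfg.threshold
    )
    return table, pca


def run_treespace_stage(
    gene_trees: dict[str, Phylogeny],
    subsets: dict[str, list[str]] | None,
    cfg: PipelineConfig,
):
    return build_treespace(
        gene_trees,
        subsets=subsets,
        n_reps=cfg.n_null_reps,
        seed=rng_for(cfg.rng_seed, "treespace_null"),
    )


def run_properties_stage(
    loci: dict[str, LocusAlignment],
    gene_trees: dict[str, Phylogeny],
    reference: Phylogeny | None,
    clades: dict[str, set[str]] | None = None,
):
    records = []
    recovery_rows = []
    for lid, aln in loci.items():
        gt = gene_trees.get(lid)
        records.append(compute_properties(aln, gt, reference))
        if gt is not None and clades:
            rec = clade_recovery(gt, clades, locus_id=lid)
            recovery_rows.append(
                {
                    "locus_id": lid,
                    "proportion_recovered": rec.proportion_recovered,
                    **{f"clade_{k}": v for k, v in rec.status.items()},
                }
            )
    frame = records_to_frame(records)
    recovery = pd.DataFrame(recovery_rows) if recovery_rows else None
    return frame, recovery


def run_determinants_stage(
    scores: np.ndarray,
    table: pd.DataFrame,
    properties: pd.DataFrame,
    cfg: PipelineConfig,
):
    """Vector-fit scan plus the classification tree on the A/B/C factor."""
    merged = table[["locus_id", "category"]].merge(
        properties, on="locus_id", how="inner"
    )
    prop_cols = [c for c in properties.columns if c != "locus_id"]
    scan = determinant_scan(
        scores,
        table[["locus_id"]].merge(properties, on="locus_id", how="left")[
            ["locus_id"] + prop_cols
        ],
        n_perm=cfg.n_permutations,
        seed=int(rng_for(cfg.rng_seed, "vector_fit").integers(2**31)),
    )
    factor = categorize_factor(merged)
    tree = fit_classification_tree(
        merged[["locus_id"] + prop_cols],
        factor,
        alpha=cfg.alpha,
        seed=int(rng_for(cfg.rng_seed, "ctree").integers(2**31)),
    )
    return scan, tree


def run_all(base_dir: str, out_dir: str, cfg: PipelineConfig) -> dict:
    """Full pipeline on a directory of inputs; writes TSV reports."""
    os.makedirs(out_dir, exist_ok=True)
    loci, gene_trees, topologies, clades = load_inputs(base_dir, cfg)
    logger.info(
        "loaded %d loci, %d gene trees, %d topologies",
        len(loci), len(gene_trees), len(topologies),
    )
    table, pca = run_gls_stage(loci, topologies, cfg)
    export.write_tsv(
        export.gls_table(table, pca.scores), os.path.join(out_dir, "gls.tsv")
    )
    export.write_tsv(
        export.category_breakdown(table),
        os.path.join(out_dir, "category_breakdown.tsv"),
    )
    export.write_tsv(
        category_summary(table), os.path.join(out_dir, "category_summary.tsv")
    )

    reference = topologies.get(cfg.focal_topology_id)
    props, recovery = run_properties_stage(loci, gene_trees, reference, clades)
    export.write_tsv(props, os.path.join(out_dir, "properties.tsv"))
    if recovery is not None:
        export.write_tsv(recovery, os.path.join(out_dir, "clade_recovery.tsv"))

    try:
        ranking = usefulness_sort(props)
        subsets = {
            "useful_half": subset_by_usefulness(ranking.ranked_ids, fraction=0.5),
            "useful_quarter": subset_by_usefulness(
                ranking.ranked_ids, fraction=0.25
            ),
        }
    except ValueError as e:
        logger.warning("usefulness ranking unavailable: %s", e)
        ranking, subsets = None, None
    ts = run_treespace_stage(
        {k: v for k, v in gene_trees.items()}, subsets, cfg
    )
    export.write_tsv(
        export.distance_matrix_frame(ts.dissimilarity, ts.ids),
        os.path.join(out_dir, "quartet_distances.tsv"),
    )
    export.write_tsv(
        export.disparity_report(ts), os.path.join(out_dir, "disparity.tsv")
    )

    scan, ctree = run_determinants_stage(pca.scores, table, props, cfg)
    export.write_tsv(scan, os.path.join(out_dir, "determinants.tsv"))
    with open(os.path.join(out_dir, "classification_tree.txt"), "w") as fh:
        fh.write(ctree.to_text())
    export.write_tsv(
        pd.DataFrame(ctree.to_records()),
        os.path.join(out_dir, "classification_tree.tsv"),
    )
    return {
        "table": table,
        "pca": pca,
        "properties": props,
        "ranking": ranking,
        "treespace": ts,
        "determinants": scan,
        "ctree": ctree,
        "recovery": recovery,
    }
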
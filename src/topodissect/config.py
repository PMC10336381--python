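"""Pipeline configuration and seed management.

All randomness flows from a single seed fanned out to named substreams per
stage (`rng_for`), so a full pipeline run is replayable and stages can be
re-run independently without perturbing each other's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .simulate import rng_for  # noqa: F401  (re-exported: the seed fan-out)


@dataclass
class PipelineConfig:
    """Paths and knobs for a full dissection run.

    Defaults follow the study design: a ±2 log-likelihood-unit ΔGLS
    threshold, 1000 subsampling replicates for treespace nulls, and 10 000
    permutations for determinant tests.
    """

    alignment_dir: str = "alignments"
    gene_tree_dir: str = "gene_trees"
    topology_paths: dict[str, str] = field(default_factory=dict)
    clade_file: str = "clades.tsv"
    focal_topology_id: str = "T1"
    threshold: float = 2.0
    n_null_reps: int = 1000
    n_permutations: int = 10_000
    rng_seed: int = 0
    model_choices: list[str] = field(
        default_factory=lambda: ["LG"]
    )
    alpha: float = 0.05

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.n_null_reps < 1 or self.n_permutations < 1:
            raise ValueError("replicate/permutation counts must be >= 1")
        if self.topology_paths and self.focal_topology_id not in self.topology_paths:
            raise ValueError(
                f"focal topology {self.focal_topology_id!r} not among "
                f"supplied topologies {sorted(self.topology_paths)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_clade_file(path) -> dict[str, set[str]]:
    """Parse a two-column 'clade_name TAB taxon' file."""
    clades: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, taxon = line.split("\t")
            clades.setdefault(name, set()).add(taxon)
    for name, members in clades.items():
        if len(members) < 2:
            raise ValueError(
                f"clade {name!r} has {len(members)} member(s); need >= 2 "
                "for monophyly to be testable"
            )
    return clades
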
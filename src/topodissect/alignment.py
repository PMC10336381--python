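"""Per-locus amino-acid alignments.

A locus is a small (typically 100-650 column) amino-acid alignment over a
subset of the study's taxa. Gaps and ambiguity codes are treated as fully
missing: they contribute partial-likelihood vectors of ones and are skipped
when computing compositions and pairwise distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Amino-acid one-letter codes in the conventional (PAML) order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Characters coded as fully missing.  'B', 'Z', 'J' are ambiguity codes,
#: '*' a stop, 'X'/'?' explicit missing, '-'/'.' gaps.
MISSING_CHARS = set("BZJX?*-.")


@dataclass
class LocusAlignment:
    """One gene's amino-acid alignment.

    Parameters
    ----------
    locus_id : str
        Unique locus identifier.
    taxa : list of str
        Taxon labels, unique within the locus.
    sequences : list of str
        Equal-length residue strings aligned with ``taxa``.
    """

    locus_id: str
    taxa: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError(
                f"{self.locus_id}: {len(self.taxa)} taxa but "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.taxa)) != len(self.taxa):
            seen, dup = set(), None
            for t in self.taxa:
                if t in seen:
                    dup = t
                    break
                seen.add(t)
            raise ValueError(f"{self.locus_id}: duplicate taxon label {dup!r}")
        if self.sequences:
            n = len(self.sequences[0])
            for t, s in zip(self.taxa, self.sequences):
                if len(s) != n:
                    raise ValueError(
                        f"{self.locus_id}: sequence for taxon {t!r} has length "
                        f"{len(s)}, expected {n}"
                    )
            if n < 1:
                raise ValueError(f"{self.locus_id}: zero-length alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def likelihood_ready(self) -> bool:
        """At least four taxa are required for meaningful likelihood work."""
        return self.n_taxa >= 4

    def encode(self) -> np.ndarray:
        """Integer-encode: (n_taxa, n_sites), state index or -1 for missing."""
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int8)
        for i, s in enumerate(self.sequences):
            for j, c in enumerate(s):
                out[i, j] = AA_INDEX.get(c, -1)
        return out

    def restrict(self, taxa: list[str]) -> "LocusAlignment":
        """Alignment restricted to ``taxa`` (kept in this alignment's order)."""
        keep = [t for t in self.taxa if t in set(taxa)]
        idx = {t: i for i, t in enumerate(self.taxa)}
        return LocusAlignment(
            self.locus_id,
            keep,
            [self.sequences[idx[t]] for t in keep],
        )

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{s}\n" for t, s in zip(self.taxa, self.sequences))


def _normalize_seq(raw: str, taxon: str, locus_id: str) -> str:
    """Uppercase, unify missing codes; warn once per unknown character."""
    out = []
    for c in raw.upper():
        if c in AA_INDEX:
            out.append(c)
        elif c in "-.":
            out.append("-")
        elif c in MISSING_CHARS:
            out.append("X")
        else:
            logger.warning(
                "%s/%s: unknown residue %r coded as missing", locus_id, taxon, c
            )
            out.append("X")
    return "".join(out)


def read_alignment(path, format: str = "fasta", locus_id: str | None = None) -> LocusAlignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    Residues are case-normalized; ambiguity codes and unknown characters are
    mapped to missing ('X') with a logged warning; gaps are kept as '-'.
    Ragged sequences and duplicate taxon labels raise ``ValueError``.
    """
    path = str(path)
    if locus_id is None:
        import os

        locus_id = os.path.splitext(os.path.basename(path))[0]
    taxa: list[str] = []
    seqs: list[str] = []
    if format == "fasta":
        from Bio import SeqIO

        for rec in SeqIO.parse(path, "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq))
        if not taxa:
            raise ValueError(f"{path}: no FASTA records found")
    elif format in ("phylip-relaxed", "phylip"):
        from Bio import AlignIO

        try:
            msa = AlignIO.read(path, "phylip-relaxed")
        except ValueError as e:
            raise ValueError(f"{path}: failed to parse relaxed PHYLIP: {e}") from e
        for rec in msa:
            taxa.append(rec.id)
            seqs.append(str(rec.seq))
    else:
        raise ValueError(f"unsupported alignment format {format!r}")

    # ragged check with the offending taxon named (FASTA parsing is lenient)
    if seqs:
        n = len(seqs[0])
        for t, s in zip(taxa, seqs):
            if len(s) != n:
                raise ValueError(
                    f"{path}: sequence for taxon {t!r} has length {len(s)}, "
                    f"expected {n}"
                )
    seqs = [_normalize_seq(s, t, locus_id) for t, s in zip(taxa, seqs)]
    return LocusAlignment(locus_id, taxa, seqs)


def write_alignment(aln: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(aln.to_fasta())


def slice_supermatrix(
    supermatrix: LocusAlignment, partitions: list[tuple[str, int, int]]
) -> list[LocusAlignment]:
    """Cut a concatenated alignment into loci.

    ``partitions`` rows are (locus_id, start, end), 1-based inclusive, the
    common partition-table convention.  Taxa entirely missing within a
    partition's columns are dropped from that locus.
    """
    loci = []
    for locus_id, start, end in partitions:
        if not (1 <= start <= end <= supermatrix.n_sites):
            raise ValueError(
                f"partition {locus_id}: range {start}-{end} outside "
                f"1-{supermatrix.n_sites}"
            )
        taxa, seqs = [], []
        for t, s in zip(supermatrix.taxa, supermatrix.sequences):
            sub = s[start - 1 : end]
            if any(c in AA_INDEX for c in sub):
                taxa.append(t)
                seqs.append(sub)
        loci.append(LocusAlignment(locus_id, taxa, seqs))
    return loci


def read_partition_table(path) -> list[tuple[str, int, int]]:
    """Parse 'locus_id TAB start TAB end' rows (1-based, inclusive)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"bad partition row: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return rows
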
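"""Shared domain types and readers/writers for FASTA, Newick and TSV matrices.

The pipeline's in-memory currency is small and explicit: sequence records,
annotation records, labelled distance matrices, gene-family count matrices
(``PanMatrix``) and phylogenetic trees. Trees are carried as
:class:`dendropy.Tree` objects throughout.

Undefined distances (e.g. a saturated TN93 estimate) are carried as ``NaN``
and serialized as the literal ``NA``; they are never silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("pandiverge")

#: Sentinel for undefined distances / rates. Compare with :func:`is_undefined`.
UNDEFINED = math.nan

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NUC_CHARS = frozenset("ACGTN-")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_PROT_CHARS = frozenset(_AA + "X-")

#: dendropy tree type used across the package.
PhyloTree = dendropy.Tree


def is_undefined(x: float) -> bool:
    """True if *x* is the undefined sentinel (NaN)."""
    return isinstance(x, float) and math.isnan(x)


class ParseError(ValueError):
    """Raised on malformed input files."""


@dataclass
class SequenceRecord:
    """One nucleotide or protein sequence.

    Residues are uppercased on construction; characters outside the declared
    alphabet are replaced by ``N`` (nucleotide) or ``X`` (protein) with a
    logged warning — public sequence data is dirty and should not abort a run.
    """

    id: str
    description: str
    residues: str
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown alphabet: {self.alphabet!r}")
        seq = self.residues.upper()
        allowed = _NUC_CHARS if self.alphabet == NUCLEOTIDE else _PROT_CHARS
        if not set(seq) <= allowed:
            repl = "N" if self.alphabet == NUCLEOTIDE else "X"
            bad = sum(1 for c in seq if c not in allowed)
            logger.warning(
                "record %s: %d residue(s) outside %s alphabet replaced by %s",
                self.id, bad, self.alphabet, repl,
            )
            seq = "".join(c if c in allowed else repl for c in seq)
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRecord:
    """Gene annotation: 1-based inclusive coordinates, GenBank style."""

    genome_id: str
    gene_id: str
    product: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


class DistanceMatrix:
    """Symmetric labelled distance matrix; NaN marks undefined entries."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            if np.any(values[~np.isnan(values)] < 0):
                raise ValueError("distances must be non-negative")
        if not np.allclose(np.nan_to_num(values), np.nan_to_num(values.T)):
            raise ValueError("matrix must be symmetric")
        np.fill_diagonal(values, 0.0)
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def has_undefined(self) -> bool:
        off = ~np.eye(len(self), dtype=bool)
        return bool(np.isnan(self.values[off]).any())


class PanMatrix:
    """Gene-family x genome matrix of member counts.

    The pivot between ortholog clustering, rarefaction and gain/loss
    reconstruction. ``counts[f, g]`` is the number of genes of genome ``g``
    in family ``f``; presence/absence is obtained by thresholding at >= 1.
    """

    def __init__(self, family_ids: Sequence[str], genome_ids: Sequence[str],
                 counts: np.ndarray):
        counts = np.asarray(counts, dtype=int)
        family_ids = list(family_ids)
        genome_ids = list(genome_ids)
        if counts.shape != (len(family_ids), len(genome_ids)):
            raise ValueError("counts shape does not match ids")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(family_ids) and np.any(counts.sum(axis=1) == 0):
            raise ValueError("every family must occur in at least one genome")
        if len(set(family_ids)) != len(family_ids):
            raise ValueError("family ids must be unique")
        if len(set(genome_ids)) != len(genome_ids):
            raise ValueError("genome ids must be unique")
        self.family_ids = family_ids
        self.genome_ids = genome_ids
        self.counts = counts

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def presence(self) -> np.ndarray:
        """Boolean family x genome presence matrix."""
        return self.counts >= 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Order is preserved; whitespace inside sequences is stripped and residues
    uppercased. Raises :class:`ParseError` on a file whose first non-blank
    line is not a header, and on duplicate record ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header '>'"
                    )
                break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, desc, str(rec.seq), alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                line_width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at *line_width*."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick tree file (underscores preserved in labels)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise ParseError(f"{path}: not valid Newick: {exc}") from exc
    return tree


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialize a tree as Newick with branch lengths at 10 significant digits."""
    tree.write(
        path=str(path), schema="newick", unquoted_underscores=True,
        suppress_rooting=False, real_value_format_specifier=".10g",
    )


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def write_tsv_matrix(matrix: DistanceMatrix | PanMatrix, path: str | Path) -> None:
    """Write a labelled matrix as TSV.

    Distance matrices print reals at 6 decimals with ``NA`` for undefined
    cells; pan-matrices print integer counts (rows = families, columns =
    genomes).
    """
    with open(path, "w") as fh:
        if isinstance(matrix, DistanceMatrix):
            fh.write("\t" + "\t".join(matrix.labels) + "\n")
            for lab, row in zip(matrix.labels, matrix.values):
                cells = ["NA" if math.isnan(v) else f"{v:.6f}" for v in row]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")
        elif isinstance(matrix, PanMatrix):
            fh.write("family\t" + "\t".join(matrix.genome_ids) + "\n")
            for fam, row in zip(matrix.family_ids, matrix.counts):
                fh.write(fam + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        else:
            raise TypeError(f"cannot serialize {type(matrix).__name__}")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Read back a TSV distance matrix written by :func:`write_tsv_matrix`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")[1:]
            rows.append([math.nan if c == "NA" else float(c) for c in cells])
    return DistanceMatrix(header, np.array(rows))


def read_pan_tsv(path: str | Path) -> PanMatrix:
    """Read back a TSV pan-matrix written by :func:`write_tsv_matrix`."""
    with open(path) as fh:
        genome_ids = fh.readline().rstrip("\n").split("\t")[1:]
        fams, rows = [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            fams.append(cells[0])
            rows.append([int(c) for c in cells[1:]])
    return PanMatrix(fams, genome_ids, np.array(rows, dtype=int))
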
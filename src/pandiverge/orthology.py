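"""Ortholog clustering into gene families and the pan-genome partition.

Mobile-genetic-element genes (transposases, integrases, phage genes, ...)
are flagged by keyword and excluded before clustering — such lineage-specific
expansions would otherwise inflate accessory counts. Remaining proteins are
clustered greedily around length-sorted centroids (USEARCH-style): each
protein joins the first centroid it matches at >= 50% identity over >= 50%
of the shorter sequence, else founds a new family. The family-by-genome
count matrix then partitions into core (all genomes), accessory (>= 2 but
not all) and unique (single genome) families.

Identity is computed from a global alignment with affine gaps under
BLOSUM62, as matches over alignment columns excluding terminal gaps; the
denominator convention matters at the 50% cutoff and is stated here because
identity definitions differ between tools.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_core import AnnotationRecord, PanMatrix, SequenceRecord

DEFAULT_MGE_KEYWORDS = frozenset({
    "transposase", "integrase", "insertion sequence", "is family",
    "phage", "prophage", "recombinase",
})

DEFAULT_IDENTITY_CUTOFF = 50.0
DEFAULT_COVERAGE_CUTOFF = 0.5


@dataclass
class Orthogroup:
    family_id: str
    members: list[tuple[str, str]]        # (genome_id, gene_id)
    representative: str                   # centroid gene id


@dataclass
class PanPartition:
    """Core / accessory / unique split of gene families."""

    core: list[str]
    accessory: list[str]
    unique: dict[str, list[str]]          # genome -> its private families
    core_proportion: dict[str, float]     # per genome: core / families present

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_accessory(self) -> int:
        return len(self.accessory)

    @property
    def unique_counts(self) -> dict[str, int]:
        return {g: len(f) for g, f in self.unique.items()}


def flag_mge(annotations: list[AnnotationRecord],
             keyword_set: frozenset[str] = DEFAULT_MGE_KEYWORDS) -> set[str]:
    """Gene ids whose product matches an MGE keyword (case-insensitive
    substring match)."""
    flagged = set()
    for ann in annotations:
        product = ann.product.lower()
        if any(kw in product for kw in keyword_set):
            flagged.add(ann.gene_id)
    return flagged


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(prot_a: SequenceRecord | str, prot_b: SequenceRecord | str,
                      aligner: PairwiseAligner | None = None,
                      ) -> tuple[float, float]:
    """Percent identity and coverage of the shorter protein.

    Identity = matches / alignment columns excluding terminal gaps;
    coverage = aligned span on the shorter sequence / its length.
    """
    a = prot_a.residues if isinstance(prot_a, SequenceRecord) else prot_a
    b = prot_b.residues if isinstance(prot_b, SequenceRecord) else prot_b
    if not a or not b:
        raise ValueError("empty protein sequence")
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    ta, qa = aln.aligned                       # blocks on a and on b
    if len(ta) == 0:
        return 0.0, 0.0
    paired = sum(int(e - s) for s, e in ta)
    matches = sum(
        sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
        for (sa, ea), (sb, eb) in zip(ta, qa)
    )
    span_a = int(ta[-1][1] - ta[0][0])
    span_b = int(qa[-1][1] - qa[0][0])
    columns = span_a + span_b - paired         # internal gaps counted once
    identity = 100.0 * matches / columns if columns else 0.0
    short_span = span_a if len(a) <= len(b) else span_b
    coverage = short_span / min(len(a), len(b))
    return identity, coverage


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def cluster_orthogroups(
    proteomes: dict[str, list[SequenceRecord]],
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    coverage_cutoff: float = DEFAULT_COVERAGE_CUTOFF,
    exclude: set[str] | None = None,
    min_shared_kmers: int = 2,
) -> list[Orthogroup]:
    """Greedy centroid clustering of all proteomes into gene families.

    Proteins are processed longest-first (ties by lexicographic gene id), so
    the outcome does not depend on the order genomes are supplied in. Each
    protein joins the first (oldest) centroid reaching both cutoffs, else
    founds a new family. A shared-4-mer prefilter skips alignments against
    centroids sharing fewer than ``min_shared_kmers`` distinct 4-mers; a
    pair at the 50% identity cutoff shares ~9 such 4-mers in expectation
    while unrelated proteins share ~0.1, so the filter prunes nearly all
    futile alignments at negligible risk of splitting a genuine family. It
    never merges anything — the alignment still decides.

    Genes listed in *exclude* (e.g. MGE-flagged ids) are left out entirely.
    """
    exclude = exclude or set()
    pool: list[tuple[str, str, str]] = []      # (genome, gene_id, residues)
    for genome in proteomes:
        for rec in proteomes[genome]:
            if rec.id not in exclude:
                pool.append((genome, rec.id, rec.residues))
    pool.sort(key=lambda t: (-len(t[2]), t[1]))

    aligner = _make_aligner()
    groups: list[Orthogroup] = []
    centroid_seqs: list[str] = []
    kmer_index: dict[str, set[int]] = defaultdict(set)

    for genome, gene_id, seq in pool:
        kmers = _kmer_set(seq)
        shared: Counter = Counter()
        for km in kmers:
            for ci in kmer_index.get(km, ()):
                shared[ci] += 1
        candidates = [ci for ci, c in shared.items() if c >= min_shared_kmers]
        joined = False
        for ci in sorted(candidates):
            identity, coverage = pairwise_identity(
                seq, centroid_seqs[ci], aligner)
            if identity >= identity_cutoff and coverage >= coverage_cutoff:
                groups[ci].members.append((genome, gene_id))
                joined = True
                break
        if not joined:
            ci = len(groups)
            groups.append(Orthogroup(
                family_id=f"OG{ci + 1:06d}",
                members=[(genome, gene_id)],
                representative=gene_id,
            ))
            centroid_seqs.append(seq)
            for km in kmers:
                kmer_index[km].add(ci)
    return groups


def build_pan_matrix(orthogroups: list[Orthogroup],
                     genome_ids: list[str]) -> PanMatrix:
    """Family-by-genome member-count matrix from a clustering result."""
    gidx = {g: j for j, g in enumerate(genome_ids)}
    counts = np.zeros((len(orthogroups), len(genome_ids)), dtype=int)
    for i, og in enumerate(orthogroups):
        for genome, _ in og.members:
            if genome not in gidx:
                raise ValueError(f"genome {genome!r} not in genome_ids")
            counts[i, gidx[genome]] += 1
    return PanMatrix([og.family_id for og in orthogroups], genome_ids, counts)


def partition_pangenome(pan_matrix: PanMatrix) -> PanPartition:
    """Classify families as core / accessory / unique by presence pattern."""
    presence = pan_matrix.presence()
    n_genomes = pan_matrix.n_genomes
    n_present = presence.sum(axis=1)
    core, accessory = [], []
    unique: dict[str, list[str]] = {g: [] for g in pan_matrix.genome_ids}
    # with a single genome "in all" and "in one" coincide; call it unique
    for fam, row, k in zip(pan_matrix.family_ids, presence, n_present):
        if k == n_genomes and n_genomes > 1:
            core.append(fam)
        elif k == 1:
            unique[pan_matrix.genome_ids[int(np.argmax(row))]].append(fam)
        else:
            accessory.append(fam)
    n_core = len(core)
    per_genome = presence.sum(axis=0)
    core_prop = {
        g: (n_core / int(t)) if t else 0.0
        for g, t in zip(pan_matrix.genome_ids, per_genome)
    }
    return PanPartition(core, accessory, unique, core_prop)
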
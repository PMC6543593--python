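"""ANIb-style average nucleotide identity and species delineation.

A query genome is cut into consecutive non-overlapping fragments (1,020 bp
by convention); each fragment is aligned to the subject genome by a k-mer
seeded local alignment; fragments whose best hit reaches >= 30% identity
over >= 70% of the fragment length are accepted, and ANI is the mean
identity over accepted fragments. Two genomes are called the same species
when ANI >= 95%.

The fragment aligner seeds with exact 11-mers on both strands and runs a
local alignment (match +1, mismatch -1, gap open -5, gap extend -2) of the
fragment against the seeded subject window. ANI is direction-dependent;
both directions are surfaced, never averaged away silently.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .io_core import UNDEFINED, SequenceRecord, is_undefined

_RC = str.maketrans("ACGTN", "TGCAN")

DEFAULT_FRAGMENT_LENGTH = 1020
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_FRAG_COVERAGE = 0.70
SPECIES_ANI_THRESHOLD = 95.0


@dataclass
class AniResult:
    query_id: str
    subject_id: str
    mean_identity: float          # percent, NaN when no fragment accepted
    fragments_total: int
    fragments_accepted: int


@dataclass
class FragmentHit:
    identity: float               # percent over alignment columns
    aligned_fraction: float       # aligned span / fragment length
    strand: str                   # '+' or '-'
    score: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _as_contigs(genome) -> list[str]:
    if isinstance(genome, str):
        contigs = [genome]
    elif isinstance(genome, SequenceRecord):
        contigs = [genome.residues]
    else:
        contigs = [r.residues if isinstance(r, SequenceRecord) else r
                   for r in genome]
    contigs = [c.upper() for c in contigs if c]
    if not contigs:
        raise ValueError("empty genome")
    return contigs


def fragment_genome(genome, fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                    ) -> list[str]:
    """Cut each contig into consecutive non-overlapping windows.

    The trailing window is kept only if it is at least half the fragment
    length — shorter tails contribute too little alignable sequence and
    would distort the mean.
    """
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    fragments: list[str] = []
    for contig in _as_contigs(genome):
        for start in range(0, len(contig), fragment_length):
            frag = contig[start:start + fragment_length]
            if len(frag) >= 0.5 * fragment_length:
                fragments.append(frag)
    return fragments


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


class SubjectIndex:
    """k-mer position index over a subject genome (contigs concatenated with
    an N spacer so seeds and alignments cannot meaningfully bridge contigs)."""

    def __init__(self, genome, k: int = 11):
        self.k = k
        self.sequence = ("N" * 20).join(_as_contigs(genome))
        self.positions: dict[str, list[int]] = defaultdict(list)
        seq = self.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                self.positions[kmer].append(i)

    def seed_diagonals(self, fragment: str) -> list[int]:
        diags = []
        k = self.k
        for f in range(0, len(fragment) - k + 1):
            kmer = fragment[f:f + k]
            for p in self.positions.get(kmer, ()):
                diags.append(p - f)
        return diags


def _cluster_diagonals(diags: list[int], gap: int = 150) -> list[tuple[int, int, int]]:
    """Group nearby diagonals; return (lo, hi, n_seeds) sorted by seed count."""
    diags = sorted(diags)
    clusters = []
    lo = hi = diags[0]
    n = 1
    for d in diags[1:]:
        if d - hi <= gap:
            hi = d
            n += 1
        else:
            clusters.append((lo, hi, n))
            lo = hi = d
            n = 1
    clusters.append((lo, hi, n))
    clusters.sort(key=lambda c: -c[2])
    return clusters


def align_fragment(fragment: str, subject: "SubjectIndex | str",
                   max_candidates: int = 4) -> Optional[FragmentHit]:
    """Best local alignment of a fragment against a subject genome.

    Seeds on both strands locate candidate subject windows; candidates are
    tried in decreasing seed-count order and the best-scoring local
    alignment is returned, or ``None`` when no seed is found anywhere.
    Once a near-full-length hit exists, remaining near-seedless candidates
    (chance 11-mer matches) are not aligned.
    """
    if not isinstance(subject, SubjectIndex):
        subject = SubjectIndex(subject)
    aligner = _make_aligner()
    pad = 100
    seq = subject.sequence

    candidates: list[tuple[int, str, str, int, int]] = []
    for strand, frag in (("+", fragment), ("-", reverse_complement(fragment))):
        diags = subject.seed_diagonals(frag)
        if diags:
            for lo, hi, n in _cluster_diagonals(diags)[:max_candidates]:
                candidates.append((n, strand, frag, lo, hi))
    candidates.sort(key=lambda c: -c[0])

    best: Optional[FragmentHit] = None
    for n_seeds, strand, frag, lo, hi in candidates[:2 * max_candidates]:
        if best is not None and best.aligned_fraction >= 0.9 and n_seeds < 3:
            break
        wstart = max(0, lo - pad)
        wend = min(len(seq), hi + len(frag) + pad)
        window = seq[wstart:wend]
        alignments = aligner.align(window, frag)
        try:
            aln = alignments[0]
        except IndexError:
            continue
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            continue
        qblocks = aln.aligned[1]
        span = qblocks[-1][1] - qblocks[0][0]
        hit = FragmentHit(
            identity=100.0 * counts.identities / columns,
            aligned_fraction=span / len(fragment),
            strand=strand,
            score=float(aln.score),
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def anib(query_genome, subject_genome,
         query_id: str = "query", subject_id: str = "subject",
         fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
         min_identity: float = DEFAULT_MIN_IDENTITY,
         min_frag_coverage: float = DEFAULT_MIN_FRAG_COVERAGE) -> AniResult:
    """One-directional ANIb: mean identity of accepted query fragments
    against the subject. Undefined (NaN) when no fragment is accepted."""
    if isinstance(query_genome, SequenceRecord):
        query_id = query_genome.id
    if isinstance(subject_genome, SequenceRecord):
        subject_id = subject_genome.id
    fragments = fragment_genome(query_genome, fragment_length)
    index = SubjectIndex(subject_genome)
    identities = []
    for frag in fragments:
        hit = align_fragment(frag, index)
        if hit is None:
            continue
        if hit.identity >= min_identity and hit.aligned_fraction >= min_frag_coverage:
            identities.append(hit.identity)
    mean = float(np.mean(identities)) if identities else UNDEFINED
    return AniResult(query_id, subject_id, mean, len(fragments), len(identities))


def species_call(ani_result: AniResult,
                 threshold: float = SPECIES_ANI_THRESHOLD) -> str:
    """Species delineation at the conventional 95% ANI threshold
    (same species iff mean identity >= threshold)."""
    if is_undefined(ani_result.mean_identity):
        return "undefined"
    return ("same_species" if ani_result.mean_identity >= threshold
            else "different_species")


def anib_matrix(genomes: dict[str, object], **kwargs) -> pd.DataFrame:
    """All ordered pairs: rows are queries, columns subjects. The two
    directions of a pair generally differ slightly and both are reported."""
    ids = list(genomes)
    out = pd.DataFrame(np.full((len(ids), len(ids)), math.nan),
                       index=ids, columns=ids)
    indexes = {g: SubjectIndex(genomes[g]) for g in ids}
    for q in ids:
        for s in ids:
            if q == s:
                out.loc[q, s] = 100.0
                continue
            fragments = fragment_genome(genomes[q],
                                        kwargs.get("fragment_length",
                                                   DEFAULT_FRAGMENT_LENGTH))
            identities = []
            for frag in fragments:
                hit = align_fragment(frag, indexes[s])
                if (hit is not None
                        and hit.identity >= kwargs.get("min_identity",
                                                       DEFAULT_MIN_IDENTITY)
                        and hit.aligned_fraction >= kwargs.get(
                            "min_frag_coverage", DEFAULT_MIN_FRAG_COVERAGE)):
                    identities.append(hit.identity)
            if identities:
                out.loc[q, s] = float(np.mean(identities))
    return out
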
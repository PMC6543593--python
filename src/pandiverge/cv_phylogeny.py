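"""Composition-vector (K-tuple) alignment-free phylogeny of proteomes.

Each genome's proteome is summarized by the frequencies of amino-acid
K-tuples (K = 6 by default; windows never span protein boundaries). A
(K-2)-order Markov background

    f0(a1..aK) = f(a1..a_{K-1}) * f(a2..aK) / f(a2..a_{K-1})

is subtracted to suppress shared compositional and low-order signal, leaving
the normalized deviations a(t) = (f(t) - f0(t)) / f0(t) (a(t) = 0 where
f0(t) = 0). The distance between two genomes is (1 - C)/2, where C is the
cosine between their deviation vectors over the union of tuples — 0 for
identical composition, 1/2 for orthogonal, 1 for anti-parallel.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .io_core import DistanceMatrix, SequenceRecord


@dataclass
class CompositionVector:
    genome_id: str
    K: int
    components: dict[str, float]

    def norm(self) -> float:
        return float(np.sqrt(sum(v * v for v in self.components.values())))


def _sequences(proteome) -> list[str]:
    return [r.residues if isinstance(r, SequenceRecord) else r
            for r in proteome]


def ktuple_counts(proteome, K: int) -> tuple[Counter, int]:
    """Counts of all K-tuples over a proteome and the total window count.

    Windows are taken within each protein only (tuples never bridge two
    proteins). Raises if every protein is shorter than K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    counts: Counter = Counter()
    total = 0
    for seq in _sequences(proteome):
        for i in range(len(seq) - K + 1):
            counts[seq[i:i + K]] += 1
            total += 1
    if total == 0:
        raise ValueError(f"no protein of length >= K={K} in proteome")
    return counts, total


def markov_expected(counts_k: tuple[Counter, int],
                    counts_km1: tuple[Counter, int],
                    counts_km2: tuple[Counter, int]) -> dict[str, float]:
    """Expected K-tuple frequencies under the (K-2)-order Markov background.

    Returns f0 for every tuple with a positive expectation — i.e. every
    combination of an observed (K-1)-prefix and (K-1)-suffix overlapping in
    an observed (K-2)-mer — with 0 implied elsewhere.
    """
    ck, nk = counts_k
    c1, n1 = counts_km1
    c2, n2 = counts_km2
    by_suffix: dict[str, list[str]] = defaultdict(list)   # mid -> prefixes
    by_prefix: dict[str, list[str]] = defaultdict(list)   # mid -> suffixes
    for t in c1:
        by_suffix[t[1:]].append(t)
        by_prefix[t[:-1]].append(t)
    f0: dict[str, float] = {}
    for mid, c_mid in c2.items():
        prefixes = by_prefix.get(mid)
        suffixes = by_suffix.get(mid)
        if not prefixes or not suffixes:
            continue
        f_mid = c_mid / n2
        for p in prefixes:
            fp = c1[p] / n1
            for s in suffixes:
                fs = c1[s] / n1
                f0[p + s[-1]] = fp * fs / f_mid
    return f0


def cv_vector(proteome, genome_id: str = "", K: int = 6) -> CompositionVector:
    """Normalized K-tuple deviation vector a(t) = (f - f0)/f0 for a proteome."""
    if K < 3:
        raise ValueError("K must be >= 3 (needs K-1 and K-2 marginals)")
    ck, nk = ktuple_counts(proteome, K)
    c1 = ktuple_counts(proteome, K - 1)
    c2 = ktuple_counts(proteome, K - 2)
    f0 = markov_expected((ck, nk), c1, c2)
    components = {}
    for t, exp in f0.items():
        if exp <= 0:
            continue
        f = ck.get(t, 0) / nk
        components[t] = (f - exp) / exp
    return CompositionVector(genome_id, K, components)


def cv_cosine(u: CompositionVector, v: CompositionVector) -> float:
    """Cosine of the angle between two deviation vectors over the tuple union."""
    if u.K != v.K:
        raise ValueError("vectors must share the same K")
    nu, nv = u.norm(), v.norm()
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm composition vector")
    small, large = (u.components, v.components) \
        if len(u.components) <= len(v.components) else (v.components, u.components)
    dot = sum(val * large[t] for t, val in small.items() if t in large)
    return dot / (nu * nv)


def cv_distance_matrix(vectors: list[CompositionVector]) -> DistanceMatrix:
    """Pairwise CV distances d = (1 - cosine)/2 in [0, 1]."""
    if len(vectors) < 2:
        raise ValueError("need >= 2 composition vectors")
    labels = [v.genome_id for v in vectors]
    n = len(vectors)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = cv_cosine(vectors[i], vectors[j])
            d = (1.0 - c) / 2.0
            d = min(max(d, 0.0), 1.0)          # guard rounding at the ends
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
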
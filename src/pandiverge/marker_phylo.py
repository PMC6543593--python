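"""Marker-gene (16S-style) phylogeny pipeline.

Length/redundancy filtering, pairwise TN93 distances with an explicit
saturation check (transitions vs. transversions), neighbor-joining tree
building, and outgroup rooting.

The TN93 estimator distinguishes the two transition classes — P1 is the
proportion of sites differing A<->G, P2 the proportion differing C<->T —
from the transversion proportion Q, with unequal base frequencies. When a
logarithm argument of the closed form is non-positive the pair is beyond
the estimator's reach and the distance is reported as the undefined
sentinel rather than a number.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_core import (
    UNDEFINED, DistanceMatrix, PhyloTree, SequenceRecord, is_undefined,
)

logger = logging.getLogger("pandiverge")

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SubstitutionSummary:
    """Pairwise substitution proportions over comparable sites.

    P1: A<->G differences; P2: C<->T differences; Q: transversion
    differences — all as proportions of ``sites_used``. Base frequencies
    are averaged over the two sequences at the used sites.
    """

    P1: float
    P2: float
    Q: float
    base_freqs: tuple[float, float, float, float]
    sites_used: int

    def __post_init__(self) -> None:
        if min(self.P1, self.P2, self.Q) < 0 or self.P1 + self.P2 + self.Q > 1 + 1e-12:
            raise ValueError("invalid substitution proportions")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped_length: int
    n_dropped_duplicate: int


@dataclass
class SaturationReport:
    """Per-pair transition/transversion proportions and the overall verdict.

    A pair counts as saturated when transversion differences reach or exceed
    transition differences (``v >= s``), excluding identical pairs (s = v = 0).
    The alignment verdict is ``saturated`` when at least half of all pairs
    are saturated — an operationalization of the usual visual
    transitions-vs-distance diagnostic.
    """

    rows: list[tuple[str, str, float, float, float]]  # (a, b, s, v, tn93)
    saturated_fraction: float
    verdict: str


def filter_marker_sequences(
    records: list[SequenceRecord], min_len: int = 1300, max_len: int = 1550,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Keep records with min_len <= length <= max_len (bounds inclusive) and
    drop exact duplicate sequences, keeping the first occurrence."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept: list[SequenceRecord] = []
    seen: set[str] = set()
    n_len = n_dup = 0
    for rec in records:
        if not (min_len <= len(rec) <= max_len):
            n_len += 1
            continue
        if rec.residues in seen:
            n_dup += 1
            continue
        seen.add(rec.residues)
        kept.append(rec)
    return kept, FilterReport(len(records), len(kept), n_len, n_dup)


def pairwise_substitution_proportions(
    seq_a: SequenceRecord | str, seq_b: SequenceRecord | str,
) -> SubstitutionSummary:
    """Count A<->G, C<->T and transversion differences between two aligned
    sequences, excluding any site with a gap or ambiguity in either
    (pairwise deletion)."""
    a = seq_a.residues if isinstance(seq_a, SequenceRecord) else seq_a.upper()
    b = seq_b.residues if isinstance(seq_b, SequenceRecord) else seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ia = np.array([_IDX.get(c, -1) for c in a], dtype=np.int8)
    ib = np.array([_IDX.get(c, -1) for c in b], dtype=np.int8)
    usable = (ia >= 0) & (ib >= 0)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    ua, ub = ia[usable], ib[usable]
    diff = ua != ub
    pair_min = np.minimum(ua, ub)
    pair_max = np.maximum(ua, ub)
    p1 = int((diff & (pair_min == 0) & (pair_max == 2)).sum())  # A<->G
    p2 = int((diff & (pair_min == 1) & (pair_max == 3)).sum())  # C<->T
    q = int(diff.sum()) - p1 - p2
    freqs = tuple(
        float(((ua == k).sum() + (ub == k).sum()) / (2 * n)) for k in range(4)
    )
    return SubstitutionSummary(p1 / n, p2 / n, q / n, freqs, n)


def tn93_distance(summary: SubstitutionSummary) -> float:
    """Closed-form TN93 distance from pairwise substitution proportions.

    Returns the undefined sentinel (NaN) when a required base-frequency
    class is empty or any logarithm argument is non-positive (the estimator
    is saturated for that pair).
    """
    pa, pc, pg, pt = summary.base_freqs
    pr, py = pa + pg, pc + pt
    p1, p2, q = summary.P1, summary.P2, summary.Q
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    if min(pa * pg, pc * pt, pr, py) <= 0:
        logger.warning("TN93 undefined: empty base-frequency class")
        return UNDEFINED
    w1 = 1.0 - pr * p1 / (2 * pa * pg) - q / (2 * pr)
    w2 = 1.0 - py * p2 / (2 * pc * pt) - q / (2 * py)
    w3 = 1.0 - q / (2 * pr * py)
    if min(w1, w2, w3) <= 0:
        return UNDEFINED
    k1 = 2 * pa * pg / pr
    k2 = 2 * pc * pt / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    return -(k1 * math.log(w1) + k2 * math.log(w2) + k3 * math.log(w3))


def tn93_distance_matrix(alignment: list[SequenceRecord]) -> DistanceMatrix:
    """All-pairs TN93 distances; undefined pairs carried as NaN."""
    labels = [r.id for r in alignment]
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = tn93_distance(
            pairwise_substitution_proportions(alignment[i], alignment[j]))
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def saturation_assessment(alignment: list[SequenceRecord]) -> SaturationReport:
    """Transitions-vs-transversions saturation diagnostic over all pairs."""
    if len(alignment) < 2:
        raise ValueError("saturation assessment needs >= 2 sequences")
    rows = []
    n_sat = 0
    for ra, rb in itertools.combinations(alignment, 2):
        s = pairwise_substitution_proportions(ra, rb)
        ts, tv = s.P1 + s.P2, s.Q
        d = tn93_distance(s)
        rows.append((ra.id, rb.id, ts, tv, d))
        if tv >= ts and (ts > 0 or tv > 0):
            n_sat += 1
    frac = n_sat / len(rows)
    verdict = "not_saturated" if frac < 0.5 else "saturated"
    return SaturationReport(rows, frac, verdict)


def plot_saturation(report: SaturationReport, path: str) -> None:
    """Scatter of transition/transversion proportions against TN93 distance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = [r[4] for r in report.rows if not is_undefined(r[4])]
    s = [r[2] for r in report.rows if not is_undefined(r[4])]
    v = [r[3] for r in report.rows if not is_undefined(r[4])]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d, s, marker="x", s=14, label="transitions")
    ax.scatter(d, v, marker="^", s=14, facecolors="none",
               edgecolors="tab:orange", label="transversions")
    ax.set_xlabel("TN93 distance")
    ax.set_ylabel("proportion of sites")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Produces an unrooted tree (trifurcating at the seed node). Ties in the
    Q-criterion are broken by the lexicographically smallest label pair so
    the output is reproducible; negative branch lengths are clamped to zero
    with a warning.

    On an additive distance matrix the generating topology and branch
    lengths are recovered exactly.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if matrix.has_undefined():
        raise ValueError(
            "distance matrix contains undefined entries; drop those taxa first")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    d = matrix.values.astype(float).copy()
    nodes: list[dendropy.Node] = []
    labels = list(matrix.labels)
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(lab)
        nodes.append(node)

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            if x < -1e-12:
                logger.warning("NJ: negative branch length %.3g on %s--%s "
                               "clamped to 0", x, a, b)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        qmat = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        qmin = qmat.min()
        ties = np.argwhere(np.isclose(qmat, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in ties if i < j
        )
        _, i, j = best
        lij = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lji = d[i, j] - lij
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(lij, labels[i], labels[j])
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lji, labels[j], labels[i])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(best[0])]

    # final three nodes joined at the (trifurcating) seed node
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    root = tree.seed_node
    for node, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        root.add_child(node)
        node.edge.length = clamp(length, "", "")
    tree.update_taxon_namespace()
    return tree


def root_by_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root the tree on the edge subtending the outgroup leaf, placing the
    root at the midpoint of that edge. The input tree is not modified."""
    rooted = tree.clone(depth=1)
    leaf = None
    for node in rooted.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == outgroup_label:
            leaf = node
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    total = leaf.edge.length or 0.0
    rooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
    rooted.is_rooted = True
    root = rooted.seed_node
    for child in root.child_nodes():
        child.edge.length = total / 2.0
    return rooted
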
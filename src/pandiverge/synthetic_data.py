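"""Synthetic clade generator with known ground truth.

Emulates the data structure of a small bacterial clade study: a rooted
(Yule) species tree; gene-family content evolving by gain/loss along its
branches (gains found brand-new families — the infinite-alleles regime of an
open pan-genome; a lost family is never regained, which keeps the parsimony
ground truth well defined); a gapless marker-gene alignment evolved under
the TN93 substitution model; per-genome proteomes whose within-family
identity decays with tree distance; and whole-genome nucleotide sequences
for average-nucleotide-identity work.

Every stage is driven by a numpy Generator derived from ``config.seed``, so
an identical configuration reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
from scipy.linalg import expm

from .io_core import (
    NUCLEOTIDE, PROTEIN, AnnotationRecord, PanMatrix, PhyloTree,
    SequenceRecord, write_fasta, write_newick, write_tsv_matrix,
)

_NUC = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

MGE_PRODUCTS = (
    "IS3 family transposase",
    "integrase core domain protein",
    "phage tail fiber protein",
    "site-specific recombinase",
)
_BENIGN_PRODUCTS = (
    "hypothetical protein",
    "carbonic anhydrase",
    "sulfur oxidation protein SoxB",
    "ABC transporter permease",
    "50S ribosomal protein L2",
)


@dataclass
class TN93Params:
    """TN93 substitution-model parameters.

    ``kappa1``/``kappa2`` are the A<->G and C<->T transition rates relative
    to the transversion rate. Defaults are 16S-like: purine-rich stationary
    composition and a strong transition bias.
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.23, 0.31, 0.21)
    kappa1: float = 4.0
    kappa2: float = 8.0
    transversion: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if min(self.base_freqs) <= 0:
            raise ValueError("base frequencies must be positive")
        if min(self.kappa1, self.kappa2, self.transversion) < 0:
            raise ValueError("rates must be non-negative")

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix (order A,C,G,T) scaled to one expected substitution
        per site per unit branch length."""
        pi = np.asarray(self.base_freqs)
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pair = {i, j}
                if pair == {0, 2}:        # A<->G
                    rate = self.kappa1
                elif pair == {1, 3}:      # C<->T
                    rate = self.kappa2
                else:
                    rate = self.transversion
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic clade.

    Rates are events per unit branch length: ``gain_rate`` for the whole
    family pool (Poisson arrivals of new families), ``loss_rate`` per extant
    family (exponential survival). ``protein_identity_decay`` is the
    per-site amino-acid substitution rate, so two leaves at tree distance t
    share roughly ``exp(-decay * t)`` identity within a family.
    """

    n_genomes: int = 10
    tree_mode: str = "random_yule"            # or "fixed_newick"
    fixed_newick: Optional[str] = None
    tree_height: float = 1.0                  # root-to-tip depth after rescaling
    root_family_count: int = 200
    gain_rate: float = 30.0
    loss_rate: float = 0.1
    marker_length: int = 1500
    marker_rate: float = 0.1    # marker substitutions/site per unit tree distance
    tn93: TN93Params = field(default_factory=TN93Params)
    protein_identity_decay: float = 0.15
    protein_length_range: tuple[int, int] = (120, 250)
    mge_fraction: float = 0.0
    genome_length: int = 50_000
    genome_divergence_rate: float = 0.02      # nucleotide subs/site/unit branch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ValueError("n_genomes must be >= 3")
        if self.root_family_count < 1:
            raise ValueError("root_family_count must be >= 1")
        if min(self.gain_rate, self.loss_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.marker_length < 100:
            raise ValueError("marker_length must be >= 100")
        if self.tree_mode not in ("random_yule", "fixed_newick"):
            raise ValueError(f"unknown tree_mode: {self.tree_mode!r}")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the synthetic data."""

    true_tree: PhyloTree
    branch_events: dict[str, tuple[int, int]]       # child label -> (gains, losses)
    membership: dict[str, dict[str, list[str]]]     # family -> genome -> gene ids
    family_origin: dict[str, str]                   # family -> node label of gain
    node_families: dict[str, list[str]]             # node label -> families present
    marker_alignment: list[SequenceRecord]
    seed: int = 0


@dataclass
class SimulationResult:
    tree: PhyloTree
    truth: TruthRecord
    pan_matrix: PanMatrix
    marker_alignment: list[SequenceRecord]
    proteomes: dict[str, list[SequenceRecord]]
    annotations: list[AnnotationRecord]
    genomes: dict[str, SequenceRecord]
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _label_nodes(tree: PhyloTree) -> None:
    """Give every unlabelled internal node a stable preorder label N1, N2, ...
    (skipping labels already taken)."""
    taken = {node_name(n) for n in tree.preorder_node_iter()}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label:
            continue
        i += 1
        while f"N{i}" in taken:
            i += 1
        node.label = f"N{i}"
        taken.add(f"N{i}")


def node_name(node: dendropy.Node) -> str:
    """Leaf taxon label or internal node label."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> PhyloTree:
    """Rooted binary tree with ``n_genomes`` leaves.

    ``random_yule`` grows a pure-birth (rate 1) tree and rescales it so the
    root-to-tip depth equals ``tree_height``; ``fixed_newick`` returns the
    supplied tree unchanged. Deterministic under a fixed seed.
    """
    if config.tree_mode == "fixed_newick":
        if not config.fixed_newick:
            raise ValueError("fixed_newick mode requires a newick string")
        tree = dendropy.Tree.get(
            data=config.fixed_newick, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        _label_nodes(tree)
        return tree

    rng = rng if rng is not None else _stage_rng(config, 1)
    n = config.n_genomes
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    t = 0.0
    root = tree.seed_node
    birth: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[child] = 0.0
        active.append(child)
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        node = active.pop(idx)
        node.edge.length = t - birth.pop(node)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / n)
    for i, node in enumerate(active):
        node.edge.length = t - birth[node]
    # deterministic leaf labels in tree traversal order
    width = len(str(n))
    for i, leaf in enumerate(tree.leaf_node_iter(), 1):
        taxon = taxa.new_taxon(f"G{i:0{width}d}")
        leaf.taxon = taxon
    scale = config.tree_height / t
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    root.edge.length = None
    _label_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# Gene content
# ---------------------------------------------------------------------------

def simulate_gene_content(
    tree: PhyloTree, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PanMatrix, TruthRecord]:
    """Evolve gene-family presence along the tree.

    Per branch of length L, each extant family survives with probability
    ``exp(-loss_rate * L)`` and ``Poisson(gain_rate * L)`` brand-new families
    arrive. Returns the leaf presence matrix and the full event history.
    """
    rng = rng if rng is not None else _stage_rng(config, 2)
    counter = config.root_family_count
    root_label = node_name(tree.seed_node)
    fam_width = 6
    root_families = [f"F{i:0{fam_width}d}" for i in range(1, counter + 1)]
    node_families: dict[str, list[str]] = {root_label: root_families}
    family_origin = {f: root_label for f in root_families}
    branch_events: dict[str, tuple[int, int]] = {}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        label = node_name(node)
        length = node.edge.length or 0.0
        parent_fams = node_families[node_name(node.parent_node)]
        keep = rng.random(len(parent_fams)) < np.exp(-config.loss_rate * length)
        survivors = [f for f, k in zip(parent_fams, keep) if k]
        n_gain = int(rng.poisson(config.gain_rate * length))
        gained = [f"F{counter + i:0{fam_width}d}" for i in range(1, n_gain + 1)]
        counter += n_gain
        for f in gained:
            family_origin[f] = label
        node_families[label] = survivors + gained
        branch_events[label] = (n_gain, len(parent_fams) - len(survivors))

    leaves = sorted(node_name(l) for l in tree.leaf_node_iter())
    membership: dict[str, dict[str, list[str]]] = {}
    for g in leaves:
        for f in node_families[g]:
            membership.setdefault(f, {}).setdefault(g, []).append(f"{g}:{f}")
    families = sorted(membership)
    counts = np.zeros((len(families), len(leaves)), dtype=int)
    for i, f in enumerate(families):
        for j, g in enumerate(leaves):
            counts[i, j] = len(membership[f].get(g, ()))
    pan = PanMatrix(families, leaves, counts)
    truth = TruthRecord(
        true_tree=tree, branch_events=branch_events, membership=membership,
        family_origin=family_origin, node_families=node_families,
        marker_alignment=[], seed=config.seed,
    )
    return pan, truth


# ---------------------------------------------------------------------------
# Marker alignment
# ---------------------------------------------------------------------------

def _evolve_states(parent: np.ndarray, pmat: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(pmat, axis=1)
    r = rng.random(parent.shape[0])
    return (r[:, None] >= cum[parent]).sum(axis=1).astype(np.int8)


def simulate_marker_alignment(
    tree: PhyloTree, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SequenceRecord]:
    """Gapless marker alignment evolved under TN93 along the tree.

    The root sequence is drawn from the stationary base frequencies; each
    branch applies the matrix exponential of the scaled TN93 rate matrix.
    Branch lengths are multiplied by ``marker_rate`` — a conserved marker
    gene accumulates far fewer substitutions than the genome-wide
    divergence the tree is scaled in. One sequence per genome, sorted by
    leaf label.
    """
    rng = rng if rng is not None else _stage_rng(config, 3)
    q = config.tn93.rate_matrix() * config.marker_rate
    pi = np.asarray(config.tn93.base_freqs)
    root_states = rng.choice(4, size=config.marker_length, p=pi).astype(np.int8)
    states = {node_name(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        pmat = expm(q * (node.edge.length or 0.0))
        states[node_name(node)] = _evolve_states(
            states[node_name(node.parent_node)], pmat, rng)
    nuc = np.frombuffer(_NUC.encode(), dtype=np.uint8)
    records = []
    for leaf in sorted(tree.leaf_node_iter(), key=node_name):
        lab = node_name(leaf)
        seq = nuc[states[lab]].tobytes().decode()
        records.append(SequenceRecord(lab, "synthetic marker gene", seq, NUCLEOTIDE))
    return records


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------

def _mutate_protein(seq: np.ndarray, p: float,
                    rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.shape[0]) < p
    if mask.any():
        # shift by 1..19 mod 20 => always a different residue
        out[mask] = (out[mask] + rng.integers(1, 20, mask.sum())) % 20
    return out


def simulate_proteomes(
    tree: PhyloTree, truth: TruthRecord, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[SequenceRecord]], list[AnnotationRecord]]:
    """One protein per gene, evolved from a random family ancestor.

    Sequences mutate by i.i.d. site substitution (no indels) at rate
    ``protein_identity_decay`` per unit branch length from the family's gain
    node downward, so within-family percent identity is analytically
    controllable. A ``mge_fraction`` of each genome's genes is annotated
    with mobile-genetic-element product strings for exclusion testing.
    """
    rng = rng if rng is not None else _stage_rng(config, 4)
    lo, hi = config.protein_length_range
    nodes = {node_name(n): n for n in tree.preorder_node_iter()}
    preorder = [node_name(n) for n in tree.preorder_node_iter()]
    order_idx = {lab: i for i, lab in enumerate(preorder)}
    proteomes: dict[str, list[SequenceRecord]] = {
        g: [] for g in sorted(n for n in preorder if nodes[n].is_leaf())
    }
    aa = np.frombuffer(_AA.encode(), dtype=np.uint8)

    for fam in sorted(truth.family_origin):
        origin = truth.family_origin[fam]
        present = {
            lab for lab, fams in truth.node_families.items() if fam in fams
        }
        if not present & set(proteomes):
            continue    # family lost before reaching any leaf
        length = int(rng.integers(lo, hi + 1))
        seqs = {origin: rng.integers(0, 20, length)}
        for lab in preorder:
            if lab == origin or lab not in present:
                continue
            node = nodes[lab]
            parent = node_name(node.parent_node)
            if parent not in seqs:
                continue
            p = 1.0 - np.exp(-config.protein_identity_decay
                             * (node.edge.length or 0.0))
            seqs[lab] = _mutate_protein(seqs[parent], p, rng)
        for g in sorted(present & set(proteomes)):
            gene_id = f"{g}:{fam}"
            residues = aa[seqs[g]].tobytes().decode()
            proteomes[g].append(
                SequenceRecord(gene_id, f"family {fam}", residues, PROTEIN))

    annotations: list[AnnotationRecord] = []
    for g, records in proteomes.items():
        n_mge = int(round(config.mge_fraction * len(records)))
        mge_idx = set(
            rng.choice(len(records), size=n_mge, replace=False).tolist()
        ) if n_mge else set()
        pos = 1
        for i, rec in enumerate(records):
            if i in mge_idx:
                product = MGE_PRODUCTS[i % len(MGE_PRODUCTS)]
            else:
                product = _BENIGN_PRODUCTS[i % len(_BENIGN_PRODUCTS)]
            span = 3 * len(rec.residues)
            annotations.append(AnnotationRecord(
                genome_id=g, gene_id=rec.id, product=product,
                start=pos, end=pos + span - 1,
                strand="+" if i % 2 == 0 else "-",
            ))
            pos += span + 50
    return proteomes, annotations


# ---------------------------------------------------------------------------
# Whole genomes (for ANI)
# ---------------------------------------------------------------------------

def random_genome(length: int, rng: np.random.Generator,
                  gc: float = 0.5) -> str:
    """I.i.d. random nucleotide sequence at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    nuc = np.frombuffer(_NUC.encode(), dtype=np.uint8)
    return nuc[rng.choice(4, size=length, p=p)].tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability *rate* (to a different base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = {ord(c): i for i, c in enumerate(_NUC)}
    states = np.array([idx.get(b, 0) for b in arr], dtype=np.int64)
    mask = rng.random(len(arr)) < rate
    states[mask] = (states[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    nuc = np.frombuffer(_NUC.encode(), dtype=np.uint8)
    return nuc[states].tobytes().decode()


def simulate_genomes(
    tree: PhyloTree, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, SequenceRecord]:
    """Whole-genome nucleotide sequences evolved by per-site substitution.

    A single random ancestral chromosome diverges along the tree at
    ``genome_divergence_rate`` substitutions per site per unit branch, giving
    the clade an interpretable average-nucleotide-identity structure.
    """
    rng = rng if rng is not None else _stage_rng(config, 5)
    seqs = {node_name(tree.seed_node): random_genome(config.genome_length, rng)}
    out: dict[str, SequenceRecord] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lab = node_name(node)
        length = node.edge.length or 0.0
        p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * config.genome_divergence_rate
                                 * length))
        seqs[lab] = mutate_sequence(seqs[node_name(node.parent_node)], p, rng)
        if node.is_leaf():
            out[lab] = SequenceRecord(lab, "synthetic chromosome",
                                      seqs[lab], NUCLEOTIDE)
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulationResult:
    """Run all stages and bundle the outputs with their ground truth."""
    tree = simulate_tree(config)
    pan, truth = simulate_gene_content(tree, config)
    marker = simulate_marker_alignment(tree, config)
    truth.marker_alignment = marker
    proteomes, annotations = simulate_proteomes(tree, truth, config)
    genomes = simulate_genomes(tree, config)
    return SimulationResult(
        tree=tree, truth=truth, pan_matrix=pan, marker_alignment=marker,
        proteomes=proteomes, annotations=annotations, genomes=genomes,
        config=config,
    )


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write a simulation to disk: genomes/, proteomes/, marker.fasta,
    tree.nwk, pan_matrix.tsv, annotations.tsv, truth.json."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    for g, rec in result.genomes.items():
        write_fasta([rec], outdir / "genomes" / f"{g}.fasta")
    for g, recs in result.proteomes.items():
        write_fasta(recs, outdir / "proteomes" / f"{g}.faa")
    write_fasta(result.marker_alignment, outdir / "marker.fasta")
    write_newick(result.tree, outdir / "tree.nwk")
    write_tsv_matrix(result.pan_matrix, outdir / "pan_matrix.tsv")
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tproduct\tstart\tend\tstrand\n")
        for a in result.annotations:
            fh.write(f"{a.genome_id}\t{a.gene_id}\t{a.product}\t"
                     f"{a.start}\t{a.end}\t{a.strand}\n")
    truth = result.truth
    payload = {
        "seed": truth.seed,
        "branch_events": {k: list(v) for k, v in truth.branch_events.items()},
        "membership": truth.membership,
        "family_origin": truth.family_origin,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
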
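"""Ground-truth generator: determinism, event statistics, model fidelity."""

import numpy as np
import pytest
from scipy.linalg import expm

from pandiverge import (
    SimulationConfig, TN93Params, simulate, simulate_gene_content,
    simulate_marker_alignment, simulate_proteomes, simulate_tree,
)
from pandiverge.orthology import pairwise_identity
from pandiverge.synthetic_data import node_name


FIXED = "((A:0.2,B:0.2):0.3,(C:0.1,D:0.4):0.1);"


class TestSimulateTree:
    def test_fixed_newick_returned_unchanged(self):
        cfg = SimulationConfig(tree_mode="fixed_newick", fixed_newick=FIXED)
        tree = simulate_tree(cfg)
        labels = sorted(node_name(l) for l in tree.leaf_node_iter())
        assert labels == ["A", "B", "C", "D"]
        assert tree.is_rooted

    def test_same_seed_same_tree(self):
        cfg = SimulationConfig(n_genomes=12, seed=5)
        t1 = simulate_tree(cfg).as_string(schema="newick")
        t2 = simulate_tree(cfg).as_string(schema="newick")
        assert t1 == t2

    def test_yule_node_arithmetic(self):
        cfg = SimulationConfig(n_genomes=28, seed=1)
        tree = simulate_tree(cfg)
        assert len(tree.leaf_nodes()) == 28
        assert sum(1 for n in tree if not n.is_leaf()) == 27
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0


class TestGeneContent:
    def test_no_events_means_all_core(self):
        cfg = SimulationConfig(n_genomes=5, seed=3, gain_rate=0.0,
                               loss_rate=0.0, root_family_count=40)
        tree = simulate_tree(cfg)
        pan, truth = simulate_gene_content(tree, cfg)
        assert pan.n_families == 40
        assert np.all(pan.counts == 1)
        assert all(ev == (0, 0) for ev in truth.branch_events.values())

    def test_without_loss_presence_is_a_clade(self):
        """With loss_rate=0 every family occupies exactly the leaf set below
        its gain branch — presence replayed from the recorded history."""
        cfg = SimulationConfig(n_genomes=8, seed=11, gain_rate=25.0,
                               loss_rate=0.0, root_family_count=30)
        tree = simulate_tree(cfg)
        pan, truth = simulate_gene_content(tree, cfg)
        nodes = {node_name(n): n for n in tree.preorder_node_iter()}
        for fam, origin in truth.family_origin.items():
            expected = sorted(
                node_name(l) for l in nodes[origin].leaf_iter()
            )
            observed = sorted(truth.membership.get(fam, {}).keys())
            assert observed == expected

    def test_pan_size_monotone_in_genomes_added(self):
        cfg = SimulationConfig(n_genomes=10, seed=2, gain_rate=40.0,
                               loss_rate=0.2, root_family_count=50)
        tree = simulate_tree(cfg)
        pan, _ = simulate_gene_content(tree, cfg)
        presence = pan.presence()
        rng = np.random.default_rng(0)
        for _ in range(5):
            order = rng.permutation(pan.n_genomes)
            sizes = np.logical_or.accumulate(presence[:, order], axis=1).sum(0)
            assert np.all(np.diff(sizes) >= 0)

    def test_event_counts_match_poisson_binomial_means(self):
        """Mean per-branch gains/losses over replicates within 3 SE of the
        Poisson(gain*L) and Binomial(n, 1-exp(-loss*L)) expectations."""
        cfg0 = SimulationConfig(tree_mode="fixed_newick", fixed_newick=FIXED,
                                gain_rate=10.0, loss_rate=0.5,
                                root_family_count=60)
        tree = simulate_tree(cfg0)
        lengths = {
            node_name(n): n.edge.length
            for n in tree.preorder_node_iter() if n.parent_node is not None
        }
        reps = 200
        gains = {b: [] for b in lengths}
        for seed in range(reps):
            cfg = SimulationConfig(tree_mode="fixed_newick", fixed_newick=FIXED,
                                   gain_rate=10.0, loss_rate=0.5,
                                   root_family_count=60, seed=seed)
            _, truth = simulate_gene_content(simulate_tree(cfg), cfg)
            for b, (g, _) in truth.branch_events.items():
                gains[b].append(g)
        for b, length in lengths.items():
            lam = 10.0 * length
            se = np.sqrt(lam / reps)
            assert abs(np.mean(gains[b]) - lam) < 3 * se + 1e-9


class TestMarkerAlignment:
    def test_zero_branch_lengths_identical_sequences(self):
        nwk = "((A:0,B:0):0,(C:0,D:0):0);"
        cfg = SimulationConfig(tree_mode="fixed_newick", fixed_newick=nwk,
                               marker_length=400)
        tree = simulate_tree(cfg)
        records = simulate_marker_alignment(tree, cfg)
        assert len({r.residues for r in records}) == 1

    def test_same_seed_identical_alignment(self):
        cfg = SimulationConfig(n_genomes=5, seed=9, marker_length=300)
        tree = simulate_tree(cfg)
        a1 = simulate_marker_alignment(tree, cfg)
        a2 = simulate_marker_alignment(tree, cfg)
        assert [r.residues for r in a1] == [r.residues for r in a2]

    def test_pair_pattern_matches_tn93_transition_probabilities(self):
        """Observed joint base-pair frequencies across a two-branch split
        match pi_i * P_ij(2t) from the matrix exponential, within 3 SE."""
        t = 0.4
        nwk = f"((A:{t},B:{t}):0.0,(C:{t},D:{t}):0.0);"
        cfg = SimulationConfig(tree_mode="fixed_newick", fixed_newick=nwk,
                               marker_length=10_000, seed=21, marker_rate=1.0,
                               tn93=TN93Params(kappa1=1.0, kappa2=1.0))
        tree = simulate_tree(cfg)
        records = {r.id: r.residues for r in simulate_marker_alignment(tree, cfg)}
        q = cfg.tn93.rate_matrix()
        pi = np.array(cfg.tn93.base_freqs)
        joint = pi[:, None] * expm(q * 2 * t)
        idx = {c: i for i, c in enumerate("ACGT")}
        counts = np.zeros((4, 4))
        for x, y in zip(records["A"], records["B"]):
            counts[idx[x], idx[y]] += 1
        n = counts.sum()
        for i in range(4):
            for j in range(4):
                p = joint[i, j]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(counts[i, j] / n - p) < 3 * se + 2e-3


class TestProteomes:
    def _sim(self, decay, seed=4):
        cfg = SimulationConfig(n_genomes=5, seed=seed, gain_rate=5.0,
                               loss_rate=0.0, root_family_count=25,
                               protein_identity_decay=decay)
        tree = simulate_tree(cfg)
        pan, truth = simulate_gene_content(tree, cfg)
        prot, ann = simulate_proteomes(tree, truth, cfg)
        return truth, prot, ann

    def test_zero_decay_within_family_identical(self):
        truth, prot, _ = self._sim(decay=0.0)
        seqs = {r.id: r.residues for recs in prot.values() for r in recs}
        for fam, per in truth.membership.items():
            fam_seqs = {seqs[g] for genes in per.values() for g in genes}
            assert len(fam_seqs) == 1

    def test_decay_puts_planted_family_below_cutoff(self):
        """At high decay a deep family pair falls under the 50% clustering
        cutoff, as measured by the orthology module's own aligner."""
        truth, prot, _ = self._sim(decay=3.0)
        seqs = {r.id: r.residues for recs in prot.values() for r in recs}
        root_label = node_name(truth.true_tree.seed_node)
        deep = [f for f, o in truth.family_origin.items()
                if o == root_label and len(truth.membership.get(f, {})) >= 2]
        idents = []
        for fam in deep[:10]:
            genes = [g for genes in truth.membership[fam].values() for g in genes]
            ident, _ = pairwise_identity(seqs[genes[0]], seqs[genes[-1]])
            idents.append(ident)
        assert np.median(idents) < 50.0

    def test_every_gene_in_exactly_one_family(self):
        truth, prot, _ = self._sim(decay=0.3)
        gene_to_fams = {}
        for fam, per in truth.membership.items():
            for genes in per.values():
                for g in genes:
                    gene_to_fams.setdefault(g, []).append(fam)
        all_genes = [r.id for recs in prot.values() for r in recs]
        assert sorted(gene_to_fams) == sorted(all_genes)
        assert all(len(f) == 1 for f in gene_to_fams.values())

    def test_mge_fraction_flags_exact_subset(self):
        cfg = SimulationConfig(n_genomes=5, seed=8, gain_rate=0.0,
                               loss_rate=0.0, root_family_count=20,
                               mge_fraction=0.1)
        tree = simulate_tree(cfg)
        pan, truth = simulate_gene_content(tree, cfg)
        _, ann = simulate_proteomes(tree, truth, cfg)
        from pandiverge.orthology import flag_mge
        flagged = flag_mge(ann)
        per_genome = {}
        for a in ann:
            per_genome.setdefault(a.genome_id, []).append(a.gene_id in flagged)
        for flags in per_genome.values():
            assert sum(flags) == round(0.1 * len(flags))


class TestReproducibility:
    def test_full_simulation_is_deterministic(self):
        cfg = SimulationConfig(n_genomes=6, seed=77, root_family_count=30,
                               marker_length=200, genome_length=2000)
        r1, r2 = simulate(cfg), simulate(cfg)
        assert r1.tree.as_string(schema="newick") == \
            r2.tree.as_string(schema="newick")
        assert np.array_equal(r1.pan_matrix.counts, r2.pan_matrix.counts)
        assert [x.residues for x in r1.marker_alignment] == \
            [x.residues for x in r2.marker_alignment]
        for g in r1.proteomes:
            assert [x.residues for x in r1.proteomes[g]] == \
                [x.residues for x in r2.proteomes[g]]
        assert all(r1.genomes[g].residues == r2.genomes[g].residues
                   for g in r1.genomes)
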
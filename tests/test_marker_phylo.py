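"""TN93 distances, saturation checks, neighbor joining, outgroup rooting."""

import math

import numpy as np
import pytest

from pandiverge import (
    DistanceMatrix, SequenceRecord, SimulationConfig, filter_marker_sequences,
    is_undefined, nj_tree, pairwise_substitution_proportions, root_by_outgroup,
    saturation_assessment, simulate_marker_alignment, simulate_tree,
    tn93_distance, tn93_distance_matrix,
)
from pandiverge.marker_phylo import SubstitutionSummary

from conftest import (
    additive_matrix, patristic_lookup, random_tree_with_lengths, rf_unrooted,
)


def _rec(id_, seq):
    return SequenceRecord(id_, "", seq)


class TestFilter:
    def test_window_bounds_inclusive(self):
        records = [_rec(f"s{n}", "A" * n) for n in (1250, 1300, 1550, 1600)]
        kept, report = filter_marker_sequences(records, 1300, 1550)
        assert [len(r) for r in kept] == [1300, 1550]
        assert report.n_dropped_length == 2

    def test_exact_duplicates_dropped_keeping_first(self):
        records = [_rec("a", "ACGT" * 400), _rec("b", "ACGT" * 400)]
        kept, report = filter_marker_sequences(records, 100, 2000)
        assert [r.id for r in kept] == ["a"]
        assert report.n_dropped_duplicate == 1

    def test_empty_input(self):
        kept, report = filter_marker_sequences([], 1300, 1550)
        assert kept == [] and report.n_input == 0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            filter_marker_sequences([], 1550, 1300)


class TestSubstitutionProportions:
    def test_identical_sequences_zero(self):
        s = pairwise_substitution_proportions("ACGTACGT", "ACGTACGT")
        assert (s.P1, s.P2, s.Q) == (0.0, 0.0, 0.0)

    def test_single_transition_counted(self):
        s = pairwise_substitution_proportions("AG", "GG")
        assert (s.P1, s.P2, s.Q) == (0.5, 0.0, 0.0)

    def test_planted_difference_counts(self):
        """1,000 sites with 30 A<->G, 20 C<->T and 10 transversion
        differences -> (0.03, 0.02, 0.01)."""
        a = ["A"] * 500 + ["C"] * 500
        b = list(a)
        for i in range(30):
            b[i] = "G"
        for i in range(500, 520):
            b[i] = "T"
        for i in range(520, 530):
            b[i] = "G"
        s = pairwise_substitution_proportions("".join(a), "".join(b))
        assert (s.P1, s.P2, s.Q) == (0.03, 0.02, 0.01)
        assert s.sites_used == 1000

    def test_pairwise_deletion_of_gaps_and_ns(self):
        s = pairwise_substitution_proportions("ACG-N", "A-GTN")
        assert s.sites_used == 2

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="no comparable"):
            pairwise_substitution_proportions("--", "AC")


def k2p(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestTn93Distance:
    def test_zero_at_identity(self):
        s = SubstitutionSummary(0, 0, 0, (0.25,) * 4, 100)
        assert tn93_distance(s) == 0.0

    @pytest.mark.parametrize("P,Q", [(0.02, 0.01), (0.10, 0.05), (0.2, 0.1)])
    def test_equal_frequency_limit_is_k2p(self, P, Q):
        s = SubstitutionSummary(P / 2, P / 2, Q, (0.25,) * 4, 1000)
        assert tn93_distance(s) == pytest.approx(k2p(P, Q), abs=1e-12)

    def test_jc69_limit(self):
        """With proportions in the 1:2 transition:transversion ratio of a
        uniform process, TN93 collapses to the Jukes-Cantor closed form."""
        p = 0.15  # total differences
        s = SubstitutionSummary(p / 6, p / 6, 2 * p / 3, (0.25,) * 4, 1000)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_distance(s) == pytest.approx(jc, abs=1e-12)

    def test_saturated_input_returns_undefined(self):
        s = SubstitutionSummary(0.45, 0.0, 0.1, (0.25,) * 4, 1000)
        assert is_undefined(tn93_distance(s))

    def test_symmetric_in_sequence_order(self):
        a, b = "ACGTACGTGG", "ACGAACGTGC"
        d1 = tn93_distance(pairwise_substitution_proportions(a, b))
        d2 = tn93_distance(pairwise_substitution_proportions(b, a))
        assert d1 == d2 and d1 > 0

    def test_estimate_approaches_true_path_length(self):
        """On a long synthetic marker the TN93 estimate converges to the
        simulated path length (50 kb sites, 5% tolerance)."""
        t = 0.15
        nwk = f"((A:{t},B:{t}):0.05,(C:{t},D:{t}):0.05);"
        cfg = SimulationConfig(tree_mode="fixed_newick", fixed_newick=nwk,
                               marker_length=50_000, seed=13, marker_rate=1.0)
        tree = simulate_tree(cfg)
        records = {r.id: r for r in simulate_marker_alignment(tree, cfg)}
        d = tn93_distance(
            pairwise_substitution_proportions(records["A"], records["B"]))
        assert d == pytest.approx(2 * t, rel=0.05)


class TestSaturation:
    def test_low_divergence_transition_biased_not_saturated(self):
        cfg = SimulationConfig(n_genomes=6, seed=2, marker_length=1500,
                               tree_height=0.1)
        tree = simulate_tree(cfg)
        report = saturation_assessment(simulate_marker_alignment(tree, cfg))
        assert report.verdict == "not_saturated"
        assert len(report.rows) == 15

    def test_random_sequences_saturated(self, rng):
        nuc = np.array(list("ACGT"))
        records = [
            _rec(f"r{i}", "".join(rng.choice(nuc, 10_000))) for i in range(4)
        ]
        report = saturation_assessment(records)
        assert report.verdict == "saturated"
        assert report.saturated_fraction == 1.0

    def test_identical_pair_not_counted_saturated(self):
        records = [_rec("a", "ACGT" * 10), _rec("b", "ACGT" * 10)]
        report = saturation_assessment(records)
        assert report.saturated_fraction == 0.0

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            saturation_assessment([_rec("a", "ACGT")])


class TestNeighborJoining:
    def test_three_taxa_solves_exactly(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        tree = nj_tree(d)
        dist = patristic_lookup(tree)
        assert dist[("A", "B")] == pytest.approx(3)
        assert dist[("A", "C")] == pytest.approx(5)
        assert dist[("B", "C")] == pytest.approx(6)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovered(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree_with_lengths(int(rng.integers(4, 13)), rng)
        matrix = additive_matrix(tree)
        recovered = nj_tree(matrix)
        assert rf_unrooted(tree, recovered) == 0
        dist = patristic_lookup(recovered)
        for (a, b), d in patristic_lookup(tree).items():
            assert dist[(a, b)] == pytest.approx(d, abs=1e-9)

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        """Independent cross-check against scikit-bio's NJ on a noisy
        (non-additive) matrix: same topology."""
        skbio = pytest.importorskip("skbio")
        import io
        import dendropy
        n = 7
        base = np.abs(rng.normal(1.0, 0.3, size=(n, n)))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(labels, d))
        dm = skbio.DistanceMatrix(d, ids=labels)
        theirs_nwk = str(skbio.tree.nj(dm))
        theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick")
        assert rf_unrooted(ours, theirs) == 0

    def test_all_equal_distances_deterministic(self):
        labels = ["d", "c", "b", "a"]
        d = DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
        t1 = nj_tree(d).as_string(schema="newick")
        t2 = nj_tree(d).as_string(schema="newick")
        assert t1 == t2

    def test_undefined_entries_rejected(self):
        vals = np.array([[0, 1, math.nan], [1, 0, 1], [math.nan, 1, 0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(["a", "b", "c"], vals))


class TestRooting:
    def test_outgroup_becomes_sister_to_rest(self):
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 2, 5, 8], [2, 0, 5, 8], [5, 5, 0, 9], [8, 8, 9, 0]],
                     float))
        rooted = root_by_outgroup(nj_tree(d), "D")
        assert rooted.is_rooted
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [sorted(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert ["D"] in sides
        # root splits the outgroup edge at its midpoint
        for c in children:
            assert c.edge.length == pytest.approx(children[0].edge.length)

    def test_root_unroot_round_trip(self, rng):
        tree = random_tree_with_lengths(6, rng)
        unrooted = nj_tree(additive_matrix(tree))
        label = sorted(l.taxon.label for l in unrooted.leaf_node_iter())[0]
        rooted = root_by_outgroup(unrooted, label)
        assert rf_unrooted(unrooted, rooted) == 0

    def test_missing_outgroup_rejected(self, rng):
        tree = nj_tree(additive_matrix(random_tree_with_lengths(4, rng)))
        with pytest.raises(ValueError, match="not a leaf"):
            root_by_outgroup(tree, "nope")


def test_distance_matrix_pipeline_carries_undefined(rng):
    nuc = np.array(list("ACGT"))
    random_recs = [
        _rec(f"x{i}", "".join(rng.choice(nuc, 2000))) for i in range(3)
    ]
    matrix = tn93_distance_matrix(random_recs)
    assert matrix.has_undefined() or np.all(matrix.values >= 0)
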
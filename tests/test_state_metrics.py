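"""EMT scoring, hybridness, JSD, J metric, and frustration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emphybrid as eh
from emphybrid.phenotypes import PhenotypeDistribution
from emphybrid.state_metrics import (
    NodePartition,
    phenotype_frequencies,
    state_correlations,
)


def _dist(freqs, nodes, full=None):
    return PhenotypeDistribution(freqs=freqs, nodes=nodes, full_states=full)


@pytest.fixture
def part4():
    return NodePartition(
        nodes=("E1", "E2", "M1", "M2"),
        e_nodes=frozenset({"E1", "E2"}),
        m_nodes=frozenset({"M1", "M2"}),
    )


class TestPartitionNodes:
    def test_perfect_two_block_matrix_recovered(self):
        nodes = ("A", "B", "C", "D")
        C = np.array(
            [
                [1, 1, -1, -1],
                [1, 1, -1, -1],
                [-1, -1, 1, 1],
                [-1, -1, 1, 1],
            ],
            dtype=float,
        )
        part = eh.partition_nodes(C, nodes, anchors={"A": "E"})
        assert part.e_nodes == {"A", "B"} and part.m_nodes == {"C", "D"}

    def test_anchor_flips_labels(self):
        nodes = ("A", "B")
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        as_e = eh.partition_nodes(C, nodes, anchors={"B": "E"})
        assert "B" in as_e.e_nodes and "A" in as_e.m_nodes

    def test_two_node_toggle_splits(self):
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        part = eh.partition_nodes(C, ("A", "B"))
        assert len(part.e_nodes) == 1 and len(part.m_nodes) == 1

    def test_no_anchor_warns(self, caplog):
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with caplog.at_level("WARNING"):
            eh.partition_nodes(C, ("A", "B"))
        assert any("anchors" in rec.message for rec in caplog.records)

    def test_conflicting_anchors_raise(self):
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError, match="disagree"):
            eh.partition_nodes(C, ("A", "B"), anchors={"A": "E", "B": "E"})


class TestEMTScore:
    @pytest.mark.parametrize(
        "state, expected",
        [("1100", 1.0), ("0011", -1.0), ("1010", 0.0), ("1110", 0.5)],
    )
    def test_examples(self, part4, state, expected):
        assert eh.emt_score(state, part4) == pytest.approx(expected)

    def test_antisymmetric_under_label_swap(self, part4):
        for state in ("1100", "1010", "0111", "0001"):
            assert eh.emt_score(state, part4) == pytest.approx(
                -eh.emt_score(state, part4.swapped())
            )

    def test_wrong_length_raises(self, part4):
        with pytest.raises(ValueError, match="length"):
            eh.emt_score("110", part4)


class TestClassifyState:
    @pytest.mark.parametrize(
        "state, label",
        [("1100", "E"), ("0011", "M"), ("1010", "hybrid"), ("1110", "hybrid")],
    )
    def test_examples_including_inclusive_boundary(self, part4, state, label):
        # "1110" scores exactly +0.5: the boundary counts as hybrid
        assert eh.classify_state(state, part4) == label


class TestHybridness:
    def test_mixed_distribution(self, part4):
        dist = _dist({"1100": 0.5, "0011": 0.3, "1010": 0.2}, part4.nodes)
        assert eh.hybridness(dist, part4) == pytest.approx(0.2)

    def test_extremes(self, part4):
        assert eh.hybridness(_dist({"1100": 1.0}, part4.nodes), part4) == 0.0
        assert eh.hybridness(_dist({"1010": 1.0}, part4.nodes), part4) == 1.0

    def test_class_frequencies_partition_unity(self, part4):
        rng = np.random.default_rng(0)
        states = ["".join(rng.choice(["0", "1"], 4)) for _ in range(6)]
        w = rng.dirichlet(np.ones(len(set(states))))
        dist = _dist(dict(zip(sorted(set(states)), w)), part4.nodes)
        freqs = phenotype_frequencies(dist, part4)
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert freqs["hybrid"] == pytest.approx(eh.hybridness(dist, part4))


class TestJSD:
    def test_identical_distributions_are_zero(self):
        d = _dist({"10": 0.6, "01": 0.4}, ("A", "B"))
        assert eh.jensen_shannon_divergence(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_are_one(self):
        d1 = _dist({"10": 1.0}, ("A", "B"))
        d2 = _dist({"01": 1.0}, ("A", "B"))
        assert eh.jensen_shannon_divergence(d1, d2) == pytest.approx(1.0)

    def test_point_mass_vs_even_split(self):
        # direct evaluation of 0.5*KL(f1||M) + 0.5*KL(f2||M) in log2
        d1 = _dist({"1": 1.0}, ("A",))
        d2 = _dist({"1": 0.5, "0": 0.5}, ("A",))
        expected = 0.5 * np.log2(4 / 3) + 0.5 * (0.5 * np.log2(2 / 3) + 0.5)
        assert eh.jensen_shannon_divergence(d1, d2) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.3113, abs=5e-5)

    def test_mismatched_node_sets_raise(self):
        d1 = _dist({"10": 1.0}, ("A", "B"))
        d2 = _dist({"10": 1.0}, ("A", "C"))
        with pytest.raises(ValueError):
            eh.jensen_shannon_divergence(d1, d2)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_metric_axioms_on_random_distributions(self, data):
        """Symmetry, identity of indiscernibles, and [0, 1] bounds."""
        states = ["00", "01", "10", "11"]
        w1 = data.draw(st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
        w2 = data.draw(st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
        f1 = dict(zip(states, np.array(w1) / sum(w1)))
        f2 = dict(zip(states, np.array(w2) / sum(w2)))
        d1, d2 = _dist(f1, ("A", "B")), _dist(f2, ("A", "B"))
        j12 = eh.jensen_shannon_divergence(d1, d2)
        assert 0 <= j12 <= 1
        assert j12 == pytest.approx(eh.jensen_shannon_divergence(d2, d1), abs=1e-12)
        assert eh.jensen_shannon_divergence(d1, d1) == pytest.approx(0.0, abs=1e-12)


class TestJMetric:
    def test_examples(self):
        assert eh.j_metric(np.array([[1, 0.5], [0.5, 1]])) == pytest.approx(0.5)
        assert eh.j_metric(np.eye(3)) == 0.0
        assert eh.j_metric(np.ones((3, 3))) == pytest.approx(3.0)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            eh.j_metric(np.ones((2, 3)))


class TestStateFrustration:
    def test_toggle_states(self, toggle):
        assert eh.state_frustration("10", toggle) == 0.0
        assert eh.state_frustration("01", toggle) == 0.0
        assert eh.state_frustration("11", toggle) == 1.0
        assert eh.state_frustration("00", toggle) == 1.0

    def test_repressilator_partial(self, repressilator):
        assert eh.state_frustration("100", repressilator) == pytest.approx(1 / 3)

    def test_repressilator_floor_is_one_third(self, repressilator):
        """Exhaustive: no state of the negative 3-cycle beats 1/3."""
        values = [
            eh.state_frustration(format(s, "03b"), repressilator) for s in range(8)
        ]
        assert min(values) == pytest.approx(1 / 3)
        assert max(values) == 1.0

    def test_self_loops(self):
        net = eh.GRNTopology.from_edges("s", [("A", "A", 1), ("B", "B", -1)])
        assert eh.state_frustration("11", net) == pytest.approx(0.5)  # only B's loop

    def test_missing_bits_raise(self, toggle):
        with pytest.raises(ValueError, match="full"):
            eh.state_frustration("1", toggle)


class TestNetworkFrustration:
    def test_toggle_polarized_states_unfrustrated(self, toggle):
        dist = _dist(
            {"10": 0.5, "01": 0.5}, ("A", "B"), full={"10": "10", "01": "01"}
        )
        stats = eh.network_frustration(dist, toggle)
        assert (stats.min, stats.mean, stats.max) == (0.0, 0.0, 0.0)

    def test_single_state_collapses(self, toggle):
        dist = _dist({"11": 1.0}, ("A", "B"), full={"11": "11"})
        stats = eh.network_frustration(dist, toggle)
        assert stats.min == stats.mean == stats.max == 1.0

    def test_mean_unweighted_vs_weighted(self, toggle):
        dist = _dist(
            {"10": 0.9, "11": 0.1}, ("A", "B"), full={"10": "10", "11": "11"}
        )
        assert eh.network_frustration(dist, toggle).mean == pytest.approx(0.5)
        weighted = eh.network_frustration(dist, toggle, frequency_weighted_mean=True)
        assert weighted.mean == pytest.approx(0.1)

    def test_empty_distribution_raises(self, toggle):
        with pytest.raises(ValueError):
            eh.network_frustration(_dist({}, ("A", "B"), full={}), toggle)


class TestStateCorrelations:
    def test_perfectly_anticorrelated_pair(self):
        dist = _dist({"10": 0.5, "01": 0.5}, ("A", "B"))
        C = state_correlations(dist)
        assert C[0, 1] == pytest.approx(-1.0)

    def test_constant_node_gets_zero(self):
        dist = _dist({"10": 0.5, "11": 0.5}, ("A", "B"))
        C = state_correlations(dist)
        assert C[0, 1] == 0.0
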
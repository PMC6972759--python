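"""Unit and property tests for the neuron/area/connection primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craet.model import (
    ASSOCIATION,
    CONCEPT,
    FEATURE,
    ORDER_DEPENDENT,
    ORDER_INDEPENDENT,
    Area,
    DimensionMismatch,
    FeatureNeuron,
    NetworkState,
    ThresholdSpec,
    activate_association,
    activate_concept,
    activate_feature,
    expand_feature_synapses,
    find_winner,
    wta_update,
)


def _area(threshold=("relative", 0.25), distance="euclidean"):
    return Area(id=0, level=FEATURE, tag="t", channel="c",
                threshold=ThresholdSpec(*threshold), distance_kind=distance)


def _neuron(w, nid=1):
    return FeatureNeuron(id=nid, area_id=0, weight_groups=[np.asarray(w, dtype=float)])


class TestActivateFeature:
    @pytest.mark.parametrize(
        "w, y, expect_fired, expect_dist",
        [
            ((1, 0), (1, 0), 1, 0.0),  # zero distance always fires
            ((1, 0), (1.3, 0), 0, 0.3),  # 0.3 > theta 0.25*||w||=0.25
            ((3, 4), (3, 5.2), 1, 1.2),  # ||w||=5 -> theta 1.25 >= 1.2
        ],
    )
    def test_relative_quarter_norm_rule(self, w, y, expect_fired, expect_dist):
        fired, dist = activate_feature(_neuron(w), y, _area())
        assert fired == expect_fired
        assert dist == pytest.approx(expect_dist, abs=1e-12)

    def test_dimension_mismatch_names_neuron(self):
        with pytest.raises(DimensionMismatch, match="neuron 7"):
            activate_feature(_neuron((1, 0), nid=7), (1, 0, 0), _area())

    def test_threshold_resolves_against_current_weights(self):
        # after a weight update, the relative threshold follows ||w||
        n = _neuron((1, 0))
        wta_update(n, np.array([3.0, 0.0]))
        assert np.allclose(n.native_weights(), [2.0, 0.0])
        fired, _ = activate_feature(n, (2.5, 0), _area())  # theta now 0.5
        assert fired == 1


class TestFindWinner:
    def _net(self, weights):
        net = NetworkState()
        area = net.ensure_area(FEATURE, "t", "c", threshold=ThresholdSpec("absolute", 1.0))
        for w in weights:
            net.add_feature_neuron(area, [np.asarray(w, dtype=float)])
        return net, area

    def test_nearest_neuron_wins(self):
        net, area = self._net([(0, 0), (2, 2)])
        winner, dist, runner, _ = find_winner(net, area, (0.1, 0))
        first = min(net.feature_neurons)
        assert winner == first
        assert runner == first + 1
        assert dist == pytest.approx(0.1)

    def test_equidistant_breaks_to_lower_id(self):
        net, area = self._net([(1, 0), (-1, 0)])
        winner, _, _, _ = find_winner(net, area, (0, 0))
        assert winner == min(net.feature_neurons)

    def test_matches_exhaustive_scan(self, rng):
        ws = rng.normal(size=(5, 3))
        net, area = self._net(ws)
        y = rng.normal(size=3)
        winner, dist, _, _ = find_winner(net, area, y)
        ids = sorted(net.feature_neurons)
        brute = min(range(5), key=lambda i: (np.linalg.norm(y - ws[i]), i))
        assert winner == ids[brute]
        assert dist == pytest.approx(np.linalg.norm(y - ws[brute]))

    def test_empty_area_yields_sentinel(self):
        net, area = self._net([])
        assert find_winner(net, area, (0.0,)) == (None, float("inf"), None, float("inf"))


class TestWtaUpdate:
    def test_mean_of_two_points(self):
        n = _neuron((0, 0))
        wta_update(n, (2, 2))
        assert np.allclose(n.native_weights(), (1, 1))
        assert n.sigma == 2

    def test_three_point_mean(self):
        n = _neuron((0, 0))
        for y in [(3, 0), (0, 3)]:
            wta_update(n, y)
        assert np.allclose(n.native_weights(), (1, 1))
        assert n.sigma == 3

    def test_fixed_point(self):
        n = _neuron((1.5, -2.0))
        wta_update(n, (1.5, -2.0))
        assert np.array_equal(n.native_weights(), [1.5, -2.0])
        assert n.sigma == 2

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.floats(-50, 50), min_size=3, max_size=3),
            min_size=1,
            max_size=50,
        )
    )
    def test_running_mean_equivalence(self, ys):
        """Weights after any input stream equal the arithmetic mean of it."""
        n = _neuron(ys[0])
        for y in ys[1:]:
            wta_update(n, y)
        assert np.allclose(n.native_weights(), np.mean(ys, axis=0), atol=1e-9)
        assert n.sigma == len(ys)


class TestExpansion:
    def test_appends_group(self):
        n = _neuron((1, 2))
        expand_feature_synapses(n, (3,))
        assert [g.tolist() for g in n.weight_groups] == [[1, 2], [3]]
        assert n.native_dim() == 3

    def test_group_zero_bit_exact(self):
        w0 = np.array([0.1, 0.2, 0.30000000001])
        n = FeatureNeuron(id=1, area_id=0, weight_groups=[w0.copy()])
        expand_feature_synapses(n, (9.0, 9.0))
        assert np.array_equal(n.weight_groups[0], w0)

    def test_full_space_activation_after_expansion(self):
        n = _neuron((1, 2))
        expand_feature_synapses(n, (3,))
        fired, dist = activate_feature(n, (1, 2, 3), _area())
        assert (fired, dist) == (1, 0.0)

    def test_repeated_expansion_rejected(self):
        n = _neuron((1, 2))
        expand_feature_synapses(n, (3,))
        with pytest.raises(ValueError, match="already"):
            expand_feature_synapses(n, (4,))


class TestConceptActivation:
    def _net(self):
        net = NetworkState()
        fa = net.ensure_area(FEATURE, "f", "ch")
        ca = net.ensure_area(CONCEPT, "c", "ch")
        ids = [net.add_feature_neuron(fa, [np.zeros(1)]).id for _ in range(4)]
        return net, ca, ids

    def test_order_independent_subset(self):
        net, ca, ids = self._net()
        concept = net.add_concept_neuron(ca, ORDER_INDEPENDENT, [ids[0], ids[1]])
        assert activate_concept(net, concept, [ids[1], ids[0]]) == 1
        assert activate_concept(net, concept, [ids[0]]) == 0

    def test_order_dependent_exact_sequence(self):
        net, ca, ids = self._net()
        word = net.add_concept_neuron(ca, ORDER_DEPENDENT, [ids[0], ids[1]])
        assert activate_concept(net, word, [ids[0], ids[1]]) == 1
        assert activate_concept(net, word, [ids[1], ids[0]]) == 0
        # a longer sequence is not the same word
        assert activate_concept(net, word, [ids[0], ids[1], ids[2]]) == 0


class TestAssociationActivation:
    def test_matches_or_oracle_over_all_subsets(self):
        net = NetworkState()
        for tag, ch in (("f1", "ch1"), ("f2", "ch2")):
            net.ensure_area(FEATURE, tag, ch)
            net.ensure_area(CONCEPT, f"c_{tag}", ch)
        fa1 = net.area_by_tag(FEATURE, "f1")
        fa2 = net.area_by_tag(FEATURE, "f2")
        ca1 = net.area_by_tag(CONCEPT, "c_f1")
        ca2 = net.area_by_tag(CONCEPT, "c_f2")
        c1 = net.add_concept_neuron(ca1, ORDER_INDEPENDENT,
                                    [net.add_feature_neuron(fa1, [np.zeros(1)]).id])
        c2 = net.add_concept_neuron(ca1, ORDER_INDEPENDENT,
                                    [net.add_feature_neuron(fa1, [np.ones(1)]).id])
        c3 = net.add_concept_neuron(ca2, ORDER_INDEPENDENT,
                                    [net.add_feature_neuron(fa2, [np.zeros(1)]).id])
        assoc = net.add_assoc_neuron()
        net.add_assoc_conn(c1.id, assoc.id, c3.id)
        net.add_assoc_conn(c2.id, assoc.id, c3.id)
        linked = [c1.id, c2.id, c3.id]
        universe = linked + [999]
        for bits in range(2 ** len(universe)):
            active = {universe[i] for i in range(len(universe)) if bits >> i & 1}
            expected = 1 if any(c in active for c in linked) else 0
            assert activate_association(net, assoc, active) == expected


class TestSerialization:
    def test_round_trip_byte_identical(self, trained):
        net, _ = trained
        blob = net.to_json()
        again = NetworkState.from_json(blob).to_json()
        assert blob == again

    def test_round_trip_preserves_structure(self, empty_net):
        area = empty_net.area_by_tag(FEATURE, "toy")
        n = empty_net.add_feature_neuron(area, [np.array([1.0, 2.0])])
        expand_feature_synapses(n, [0.5])
        n.embedded["x"] = 2
        n.weight_groups.append(np.array([[1.0, 2.0], [3.0, 4.0]]))
        n.group_sigmas[2] = 3
        blob = empty_net.to_json()
        loaded = NetworkState.from_json(blob)
        m = loaded.feature_neurons[n.id]
        assert m.expanded and m.embedded == {"x": 2} and m.group_sigmas == {2: 3}
        assert m.weight_groups[2].shape == (2, 2)
        assert loaded.to_json() == blob

    def test_version_mismatch_rejected(self, empty_net):
        d = empty_net.to_dict()
        d["meta"]["version"] = 999
        with pytest.raises(ValueError, match="version"):
            NetworkState.from_dict(d)


def test_threshold_spec_validation():
    with pytest.raises(ValueError):
        ThresholdSpec("relative", 1.5)
    with pytest.raises(ValueError):
        ThresholdSpec("absolute", -1.0)
    assert ThresholdSpec("relative", 0.25).resolve([3, 4]) == pytest.approx(1.25)
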
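"""Multimodal association: four-case binding, channel expansion, recall."""

import numpy as np
import pytest

from craet.association import (
    OracleExhausted,
    ScriptedOracle,
    associate_pair,
    expand_response_modal,
    recall,
)
from craet.concepts import ConceptEvent
from craet.model import (
    CONCEPT,
    FEATURE,
    ORDER_INDEPENDENT,
    NetworkState,
    ThresholdSpec,
    activate_association,
)


def _net(channels=("visual", "auditory", "gustatory")):
    net = NetworkState()
    for ch in channels:
        net.ensure_area(FEATURE, f"f_{ch}", ch, threshold=ThresholdSpec("absolute", 1))
        net.ensure_area(CONCEPT, ch, ch, mode=ORDER_INDEPENDENT)
    return net


def _concept(net, channel, value=0.0):
    fa = net.area_by_tag(FEATURE, f"f_{channel}")
    ca = net.area_by_tag(CONCEPT, channel)
    fid = net.add_feature_neuron(fa, [np.array([value])]).id
    concept = net.add_concept_neuron(ca, ORDER_INDEPENDENT, [fid])
    return ConceptEvent(ca.id, concept.id, created=True)


def yes(n=1):
    return ScriptedOracle([{"question_kind": None, "answer": True}] * n)


def no(n=1):
    return ScriptedOracle([{"question_kind": None, "answer": False}] * n)


class TestAssociatePair:
    def test_first_pair_is_one_to_one(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        ev = associate_pair(net, v, a, yes())
        assert ev.case == "both_new"
        assert len(net.assoc_neurons) == 1 and len(net.assoc_conns) == 1
        conn = next(iter(net.assoc_conns.values()))
        assert conn.rho == 1

    def test_same_pair_again_strengthens(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        ev = associate_pair(net, v, a, yes())
        assert ev.case == "consistent"
        assert next(iter(net.assoc_conns.values())).rho == 2
        assert len(net.assoc_neurons) == 1

    def test_known_name_new_view_accepted_connects_through_every_hub(self):
        net = _net()
        # name already bound through two hubs (two prior views)
        v1, v2, a = _concept(net, "visual"), _concept(net, "visual", 5.0), _concept(net, "auditory")
        a1 = net.add_assoc_neuron()
        net.add_assoc_conn(v1.concept_id, a1.id, a.concept_id)
        a2 = net.add_assoc_neuron()
        net.add_assoc_conn(v2.concept_id, a2.id, a.concept_id)
        v3 = _concept(net, "visual", 9.0)
        n_before = len(net.assoc_conns)
        ev = associate_pair(net, v3, a, yes())
        assert ev.case == "new_view" and ev.accepted
        assert sorted(ev.assoc_ids) == [a1.id, a2.id]
        assert len(net.assoc_conns) - n_before == 2

    def test_known_name_new_view_declined_stores_type_o_circuit(self):
        net = _net()
        v1, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v1, a, yes())
        v2 = _concept(net, "visual", 5.0)
        ev = associate_pair(net, v2, a, no())
        assert ev.case == "new_view" and not ev.accepted
        # a fresh association neuron holds only the rejected view
        type_o = net.assoc_neurons[ev.assoc_ids[0]]
        assert type_o.linked_concepts() == {v2.concept_id}
        assert len(net.assoc_conns) == 1  # no new cross-channel connection

    def test_known_view_new_name_accepted(self):
        net = _net()
        v, a1 = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a1, yes())
        a2 = _concept(net, "auditory", 5.0)
        ev = associate_pair(net, v, a2, yes())
        assert ev.case == "new_name" and ev.accepted
        assert len(net.assoc_conns) == 2 and len(net.assoc_neurons) == 1

    def test_known_view_new_name_declined_rejects_name(self):
        net = _net()
        v, a1 = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a1, yes())
        a2 = _concept(net, "auditory", 5.0)
        ev = associate_pair(net, v, a2, no())
        assert ev.case == "new_name" and not ev.accepted
        assert len(net.assoc_conns) == 1 and len(net.assoc_neurons) == 1

    def test_disjoint_hubs_accepted_connects_union(self):
        net = _net()
        v1, a1 = _concept(net, "visual"), _concept(net, "auditory")
        v2, a2 = _concept(net, "visual", 5.0), _concept(net, "auditory", 5.0)
        associate_pair(net, v1, a1, yes())
        associate_pair(net, v2, a2, yes())
        ev = associate_pair(net, v1, a2, yes())
        assert ev.case == "inconsistent_accepted"
        assert len(ev.connection_ids) == 2  # through both hubs

    def test_disjoint_hubs_declined_adds_nothing(self):
        net = _net()
        v1, a1 = _concept(net, "visual"), _concept(net, "auditory")
        v2, a2 = _concept(net, "visual", 5.0), _concept(net, "auditory", 5.0)
        associate_pair(net, v1, a1, yes())
        associate_pair(net, v2, a2, yes())
        before = (len(net.assoc_neurons), len(net.assoc_conns))
        ev = associate_pair(net, v1, a2, no())
        assert ev.case == "inconsistent_rejected"
        assert (len(net.assoc_neurons), len(net.assoc_conns)) == before

    def test_scripted_oracle_exhaustion_raises(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        a2 = _concept(net, "auditory", 5.0)
        with pytest.raises(OracleExhausted):
            associate_pair(net, v, a2, ScriptedOracle([]))


class TestResponseModalExpansion:
    def test_new_channel_grows_onto_existing_hub_without_questions(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        g = _concept(net, "gustatory")
        ev = expand_response_modal(net, v, g)
        assert ev.case == "expanded"
        assoc = net.assoc_neurons[ev.assoc_ids[0]]
        # reverse pathway: the hub now answers from the new channel alone
        assert activate_association(net, assoc, {g.concept_id}) == 1
        # and still answers from its original channels
        assert activate_association(net, assoc, {v.concept_id}) == 1
        assert activate_association(net, assoc, {a.concept_id}) == 1

    def test_repeat_pair_strengthens_not_duplicates(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        g = _concept(net, "gustatory")
        expand_response_modal(net, v, g)
        n_conns = len(net.assoc_conns)
        ev = expand_response_modal(net, v, g)
        assert ev.case == "consistent"
        assert len(net.assoc_conns) == n_conns
        conn = net.assoc_conns[ev.connection_ids[0]]
        assert conn.rho == 2

    def test_two_hubs_get_two_new_connections(self):
        net = _net()
        v1, v2 = _concept(net, "visual"), _concept(net, "visual", 5.0)
        a = _concept(net, "auditory")
        h1 = net.add_assoc_neuron()
        net.add_assoc_conn(v1.concept_id, h1.id, a.concept_id)
        h2 = net.add_assoc_neuron()
        net.add_assoc_conn(v1.concept_id, h2.id, a.concept_id)
        g = _concept(net, "gustatory")
        ev = expand_response_modal(net, v1, g)
        assert len(ev.connection_ids) == 2
        assert sorted(ev.assoc_ids) == [h1.id, h2.id]

    def test_both_channels_new_makes_one_to_one(self):
        net = _net()
        v, g = _concept(net, "visual"), _concept(net, "gustatory")
        ev = expand_response_modal(net, v, g)
        assert ev.case == "both_new"
        assert len(net.assoc_neurons) == 1

    def test_expansion_never_removes_links(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        before = {i: set(n.linked_concepts()) for i, n in net.assoc_neurons.items()}
        g = _concept(net, "gustatory")
        expand_response_modal(net, v, g)
        for i, linked in before.items():
            assert linked <= net.assoc_neurons[i].linked_concepts()


class TestRecall:
    def test_one_pair_recalls_both_directions(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        assert recall(net, v.concept_id, "auditory") == [a.concept_id]
        assert recall(net, a.concept_id, "visual") == [v.concept_id]

    def test_unattached_channel_is_empty(self):
        net = _net()
        v, a = _concept(net, "visual"), _concept(net, "auditory")
        associate_pair(net, v, a, yes())
        assert recall(net, v.concept_id, "gustatory") == []

    def test_ranking_follows_connection_strength(self):
        net = _net()
        v = _concept(net, "visual")
        a1, a2 = _concept(net, "auditory"), _concept(net, "auditory", 5.0)
        associate_pair(net, v, a1, yes())
        associate_pair(net, v, a1, yes())  # strengthen a1
        associate_pair(net, v, a2, yes())
        assert recall(net, v.concept_id, "auditory") == [a1.concept_id, a2.concept_id]
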
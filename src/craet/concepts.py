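"""Unimodal concept learning: bind activated feature neurons incrementally.

A concept neuron is an AND-circuit over feature neurons.  Visual concepts
are order-independent sets (shape + color); word concepts are
order-dependent syllable sequences.  Matching is match-or-create, and
concepts can *grow* links: a shape-only concept learned before color
receptors existed gains a color link the first time it is co-activated
with a color feature — synapse growth at the concept level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import (
    ORDER_DEPENDENT,
    ORDER_INDEPENDENT,
    Area,
    ConceptNeuron,
    NetworkState,
)
from .primary import FeatureEvent


@dataclass
class ConceptEvent:
    area_id: int
    concept_id: int
    created: bool
    extended: bool = False


def _events_by_area(net: NetworkState, events: Sequence[FeatureEvent]) -> dict[int, list[int]]:
    grouped: dict[int, list[int]] = {}
    for ev in events:
        grouped.setdefault(ev.area_id, []).append(ev.neuron_id)
    return grouped


def _links_by_area(net: NetworkState, concept: ConceptNeuron) -> dict[int, list[int]]:
    grouped: dict[int, list[int]] = {}
    for cid in concept.feature_links:
        conn = net.feature_conns[cid]
        area_id = net.feature_neurons[conn.feature_id].area_id
        grouped.setdefault(area_id, []).append(conn.feature_id)
    return grouped


def match_or_create_concept(
    net: NetworkState,
    area: Area,
    events: Sequence[FeatureEvent],
    mode: str | None = None,
) -> ConceptEvent:
    """Activate an existing concept for the event set, or create one.

    Order-independent matching is per feature area: every area in which
    both the concept and the events have entries must agree exactly; event
    areas the concept has no links in yet trigger link growth (the concept
    is extended, new links start at rho = 1).  Order-dependent matching
    requires the exact feature sequence.  Exact full matches are preferred
    over growth matches; remaining ties break toward the lowest concept id.
    On activation, every traversed connection's rho is incremented.
    """
    if not events:
        raise ValueError("at least one feature event is required")
    for ev in events:
        src = net.areas[ev.area_id]
        wired = net.wiring.get(src.tag)
        if wired is not None and wired != area.tag:
            raise ValueError(
                f"feature area {src.tag!r} is wired to concept area {wired!r}, not {area.tag!r}"
            )
    mode = mode or area.mode or ORDER_INDEPENDENT
    candidates = sorted(net.concept_neurons_in(area.id), key=lambda c: c.id)

    if mode == ORDER_DEPENDENT:
        seq = [ev.neuron_id for ev in events]
        for concept in candidates:
            if concept.mode == ORDER_DEPENDENT and net.concept_feature_ids(concept) == seq:
                for cid in concept.feature_links:
                    net.feature_conns[cid].rho += 1
                return ConceptEvent(area.id, concept.id, False)
        concept = net.add_concept_neuron(area, ORDER_DEPENDENT, seq)
        return ConceptEvent(area.id, concept.id, True)

    ev_areas = _events_by_area(net, events)
    exact = None
    growable = None
    for concept in candidates:
        if concept.mode != ORDER_INDEPENDENT:
            continue
        links = _links_by_area(net, concept)
        common = set(links) & set(ev_areas)
        if any(set(links[a]) != set(ev_areas[a]) for a in common):
            continue
        # concept areas absent from this sample are simply not tested;
        # event areas absent from the concept are candidates for link growth
        missing = set(ev_areas) - set(links)
        if not missing and set(links) == set(ev_areas):
            exact = exact or concept
        elif growable is None:
            growable = (concept, missing)
        if exact is not None:
            break

    if exact is not None:
        ev_ids = {ev.neuron_id for ev in events}
        for cid in exact.feature_links:
            if net.feature_conns[cid].feature_id in ev_ids:
                net.feature_conns[cid].rho += 1
        return ConceptEvent(area.id, exact.id, False)

    if growable is not None:
        concept, missing = growable
        ev_ids = {ev.neuron_id for ev in events}
        for cid in concept.feature_links:
            if net.feature_conns[cid].feature_id in ev_ids:
                net.feature_conns[cid].rho += 1
        pos = len(concept.feature_links)
        for ev in events:
            if ev.area_id in missing:
                net.link_concept_feature(concept, ev.neuron_id, pos)
                pos += 1
        return ConceptEvent(area.id, concept.id, False, extended=True)

    concept = net.add_concept_neuron(area, ORDER_INDEPENDENT, [ev.neuron_id for ev in events])
    return ConceptEvent(area.id, concept.id, True)
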
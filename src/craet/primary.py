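"""Online competitive learning in the primary sensory areas.

Every sample runs the same match-or-create loop: the arg-min winner is
sought in the area; if it fires within the area threshold it absorbs the
input through the winner-take-all incremental mean, otherwise a fresh
neuron ``{y, 1}`` records the input.  When a stage adds receptors, the
four-case dimensionality-increasing step routes inputs between the original
space R^n and the extended space R^(n+m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import SyllableSequence
from .model import (
    Area,
    FeatureNeuron,
    NetworkState,
    activate_feature,
    expand_feature_synapses,
    find_winner,
    wta_update,
)


@dataclass
class FeatureEvent:
    """Activation signal a primary area passes upward to the concept level."""

    area_id: int
    neuron_id: int
    created: bool
    distance: float
    runner_up_id: int | None = None


def process_feature(net: NetworkState, area: Area, y) -> FeatureEvent:
    """Match-or-create competitive step for a Euclidean feature area.

    The input is matched in the space whose dimensionality it has: the full
    native space normally, or the original (group-0) space when the area
    has already grown beyond the input's receptors — so older, partial
    observations keep activating their neurons after an expansion stage.
    """
    y = np.asarray(y, dtype=float)
    pool = net.feature_neurons_in(area.id)
    space = "native"
    if pool:
        native_dims = {n.native_dim() for n in pool}
        orig_dims = {n.original_weights().size for n in pool}
        if y.size in native_dims:
            space = "native"
            pool = [n for n in pool if n.native_dim() == y.size]
        elif y.size in orig_dims:
            space = "original"
            pool = [n for n in pool if n.original_weights().size == y.size]
        else:
            raise ValueError(
                f"input of length {y.size} matches no space in area {area.tag!r} "
                f"(native {sorted(native_dims)}, original {sorted(orig_dims)})"
            )
    winner_id, dist, runner_id, _ = find_winner(net, area, y, space=space, candidates=pool)
    if winner_id is not None:
        winner = net.feature_neurons[winner_id]
        fired, dist = activate_feature(winner, y, area, space=space)
        if fired:
            wta_update(winner, y, space=space)
            return FeatureEvent(area.id, winner_id, False, dist, runner_id)
    neuron = net.add_feature_neuron(area, [y])
    return FeatureEvent(area.id, neuron.id, True, 0.0, winner_id)


def process_syllables(net: NetworkState, area: Area, seq: SyllableSequence) -> list[FeatureEvent]:
    """Match-or-create over a DTW template area, one event per syllable.

    A matched syllable neuron increments its activation count; its stored
    template matrix stays frozen (incremental means are undefined across
    variable-length alignments).  Unmatched syllables are recorded verbatim
    as new templates.
    """
    if area.distance_kind != "dtw":
        raise ValueError(f"area {area.tag!r} is not a DTW area")
    events = []
    for m in seq:
        winner_id, dist, runner_id, _ = find_winner(net, area, m, space="original")
        if winner_id is not None:
            winner = net.feature_neurons[winner_id]
            fired, dist = activate_feature(winner, m, area, space="original")
            if fired:
                winner.sigma += 1
                events.append(FeatureEvent(area.id, winner_id, False, dist, runner_id))
                continue
        neuron = net.add_feature_neuron(area, [np.asarray(m, dtype=float)])
        events.append(FeatureEvent(area.id, neuron.id, True, 0.0, winner_id))
    return events


def self_organize(
    net: NetworkState, area: Area, winner_id: int, runner_up_id: int | None,
    max_age: int = 50, prune: bool = True,
) -> None:
    """Competitive-Hebbian topology update (growing-neural-gas style).

    Ages every edge incident to the winner, creates or refreshes the
    (winner, runner-up) edge, and prunes edges older than ``max_age``.
    Edges are topology metadata only; they never gate activation.
    """
    if runner_up_id is None or winner_id == runner_up_id:
        return
    edges = net.edges.setdefault(area.id, {})
    for pair in list(edges):
        if winner_id in pair:
            edges[pair] += 1
    key = (min(winner_id, runner_up_id), max(winner_id, runner_up_id))
    edges[key] = 0
    if prune:
        for pair, age in list(edges.items()):
            if age > max_age:
                del edges[pair]


def dimensionality_increase_step(net: NetworkState, area: Area, y_I, y_II) -> FeatureEvent:
    """Four-case routing when novel receptors extend an area's input space.

    Winner A is the arg-min over *all* neurons in the original space
    (group-0 weights) against ``y_I``; winner B is the arg-min over the
    already-expanded neurons in the full space against ``y = (y_I, y_II)``.
    Cases:

    * B fires — the full input is recognized; B inhibits A and absorbs
      ``y`` (covers both the A-and-B and the B-only case),
    * only A fires and A has not yet expanded — A absorbs ``y_I`` and then
      grows synapses initialised to ``y_II`` (the dimensionality increase),
    * otherwise — nothing recognizes the full input (including the case of
      an already-expanded A whose new-receptor synapses disagree), so a new
      full-dimension neuron ``{y, 1}`` is created.
    """
    y_I = np.asarray(y_I, dtype=float)
    y_II = np.asarray(y_II, dtype=float)
    y = np.concatenate([y_I, y_II])

    pool = net.feature_neurons_in(area.id)
    a_id, _, a_runner, _ = find_winner(net, area, y_I, space="original", candidates=pool)
    expanded_pool = [n for n in pool if n.expanded]
    b_id, _, _, _ = find_winner(net, area, y, space="native", candidates=expanded_pool)

    f_a, f_b = 0, 0
    if a_id is not None:
        f_a, d_a = activate_feature(net.feature_neurons[a_id], y_I, area, space="original")
    if b_id is not None:
        f_b, d_b = activate_feature(net.feature_neurons[b_id], y, area, space="native")

    if f_b:
        wta_update(net.feature_neurons[b_id], y, space="native")
        return FeatureEvent(area.id, b_id, False, d_b, None)
    if f_a and not net.feature_neurons[a_id].expanded:
        neuron = net.feature_neurons[a_id]
        wta_update(neuron, y_I, space="original")
        expand_feature_synapses(neuron, y_II)
        return FeatureEvent(area.id, a_id, False, d_a, a_runner)
    neuron = net.add_feature_neuron(area, [y_I, y_II], expanded=True)
    return FeatureEvent(area.id, neuron.id, True, 0.0, None)
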
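"""Modality embedding: plant an exogenous modality on host feature neurons.

An exogenous sample ``x_e`` cannot reach the network through any existing
receptor, so a *guidance* signal ``x_g`` on a trained reference channel G
routes it: ``x_g`` ascends to the multimodal area, the activated
association neurons descend through the target channel T's concept neurons
to the host feature area, and the hosts grow a dedicated synapse group
holding the exogenous pattern.  The embedded group has its own activation
counter and its own threshold/distance rule, and group 0 is never touched —
hosts keep their original receptive field (non-hijacking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import SyllableSequence
from .model import (
    Area,
    FeatureNeuron,
    NetworkState,
    ThresholdSpec,
    activate_concept,
    activate_feature,
    find_winner,
)


class NoGuidancePath(RuntimeError):
    """The guidance signal failed to activate any association neuron."""


def default_exog_features(x):
    """Identity-style extractor: stack a syllable sequence, pass arrays through."""
    if isinstance(x, SyllableSequence):
        return np.vstack(list(x))
    return np.asarray(x, dtype=float)


@dataclass
class EmbedConfig:
    guidance_channel: str  # e.g. "gustatory"
    target_channel: str  # e.g. "visual"
    host_area: str  # feature-area tag, e.g. "shape"
    modality: str  # tag for the embedded group, e.g. "ultrasonic"
    delta: float | None = None  # None -> 1/sigma incremental mean
    distance_kind: str = "dtw"  # rule for the embedded group
    threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("absolute", 9.0))
    embed_all_hosts: bool = True  # False -> only the first (lowest-id) host
    f_exog: object = None  # callable; None -> default_exog_features

    def __post_init__(self) -> None:
        if self.delta is not None and not (0 < self.delta <= 1):
            raise ValueError("fixed learning rate delta must be in (0, 1]")
        if self.f_exog is None:
            self.f_exog = default_exog_features


def descend_guidance(net: NetworkState, x_g, cfg: EmbedConfig) -> list[int]:
    """Route a guidance signal to host feature neurons of the target channel.

    ``x_g`` is matched (inference only, no learning) in the guidance
    channel's feature areas; the activated features activate guidance
    concepts, those reach association neurons, whose target-channel concept
    links lead down to feature neurons of the host area.  Returns
    de-duplicated host ids in ascending order.
    """
    g_feature_areas = [
        a for a in net.areas.values()
        if a.level == "feature" and a.channel == cfg.guidance_channel
    ]
    if not g_feature_areas:
        raise NoGuidancePath(f"no feature areas in guidance channel {cfg.guidance_channel!r}")
    activated_features: list[int] = []
    x_g = np.asarray(x_g, dtype=float)
    for area in sorted(g_feature_areas, key=lambda a: a.id):
        pool = [n for n in net.feature_neurons_in(area.id)
                if area.distance_kind == "dtw" or n.native_dim() == x_g.size]
        winner_id, _, _, _ = find_winner(net, area, x_g, space="native", candidates=pool)
        if winner_id is None:
            continue
        fired, _ = activate_feature(net.feature_neurons[winner_id], x_g, area, space="native")
        if fired:
            activated_features.append(winner_id)
    if not activated_features:
        raise NoGuidancePath("guidance signal activates no feature neuron")

    g_concepts = [
        c.id
        for c in sorted(net.concept_neurons.values(), key=lambda c: c.id)
        if net.concept_channel(c.id) == cfg.guidance_channel
        and activate_concept(net, c, activated_features)
    ]
    assoc_ids = sorted(
        {aid for cid in g_concepts for aid in net.assocs_linked_to(cid)}
    )
    if not assoc_ids:
        raise NoGuidancePath("guidance signal activates no association neuron")

    host_area = net.area_by_tag("feature", cfg.host_area)
    if host_area is None:
        raise KeyError(f"host area {cfg.host_area!r} does not exist")
    hosts: set[int] = set()
    for aid in assoc_ids:
        assoc = net.assoc_neurons[aid]
        for cid in assoc.concept_links.get(cfg.target_channel, []):
            concept = net.concept_neurons[cid]
            for fid in net.concept_feature_ids(concept):
                if net.feature_neurons[fid].area_id == host_area.id:
                    hosts.add(fid)
    return sorted(hosts)


def embed(net: NetworkState, host_id: int, x_e, cfg: EmbedConfig) -> FeatureNeuron:
    """Embed one exogenous sample into a host neuron's dedicated group.

    First contact grows a new synapse group initialised to
    ``f_exog(x_e)`` with its own activation count of 1; later samples
    update the group with the incremental mean (default) or a fixed
    learning-rate rule ``w <- w + delta (f_exog(x_e) - w)``.
    """
    host = net.feature_neurons[host_id]
    w_new = np.asarray(cfg.f_exog(x_e), dtype=float)
    if cfg.modality not in host.embedded:
        host.weight_groups.append(w_new.copy())
        gi = len(host.weight_groups) - 1
        host.embedded[cfg.modality] = gi
        host.group_sigmas[gi] = 1
        return host
    gi = host.embedded[cfg.modality]
    w = host.weight_groups[gi]
    if w.shape != w_new.shape:
        raise ValueError(
            f"exogenous feature shape {w_new.shape} drifted from embedded group {w.shape}"
        )
    host.group_sigmas[gi] += 1
    delta = cfg.delta if cfg.delta is not None else 1.0 / host.group_sigmas[gi]
    host.weight_groups[gi] = w + delta * (w_new - w)
    return host


def embed_pair(net: NetworkState, x_e, x_g, cfg: EmbedConfig) -> list[int]:
    """Full embedding step for one (exogenous, guidance) sample pair."""
    hosts = descend_guidance(net, x_g, cfg)
    if not cfg.embed_all_hosts:
        hosts = hosts[:1]
    for hid in hosts:
        embed(net, hid, x_e, cfg)
    return hosts


def embedded_activation(net: NetworkState, host_id: int, x_e, cfg: EmbedConfig) -> tuple[int, float]:
    """Evaluate a host's response through its embedded synapse group."""
    host = net.feature_neurons[host_id]
    area = net.areas[host.area_id]
    probe_area = Area(
        id=-1, level="feature", tag=cfg.modality, channel=area.channel,
        threshold=cfg.threshold, distance_kind=cfg.distance_kind,
    )
    return activate_feature(
        host, cfg.f_exog(x_e), probe_area, space=("embedded", cfg.modality),
        threshold=cfg.threshold,
    )
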
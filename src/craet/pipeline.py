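"""Run the staged multimodal experiment end to end.

`run_protocol` wires the whole stack: synthetic stream -> feature
extraction -> primary competitive learning (switching to the
dimensionality-increasing step when a stage adds receptors) -> unimodal
concept learning -> multimodal association (switching to response-modal
expansion when a stage adds a channel), with per-stage bookkeeping and
cross-modal recall scoring at the end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import features as F
from .association import (
    AnswerOracle,
    GroundTruthOracle,
    associate_pair,
    expand_response_modal,
    recall,
)
from .concepts import ConceptEvent, match_or_create_concept
from .model import (
    ASSOCIATION,
    CONCEPT,
    FEATURE,
    ORDER_DEPENDENT,
    ORDER_INDEPENDENT,
    NetworkState,
    ThresholdSpec,
)
from .primary import dimensionality_increase_step, process_feature, process_syllables, self_organize
from .synthetic import Sample, StagePlan, default_plan, default_world, generate_stream

log = logging.getLogger("craet")


@dataclass
class RunConfig:
    """All knobs of a protocol run; thresholds default to the study settings.

    Shape and color neurons fire within 1/4 of the L2 norm of their
    weights; audible syllable neurons within DTW 200; ultrasonic syllable
    neurons within DTW 9; basic flavor neurons within 0.015.
    """

    seed: int = 0
    passes: int = 2
    shape_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("relative", 0.25))
    color_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("relative", 0.25))
    audible_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("absolute", 200.0))
    ultrasonic_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("absolute", 9.0))
    flavor_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("absolute", 0.015))
    n_descriptors: int = 32
    hist_bins: int = 8
    mfcc_coeff: int = 12
    energy_thresh: float = 1e-4
    zcr_thresh: float = 0.35
    min_syllable_frames: int = 3
    max_edge_age: int = 50
    prune_edges: bool = True
    oracle: str = "ground_truth"  # ground_truth | interactive; or pass an AnswerOracle

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = {"kind": v.kind, "value": v.value} if isinstance(v, ThresholdSpec) else v
        return d


@dataclass
class RunReport:
    stage_counts: list = field(default_factory=list)
    questions: list = field(default_factory=list)
    rejected: list = field(default_factory=list)
    recall_accuracy: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)  # concept id -> object name
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "questions": self.questions,
            "rejected": self.rejected,
            "recall_accuracy": self.recall_accuracy,
            "labels": {str(k): v for k, v in sorted(self.labels.items())},
            "config": self.config,
        }


def build_network(cfg: RunConfig) -> NetworkState:
    """Create the empty network with the visual channel's areas pre-wired.

    Later channels (auditory, gustatory) appear lazily when their first
    sample arrives — the online-extension requirement.
    """
    net = NetworkState(seed=cfg.seed)
    net.ensure_area(FEATURE, "shape", "visual", threshold=cfg.shape_threshold)
    net.ensure_area(FEATURE, "color", "visual", threshold=cfg.color_threshold)
    net.ensure_area(CONCEPT, "visual", "visual", mode=ORDER_INDEPENDENT)
    net.wiring.update({"shape": "visual", "color": "visual"})
    return net


class ProtocolRunner:
    """Stateful sample-by-sample executor of the staged protocol."""

    def __init__(self, cfg: RunConfig, oracle: AnswerOracle | None = None):
        self.cfg = cfg
        self.net = build_network(cfg)
        self.labels: dict[int, str] = {}  # concept id -> object name
        self.oracle = oracle or GroundTruthOracle(self.labels)
        self.questions: list = []
        self.rejected: list = []
        self._expanded_color = False

    # -- per-channel steps ------------------------------------------------

    def _visual_events(self, sample: Sample):
        cfg, net = self.cfg, self.net
        img = sample.image
        shape_area = net.area_by_tag(FEATURE, "shape")
        d = F.shape_descriptor(img, n_desc=cfg.n_descriptors)
        ev_shape = process_feature(net, shape_area, d)
        self_organize(net, shape_area, ev_shape.neuron_id, ev_shape.runner_up_id,
                      max_age=cfg.max_edge_age, prune=cfg.prune_edges)
        events = [ev_shape]

        color_channels = [c for c in ("grey", "G", "B", "R") if c in img.planes]
        if len(color_channels) > 1:
            color_area = net.area_by_tag(FEATURE, "color")
            if "R" in color_channels:
                y_I = F.color_histogram(img, [c for c in color_channels if c != "R"], cfg.hist_bins)
                y_II = F.color_histogram(img, ["R"], cfg.hist_bins)
                ev_color = dimensionality_increase_step(net, color_area, y_I, y_II)
            else:
                h = F.color_histogram(img, color_channels, cfg.hist_bins)
                ev_color = process_feature(net, color_area, h)
                self_organize(net, color_area, ev_color.neuron_id, ev_color.runner_up_id,
                              max_age=cfg.max_edge_age, prune=cfg.prune_edges)
            events.append(ev_color)
        visual_area = self.net.area_by_tag(CONCEPT, "visual")
        cev = match_or_create_concept(net, visual_area, events, ORDER_INDEPENDENT)
        self._label(cev, sample)
        return cev

    def _auditory_events(self, sample: Sample) -> ConceptEvent:
        cfg, net = self.cfg, self.net
        concept_area = net.ensure_area(CONCEPT, "auditory", "auditory", mode=ORDER_DEPENDENT)
        if sample.audible is not None:
            area = net.ensure_area(
                FEATURE, "syllable", "auditory",
                threshold=cfg.audible_threshold, distance_kind="dtw",
            )
            net.wiring.setdefault("syllable", "auditory")
            ranges = F.segment_syllables(
                sample.audible, cfg.energy_thresh, cfg.zcr_thresh, cfg.min_syllable_frames
            )
            seq = F.mfcc_features(sample.audible, ranges, n_coeff=cfg.mfcc_coeff)
        else:
            area = net.ensure_area(
                FEATURE, "ultrasonic", "auditory",
                threshold=cfg.ultrasonic_threshold, distance_kind="dtw",
            )
            net.wiring.setdefault("ultrasonic", "auditory")
            seq = sample.ultrasonic
        f_events = process_syllables(net, area, seq)
        cev = match_or_create_concept(net, concept_area, f_events, ORDER_DEPENDENT)
        self._label(cev, sample)
        return cev

    def _gustatory_events(self, sample: Sample) -> ConceptEvent:
        cfg, net = self.cfg, self.net
        area = net.ensure_area(FEATURE, "flavor", "gustatory", threshold=cfg.flavor_threshold)
        concept_area = net.ensure_area(CONCEPT, "gustatory", "gustatory", mode=ORDER_INDEPENDENT)
        net.wiring.setdefault("flavor", "gustatory")
        fv = F.flavor_features(sample.flavor)
        ev = process_feature(net, area, fv)
        cev = match_or_create_concept(net, concept_area, [ev], ORDER_INDEPENDENT)
        self._label(cev, sample)
        return cev

    def _label(self, cev: ConceptEvent, sample: Sample) -> None:
        # ground truth of the most recent activator: a concept shared by
        # several objects (the confusable pair before the R receptor) keeps
        # whichever object touched it last, and settles once concepts split
        self.labels[cev.concept_id] = sample.name
        if cev.created:
            log.info("stage %d: new concept %d (%s) in area %d",
                     sample.stage, cev.concept_id, sample.name, cev.area_id)

    # -- sample loop ------------------------------------------------------

    def step(self, sample: Sample) -> None:
        v_event = self._visual_events(sample) if sample.image is not None else None
        if sample.audible is not None or sample.ultrasonic is not None:
            a_event = self._auditory_events(sample)
            if v_event is not None:
                ev = associate_pair(self.net, v_event, a_event, self.oracle)
                log.info("stage %d (%s): association case %s via %s",
                         sample.stage, sample.name, ev.case, ev.assoc_ids)
                if not ev.accepted:
                    self.rejected.append({"stage": sample.stage, "object": sample.name,
                                          "case": ev.case})
        if sample.flavor is not None:
            g_event = self._gustatory_events(sample)
            if v_event is not None:
                ev = expand_response_modal(self.net, v_event, g_event)
                log.info("stage %d (%s): response-modal case %s via %s",
                         sample.stage, sample.name, ev.case, ev.assoc_ids)

    def counts(self) -> dict:
        net = self.net
        per_area = {}
        for area in sorted(net.areas.values(), key=lambda a: a.id):
            if area.level == FEATURE:
                per_area[area.tag] = len(net.feature_neurons_in(area.id))
        return {
            "feature_neurons": per_area,
            "concept_neurons": len(net.concept_neurons),
            "assoc_neurons": len(net.assoc_neurons),
            "assoc_connections": len(net.assoc_conns),
        }


def object_concepts(net: NetworkState, labels: dict[int, str], channel: str) -> dict[str, list[int]]:
    """Concept ids per object name within one channel."""
    out: dict[str, list[int]] = {}
    for cid, name in labels.items():
        if cid in net.concept_neurons and net.concept_channel(cid) == channel:
            out.setdefault(name, []).append(cid)
    return out


def recall_accuracy(
    net: NetworkState, labels: dict[int, str], src_channel: str, dst_channel: str
) -> float:
    """Fraction of source concepts whose top recall hit is the right object."""
    src = object_concepts(net, labels, src_channel)
    total = correct = 0
    for name, cids in sorted(src.items()):
        for cid in cids:
            total += 1
            ranked = recall(net, cid, dst_channel)
            if ranked and labels.get(ranked[0]) == name:
                correct += 1
    return correct / total if total else 0.0


def run_protocol(
    cfg: RunConfig,
    specs=None,
    plan: StagePlan | None = None,
    oracle: AnswerOracle | None = None,
) -> tuple[NetworkState, RunReport]:
    """Execute the staged schedule and score cross-modal recall."""
    specs = specs if specs is not None else default_world()
    plan = plan if plan is not None else default_plan(passes=cfg.passes, seed=cfg.seed)
    runner = ProtocolRunner(cfg, oracle=oracle)
    report = RunReport(config=cfg.to_dict())
    stream = generate_stream(specs, plan)
    current_stage = None
    for sample in stream:
        if sample.stage != current_stage:
            if current_stage is not None:
                report.stage_counts.append({"stage": current_stage, **runner.counts()})
            current_stage = sample.stage
        runner.step(sample)
    report.stage_counts.append({"stage": current_stage, **runner.counts()})
    for src, dst in (
        ("visual", "auditory"), ("auditory", "visual"),
        ("visual", "gustatory"), ("gustatory", "visual"),
    ):
        report.recall_accuracy[f"{src}->{dst}"] = recall_accuracy(runner.net, runner.labels, src, dst)
    report.rejected = runner.rejected
    report.questions = list(getattr(runner.oracle, "log", []))
    report.labels = dict(runner.labels)
    return runner.net, report


# -- persistence and inspection ---------------------------------------------


def save_network(net: NetworkState, path) -> None:
    with open(path, "w") as fh:
        fh.write(net.to_json())


def load_network(path) -> NetworkState:
    with open(path) as fh:
        try:
            return NetworkState.from_json(fh.read())
        except (KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed network file {path}: {exc}") from exc


def circuit_report(net: NetworkState, assoc_id: int) -> dict:
    """Structured description of one association neuron's circuit."""
    if assoc_id not in net.assoc_neurons:
        raise KeyError(f"association neuron {assoc_id} does not exist")
    assoc = net.assoc_neurons[assoc_id]
    channels = {}
    for channel, cids in sorted(assoc.concept_links.items()):
        entries = []
        for cid in cids:
            concept = net.concept_neurons[cid]
            feats = []
            for conn_id in concept.feature_links:
                conn = net.feature_conns[conn_id]
                neuron = net.feature_neurons[conn.feature_id]
                w = neuron.weight_groups[0]
                feats.append({
                    "feature_id": conn.feature_id,
                    "area": net.areas[neuron.area_id].tag,
                    "position": conn.position,
                    "rho": conn.rho,
                    "sigma": neuron.sigma,
                    "weight_summary": {
                        "dim": int(np.asarray(w).size),
                        "groups": len(neuron.weight_groups),
                        "norm": float(np.linalg.norm(np.asarray(w))),
                    },
                })
            entries.append({"concept_id": cid, "mode": concept.mode, "features": feats})
        channels[channel] = entries
    conns = [
        {"concept_m": c.concept_m_id, "concept_n": c.concept_n_id, "rho": c.rho}
        for c in net.conns_through(assoc_id)
    ]
    return {"assoc_id": assoc_id, "channels": channels, "connections": conns}


def format_circuit_report(report: dict) -> str:
    lines = [f"association neuron {report['assoc_id']}"]
    for channel, entries in report["channels"].items():
        lines.append(f"  [{channel}]")
        for entry in entries:
            lines.append(f"    concept {entry['concept_id']} ({entry['mode']})")
            for f in entry["features"]:
                lines.append(
                    f"      feature {f['feature_id']} in {f['area']} "
                    f"(pos {f['position']}, rho {f['rho']}, sigma {f['sigma']}, "
                    f"dim {f['weight_summary']['dim']})"
                )
    lines.append("  connections:")
    for c in report["connections"]:
        lines.append(f"    {c['concept_m']} <-> {c['concept_n']} (rho {c['rho']})")
    return "\n".join(lines)
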
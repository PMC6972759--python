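"""Core data model of the perception-coordination network.

The network has three levels:

* **feature neurons** in primary sensory areas — prototype units ``{w, sigma}``
  that fire when an input lies within a threshold of their weight vector,
* **concept neurons** in unimodal association areas — AND-circuits over
  feature neurons (order-independent for vision, order-dependent for words),
* **association neurons** in the multimodal association area — OR-hubs that
  bind concept neurons across perceptual channels.

Feature neurons are *synapse expandable*: their weights are an ordered list
of groups.  Group 0 holds the original synapses; later groups are appended
when new receptors arrive (dimensionality increase) or when an exogenous
modality is embedded.  Appending a group never rewrites an existing one,
which is what guarantees the non-hijacking property: responses computed on
the original synapses are identical before and after any expansion.

All plasticity bookkeeping is two integer counters: ``sigma`` (cumulative
activations of a neuron) and ``rho`` (cumulative activations of a
connection).  Weight learning is the winner-take-all incremental mean
``sigma += 1; w += (y - w)/sigma``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .features import dtw_distance

SCHEMA_VERSION = 1

FEATURE = "feature"
CONCEPT = "concept"
ASSOCIATION = "association"

ORDER_INDEPENDENT = "order_independent"
ORDER_DEPENDENT = "order_dependent"


class DimensionMismatch(ValueError):
    """Input vector length does not match a neuron's synapse count."""


@dataclass
class ThresholdSpec:
    """Response-range rule for an area.

    ``relative`` thresholds resolve against the current L2 norm of the
    weight vector being tested (the visual areas use 1/4 of ``||w||``);
    ``absolute`` thresholds are plain scalars (syllable and flavor areas).
    """

    kind: str  # "relative" | "absolute"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "absolute"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("threshold must be non-negative")
        if self.kind == "relative" and not (0 < self.value <= 1):
            raise ValueError("relative threshold fraction must be in (0, 1]")

    def resolve(self, w) -> float:
        if self.kind == "absolute":
            return float(self.value)
        return float(self.value) * float(np.linalg.norm(np.asarray(w, dtype=float)))


@dataclass
class Area:
    id: int
    level: str  # feature | concept | association
    tag: str  # modality tag: shape, color, syllable, ultrasonic, flavor, ...
    channel: str  # perceptual channel: visual, auditory, gustatory, ...
    threshold: ThresholdSpec | None = None
    distance_kind: str = "euclidean"  # euclidean | dtw
    mode: str | None = None  # concept areas: order_(in)dependent default


@dataclass
class FeatureNeuron:
    """Synapse-expandable prototype unit ``{w, sigma}``.

    ``weight_groups[0]`` is the original receptive field and is never
    re-dimensioned.  Native groups (original + receptor expansions) are
    concatenated to form the full-space weight vector; embedded groups
    (exogenous modalities, keyed in ``embedded``) live in their own space
    with their own activation counters ``group_sigmas``.
    """

    id: int
    area_id: int
    weight_groups: list  # list of np.ndarray (1-D, or 2-D for DTW templates)
    sigma: int = 1
    expanded: bool = False  # completed the dimensionality-increasing process
    embedded: dict = field(default_factory=dict)  # modality tag -> group index
    group_sigmas: dict = field(default_factory=dict)  # group index -> count

    def original_weights(self) -> np.ndarray:
        return self.weight_groups[0]

    def native_group_indices(self) -> list[int]:
        emb = set(self.embedded.values())
        return [i for i in range(len(self.weight_groups)) if i not in emb]

    def native_weights(self) -> np.ndarray:
        groups = [self.weight_groups[i] for i in self.native_group_indices()]
        if len(groups) == 1:
            return groups[0]
        return np.concatenate(groups)

    def native_dim(self) -> int:
        return sum(self.weight_groups[i].size for i in self.native_group_indices())


@dataclass
class FeatureConnection:
    id: int
    concept_id: int
    feature_id: int
    position: int  # 0-based index in the concept's circuit
    rho: int = 1


@dataclass
class ConceptNeuron:
    id: int
    area_id: int
    mode: str  # order_independent | order_dependent
    feature_links: list = field(default_factory=list)  # FeatureConnection ids


@dataclass
class AssociationNeuron:
    id: int
    concept_links: dict = field(default_factory=dict)  # channel -> [concept ids]

    def linked_concepts(self) -> set[int]:
        return {cid for cids in self.concept_links.values() for cid in cids}

    def add_link(self, channel: str, concept_id: int) -> None:
        ids = self.concept_links.setdefault(channel, [])
        if concept_id not in ids:
            ids.append(concept_id)


@dataclass
class AssociationConnection:
    """Connection triple c_(m,i,n): concepts m, n bound through association i.

    Stored with ``concept_m_id < concept_n_id`` so the triple is unique
    regardless of presentation order; ``rho`` counts its activations.
    """

    id: int
    concept_m_id: int
    assoc_id: int
    concept_n_id: int
    rho: int = 1

    def key(self) -> tuple[int, int, int]:
        return (self.concept_m_id, self.assoc_id, self.concept_n_id)


class NetworkState:
    """All areas, neurons and connections, plus id bookkeeping.

    Areas are created lazily as channels appear.  Ids are global monotone
    integers and are never reused, so a serialized network replays
    deterministically.
    """

    def __init__(self, seed: int = 0) -> None:
        self.seed = int(seed)
        self._next_id = 1
        self.areas: dict[int, Area] = {}
        self.feature_neurons: dict[int, FeatureNeuron] = {}
        self.concept_neurons: dict[int, ConceptNeuron] = {}
        self.assoc_neurons: dict[int, AssociationNeuron] = {}
        self.feature_conns: dict[int, FeatureConnection] = {}
        self.assoc_conns: dict[int, AssociationConnection] = {}
        # competitive-Hebbian topology metadata: area id -> {(i, j): age}
        self.edges: dict[int, dict[tuple[int, int], int]] = {}
        # feature-area tag -> concept-area tag it feeds
        self.wiring: dict[str, str] = {}

    # -- id and lookup helpers -------------------------------------------

    def new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def area_by_tag(self, level: str, tag: str) -> Area | None:
        for area in self.areas.values():
            if area.level == level and area.tag == tag:
                return area
        return None

    def ensure_area(self, level: str, tag: str, channel: str, **kw) -> Area:
        area = self.area_by_tag(level, tag)
        if area is None:
            area = Area(id=self.new_id(), level=level, tag=tag, channel=channel, **kw)
            self.areas[area.id] = area
        return area

    def feature_neurons_in(self, area_id: int) -> list[FeatureNeuron]:
        return [n for n in self.feature_neurons.values() if n.area_id == area_id]

    def concept_neurons_in(self, area_id: int) -> list[ConceptNeuron]:
        return [n for n in self.concept_neurons.values() if n.area_id == area_id]

    def concept_channel(self, concept_id: int) -> str:
        return self.areas[self.concept_neurons[concept_id].area_id].channel

    def concept_feature_ids(self, concept: ConceptNeuron) -> list[int]:
        return [self.feature_conns[cid].feature_id for cid in concept.feature_links]

    def assocs_linked_to(self, concept_id: int) -> list[int]:
        return sorted(
            a.id for a in self.assoc_neurons.values() if concept_id in a.linked_concepts()
        )

    def conns_through(self, assoc_id: int) -> list[AssociationConnection]:
        return sorted(
            (c for c in self.assoc_conns.values() if c.assoc_id == assoc_id),
            key=lambda c: c.id,
        )

    def find_assoc_conn(self, c1: int, assoc_id: int, c2: int) -> AssociationConnection | None:
        m, n = min(c1, c2), max(c1, c2)
        for c in self.assoc_conns.values():
            if c.key() == (m, assoc_id, n):
                return c
        return None

    # -- construction helpers --------------------------------------------

    def add_feature_neuron(self, area: Area, groups: Sequence, expanded: bool = False) -> FeatureNeuron:
        neuron = FeatureNeuron(
            id=self.new_id(),
            area_id=area.id,
            weight_groups=[np.array(g, dtype=float) for g in groups],
            sigma=1,
            expanded=expanded,
        )
        self.feature_neurons[neuron.id] = neuron
        return neuron

    def add_concept_neuron(self, area: Area, mode: str, feature_ids: Sequence[int]) -> ConceptNeuron:
        if not feature_ids:
            raise ValueError("a concept needs at least one feature link")
        concept = ConceptNeuron(id=self.new_id(), area_id=area.id, mode=mode)
        self.concept_neurons[concept.id] = concept
        for pos, fid in enumerate(feature_ids):
            self.link_concept_feature(concept, fid, pos)
        return concept

    def link_concept_feature(self, concept: ConceptNeuron, feature_id: int, position: int) -> FeatureConnection:
        if feature_id not in self.feature_neurons:
            raise KeyError(f"feature neuron {feature_id} does not exist")
        conn = FeatureConnection(
            id=self.new_id(), concept_id=concept.id, feature_id=feature_id, position=position
        )
        self.feature_conns[conn.id] = conn
        concept.feature_links.append(conn.id)
        return conn

    def add_assoc_neuron(self) -> AssociationNeuron:
        neuron = AssociationNeuron(id=self.new_id())
        self.assoc_neurons[neuron.id] = neuron
        return neuron

    def add_assoc_conn(self, c1: int, assoc_id: int, c2: int) -> AssociationConnection:
        ch1 = self.concept_channel(c1)
        ch2 = self.concept_channel(c2)
        if ch1 == ch2:
            raise ValueError("association connection endpoints must be in different channels")
        if self.find_assoc_conn(c1, assoc_id, c2) is not None:
            raise ValueError(f"triple ({c1},{assoc_id},{c2}) already exists")
        m, n = min(c1, c2), max(c1, c2)
        conn = AssociationConnection(id=self.new_id(), concept_m_id=m, assoc_id=assoc_id, concept_n_id=n)
        self.assoc_conns[conn.id] = conn
        assoc = self.assoc_neurons[assoc_id]
        assoc.add_link(ch1, c1)
        assoc.add_link(ch2, c2)
        return conn

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a: np.ndarray):
            return {"shape": list(a.shape), "data": np.asarray(a, dtype=float).ravel().tolist()}

        return {
            "meta": {"version": SCHEMA_VERSION, "seed": self.seed, "next_id": self._next_id},
            "wiring": dict(sorted(self.wiring.items())),
            "areas": [
                {
                    "id": a.id,
                    "level": a.level,
                    "tag": a.tag,
                    "channel": a.channel,
                    "threshold": None
                    if a.threshold is None
                    else {"kind": a.threshold.kind, "value": a.threshold.value},
                    "distance_kind": a.distance_kind,
                    "mode": a.mode,
                }
                for a in sorted(self.areas.values(), key=lambda a: a.id)
            ],
            "feature_neurons": [
                {
                    "id": n.id,
                    "area_id": n.area_id,
                    "weight_groups": [arr(g) for g in n.weight_groups],
                    "sigma": n.sigma,
                    "expanded": n.expanded,
                    "embedded": dict(sorted(n.embedded.items())),
                    "group_sigmas": {str(k): v for k, v in sorted(n.group_sigmas.items())},
                }
                for n in sorted(self.feature_neurons.values(), key=lambda n: n.id)
            ],
            "concept_neurons": [
                {"id": n.id, "area_id": n.area_id, "mode": n.mode, "feature_links": list(n.feature_links)}
                for n in sorted(self.concept_neurons.values(), key=lambda n: n.id)
            ],
            "assoc_neurons": [
                {"id": n.id, "concept_links": {k: list(v) for k, v in sorted(n.concept_links.items())}}
                for n in sorted(self.assoc_neurons.values(), key=lambda n: n.id)
            ],
            "feature_conns": [
                {
                    "id": c.id,
                    "concept_id": c.concept_id,
                    "feature_id": c.feature_id,
                    "position": c.position,
                    "rho": c.rho,
                }
                for c in sorted(self.feature_conns.values(), key=lambda c: c.id)
            ],
            "assoc_conns": [
                {
                    "id": c.id,
                    "concept_m_id": c.concept_m_id,
                    "assoc_id": c.assoc_id,
                    "concept_n_id": c.concept_n_id,
                    "rho": c.rho,
                }
                for c in sorted(self.assoc_conns.values(), key=lambda c: c.id)
            ],
            "edges": {
                str(area_id): [[i, j, age] for (i, j), age in sorted(pairs.items())]
                for area_id, pairs in sorted(self.edges.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkState":
        meta = d["meta"]
        if meta.get("version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported network schema version {meta.get('version')!r}")
        net = cls(seed=meta["seed"])
        net._next_id = meta["next_id"]
        net.wiring = dict(d.get("wiring", {}))
        for a in d["areas"]:
            thr = a["threshold"]
            net.areas[a["id"]] = Area(
                id=a["id"],
                level=a["level"],
                tag=a["tag"],
                channel=a["channel"],
                threshold=None if thr is None else ThresholdSpec(thr["kind"], thr["value"]),
                distance_kind=a["distance_kind"],
                mode=a["mode"],
            )
        for n in d["feature_neurons"]:
            net.feature_neurons[n["id"]] = FeatureNeuron(
                id=n["id"],
                area_id=n["area_id"],
                weight_groups=[
                    np.array(g["data"], dtype=float).reshape(g["shape"]) for g in n["weight_groups"]
                ],
                sigma=n["sigma"],
                expanded=n["expanded"],
                embedded=dict(n["embedded"]),
                group_sigmas={int(k): v for k, v in n["group_sigmas"].items()},
            )
        for n in d["concept_neurons"]:
            net.concept_neurons[n["id"]] = ConceptNeuron(
                id=n["id"], area_id=n["area_id"], mode=n["mode"], feature_links=list(n["feature_links"])
            )
        for n in d["assoc_neurons"]:
            net.assoc_neurons[n["id"]] = AssociationNeuron(
                id=n["id"], concept_links={k: list(v) for k, v in n["concept_links"].items()}
            )
        for c in d["feature_conns"]:
            net.feature_conns[c["id"]] = FeatureConnection(
                id=c["id"],
                concept_id=c["concept_id"],
                feature_id=c["feature_id"],
                position=c["position"],
                rho=c["rho"],
            )
        for c in d["assoc_conns"]:
            net.assoc_conns[c["id"]] = AssociationConnection(
                id=c["id"],
                concept_m_id=c["concept_m_id"],
                assoc_id=c["assoc_id"],
                concept_n_id=c["concept_n_id"],
                rho=c["rho"],
            )
        for area_id, triples in d.get("edges", {}).items():
            net.edges[int(area_id)] = {(i, j): age for i, j, age in triples}
        return net

    @classmethod
    def from_json(cls, s: str) -> "NetworkState":
        return cls.from_dict(json.loads(s))


# -- primitive operations --------------------------------------------------


def _select_weights(neuron: FeatureNeuron, space) -> np.ndarray:
    """Pick the weight vector for a search space.

    ``space`` is one of ``"original"`` (group 0), ``"native"`` (all
    non-embedded groups concatenated) or ``("embedded", tag)``.
    """
    if space == "original":
        return neuron.original_weights()
    if space == "native":
        return neuron.native_weights()
    if isinstance(space, tuple) and space[0] == "embedded":
        tag = space[1]
        if tag not in neuron.embedded:
            raise KeyError(f"neuron {neuron.id} has no embedded modality {tag!r}")
        return neuron.weight_groups[neuron.embedded[tag]]
    raise ValueError(f"unknown space selector {space!r}")


def feature_distance(neuron: FeatureNeuron, y, area: Area, space="native") -> float:
    w = _select_weights(neuron, space)
    if area.distance_kind == "dtw":
        return dtw_distance(np.atleast_2d(np.asarray(y, dtype=float)), np.atleast_2d(w))
    y = np.asarray(y, dtype=float)
    if y.shape != w.shape:
        raise DimensionMismatch(
            f"neuron {neuron.id}: input of length {y.size} does not match "
            f"expected length {w.size} in space {space!r}"
        )
    return float(np.linalg.norm(y - w))


def activate_feature(
    neuron: FeatureNeuron, y, area: Area, space="native", threshold: ThresholdSpec | None = None
) -> tuple[int, float]:
    """Evaluate the feature-neuron activation function.

    Fires (returns 1) iff the distance between the input and the selected
    weight group is within the resolved threshold.  Euclidean areas use the
    inclusive rule ``d <= theta``; DTW areas use the strict rule ``d < theta``.
    The neuron is not modified.
    """
    thr_spec = threshold if threshold is not None else area.threshold
    if thr_spec is None:
        raise ValueError(f"area {area.tag!r} has no threshold")
    d = feature_distance(neuron, y, area, space)
    theta = thr_spec.resolve(_select_weights(neuron, space))
    if area.distance_kind == "dtw":
        fired = d < theta
    else:
        fired = d <= theta
    return (1 if fired else 0), d


def find_winner(
    net: NetworkState,
    area: Area,
    y,
    space="native",
    candidates: Iterable[FeatureNeuron] | None = None,
) -> tuple[int | None, float, int | None, float]:
    """Arg-min competition over an area.

    Returns ``(winner_id, winner_distance, runner_up_id, runner_up_distance)``.
    Ties break deterministically toward the smaller neuron id.  An empty
    candidate set yields the sentinel ``(None, inf, None, inf)`` — the caller
    then creates a neuron.
    """
    pool = list(candidates) if candidates is not None else net.feature_neurons_in(area.id)
    best: tuple[float, int] | None = None
    second: tuple[float, int] | None = None
    for n in sorted(pool, key=lambda n: n.id):
        d = feature_distance(n, y, area, space)
        entry = (d, n.id)
        if best is None or entry < best:
            second = best
            best = entry
        elif second is None or entry < second:
            second = entry
    if best is None:
        return None, float("inf"), None, float("inf")
    if second is None:
        return best[1], best[0], None, float("inf")
    return best[1], best[0], second[1], second[0]


def wta_update(neuron: FeatureNeuron, y, space="native") -> FeatureNeuron:
    """Winner-take-all incremental-mean update: sigma += 1, w += (y - w)/sigma.

    For ``space="original"`` only group 0 is moved (the original receptive
    field absorbs a partial observation); for ``space="native"`` the update
    is applied across all native groups.  DTW template neurons pass 2-D
    weights of matching shape.
    """
    y = np.asarray(y, dtype=float)
    neuron.sigma += 1
    if space == "original":
        w = neuron.original_weights()
        if y.shape != w.shape:
            raise DimensionMismatch(
                f"neuron {neuron.id}: update of length {y.size} vs original length {w.size}"
            )
        neuron.weight_groups[0] = w + (y - w) / neuron.sigma
        return neuron
    if space != "native":
        raise ValueError(f"unknown update space {space!r}")
    idx = neuron.native_group_indices()
    sizes = [neuron.weight_groups[i].size for i in idx]
    if y.ndim != 1 or y.size != sum(sizes):
        raise DimensionMismatch(
            f"neuron {neuron.id}: update of length {y.size} vs native length {sum(sizes)}"
        )
    w = np.concatenate([neuron.weight_groups[i] for i in idx])
    w = w + (y - w) / neuron.sigma
    offset = 0
    for i, size in zip(idx, sizes):
        neuron.weight_groups[i] = w[offset : offset + size]
        offset += size
    return neuron


def expand_feature_synapses(neuron: FeatureNeuron, y_II) -> FeatureNeuron:
    """Append a new native weight group initialised to ``y_II``.

    Realises the dimensionality-increasing step: the neuron grows synapses
    for the novel receptors, extending its receptive field from R^n to
    R^(n+m) while leaving group 0 bit-identical.  A neuron expands at most
    once per receptor set.
    """
    if neuron.expanded:
        raise ValueError(
            f"neuron {neuron.id} already completed dimensionality increase; "
            "use wta_update in the full space instead"
        )
    neuron.weight_groups.append(np.array(y_II, dtype=float))
    neuron.expanded = True
    return neuron


def activate_concept(net: NetworkState, concept: ConceptNeuron, events: Sequence[int]) -> int:
    """Concept-neuron activation over a list of activated feature ids.

    Order-independent mode fires when the concept's full feature set is a
    subset of the activated set; order-dependent mode requires the exact
    activation sequence (same length, same order).
    """
    linked = net.concept_feature_ids(concept)
    if concept.mode == ORDER_INDEPENDENT:
        return 1 if set(linked) <= set(events) else 0
    if concept.mode == ORDER_DEPENDENT:
        return 1 if list(linked) == list(events) else 0
    raise ValueError(f"unknown activation mode {concept.mode!r}")


def activate_association(net: NetworkState, assoc: AssociationNeuron, activated: Iterable[int]) -> int:
    """Multimodality activation: any one linked concept suffices (OR)."""
    return 1 if assoc.linked_concepts() & set(activated) else 0
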
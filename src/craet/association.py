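"""Multimodal association learning and cross-modal recall.

The multimodal area binds concept neurons of different channels through
association neurons.  Binding a vision/audition pair follows a four-case
logic driven by which of the two concepts already reaches the association
level; the ambiguous cases are resolved by asking the user a yes/no
question.  When an entirely new channel comes online (e.g. gustation) the
same four cases run *without* questions — the response-modal expansion:
existing association neurons simply grow synapses to the new channel's
concepts, which immediately gives them a reverse signal pathway from the
new channel back to the old ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .concepts import ConceptEvent
from .model import NetworkState


class OracleExhausted(RuntimeError):
    """A scripted oracle ran out of answers."""


class AnswerOracle:
    """Contract: given (question kind, concept ids involved) return yes/no."""

    def answer(self, kind: str, subject_ids, candidate_ids) -> bool:  # pragma: no cover
        raise NotImplementedError


class ScriptedOracle(AnswerOracle):
    """Consume a fixed list of {"question_kind": ..., "answer": bool} entries."""

    def __init__(self, script: list[dict]):
        self.script = list(script)
        self.cursor = 0
        self.log: list[dict] = []

    @classmethod
    def from_file(cls, path) -> "ScriptedOracle":
        with open(path) as fh:
            return cls(json.load(fh))

    def answer(self, kind, subject_ids, candidate_ids) -> bool:
        if self.cursor >= len(self.script):
            raise OracleExhausted(f"no scripted answer left for question {kind!r}")
        entry = self.script[self.cursor]
        self.cursor += 1
        if entry.get("question_kind") not in (None, kind):
            raise OracleExhausted(
                f"scripted question {entry['question_kind']!r} does not match asked {kind!r}"
            )
        self.log.append({"question_kind": kind, "answer": bool(entry["answer"])})
        return bool(entry["answer"])


class GroundTruthOracle(AnswerOracle):
    """Answer from synthetic ground truth: yes iff all concepts share a label."""

    def __init__(self, labels: dict[int, str]):
        self.labels = labels
        self.log: list[dict] = []

    def answer(self, kind, subject_ids, candidate_ids) -> bool:
        ids = list(subject_ids) + list(candidate_ids)
        known = {self.labels[i] for i in ids if i in self.labels}
        ans = len(known) <= 1
        self.log.append({"question_kind": kind, "ids": ids, "answer": ans})
        return ans


class InteractiveOracle(AnswerOracle):
    """Prompt on stdin, mirroring the network's question phrasing."""

    QUESTIONS = {
        "name_known_view_new": (
            "I find the current input name {subj} has been used to call other "
            "views in {cand}; can it also represent the current input view? [y/n] "
        ),
        "view_known_name_new": (
            "The object was called {cand} previously. Is it also called {subj}? [y/n] "
        ),
        "inconsistent_pair": (
            "The current input pair {subj} is inconsistent with previous pairs, "
            "is this pair an expected combination? [y/n] "
        ),
    }

    def answer(self, kind, subject_ids, candidate_ids) -> bool:  # pragma: no cover
        prompt = self.QUESTIONS.get(kind, "{subj} vs {cand}? [y/n] ")
        reply = input(prompt.format(subj=list(subject_ids), cand=list(candidate_ids)))
        return reply.strip().lower().startswith("y")


@dataclass
class AssociationEvent:
    case: str  # new_view | new_name | consistent | inconsistent_accepted |
    #            inconsistent_rejected | both_new | expanded
    assoc_ids: list = field(default_factory=list)
    accepted: bool = True
    connection_ids: list = field(default_factory=list)


def _connect_through(net: NetworkState, assoc_ids, c1: int, c2: int) -> list[int]:
    """Create (or, defensively, strengthen) the c1-c2 triple through each hub."""
    conn_ids = []
    for aid in sorted(assoc_ids):
        conn = net.find_assoc_conn(c1, aid, c2)
        if conn is None:
            conn = net.add_assoc_conn(c1, aid, c2)
        else:
            conn.rho += 1
        conn_ids.append(conn.id)
    return conn_ids


def _new_one_to_one(net: NetworkState, c1: int, c2: int) -> tuple[int, int]:
    assoc = net.add_assoc_neuron()
    conn = net.add_assoc_conn(c1, assoc.id, c2)
    return assoc.id, conn.id


def associate_pair(
    net: NetworkState, v_event: ConceptEvent, a_event: ConceptEvent, oracle: AnswerOracle
) -> AssociationEvent:
    """Four-case binding of a just-activated cross-channel concept pair.

    With N_v / N_a the association neurons reachable from the two concepts:

    * both empty — a brand-new combination; one association neuron with a
      1-to-1 circuit records it,
    * only the name known — ask whether the known name covers the new view;
      yes connects the pair through every hub of the name, no stores the
      view alone on a fresh hub (a single-endpoint "Type O" circuit),
    * only the view known — ask whether the object also bears the new name;
      yes connects through every hub of the view, no rejects the name,
    * both known — an intersection of hubs means a familiar pair, whose
      common connections are strengthened (rho + 1); disjoint hubs mean an
      inconsistent pair, accepted (connected through the union of hubs)
      or rejected per the user's answer.
    """
    v, a = v_event.concept_id, a_event.concept_id
    n_v = set(net.assocs_linked_to(v))
    n_a = set(net.assocs_linked_to(a))

    if not n_v and not n_a:
        assoc_id, conn_id = _new_one_to_one(net, v, a)
        return AssociationEvent("both_new", [assoc_id], True, [conn_id])

    if not n_v and n_a:
        known_views = sorted(
            {c.concept_m_id if c.concept_m_id != a else c.concept_n_id
             for aid in n_a for c in net.conns_through(aid)} - {a}
        )
        if oracle.answer("name_known_view_new", [a], known_views):
            conn_ids = _connect_through(net, n_a, v, a)
            return AssociationEvent("new_view", sorted(n_a), True, conn_ids)
        assoc = net.add_assoc_neuron()
        assoc.add_link(net.concept_channel(v), v)
        return AssociationEvent("new_view", [assoc.id], False, [])

    if n_v and not n_a:
        known_names = sorted(
            {c.concept_m_id if c.concept_m_id != v else c.concept_n_id
             for aid in n_v for c in net.conns_through(aid)} - {v}
        )
        if oracle.answer("view_known_name_new", [a], known_names):
            conn_ids = _connect_through(net, n_v, v, a)
            return AssociationEvent("new_name", sorted(n_v), True, conn_ids)
        return AssociationEvent("new_name", [], False, [])

    common = n_v & n_a
    if common:
        conn_ids = []
        for aid in sorted(common):
            conn = net.find_assoc_conn(v, aid, a)
            if conn is None:
                conn = net.add_assoc_conn(v, aid, a)
            else:
                conn.rho += 1
            conn_ids.append(conn.id)
        return AssociationEvent("consistent", sorted(common), True, conn_ids)
    if oracle.answer("inconsistent_pair", [v, a], sorted(n_v | n_a)):
        conn_ids = _connect_through(net, n_v | n_a, v, a)
        return AssociationEvent("inconsistent_accepted", sorted(n_v | n_a), True, conn_ids)
    return AssociationEvent("inconsistent_rejected", [], False, [])


def expand_response_modal(
    net: NetworkState, l_event: ConceptEvent, x_event: ConceptEvent
) -> AssociationEvent:
    """Automatic four-case binding when a new channel X joins the system.

    Identical case structure to :func:`associate_pair` but with no user
    questions: the hubs of the inherent channel L simply grow synapses to
    the new channel's concept (response-modal expansion), after which every
    affected association neuron answers from either channel.
    """
    l_c, x_c = l_event.concept_id, x_event.concept_id
    n_l = set(net.assocs_linked_to(l_c))
    n_x = set(net.assocs_linked_to(x_c))

    if not n_l and not n_x:
        assoc_id, conn_id = _new_one_to_one(net, l_c, x_c)
        return AssociationEvent("both_new", [assoc_id], True, [conn_id])
    if n_l and not n_x:
        conn_ids = _connect_through(net, n_l, l_c, x_c)
        return AssociationEvent("expanded", sorted(n_l), True, conn_ids)
    if n_x and not n_l:
        conn_ids = _connect_through(net, n_x, l_c, x_c)
        return AssociationEvent("expanded", sorted(n_x), True, conn_ids)
    common = n_l & n_x
    if common:
        conn_ids = []
        for aid in sorted(common):
            conn = net.find_assoc_conn(l_c, aid, x_c)
            if conn is None:
                conn = net.add_assoc_conn(l_c, aid, x_c)
            else:
                conn.rho += 1
            conn_ids.append(conn.id)
        return AssociationEvent("consistent", sorted(common), True, conn_ids)
    conn_ids = _connect_through(net, n_l | n_x, l_c, x_c)
    return AssociationEvent("expanded", sorted(n_l | n_x), True, conn_ids)


def recall(net: NetworkState, source_concept: int, target_channel: str) -> list[int]:
    """Concepts of ``target_channel`` reachable from a source concept.

    Traversal goes source -> linked association neurons -> connections ->
    concepts in the target channel; results are ranked by total connection
    rho (descending), ties toward the smaller concept id.  An unreachable
    channel yields an empty list.
    """
    scores: dict[int, int] = {}
    for aid in net.assocs_linked_to(source_concept):
        for conn in net.conns_through(aid):
            for cid in (conn.concept_m_id, conn.concept_n_id):
                if cid == source_concept:
                    continue
                if net.concept_channel(cid) == target_channel:
                    scores[cid] = scores.get(cid, 0) + conn.rho
    return sorted(scores, key=lambda cid: (-scores[cid], cid))
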
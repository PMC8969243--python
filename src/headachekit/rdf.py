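"""Knowledge-graph export of diary records and classification results.

Attacks, contextual events and classifications are emitted as RDF resources
under a single package namespace, with one property per record field; the
attack and event mapping round-trips losslessly.  The namespace is this
package's own — it documents a field-for-field mapping rather than claiming
identity with any published clinical ontology.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

from rdflib import RDF, BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import XSD

from .criteria import ClassificationResult
from .io import from_record, to_record
from .records import AttackRegistration, ContextEvent

__all__ = ["HK", "export_knowledge_graph", "import_knowledge_graph"]

HK = Namespace("https://headachekit.invalid/ns#")


def _emit(graph: Graph, node: URIRef, rdf_type: URIRef, rec: dict) -> None:
    graph.add((node, RDF.type, rdf_type))
    for key, value in rec.items():
        if key == "kind" or value is None:
            continue
        graph.add((node, HK[key], Literal(value)))


def export_knowledge_graph(
    attacks: Sequence[AttackRegistration] = (),
    events: Sequence[ContextEvent] = (),
    results: Sequence[ClassificationResult] = (),
) -> Graph:
    """Serialize records and classifications into one RDF graph."""
    graph = Graph()
    graph.bind("hk", HK)
    attack_nodes = {}
    for i, attack in enumerate(attacks):
        node = HK[f"attack/{attack.patient_id}/{i}"]
        attack_nodes[id(attack)] = node
        _emit(graph, node, HK.HeadacheAttack, to_record(attack))
    for i, event in enumerate(events):
        _emit(graph, HK[f"event/{event.patient_id}/{i}"], HK.ContextEvent, to_record(event))
    for i, result in enumerate(results):
        for disorder, flags in result.labels.items():
            node = HK[f"classification/{result.attack.patient_id}/{i}/{disorder.value}"]
            graph.add((node, RDF.type, HK.Classification))
            graph.add((node, HK.disorder, Literal(disorder.value)))
            graph.add((node, HK.criteriaVersion, Literal(int(result.version))))
            subject = attack_nodes.get(id(result.attack))
            if subject is not None:
                graph.add((node, HK.classifies, subject))
            for criterion, ok in flags.items():
                flag = BNode()
                graph.add((node, HK.additionallyEvaluated, flag))
                graph.add((flag, HK.criterion, Literal(criterion)))
                graph.add((flag, HK.fulfilled, Literal(bool(ok))))
    return graph


def _collect(graph: Graph, rdf_type: URIRef, kind: str) -> List[dict]:
    records = []
    for node in sorted(graph.subjects(RDF.type, rdf_type)):
        rec = {"kind": kind}
        for _, prop, value in graph.triples((node, None, None)):
            if prop == RDF.type:
                continue
            key = str(prop).rsplit("#", 1)[-1]
            rec[key] = value.toPython()
        records.append(rec)
    return records


def import_knowledge_graph(
    graph: Graph,
) -> Tuple[List[AttackRegistration], List[ContextEvent]]:
    """Rebuild attacks and events from an exported graph (lossless round trip)."""
    attacks = [from_record(rec) for rec in _collect(graph, HK.HeadacheAttack, "attack")]
    events = [from_record(rec) for rec in _collect(graph, HK.ContextEvent, "event")]
    return attacks, events
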
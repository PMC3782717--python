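"""Directed graphs of interactions linked by cooperative effects and
ordered-assembly relations.

Nodes are interaction records after merging the curation idiom of repeated
records: because only one cooperative effect fits in an interaction's
attribute list, a binding event with several effects is curated as several
records that differ only in their attributes.  Records sharing an identical
participant reference set and interaction type are treated as the same
binding event and merged onto the lowest record id.

Two edge families:

* *coop edges* — one per extracted cooperative effect, from the exerting
  binding event to the affected one.  These may form cycles (mutually
  stabilizing binding events do occur).
* *assembly edges* — one per participant-as-interaction reference, from the
  component interaction to the consuming one.  These must be acyclic: they
  encode the partial order of sequential complex assembly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx

from .cooperativity import (
    AllostericMechanismKind,
    AllostericResponse,
    AllosteryType,
    CooperativeEffect,
    Mechanism,
    Outcome,
    PreassemblyResponse,
    extract_effects,
    validate,
)
from .cv import CvRegistry
from .errors import CycleError, GraphBuildError, UsageError
from .model import Entry

__all__ = [
    "CoopEdge",
    "CoopGraph",
    "build_graph",
    "assembly_order",
    "export_graph",
    "import_graph",
]


@dataclass(frozen=True)
class CoopEdge:
    """A cooperative effect as a graph edge between merged nodes."""

    source: int
    target: int
    effect: CooperativeEffect


@dataclass
class CoopGraph:
    nodes: dict[int, str]  # merged interaction id -> label
    coop_edges: list[CoopEdge] = field(default_factory=list)
    assembly_edges: list[tuple[int, int]] = field(default_factory=list)

    def assembly_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.assembly_edges)
        return g


def _merge_records(entry: Entry) -> dict[int, int]:
    """Map each interaction record id to its merged representative.

    The grouping key is the multiset of participant references (with
    interaction references canonicalized through the mapping itself) plus
    the interaction type; iterated to a fixpoint so chains of repeated
    records collapse consistently.
    """
    rep = {i.id: i.id for i in entry.interactions}
    for _ in range(len(entry.interactions) + 1):
        groups: dict[tuple, list[int]] = {}
        for inter in entry.interactions:
            refs = []
            for p in inter.participants:
                if p.interactor_ref is not None:
                    refs.append(("interactor", p.interactor_ref))
                else:
                    refs.append(("interaction", rep[p.interaction_ref]))
            itype = (
                inter.interaction_type.accession
                if inter.interaction_type
                else None
            )
            key = (tuple(sorted(refs)), itype)
            groups.setdefault(key, []).append(inter.id)
        new_rep = {}
        for ids in groups.values():
            target = min(ids)
            for i in ids:
                new_rep[i] = target
        if new_rep == rep:
            return rep
        rep = new_rep
    return rep


def build_graph(entry: Entry, registry: CvRegistry) -> CoopGraph:
    """Build the cooperativity/assembly graph for a validated entry.

    Raises :class:`GraphBuildError` (carrying the findings) if semantic
    validation reports any ERROR.
    """
    errors = [
        f for f in validate(entry, registry) if f.severity.value == "error"
    ]
    if errors:
        raise GraphBuildError(
            f"{len(errors)} validation error(s); fix the entry before "
            "building a graph",
            findings=errors,
        )
    effects = extract_effects(entry, registry)
    rep = _merge_records(entry)

    nodes: dict[int, str] = {}
    for inter in entry.interactions:
        node = rep[inter.id]
        if node not in nodes or inter.id == node:
            nodes[node] = entry.interaction(node).short_label

    coop_edges = [
        CoopEdge(
            source=rep[e.source_interaction_id],
            target=rep[e.affected_interaction_id],
            effect=e,
        )
        for e in effects
    ]

    assembly: set[tuple[int, int]] = set()
    for inter in entry.interactions:
        for p in inter.participants:
            if p.interaction_ref is not None:
                edge = (rep[p.interaction_ref], rep[inter.id])
                if edge[0] != edge[1]:
                    assembly.add(edge)

    graph = CoopGraph(
        nodes=dict(sorted(nodes.items())),
        coop_edges=coop_edges,
        assembly_edges=sorted(assembly),
    )
    # model-level resolution already forbids assembly cycles; double-check
    if not nx.is_directed_acyclic_graph(graph.assembly_digraph()):
        cycle = [u for u, _ in nx.find_cycle(graph.assembly_digraph())]
        raise GraphBuildError(f"assembly edges form a cycle: {cycle}")
    return graph


def assembly_order(graph: CoopGraph) -> list[int]:
    """Topological order of nodes under assembly edges, deterministic with
    ties broken by ascending interaction id."""
    g = graph.assembly_digraph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise CycleError(
            f"assembly edges form a cycle through {cycle}", cycle=cycle
        ) from None


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

_ENUMS = {
    "mechanism": Mechanism,
    "outcome": Outcome,
    "response": AllostericResponse,
    "allosteric_mechanism": AllostericMechanismKind,
    "allostery_type": AllosteryType,
    "preassembly_response": PreassemblyResponse,
}


def _effect_to_dict(effect: CooperativeEffect) -> dict:
    out = asdict(effect)
    for key, enum_cls in _ENUMS.items():
        val = out[key]
        out[key] = val.name if val is not None else None
    out["outcome"] = effect.outcome.name
    return out


def _effect_from_dict(data: dict) -> CooperativeEffect:
    kwargs = dict(data)
    for key, enum_cls in _ENUMS.items():
        if kwargs.get(key) is not None:
            kwargs[key] = enum_cls[kwargs[key]]
    if kwargs.get("outcome") is None:
        kwargs["outcome"] = Outcome.UNSPECIFIED
    return CooperativeEffect(**kwargs)


_DOT_STYLE = {
    Outcome.POSITIVE: "solid",
    Outcome.NEGATIVE: "dashed",
    Outcome.UNSPECIFIED: "dotted",
}


def export_graph(graph: CoopGraph, format: str = "DOT") -> str:
    """Serialize the graph as Graphviz DOT or a JSON node-link document.

    DOT coop edges are styled by outcome (solid positive, dashed negative,
    dotted unspecified) and labelled with the mechanism; assembly edges are
    drawn bold and unlabelled.  The JSON form is lossless and re-importable
    with :func:`import_graph`.
    """
    fmt = format.upper()
    if fmt == "DOT":
        lines = ["digraph cooperativity {"]
        for node, label in graph.nodes.items():
            lines.append(f'  {node} [label="{label} ({node})"];')
        for edge in graph.coop_edges:
            mech = edge.effect.mechanism.name.lower().replace("_", "-")
            style = _DOT_STYLE[edge.effect.outcome]
            lines.append(
                f"  {edge.source} -> {edge.target} "
                f'[class="coop" style="{style}" label="{mech}"];'
            )
        for src, dst in graph.assembly_edges:
            lines.append(
                f'  {src} -> {dst} [class="assembly" style="bold"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "JSON":
        doc = {
            "nodes": [
                {"id": node, "label": label}
                for node, label in graph.nodes.items()
            ],
            "coop_edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "effect": _effect_to_dict(e.effect),
                }
                for e in graph.coop_edges
            ],
            "assembly_edges": [list(edge) for edge in graph.assembly_edges],
        }
        return json.dumps(doc, indent=2) + "\n"
    raise UsageError(f"unknown graph format {format!r}; use DOT or JSON")


def import_graph(text: str) -> CoopGraph:
    """Rebuild a :class:`CoopGraph` from its JSON export."""
    doc = json.loads(text)
    return CoopGraph(
        nodes={int(n["id"]): n["label"] for n in doc["nodes"]},
        coop_edges=[
            CoopEdge(
                source=e["source"],
                target=e["target"],
                effect=_effect_from_dict(e["effect"]),
            )
            for e in doc["coop_edges"]
        ],
        assembly_edges=[tuple(e) for e in doc["assembly_edges"]],
    )
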
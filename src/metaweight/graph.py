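"""Super-metabolic enzyme graphs.

The super-metabolic graph has one node per enzyme (complete four-field EC
number) known in the reaction universe, and an undirected edge between two
enzymes whenever some reaction of one and some reaction of the other share a
compound.  A species' metabolism is then an instantiation (node subset) of
this one graph, which is what makes weighted-node summaries over many genomes
cheap: the topology is built once.

Compounds are pooled per reaction (substrates union products) before testing
intersection, so reaction directionality plays no role.  Only compound ids
beginning with ``"C"`` are considered, and ids on the cofactor exclusion list
(ATP, NADH and the like -- currency metabolites that would otherwise connect
nearly everything) are removed before edges are formed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Reaction",
    "SuperGraph",
    "Pathway",
    "is_complete_ec",
    "filter_compounds",
    "build_supergraph",
    "build_pathway_graph",
]

#: A complete EC code has four dotted numeric fields, e.g. ``"2.7.1.40"``.
_EC_COMPLETE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


def is_complete_ec(ec: str) -> bool:
    """True iff *ec* is a complete (wildcard-free) four-field EC code."""
    return bool(_EC_COMPLETE.match(ec))


@dataclass(frozen=True)
class Reaction:
    """One reaction: its EC annotations and the compounds on either side.

    ``pathways`` records which pathways the reaction itself belongs to; it is
    optional and only consulted when building per-pathway subgraphs.
    """

    reaction_id: str
    ec_numbers: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    pathways: frozenset[str] = field(default_factory=frozenset)

    @property
    def compounds(self) -> frozenset[str]:
        """Substrates and products pooled (directionality is ignored)."""
        return self.substrates | self.products


@dataclass
class SuperGraph:
    """Enzyme nodes, compound-sharing edges, and pathway membership.

    Edges are stored once as unordered ``frozenset`` pairs; self-edges are
    never stored.
    """

    nodes: set[str]
    edges: set[frozenset[str]]
    pathway_membership: dict[str, set[str]] = field(default_factory=dict)

    def neighbors(self, ec: str) -> set[str]:
        return {next(iter(e - {ec})) for e in self.edges if ec in e}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(tuple(sorted(e)) for e in self.edges))
        return g


@dataclass
class Pathway:
    """A pathway subgraph: member enzymes and in-pathway compound-sharing edges."""

    pathway_id: str
    name: str
    enzymes: set[str]
    edges: set[frozenset[str]]


def filter_compounds(reaction: Reaction, cofactors: Iterable[str]) -> Reaction:
    """Drop non-"C" compound ids and listed cofactors from both sides.

    EC annotations are untouched; empty compound sets are legal output.
    """
    excl = set(cofactors)

    def keep(ids: frozenset[str]) -> frozenset[str]:
        return frozenset(c for c in ids if c.startswith("C") and c not in excl)

    return replace(reaction, substrates=keep(reaction.substrates),
                   products=keep(reaction.products))


def _validate_ecs(reactions: Iterable[Reaction]) -> None:
    for r in reactions:
        if not r.ec_numbers:
            raise ValueError(f"reaction {r.reaction_id!r} has no EC numbers")
        for ec in r.ec_numbers:
            if not is_complete_ec(ec):
                raise ValueError(
                    f"reaction {r.reaction_id!r}: malformed or incomplete EC "
                    f"code {ec!r} (four numeric fields required)")


def _compound_index(reactions: Iterable[Reaction]) -> dict[str, set[str]]:
    """Map compound id -> set of ECs with a reaction touching it."""
    index: dict[str, set[str]] = {}
    for r in reactions:
        for c in r.compounds:
            index.setdefault(c, set()).update(r.ec_numbers)
    return index


def _edges_from_index(index: Mapping[str, set[str]]) -> set[frozenset[str]]:
    edges: set[frozenset[str]] = set()
    for ecs in index.values():
        ordered = sorted(ecs)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                edges.add(frozenset((a, b)))
    return edges


def build_supergraph(
    reactions: Iterable[Reaction],
    cofactors: Iterable[str] = (),
    pathway_membership: Mapping[str, Iterable[str]] | None = None,
) -> SuperGraph:
    """Build the super-metabolic graph from a reaction table.

    The node set is the union of all (complete) EC annotations; an edge
    ``{a, b}`` exists iff, after compound filtering, some reaction annotated
    with *a* and some reaction annotated with *b* share at least one compound.
    Multiple reactions per EC use existential semantics: the graph is a union
    over reactions.

    Raises ``ValueError`` on malformed EC codes (fewer than four numeric
    fields, or wildcard fields).
    """
    reactions = list(reactions)
    _validate_ecs(reactions)
    excl = set(cofactors)
    filtered = [filter_compounds(r, excl) for r in reactions]
    nodes: set[str] = set()
    for r in filtered:
        nodes.update(r.ec_numbers)
    edges = _edges_from_index(_compound_index(filtered))
    membership = (
        {p: set(ecs) for p, ecs in pathway_membership.items()}
        if pathway_membership is not None else {}
    )
    return SuperGraph(nodes=nodes, edges=edges, pathway_membership=membership)


def _in_pathway(reaction: Reaction, pathway_id: str, members: set[str]) -> bool:
    # Explicit assignment wins; otherwise fall back to EC membership (a
    # reaction is in-pathway iff all its ECs are pathway members).
    if reaction.pathways:
        return pathway_id in reaction.pathways
    return bool(reaction.ec_numbers) and reaction.ec_numbers <= members


def build_pathway_graph(
    supergraph: SuperGraph,
    pathway_id: str,
    reactions: Iterable[Reaction],
    cofactors: Iterable[str] = (),
) -> Pathway:
    """Build one pathway's subgraph, analogous to the super-graph build.

    Member enzymes come from ``supergraph.pathway_membership``; edges are
    computed only from reactions assigned to this pathway, restricted to
    member pairs.  Two member enzymes sharing a compound only via an
    out-of-pathway reaction are *not* connected.

    Raises ``KeyError`` for an unknown ``pathway_id``.
    """
    if pathway_id not in supergraph.pathway_membership:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    members = set(supergraph.pathway_membership[pathway_id])
    excl = set(cofactors)
    assigned = [
        filter_compounds(r, excl) for r in reactions
        if _in_pathway(r, pathway_id, members)
    ]
    index: dict[str, set[str]] = {}
    for r in assigned:
        in_members = r.ec_numbers & members
        for c in r.compounds:
            index.setdefault(c, set()).update(in_members)
    edges = {e for e in _edges_from_index(index) if e <= members}
    return Pathway(pathway_id=pathway_id, name=pathway_id, enzymes=members,
                   edges=edges)
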
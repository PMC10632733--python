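"""Network structure, node classes, perturbation maps and treatment conditions.

The signaling network is a directed graph over named nodes (receptors,
enzymes, transcription factors, ligands).  Each directed link carries one
free local response coefficient ``r`` describing the direct effect of the
source node's activity on the target node when the rest of the network is
held fixed.  Perturbation agents act on exactly one node each, either as an
inhibitor (attenuating the node's outgoing signal) or as a stimulation /
withdrawal (an additive input to the node).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

NODE_CLASSES = frozenset({"ligand", "receptor", "enzyme", "transcription_factor"})

MODE_INHIBITION = "inhibition"
MODE_STIMULATION = "stimulation"


class StructureError(ValueError):
    """Raised for invalid network structures or perturbation maps."""


Link = tuple[str, str]


@dataclass(frozen=True)
class NetworkStructure:
    """Directed signaling network with node classes and optional sign hints.

    Parameters
    ----------
    nodes
        Ordered node identifiers.
    links
        Ordered ``(source, target)`` pairs, one local response coefficient each.
    node_classes
        Map node -> one of ``ligand``, ``receptor``, ``enzyme``,
        ``transcription_factor``.
    sign_hints
        Optional map link -> +1/-1, used only to orient initial guesses.
    """

    nodes: tuple[str, ...]
    links: tuple[Link, ...]
    node_classes: Mapping[str, str] = field(default_factory=dict)
    sign_hints: Mapping[Link, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise StructureError("duplicate node identifiers")
        seen: set[Link] = set()
        node_set = set(self.nodes)
        for src, tgt in self.links:
            if src == tgt:
                raise StructureError(f"self-link {src}->{tgt} not allowed")
            if (src, tgt) in seen:
                raise StructureError(f"duplicate link {src}->{tgt}")
            seen.add((src, tgt))
            for n in (src, tgt):
                if n not in node_set:
                    raise StructureError(f"link references unknown node {n!r}")
        for n, cls in self.node_classes.items():
            if n not in node_set:
                raise StructureError(f"node class given for unknown node {n!r}")
            if cls not in NODE_CLASSES:
                raise StructureError(f"unknown node class {cls!r} for node {n!r}")

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def has_link(self, src: str, tgt: str) -> bool:
        return (src, tgt) in set(self.links)

    def with_link(self, src: str, tgt: str, sign_hint: int | None = None) -> "NetworkStructure":
        """Return a copy with one additional link appended."""
        hints = dict(self.sign_hints)
        if sign_hint is not None:
            hints[(src, tgt)] = sign_hint
        return NetworkStructure(self.nodes, self.links + ((src, tgt),), dict(self.node_classes), hints)

    def without_link(self, src: str, tgt: str) -> "NetworkStructure":
        """Return a copy with the given link removed."""
        if not self.has_link(src, tgt):
            raise StructureError(f"link {src}->{tgt} not in structure")
        links = tuple(l for l in self.links if l != (src, tgt))
        hints = {k: v for k, v in self.sign_hints.items() if k != (src, tgt)}
        return NetworkStructure(self.nodes, links, dict(self.node_classes), hints)

    def to_graph(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.links)
        return g


@dataclass(frozen=True)
class PerturbationMap:
    """Map from perturbation agent to its single target node and mode."""

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for agent, (target, mode) in self.entries.items():
            if mode not in (MODE_INHIBITION, MODE_STIMULATION):
                raise StructureError(f"agent {agent!r}: unknown mode {mode!r}")

    def validate_against(self, structure: NetworkStructure) -> None:
        for agent, (target, _mode) in self.entries.items():
            if target not in structure.nodes:
                raise StructureError(f"agent {agent!r} targets unknown node {target!r}")

    @property
    def agents(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def inhibitors(self) -> tuple[str, ...]:
        return tuple(a for a, (_t, m) in self.entries.items() if m == MODE_INHIBITION)

    @property
    def stimulations(self) -> tuple[str, ...]:
        return tuple(a for a, (_t, m) in self.entries.items() if m == MODE_STIMULATION)

    def target(self, agent: str) -> str:
        return self.entries[agent][0]

    def mode(self, agent: str) -> str:
        return self.entries[agent][1]


def condition(agents: Iterable[str] = ()) -> tuple[str, ...]:
    """Canonical treatment condition: a sorted tuple of active agent ids.

    The empty tuple is the vehicle control.
    """
    return tuple(sorted(set(agents)))


def validate_conditions(conditions: Sequence[tuple[str, ...]], pmap: PerturbationMap) -> None:
    known = set(pmap.agents)
    for cond in conditions:
        for agent in cond:
            if agent not in known:
                raise StructureError(f"condition {cond!r} uses unknown agent {agent!r}")
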
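"""Composite pathway coefficients and the two-cell-line comparison.

The local response coefficients along a continuous path (or around a
closed feedback loop) multiply into a single composite "pathway
coefficient" — the unit at which the two cell-line models are compared.
Three kinds are enumerated:

* ``canonical`` — from a ligand/withdrawal entry node to the most
  downstream protein of its literature pathway; the stimulation strength
  is included in the product, so e.g. the Activin coefficient is one
  interpretable number per cell line.
* ``feedback_loop`` — every simple directed cycle (up to a length cap).
* ``crosstalk`` — every maximal continuous path from a ligand entry to a
  measured terminal that traverses at least one added (non-literature)
  link; paths spanning more than two canonical pathways are computed but
  flagged.

Confidence intervals are propagated through the parameter dependencies
recorded by the profile likelihood: along each member's profile, the path
product is evaluated with the co-fitted values of the other members, and
the propagated interval is the envelope of those products over every
member's confidence region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .profile import ProfileResult
from .structure import NetworkStructure, PerturbationMap

Link = tuple[str, str]

SATURATION_TOL = 1e-3   # product drift at the walk edge below this counts as saturated


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PathDefinition:
    """A named product of parameters along a path or loop."""

    name: str
    kind: str                      # canonical | feedback_loop | crosstalk
    links: tuple[Link, ...]
    agent: str | None = None       # stimulation agent (canonical/crosstalk)
    spans: tuple[str, ...] = ()    # canonical pathways touched (crosstalk)
    flagged: bool = False          # spans more than two canonical pathways

    @property
    def members(self) -> tuple[str, ...]:
        names = tuple(f"r:{s}->{t}" for s, t in self.links)
        if self.agent is not None:
            names = (f"k:{self.agent}",) + names
        return names


@dataclass
class PathwayCoefficient:
    """Composite coefficient with propagated confidence interval."""

    path: PathDefinition
    value: float
    ci: tuple[float, float] | None = None
    cell_line: str = ""

    @property
    def name(self) -> str:
        return self.path.name

    @property
    def negative(self) -> bool:
        """Net-inhibitory path/loop."""
        return self.value < 0


# --------------------------------------------------------------------- #
# enumeration

def _maximal_paths(graph: nx.DiGraph, source: str, targets: set[str],
                   cutoff: int) -> list[tuple[str, ...]]:
    """Simple paths source->target (target measured) not a prefix of a longer one."""
    paths: list[tuple[str, ...]] = []
    for t in sorted(targets):
        if t == source or not graph.has_node(t):
            continue
        for p in nx.all_simple_paths(graph, source, t, cutoff=cutoff):
            paths.append(tuple(p))
    keep = []
    for p in paths:
        if not any(q != p and q[: len(p)] == p for q in paths):
            keep.append(p)
    return sorted(set(keep))


def _rotate_cycle(cycle: Sequence[str]) -> tuple[str, ...]:
    i = int(np.argmin(cycle))
    return tuple(cycle[i:]) + tuple(cycle[:i])


def enumerate_paths(structure: NetworkStructure, pmap: PerturbationMap,
                    measured_nodes: Sequence[str],
                    base_links: Sequence[Link] | None = None,
                    max_len: int = 8) -> list[PathDefinition]:
    """Enumerate canonical pathways, feedback loops and crosstalk paths.

    ``base_links`` is the literature network (defaults to all links, in
    which case no link counts as "added" and no crosstalk is reported).
    """
    measured = set(measured_nodes)
    all_links = tuple(structure.links)
    base = tuple(base_links) if base_links is not None else all_links
    for l in base:
        if l not in set(all_links):
            raise InferenceError(f"base link {l} not in structure")
    added = [l for l in all_links if l not in set(base)]

    g_full = nx.DiGraph(list(all_links))
    g_base = nx.DiGraph(list(base))

    out: list[PathDefinition] = []

    # canonical: per stimulation agent, maximal base-network path to a measured node
    node_pathways: dict[str, set[str]] = {}
    for agent in pmap.stimulations:
        entry = pmap.target(agent)
        if not g_base.has_node(entry):
            continue
        for p in _maximal_paths(g_base, entry, measured, cutoff=max_len):
            links = tuple(zip(p[:-1], p[1:]))
            out.append(PathDefinition(
                name=f"canonical:{agent}:" + "->".join(p),
                kind="canonical", links=links, agent=agent))
            for node in p:
                node_pathways.setdefault(node, set()).add(agent)

    # feedback loops: simple directed cycles up to max_len
    for cycle in nx.simple_cycles(g_full):
        if len(cycle) < 2 or len(cycle) > max_len:
            continue
        cyc = _rotate_cycle(cycle)
        links = tuple(zip(cyc, cyc[1:] + (cyc[0],)))
        out.append(PathDefinition(
            name="loop:" + "->".join(cyc + (cyc[0],)),
            kind="feedback_loop", links=links))

    # crosstalk: ligand entry -> measured terminal, using >= 1 added link
    if added:
        for agent in pmap.stimulations:
            entry = pmap.target(agent)
            if not g_full.has_node(entry):
                continue
            for p in _maximal_paths(g_full, entry, measured, cutoff=max_len):
                links = tuple(zip(p[:-1], p[1:]))
                if not any(l in set(added) for l in links):
                    continue
                spans = sorted(set().union(*(node_pathways.get(n, set()) for n in p)))
                out.append(PathDefinition(
                    name=f"crosstalk:{agent}:" + "->".join(p),
                    kind="crosstalk", links=links, agent=agent,
                    spans=tuple(spans), flagged=len(spans) > 2))
    return out


# --------------------------------------------------------------------- #
# coefficients and CI propagation

def pathway_coefficient(results, path: PathDefinition) -> PathwayCoefficient:
    """Product of the member parameter estimates."""
    value = float(np.prod([results.get(m) for m in path.members]))
    return PathwayCoefficient(path=path, value=value,
                              cell_line=results.model.dataset.cell_line)


def _member_product(params_vec: np.ndarray, idx: Sequence[int]) -> float:
    return float(np.prod(params_vec[list(idx)]))


def propagate_ci(profiles: Mapping[str, ProfileResult], path: PathDefinition,
                 results) -> tuple[float, float]:
    """Propagate member profiles into a path-coefficient interval.

    For each member's profile, the product is evaluated at every grid
    point inside that member's confidence region using the co-fitted
    values of all other members; the interval is the envelope over all
    members.  A member with an unbounded CI yields an unbounded side
    unless the product saturates (stops drifting) at the walk edge — the
    signature of compensating, structurally coupled parameters whose
    product remains identifiable.
    """
    names = results.param_names
    idx = [names.index(m) for m in path.members]
    for m in path.members:
        if m not in profiles:
            raise InferenceError(f"no profile available for member {m!r}")
    mle_prod = _member_product(results.params, idx)
    lo, hi = mle_prod, mle_prod
    for m in path.members:
        prof = profiles[m]
        inside = prof.within_ci()
        ok = inside & np.isfinite(prof.ssr_profile)
        if not ok.any():
            continue
        prods = np.array([_member_product(prof.co_params[i], idx)
                          for i in np.where(ok)[0]])
        lo = min(lo, float(prods.min()))
        hi = max(hi, float(prods.max()))
        # unbounded member: check saturation of the product at each open edge
        for side, edge in ((prof.ci_low, 0), (prof.ci_high, -1)):
            if np.isfinite(side):
                continue
            pts = prods if edge == -1 else prods[::-1]
            if len(pts) >= 2:
                drift = abs(pts[-1] - pts[-2])
                if drift <= SATURATION_TOL * max(1.0, abs(pts[-1])):
                    continue
                if pts[-1] >= pts[-2]:
                    hi = np.inf
                else:
                    lo = -np.inf
            else:
                lo, hi = -np.inf, np.inf
    return float(lo), float(hi)


def pathway_table(results, paths: Sequence[PathDefinition],
                  profiles: Mapping[str, ProfileResult] | None = None) -> pd.DataFrame:
    """Coefficient table for one fitted model (CIs if profiles given)."""
    rows = []
    for path in paths:
        coef = pathway_coefficient(results, path)
        lo = hi = np.nan
        if profiles is not None:
            lo, hi = propagate_ci(profiles, path, results)
        rows.append({"name": path.name, "kind": path.kind, "flagged": path.flagged,
                     "value": coef.value, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def intervals_disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Strict non-overlap; intervals sharing an endpoint count as overlapping."""
    return bool(a[1] < b[0] or b[1] < a[0])


def compare_models(results_a, results_b, paths: Sequence[PathDefinition],
                   profiles_a: Mapping[str, ProfileResult],
                   profiles_b: Mapping[str, ProfileResult]) -> pd.DataFrame:
    """Flag pathway coefficients whose 95% CIs do not overlap.

    Touching intervals count as overlapping (not significant).  Both fits
    must share the network structure.
    """
    if results_a.model.structure.links != results_b.model.structure.links:
        raise InferenceError("models do not share a network structure")
    la = results_a.model.dataset.cell_line or "A"
    lb = results_b.model.dataset.cell_line or "B"
    rows = []
    for path in paths:
        va = pathway_coefficient(results_a, path).value
        vb = pathway_coefficient(results_b, path).value
        lo_a, hi_a = propagate_ci(profiles_a, path, results_a)
        lo_b, hi_b = propagate_ci(profiles_b, path, results_b)
        significant = intervals_disjoint((lo_a, hi_a), (lo_b, hi_b))
        rows.append({"name": path.name, "kind": path.kind, "flagged": path.flagged,
                     f"value_{la}": va, f"ci_low_{la}": lo_a, f"ci_high_{la}": hi_a,
                     f"value_{lb}": vb, f"ci_low_{lb}": lo_b, f"ci_high_{lb}": hi_b,
                     "significant": significant})
    return pd.DataFrame(rows)
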
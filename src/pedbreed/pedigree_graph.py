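"""Pedigree DAG construction and queries.

The pedigree is a directed acyclic graph under the parent-of relation.
Founders are individuals with both parents unknown; a record with exactly one
known parent gets a *phantom founder* standing in for the unknown parental
gamete, so that gene-flow accounting (kinship, founder-allele IBD) stays
conservative.  Phantom founders never appear in user-facing founder lists.

Kinship coefficients use the standard recursive (tabular) method:
f(x,x) = 1/2 (1 + f(mother(x), father(x))), and for x introduced after y,
f(x,y) = 1/2 (f(mother(x), y) + f(father(x), y)), with missing-parent terms 0
and founder-founder kinship 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .pedfile_io import PedigreeRecord

__all__ = [
    "PedigreeGraph",
    "KinshipMatrix",
    "CycleError",
    "build_graph",
    "founders",
    "ancestor_closure",
    "generation_layers",
    "kinship",
    "to_dot",
    "to_graphml",
    "to_networkx",
]

PHANTOM_PREFIX = "~P:"


class CycleError(ValueError):
    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("parentage cycle: " + " -> ".join(cycle))


@dataclass
class PedigreeGraph:
    nodes: list[str] = field(default_factory=list)  # file order, phantoms appended
    maternal_edge: dict[str, str] = field(default_factory=dict)  # child -> mother
    paternal_edge: dict[str, str] = field(default_factory=dict)  # child -> father
    phantoms: set[str] = field(default_factory=set)

    def parents(self, name: str) -> tuple[str | None, str | None]:
        return self.maternal_edge.get(name), self.paternal_edge.get(name)

    def children(self, name: str) -> list[str]:
        return [
            c
            for c in self.nodes
            if self.maternal_edge.get(c) == name or self.paternal_edge.get(c) == name
        ]

    def is_selfing(self, name: str) -> bool:
        m, p = self.parents(name)
        return m is not None and m == p

    def __contains__(self, name: str) -> bool:
        return name in set(self.nodes)


def build_graph(records: list[PedigreeRecord]) -> PedigreeGraph:
    """Build the pedigree DAG from validated pedigree records.

    Raises :class:`CycleError` (listing one witness cycle) if the parent-of
    relation is cyclic.  Records with exactly one known parent receive a
    phantom founder for the unknown side.
    """
    g = PedigreeGraph()
    for rec in records:
        g.nodes.append(rec.name)
    known = set(g.nodes)
    for rec in records:
        m, p = rec.mother, rec.father
        if m is None and p is not None:
            m = f"{PHANTOM_PREFIX}{rec.name}:m"
            g.phantoms.add(m)
            g.nodes.append(m)
        elif p is None and m is not None:
            p = f"{PHANTOM_PREFIX}{rec.name}:f"
            g.phantoms.add(p)
            g.nodes.append(p)
        if m is not None:
            if m not in known and m not in g.phantoms:
                raise KeyError(f"mother {m!r} of {rec.name!r} is not a declared individual")
            g.maternal_edge[rec.name] = m
        if p is not None:
            if p not in known and p not in g.phantoms:
                raise KeyError(f"father {p!r} of {rec.name!r} is not a declared individual")
            g.paternal_edge[rec.name] = p

    dg = to_networkx(g)
    if not nx.is_directed_acyclic_graph(dg):
        cyc = nx.find_cycle(dg)
        witness = [e[0] for e in cyc] + [cyc[-1][1]]
        raise CycleError(witness)
    return g


def to_networkx(graph: PedigreeGraph) -> nx.DiGraph:
    """Parent -> child digraph with edge attribute role in {maternal, paternal}."""
    dg = nx.DiGraph()
    dg.add_nodes_from(graph.nodes)
    for child, mother in graph.maternal_edge.items():
        dg.add_edge(mother, child, role="maternal")
    for child, father in graph.paternal_edge.items():
        # selfing: one parent node carrying both roles
        if dg.has_edge(father, child):
            dg[father][child]["role"] = "both"
        else:
            dg.add_edge(father, child, role="paternal")
    return dg


def founders(graph: PedigreeGraph, include_phantoms: bool = False) -> set[str]:
    """Individuals with neither parent recorded (phantoms excluded by default)."""
    out = {
        n
        for n in graph.nodes
        if n not in graph.maternal_edge and n not in graph.paternal_edge
    }
    if not include_phantoms:
        out -= graph.phantoms
    return out


def ancestor_closure(graph: PedigreeGraph, subset: set[str] | list[str]) -> set[str]:
    """Smallest superset of *subset* closed under taking parents.

    Used to build displayable pedigrees: the members plus every connecting
    ancestor.  Phantom founders are included when reached.
    """
    node_set = set(graph.nodes)
    closure = set()
    stack = list(subset)
    for n in stack:
        if n not in node_set:
            raise KeyError(f"unknown individual {n!r}")
    while stack:
        n = stack.pop()
        if n in closure:
            continue
        closure.add(n)
        for parent in graph.parents(n):
            if parent is not None and parent not in closure:
                stack.append(parent)
    return closure


def generation_layers(graph: PedigreeGraph) -> dict[str, int]:
    """Longest-path generation index: founders at 0, child at 1 + max(parent layers).

    Longest-path (rather than shortest) layering puts backcross offspring
    below both parents, matching the usual visual convention for crossing
    schemes.
    """
    dg = to_networkx(graph)
    layers: dict[str, int] = {}
    for n in nx.topological_sort(dg):
        preds = list(dg.predecessors(n))
        layers[n] = 0 if not preds else 1 + max(layers[p] for p in preds)
    return layers


@dataclass
class KinshipMatrix:
    names: list[str]
    values: np.ndarray  # symmetric, entries in [0, 1]

    def get(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.values[i, j])

    def inbreeding(self, a: str) -> float:
        """F(a) = 2 f(a,a) - 1 for a diploid."""
        return 2.0 * self.get(a, a) - 1.0


def kinship(graph: PedigreeGraph) -> KinshipMatrix:
    """Pedigree kinship matrix over all nodes (phantom founders included).

    Processes individuals in topological order so parents precede children;
    founder self-kinship is 1/2 and founder-founder kinship 0.
    """
    dg = to_networkx(graph)
    order = list(nx.topological_sort(dg))
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    f = np.zeros((n, n))
    for x in order:
        i = idx[x]
        m, p = graph.parents(x)
        im = idx[m] if m is not None else None
        ip = idx[p] if p is not None else None
        fmp = f[im, ip] if (im is not None and ip is not None) else 0.0
        f[i, i] = 0.5 * (1.0 + fmp)
        for y in order:
            j = idx[y]
            if j >= i:
                break
            val = 0.0
            if im is not None:
                val += 0.5 * f[im, j]
            if ip is not None:
                val += 0.5 * f[ip, j]
            f[i, j] = f[j, i] = val
    # report in graph node order
    perm = [idx[n_] for n_ in graph.nodes]
    values = f[np.ix_(perm, perm)]
    return KinshipMatrix(names=list(graph.nodes), values=values)


def to_dot(graph: PedigreeGraph) -> str:
    """Plain adjacency DOT export (no mating junctions; see pedigree_viz.render
    for the publication-style drawing)."""
    lines = ["digraph pedigree {"]
    for n in graph.nodes:
        shape = "point" if n in graph.phantoms else "box"
        lines.append(f'  "{n}" [shape={shape}];')
    for child, mother in graph.maternal_edge.items():
        lines.append(f'  "{mother}" -> "{child}" [color=red];')
    for child, father in graph.paternal_edge.items():
        lines.append(f'  "{father}" -> "{child}" [color=purple];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(graph: PedigreeGraph) -> str:
    return "\n".join(nx.generate_graphml(to_networkx(graph))) + "\n"
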
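"""Publication-style pedigree drawings.

Filtered pedigrees are drawn layered by generation, with one explicit mating
junction ('x') per distinct parent pair, maternal edges in red and paternal
edges in purple; selfing junctions are circled.  Node boxes are filled by
trait value (quantitative traits binned into at most seven equal-width
classes), missing values are white, and context-only ancestors (present to
connect the pedigree but outside the selected subpopulation) stay uncolored.

Outputs are plain text: SVG as the canonical drawing and DOT for external
graph tooling.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field

from .pedfile_io import CATEGORICAL, QUANTITATIVE, PedimapDataset
from .pedigree_graph import PedigreeGraph, generation_layers

__all__ = ["RenderSpec", "layout", "render", "make_palette", "Drawing"]

MATERNAL_COLOR = "red"
PATERNAL_COLOR = "purple"
CHILD_COLOR = "black"
MISSING_FILL = "white"

# colorblind-friendly sequential shades for quantitative bins
_QUANT_SHADES = ["#ffffcc", "#ffeda0", "#fed976", "#feb24c", "#fd8d3c", "#fc4e2a", "#e31a1c"]
_CAT_COLORS = ["#a6cee3", "#b2df8a", "#fb9a99", "#fdbf6f", "#cab2d6", "#1f78b4", "#33a02c"]


@dataclass
class RenderSpec:
    trait: str | None = None
    palette: dict[str, str] | None = None  # category/bin label -> fill color
    n_bins: int = 7  # max equal-width bins for quantitative traits
    show_context_nodes: bool = True


@dataclass
class Drawing:
    svg: str
    dot: str
    legend: list[tuple[str, str]] = field(default_factory=list)  # (label, color)


def layout(graph: PedigreeGraph, display: set[str]) -> dict[str, tuple[int, int]]:
    """Deterministic layered layout: (generation layer, within-layer x slot).

    *display* must be closed under ancestry.  X slots start from node insertion
    order and are refined by a fixed number of barycenter sweeps (median of
    parent slots going down, of child slots going up) to reduce crossings;
    ties keep prior order, so the result is reproducible.
    """
    display = set(display)
    for n in display:
        for p in graph.parents(n):
            if p is not None and p not in display:
                raise ValueError(f"display set is not ancestor-closed: {n!r} lacks parent {p!r}")

    layers_all = generation_layers(graph)
    layers = {n: layers_all[n] for n in display}
    by_layer: dict[int, list[str]] = {}
    for n in graph.nodes:  # insertion order -> deterministic initial order
        if n in display:
            by_layer.setdefault(layers[n], []).append(n)

    def slot_map() -> dict[str, int]:
        return {n: i for lay in by_layer.values() for i, n in enumerate(lay)}

    for sweep in range(4):
        slots = slot_map()
        downward = sweep % 2 == 0
        layer_ids = sorted(by_layer) if downward else sorted(by_layer, reverse=True)
        for li in layer_ids:
            def barycenter(n: str) -> float:
                if downward:
                    refs = [slots[p] for p in graph.parents(n) if p is not None and p in slots]
                else:
                    refs = [slots[c] for c in graph.children(n) if c in slots]
                return sum(refs) / len(refs) if refs else float(slots[n])

            by_layer[li] = sorted(by_layer[li], key=lambda n: (barycenter(n), slots[n]))
    return {n: (layers[n], i) for nodes in by_layer.values() for i, n in enumerate(nodes)}


def make_palette(dataset: PedimapDataset, spec: RenderSpec, display: set[str]) -> tuple[dict[str, str], dict[str, str]]:
    """Resolve (node fill map, legend label -> color) for the displayed trait.

    Missing values map to white; a user palette must cover every category
    present in the displayed data.
    """
    if spec.trait is None:
        return {n: MISSING_FILL for n in display}, {}
    col = dataset.trait(spec.trait)
    values = {r.name: r.phenotypes.get(spec.trait) for r in dataset.records if r.name in display}

    fills: dict[str, str] = {}
    if col.kind == CATEGORICAL:
        cats = sorted({str(v) for v in values.values() if v is not None})
        if spec.palette is not None:
            missing = [c for c in cats if c not in spec.palette]
            if missing:
                raise ValueError(f"palette missing categories: {missing}")
            legend = {c: spec.palette[c] for c in cats}
        else:
            legend = {c: _CAT_COLORS[i % len(_CAT_COLORS)] for i, c in enumerate(cats)}
        for n, v in values.items():
            fills[n] = MISSING_FILL if v is None else legend[str(v)]
    else:
        nums = [float(v) for v in values.values() if v is not None]
        if not nums:
            return {n: MISSING_FILL for n in display}, {}
        lo, hi = min(nums), max(nums)
        nb = max(1, min(spec.n_bins, len(_QUANT_SHADES)))
        width = (hi - lo) / nb if hi > lo else 1.0
        legend = {}
        edges = [(lo + i * width, lo + (i + 1) * width) for i in range(nb)]
        for i, (a, b) in enumerate(edges):
            legend[f"[{a:g}, {b:g}{']' if i == nb - 1 else ')'}"] = _QUANT_SHADES[i]
        shade_list = [_QUANT_SHADES[i] for i in range(nb)]
        for n, v in values.items():
            if v is None:
                fills[n] = MISSING_FILL
            else:
                i = min(int((float(v) - lo) / width), nb - 1) if hi > lo else 0
                fills[n] = shade_list[i]
    for n in display:
        fills.setdefault(n, MISSING_FILL)
    return fills, legend


def _mating_pairs(graph: PedigreeGraph, display: set[str]) -> dict[tuple[str, ...], list[str]]:
    """Distinct (mother, father) pairs among displayed children; selfing pairs
    collapse to a single-parent key."""
    pairs: dict[tuple[str, ...], list[str]] = {}
    for child in graph.nodes:
        if child not in display:
            continue
        m, p = graph.parents(child)
        if m is None and p is None:
            continue
        key = (m,) if m == p else (m, p)
        pairs.setdefault(tuple(x for x in key if x is not None), []).append(child)
    return pairs


def render(
    graph: PedigreeGraph,
    dataset: PedimapDataset,
    spec: RenderSpec,
    positions: dict[str, tuple[int, int]],
) -> Drawing:
    """Emit SVG + DOT for a laid-out display set.

    Maternal edges red, paternal purple; one 'x' junction node per mating
    pair (circled for selfing); node fill per :func:`make_palette`; a legend
    block lists the palette.
    """
    display = set(positions)
    fills, legend = make_palette(dataset, spec, display)
    pairs = _mating_pairs(graph, display)

    # --- DOT
    dot: list[str] = ["digraph pedigree {", "  rankdir=TB;"]
    for n in sorted(display, key=lambda n: (positions[n][0], positions[n][1])):
        fill = fills[n]
        dot.append(
            f'  "{n}" [shape=box style=filled fillcolor="{fill}" label="{n}"];'
        )
    for key, children in pairs.items():
        jid = "junction_" + "_x_".join(key)
        shape = "circle" if len(key) == 1 else "plaintext"
        dot.append(f'  "{jid}" [shape={shape} label="x" class=junction];')
        mother = key[0]
        father = key[0] if len(key) == 1 else key[1]
        dot.append(f'  "{mother}" -> "{jid}" [color={MATERNAL_COLOR}];')
        dot.append(f'  "{father}" -> "{jid}" [color={PATERNAL_COLOR}];')
        for child in children:
            dot.append(f'  "{jid}" -> "{child}" [color={CHILD_COLOR}];')
    dot.append("}")
    dot_text = "\n".join(dot) + "\n"

    # --- SVG
    bw, bh, dx, dy, margin = 120, 34, 150, 110, 30
    legend_h = 24 * len(legend) + (30 if legend else 0)
    n_slots = max((s for _, s in positions.values()), default=0) + 1
    n_layers = max((l for l, _ in positions.values()), default=0) + 1
    width = margin * 2 + n_slots * dx
    height = margin * 2 + n_layers * dy + legend_h

    def center(n: str) -> tuple[float, float]:
        lay, slot = positions[n]
        return margin + slot * dx + bw / 2, margin + lay * dy + bh / 2

    svg: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="sans-serif" font-size="12">'
    ]
    # junction coordinates: midway between parents and children layers
    jxy: dict[tuple[str, ...], tuple[float, float]] = {}
    for key, children in pairs.items():
        pcs = [center(p) for p in key]
        ccs = [center(c) for c in children]
        jx = sum(x for x, _ in pcs + ccs) / (len(pcs) + len(ccs))
        jy = (max(y for _, y in pcs) + min(y for _, y in ccs)) / 2
        jxy[key] = (jx, jy)

    for key, children in pairs.items():
        jx, jy = jxy[key]
        mother = key[0]
        father = key[0] if len(key) == 1 else key[1]
        mx, my = center(mother)
        fx, fy = center(father)
        svg.append(f'<line x1="{mx:.1f}" y1="{my + bh / 2:.1f}" x2="{jx:.1f}" y2="{jy:.1f}" stroke="{MATERNAL_COLOR}"/>')
        svg.append(f'<line x1="{fx:.1f}" y1="{fy + bh / 2:.1f}" x2="{jx:.1f}" y2="{jy:.1f}" stroke="{PATERNAL_COLOR}"/>')
        for c in children:
            cx, cy = center(c)
            svg.append(f'<line x1="{jx:.1f}" y1="{jy:.1f}" x2="{cx:.1f}" y2="{cy - bh / 2:.1f}" stroke="{CHILD_COLOR}"/>')
        if len(key) == 1:  # selfing: 'x' in a circle
            svg.append(f'<circle cx="{jx:.1f}" cy="{jy:.1f}" r="9" fill="white" stroke="black"/>')
        svg.append(
            f'<text x="{jx:.1f}" y="{jy + 4:.1f}" text-anchor="middle">&#215;</text>'
        )

    for n in display:
        cx, cy = center(n)
        x, y = cx - bw / 2, cy - bh / 2
        svg.append(
            f'<rect x="{x:.1f}" y="{y:.1f}" width="{bw}" height="{bh}" fill="{fills[n]}" stroke="black"/>'
        )
        svg.append(
            f'<text x="{cx:.1f}" y="{cy + 4:.1f}" text-anchor="middle">{html.escape(n)}</text>'
        )

    if legend:
        ly = margin + n_layers * dy + 20
        svg.append(f'<text x="{margin}" y="{ly}" font-weight="bold">{html.escape(spec.trait or "")}</text>')
        for i, (label, color) in enumerate(legend.items()):
            yy = ly + 14 + i * 24
            svg.append(f'<rect x="{margin}" y="{yy}" width="18" height="14" fill="{color}" stroke="black"/>')
            svg.append(f'<text x="{margin + 26}" y="{yy + 12}">{html.escape(label)}</text>')
    svg.append("</svg>")
    return Drawing(svg="\n".join(svg) + "\n", dot=dot_text, legend=list(legend.items()))
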
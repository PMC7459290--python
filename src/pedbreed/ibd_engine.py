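"""Founder-allele identity-by-descent (IBD) probabilities on a pedigree.

Two routes compute, for every individual, the expected number of its gene
copies descending from each founder allele:

* :func:`ibd_exact` — the exact single-position recursion.  A founder's
  vector is the unit indicator on its own allele slots; a non-founder's is
  the average of its parents' vectors.  Without conditioning on marker data
  the expectation is the same at every map position, so one vector serves
  all positions.
* :func:`gene_drop` — Monte-Carlo gene dropping.  Founder alleles are
  labelled and dropped down the pedigree; within a replicate, crossovers
  between adjacent map positions occur with the Haldane recombination
  fraction r = (1 - exp(-2 d / 100)) / 2 for a distance of d centimorgans
  (no interference).

Vectors are normalized to expected *counts*: every row sums to the ploidy.
Ploidy is 2 throughout the transmission model (rice is diploid); the exact
recursion itself is ploidy-agnostic given a founder-allele index.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .pedfile_io import (
    IBDBlock,
    LinkageGroupMap,
    PedimapDataset,
)
from .pedigree_graph import PedigreeGraph, build_graph, founders, to_networkx

__all__ = [
    "FounderAlleleIndex",
    "GeneDropResult",
    "founder_allele_index",
    "ibd_exact",
    "gene_drop",
    "attach_ibd",
    "haldane",
    "ibd_to_tsv",
]

PLOIDY = 2  # gene-drop transmission model is diploid


def haldane(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


@dataclass
class FounderAlleleIndex:
    """Deterministic ordering of founder allele slots.

    One entry per (founder, slot) pair, founders in pedigree-file order (true
    founders first, then phantom founders), slots 1..ploidy within a founder.
    """

    entries: list[tuple[str, int]]

    def __len__(self) -> int:
        return len(self.entries)

    def slots_of(self, founder: str) -> list[int]:
        return [i for i, (f, _) in enumerate(self.entries) if f == founder]


def founder_allele_index(graph: PedigreeGraph, ploidy: int = PLOIDY) -> FounderAlleleIndex:
    founder_set = founders(graph, include_phantoms=True)
    ordered = [n for n in graph.nodes if n in founder_set]
    return FounderAlleleIndex([(f, s + 1) for f in ordered for s in range(ploidy)])


def ibd_exact(
    graph: PedigreeGraph, index: FounderAlleleIndex | None = None, ploidy: int = PLOIDY
) -> dict[str, np.ndarray]:
    """Exact expected founder-allele counts per individual (one vector each).

    Conservation holds by construction: each vector sums to the ploidy.
    """
    if index is None:
        index = founder_allele_index(graph, ploidy)
    n = len(index)
    slot_of = {}
    for i, (f, _) in enumerate(index.entries):
        slot_of.setdefault(f, []).append(i)

    dg = to_networkx(graph)
    out: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(dg):
        m = graph.maternal_edge.get(node)
        p = graph.paternal_edge.get(node)
        if m is None and p is None:
            v = np.zeros(n)
            if node not in slot_of:
                raise KeyError(f"founder {node!r} missing from the founder-allele index")
            v[slot_of[node]] = 1.0
        else:
            v = 0.5 * out[m] + 0.5 * out[p]
        out[node] = v
    return out


@dataclass
class GeneDropResult:
    index: FounderAlleleIndex
    positions: list[tuple[str, float]]  # (group, cM)
    freq: dict[str, np.ndarray]  # individual -> (n_positions, n_alleles) mean counts
    se: dict[str, np.ndarray]  # matching Monte-Carlo standard errors
    n_reps: int

    def vector(self, individual: str, pos_i: int = 0) -> np.ndarray:
        return self.freq[individual][pos_i]


def _drop_alleles(
    graph: PedigreeGraph,
    positions_cm: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    index: FounderAlleleIndex,
) -> dict[str, np.ndarray]:
    """Simulate founder-allele labels for each individual.

    Returns individual -> int array of shape (n_reps, n_pos, 2) holding
    founder-allele indices for the two gene copies.
    """
    n_pos = len(positions_cm)
    r = haldane(np.diff(positions_cm)) if n_pos > 1 else np.empty(0)
    slot_of: dict[str, list[int]] = {}
    for i, (f, _) in enumerate(index.entries):
        slot_of.setdefault(f, []).append(i)

    dg = to_networkx(graph)
    alleles: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(dg):
        m = graph.maternal_edge.get(node)
        p = graph.paternal_edge.get(node)
        if m is None and p is None:
            s = slot_of[node]
            a = np.empty((n_reps, n_pos, 2), dtype=np.int32)
            a[:, :, 0] = s[0]
            a[:, :, 1] = s[1]
            alleles[node] = a
        else:
            a = np.empty((n_reps, n_pos, 2), dtype=np.int32)
            for copy, parent in ((0, m), (1, p)):
                # which of the parent's two copies is transmitted, per rep x pos:
                # uniform start, then crossover (indicator flip) with prob r
                start = rng.integers(0, 2, size=(n_reps, 1))
                if n_pos > 1:
                    flips = rng.random((n_reps, n_pos - 1)) < r
                    which = (start + np.concatenate(
                        [np.zeros((n_reps, 1), dtype=np.int64), np.cumsum(flips, axis=1)], axis=1
                    )) % 2
                else:
                    which = np.broadcast_to(start, (n_reps, n_pos))
                a[:, :, copy] = np.take_along_axis(
                    alleles[parent], which[:, :, None].astype(np.int32), axis=2
                )[:, :, 0]
            alleles[node] = a
    return alleles


def gene_drop(
    graph: PedigreeGraph,
    lg_map: LinkageGroupMap,
    n_reps: int,
    seed: int,
    positions_cm: list[float] | None = None,
) -> GeneDropResult:
    """Monte-Carlo gene dropping over the positions of one linkage-group map.

    Identical seeds give identical output.  Standard errors are per-entry
    binomial-style MC errors (sd of the per-replicate counts / sqrt(n_reps)).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if positions_cm is None:
        positions_cm = lg_map.positions
    if not positions_cm:
        raise ValueError(f"map {lg_map.group_name!r} has no positions")
    lo, hi = min(lg_map.positions), max(lg_map.positions)
    for p in positions_cm:
        if p < lo - 1e-9 or p > hi + 1e-9:
            raise ValueError(f"position {p} cM outside map range [{lo}, {hi}]")

    rng = np.random.default_rng(seed)
    index = founder_allele_index(graph)
    pos = np.asarray(sorted(positions_cm), dtype=float)
    alleles = _drop_alleles(graph, pos, n_reps, rng, index)

    n_all = len(index)
    freq: dict[str, np.ndarray] = {}
    se: dict[str, np.ndarray] = {}
    for ind, a in alleles.items():
        # per-replicate count of copies from each founder allele
        counts = np.zeros((n_reps, len(pos), n_all), dtype=np.float64)
        for copy in (0, 1):
            np.add.at(
                counts.reshape(-1, n_all),
                (np.arange(n_reps * len(pos)), a[:, :, copy].reshape(-1)),
                1.0,
            )
        freq[ind] = counts.mean(axis=0)
        se[ind] = counts.std(axis=0, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.zeros_like(freq[ind])
    return GeneDropResult(
        index=index,
        positions=[(lg_map.group_name, float(p)) for p in pos],
        freq=freq,
        se=se,
        n_reps=n_reps,
    )


def kinship_gene_drop(graph: PedigreeGraph, n_reps: int, seed: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Monte-Carlo kinship: P(random gamete of x IBD to random gamete of y).

    Estimated at a single position from independent gene drops; returns
    (names, estimate matrix, standard-error matrix).  Serves as the
    simulation cross-check of the closed-form pedigree kinship.
    """
    rng = np.random.default_rng(seed)
    index = founder_allele_index(graph)
    alleles = _drop_alleles(graph, np.array([0.0]), n_reps, rng, index)
    names = list(graph.nodes)
    k = len(names)
    est = np.zeros((k, k))
    sem = np.zeros((k, k))
    mats = {n: alleles[n][:, 0, :] for n in names}  # (n_reps, 2)
    for i, x in enumerate(names):
        ax = mats[x]
        for j in range(i, k):
            ay = mats[names[j]]
            # P over the 4 gamete pairings that the sampled copies are identical
            match = (ax[:, :, None] == ay[:, None, :]).mean(axis=(1, 2))
            est[i, j] = est[j, i] = match.mean()
            sem[i, j] = sem[j, i] = match.std(ddof=1) / np.sqrt(n_reps)
    return names, est, sem


def attach_ibd(
    dataset: PedimapDataset,
    method: str = "exact",
    n_reps: int = 20000,
    seed: int = 0,
) -> PedimapDataset:
    """Populate the dataset's IBD blocks (and NALLELES) in place and return it.

    ``method='exact'`` writes the position-independent expectation at every
    map position (or at a single pseudo-position for map-less files);
    ``method='gene_drop'`` requires a linkage map and writes empirical
    frequencies.  Raises if an existing NALLELES conflicts with the pedigree.
    """
    graph = build_graph(dataset.records)
    index = founder_allele_index(graph, dataset.header.ploidy if method == "exact" else PLOIDY)
    nalleles = len(index)
    if dataset.header.n_founder_alleles is not None and dataset.header.n_founder_alleles != nalleles:
        raise ValueError(
            f"header NALLELES={dataset.header.n_founder_alleles} conflicts with "
            f"ploidy x founders = {nalleles}"
        )

    real = [r.name for r in dataset.records]
    blocks: list[IBDBlock] = []
    if method == "exact":
        vectors = ibd_exact(graph, index, ploidy=dataset.header.ploidy)
        positions = [(m.group_name, pos) for m in dataset.maps for pos in m.positions]
        if not positions:
            positions = [("pedigree", 0.0)]
        for group, pos in positions:
            blocks.append(
                IBDBlock(group, pos, {n: [float(v) for v in vectors[n]] for n in real})
            )
    elif method == "gene_drop":
        if not dataset.maps:
            raise ValueError("gene_drop requires a linkage-group map")
        for m in dataset.maps:
            res = gene_drop(graph, m, n_reps=n_reps, seed=seed)
            for pi, (group, pos) in enumerate(res.positions):
                blocks.append(
                    IBDBlock(group, pos, {n: [float(v) for v in res.freq[n][pi]] for n in real})
                )
    else:
        raise ValueError(f"unknown IBD method {method!r}")

    dataset.ibd = blocks
    dataset.header.n_founder_alleles = nalleles
    return dataset


def ibd_to_tsv(dataset: PedimapDataset) -> str:
    """Long-format TSV of the IBD section: individual, group, position, founder allele, probability."""
    graph = build_graph(dataset.records)
    index = founder_allele_index(graph, dataset.header.ploidy)
    lines = ["individual\tgroup\tposition_cm\tfounder\tallele_slot\tprobability"]
    for block in dataset.ibd:
        for ind, probs in block.rows.items():
            for (fndr, slot), p in zip(index.entries, probs):
                lines.append(f"{ind}\t{block.group_name}\t{block.position_cm:g}\t{fndr}\t{slot}\t{p:.6f}")
    return "\n".join(lines) + "\n"
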
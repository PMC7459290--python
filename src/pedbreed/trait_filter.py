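"""Declarative trait-threshold selection of parent subpopulations.

A :class:`SelectionCriteria` is an ordered list of per-trait predicates —
inclusive thresholds or ranges on quantitative traits, category membership on
categorical ones.  Criteria combine by conjunction; the order expresses the
breeder's priority and affects reporting only, never membership.  Individuals
missing a filtered trait are excluded under the default missing policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
import yaml

from .pedfile_io import CATEGORICAL, QUANTITATIVE, PedimapDataset
from .pedigree_graph import PedigreeGraph, ancestor_closure

__all__ = [
    "Criterion",
    "SelectionCriteria",
    "apply_criteria",
    "selection_report",
    "display_set",
    "load_criteria",
    "criteria_from_dict",
]

_OPS = {"ge", "le", "between", "in"}


@dataclass
class Criterion:
    trait: str
    op: str  # ge | le | between (quantitative) | in (categorical)
    value: object = None  # number, (low, high) pair, or set of labels

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown criterion op {self.op!r}")

    def matches(self, value: float | str | None) -> bool:
        if value is None:
            return False
        if self.op == "ge":
            return float(value) >= float(self.value)  # type: ignore[arg-type]
        if self.op == "le":
            return float(value) <= float(self.value)  # type: ignore[arg-type]
        if self.op == "between":
            lo, hi = self.value  # type: ignore[misc]
            return float(lo) <= float(value) <= float(hi)
        return str(value) in set(self.value)  # type: ignore[arg-type]

    def describe(self) -> str:
        if self.op == "ge":
            return f"{self.trait} >= {self.value}"
        if self.op == "le":
            return f"{self.trait} <= {self.value}"
        if self.op == "between":
            lo, hi = self.value  # type: ignore[misc]
            return f"{lo} <= {self.trait} <= {hi}"
        return f"{self.trait} in {{{', '.join(sorted(set(self.value)))}}}"  # type: ignore[arg-type]


@dataclass
class SelectionCriteria:
    criteria: list[Criterion] = field(default_factory=list)  # priority order
    missing_policy: str = "exclude"  # exclude | include

    def __post_init__(self) -> None:
        if self.missing_policy not in ("exclude", "include"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")

    def validate_against(self, dataset: PedimapDataset) -> None:
        kinds = {t.name: t.kind for t in dataset.traits}
        for c in self.criteria:
            if c.trait not in kinds:
                raise KeyError(f"criterion trait {c.trait!r} not in dataset")
            wanted = CATEGORICAL if c.op == "in" else QUANTITATIVE
            if kinds[c.trait] != wanted:
                raise TypeError(
                    f"criterion on {c.trait!r} needs a {wanted} trait, dataset has {kinds[c.trait]}"
                )


def apply_criteria(dataset: PedimapDataset, criteria: SelectionCriteria) -> list[str]:
    """Individuals satisfying every criterion, in pedigree-file order.

    Under ``missing_policy='exclude'`` an individual missing any filtered
    trait is dropped; under ``'include'`` a missing value passes that
    criterion (useful for display-oriented selections).
    """
    criteria.validate_against(dataset)
    selected = []
    for rec in dataset.records:
        ok = True
        for c in criteria.criteria:
            v = rec.phenotypes.get(c.trait)
            if v is None:
                if criteria.missing_policy == "exclude":
                    ok = False
                    break
                continue
            if not c.matches(v):
                ok = False
                break
        if ok:
            selected.append(rec.name)
    return selected


def selection_report(
    dataset: PedimapDataset, criteria: SelectionCriteria, subpop: Iterable[str]
) -> dict:
    """Per-criterion pass/fail matrix and per-trait summaries for a subpopulation.

    The summaries support statements like "only k members are fully
    resistant": categorical traits get level counts, quantitative traits get
    (min, mean, max) over the non-missing members.
    """
    subpop = list(subpop)
    recs = {r.name: r for r in dataset.records}
    matrix = pd.DataFrame(
        {
            c.describe(): [c.matches(recs[n].phenotypes.get(c.trait)) for n in subpop]
            for c in criteria.criteria
        },
        index=subpop,
    )
    kinds = {t.name: t.kind for t in dataset.traits}
    summaries: dict[str, object] = {}
    for c in criteria.criteria:
        vals = [recs[n].phenotypes.get(c.trait) for n in subpop]
        vals = [v for v in vals if v is not None]
        if not vals:
            summaries[c.trait] = {}
            continue
        if kinds[c.trait] == CATEGORICAL:
            counts: dict[str, int] = {}
            for v in vals:
                counts[str(v)] = counts.get(str(v), 0) + 1
            summaries[c.trait] = counts
        else:
            arr = [float(v) for v in vals]
            summaries[c.trait] = {
                "min": min(arr),
                "mean": sum(arr) / len(arr),
                "max": max(arr),
                "n": len(arr),
            }
    return {"matrix": matrix, "summaries": summaries}


def display_set(graph: PedigreeGraph, subpop: Iterable[str]) -> tuple[set[str], set[str]]:
    """Ancestor closure of the subpopulation for drawing a connected pedigree.

    Returns (display nodes, context-only nodes); context-only members are the
    connecting ancestors outside the subpopulation, rendered uncolored.
    """
    subpop = set(subpop)
    closure = ancestor_closure(graph, subpop)
    return closure, closure - subpop


def criteria_from_dict(doc: dict) -> SelectionCriteria:
    crits = []
    for item in doc.get("criteria", []):
        op = item["op"]
        if op == "in":
            value = list(item["values"])
        elif op == "between":
            value = (item["values"][0], item["values"][1])
        else:
            value = item["value"]
        crits.append(Criterion(trait=item["trait"], op=op, value=value))
    return SelectionCriteria(criteria=crits, missing_policy=doc.get("missing_policy", "exclude"))


def load_criteria(path) -> SelectionCriteria:
    """Read criteria from a YAML file (see data/criteria for examples)."""
    with open(path) as fh:
        return criteria_from_dict(yaml.safe_load(fh))
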
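"""Reader, writer and validator for the sectioned tab-delimited pedigree file dialect.

A pedigree file carries, in order: a header (population name, ploidy and the
codes used for missing / possible-null / confirmed-null data, plus the optional
founder-allele count ``NALLELES``), a pedigree-and-phenotype table, and an
optional genotypic part made of linkage-group maps, observed marker alleles,
and founder-allele identity-by-descent (IBD) probability blocks.  The exact
grammar is documented in ``FORMAT.md`` at the repository root.

Values in phenotype cells are floats for quantitative traits and bare tokens
for categorical traits; the header's unknown-code marks a missing value and is
represented in memory as ``None``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

__all__ = [
    "HeaderSpec",
    "PedigreeRecord",
    "TraitColumn",
    "LinkageGroupMap",
    "MarkerGenotype",
    "IBDBlock",
    "PedimapDataset",
    "ValidationIssue",
    "PedimapError",
    "PedimapParseError",
    "PedimapValidationError",
    "parse_pedimap",
    "write_pedimap",
    "validate_dataset",
    "pedigree_to_csv",
]

# Reserved keywords that open header fields or file sections.
_HEADER_KEYS = {"POPULATION", "PLOIDY", "UNKNOWN", "POSSIBLENULL", "CONFIRMEDNULL", "NALLELES"}
_SECTION_KEYS = {"PEDIGREE", "MAP", "LOCUS", "IBD"}

QUANTITATIVE = "quantitative"
CATEGORICAL = "categorical"

IBD_ROW_SUM_TOL = 1e-6


class PedimapError(Exception):
    """Base class for pedigree-file errors."""


class PedimapParseError(PedimapError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        loc = f"line {line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")


class PedimapValidationError(PedimapError):
    """Raised when a dataset violates its invariants; carries the full report."""

    def __init__(self, report: list["ValidationIssue"]):
        self.report = report
        errors = [i for i in report if i.severity == "error"]
        super().__init__(
            "; ".join(f"[{i.location}] {i.message}" for i in errors) or "validation failed"
        )


@dataclass
class HeaderSpec:
    population_name: str
    ploidy: int = 2
    code_unknown: str = "-"
    code_possible_null: str = "?"
    code_confirmed_null: str = "!"
    n_founder_alleles: int | None = None


@dataclass
class PedigreeRecord:
    name: str
    mother: str | None
    father: str | None
    phenotypes: dict[str, float | str | None] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


@dataclass
class TraitColumn:
    name: str
    kind: str = QUANTITATIVE  # quantitative | categorical
    units: str = ""


@dataclass
class LinkageGroupMap:
    group_name: str
    loci: list[tuple[str, float]] = field(default_factory=list)

    @property
    def locus_names(self) -> list[str]:
        return [name for name, _ in self.loci]

    @property
    def positions(self) -> list[float]:
        return [pos for _, pos in self.loci]


@dataclass
class MarkerGenotype:
    individual: str
    locus: str
    alleles: list[str] = field(default_factory=list)


@dataclass
class IBDBlock:
    group_name: str
    position_cm: float
    rows: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class PedimapDataset:
    header: HeaderSpec
    records: list[PedigreeRecord] = field(default_factory=list)
    traits: list[TraitColumn] = field(default_factory=list)
    maps: list[LinkageGroupMap] = field(default_factory=list)
    genotypes: list[MarkerGenotype] = field(default_factory=list)
    ibd: list[IBDBlock] = field(default_factory=list)

    def record(self, name: str) -> PedigreeRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def trait(self, name: str) -> TraitColumn:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def founder_names(self) -> list[str]:
        return [r.name for r in self.records if r.is_founder]

    def equals(self, other: "PedimapDataset", ibd_tol: float = 0.0) -> bool:
        """Field-for-field equality, with an optional tolerance on IBD entries."""
        if (
            self.header != other.header
            or self.records != other.records
            or self.traits != other.traits
            or self.maps != other.maps
            or self.genotypes != other.genotypes
            or len(self.ibd) != len(other.ibd)
        ):
            return False
        for a, b in zip(self.ibd, other.ibd):
            if a.group_name != b.group_name or a.position_cm != b.position_cm:
                return False
            if list(a.rows) != list(b.rows):
                return False
            for k in a.rows:
                ra, rb = a.rows[k], b.rows[k]
                if len(ra) != len(rb):
                    return False
                if any(abs(x - y) > ibd_tol for x, y in zip(ra, rb)):
                    return False
        return True


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str
    message: str


# ---------------------------------------------------------------------------
# parsing


def _fmt_num(v: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    if isinstance(v, float) and v.is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _parse_trait_header(token: str) -> TraitColumn:
    # column headers may be annotated as name:Q[:units] or name:C[:units]
    parts = token.split(":")
    name = parts[0]
    if len(parts) == 1:
        return TraitColumn(name=name, kind="", units="")  # kind inferred later
    kind = {"Q": QUANTITATIVE, "C": CATEGORICAL}.get(parts[1].upper())
    if kind is None:
        raise PedimapParseError(f"unknown trait kind {parts[1]!r} in column {token!r}")
    units = parts[2] if len(parts) > 2 else ""
    return TraitColumn(name=name, kind=kind, units=units)


def parse_pedimap(source: str | TextIO) -> PedimapDataset:
    """Parse a sectioned pedigree file into a :class:`PedimapDataset`.

    Accepts a string or a readable text stream.  The resulting dataset has
    been validated; any error-severity issue raises
    :class:`PedimapValidationError` (structural problems that prevent reading
    at all raise :class:`PedimapParseError` with the offending line number).
    """
    text = source.read() if hasattr(source, "read") else str(source)
    lines = text.splitlines()

    header_fields: dict[str, str] = {}
    records: list[PedigreeRecord] = []
    traits: list[TraitColumn] = []
    maps: list[LinkageGroupMap] = []
    genotypes: list[MarkerGenotype] = []
    ibd: list[IBDBlock] = []

    section = "header"
    trait_cols: list[TraitColumn] | None = None
    raw_trait_values: dict[str, list[str]] = {}
    current_map: LinkageGroupMap | None = None
    current_locus: str | None = None
    current_ibd: IBDBlock | None = None
    unknown = None  # filled once header complete

    def finish_header(lineno: int) -> HeaderSpec:
        missing = [k for k in ("POPULATION", "PLOIDY", "UNKNOWN", "POSSIBLENULL", "CONFIRMEDNULL") if k not in header_fields]
        if missing:
            raise PedimapParseError(f"missing mandatory header element(s): {', '.join(missing)}", lineno)
        try:
            ploidy = int(header_fields["PLOIDY"])
        except ValueError:
            raise PedimapParseError("PLOIDY must be an integer", lineno) from None
        nall = None
        if "NALLELES" in header_fields:
            try:
                nall = int(header_fields["NALLELES"])
            except ValueError:
                raise PedimapParseError("NALLELES must be an integer", lineno) from None
        return HeaderSpec(
            population_name=header_fields["POPULATION"],
            ploidy=ploidy,
            code_unknown=header_fields["UNKNOWN"],
            code_possible_null=header_fields["POSSIBLENULL"],
            code_confirmed_null=header_fields["CONFIRMEDNULL"],
            n_founder_alleles=nall,
        )

    header: HeaderSpec | None = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        key = fields[0].strip().upper()

        if key in _SECTION_KEYS:
            if header is None:
                header = finish_header(lineno)
                unknown = header.code_unknown
            if key == "PEDIGREE":
                section = "pedigree"
                trait_cols = None
            elif key == "MAP":
                if len(fields) < 2 or not fields[1].strip():
                    raise PedimapParseError("MAP requires a linkage-group name", lineno)
                current_map = LinkageGroupMap(group_name=fields[1].strip())
                maps.append(current_map)
                section = "map"
            elif key == "LOCUS":
                if len(fields) < 2 or not fields[1].strip():
                    raise PedimapParseError("LOCUS requires a locus name", lineno)
                current_locus = fields[1].strip()
                section = "locus"
            elif key == "IBD":
                if len(fields) < 3:
                    raise PedimapParseError("IBD requires a group name and a cM position", lineno)
                try:
                    pos = float(fields[2])
                except ValueError:
                    raise PedimapParseError(f"invalid IBD position {fields[2]!r}", lineno) from None
                current_ibd = IBDBlock(group_name=fields[1].strip(), position_cm=pos)
                ibd.append(current_ibd)
                section = "ibd"
            continue

        if section == "header":
            if key not in _HEADER_KEYS:
                raise PedimapParseError(f"unexpected line in header: {fields[0]!r}", lineno)
            if len(fields) < 2 or not fields[1].strip():
                raise PedimapParseError(f"header element {key} has no value", lineno)
            header_fields[key] = fields[1].strip()

        elif section == "pedigree":
            if trait_cols is None:
                # column header row
                if len(fields) < 3:
                    raise PedimapParseError("pedigree header row needs Name, Mother, Father columns", lineno)
                trait_cols = [_parse_trait_header(tok.strip()) for tok in fields[3:]]
                names_seen = set()
                for t in trait_cols:
                    if t.name in names_seen:
                        raise PedimapParseError(f"duplicate trait column {t.name!r}", lineno)
                    names_seen.add(t.name)
                traits.extend(trait_cols)
                for t in trait_cols:
                    raw_trait_values[t.name] = []
                continue
            if len(fields) != 3 + len(trait_cols):
                raise PedimapParseError(
                    f"pedigree row has {len(fields)} fields, expected {3 + len(trait_cols)}", lineno
                )
            name, mother, father = (f.strip() for f in fields[:3])
            if not name:
                raise PedimapParseError("empty individual name", lineno)
            rec = PedigreeRecord(
                name=name,
                mother=None if mother == unknown else mother,
                father=None if father == unknown else father,
            )
            for t, cell in zip(trait_cols, fields[3:]):
                cell = cell.strip()
                raw_trait_values[t.name].append(cell)
                rec.phenotypes[t.name] = None if cell == unknown else cell
            records.append(rec)

        elif section == "map":
            if len(fields) != 2:
                raise PedimapParseError("map row must be '<locus>\\t<position_cM>'", lineno)
            try:
                pos = float(fields[1])
            except ValueError:
                raise PedimapParseError(f"invalid map position {fields[1]!r}", lineno) from None
            assert current_map is not None
            current_map.loci.append((fields[0].strip(), pos))

        elif section == "locus":
            assert current_locus is not None and header is not None
            alleles = [f.strip() for f in fields[1:]]
            if len(alleles) != header.ploidy:
                raise PedimapParseError(
                    f"individual {fields[0]!r} at locus {current_locus!r}: "
                    f"{len(alleles)} allele(s), expected ploidy {header.ploidy}",
                    lineno,
                )
            genotypes.append(MarkerGenotype(individual=fields[0].strip(), locus=current_locus, alleles=alleles))

        elif section == "ibd":
            assert current_ibd is not None
            try:
                probs = [float(f) for f in fields[1:]]
            except ValueError:
                raise PedimapParseError("non-numeric IBD probability", lineno) from None
            ind = fields[0].strip()
            if header is not None and header.n_founder_alleles is not None and len(probs) != header.n_founder_alleles:
                raise PedimapParseError(
                    f"IBD row for {ind!r} has {len(probs)} entries, expected NALLELES={header.n_founder_alleles}",
                    lineno,
                )
            current_ibd.rows[ind] = probs

    if header is None:
        header = finish_header(len(lines))

    # resolve trait kinds left unannotated: quantitative iff every non-missing
    # cell parses as a number
    for t in traits:
        if t.kind:
            continue
        vals = [v for v in raw_trait_values.get(t.name, []) if v != header.code_unknown]
        t.kind = QUANTITATIVE if vals and all(_is_number(v) for v in vals) else CATEGORICAL
        if not vals:
            t.kind = CATEGORICAL

    # coerce quantitative phenotype cells to floats
    kind_of = {t.name: t.kind for t in traits}
    for lineno_offset, rec in enumerate(records):
        for tname, val in rec.phenotypes.items():
            if val is None:
                continue
            if kind_of[tname] == QUANTITATIVE:
                try:
                    rec.phenotypes[tname] = float(val)
                except ValueError:
                    raise PedimapParseError(
                        f"non-numeric value {val!r} for quantitative trait {tname!r} "
                        f"(individual {rec.name})"
                    ) from None

    ds = PedimapDataset(header=header, records=records, traits=traits, maps=maps, genotypes=genotypes, ibd=ibd)
    report = validate_dataset(ds)
    errors = [i for i in report if i.severity == "error"]
    if errors:
        raise PedimapValidationError(report)
    return ds


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# writing


def write_pedimap(dataset: PedimapDataset, stream: TextIO | None = None) -> str:
    """Serialize a dataset to the tab-delimited dialect.

    Sections are emitted in canonical order (header, pedigree, maps, marker
    genotypes, IBD).  Invariant violations are reported before any output is
    produced.  Returns the text; also writes to *stream* if given.
    """
    report = validate_dataset(dataset)
    errors = [i for i in report if i.severity == "error"]
    if errors:
        raise PedimapValidationError(report)

    h = dataset.header
    out = io.StringIO()
    w = out.write
    w(f"POPULATION\t{h.population_name}\n")
    w(f"PLOIDY\t{h.ploidy}\n")
    w(f"UNKNOWN\t{h.code_unknown}\n")
    w(f"POSSIBLENULL\t{h.code_possible_null}\n")
    w(f"CONFIRMEDNULL\t{h.code_confirmed_null}\n")
    if h.n_founder_alleles is not None:
        w(f"NALLELES\t{h.n_founder_alleles}\n")
    w("\n")

    w("PEDIGREE\n")
    cols = ["Name", "Mother", "Father"]
    for t in dataset.traits:
        tag = "Q" if t.kind == QUANTITATIVE else "C"
        cols.append(f"{t.name}:{tag}:{t.units}" if t.units else f"{t.name}:{tag}")
    w("\t".join(cols) + "\n")
    for rec in dataset.records:
        cells = [rec.name, rec.mother or h.code_unknown, rec.father or h.code_unknown]
        for t in dataset.traits:
            v = rec.phenotypes.get(t.name)
            if v is None:
                cells.append(h.code_unknown)
            elif t.kind == QUANTITATIVE:
                cells.append(_fmt_num(float(v)))
            else:
                cells.append(str(v))
        w("\t".join(cells) + "\n")

    for m in dataset.maps:
        w(f"\nMAP\t{m.group_name}\n")
        for locus, pos in m.loci:
            w(f"{locus}\t{_fmt_num(pos)}\n")

    by_locus: dict[str, list[MarkerGenotype]] = {}
    for g in dataset.genotypes:
        by_locus.setdefault(g.locus, []).append(g)
    for locus, gens in by_locus.items():
        w(f"\nLOCUS\t{locus}\n")
        for g in gens:
            w(g.individual + "\t" + "\t".join(g.alleles) + "\n")

    for block in dataset.ibd:
        w(f"\nIBD\t{block.group_name}\t{_fmt_num(block.position_cm)}\n")
        for ind, probs in block.rows.items():
            w(ind + "\t" + "\t".join(_fmt_num(p) for p in probs) + "\n")

    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# validation


def validate_dataset(dataset: PedimapDataset) -> list[ValidationIssue]:
    """Check every dataset invariant; returns a report of (severity, location, message).

    The report contains no error-severity entries iff all invariants hold.
    Warnings flag suspicious but legal content (map loci with no observed
    genotypes; records with exactly one known parent).
    """
    issues: list[ValidationIssue] = []
    err = lambda loc, msg: issues.append(ValidationIssue("error", loc, msg))
    warn = lambda loc, msg: issues.append(ValidationIssue("warning", loc, msg))

    h = dataset.header
    if h.ploidy < 1:
        err("header", f"ploidy must be >= 1, got {h.ploidy}")
    codes = [h.code_unknown, h.code_possible_null, h.code_confirmed_null]
    if len(set(codes)) != 3:
        err("header", f"missing/possible-null/confirmed-null codes must be pairwise distinct, got {codes}")
    if not h.population_name or any(c.isspace() for c in h.population_name):
        err("header", "population name must be a non-empty token without whitespace")

    names: set[str] = set()
    for i, rec in enumerate(dataset.records):
        loc = f"pedigree[{i}] {rec.name}"
        if not rec.name or any(c.isspace() for c in rec.name):
            err(loc, "individual name must be non-empty without whitespace")
        if rec.name in names:
            err(loc, f"duplicate individual name {rec.name!r}")
        names.add(rec.name)
    for i, rec in enumerate(dataset.records):
        loc = f"pedigree[{i}] {rec.name}"
        for role, parent in (("mother", rec.mother), ("father", rec.father)):
            if parent is not None and parent not in names:
                err(loc, f"{role} {parent!r} is not declared in the pedigree section")
        if (rec.mother is None) != (rec.father is None):
            warn(loc, "exactly one known parent; the unknown gamete is treated as a phantom founder")

    # parentage must be acyclic
    cycle = _find_cycle(dataset.records)
    if cycle:
        err("pedigree", "parentage cycle detected: " + " -> ".join(cycle))

    tnames = [t.name for t in dataset.traits]
    if len(set(tnames)) != len(tnames):
        err("traits", "trait names must be unique within a file")
    for t in dataset.traits:
        if t.kind not in (QUANTITATIVE, CATEGORICAL):
            err(f"trait {t.name}", f"unknown kind {t.kind!r}")

    locus_groups: dict[str, str] = {}
    for m in dataset.maps:
        last = -math.inf
        for locus, pos in m.loci:
            if pos < 0:
                err(f"map {m.group_name}", f"locus {locus} has negative position {pos}")
            if pos < last:
                err(f"map {m.group_name}", f"positions not non-decreasing at locus {locus}")
            last = pos
            if locus in locus_groups:
                err(f"map {m.group_name}", f"locus {locus!r} already defined in group {locus_groups[locus]!r}")
            locus_groups[locus] = m.group_name

    used_loci = set()
    for g in dataset.genotypes:
        loc = f"genotype {g.individual}@{g.locus}"
        if g.individual not in names:
            err(loc, f"individual {g.individual!r} not in pedigree")
        if g.locus not in locus_groups:
            err(loc, f"locus {g.locus!r} not on any linkage-group map")
        if len(g.alleles) != h.ploidy:
            err(loc, f"{len(g.alleles)} allele(s), expected ploidy {h.ploidy}")
        used_loci.add(g.locus)
    if dataset.genotypes:
        for locus in locus_groups:
            if locus not in used_loci:
                warn(f"locus {locus}", "no observed genotypes for this mapped locus")

    n_founders = sum(1 for r in dataset.records if r.is_founder)
    n_phantoms = sum(1 for r in dataset.records if (r.mother is None) != (r.father is None))
    expected_nalleles = h.ploidy * (n_founders + n_phantoms)
    if dataset.ibd and h.n_founder_alleles is None:
        err("header", "NALLELES is required when IBD blocks are present")
    if h.n_founder_alleles is not None and h.n_founder_alleles != expected_nalleles:
        err(
            "header",
            f"NALLELES={h.n_founder_alleles} inconsistent with ploidy x founders "
            f"({h.ploidy} x {n_founders + n_phantoms} = {expected_nalleles})",
        )
    for block in dataset.ibd:
        bloc = f"IBD {block.group_name}@{_fmt_num(block.position_cm)}"
        if dataset.maps and block.group_name not in {m.group_name for m in dataset.maps}:
            err(bloc, f"group {block.group_name!r} not among the linkage-group maps")
        for ind, probs in block.rows.items():
            if ind not in names:
                err(bloc, f"individual {ind!r} not in pedigree")
            if h.n_founder_alleles is not None and len(probs) != h.n_founder_alleles:
                err(bloc, f"row {ind}: length {len(probs)} != NALLELES {h.n_founder_alleles}")
            if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
                err(bloc, f"row {ind}: probability outside [0, 1]")
            if abs(sum(probs) - h.ploidy) > IBD_ROW_SUM_TOL:
                err(bloc, f"row {ind}: sums to {sum(probs):.8f}, expected ploidy {h.ploidy}")

    return issues


def _find_cycle(records: list[PedigreeRecord]) -> list[str] | None:
    """Return one witness cycle in the parent-of relation, or None."""
    parents = {r.name: [p for p in (r.mother, r.father) if p is not None] for r in records}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in parents}
    stack_path: list[str] = []

    def dfs(node: str) -> list[str] | None:
        color[node] = GREY
        stack_path.append(node)
        for p in parents.get(node, ()):  # parent edges
            if p not in color:
                continue
            if color[p] == GREY:
                i = stack_path.index(p)
                return stack_path[i:] + [p]
            if color[p] == WHITE:
                found = dfs(p)
                if found:
                    return found
        color[node] = BLACK
        stack_path.pop()
        return None

    for n in parents:
        if color[n] == WHITE:
            found = dfs(n)
            if found:
                return found
    return None


# ---------------------------------------------------------------------------
# interoperability


def pedigree_to_csv(dataset: PedimapDataset) -> pd.DataFrame:
    """Export the pedigree+phenotype section as a tidy DataFrame (one row per individual)."""
    rows = []
    for rec in dataset.records:
        row: dict[str, object] = {"name": rec.name, "mother": rec.mother, "father": rec.father}
        row.update(rec.phenotypes)
        rows.append(row)
    cols = ["name", "mother", "father"] + [t.name for t in dataset.traits]
    return pd.DataFrame(rows, columns=cols)
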
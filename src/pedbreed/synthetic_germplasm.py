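"""Synthetic germplasm generator.

Emulates a curated rice-breeding germplasm database: a multi-generation
pedigree over named founders (landraces and old varieties), crosses, selfings
and backcrosses; quantitative traits under the additive infinitesimal model at
stated heritabilities; fully penetrant single-locus categorical traits
inherited by gene drop; sparse missingness; and optional SSR-style marker
genotypes dropped over a linkage map.  Output is a complete
:class:`~pedbreed.pedfile_io.PedimapDataset` plus the simulated true breeding
values (TBVs), which are kept out of the pedigree file and serve only as
ground truth.

Generative model per quantitative trait (units are the trait's own):
founder TBV ~ N(0, sigma2_A); offspring TBV = midparent + N(0, sigma2_A / 2)
(Mendelian sampling); phenotype P = mu + TBV + N(0, sigma2_E).  The implied
heritability is H^2 = sigma2_A / (sigma2_A + sigma2_E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedfile_io import (
    CATEGORICAL,
    QUANTITATIVE,
    HeaderSpec,
    LinkageGroupMap,
    MarkerGenotype,
    PedigreeRecord,
    PedimapDataset,
    TraitColumn,
)
from .pedigree_graph import build_graph
from .ibd_engine import _drop_alleles, founder_allele_index

__all__ = [
    "QuantTraitSpec",
    "CatTraitSpec",
    "GenerationPlan",
    "SimConfig",
    "simulate",
    "default_config",
    "study_scale_config",
    "fixture_suite",
    "tbv_to_tsv",
]


@dataclass
class QuantTraitSpec:
    name: str
    mu: float
    var_a: float  # additive genetic variance, units^2
    var_e: float  # environmental variance, units^2
    direction: str = "higher-better"
    units: str = ""

    def __post_init__(self) -> None:
        if self.var_a < 0 or self.var_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.var_a + self.var_e
        return self.var_a / tot if tot > 0 else 0.0


@dataclass
class CatTraitSpec:
    """Fully penetrant single-locus categorical trait.

    ``levels`` are listed in dominance order (first level dominant): the
    displayed phenotype is the more dominant of the two inherited alleles, so
    filter counts are deterministic given the gene drop.
    """

    name: str
    levels: list[str]
    founder_freqs: list[float]
    missing_rate: float | None = None  # overrides SimConfig.missing_rate

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.founder_freqs):
            raise ValueError("levels and founder_freqs must align")
        if abs(sum(self.founder_freqs) - 1.0) > 1e-9:
            raise ValueError("founder level frequencies must sum to 1")


@dataclass
class GenerationPlan:
    n_crosses: int = 0
    n_selfings: int = 0
    n_backcrosses: int = 0


@dataclass
class SimConfig:
    population_name: str = "SYNTH"
    n_founders: int = 12
    plan: list[GenerationPlan] = field(default_factory=lambda: [GenerationPlan(n_crosses=8)])
    traits: list[QuantTraitSpec] = field(default_factory=list)
    categorical_traits: list[CatTraitSpec] = field(default_factory=list)
    missing_rate: float = 0.05
    lg_map: LinkageGroupMap | None = None
    n_intermediates: int = 0  # unreported F1s, each selfed into one named line
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def default_config(seed: int = 0) -> SimConfig:
    """Small germplasm with the rice trait schema and stated heritabilities.

    Heritabilities are 0.50 for yield and 0.85 for maturity period and plant
    height; means and variances are set so simulated values span the ranges
    typical of irrigated indica germplasm (yield ~4-8 mt/ha, maturity ~80-135
    days, height ~48-104 cm).
    """
    return SimConfig(
        population_name="SYNTH_RICE",
        n_founders=12,
        plan=[GenerationPlan(n_crosses=8), GenerationPlan(n_crosses=6, n_selfings=3, n_backcrosses=3)],
        traits=_rice_traits(),
        categorical_traits=_rice_categoricals(),
        missing_rate=0.05,
        lg_map=LinkageGroupMap("LG1", [("RM001", 0.0), ("RM005", 25.0), ("RM009", 50.0)]),
        seed=seed,
    )


def study_scale_config(seed: int = 0) -> SimConfig:
    """Germplasm at the scale of the RRDI breeding database: 224 individuals,
    36 of them unreported intermediates (F1/F2), 188 named cultivars/accessions."""
    return SimConfig(
        population_name="RRDI_SYNTH",
        n_founders=60,
        plan=[
            GenerationPlan(n_crosses=40),
            GenerationPlan(n_crosses=32, n_selfings=10),
            GenerationPlan(n_backcrosses=10),
        ],
        traits=_rice_traits(),
        categorical_traits=_rice_categoricals(),
        missing_rate=0.05,
        lg_map=LinkageGroupMap("LG1", [("RM001", 0.0), ("RM005", 25.0), ("RM009", 50.0)]),
        n_intermediates=36,
        seed=seed,
    )


def _rice_traits() -> list[QuantTraitSpec]:
    return [
        QuantTraitSpec("yield", mu=5.5, var_a=0.40, var_e=0.40, direction="higher-better", units="mt/ha"),
        QuantTraitSpec("maturity_yala", mu=105.0, var_a=161.5, var_e=28.5, direction="lower-better", units="days"),
        QuantTraitSpec("maturity_maha", mu=107.0, var_a=161.5, var_e=28.5, direction="lower-better", units="days"),
        QuantTraitSpec("plant_height", mu=70.0, var_a=122.4, var_e=21.6, direction="lower-better", units="cm"),
    ]


def _rice_categoricals() -> list[CatTraitSpec]:
    return [
        CatTraitSpec("pericarp_color", ["white", "red"], [0.6, 0.4]),
        CatTraitSpec("grain_shape", ["short_round", "intermediate_bold", "long_slender"], [0.3, 0.4, 0.3]),
        CatTraitSpec("bph", ["R", "MR", "S"], [0.15, 0.35, 0.5]),
        CatTraitSpec("blast", ["R", "MR", "S"], [0.15, 0.35, 0.5]),
        CatTraitSpec("amylose", ["high", "high_intermediate", "intermediate", "low"], [0.3, 0.25, 0.25, 0.2]),
        # phosphorus-deficiency tolerance is scored for only a small minority
        CatTraitSpec("pdt", ["high", "moderate", "sensitive"], [0.2, 0.4, 0.4], missing_rate=0.85),
    ]


def _build_pedigree(config: SimConfig, rng: np.random.Generator) -> tuple[list[PedigreeRecord], set[str]]:
    """Pedigree topology: returns (records, intermediate-name set)."""
    records: list[PedigreeRecord] = []
    founders = [f"L{i + 1:03d}" for i in range(config.n_founders)]
    for f in founders:
        records.append(PedigreeRecord(name=f, mother=None, father=None))

    intermediates: set[str] = set()
    serial = 0

    def new_name() -> str:
        nonlocal serial
        serial += 1
        return f"C{serial:03d}"

    # unreported F1 intermediates, each selfed into one named line (RIL-style)
    for i in range(config.n_intermediates):
        m, p = rng.choice(founders, size=2, replace=False)
        xname = f"X{i + 1:03d}"
        intermediates.add(xname)
        records.append(PedigreeRecord(name=xname, mother=str(m), father=str(p)))
        records.append(PedigreeRecord(name=new_name(), mother=xname, father=xname))

    pool = [r.name for r in records if r.name not in intermediates]
    for gen in config.plan:
        created: list[str] = []
        for _ in range(gen.n_crosses):
            m, p = rng.choice(pool, size=2, replace=False)
            name = new_name()
            records.append(PedigreeRecord(name=name, mother=str(m), father=str(p)))
            created.append(name)
        for _ in range(gen.n_selfings):
            m = str(rng.choice(pool))
            name = new_name()
            records.append(PedigreeRecord(name=name, mother=m, father=m))
            created.append(name)
        if gen.n_backcrosses:
            crossed = [r for r in records if r.mother is not None and r.mother != r.father]
            for _ in range(gen.n_backcrosses):
                child = crossed[int(rng.integers(len(crossed)))]
                recurrent = child.mother if rng.random() < 0.5 else child.father
                name = new_name()
                records.append(PedigreeRecord(name=name, mother=child.name, father=str(recurrent)))
                created.append(name)
        pool = pool + created
    return records, intermediates


def simulate(config: SimConfig) -> tuple[PedimapDataset, pd.DataFrame]:
    """Generate a germplasm dataset and its true breeding values.

    Returns ``(dataset, tbv)`` where ``tbv`` is a DataFrame indexed by
    individual with one column per quantitative trait.  The dataset passes
    file validation and round-trips through the pedigree-file dialect.  One
    master seed governs topology, genetics, noise, missingness and markers
    through independent substreams.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_topo, rng_gen, rng_noise, rng_miss, rng_mark = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    records, intermediates = _build_pedigree(config, rng_topo)
    by_name = {r.name: r for r in records}

    # --- quantitative traits: additive infinitesimal model
    tbv = pd.DataFrame(index=[r.name for r in records], dtype=float)
    for spec in config.traits:
        vals: dict[str, float] = {}
        for r in records:
            if r.is_founder:
                vals[r.name] = rng_gen.normal(0.0, np.sqrt(spec.var_a))
            else:
                mid = 0.5 * (vals[r.mother] + vals[r.father])
                vals[r.name] = mid + rng_gen.normal(0.0, np.sqrt(spec.var_a / 2.0))
        tbv[spec.name] = [vals[r.name] for r in records]
        for r in records:
            if r.name in intermediates:
                r.phenotypes[spec.name] = None
            else:
                p = spec.mu + vals[r.name] + rng_noise.normal(0.0, np.sqrt(spec.var_e))
                r.phenotypes[spec.name] = float(p)

    # --- categorical traits: one fully penetrant locus each
    for spec in config.categorical_traits:
        genotype: dict[str, tuple[int, int]] = {}
        for r in records:
            if r.is_founder:
                a = rng_gen.choice(len(spec.levels), size=2, p=spec.founder_freqs)
                genotype[r.name] = (int(a[0]), int(a[1]))
            else:
                gm, gp = genotype[r.mother], genotype[r.father]
                genotype[r.name] = (
                    gm[int(rng_gen.integers(2))],
                    gp[int(rng_gen.integers(2))],
                )
        for r in records:
            if r.name in intermediates:
                r.phenotypes[spec.name] = None
            else:
                r.phenotypes[spec.name] = spec.levels[min(genotype[r.name])]

    # --- sparse missingness over named individuals
    for spec_name, rate in [(t.name, config.missing_rate) for t in config.traits] + [
        (c.name, c.missing_rate if c.missing_rate is not None else config.missing_rate)
        for c in config.categorical_traits
    ]:
        for r in records:
            if r.name in intermediates:
                continue
            if r.phenotypes.get(spec_name) is not None and rng_miss.random() < rate:
                r.phenotypes[spec_name] = None

    # --- marker genotypes via gene drop over the linkage map
    genotypes: list[MarkerGenotype] = []
    maps: list[LinkageGroupMap] = []
    if config.lg_map is not None:
        maps = [config.lg_map]
        graph = build_graph(records)
        index = founder_allele_index(graph)
        pos = np.asarray(config.lg_map.positions, dtype=float)
        dropped = _drop_alleles(graph, pos, n_reps=1, rng=rng_mark, index=index)
        # locus-major order to match the on-disk LOCUS block layout
        for li, (locus, _) in enumerate(config.lg_map.loci):
            for r in records:
                a = dropped[r.name][0]  # (n_pos, 2) founder-allele ids
                codes = [str(100 + 2 * int(a[li, c])) for c in range(2)]
                genotypes.append(MarkerGenotype(individual=r.name, locus=locus, alleles=codes))

    traits = [TraitColumn(t.name, QUANTITATIVE, t.units) for t in config.traits] + [
        TraitColumn(c.name, CATEGORICAL) for c in config.categorical_traits
    ]
    header = HeaderSpec(population_name=config.population_name, ploidy=2)
    dataset = PedimapDataset(header=header, records=records, traits=traits, maps=maps, genotypes=genotypes)
    return dataset, tbv


def tbv_to_tsv(tbv: pd.DataFrame) -> str:
    """Ground-truth sidecar: one row per individual, one column per trait."""
    return tbv.to_csv(sep="\t", index_label="name")


# ---------------------------------------------------------------------------
# deterministic fixtures


def fixture_suite() -> dict:
    """Named deterministic fixtures for tests and examples.

    Returns a dict with datasets under 'trio', 'backcross' and 'germplasm50',
    and a dict of malformed raw texts (each failing one parser error class)
    under 'malformed'.
    """
    trio = PedimapDataset(
        header=HeaderSpec(population_name="TRIO", ploidy=2),
        records=[
            PedigreeRecord("A", None, None, {"yield": 6.0, "pericarp_color": "white"}),
            PedigreeRecord("B", None, None, {"yield": 4.0, "pericarp_color": "red"}),
            PedigreeRecord("F1", "A", "B", {"yield": 5.5, "pericarp_color": None}),
        ],
        traits=[
            TraitColumn("yield", QUANTITATIVE, "mt/ha"),
            TraitColumn("pericarp_color", CATEGORICAL),
        ],
    )

    # phase-1 cross, selfing chain to a RIL, phase-2 backcross to a donor
    backcross = PedimapDataset(
        header=HeaderSpec(population_name="BCSCHEME", ploidy=2),
        records=[
            PedigreeRecord("P1", None, None, {"yield": 7.0}),
            PedigreeRecord("P2", None, None, {"yield": 4.5}),
            PedigreeRecord("DONOR", None, None, {"yield": 4.2}),
            PedigreeRecord("F1", "P1", "P2", {"yield": None}),
            PedigreeRecord("F2", "F1", "F1", {"yield": None}),
            PedigreeRecord("RIL", "F2", "F2", {"yield": 6.1}),
            PedigreeRecord("BC1", "RIL", "DONOR", {"yield": 5.8}),
        ],
        traits=[TraitColumn("yield", QUANTITATIVE, "mt/ha")],
    )

    germplasm50 = simulate(
        SimConfig(
            population_name="G50",
            n_founders=12,
            plan=[
                GenerationPlan(n_crosses=14),
                GenerationPlan(n_crosses=12, n_selfings=6, n_backcrosses=6),
            ],
            traits=_rice_traits(),
            categorical_traits=_rice_categoricals(),
            missing_rate=0.05,
            lg_map=LinkageGroupMap("LG1", [("RM001", 0.0), ("RM005", 25.0), ("RM009", 50.0)]),
            seed=20240601,
        )
    )[0]

    valid_header = (
        "POPULATION\tBAD\nPLOIDY\t2\nUNKNOWN\t-\nPOSSIBLENULL\t?\nCONFIRMEDNULL\t!\n"
    )
    malformed = {
        "missing_header_element": (
            "POPULATION\tBAD\nPLOIDY\t2\nUNKNOWN\t-\n"
            "PEDIGREE\nName\tMother\tFather\nA\t-\t-\n"
        ),
        "duplicate_name": valid_header
        + "PEDIGREE\nName\tMother\tFather\nA\t-\t-\nA\t-\t-\n",
        "undeclared_parent": valid_header
        + "PEDIGREE\nName\tMother\tFather\nA\t-\t-\nK1\tA\tZZZ\n",
        "parentage_cycle": valid_header
        + "PEDIGREE\nName\tMother\tFather\nA\tB\tB\nB\tA\tA\n",
        "allele_count_mismatch": valid_header
        + "PEDIGREE\nName\tMother\tFather\nA\t-\t-\n"
        + "MAP\tLG1\nRM001\t0\nLOCUS\tRM001\nA\t101\t103\t105\n",
        "ibd_row_length": valid_header
        + "NALLELES\t4\n"
        + "PEDIGREE\nName\tMother\tFather\nA\t-\t-\nB\t-\t-\nF1\tA\tB\n"
        + "IBD\tpedigree\t0\nF1\t0.5\t0.5\t0.5\n",
        "nalleles_mismatch": valid_header
        + "NALLELES\t6\n"
        + "PEDIGREE\nName\tMother\tFather\nA\t-\t-\nB\t-\t-\nF1\tA\tB\n"
        + "IBD\tpedigree\t0\nF1\t0.5\t0.5\t0.5\t0.5\t0\t0\n",
    }
    return {
        "trio": trio,
        "backcross": backcross,
        "germplasm50": germplasm50,
        "malformed": malformed,
    }
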
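"""Estimated breeding values (EBV) and competition ranking.

Mass selection on a single phenotypic record gives the EBV as the
heritability-shrunk phenotypic superiority,

    EBV = H^2 (P - Pbar)

with H^2 the (broad-sense) heritability of the trait, P the individual's trait
value and Pbar the population mean.  The theoretical accuracy of such an EBV —
its correlation with the true breeding value — is sqrt(H^2).

Ranking uses competition ("min") ranks in the desirable direction: tied EBVs
share the smallest rank of the tie group and the next distinct value takes
rank 1 + (number of strictly better entries).  Higher yield is desirable;
shorter maturity and lower plant height are desirable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedfile_io import QUANTITATIVE, PedimapDataset

__all__ = [
    "TraitModel",
    "PopulationStats",
    "ebv",
    "recover_population_mean",
    "rank_competition",
    "accuracy",
    "ebv_table",
    "population_stats",
    "HIGHER_BETTER",
    "LOWER_BETTER",
]

HIGHER_BETTER = "higher-better"
LOWER_BETTER = "lower-better"


@dataclass
class TraitModel:
    trait: str
    h2: float  # heritability, in [0, 1]
    direction: str = HIGHER_BETTER

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"heritability must be in [0, 1], got {self.h2}")
        if self.direction not in (HIGHER_BETTER, LOWER_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class PopulationStats:
    means: dict[str, float]  # trait -> mean over non-missing records
    counts: dict[str, int]  # trait -> number of contributing records


def ebv(model: TraitModel, phenotype: float, population_mean: float) -> float:
    """EBV = H^2 (P - Pbar), in the trait's own units."""
    return model.h2 * (phenotype - population_mean)


def recover_population_mean(model: TraitModel, phenotype: float, ebv_value: float) -> float:
    """Invert the EBV formula: Pbar = P - EBV / H^2.

    Lets a published (phenotype, EBV) pair reconstruct the population mean the
    table was computed against.
    """
    if model.h2 <= 0:
        raise ValueError("population mean is unrecoverable when H^2 = 0")
    return phenotype - ebv_value / model.h2


def rank_competition(
    values: list[tuple[str, float]], direction: str = HIGHER_BETTER
) -> dict[str, int]:
    """Competition ranking of (name, value) pairs in the desirable direction.

    Ties share the minimum rank; e.g. values 1.53, 1.03 x 4, 0.98 rank as
    1, 2, 2, 2, 2, 6.
    """
    if not values:
        raise ValueError("values must be non-empty")
    arr = np.array([v for _, v in values], dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    key = -arr if direction == HIGHER_BETTER else arr
    ranks = stats.rankdata(key, method="min").astype(int)
    return {name: int(r) for (name, _), r in zip(values, ranks)}


def accuracy(ebvs: np.ndarray, tbvs: np.ndarray) -> float:
    """Pearson correlation of EBVs with true breeding values.

    Because the EBV is a positive scaling of the centered phenotype, this
    equals the accuracy of the raw phenotype itself.
    """
    ebvs = np.asarray(ebvs, dtype=float)
    tbvs = np.asarray(tbvs, dtype=float)
    if ebvs.shape != tbvs.shape or ebvs.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(ebvs) == 0 or np.std(tbvs) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    return float(np.corrcoef(ebvs, tbvs)[0, 1])


def population_stats(dataset: PedimapDataset, traits: list[str]) -> PopulationStats:
    """Per-trait mean and count over non-missing records."""
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for trait in traits:
        vals = [
            float(r.phenotypes[trait])
            for r in dataset.records
            if r.phenotypes.get(trait) is not None
        ]
        if not vals:
            raise ValueError(f"trait {trait!r} has no non-missing records")
        means[trait] = float(np.mean(vals))
        counts[trait] = len(vals)
    return PopulationStats(means=means, counts=counts)


def ebv_table(
    dataset: PedimapDataset,
    models: list[TraitModel],
    population_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-cultivar EBV and competition rank for each modeled trait.

    Columns: individual, trait, phenotype, population_mean, ebv, rank.
    ``population_means`` overrides the dataset means (the "recovered-mean"
    mode for reproducing a published excerpt); by default means are computed
    over non-missing records.  EBVs are computed and ranked at full precision;
    round only for display.  Individuals missing the trait are omitted from
    that trait's ranking.
    """
    for m in models:
        col = dataset.trait(m.trait)
        if col.kind != QUANTITATIVE:
            raise ValueError(f"trait {m.trait!r} is not quantitative")
    stats_ = population_stats(dataset, [m.trait for m in models])
    rows = []
    for m in models:
        pbar = (population_means or {}).get(m.trait, stats_.means[m.trait])
        pairs = [
            (r.name, float(r.phenotypes[m.trait]))
            for r in dataset.records
            if r.phenotypes.get(m.trait) is not None
        ]
        ebvs = [(name, ebv(m, p, pbar)) for name, p in pairs]
        ranks = rank_competition(ebvs, m.direction)
        for (name, p), (_, e) in zip(pairs, ebvs):
            rows.append(
                {
                    "individual": name,
                    "trait": m.trait,
                    "phenotype": p,
                    "population_mean": pbar,
                    "ebv": e,
                    "rank": ranks[name],
                }
            )
    return pd.DataFrame(rows, columns=["individual", "trait", "phenotype", "population_mean", "ebv", "rank"])
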
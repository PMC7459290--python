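"""Packaged reference data.

``load_reference_breeding_values`` returns the published breeding-value table
for 34 cultivars of the RRDI (Sri Lanka) rice germplasm: per cultivar the mean
phenotype, EBV and germplasm-wide competition rank for yield (mt/ha), maturity
period in the Yala and Maha seasons (days) and plant height (cm).  The EBVs
were published against the full 188-cultivar germplasm, so the table's
maturity/height ranks are not recomputable from the excerpt alone, but the
population mean behind each trait column can be recovered exactly by
inverting EBV = H^2 (P - Pbar) on any row (H^2 = 0.50 for yield, 0.85 for
maturity and height).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .ebv_stats import HIGHER_BETTER, LOWER_BETTER, TraitModel

__all__ = [
    "load_reference_breeding_values",
    "reference_trait_models",
    "example_criteria_path",
    "REFERENCE_TRAITS",
]

# trait key -> (mean column, ebv column, rank column)
REFERENCE_TRAITS = {
    "yield": ("yield_mean", "yield_ebv", "yield_rank"),
    "maturity_yala": ("yala_mean", "yala_ebv", "yala_rank"),
    "maturity_maha": ("maha_mean", "maha_ebv", "maha_rank"),
    "plant_height": ("height_mean", "height_ebv", "height_rank"),
}


def load_reference_breeding_values() -> pd.DataFrame:
    with resources.files("pedbreed.data").joinpath("rrdi_breeding_values.csv").open() as fh:
        return pd.read_csv(fh)


def reference_trait_models() -> list[TraitModel]:
    """The heritabilities and desirable directions used for the reference table."""
    return [
        TraitModel("yield", 0.50, HIGHER_BETTER),
        TraitModel("maturity_yala", 0.85, LOWER_BETTER),
        TraitModel("maturity_maha", 0.85, LOWER_BETTER),
        TraitModel("plant_height", 0.85, LOWER_BETTER),
    ]


def example_criteria_path(name: str) -> Path:
    """Path to a packaged criteria file: 'example1', 'example2' or 'example3'."""
    p = resources.files("pedbreed.data").joinpath(f"criteria/{name}.yaml")
    return Path(str(p))
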
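"""Substance property table.

Pesticide properties (sorption, octanol-water partitioning, soil and water
half-lives) drive both the synthetic wash-off mechanism and the covariates of
the concentration model.  Values for the default substances are rounded
literature values of the kind tabulated in the PPDB (Lewis et al.); they span
fast-degrading (DT50_soil ~ 19 d) to very persistent (> 270 d) compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SubstanceProperties", "default_substances", "substances_to_frame"]


@dataclass(frozen=True)
class SubstanceProperties:
    """Physico-chemical properties of one active ingredient.

    Attributes
    ----------
    name : str
    loq_ng_l : float
        Limit of quantification of the analytical method (ng/L); values
        below it are interval-censored between 0 and the LOQ.
    k_foc : float
        Freundlich sorption coefficient normalised to organic carbon (L/kg).
    log10_kow : float
        Octanol-water partition coefficient, stored on log10 scale.
    dt50_soil_d : float
        Soil half-life in days.
    dt50_water_d : float
        Water (hydrolysis/photolysis aggregate) half-life in days.
    is_transformation_product : bool
    """

    name: str
    loq_ng_l: float = 20.0
    k_foc: float = 100.0
    log10_kow: float = 2.0
    dt50_soil_d: float = 30.0
    dt50_water_d: float = 20.0
    is_transformation_product: bool = False

    def __post_init__(self) -> None:
        if self.loq_ng_l <= 0:
            raise ValueError(f"{self.name}: LOQ must be > 0")
        if self.dt50_soil_d <= 0 or self.dt50_water_d <= 0:
            raise ValueError(f"{self.name}: DT50 values must be > 0")
        if self.k_foc <= 0:
            raise ValueError(f"{self.name}: K_foc must be > 0")


#: Default panel: herbicides/fungicides typical of Swiss arable rotations
#: (grains, potatoes, sugar beet).  Properties are rounded PPDB-style values.
_DEFAULTS = [
    #                   name          LOQ   K_foc  logKow DT50s  DT50w
    SubstanceProperties("metamitron", 20.0, 78.0, 0.85, 19.0, 11.0),
    SubstanceProperties("ethofumesate", 20.0, 147.0, 2.70, 22.0, 20.0),
    SubstanceProperties("terbuthylazine", 20.0, 231.0, 3.40, 72.0, 40.0),
    SubstanceProperties("propamocarb", 20.0, 719.0, 0.84, 39.0, 30.0),
    SubstanceProperties("metribuzin", 20.0, 38.0, 1.65, 19.0, 40.0),
    SubstanceProperties("pencycuron", 20.0, 1570.0, 4.68, 85.0, 50.0),
    SubstanceProperties("epoxiconazole", 20.0, 1073.0, 3.30, 120.0, 60.0),
    SubstanceProperties("bixafen", 20.0, 1292.0, 3.30, 280.0, 100.0),
    SubstanceProperties("prosulfocarb", 20.0, 1693.0, 4.48, 12.0, 15.0),
    SubstanceProperties("fluopicolide", 20.0, 321.0, 2.90, 286.0, 150.0),
    SubstanceProperties("napropamide", 20.0, 839.0, 3.30, 72.0, 30.0),
    SubstanceProperties("diflufenican", 20.0, 3186.0, 4.20, 142.0, 100.0),
]


def default_substances(n: int | None = None) -> list[SubstanceProperties]:
    """Return the default substance panel (optionally the first ``n``)."""
    if n is None:
        return list(_DEFAULTS)
    if n < 1 or n > len(_DEFAULTS):
        raise ValueError(f"n must be in [1, {len(_DEFAULTS)}]")
    return list(_DEFAULTS[:n])


def substances_to_frame(substances: list[SubstanceProperties]) -> pd.DataFrame:
    """Tabulate substances; one row per compound, indexed by name."""
    rows = [
        {
            "name": s.name,
            "loq_ng_l": s.loq_ng_l,
            "k_foc": s.k_foc,
            "log10_kow": s.log10_kow,
            "dt50_soil_d": s.dt50_soil_d,
            "dt50_water_d": s.dt50_water_d,
            "is_transformation_product": s.is_transformation_product,
        }
        for s in substances
    ]
    return pd.DataFrame(rows).set_index("name", drop=False)
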
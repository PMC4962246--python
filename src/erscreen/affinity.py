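"""Tier 2: binding free energy to relative binding affinity.

The quantitative tier maps a docking/MM-GBSA binding free energy
(kcal/mol) for a predicted binder to a log10 relative binding affinity
(logRBA), on the scale where 17beta-estradiol has logRBA = 2, through the
fixed affine model

    logRBA = -7.719 - 0.086 * dG

Docking and the free-energy calculation themselves are upstream of this
package; a compound whose docking failed is simply absent from the energy
map.  Free energies are assumed to be in kcal/mol with the usual sign
convention (more negative = stronger binding), so the negative slope maps
stronger binders to higher affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DEFAULT_INTERCEPT",
    "DEFAULT_SLOPE",
    "ConversionModel",
    "AffinityEstimate",
    "free_energy_to_logrba",
    "batch_convert",
]

DEFAULT_INTERCEPT = -7.719
DEFAULT_SLOPE = -0.086


@dataclass(frozen=True)
class ConversionModel:
    """Affine map from binding free energy (kcal/mol) to logRBA."""

    intercept: float = DEFAULT_INTERCEPT
    slope: float = DEFAULT_SLOPE

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("conversion coefficients must be finite")


@dataclass(frozen=True)
class AffinityEstimate:
    compound_id: str
    free_energy: float
    logrba: float


def free_energy_to_logrba(dg: float, model: ConversionModel = ConversionModel()) -> float:
    """Apply the affine conversion to one binding free energy."""
    if not math.isfinite(dg):
        raise ValueError(f"binding free energy must be finite, got {dg!r}")
    return model.intercept + model.slope * dg


def batch_convert(
    energies: dict[str, float], model: ConversionModel = ConversionModel()
) -> list[AffinityEstimate]:
    """Convert every entry of an id -> free-energy map, preserving order."""
    return [
        AffinityEstimate(
            compound_id=cid,
            free_energy=float(dg),
            logrba=free_energy_to_logrba(float(dg), model),
        )
        for cid, dg in energies.items()
    ]
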
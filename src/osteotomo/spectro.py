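"""X-ray attenuation and simplified bone composition arithmetic.

The attenuation law I/I0 = exp(-(mu/rho) * rho * L) estimates how much of the
generated characteristic X-ray intensity survives a path of length L through
bone; with the tabulated cortical-bone mass attenuation coefficient at 1 keV
(3.781e3 cm^2/g), density 1.8 g/cm^3 and the 700 nm maximum rod diameter,
about 38% of low-energy X-rays are absorbed — a first-order account of the
low EDX signal-to-noise in the thickest sample regions.

The composition helper models bone as 70 wt% mineral (hydroxyapatite, split
between Ca and P at the exact Ca10(PO4)6(OH)2 stoichiometry) and 30 wt%
organic (carbon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "ATOMIC_MASS_CA",
    "ATOMIC_MASS_P",
    "AttenuationParams",
    "CompositionModel",
    "transmitted_fraction",
    "absorbed_fraction",
    "absorption_correct",
    "hydroxyapatite_ca_p",
    "simplified_bone_weights",
    "ca_p_weight_to_atomic",
]

ATOMIC_MASS_CA = 40.078  # g/mol
ATOMIC_MASS_P = 30.974  # g/mol

_NM_PER_CM = 1e7


@dataclass
class AttenuationParams:
    """(mu/rho, rho, L) triple for the attenuation law.

    mass_attenuation in cm^2/g (default: tabulated cortical bone at 1 keV),
    density in g/cm^3, path_length in nm.
    """

    mass_attenuation: float = 3.781e3
    density: float = 1.8
    path_length: float = 700.0

    def validate(self) -> None:
        if self.mass_attenuation < 0 or self.density < 0 or self.path_length < 0:
            raise ValueError("attenuation parameters must be non-negative")


def transmitted_fraction(params: AttenuationParams) -> float:
    """Fraction of X-rays not absorbed: exp(-(mu/rho) * rho * L)."""
    params.validate()
    exponent = params.mass_attenuation * params.density * (params.path_length / _NM_PER_CM)
    return float(np.exp(-exponent))


def absorbed_fraction(params: AttenuationParams) -> float:
    """Fraction of X-rays absorbed along the path: 1 - I/I0."""
    return 1.0 - transmitted_fraction(params)


def absorption_correct(intensity, params: AttenuationParams):
    """First-order absorption correction of a net intensity (divide by the
    transmitted fraction)."""
    t = transmitted_fraction(params)
    if t <= 0:
        raise ValueError("transmitted fraction is zero; cannot correct")
    return intensity / t


def hydroxyapatite_ca_p() -> float:
    """Ca/P atomic ratio of hydroxyapatite, Ca10(PO4)6(OH)2: exactly 10/6
    (1.67 to two decimals)."""
    return 10.0 / 6.0


@dataclass
class CompositionModel:
    """Simplified bone: mineral_weight_fraction of hydroxyapatite (only Ca and
    P retained) plus an organic fraction modelled as carbon."""

    mineral_weight_fraction: float = 0.70
    organic_weight_fraction: float = 0.30
    ca_p_atomic_ratio: float = field(default_factory=hydroxyapatite_ca_p)
    atomic_mass_ca: float = ATOMIC_MASS_CA
    atomic_mass_p: float = ATOMIC_MASS_P

    def validate(self) -> None:
        if not np.isclose(self.mineral_weight_fraction + self.organic_weight_fraction, 1.0):
            raise ValueError("mineral and organic weight fractions must sum to 1")
        if not (0 <= self.mineral_weight_fraction <= 1):
            raise ValueError("mineral_weight_fraction must lie in [0, 1]")
        if self.ca_p_atomic_ratio <= 0:
            raise ValueError("ca_p_atomic_ratio must be positive")


def simplified_bone_weights(model: CompositionModel | None = None) -> Tuple[float, float, float]:
    """(wCa, wP, wC) weight fractions of the simplified bone compound.

    Solves wCa + wP = mineral fraction with wCa/wP fixed by the atomic ratio
    times the atomic-mass ratio; with the defaults this reproduces 47.8 wt% Ca
    and 22.2 wt% P. Using the exact 10/6 stoichiometry matters: the rounded
    ratio 1.67 would give 22.1 wt% P instead.
    """
    if model is None:
        model = CompositionModel()
    model.validate()
    weight_ratio = model.ca_p_atomic_ratio * model.atomic_mass_ca / model.atomic_mass_p
    w_p = model.mineral_weight_fraction / (1.0 + weight_ratio)
    w_ca = model.mineral_weight_fraction - w_p
    return w_ca, w_p, model.organic_weight_fraction


def ca_p_weight_to_atomic(w_ca: float, w_p: float) -> float:
    """Atomic Ca/P ratio from weight fractions (or weight-like intensities)."""
    if w_p == 0:
        raise ZeroDivisionError("wP must be nonzero")
    return (w_ca / ATOMIC_MASS_CA) / (w_p / ATOMIC_MASS_P)
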
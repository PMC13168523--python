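"""Material parameter records.

Unit system (project-wide): lengths µm, moduli Pa, forces pN, spring
stiffness pN/µm.  These are mutually consistent: 1 Pa·µm² = 1 pN, so a
modulus in Pa times an area in µm² is directly a force in pN.

Defaults are the cell-model constants used throughout: a 0.2 µm elastic
membrane (E = 7 kPa, ν = 0.3), soft cytoplasm (0.25 kPa, ν = 0.3), a stiffer
nearly incompressible nucleus (1 kPa, ν = 0.45), and actin filaments treated
as pre-strained trusses (250 kPa, ν = 0.3, cross-section radius 0.25 µm,
20% pre-strain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def _check_elastic(E: float, nu: float, what: str) -> None:
    if E <= 0:
        raise ValueError(f"{what}: Young's modulus must be > 0, got {E}")
    if not 0 <= nu < 0.5:
        raise ValueError(f"{what}: Poisson's ratio must be in [0, 0.5), got {nu}")


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic solid: Young's modulus (Pa), Poisson's ratio."""

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        _check_elastic(self.youngs_modulus, self.poisson_ratio, type(self).__name__)


@dataclass(frozen=True)
class MembraneMaterial(ElasticMaterial):
    """Membrane shell: in-plane elasticity only, with a thickness in µm."""

    thickness: float = 0.2

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.thickness < 0:
            raise ValueError(f"membrane thickness must be >= 0, got {self.thickness}")


@dataclass(frozen=True)
class FiberMaterial:
    """Actin filament truss: axial stiffness E·A with built-in pre-strain.

    ``pre_strain`` is the contractile strain ε₀ carried by every filament;
    it is the sole load of the cell model.
    """

    youngs_modulus: float = 2.5e5
    poisson_ratio: float = 0.3
    cross_section_radius: float = 0.25
    pre_strain: float = 0.2

    def __post_init__(self) -> None:
        _check_elastic(self.youngs_modulus, self.poisson_ratio, "fiber")
        if self.cross_section_radius <= 0:
            raise ValueError("fiber cross_section_radius must be > 0")
        if self.pre_strain < 0:
            raise ValueError("fiber pre_strain must be >= 0")

    @property
    def cross_section_area(self) -> float:
        """π·r², µm²."""
        return math.pi * self.cross_section_radius**2

    @property
    def axial_rigidity(self) -> float:
        """E·A in pN (Pa·µm²)."""
        return self.youngs_modulus * self.cross_section_area


@dataclass(frozen=True)
class MaterialParams:
    """Material set for the four-part cell model."""

    membrane: MembraneMaterial = field(
        default_factory=lambda: MembraneMaterial(7000.0, 0.3, thickness=0.2)
    )
    cytoplasm: ElasticMaterial = field(default_factory=lambda: ElasticMaterial(250.0, 0.3))
    nucleus: ElasticMaterial = field(default_factory=lambda: ElasticMaterial(1000.0, 0.45))
    fiber: FiberMaterial = field(default_factory=FiberMaterial)
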
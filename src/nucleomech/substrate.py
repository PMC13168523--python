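"""Two-spring focal-adhesion / substrate coupling.

Each fiber anchor feels the focal-adhesion spring (stiffness k_a) in series
with an equivalent substrate spring E_s·d/(1 − ν_s²), where E_s and ν_s are
the substrate Young's modulus and Poisson's ratio and d the focal-adhesion
diameter:

    k_eff = ( 1/k_a + (1 − ν_s²)/(E_s·d) )⁻¹

With E_s in Pa and d in µm, E_s·d is directly a stiffness in pN/µm
(1 Pa·µm = 1 pN/µm), matching the project unit system.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SubstrateParams:
    """Two-spring model parameters.

    k_a : focal-adhesion spring stiffness, pN/µm (default 1e5 = 0.1 N/m)
    E_s : substrate Young's modulus, Pa
    nu_s : substrate Poisson's ratio
    d : focal-adhesion diameter, µm
    """

    k_a: float = 1.0e5
    E_s: float = 4.0e4
    nu_s: float = 0.3
    d: float = 2.0

    def __post_init__(self) -> None:
        if self.k_a <= 0:
            raise ValueError(f"k_a must be > 0, got {self.k_a}")
        if self.E_s <= 0:
            raise ValueError(f"E_s must be > 0, got {self.E_s}")
        if not 0.0 <= self.nu_s < 0.5:
            raise ValueError(f"nu_s must be in [0, 0.5), got {self.nu_s}")
        if self.d <= 0:
            raise ValueError(f"d must be > 0, got {self.d}")

    @property
    def substrate_spring(self) -> float:
        """Equivalent substrate spring E_s·d/(1 − ν_s²), pN/µm."""
        return self.E_s * self.d / (1.0 - self.nu_s**2)


def effective_stiffness(params: SubstrateParams) -> float:
    """Series stiffness k_eff of the focal-adhesion + substrate springs, pN/µm.

    Strictly increasing in E_s, k_a and d, and strictly below both series
    members.
    """
    return 1.0 / (1.0 / params.k_a + 1.0 / params.substrate_spring)
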
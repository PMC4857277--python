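"""Neo-Hookean material parameters for the plaque components.

Each component is nearly incompressible neo-Hookean with strain energy

    W = C10 (I1_bar - 3) + (K / 2) (J - 1)^2

where the shear modulus is G = 2 C10 and the bulk modulus K = 1 / D1.  The
soft compressible buffer ring restrains rigid-body motion without loading the
vessel wall.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import FEError

#: 1 mmHg in kPa (101.325 kPa / 760 mmHg).
MMHG_TO_KPA = 101.325 / 760.0


@dataclass(frozen=True)
class MaterialSpec:
    name: str
    E: float  # kPa, small-strain Young's modulus
    nu: float
    C10: float  # kPa
    D1: float  # 1/kPa

    def __post_init__(self):
        if self.C10 <= 0 or self.D1 <= 0:
            raise FEError("C10 and D1 must be positive")

    @property
    def shear_modulus(self) -> float:
        return 2.0 * self.C10

    @property
    def bulk_modulus(self) -> float:
        return 1.0 / self.D1


def neo_hookean_from_linear(
    E: float, incompressible: bool = True, nu: float = 0.5
) -> tuple[float, float]:
    """(C10, D1) from a small-strain modulus.

    Incompressible convention: G = E/3 so C10 = E/6, with D1 left to the
    component table (a tiny penalty value).  Compressible: C10 = E/(4(1+nu)),
    D1 = 3(1-2nu)/E.
    """
    if E <= 0:
        raise FEError("E must be positive")
    if incompressible:
        return E / 6.0, 1e-5
    if nu >= 0.5:
        raise FEError("compressible conversion needs nu < 0.5")
    return E / (4.0 * (1.0 + nu)), 3.0 * (1.0 - 2.0 * nu) / E


#: Component table: intima, media+adventitia (pooled), NC, and the buffer.
DEFAULT_MATERIALS = {
    "intima": MaterialSpec("intima", 1000.0, 0.498, 166.7, 1e-5),
    "media_adventitia": MaterialSpec("media_adventitia", 1500.0, 0.498, 250.0, 1e-5),
    "nc": MaterialSpec("nc", 6.0, 0.498, 1.0, 1e-5),
    "buffer": MaterialSpec("buffer", 60.0, 0.45, 10.0, 0.02),
}
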
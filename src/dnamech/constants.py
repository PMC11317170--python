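"""Physical constants and unit conventions.

Canonical units throughout the package:

========================  =========
quantity                  unit
========================  =========
extension, contour length  μm
force                      pN
persistence length, Δx     nm
thermal energy kBT         pN·nm
ligand concentration       nM (interface), M inside isotherms
rates                      1/s; bimolecular 1/(nM·s)
========================  =========

All cross-unit conversions live here so that no module hard-codes a
factor of 1000.
"""

from dataclasses import dataclass

#: Thermal energy kB*T at 298.15 K (25 degC) in pN*nm.
KBT_ROOM_PN_NM = 4.114

#: nm per μm.
NM_PER_UM = 1000.0

#: M per nM.
M_PER_NM = 1e-9

#: Number of base pairs of full-length λ-phage dsDNA.
LAMBDA_PHAGE_BP = 48502

#: B-form contour length of λ-phage dsDNA in μm.
LAMBDA_CONTOUR_UM = 16.37


@dataclass(frozen=True)
class ThermalConstants:
    """Thermal energy bundle used by every force-dependent model.

    Parameters
    ----------
    kbt : float
        Product kB*T in pN*nm.  Default corresponds to 25 degC.
    """

    kbt: float = KBT_ROOM_PN_NM

    def __post_init__(self):
        if not self.kbt > 0:
            raise ValueError(f"kBT must be positive, got {self.kbt}")


def um_to_nm(x):
    return x * NM_PER_UM


def nm_to_um(x):
    return x / NM_PER_UM


def nM_to_M(c):
    return c * M_PER_NM
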
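"""In vitro-in vivo extrapolation of hepatic clearance.

Two steps:

1. Physiological scaling of the microsomal intrinsic clearance,

       Clint [mL/min/kg] = Clint,in vitro [mL/min/mg]
                           x mppgl [mg protein / g liver]
                           x liver mass [g liver / kg body weight]

2. The well-stirred liver model,

       Cl_H = Q * Clint / (Q + Clint),

   with Q the hepatic blood flow (mL/min/kg).  This is the verbatim printed
   form without unbound-fraction or blood/plasma correction; the extended
   variant Cl_H = Q * fu_b * Clint / (Q + fu_b * Clint) with
   fu_b = fup / Rbp is available through the optional arguments for
   consistency checks against the PBPK simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .physiology import SpeciesPhysiology, get_physiology

__all__ = ["ClearanceSet", "scale_clint", "well_stirred_clh", "ivive_clearances"]


@dataclass(frozen=True)
class ClearanceSet:
    """Clearances along the IVIVE chain for one species."""

    species: str
    clint_in_vitro: float  # mL/min/mg
    clint_in_vivo: float  # mL/min/kg
    cl_hepatic: float  # mL/min/kg
    extraction_ratio: float  # Cl_H / Q, dimensionless

    def __post_init__(self) -> None:
        for v, label in [
            (self.clint_in_vitro, "clint_in_vitro"),
            (self.clint_in_vivo, "clint_in_vivo"),
            (self.cl_hepatic, "cl_hepatic"),
        ]:
            if v < 0:
                raise DomainError(f"{label} must be >= 0")


def scale_clint(clint_in_vitro: float, physiology: SpeciesPhysiology) -> float:
    """Scale microsomal Clint (mL/min/mg) to whole-body Clint (mL/min/kg)."""
    if clint_in_vitro < 0:
        raise DomainError("clint_in_vitro must be >= 0")
    return clint_in_vitro * physiology.mppgl * physiology.liver_mass


def well_stirred_clh(
    q: float,
    clint_in_vivo: float,
    fup: float | None = None,
    rbp: float | None = None,
) -> tuple[float, float]:
    """Hepatic clearance from the well-stirred liver model.

    Parameters
    ----------
    q : float
        Hepatic blood flow, mL/min/kg (> 0).
    clint_in_vivo : float
        Scaled intrinsic clearance, mL/min/kg (>= 0).
    fup, rbp : float, optional
        Supplying both switches to the extended unbound-corrected form with
        fu_b = fup / rbp.  Default is the plain form.

    Returns
    -------
    (cl_hepatic, extraction_ratio)
    """
    if not q > 0:
        raise DomainError("hepatic blood flow Q must be > 0")
    if clint_in_vivo < 0:
        raise DomainError("clint_in_vivo must be >= 0")
    if (fup is None) != (rbp is None):
        raise DomainError("fup and rbp must be supplied together")
    eff = clint_in_vivo if fup is None else (fup / rbp) * clint_in_vivo
    clh = q * eff / (q + eff)
    return clh, clh / q


def ivive_clearances(
    species: str,
    clint_in_vitro: float,
    physiology: SpeciesPhysiology | None = None,
) -> ClearanceSet:
    """Full IVIVE chain: in vitro Clint -> scaled Clint -> well-stirred Cl_H."""
    phys = physiology if physiology is not None else get_physiology(species)
    clint_vivo = scale_clint(clint_in_vitro, phys)
    clh, er = well_stirred_clh(phys.hepatic_blood_flow, clint_vivo)
    return ClearanceSet(
        species=phys.species,
        clint_in_vitro=clint_in_vitro,
        clint_in_vivo=clint_vivo,
        cl_hepatic=clh,
        extraction_ratio=er,
    )
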
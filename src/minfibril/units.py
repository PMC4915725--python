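"""Unit system of the mesoscale model.

Internal units follow the LAMMPS ``real`` convention used throughout the
model: length in Å, energy in kcal·mol⁻¹, mass in amu, time in fs.  Derived
quantities therefore come out in kcal·mol⁻¹·Å⁻¹ (force) and
kcal·mol⁻¹·Å⁻³ (stress), which are converted once, through the constants
below, to pN and GPa for reporting.

The anchor constant is the force conversion 1 kcal·mol⁻¹·Å⁻¹ = 69.479 pN.
Every stress in GPa flows through the single factor
``STRESS_GPA = 6.9479`` GPa per kcal·mol⁻¹·Å⁻³, which is the same constant
divided by Å² (69.479 pN/Å² = 6.9479 GPa).
"""

from __future__ import annotations

from dataclasses import dataclass

#: pN per kcal·mol⁻¹·Å⁻¹ (reference constant; exact within the model).
FORCE_PN: float = 69.479

#: GPa per kcal·mol⁻¹·Å⁻³.  Derived from FORCE_PN: 69.479 pN/Å².
STRESS_GPA: float = 6.9479

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB: float = 1.987204259e-3

#: Acceleration conversion: (kcal·mol⁻¹·Å⁻¹)/amu → Å·fs⁻².
#: 4184 J kcal⁻¹ / N_A / (1e-10 m) / (1 amu) expressed in Å fs⁻².
ACC_CONV: float = 4.184e-4

#: Å per nm.
NM: float = 10.0

#: Displacement-rate conversion: 1 m·s⁻¹ = 1e-5 Å·fs⁻¹.
MPS_TO_APFS: float = 1.0e-5


def force_to_pN(f: float) -> float:
    """Convert a force from kcal·mol⁻¹·Å⁻¹ to pN."""
    return f * FORCE_PN


def pN_to_force(f_pn: float) -> float:
    """Convert a force from pN back to kcal·mol⁻¹·Å⁻¹."""
    return f_pn / FORCE_PN


def stress_to_GPa(s: float) -> float:
    """Convert a stress from kcal·mol⁻¹·Å⁻³ to GPa."""
    return s * STRESS_GPA


def GPa_to_stress(s_gpa: float) -> float:
    """Convert a stress from GPa back to kcal·mol⁻¹·Å⁻³."""
    return s_gpa / STRESS_GPA


def nm_to_A(x: float) -> float:
    return x * NM


def A_to_nm(x: float) -> float:
    return x / NM


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the model's base and derived units (informational)."""

    length: str = "angstrom"
    energy: str = "kcal/mol"
    mass: str = "amu"
    time: str = "fs"
    force: str = "kcal/mol/angstrom"
    stress: str = "GPa"
    force_to_pN: float = FORCE_PN
    stress_to_GPa: float = STRESS_GPA


UNITS = UnitSystem()
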
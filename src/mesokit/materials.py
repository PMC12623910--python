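"""Reference material constants for the itraconazole study system.

Itraconazole (ITZ) is a rod-like triazole antifungal that forms smectic
liquid-crystalline phases on vitrification or solvent evaporation.  The
chlorinated solvents used to prepare solvent-evaporated ITZ are listed with
their room-temperature ITZ mole-fraction solubilities and boiling points,
since solvent choice (via solubility and evaporation rate) controls the
degree of lamellar order in the product.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import Composition, parse_formula

__all__ = ["ITZ_FORMULA", "itz_composition", "Solvent", "SOLVENTS", "solubility_ratio"]

#: Molecular formula of itraconazole (molar mass 705.64 g/mol).
ITZ_FORMULA = "C35H38Cl2N8O4"


def itz_composition() -> Composition:
    """Atomic composition of itraconazole."""
    return parse_formula(ITZ_FORMULA)


@dataclass(frozen=True)
class Solvent:
    name: str
    formula: str
    boiling_point_K: float
    #: room-temperature mole-fraction solubility of ITZ in the solvent (mol/mol)
    itz_mole_fraction_solubility: float


SOLVENTS = {
    "DCM": Solvent("dichloromethane", "CH2Cl2", 313.0, 3.27e-2),
    "CLF": Solvent("chloroform", "CHCl3", 334.0, 5.04e-2),
}


def solubility_ratio(solvent_a: str, solvent_b: str) -> float:
    """Ratio of ITZ mole-fraction solubilities between two solvents."""
    a = SOLVENTS[solvent_a].itz_mole_fraction_solubility
    b = SOLVENTS[solvent_b].itz_mole_fraction_solubility
    return a / b
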
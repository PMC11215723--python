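"""Equilibrium 1:1 binding thermodynamics.

The bound-complex concentration sets the thermal-equilibrium intensity of
the saturated bound protein protons in the reduced matrix, so the only
thermodynamic input the method needs is the solution of the 1:1 binding
quadratic from total concentrations and Kd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BindingState:
    """Species concentrations (uM) at equilibrium for 1:1 binding."""

    protein_total: float
    ligand_total: float
    kd: float
    complex_conc: float
    free_protein: float
    free_ligand: float

    @property
    def bound_fraction_ligand(self) -> float:
        return self.complex_conc / self.ligand_total


def solve_binding(protein_total: float, ligand_total: float, kd: float) -> BindingState:
    """Solve P + L <-> PL for the complex concentration.

    All quantities in uM.  The physical root of the quadratic
    ``[PL]^2 - (P + L + Kd)[PL] + P*L = 0`` is

        [PL] = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / 2

    evaluated in a cancellation-safe form.
    """
    if not (protein_total > 0 and ligand_total > 0 and kd > 0):
        raise ValueError("protein_total, ligand_total and kd must all be positive")
    s = protein_total + ligand_total + kd
    disc = math.sqrt(s * s - 4.0 * protein_total * ligand_total)
    # (s - disc)/2 loses precision when Kd >> P,L; use the conjugate form
    complex_conc = 2.0 * protein_total * ligand_total / (s + disc)
    complex_conc = min(complex_conc, protein_total, ligand_total)
    return BindingState(
        protein_total=protein_total,
        ligand_total=ligand_total,
        kd=kd,
        complex_conc=complex_conc,
        free_protein=protein_total - complex_conc,
        free_ligand=ligand_total - complex_conc,
    )
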
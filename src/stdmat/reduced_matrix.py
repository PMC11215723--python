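"""Reduced relaxation matrix M and calculated STD0 initial slopes.

The reduced matrix bypasses the full build-up simulation: because every
non-saturated spin sits at thermal equilibrium at t = 0, the initial slope
of each ligand proton's STD build-up is governed entirely by its direct
cross-relaxation with the clamped (saturated) protein protons.  M therefore
stacks three row-blocks, each a cross-relaxation block into the saturated
set scaled by that set's thermal-equilibrium intensity:

    free-protein rows   R_E1E2   . I_E2,0    (intensity ~ [P]free)
    bound-ligand rows   R_L'E2'  . I_E2',0   (intensity ~ [PL])
    bound-protein rows  R_E1'E2' . I_E2',0

Only the bound-ligand rows produce the epitope; the others are assembled
for completeness and oracle cross-checks.  The calculated initial slope of
ligand proton k is the negated row sum of its L' row divided by the
observed ligand equilibrium intensity (~ [L]total), so STD0 is a rate
(s^-1), positive in the slow-tumbling (sigma < 0) regime, and scales
linearly with the complex concentration.  Epitopes are reported relative to
the largest slope (= 100 %); indirect, protein-relayed saturation is
second-order in time and absent from the initial slope by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stdmat.binding_thermo import BindingState
from stdmat.relaxation_core import RelaxationParams, build_block
from stdmat.spin_system import Proton, SpinSystem


@dataclass
class ReducedM:
    """Row-blocks of the reduced matrix for one spin system."""

    system: SpinSystem
    binding: BindingState
    params: RelaxationParams
    ligand_block: np.ndarray       # (n_L, n_sat): R_L'E2' * I_E2'0
    free_protein_block: np.ndarray  # (n_E1, n_sat): R_E1E2 * I_E20
    bound_protein_block: np.ndarray  # (n_E1, n_sat): R_E1'E2' * I_E2'0


@dataclass
class CalculatedEpitope:
    """Per-ligand-proton calculated initial slopes.

    ``absolute`` is in s^-1 on the observed-ligand intensity scale (global
    scale arbitrary for epitope purposes); ``relative`` is normalized so the
    maximum is exactly 100.
    """

    keys: list[str]
    absolute: np.ndarray
    protons: list[Proton] = field(default_factory=list)

    @property
    def relative(self) -> np.ndarray:
        peak = np.max(self.absolute)
        if peak <= 0:
            raise ValueError("no saturation pathway: all calculated STD0 <= 0")
        return 100.0 * self.absolute / peak

    def as_dict(self, exclude_exchangeable: bool = True) -> dict[str, float]:
        """Relative epitope keyed for comparison with experiment.

        Exchangeable (OH/NH) ligand protons are dropped by default: their
        experimental STD0 is unreliable in H2O.  A proton with an explicit
        ``epitope_key`` is always kept.
        """
        rel = self.relative
        out: dict[str, float] = {}
        for i, key in enumerate(self.keys):
            if exclude_exchangeable and self.protons:
                p = self.protons[i]
                if p.exchangeable and p.epitope_key is None:
                    continue
            out[key] = float(rel[i])
        return out


def assemble_M(
    system: SpinSystem, params: RelaxationParams, binding: BindingState
) -> ReducedM:
    """Assemble the reduced matrix from a pruned spin system.

    Bound-state blocks use the bound correlation time; thermal-equilibrium
    intensities are proportional to species concentrations (complex for the
    bound blocks, free protein for the free block; identical free/bound
    protein geometry is assumed).
    """
    if not system.scorable:
        raise ValueError(
            "system is un-scorable: needs >=1 ligand and >=1 saturated "
            "protein proton after pruning"
        )
    lig, sat, uns = system.ligand, system.saturated, system.unsaturated
    lx, sx = system.coords(lig), system.coords(sat)
    sat_mids = [p.methyl_id for p in sat]

    sigma_ls = build_block(
        lx, sx, params, methyl_ids_b=sat_mids
    )
    if uns:
        ux = system.coords(uns)
        uns_mids = [p.methyl_id for p in uns]
        sigma_es = build_block(
            ux, sx, params, methyl_ids_a=uns_mids, methyl_ids_b=sat_mids
        )
    else:
        sigma_es = np.zeros((0, len(sat)))

    i_bound = binding.complex_conc
    i_free = binding.free_protein
    return ReducedM(
        system=system,
        binding=binding,
        params=params,
        ligand_block=sigma_ls * i_bound,
        free_protein_block=sigma_es * i_free,
        bound_protein_block=sigma_es * i_bound,
    )


def std0_calc(m: ReducedM) -> CalculatedEpitope:
    """Calculated initial slopes STD0 for every ligand proton.

    STD0_k = -(sum_j sigma_kj * I_E2'0,j) / I_L0,k with the observed ligand
    intensity I_L0 ~ [L]total (free + bound pools are both detected).  The
    sign makes STD0 positive when saturation is transferred (sigma < 0).
    """
    if m.ligand_block.size == 0 or not np.any(m.ligand_block):
        raise ValueError("no saturation pathway: ligand block of M is all zero")
    std0 = -np.sum(m.ligand_block, axis=1) / m.binding.ligand_total
    ligand = m.system.ligand
    return CalculatedEpitope(
        keys=[p.key for p in ligand], absolute=std0, protons=list(ligand)
    )


def aggregate_by_key(
    epitope: CalculatedEpitope, keys: dict[str, str] | None = None
) -> CalculatedEpitope:
    """Merge degenerate protons (methyls, equivalent pairs) into one entry.

    ``keys`` maps proton atom names to epitope keys; protons sharing a key
    are averaged (arithmetic mean of absolute STD0 before renormalization).
    With ``keys=None`` the protons' own epitope keys are used.
    """
    if keys is not None:
        unmatched = [k for k in keys if k not in epitope.keys]
        if unmatched:
            raise KeyError(f"aggregation keys match no proton: {unmatched}")
        new_keys = [keys.get(k, k) for k in epitope.keys]
    else:
        new_keys = list(epitope.keys)

    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(new_keys):
        if k not in groups:
            order.append(k)
        groups.setdefault(k, []).append(i)

    absolute = np.array(
        [np.mean(epitope.absolute[groups[k]]) for k in order]
    )
    protons = []
    if epitope.protons:
        from dataclasses import replace

        for k in order:
            rep = epitope.protons[groups[k][0]]
            exch = all(epitope.protons[i].exchangeable for i in groups[k])
            protons.append(replace(rep, epitope_key=k, exchangeable=exch))
    return CalculatedEpitope(keys=order, absolute=absolute, protons=protons)
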
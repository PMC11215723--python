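"""Proton-level representation of a protein-ligand complex.

In an STD NMR experiment the protein protons are split into those directly
hit by the saturation pulse (here ``SATURATED_PROTEIN``) and the remainder
(``UNSATURATED_PROTEIN``); the bound-ligand protons (``LIGAND``) receive
saturation through dipolar cross-relaxation.  This module builds that
partition from a pair of PDB files (protein + ligand, hydrogens already
present), applies the methyl-saturation rule, and prunes protein protons
beyond a cutoff distance from the ligand.

Inputs must be protonated upstream: no hydrogens are ever added here.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from scipy.spatial.distance import cdist


class Group(enum.Enum):
    """Spin-system role of a proton."""

    LIGAND = "ligand"
    SATURATED_PROTEIN = "saturated_protein"
    UNSATURATED_PROTEIN = "unsaturated_protein"


# CH3 hydrogen names per residue (AMBER / PDB v3 conventions).  THR HG1 is a
# hydroxyl proton and deliberately absent: "methyl" means CH3 only.
METHYL_HYDROGENS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"HB1", "HB2", "HB3"}),
    "VAL": frozenset({"HG11", "HG12", "HG13", "HG21", "HG22", "HG23"}),
    "LEU": frozenset({"HD11", "HD12", "HD13", "HD21", "HD22", "HD23"}),
    "ILE": frozenset({"HG21", "HG22", "HG23", "HD11", "HD12", "HD13"}),
    "THR": frozenset({"HG21", "HG22", "HG23"}),
    "MET": frozenset({"HE1", "HE2", "HE3"}),
    "ACE": frozenset({"HH31", "HH32", "HH33", "H1", "H2", "H3"}),
    "NME": frozenset({"HH31", "HH32", "HH33"}),
}

#: Heavy-atom elements whose attached protons exchange with water (OH/NH).
_EXCHANGEABLE_PARENTS = {"O", "N", "S"}
#: Maximum covalent H-X bond length used to find a proton's parent atom, in A.
_BOND_CUTOFF = 1.25


@dataclass(frozen=True)
class Proton:
    """A single 1H spin with its structural context."""

    atom_name: str
    residue_name: str
    residue_id: int
    coords: np.ndarray  # shape (3,), Angstrom
    group: Group
    methyl_id: str | None = None
    epitope_key: str | None = None
    exchangeable: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(
                f"proton {self.residue_name}{self.residue_id}:{self.atom_name} "
                "has non-finite or malformed coordinates"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def key(self) -> str:
        """Epitope key: explicit if set, else the atom name."""
        return self.epitope_key if self.epitope_key is not None else self.atom_name

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.residue_id}:{self.atom_name}"


@dataclass
class SpinSystem:
    """Ordered collection of protons for one structure/model/frame."""

    protons: list[Proton]
    source_label: str = ""

    def __post_init__(self) -> None:
        methyl_counts: dict[str, int] = {}
        for p in self.protons:
            if p.methyl_id is not None:
                methyl_counts[p.methyl_id] = methyl_counts.get(p.methyl_id, 0) + 1
        bad = {m: n for m, n in methyl_counts.items() if n != 3}
        if bad:
            raise ValueError(f"methyl groups without exactly 3 protons: {bad}")

    def _group(self, group: Group) -> list[Proton]:
        return [p for p in self.protons if p.group is group]

    @property
    def ligand(self) -> list[Proton]:
        return self._group(Group.LIGAND)

    @property
    def saturated(self) -> list[Proton]:
        return self._group(Group.SATURATED_PROTEIN)

    @property
    def unsaturated(self) -> list[Proton]:
        return self._group(Group.UNSATURATED_PROTEIN)

    @property
    def scorable(self) -> bool:
        """True when an STD0 prediction is defined for this system."""
        return len(self.ligand) >= 1 and len(self.saturated) >= 1

    def coords(self, protons: Sequence[Proton] | None = None) -> np.ndarray:
        ps = self.protons if protons is None else protons
        if not ps:
            return np.empty((0, 3))
        return np.vstack([p.coords for p in ps])

    def __len__(self) -> int:
        return len(self.protons)


def _is_hydrogen(element: str, name: str) -> bool:
    if element:
        return element.strip().upper() == "H"
    stripped = name.strip().lstrip("0123456789")
    return stripped.startswith("H")


def _parse_structure(source, label: str):
    """Parse PDB from a path or text; strict mode so bad records raise."""
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        if isinstance(source, (str, PathLike)) and Path(source).exists():
            return parser.get_structure(label, source)
        if isinstance(source, str):
            return parser.get_structure(label, io.StringIO(source))
        return parser.get_structure(label, source)
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"unparseable PDB record in {label}: {exc}") from exc


def _methyl_id(residue_name: str, residue_id: int, atom_name: str) -> str | None:
    names = METHYL_HYDROGENS.get(residue_name)
    if names is None or atom_name not in names:
        return None
    # group label strips the final digit: VAL HG11/HG12/HG13 -> HG1
    return f"{residue_name}{residue_id}:{atom_name[:-1]}"


def _extract_atoms(model) -> tuple[list[tuple[str, str, int, np.ndarray]], list[tuple[str, np.ndarray]]]:
    """Split a Bio.PDB model into hydrogen records and heavy-atom records."""
    hydrogens = []
    heavies = []
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            resid = residue.get_id()[1]
            for atom in residue:
                name = atom.get_name().strip()
                if _is_hydrogen(atom.element or "", atom.get_fullname()):
                    hydrogens.append((name, resname, resid, atom.coord.astype(float)))
                else:
                    heavies.append((atom.element or "", atom.coord.astype(float)))
    return hydrogens, heavies


def _exchangeable_flags(
    hydrogens: list[tuple[str, str, int, np.ndarray]],
    heavies: list[tuple[str, np.ndarray]],
) -> list[bool]:
    """A proton is exchangeable when its nearest bonded heavy atom is O/N/S."""
    if not hydrogens or not heavies:
        return [False] * len(hydrogens)
    hxyz = np.vstack([h[3] for h in hydrogens])
    qxyz = np.vstack([q[1] for q in heavies])
    elements = [q[0].strip().upper() for q in heavies]
    dist = cdist(hxyz, qxyz)
    nearest = np.argmin(dist, axis=1)
    flags = []
    for i, j in enumerate(nearest):
        flags.append(dist[i, j] <= _BOND_CUTOFF and elements[j] in _EXCHANGEABLE_PARENTS)
    return flags


def _sanitize_methyls(protons: list[Proton]) -> list[Proton]:
    """Drop methyl labels that do not cover exactly 3 protons (missing H)."""
    counts: dict[str, int] = {}
    for p in protons:
        if p.methyl_id:
            counts[p.methyl_id] = counts.get(p.methyl_id, 0) + 1
    return [
        replace(p, methyl_id=None) if p.methyl_id and counts[p.methyl_id] != 3 else p
        for p in protons
    ]


def parse_complex(
    protein_structure,
    ligand_structure,
    model_index: int = 0,
    source_label: str | None = None,
) -> SpinSystem:
    """Build a :class:`SpinSystem` from a protein PDB and a ligand PDB.

    Parameters
    ----------
    protein_structure, ligand_structure
        Path to a PDB file, or PDB text.  Every atom of the ligand file is
        ligand (two-file input makes identity explicit; no HETATM
        heuristics).  Both files must already contain hydrogens.
    model_index
        0-based index into the ligand file's MODEL blocks (docking poses).
        The protein always uses its first model.

    Protein protons start as ``UNSATURATED_PROTEIN``; use
    :func:`select_saturated` to tag the irradiated set.  Heavy atoms are
    used only to flag exchangeable (OH/NH/SH) protons, then discarded.
    """
    protein = _parse_structure(protein_structure, "protein")
    ligand = _parse_structure(ligand_structure, "ligand")

    ligand_models = list(ligand)
    if not 0 <= model_index < len(ligand_models):
        raise IndexError(
            f"ligand model_index {model_index} out of range: "
            f"file has {len(ligand_models)} model(s)"
        )

    prot_h, prot_heavy = _extract_atoms(next(iter(protein)))
    lig_h, lig_heavy = _extract_atoms(ligand_models[model_index])

    if not prot_h:
        raise ValueError(
            "protein file contains no hydrogen atoms; protonate the structure "
            "upstream (e.g. reduce, pdb2pqr, tleap) before calling stdmat"
        )
    if not lig_h:
        raise ValueError(
            "ligand file contains no hydrogen atoms; protonate the structure "
            "upstream before calling stdmat"
        )

    protons: list[Proton] = []
    for (name, resname, resid, xyz), exch in zip(
        lig_h, _exchangeable_flags(lig_h, lig_heavy)
    ):
        protons.append(
            Proton(name, resname, resid, xyz, Group.LIGAND, exchangeable=exch)
        )
    for (name, resname, resid, xyz), exch in zip(
        prot_h, _exchangeable_flags(prot_h, prot_heavy)
    ):
        protons.append(
            Proton(
                name,
                resname,
                resid,
                xyz,
                Group.UNSATURATED_PROTEIN,
                methyl_id=_methyl_id(resname, resid, name),
                exchangeable=exch,
            )
        )

    if source_label is None:
        source_label = f"model {model_index}"
    return SpinSystem(_sanitize_methyls(protons), source_label=source_label)


def select_saturated(
    system: SpinSystem,
    selection: str | Iterable[tuple[int, str] | str] = "methyls",
) -> SpinSystem:
    """Re-tag the directly irradiated protein protons.

    ``selection`` is either the built-in ``"methyls"`` rule (all CH3 protons
    of ALA/VAL/LEU/ILE/THR/MET and the ACE/NME caps) or an explicit list of
    ``(residue_id, atom_name)`` pairs / ``"resid:atomname"`` strings.
    Ligand protons are never touched.  Returns a new system.
    """
    if isinstance(selection, str) and selection == "methyls":
        def is_saturated(p: Proton) -> bool:
            return p.methyl_id is not None
        unmatched: list[str] = []
    else:
        wanted: set[tuple[int, str]] = set()
        for item in selection:  # type: ignore[union-attr]
            if isinstance(item, str):
                resid_s, _, name = item.partition(":")
                wanted.add((int(resid_s), name.strip()))
            else:
                wanted.add((int(item[0]), item[1]))
        available = {
            (p.residue_id, p.atom_name)
            for p in system.protons
            if p.group is not Group.LIGAND
        }
        missing = wanted - available
        if missing:
            raise ValueError(
                "saturation list names protein protons absent from the "
                f"structure: {sorted(missing)}"
            )

        def is_saturated(p: Proton) -> bool:
            return (p.residue_id, p.atom_name) in wanted

    protons = []
    for p in system.protons:
        if p.group is Group.LIGAND:
            protons.append(p)
        elif is_saturated(p):
            protons.append(replace(p, group=Group.SATURATED_PROTEIN))
        else:
            protons.append(replace(p, group=Group.UNSATURATED_PROTEIN))
    return SpinSystem(protons, source_label=system.source_label)


def apply_cutoff(system: SpinSystem, cutoff: float) -> SpinSystem:
    """Drop protein protons farther than ``cutoff`` (A) from every ligand proton.

    The test is on the minimum proton-proton distance; protons exactly at the
    cutoff are kept.  Ligand protons are never removed.  Idempotent, and
    monotone in ``cutoff``.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    ligand = system.ligand
    if not ligand or not np.isfinite(cutoff):
        return SpinSystem(list(system.protons), source_label=system.source_label)

    lig_xyz = system.coords(ligand)
    kept: list[Proton] = []
    for p in system.protons:
        if p.group is Group.LIGAND:
            kept.append(p)
            continue
        if np.min(np.linalg.norm(lig_xyz - p.coords, axis=1)) <= cutoff:
            kept.append(p)

    # pruning can orphan methyl groups; drop the group label rather than the spin
    counts: dict[str, int] = {}
    for p in kept:
        if p.methyl_id:
            counts[p.methyl_id] = counts.get(p.methyl_id, 0) + 1
    fixed = [
        replace(p, methyl_id=None)
        if p.methyl_id and counts[p.methyl_id] != 3
        else p
        for p in kept
    ]
    return SpinSystem(fixed, source_label=system.source_label)
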
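"""Frame-by-frame reduced-matrix scoring of MD trajectories.

Each kept frame is converted to a spin system, the saturated set and the
distance cutoff are re-applied (binding-pocket composition may change along
the trajectory), the reduced-matrix epitope is computed and scored against
the experimental epitope with the NOE R-factor.  Frames where no saturated
protein proton survives the cutoff have no defined STD0 and are flagged
dissociated instead of scored.

Input coordinates are used as stored: frames must be pre-imaged (ligand and
protein in the same periodic image).  Topology/trajectory reading goes
through MDAnalysis, so AMBER prmtop + NetCDF/DCD work as well as the
multi-model PDB files the fixture generator writes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import MDAnalysis as mda
from MDAnalysis.analysis.align import rotation_matrix

from stdmat.binding_thermo import BindingState
from stdmat.epitope_scoring import Epitope, noe_r_factor
from stdmat.reduced_matrix import aggregate_by_key, assemble_M, std0_calc
from stdmat.relaxation_core import RelaxationParams
from stdmat.spin_system import (
    Group,
    Proton,
    SpinSystem,
    _exchangeable_flags,
    _methyl_id,
    _sanitize_methyls,
    apply_cutoff,
    select_saturated,
)


@dataclass
class FrameScore:
    index: int
    time_ns: float
    dissociated: bool
    r_factor: float | None = None
    epitope: dict | None = None
    ligand_rmsd: float | None = None

    @property
    def scored(self) -> bool:
        return not self.dissociated


@dataclass
class TrajectoryScore:
    """Per-frame NOE R-factor time series."""

    frames: list[FrameScore]
    topology: str = ""
    trajectory: str = ""

    def __post_init__(self) -> None:
        times = [f.time_ns for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def r_factors(self) -> list[float | None]:
        return [f.r_factor for f in self.frames]

    @property
    def dissociated_frames(self) -> list[int]:
        return [f.index for f in self.frames if f.dissociated]

    def to_table(self) -> str:
        lines = ["frame\ttime_ns\tr_factor"]
        for f in self.frames:
            r = "NA" if f.r_factor is None else f"{f.r_factor:.3f}"
            lines.append(f"{f.index}\t{f.time_ns:.6g}\t{r}")
        return "\n".join(lines) + "\n"


def _atom_element(atom) -> str:
    try:
        el = atom.element.strip()
        if el:
            return el.upper()
    except (mda.exceptions.NoDataError, AttributeError):
        pass
    name = atom.name.strip().lstrip("0123456789")
    return name[:1].upper()


def system_from_universe(
    universe: mda.Universe,
    ligand_selection: str,
    source_label: str = "",
) -> SpinSystem:
    """Build a SpinSystem from the current frame of an MDAnalysis universe."""
    ligand_ag = universe.select_atoms(ligand_selection)
    if len(ligand_ag) == 0:
        raise ValueError(f"ligand selection {ligand_selection!r} matches no atoms")
    lig_set = set(ligand_ag.indices)

    lig_h, lig_heavy, prot_h, prot_heavy = [], [], [], []
    for atom in universe.atoms:
        el = _atom_element(atom)
        rec_h = (atom.name, atom.resname, int(atom.resid), atom.position.astype(float))
        if atom.index in lig_set:
            (lig_h if el == "H" else lig_heavy).append(
                rec_h if el == "H" else (el, atom.position.astype(float))
            )
        else:
            (prot_h if el == "H" else prot_heavy).append(
                rec_h if el == "H" else (el, atom.position.astype(float))
            )
    if not lig_h:
        raise ValueError("ligand selection contains no hydrogen atoms")

    protons: list[Proton] = []
    for (name, resname, resid, xyz), exch in zip(
        lig_h, _exchangeable_flags(lig_h, lig_heavy)
    ):
        protons.append(Proton(name, resname, resid, xyz, Group.LIGAND, exchangeable=exch))
    for (name, resname, resid, xyz), exch in zip(
        prot_h, _exchangeable_flags(prot_h, prot_heavy)
    ):
        protons.append(
            Proton(
                name, resname, resid, xyz, Group.UNSATURATED_PROTEIN,
                methyl_id=_methyl_id(resname, resid, name), exchangeable=exch,
            )
        )
    return SpinSystem(_sanitize_methyls(protons), source_label=source_label)


def detect_dissociation(system: SpinSystem, cutoff: float) -> bool:
    """True when no saturated protein proton survives the cutoff pruning."""
    return len(apply_cutoff(system, cutoff).saturated) == 0


def score_frame(
    system: SpinSystem,
    exp: Epitope,
    params: RelaxationParams,
    binding: BindingState,
    key_map: dict[str, str] | None = None,
):
    """Reduced-matrix epitope + R-factor for one already-saturated system."""
    pruned = apply_cutoff(system, params.cutoff)
    if not pruned.scorable:
        return None, None
    epitope = std0_calc(assemble_M(pruned, params, binding))
    epitope = aggregate_by_key(epitope, key_map)
    cal = Epitope.from_values(epitope.as_dict(), provenance="calculated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-frame small-n warning would spam
        score = noe_r_factor(exp, cal)
    return score, cal


def score_trajectory(
    topology,
    trajectory,
    exp: Epitope,
    params: RelaxationParams,
    binding: BindingState,
    ligand_selection: str = "resname LIG",
    saturation="methyls",
    stride: int = 1,
    dt_ns: float = 0.1,
    key_map: dict[str, str] | None = None,
    keep_epitopes: bool = False,
    compute_rmsd: bool = False,
) -> TrajectoryScore:
    """Score every ``stride``-th frame of a trajectory against ``exp``.

    Frame times are taken from the trajectory metadata when present,
    otherwise ``index * dt_ns``.  Dissociated frames (empty pruned
    saturated set) get ``r_factor=None``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    u = mda.Universe(str(topology), str(trajectory))
    ref = mda.Universe(str(topology), str(trajectory)) if compute_rmsd else None
    if ref is not None:
        ref.trajectory[0]

    # PDB-style trajectories carry no time metadata; fall back to index*dt_ns
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj_dt_ps = getattr(u.trajectory, "dt", 0.0)
    has_time = traj_dt_ps not in (None, 0.0, 1.0)

    frames: list[FrameScore] = []
    for ts in u.trajectory[::stride]:
        label = f"{trajectory}:frame{ts.frame}"
        system = select_saturated(
            system_from_universe(u, ligand_selection, label), saturation
        )
        time_ns = ts.time / 1000.0 if has_time else ts.frame * dt_ns
        rmsd = (
            ligand_rmsd(u, ref, ligand_selection) if compute_rmsd else None
        )
        if detect_dissociation(system, params.cutoff):
            frames.append(FrameScore(ts.frame, time_ns, True, ligand_rmsd=rmsd))
            continue
        score, cal = score_frame(system, exp, params, binding, key_map)
        frames.append(
            FrameScore(
                ts.frame,
                time_ns,
                False,
                r_factor=score.r_factor,
                epitope=cal.entries if keep_epitopes else None,
                ligand_rmsd=rmsd,
            )
        )
    return TrajectoryScore(frames, topology=str(topology), trajectory=str(trajectory))


def extract_frames(
    score: TrajectoryScore,
    threshold: float,
    out_pdb=None,
) -> list[int]:
    """Indices of scored frames with R-factor below ``threshold``.

    With ``out_pdb`` the selected frames are written as a multi-model PDB.
    """
    selected = [
        f.index
        for f in score.frames
        if f.r_factor is not None and f.r_factor < threshold
    ]
    if not selected:
        warnings.warn(f"no frames with R-factor < {threshold}", stacklevel=2)
        return []
    if out_pdb is not None:
        u = mda.Universe(score.topology, score.trajectory)
        with mda.Writer(str(out_pdb), multiframe=True, n_atoms=len(u.atoms)) as w:
            for ts in u.trajectory:
                if ts.frame in selected:
                    w.write(u.atoms)
    return selected


def ligand_rmsd(
    mobile: mda.Universe,
    reference: mda.Universe,
    ligand_selection: str,
    site_cutoff: float = 6.0,
) -> float:
    """Heavy-atom ligand RMSD after superposing the binding site.

    The superposition uses the reference's heavy protein atoms within
    ``site_cutoff`` A of the ligand; the RMSD is then over ligand heavy
    atoms without further fitting.
    """
    ref_lig = reference.select_atoms(ligand_selection)
    mob_lig = mobile.select_atoms(ligand_selection)
    if len(ref_lig) != len(mob_lig) or len(ref_lig) == 0:
        raise ValueError("ligand selections do not match between frames")

    site = reference.select_atoms(
        f"not ({ligand_selection}) and not name H* and "
        f"around {site_cutoff} ({ligand_selection})"
    )
    if len(site) < 3:
        raise ValueError("binding-site selection too small to superpose")
    mob_site = mobile.atoms[site.indices]

    ref_site_xyz = site.positions.astype(float)
    mob_site_xyz = mob_site.positions.astype(float)
    ref_cen = ref_site_xyz.mean(axis=0)
    mob_cen = mob_site_xyz.mean(axis=0)
    rot, _ = rotation_matrix(mob_site_xyz - mob_cen, ref_site_xyz - ref_cen)

    heavy_ref = ref_lig.positions[[_atom_element(a) != "H" for a in ref_lig]]
    heavy_mob = mob_lig.positions[[_atom_element(a) != "H" for a in mob_lig]]
    moved = (heavy_mob - mob_cen) @ rot.T + ref_cen
    return float(np.sqrt(np.mean(np.sum((moved - heavy_ref) ** 2, axis=1))))
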
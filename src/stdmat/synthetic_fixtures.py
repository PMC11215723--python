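"""Deterministic synthetic fixtures: toy spin systems, a miniature
protein-ligand complex, build-up curves and scripted trajectories.

Every template writes standard PDB files plus a ground-truth sidecar
(JSON) whose numbers are computed here by straight-line brute-force
geometry (pairwise distances, r^-6 sums, plain RMSD) so the sidecar stays
independent of the analysis modules.  Geometries are scripted, not
physical: bond lengths are plausible (C-H 1.09 A) but no force field is
involved.

Identical spec + seed => byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from stdmat.epitope_scoring import BuildUpCurve

_TEMPLATES = ("two_spin", "three_spin", "methyl_probe", "mini_complex", "poses", "trajectory")

_CH = 1.09  # C-H bond length, A


@dataclass
class FixtureSpec:
    """Named geometry template with parameters; same spec+seed => same bytes."""

    template: str
    params: dict = field(default_factory=dict)
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template not in _TEMPLATES:
            raise ValueError(
                f"unknown template {self.template!r}; choose from {_TEMPLATES}"
            )


# ---------------------------------------------------------------------------
# PDB emission

def _pdb_line(serial, name, resname, chain, resid, xyz, element):
    pname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {pname}{'':1s}{resname:<3s} {chain}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(atoms, path, model_coords=None):
    """Write atoms [(name, resname, resid, xyz, element), ...] as PDB.

    ``model_coords``: optional list of (n_atoms, 3) arrays -> one MODEL
    block per entry (names/residues repeated).
    """
    path = Path(path)
    with path.open("w") as fh:
        if model_coords is None:
            for i, (name, resname, resid, xyz, element) in enumerate(atoms, 1):
                fh.write(_pdb_line(i, name, resname, "A", resid, xyz, element))
            fh.write("END\n")
        else:
            for imodel, coords in enumerate(model_coords, 1):
                fh.write(f"MODEL     {imodel:4d}\n")
                for i, ((name, resname, resid, _, element), xyz) in enumerate(
                    zip(atoms, coords), 1
                ):
                    fh.write(_pdb_line(i, name, resname, "A", resid, xyz, element))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# geometry helpers (brute-force, no analysis-module imports)

def _methyl_hydrogens(carbon: np.ndarray, axis: np.ndarray) -> list[np.ndarray]:
    """Three H positions tetrahedrally arranged around a methyl carbon."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = []
    for k in range(3):
        ang = 2.0 * np.pi * k / 3.0
        direction = -axis * np.cos(np.radians(70.5)) + np.sin(np.radians(70.5)) * (
            u * np.cos(ang) + v * np.sin(ang)
        )
        out.append(carbon + _CH * direction)
    return out


def _closed_form_epitope(lig_h: np.ndarray, sat_h: np.ndarray) -> list[float]:
    """Relative epitope from pure r^-6 geometry (equal correlation times)."""
    strength = np.array(
        [np.sum(np.linalg.norm(sat_h - h, axis=1) ** -6.0) for h in lig_h]
    )
    return list(100.0 * strength / strength.max())


# ---------------------------------------------------------------------------
# templates

def _two_spin(params):
    r = float(params.get("r", 3.0))
    ligand = [
        ("C1", "LIG", 1, np.array([0.0, 0.0, -_CH]), "C"),
        ("H1", "LIG", 1, np.array([0.0, 0.0, 0.0]), "H"),
    ]
    protein = [
        ("CS", "SRC", 1, np.array([0.0, 0.0, r + _CH]), "C"),
        ("HS1", "SRC", 1, np.array([0.0, 0.0, r]), "H"),
    ]
    truth = {
        "saturation_list": ["1:HS1"],
        "distances": {"H1-HS1": r},
        "relative_epitope": {"H1": 100.0},
    }
    return protein, ligand, truth


def _three_spin(params):
    r1 = float(params.get("r1", 2.5))
    r2 = float(params.get("r2", 5.0))
    ligand = [
        ("C1", "LIG", 1, np.array([r1, -_CH, 0.0]), "C"),
        ("H1", "LIG", 1, np.array([r1, 0.0, 0.0]), "H"),
        ("C2", "LIG", 1, np.array([-r2, -_CH, 0.0]), "C"),
        ("H2", "LIG", 1, np.array([-r2, 0.0, 0.0]), "H"),
    ]
    protein = [
        ("CS", "SRC", 1, np.array([0.0, _CH, 0.0]), "C"),
        ("HS1", "SRC", 1, np.array([0.0, 0.0, 0.0]), "H"),
    ]
    truth = {
        "saturation_list": ["1:HS1"],
        "distances": {"H1-HS1": r1, "H2-HS1": r2},
        "relative_epitope": {"H1": 100.0, "H2": 100.0 * (r1 / r2) ** 6},
    }
    return protein, ligand, truth


def _methyl_probe(params):
    d = float(params.get("d", 4.0))
    cb = np.array([0.0, 0.0, 0.0])
    hb = _methyl_hydrogens(cb, axis=np.array([0.0, 0.0, -1.0]))
    protein = [
        ("CA", "ALA", 1, np.array([0.0, 0.0, 1.54]), "C"),
        ("CB", "ALA", 1, cb, "C"),
        ("HB1", "ALA", 1, hb[0], "H"),
        ("HB2", "ALA", 1, hb[1], "H"),
        ("HB3", "ALA", 1, hb[2], "H"),
    ]
    ligand = [
        ("C1", "LIG", 1, np.array([0.0, 0.0, -d - _CH]), "C"),
        ("H1", "LIG", 1, np.array([0.0, 0.0, -d]), "H"),
    ]
    lig_h = np.array([ligand[1][3]])
    sat_h = np.array(hb)
    truth = {
        "saturation_list": "methyls",
        "distances": {
            f"H1-HB{i+1}": float(np.linalg.norm(lig_h[0] - h)) for i, h in enumerate(hb)
        },
        "relative_epitope": dict(zip(["H1"], _closed_form_epitope(lig_h, sat_h))),
        "n_methyl_protons": 3,
    }
    return protein, ligand, truth


def _backbone(resname, resid, x0, atoms):
    """Minimal residue backbone along +x starting at x0; appends to atoms."""
    atoms += [
        ("N", resname, resid, np.array([x0, 0.0, 0.0]), "N"),
        ("H", resname, resid, np.array([x0, -1.0, 0.0]), "H"),
        ("CA", resname, resid, np.array([x0 + 1.4, 0.0, 0.0]), "C"),
        ("HA", resname, resid, np.array([x0 + 1.4, 0.0, 1.09]), "H"),
        ("C", resname, resid, np.array([x0 + 2.8, 0.5, 0.0]), "C"),
        ("O", resname, resid, np.array([x0 + 2.8, 1.7, 0.0]), "O"),
    ]


def _mini_complex(params):
    """ALA-VAL-GLY tripeptide plus a 4-proton rigid ligand near the VAL side chain."""
    atoms: list = []
    # ALA 1
    _backbone("ALA", 1, 0.0, atoms)
    cb = np.array([1.4, 1.2, -0.9])
    atoms.append(("CB", "ALA", 1, cb, "C"))
    for i, h in enumerate(_methyl_hydrogens(cb, axis=np.array([0.0, -1.2, 0.9])), 1):
        atoms.append((f"HB{i}", "ALA", 1, h, "H"))
    # VAL 2
    _backbone("VAL", 2, 3.8, atoms)
    cbv = np.array([5.2, 1.4, 0.6])
    atoms += [
        ("CB", "VAL", 2, cbv, "C"),
        ("HB", "VAL", 2, cbv + np.array([0.0, 0.0, -_CH]), "H"),
    ]
    cg1 = cbv + np.array([-0.9, 1.2, 0.4])
    cg2 = cbv + np.array([1.1, 1.1, 0.5])
    atoms.append(("CG1", "VAL", 2, cg1, "C"))
    for i, h in enumerate(_methyl_hydrogens(cg1, axis=cbv - cg1), 1):
        atoms.append((f"HG1{i}", "VAL", 2, h, "H"))
    atoms.append(("CG2", "VAL", 2, cg2, "C"))
    for i, h in enumerate(_methyl_hydrogens(cg2, axis=cbv - cg2), 1):
        atoms.append((f"HG2{i}", "VAL", 2, h, "H"))
    # GLY 3 (two alpha protons)
    _backbone("GLY", 3, 7.6, atoms)
    atoms.append(("HA3", "GLY", 3, np.array([9.0, 0.0, -1.09]), "H"))

    # ligand: 4 CH groups in a zig-zag, hovering above the VAL methyls
    base = cbv + np.array([0.0, 3.2, 1.2])
    lig = []
    offsets = [np.zeros(3), np.array([1.5, 0.3, 0.0]),
               np.array([3.0, 0.0, 0.3]), np.array([4.5, 0.4, 0.0])]
    for i, off in enumerate(offsets, 1):
        c = base + off
        h = c + np.array([0.0, -_CH, 0.0])  # H points toward the protein
        lig.append((f"C{i}", "LIG", 1, c, "C"))
        lig.append((f"H{i}", "LIG", 1, h, "H"))

    methyl_names = {("ALA", f"HB{i}") for i in (1, 2, 3)} | {
        ("VAL", f"HG{g}{i}") for g in (1, 2) for i in (1, 2, 3)
    }
    methyl_h = np.array([a[3] for a in atoms if (a[1], a[0]) in methyl_names])
    lig_h = np.array([a[3] for a in lig if a[4] == "H"])
    truth = {
        "saturation_list": "methyls",
        "n_methyl_protons": 9,
        "relative_epitope": dict(
            zip([a[0] for a in lig if a[4] == "H"], _closed_form_epitope(lig_h, methyl_h))
        ),
    }
    return atoms, lig, truth


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# ---------------------------------------------------------------------------
# public API

def make_spin_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write protein.pdb, ligand.pdb and ground_truth.json for a template.

    Returns {"protein": path, "ligand": path, "truth": dict, ...}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    builders = {
        "two_spin": _two_spin,
        "three_spin": _three_spin,
        "methyl_probe": _methyl_probe,
        "mini_complex": _mini_complex,
    }
    if spec.template == "poses":
        return _make_pose_fixture(spec, outdir)
    if spec.template == "trajectory":
        return make_trajectory_fixture(spec, outdir)
    if spec.template not in builders:
        raise ValueError(f"template {spec.template!r} is not a spin fixture")
    protein, ligand, truth = builders[spec.template](spec.params)
    truth["template"] = spec.template
    truth["seed"] = spec.seed
    ppath = write_pdb(protein, outdir / "protein.pdb")
    lpath = write_pdb(ligand, outdir / "ligand.pdb")
    tpath = outdir / "ground_truth.json"
    tpath.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"protein": ppath, "ligand": lpath, "truth": truth, "truth_path": tpath}


def _ligand_pose_coords(lig_atoms, rng, near_native: bool):
    xyz = np.array([a[3] for a in lig_atoms])
    centroid = xyz.mean(axis=0)
    if near_native:
        return xyz + rng.normal(0.0, 0.05, size=3)
    rot = _rotation(rng.normal(size=3), rng.uniform(1.0, np.pi))
    shift = rng.normal(0.0, 1.0, size=3) + rng.choice([-1, 1], size=3) * rng.uniform(2.0, 4.0, size=3)
    return (xyz - centroid) @ rot.T + centroid + shift


def _make_pose_fixture(spec: FixtureSpec, outdir: Path) -> dict:
    """Multi-MODEL ligand file: one near-native pose among decoys."""
    n_poses = int(spec.params.get("n_poses", 5))
    native = int(spec.params.get("native_index", 2))
    rng = np.random.default_rng(spec.seed)
    protein, ligand, truth = _mini_complex(spec.params)
    models = [
        _ligand_pose_coords(ligand, rng, near_native=(i == native))
        for i in range(n_poses)
    ]
    ppath = write_pdb(protein, outdir / "protein.pdb")
    lpath = write_pdb(ligand, outdir / "ligand_poses.pdb", model_coords=models)
    truth.update({"template": "poses", "seed": spec.seed, "native_index": native,
                  "n_poses": n_poses})
    tpath = outdir / "ground_truth.json"
    tpath.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"protein": ppath, "ligand": lpath, "truth": truth, "truth_path": tpath}


def make_buildup_fixture(std_max, k_sat, t_grid, noise_sd=0.0, seed=0, key="H1") -> BuildUpCurve:
    """Mono-exponential build-up samples with optional Gaussian noise."""
    if std_max <= 0 or k_sat <= 0:
        raise ValueError("std_max and k_sat must be positive")
    t = np.asarray(t_grid, dtype=float)
    std = std_max * (1.0 - np.exp(-k_sat * t))
    if noise_sd > 0:
        std = std + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return BuildUpCurve(key, t, std)


def make_trajectory_fixture(spec: FixtureSpec, outdir) -> dict:
    """Scripted trajectory of the mini complex as topology + multi-model PDB.

    Params: n_frames (default 10), dissociated (frame indices translated
    50 A away, default (4, 5, 6)), reoriented (frames with the ligand
    rotated 90 deg about its centroid, default ()).  The sidecar lists the
    dissociated frames and the brute-force ligand heavy-atom RMSD of every
    frame versus frame 0 (the protein never moves, so no superposition is
    involved).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_frames = int(spec.params.get("n_frames", 10))
    dissociated = sorted(int(i) for i in spec.params.get("dissociated", (4, 5, 6)))
    reoriented = sorted(int(i) for i in spec.params.get("reoriented", ()))

    protein, ligand, truth = _mini_complex(spec.params)
    atoms = protein + ligand
    base = np.array([a[3] for a in atoms])
    n_prot = len(protein)
    lig_xyz = base[n_prot:]
    lig_heavy = np.array([a[3] for a in ligand if a[4] != "H"])

    frames, rmsd = [], []
    for i in range(n_frames):
        coords = base.copy()
        lig = lig_xyz.copy()
        if i in reoriented:
            centroid = lig.mean(axis=0)
            lig = (lig - centroid) @ _rotation(np.array([0.0, 0.0, 1.0]), np.pi / 2).T + centroid
        if i in dissociated:
            lig = lig + np.array([50.0, 0.0, 0.0])
        coords[n_prot:] = lig
        frames.append(coords)
        heavy = np.array([c for c, a in zip(lig, ligand) if a[4] != "H"])
        rmsd.append(float(np.sqrt(np.mean(np.sum((heavy - lig_heavy) ** 2, axis=1)))))

    top = write_pdb(atoms, outdir / "complex_top.pdb")
    traj = write_pdb(atoms, outdir / "complex_traj.pdb", model_coords=frames)
    truth.update(
        {
            "template": "trajectory",
            "seed": spec.seed,
            "n_frames": n_frames,
            "dissociated_frames": dissociated,
            "reoriented_frames": reoriented,
            "ligand_rmsd": rmsd,
            "ligand_resname": "LIG",
        }
    )
    tpath = outdir / "ground_truth.json"
    tpath.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"topology": top, "trajectory": traj, "truth": truth, "truth_path": tpath}
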
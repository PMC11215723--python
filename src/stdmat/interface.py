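"""Run configuration and the two documented analysis modes.

``static`` scores one protein PDB against a (possibly multi-model) ligand
PDB and an experimental epitope, one NOE R-factor per ligand model (docking
poses are just models).  ``dynamic`` scores an MD trajectory frame by
frame.  Config files are plain ``key = value`` text; every run can write a
resolved-config run record for provenance.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import stdmat
from stdmat.binding_thermo import solve_binding
from stdmat.epitope_scoring import (
    GOOD_R_FACTOR,
    Epitope,
    classify_fit,
    noe_r_factor,
    read_epitope,
)
from stdmat.reduced_matrix import aggregate_by_key, assemble_M, std0_calc
from stdmat.relaxation_core import RelaxationParams
from stdmat.spin_system import apply_cutoff, parse_complex, select_saturated
from stdmat.trajectory_mode import extract_frames, score_frame, score_trajectory

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


@dataclass
class RunConfig:
    """Resolved parameters for one run (concentrations uM, cutoff A)."""

    mode: str = "static"
    protein: str | None = None
    ligand: str | None = None
    topology: str | None = None
    trajectory: str | None = None
    epitope: str | None = None
    frequency_mhz: float = 600.0
    tau_c_ns: float = 10.0
    tau_c_free_ns: float = 0.5
    protein_conc_uM: float = 50.0
    ligand_conc_uM: float = 1000.0
    kd_uM: float = 1000.0
    cutoff_angstrom: float = 12.0
    saturation: str = "methyls"
    ligand_selection: str = "resname LIG"
    stride: int = 1
    dt_ns: float = 0.1
    r_threshold: float = GOOD_R_FACTOR
    methyl_averaging: bool = False
    key_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frequency_mhz", "tau_c_ns", "tau_c_free_ns", "protein_conc_uM",
                     "ligand_conc_uM", "kd_uM", "cutoff_angstrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        required = {
            "static": ("protein", "ligand", "epitope"),
            "trajectory": ("topology", "trajectory", "epitope"),
            "oracle": ("protein", "ligand"),
        }
        if self.mode not in required:
            raise ValueError(f"unknown mode {self.mode!r}")
        missing = [k for k in required[self.mode] if getattr(self, k) is None]
        if missing:
            raise ValueError(f"mode {self.mode!r} requires: {missing}")

    @property
    def relaxation_params(self) -> RelaxationParams:
        return RelaxationParams(
            larmor_frequency=self.frequency_mhz,
            tau_c_bound=self.tau_c_ns,
            tau_c_free=self.tau_c_free_ns,
            cutoff=self.cutoff_angstrom,
            methyl_averaging=self.methyl_averaging,
        )

    @property
    def binding_state(self):
        return solve_binding(self.protein_conc_uM, self.ligand_conc_uM, self.kd_uM)

    @property
    def saturation_spec(self):
        if self.saturation == "methyls":
            return "methyls"
        return [s.strip() for s in self.saturation.split(",")]

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dict):
                v = ",".join(f"{a}:{b}" for a, b in v.items())
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read ``key = value`` lines ('#' comments) and apply overrides."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    kwargs: dict = {}
    types = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in types:
            raise KeyError(f"unknown config key {key!r}")
        if key == "key_map":
            kwargs[key] = dict(
                pair.split(":") for pair in value.split(",") if pair
            )
        elif key in ("stride", "seed"):
            kwargs[key] = int(value)
        elif key == "methyl_averaging":
            kwargs[key] = _BOOL[value.lower()]
        elif key in ("mode", "protein", "ligand", "topology", "trajectory",
                     "epitope", "saturation", "ligand_selection"):
            kwargs[key] = value
        else:
            kwargs[key] = float(value)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _count_models(ligand_path: str) -> int:
    n = sum(1 for line in Path(ligand_path).read_text().splitlines()
            if line.startswith("MODEL"))
    return max(n, 1)


def score_static_model(config: RunConfig, exp: Epitope, model_index: int):
    """One ligand model: parse, saturate, prune, reduced matrix, R-factor."""
    system = parse_complex(config.protein, config.ligand, model_index)
    system = select_saturated(system, config.saturation_spec)
    pruned = apply_cutoff(system, config.cutoff_angstrom)
    if not pruned.scorable:
        raise ValueError("un-scorable: no saturated protein proton within cutoff")
    params = config.relaxation_params
    binding = config.binding_state
    epitope = aggregate_by_key(std0_calc(assemble_M(pruned, params, binding)),
                               config.key_map or None)
    cal = Epitope.from_values(epitope.as_dict(), provenance="calculated")
    return noe_r_factor(exp, cal), cal


def run_static(config: RunConfig, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Score every ligand model; table sorted by R-factor (ties: model index).

    Per-model failures are reported in the ``error`` column without
    aborting the remaining models.
    """
    exp = read_epitope(config.epitope)
    rows = []
    for model in range(_count_models(config.ligand)):
        row: dict = {"model": model}
        try:
            score, cal = score_static_model(config, exp, model)
            row.update(
                r_factor=score.r_factor,
                n_matched=score.n_matched,
                classification=classify_fit(score, config.r_threshold),
                error="",
            )
            row["epitope"] = {k: round(v, 1) for k, v in cal.entries.items()}
        except (ValueError, KeyError, IndexError) as exc:
            row.update(r_factor=np.nan, n_matched=0,
                       classification="un-scorable", error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["r_factor", "model"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        export = table.drop(columns=["epitope"], errors="ignore").copy()
        export["r_factor"] = export["r_factor"].map(
            lambda r: "" if pd.isna(r) else f"{r:.3f}"
        )
        export.to_csv(out_dir / "static_scores.tsv", sep="\t", index=False)
        _write_run_record(config, out_dir, mode="static")
    return table


def run_dynamic(config: RunConfig, out_dir: str | Path | None = None):
    """Score a trajectory; write the time series and an optional frame PDB."""
    exp = read_epitope(config.epitope)
    t0 = time.perf_counter()
    score = score_trajectory(
        config.topology,
        config.trajectory,
        exp,
        config.relaxation_params,
        config.binding_state,
        ligand_selection=config.ligand_selection,
        saturation=config.saturation_spec,
        stride=config.stride,
        dt_ns=config.dt_ns,
        key_map=config.key_map or None,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "r_factor_timeseries.tsv").write_text(score.to_table())
        good = [f for f in score.frames if f.r_factor is not None
                and f.r_factor < config.r_threshold]
        if good:
            extract_frames(score, config.r_threshold,
                           out_pdb=out_dir / "selected_frames.pdb")
        _write_run_record(config, out_dir, mode="dynamic",
                          wall_s=time.perf_counter() - t0)
    return score


def _write_run_record(config: RunConfig, out_dir: Path, mode: str, wall_s=None):
    rec = [
        f"stdmat {stdmat.__version__}",
        f"mode = {mode}",
        f"wall_time_s = {wall_s:.3f}" if wall_s is not None else "",
        "",
        "# resolved configuration",
        config.to_text(),
    ]
    binding = config.binding_state
    rec.append(
        f"# bound fraction of ligand = {binding.bound_fraction_ligand:.4f} "
        f"([PL] = {binding.complex_conc:.3f} uM)"
    )
    (out_dir / "run_record.txt").write_text("\n".join(r for r in rec if r != ""))
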
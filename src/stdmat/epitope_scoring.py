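"""Experimental STD0 extraction and NOE R-factor scoring.

Experimental binding epitopes come from STD build-up curves: the STD factor
``STD(t) = (I0 - Isat)/I0`` at increasing saturation times t is fitted to
the mono-exponential ``STD(t) = STDmax (1 - exp(-ksat t))`` and the initial
slope is ``STD0 = STDmax * ksat``, the epitope quantity least biased by
differential ligand relaxation.  Calculated and experimental epitopes (both
relative, max = 100 %) are compared with the NOE R-factor

    R = sqrt( sum_k W_k (STD0exp_k - STD0cal_k)^2 / sum_k W_k (STD0exp_k)^2 )

with unit weights by default; R < 0.3 is the conventional threshold for a
validated model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Conventional "good model" NOE R-factor threshold.
GOOD_R_FACTOR = 0.3


@dataclass
class BuildUpCurve:
    """STD factor vs saturation time for one proton resonance."""

    key: str
    t_sat: np.ndarray   # s, strictly increasing
    std: np.ndarray     # dimensionless STD factors

    def __post_init__(self) -> None:
        self.t_sat = np.asarray(self.t_sat, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.t_sat.shape != self.std.shape:
            raise ValueError("t_sat and std must have equal length")
        if np.any(np.diff(self.t_sat) <= 0):
            raise ValueError("saturation times must be strictly increasing")


@dataclass(frozen=True)
class Epitope:
    """Relative binding epitope: proton key -> relative STD0 in % (max 100)."""

    entries: dict[str, float]
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("epitope has no entries")
        vals = np.array(list(self.entries.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("epitope entries must be non-negative")
        if abs(vals.max() - 100.0) > 1e-9:
            raise ValueError("epitope must be normalized to max = 100")

    @classmethod
    def from_values(cls, values: dict[str, float], provenance: str = "experimental") -> "Epitope":
        """Normalize raw (relative or absolute) STD0 values to max = 100."""
        peak = max(values.values())
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero epitope")
        return cls({k: 100.0 * v / peak for k, v in values.items()}, provenance)


@dataclass
class FitResult:
    """Mono-exponential build-up fit for one resonance."""

    key: str
    std_max: float
    k_sat: float
    residual_norm: float

    @property
    def std0(self) -> float:
        return self.std_max * self.k_sat


@dataclass
class ScoreResult:
    """NOE R-factor between an experimental and a calculated epitope."""

    r_factor: float
    pairs: dict[str, tuple[float, float]]  # key -> (exp, cal), relative %
    unmatched: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def fit_buildup(curve: BuildUpCurve, max_std: float = 1.5) -> FitResult:
    """Fit STD(t) = STDmax (1 - exp(-ksat t)) and return STD0 = STDmax*ksat.

    Needs >= 3 points.  Initialization: STDmax0 = max observed STD, ksat0 =
    1/t at half-max; both parameters bounded positive.
    """
    t, y = curve.t_sat, curve.std
    if t.size < 3:
        raise ValueError(f"{curve.key}: need >=3 build-up points, got {t.size}")
    if np.any(y < -0.05) or np.any(y > max_std):
        raise ValueError(
            f"{curve.key}: STD factors outside the [0, {max_std}] sanity band"
        )

    std_max0 = max(float(np.max(y)), 1e-6)
    above = t[y >= 0.5 * std_max0]
    k0 = 1.0 / above[0] if above.size and above[0] > 0 else 1.0 / max(t[-1], 1e-6)

    def model(tt, std_max, k_sat):
        return std_max * (1.0 - np.exp(-k_sat * tt))

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(std_max0, k0),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(
            f"{curve.key}: build-up fit did not converge "
            f"(p0=({std_max0:.4g}, {k0:.4g})): {exc}"
        ) from exc
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return FitResult(curve.key, float(popt[0]), float(popt[1]), resid)


def noe_r_factor(
    exp: Epitope, cal: Epitope, weights: dict[str, float] | None = None
) -> ScoreResult:
    """NOE R-factor over the proton keys shared by both epitopes (W_k = 1)."""
    shared = sorted(set(exp.entries) & set(cal.entries))
    if not shared:
        raise ValueError("experimental and calculated epitopes share no proton keys")
    unmatched = sorted(set(exp.entries) ^ set(cal.entries))
    if len(shared) < 4:
        warnings.warn(
            f"only {len(shared)} matched protons: R-factor is prone to "
            "false-positive/false-negative model validation",
            stacklevel=2,
        )
    w = np.array([1.0 if weights is None else weights.get(k, 1.0) for k in shared])
    e = np.array([exp.entries[k] for k in shared])
    c = np.array([cal.entries[k] for k in shared])
    denom = float(np.sum(w * e**2))
    if denom == 0.0:
        raise ValueError("all-zero experimental epitope over shared keys")
    r = math.sqrt(float(np.sum(w * (e - c) ** 2)) / denom)
    return ScoreResult(
        r_factor=r,
        pairs={k: (float(ev), float(cv)) for k, ev, cv in zip(shared, e, c)},
        unmatched=unmatched,
    )


def classify_fit(score: ScoreResult, threshold: float = GOOD_R_FACTOR) -> str:
    """'good' iff R-factor is strictly below the threshold (default 0.3)."""
    return "good" if score.r_factor < threshold else "poor"


def read_epitope(path: str | Path) -> Epitope:
    """Read an experimental epitope or build-up table from delimited text.

    Two layouts are accepted (comments with '#', comma or whitespace
    delimited):

    * two columns ``proton_key  relative_STD0_percent`` -> normalized epitope;
    * three columns ``proton_key  t_sat  STD`` (long format) -> per-key
      mono-exponential fits, then normalization of the fitted STD0 values.
    """
    df = pd.read_csv(path, comment="#", sep=None, engine="python", header=None)
    if df.shape[1] == 2:
        values = {str(k): float(v) for k, v in zip(df[0], df[1])}
        return Epitope.from_values(values)
    if df.shape[1] == 3:
        values = {}
        for key, sub in df.groupby(0, sort=False):
            sub = sub.sort_values(1)
            curve = BuildUpCurve(str(key), sub[1].to_numpy(float), sub[2].to_numpy(float))
            values[str(key)] = fit_buildup(curve).std0
        return Epitope.from_values(values)
    raise ValueError(
        f"{path}: expected 2 columns (key, relative STD0) or 3 columns "
        f"(key, t_sat, STD), got {df.shape[1]}"
    )
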
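"""Dipolar auto- and cross-relaxation rates for 1H pairs.

Isotropic rigid-body tumbling with a single correlation time per species is
assumed.  Rates use the unnormalized Lorentzian spectral density
``J(w) = tau_c / (1 + w^2 tau_c^2)`` with the dipolar prefactor

    q = (mu0 / 4 pi)^2 * gammaH^4 * hbar^2 / 10

so that the homonuclear cross-relaxation rate between protons i and j at
distance r is ``sigma = q r^-6 (6 J(2 w0) - J(w0*0))`` and the
auto-relaxation (direct dipolar contribution of each neighbour) is
``rho_i = sum_j q r_ij^-6 (6 J(2 w0) + 3 J(w0) + J(0))``.  Any
self-consistent J convention cancels in relative epitopes; this one is used
throughout the package and its oracle.

In the slow-tumbling regime (w0 tau_c >> 1, i.e. a protein-sized complex)
sigma is negative, which is the spin-diffusion regime that makes saturation
transfer efficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants
from scipy.spatial.distance import cdist

GAMMA_H = constants.value("proton gyromag. ratio")  # rad s^-1 T^-1
#: Dipolar prefactor q in SI units (m^6 s^-2); multiply by r^-6 [m^-6] and J [s].
Q_DIPOLAR = (constants.mu_0 / (4.0 * math.pi)) ** 2 * GAMMA_H**4 * constants.hbar**2 / 10.0

_ANGSTROM = 1e-10
#: Distances below this (A) are treated as steric clashes and rejected.
MIN_DISTANCE = 0.5


@dataclass(frozen=True)
class RelaxationParams:
    """Spectrometer and tumbling parameters.

    larmor_frequency : proton frequency in MHz (e.g. 600).
    tau_c_bound : rotational correlation time of the bound complex, ns.
    tau_c_free : correlation time of the free ligand, ns (oracle only).
    cutoff : protein-proton inclusion radius around the ligand, A.
    methyl_averaging : if True, cross-relaxation rates of the 3 protons of a
        CH3 group are replaced by their arithmetic mean (<r^-6> averaging);
        by default methyl protons are three explicit point spins.
    """

    larmor_frequency: float
    tau_c_bound: float
    tau_c_free: float = 0.5
    cutoff: float = 12.0
    methyl_averaging: bool = False

    def __post_init__(self) -> None:
        if min(self.larmor_frequency, self.tau_c_bound, self.tau_c_free, self.cutoff) <= 0:
            raise ValueError("all relaxation parameters must be positive")
        if not 100.0 <= self.larmor_frequency <= 1500.0:
            warnings.warn(
                f"larmor_frequency {self.larmor_frequency} MHz outside the "
                "usual 100-1500 MHz range",
                stacklevel=2,
            )

    @property
    def omega0(self) -> float:
        """Proton Larmor angular frequency, rad/s."""
        return 2.0 * math.pi * self.larmor_frequency * 1e6

    @property
    def tau_c_bound_s(self) -> float:
        return self.tau_c_bound * 1e-9

    @property
    def tau_c_free_s(self) -> float:
        return self.tau_c_free * 1e-9


def spectral_density(omega: float, tau_c: float) -> float:
    """Lorentzian J(w) = tau_c / (1 + w^2 tau_c^2); omega rad/s, tau_c s."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return tau_c / (1.0 + (omega * tau_c) ** 2)


def _sigma_factor(omega0: float, tau_c: float) -> float:
    return 6.0 * spectral_density(2.0 * omega0, tau_c) - spectral_density(0.0, tau_c)


def _rho_factor(omega0: float, tau_c: float) -> float:
    return (
        6.0 * spectral_density(2.0 * omega0, tau_c)
        + 3.0 * spectral_density(omega0, tau_c)
        + spectral_density(0.0, tau_c)
    )


def cross_relaxation_rate(
    r: float, params: RelaxationParams, tau_c: float | None = None
) -> float:
    """Homonuclear cross-relaxation rate sigma (s^-1) at distance r (A)."""
    if r <= MIN_DISTANCE:
        raise ValueError(
            f"proton-proton distance {r:.3f} A below the {MIN_DISTANCE} A clash guard"
        )
    tc = params.tau_c_bound_s if tau_c is None else tau_c
    return Q_DIPOLAR * (r * _ANGSTROM) ** -6 * _sigma_factor(params.omega0, tc)


def auto_relaxation_rate(
    distances: Sequence[float],
    params: RelaxationParams,
    tau_c: float | None = None,
    leakage: float = 0.0,
) -> float:
    """Dipolar auto-relaxation rate rho (s^-1) from neighbour distances (A).

    ``leakage`` adds an external-relaxation term (default 0).
    """
    dist = np.asarray(distances, dtype=float)
    if dist.size == 0:
        raise ValueError("auto-relaxation needs at least one neighbour")
    if np.any(dist <= MIN_DISTANCE):
        raise ValueError("neighbour distance below the clash guard")
    tc = params.tau_c_bound_s if tau_c is None else tau_c
    return float(
        Q_DIPOLAR * np.sum((dist * _ANGSTROM) ** -6.0) * _rho_factor(params.omega0, tc)
        + leakage
    )


def _methyl_average(block: np.ndarray, methyl_ids: Sequence[str | None], axis: int) -> np.ndarray:
    """Replace rows (axis=0) or columns (axis=1) of CH3 protons by their mean."""
    groups: dict[str, list[int]] = {}
    for idx, mid in enumerate(methyl_ids):
        if mid is not None:
            groups.setdefault(mid, []).append(idx)
    out = block.copy()
    for idxs in groups.values():
        if axis == 0:
            out[idxs, :] = block[idxs, :].mean(axis=0)
        else:
            out[:, idxs] = block[:, idxs].mean(axis=1, keepdims=True)
    return out


def build_block(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    params: RelaxationParams,
    tau_c: float | None = None,
    methyl_ids_a: Sequence[str | None] | None = None,
    methyl_ids_b: Sequence[str | None] | None = None,
) -> np.ndarray:
    """Cross-relaxation block sigma(a, b) for two disjoint proton sets.

    ``coords_*`` are (n, 3) arrays in A.  Raises on any pair inside the
    clash guard.  With ``params.methyl_averaging`` and methyl labels
    supplied, rates are <r^-6>-averaged over each CH3 group (the group sum
    is conserved).
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    dist = cdist(a, b)
    if np.any(dist <= MIN_DISTANCE):
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        raise ValueError(
            f"protons a[{i}] and b[{j}] at {dist[i, j]:.3f} A violate the "
            f"{MIN_DISTANCE} A clash guard"
        )
    tc = params.tau_c_bound_s if tau_c is None else tau_c
    block = Q_DIPOLAR * (dist * _ANGSTROM) ** -6.0 * _sigma_factor(params.omega0, tc)
    if params.methyl_averaging:
        if methyl_ids_a is not None:
            block = _methyl_average(block, methyl_ids_a, axis=0)
        if methyl_ids_b is not None:
            block = _methyl_average(block, methyl_ids_b, axis=1)
    return block
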
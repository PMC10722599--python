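"""Bead-level force field of the ligand-capped nanoparticle model.

Nonbonded beads interact through a solvent-quality modified
Lennard-Jones potential: the repulsive core (below the LJ minimum) is
kept at full strength and shifted so it joins an attractive tail whose
depth is scaled by a weight ``s`` in [0, 1].  ``s = 0`` reduces to the
purely repulsive Weeks-Chandler-Andersen form (athermal/good solvent),
``s = 1`` recovers the full LJ potential (vacuum/very bad solvent).
Bonds and angles are harmonic, written as ``K (x - x0)^2`` without the
conventional 1/2 because the published force constants accompany that
form.

Internally the fine-grained layer works in nanometres and k_B T at the
stated temperature; ``FGParams.martini`` carries the MARTINI-derived
bead constants (sigma_b = 0.47 nm, eps = 0.8365 kcal/mol,
r_c = 1.2 nm, K_b = 149.3787 kcal/mol/nm^2, K_theta = 2.9876 kcal/mol,
theta_0 = 180 deg) converted to k_B T at T = 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FGParams",
    "KBT_PER_KCAL_MOL",
    "lj_energy",
    "modified_lj",
    "bond_energy",
    "angle_energy",
]

#: Boltzmann constant in kcal/(mol K)
KB_KCAL_MOL_K = 0.0019872041


def KBT_PER_KCAL_MOL(T: float = 300.0) -> float:
    """1 kcal/mol expressed in units of k_B T at temperature ``T``."""
    return 1.0 / (KB_KCAL_MOL_K * T)


@dataclass(frozen=True)
class FGParams:
    """Fine-grained bead interaction parameters (nm / k_B T units)."""

    s: float  # attraction weight in [0, 1]
    sigma_b: float  # bead length scale, nm
    eps: float  # LJ energy scale, k_B T
    r_cut: float  # nonbonded cutoff, nm
    k_bond: float  # bond force constant, k_B T / nm^2
    b0: float  # equilibrium bond length, nm
    k_angle: float  # angle force constant, k_B T / rad^2
    theta0: float  # equilibrium angle, rad
    temperature: float  # K

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must lie in [0, 1]")
        for name in ("sigma_b", "eps", "r_cut", "k_bond", "b0", "k_angle", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def martini(cls, s: float, temperature: float = 300.0) -> "FGParams":
        """MARTINI C1-bead constants at the given temperature."""
        to_kbt = KBT_PER_KCAL_MOL(temperature)
        return cls(
            s=s,
            sigma_b=0.47,
            eps=0.8365 * to_kbt,
            r_cut=1.2,
            k_bond=149.3787 * to_kbt,
            b0=0.47,
            k_angle=2.9876 * to_kbt,
            theta0=np.pi,
            temperature=temperature,
        )

    def with_s(self, s: float) -> "FGParams":
        return replace(self, s=s)

    @property
    def r_min(self) -> float:
        """Position of the LJ minimum, 2^(1/6) sigma_b."""
        return 2.0 ** (1.0 / 6.0) * self.sigma_b

    @property
    def beta(self) -> float:
        return 1.0  # energies are already in k_B T


def lj_energy(r, sigma: float, eps: float):
    """Plain (unshifted, untruncated) Lennard-Jones energy."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6**2 - sr6)


def _lj_force(r, sigma: float, eps: float):
    """Radial force -du/dr of the plain LJ potential."""
    sr6 = (sigma / r) ** 6
    return 24.0 * eps * (2.0 * sr6**2 - sr6) / r


def modified_lj(r, params: FGParams):
    """Energy and radial force of the solvent-quality modified LJ pair.

    Returns ``(u, f)`` with ``f = -du/dr``; the energy is shifted so it
    vanishes continuously at the cutoff.  ``r`` may be an array.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    s, sig, eps, rc = params.s, params.sigma_b, params.eps, params.r_cut
    rmin = params.r_min
    u_lj = lj_energy(r, sig, eps)
    f_lj = _lj_force(r, sig, eps)
    core = r < rmin
    u = np.where(core, u_lj + (1.0 - s) * eps, s * u_lj)
    f = np.where(core, f_lj, s * f_lj)
    shift = s * lj_energy(np.array(rc), sig, eps)
    u = np.where(r < rc, u - shift, 0.0)
    f = np.where(r < rc, f, 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def bond_energy(b, params: FGParams):
    """Harmonic bond energy ``K_b (b - b0)^2`` and force ``-du/db``."""
    b = np.asarray(b, dtype=float)
    u = params.k_bond * (b - params.b0) ** 2
    f = -2.0 * params.k_bond * (b - params.b0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def angle_energy(theta, params: FGParams):
    """Harmonic angle energy ``K_theta (theta - theta0)^2`` and ``-du/dtheta``."""
    theta = np.asarray(theta, dtype=float)
    u = params.k_angle * (theta - params.theta0) ** 2
    dudtheta = 2.0 * params.k_angle * (theta - params.theta0)
    if u.ndim == 0:
        return float(u), float(-dudtheta)
    return u, -dudtheta
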
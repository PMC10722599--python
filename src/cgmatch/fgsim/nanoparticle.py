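"""Ligand-capped nanoparticle geometry and construction.

A nanoparticle is a rigid spherical core of diameter ``sigma_c`` with
ligand chains grafted at quasi-uniform surface sites (Fibonacci
lattice).  During mean-force sampling the whole core unit (centre plus
grafting sites) is frozen; only the ligand beads move.  Core-core
interactions are neglected — for small cores they are much weaker than
the ligand-ligand terms — so a bare (ligand-free) pair of cores
exerts exactly zero mean force on each other.

The desk-scale default (one core sphere, 42 ligands of 3 beads, 127
"atoms" per particle) keeps constrained sampling runs in the minutes
range; the full-scale geometry (275 core beads, 275 ligands of
5 beads, 1650 beads) is available but long-running.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import FGParams, modified_lj

__all__ = ["NPGeometry", "Nanoparticle", "build_nanoparticle", "fibonacci_sphere"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = 2.0 * np.pi * k / golden
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass(frozen=True)
class NPGeometry:
    """Nanoparticle architecture (lengths in nm)."""

    sigma_c: float  # core diameter
    n_core_beads: int
    n_ligands: int
    beads_per_ligand: int

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.n_core_beads < 1 or self.beads_per_ligand < 0 or self.n_ligands < 0:
            raise ValueError("counts must be non-negative (core beads >= 1)")

    @classmethod
    def full_scale(cls) -> "NPGeometry":
        """Full-scale architecture: 275 + 275 x 5 = 1650 beads."""
        return cls(sigma_c=4.2, n_core_beads=275, n_ligands=275, beads_per_ligand=5)

    @classmethod
    def desk_scale(cls) -> "NPGeometry":
        """Scaled-down architecture for minutes-scale sampling runs."""
        return cls(sigma_c=2.1, n_core_beads=1, n_ligands=42, beads_per_ligand=3)

    @property
    def n_ligand_beads(self) -> int:
        return self.n_ligands * self.beads_per_ligand

    @property
    def n_beads(self) -> int:
        return self.n_core_beads + self.n_ligand_beads

    @property
    def surface_coverage(self) -> float:
        """Ligands per nm^2 of core surface."""
        return self.n_ligands / (np.pi * self.sigma_c**2)

    def ligand_shell_thickness(self, params: FGParams) -> float:
        """Crude contour estimate lambda_s of the capping-layer thickness."""
        return self.beads_per_ligand * params.b0

    def sigma_np(self, params: FGParams) -> float:
        """Effective soft diameter sigma_c + 2 lambda_s."""
        return self.sigma_c + 2.0 * self.ligand_shell_thickness(params)

    def size_ratio(self, params: FGParams) -> float:
        """q = 2 lambda_s / sigma_c; many-body effects expected for q > 0.14."""
        return 2.0 * self.ligand_shell_thickness(params) / self.sigma_c


@dataclass
class Nanoparticle:
    """One built nanoparticle: frozen core unit + mobile ligand beads."""

    geometry: NPGeometry
    center: np.ndarray  # (3,)
    core_beads: np.ndarray  # (n_core, 3), bookkeeping/export only
    graft_sites: np.ndarray  # (n_lig, 3) absolute positions on the core surface
    beads: np.ndarray  # (n_lig * beads_per_ligand, 3) mobile ligand beads

    @property
    def n_mobile(self) -> int:
        return self.beads.shape[0]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_nanoparticle(
    geom: NPGeometry,
    params: FGParams,
    center=(0.0, 0.0, 0.0),
    seed: int | np.random.Generator = 0,
    relax_steps: int = 200,
) -> Nanoparticle:
    """Place grafting sites and initially radial ligand chains, then relax.

    The Fibonacci grafting lattice is given a seeded random orientation;
    chain beads start on the outward surface normal at multiples of the
    equilibrium bond length and residual overlaps are removed by a short
    steepest-descent minimisation of the intra-particle energy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    if geom.n_ligands > 0 and 2.0 * np.pi * (geom.sigma_c / 2.0) ** 2 < geom.n_ligands * (
        0.25 * params.sigma_b
    ) ** 2 * np.pi:
        raise ValueError("requested surface coverage is geometrically infeasible")
    rot = _random_rotation(rng)
    dirs = fibonacci_sphere(max(geom.n_ligands, 1)) @ rot.T
    dirs = dirs[: geom.n_ligands]
    radius = geom.sigma_c / 2.0
    graft_sites = center + radius * dirs
    if geom.n_core_beads == 1:
        core_beads = center[None, :].copy()
    else:
        core_beads = center + radius * (fibonacci_sphere(geom.n_core_beads) @ rot.T)
    offsets = params.b0 * (1.0 + np.arange(geom.beads_per_ligand))
    beads = (graft_sites[:, None, :] + dirs[:, None, :] * offsets[None, :, None]).reshape(-1, 3)
    # tiny seeded jitter breaks exact lattice symmetry before relaxation
    beads += 0.02 * params.sigma_b * rng.standard_normal(beads.shape)
    np_obj = Nanoparticle(geom, center, core_beads, graft_sites, beads)
    if relax_steps > 0 and geom.n_ligand_beads:
        _steepest_descent(np_obj, params, relax_steps)
    return np_obj


def _steepest_descent(np_obj: Nanoparticle, params: FGParams, n_steps: int) -> None:
    """Crude overlap removal on a single particle's ligand beads."""
    from .md import FGSystem

    sys1 = FGSystem([np_obj], params)
    x = sys1.positions
    step = 0.02 * params.sigma_b
    e_prev = None
    for _ in range(n_steps):
        f, _ = sys1.forces(x)
        norm = np.abs(f).max()
        if norm < 1e-6:
            break
        x = x + step * f / max(norm, 1.0)
        e = sys1.energy(x)
        if e_prev is not None and e > e_prev:
            step *= 0.5
            if step < 1e-6 * params.sigma_b:
                break
        e_prev = e
    sys1.positions = x
    np_obj.beads = x.copy()


def core_bead_interaction(r_center, geom: NPGeometry, params: FGParams):
    """Purely repulsive bead-core term acting at the core surface.

    The core acts as a single frozen sphere; a ligand bead at distance
    ``r`` from the core centre feels a WCA-type repulsion evaluated at
    the surface-shifted distance ``r - (sigma_c - sigma_b)/2`` so
    contact occurs at the core surface.  Returns (u, f) with f radial
    on the bead (positive = outward).
    """
    r_center = np.asarray(r_center, dtype=float)
    shift = (geom.sigma_c - params.sigma_b) / 2.0
    r_eff = np.maximum(r_center - shift, 0.05 * params.sigma_b)
    rep = params.with_s(0.0)
    u, f = modified_lj(r_eff, rep)
    return u, f
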
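"""Constrained Langevin sampling of ligand-bead systems and mean forces.

The nanoparticle cores (centre + grafting sites) are frozen rigid
composites; only ligand beads obey Langevin dynamics (BAOAB splitting).
The mean force on a nanoparticle is the time average of the total
instantaneous force exerted on its core unit: the bead-core repulsions
on the core sphere plus the grafting bond (and grafting angle) forces
on its surface sites.

Reduced MD units: lengths in nm, energies in k_B T, bead mass 1; the
time unit is then nm sqrt(m / k_B T).  Exported mean-force datasets are
converted to the coarse-grained unit system (k_B T / sigma_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ..core import Configuration
from ..forcematch import MeanForceDataset
from .forcefield import FGParams, modified_lj, lj_energy
from .nanoparticle import Nanoparticle, NPGeometry, build_nanoparticle, core_bead_interaction

__all__ = [
    "PMFCurve",
    "FGSystem",
    "md_sample_mean_forces",
    "pair_mean_force_scan",
    "integrate_pmf",
    "generate_training_configs",
    "cluster_mean_force_dataset",
]


@dataclass
class PMFCurve:
    """Tabulated mean forces F_m(R) and (optionally) the integrated PMF.

    Distances in sigma_c, forces in k_B T / sigma_c, PMF in k_B T.
    """

    r: np.ndarray
    mean_force: np.ndarray
    error: np.ndarray | None = None
    pmf: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        if self.r.shape != self.mean_force.shape:
            raise ValueError("r and mean_force must have matching shapes")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("distances must be strictly increasing")


def integrate_pmf(curve: PMFCurve) -> PMFCurve:
    """Integrate mean forces into the two-body PMF.

    ``Phi(R) = int_R^Rmax F_m(R') dR'`` by the trapezoid rule on the
    scanned grid, anchored at ``Phi(Rmax) = 0``.
    """
    total = cumulative_trapezoid(curve.mean_force, curve.r, initial=0.0)
    pmf = total[-1] - total
    return PMFCurve(curve.r, curve.mean_force, curve.error, pmf, dict(curve.meta))


# ---------------------------------------------------------------------------
# the fine-grained bead system


class FGSystem:
    """A collection of frozen-core nanoparticles with mobile ligand beads."""

    def __init__(self, particles: list[Nanoparticle], params: FGParams):
        if not particles:
            raise ValueError("need at least one nanoparticle")
        self.particles = particles
        self.params = params
        self.geometry = particles[0].geometry
        self.centers = np.array([p.center for p in particles])
        self.site_pos = (
            np.vstack([p.graft_sites for p in particles])
            if particles[0].graft_sites.size
            else np.empty((0, 3))
        )
        self.positions = (
            np.vstack([p.beads for p in particles]) if particles[0].beads.size else np.empty((0, 3))
        )
        n_lig = self.geometry.n_ligands
        bpl = self.geometry.beads_per_ligand
        self.n_np = len(particles)
        self.site_owner = np.repeat(np.arange(self.n_np), n_lig)
        self.bead_owner = np.repeat(np.arange(self.n_np), n_lig * bpl)

        # chain topology: ligand l of particle p occupies beads
        # [ (p*n_lig + l)*bpl , ... +bpl ) and grafts to site p*n_lig + l
        chains = np.arange(self.n_np * n_lig)
        first_bead = chains * bpl
        self.graft_site_idx = chains
        self.graft_bead_idx = first_bead
        cb_i, cb_j = [], []
        for k in range(bpl - 1):
            cb_i.append(first_bead + k)
            cb_j.append(first_bead + k + 1)
        self.chain_bond_i = np.concatenate(cb_i) if cb_i else np.empty(0, dtype=np.intp)
        self.chain_bond_j = np.concatenate(cb_j) if cb_j else np.empty(0, dtype=np.intp)

        # angles over consecutive triples including the grafting site,
        # indices into the combined [sites; beads] coordinate array
        n_sites = self.site_pos.shape[0]
        tri = []
        if bpl >= 2:
            tri.append(
                np.column_stack(
                    [self.graft_site_idx, n_sites + first_bead, n_sites + first_bead + 1]
                )
            )
        for k in range(bpl - 2):
            tri.append(
                np.column_stack(
                    [
                        n_sites + first_bead + k,
                        n_sites + first_bead + k + 1,
                        n_sites + first_bead + k + 2,
                    ]
                )
            )
        self.angles = np.vstack(tri) if tri else np.empty((0, 3), dtype=np.intp)
        self.n_sites = n_sites

        m = self.positions.shape[0]
        iu, ju = np.triu_indices(m, k=1)
        # exclude directly bonded (1-2) bead pairs from the nonbonded sum
        excl = np.zeros(m * m, dtype=bool)
        if self.chain_bond_i.size:
            excl[self.chain_bond_i * m + self.chain_bond_j] = True
            excl[self.chain_bond_j * m + self.chain_bond_i] = True
        keep = ~excl[iu * m + ju]
        self._iu, self._ju = iu[keep], ju[keep]

    # -- energies and forces ------------------------------------------------

    def _combined(self, x: np.ndarray) -> np.ndarray:
        return np.vstack([self.site_pos, x]) if self.n_sites else x

    def forces(self, x: np.ndarray):
        """Forces on mobile beads and total force on each core unit."""
        p = self.params
        m = x.shape[0]
        f = np.zeros((m, 3))
        core_f = np.zeros((self.n_np, 3))

        if self._iu.size:
            disp = x[self._iu] - x[self._ju]
            r = np.linalg.norm(disp, axis=1)
            close = r < p.r_cut
            if np.any(close):
                i, j = self._iu[close], self._ju[close]
                rc_, dc = r[close], disp[close]
                _, fr = modified_lj(rc_, p)
                fv = (fr / rc_)[:, None] * dc
                np.add.at(f, i, fv)
                np.add.at(f, j, -fv)

        # bead-core repulsion against every frozen core sphere
        for c in range(self.n_np):
            disp = x - self.centers[c]
            r = np.linalg.norm(disp, axis=1)
            _, fr = core_bead_interaction(r, self.geometry, p)
            fv = (fr / np.maximum(r, 1e-12))[:, None] * disp
            f += fv
            core_f[c] -= fv.sum(axis=0)

        # grafting bonds (bead <-> frozen site)
        if self.graft_bead_idx.size:
            vec = x[self.graft_bead_idx] - self.site_pos[self.graft_site_idx]
            r = np.linalg.norm(vec, axis=1)
            fb = -2.0 * p.k_bond * (r - p.b0)
            fv = (fb / np.maximum(r, 1e-12))[:, None] * vec
            np.add.at(f, self.graft_bead_idx, fv)
            np.add.at(core_f, self.site_owner[self.graft_site_idx], -fv)

        # chain bonds (mobile <-> mobile)
        if self.chain_bond_i.size:
            vec = x[self.chain_bond_i] - x[self.chain_bond_j]
            r = np.linalg.norm(vec, axis=1)
            fb = -2.0 * p.k_bond * (r - p.b0)
            fv = (fb / np.maximum(r, 1e-12))[:, None] * vec
            np.add.at(f, self.chain_bond_i, fv)
            np.add.at(f, self.chain_bond_j, -fv)

        if self.angles.size:
            self._angle_forces(x, f, core_f)
        return f, core_f

    def _angle_forces(self, x: np.ndarray, f: np.ndarray, core_f: np.ndarray) -> None:
        p = self.params
        pos = self._combined(x)
        ia, ib, ic = self.angles.T
        u = pos[ia] - pos[ib]
        v = pos[ic] - pos[ib]
        ru = np.linalg.norm(u, axis=1)
        rv = np.linalg.norm(v, axis=1)
        uh = u / ru[:, None]
        vh = v / rv[:, None]
        cth = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        th = np.arccos(cth)
        sth = np.sqrt(np.maximum(1.0 - cth**2, 0.0))
        # fac = (dU/dtheta)/sin(theta); finite limit 2K at theta -> theta0 = pi
        dU = 2.0 * p.k_angle * (th - p.theta0)
        fac = np.where(sth > 1e-8, dU / np.maximum(sth, 1e-12), -2.0 * p.k_angle)
        ga = fac[:, None] * (vh - cth[:, None] * uh) / ru[:, None]
        gc = fac[:, None] * (uh - cth[:, None] * vh) / rv[:, None]
        gb = -(ga + gc)
        self._scatter(f, core_f, ia, ga)
        self._scatter(f, core_f, ib, gb)
        self._scatter(f, core_f, ic, gc)

    def _scatter(self, f, core_f, idx, contrib) -> None:
        """Add per-angle forces to mobile beads or, for frozen sites, cores."""
        is_site = idx < self.n_sites
        if np.any(is_site):
            np.add.at(core_f, self.site_owner[idx[is_site]], contrib[is_site])
        if np.any(~is_site):
            np.add.at(f, idx[~is_site] - self.n_sites, contrib[~is_site])

    def energy(self, x: np.ndarray) -> float:
        p = self.params
        e = 0.0
        if self._iu.size:
            disp = x[self._iu] - x[self._ju]
            r = np.linalg.norm(disp, axis=1)
            close = r < p.r_cut
            if np.any(close):
                u, _ = modified_lj(r[close], p)
                e += float(np.sum(u))
        for c in range(self.n_np):
            r = np.linalg.norm(x - self.centers[c], axis=1)
            u, _ = core_bead_interaction(r, self.geometry, p)
            e += float(np.sum(u))
        if self.graft_bead_idx.size:
            r = np.linalg.norm(x[self.graft_bead_idx] - self.site_pos[self.graft_site_idx], axis=1)
            e += float(np.sum(p.k_bond * (r - p.b0) ** 2))
        if self.chain_bond_i.size:
            r = np.linalg.norm(x[self.chain_bond_i] - x[self.chain_bond_j], axis=1)
            e += float(np.sum(p.k_bond * (r - p.b0) ** 2))
        if self.angles.size:
            pos = self._combined(x)
            ia, ib, ic = self.angles.T
            u = pos[ia] - pos[ib]
            v = pos[ic] - pos[ib]
            cth = np.clip(
                np.einsum("ij,ij->i", u, v)
                / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)),
                -1.0,
                1.0,
            )
            th = np.arccos(cth)
            e += float(np.sum(p.k_angle * (th - p.theta0) ** 2))
        return e


# ---------------------------------------------------------------------------
# Langevin sampling


def relax_system(
    system: FGSystem,
    max_steps: int = 500,
    f_tol: float = 50.0,
    max_move: float | None = None,
) -> None:
    """Capped steepest descent to remove overlaps before dynamics.

    Displacements are limited to ``max_move`` (default sigma_b/20) per
    step so diverging contact forces cannot eject beads.
    """
    x = system.positions
    if x.size == 0:
        return
    if max_move is None:
        max_move = system.params.sigma_b / 20.0
    for _ in range(max_steps):
        f, _ = system.forces(x)
        fmax = np.abs(f).max()
        if fmax < f_tol:
            break
        x = x + f * (max_move / fmax)
    system.positions = x


def md_sample_mean_forces(
    system: FGSystem,
    n_steps: int,
    n_equil: int,
    dt: float = 0.004,
    friction: float = 2.0,
    seed: int | np.random.Generator = 0,
    n_blocks: int = 10,
    sample_stride: int = 2,
):
    """BAOAB Langevin dynamics of the ligand beads at frozen cores.

    Returns ``(mean_forces, block_errors, diagnostics)`` with shapes
    (n_np, 3) in k_B T / nm.  Statistics start after ``n_equil`` steps;
    errors are standard errors over ``n_blocks`` block averages.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_equil >= n_steps:
        raise ValueError(f"n_equil ({n_equil}) must be smaller than n_steps ({n_steps})")
    if system.positions.size == 0:
        z = np.zeros((system.n_np, 3))
        return z, z, {"n_samples": 0}
    relax_system(system)
    x = system.positions.copy()
    v = rng.standard_normal(x.shape)  # kT = 1, m = 1
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    f, core_f = system.forces(x)
    samples = []
    for step in range(n_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f, core_f = system.forces(x)
        if not np.all(np.isfinite(f)) or np.abs(f).max() > 1e8:
            raise RuntimeError(
                f"thermostat instability at step {step}: max |f| = {np.abs(f).max():.3g}"
            )
        if step >= n_equil and (step - n_equil) % sample_stride == 0:
            samples.append(core_f.copy())
    system.positions = x
    samples = np.array(samples)
    mean = samples.mean(axis=0)
    blocks = np.array_split(samples, n_blocks)
    bmeans = np.array([b.mean(axis=0) for b in blocks if len(b)])
    err = bmeans.std(axis=0, ddof=1) / np.sqrt(len(bmeans))
    diag = {"n_samples": len(samples), "kinetic_per_dof": float(0.5 * np.mean(v**2))}
    return mean, err, diag


# ---------------------------------------------------------------------------
# scans and training-set generation


def pair_mean_force_scan(
    geom: NPGeometry,
    params: FGParams,
    distances,
    n_steps: int = 6000,
    n_equil: int = 2000,
    dt: float = 0.004,
    seed: int = 0,
):
    """Constrained pair scan: mean force F_m(R_IJ) along the pair axis.

    ``distances`` are centre separations in units of sigma_c.  Returns
    ``(PMFCurve, MeanForceDataset)``; the dataset holds the full
    vectorial mean forces on both particles per distance, in
    k_B T / sigma_c, ready for force matching.
    """
    distances = np.asarray(distances, dtype=float)
    rng = np.random.default_rng(seed)
    sigma_c = geom.sigma_c
    fm = np.zeros(distances.size)
    fm_err = np.zeros(distances.size)
    configs, force_rows = [], []
    for k, d in enumerate(distances):
        d_nm = d * sigma_c
        np1 = build_nanoparticle(geom, params, center=(0.0, 0.0, 0.0), seed=rng)
        np2 = build_nanoparticle(geom, params, center=(d_nm, 0.0, 0.0), seed=rng)
        system = FGSystem([np1, np2], params)
        mean, err, _ = md_sample_mean_forces(
            system, n_steps, n_equil, dt=dt, seed=rng
        )
        # R_IJ = R_I - R_J with I at the origin: unit vector is -x
        rhat = np.array([-1.0, 0.0, 0.0])
        fm[k] = 0.5 * (mean[0] - mean[1]) @ rhat * sigma_c
        fm_err[k] = 0.5 * np.linalg.norm(err) * sigma_c
        configs.append(Configuration(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])))
        force_rows.append(mean * sigma_c)  # kT/nm -> kT/sigma_c
    curve = PMFCurve(distances, fm, fm_err, meta={"s": params.s, "sigma_c": sigma_c})
    dataset = MeanForceDataset(
        configs,
        force_rows,
        meta={
            "units": "kBT/sigma_c",
            "source": "fg-pair-scan",
            "s": params.s,
            "beta": 1.0,
            "n_steps": n_steps,
            "n_equil": n_equil,
            "seed": seed,
        },
    )
    return curve, dataset


def generate_training_configs(
    n_particles: int = 12,
    diameters=(14.0, 10.0, 7.0, 5.0, 4.0),
    n_per_diameter: int = 20,
    sigma_np: float = 2.0,
    seed: int = 0,
    n_sweeps: int = 300,
    record_stride: int = 10,
) -> list[Configuration]:
    """Confine CG sites in a spherical domain; record wall-free configurations.

    A diameter ladder spans very low densities (all pair distances
    beyond the interaction range, so mean forces vanish) to high
    densities where many coronas interact at once.  At each diameter,
    sites interacting through a WCA repulsion of range ``sigma_np`` plus
    a harmonic spherical wall are equilibrated by Metropolis sweeps and
    snapshots are recorded; the recorded configurations drop the wall
    (they are later frozen for constrained mean-force sampling).

    Distances in sigma_c; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out: list[Configuration] = []
    eps_wca = 1.0
    rmin = 2.0 ** (1.0 / 6.0) * sigma_np
    k_wall = 50.0

    def energy(pos, radius):
        d = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt((d**2).sum(axis=2))
        iu = np.triu_indices(len(pos), k=1)
        rr = r[iu]
        close = rr < rmin
        e = 0.0
        if np.any(close):
            e += float(np.sum(lj_energy(rr[close], sigma_np, eps_wca) + eps_wca))
        rad = np.linalg.norm(pos, axis=1)
        over = np.maximum(rad - radius, 0.0)
        e += float(np.sum(k_wall * over**2))
        return e

    for diameter in diameters:
        radius = diameter / 2.0
        pos = rng.uniform(-radius, radius, (n_particles, 3)) / np.sqrt(3.0)
        e = energy(pos, radius)
        step = 0.3

        def sweep_once(tune):
            nonlocal pos, e, step
            acc = 0
            for _ in range(n_particles):
                i = rng.integers(n_particles)
                trial = pos.copy()
                trial[i] += rng.uniform(-step, step, 3)
                e_new = energy(trial, radius)
                if e_new <= e or rng.random() < np.exp(e - e_new):
                    pos, e = trial, e_new
                    acc += 1
            if tune:
                step = min(max(step * (1.1 if acc > 0.4 * n_particles else 0.9), 0.02), 1.0)

        for sweep in range(n_sweeps):
            sweep_once(tune=sweep < n_sweeps // 2)
        # decorrelated recording phase: exactly n_per_diameter snapshots
        for _ in range(n_per_diameter):
            for _ in range(record_stride):
                sweep_once(tune=False)
            out.append(Configuration(pos.copy()))
    return out


def cluster_mean_force_dataset(
    cg_configs: list[Configuration],
    geom: NPGeometry,
    params: FGParams,
    n_steps: int = 4000,
    n_equil: int = 1500,
    dt: float = 0.004,
    seed: int = 0,
) -> MeanForceDataset:
    """Constrained mean forces for frozen CG configurations (sigma_c units)."""
    rng = np.random.default_rng(seed)
    forces = []
    for cfg in cg_configs:
        parts = [
            build_nanoparticle(geom, params, center=pos * geom.sigma_c, seed=rng)
            for pos in cfg.positions
        ]
        system = FGSystem(parts, params)
        mean, _, _ = md_sample_mean_forces(system, n_steps, n_equil, dt=dt, seed=rng)
        forces.append(mean * geom.sigma_c)
    return MeanForceDataset(
        [c.copy() for c in cg_configs],
        forces,
        meta={
            "units": "kBT/sigma_c",
            "source": "fg-cluster",
            "s": params.s,
            "beta": 1.0,
            "seed": seed,
        },
    )
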
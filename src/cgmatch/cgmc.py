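"""Metropolis Monte Carlo of coarse-grained particles.

Samples NVT or NPT ensembles of CG sites interacting through a learned
many-body potential (or any object exposing the small potential
protocol below), and measures equations of state, radial distribution
functions and fixed-geometry PMF scans.

Because the many-body PMF is a sum of per-site contributions ``Phi_K``
with a finite cutoff, a single-particle move changes ``Phi_K`` only for
sites ``K`` whose cutoff sphere contains the moved particle (old or new
position); energy differences are evaluated locally over that set,
which the test suite verifies against full re-evaluation.

Potential protocol: ``r_cut`` attribute, ``site_energies(config)`` and
``site_energies_subset(config, centers)``; an optional ``is_zero`` flag
short-circuits the ideal-gas case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Configuration, minimum_image
from .forcematch import LinearCGPotential

__all__ = [
    "MCParams",
    "Observables",
    "ZeroPotential",
    "PairPotential",
    "HardCorePotential",
    "CompositePotential",
    "mc_run",
    "mc_eos",
    "fcc_init",
    "radial_distribution",
    "geometry_scan",
]


# ---------------------------------------------------------------------------
# potential adapters


class ZeroPotential:
    """Ideal gas: no interactions (used for detailed-balance checks)."""

    is_zero = True
    r_cut = 0.0

    def site_energies(self, config):
        return np.zeros(config.n_sites)

    def site_energies_subset(self, config, centers):
        return np.zeros(np.atleast_1d(centers).size)


class PairPotential:
    """Adapter exposing an analytic pair potential u(r) as per-site energies.

    ``Phi_K = sum_{J != K} u(R_KJ)`` so the total ``sum_K Phi_K`` double
    counts pairs exactly like a radial descriptor model does; the MC
    acceptance uses energy differences, for which the convention only
    needs to be consistent.  To make totals physical the per-site terms
    are halved.
    """

    is_zero = False

    def __init__(self, u, r_cut: float):
        self.u = u
        self.r_cut = float(r_cut)

    def site_energies(self, config):
        return self.site_energies_subset(config, np.arange(config.n_sites))

    def site_energies_subset(self, config, centers):
        from .core import neighbors_of

        centers = np.atleast_1d(np.asarray(centers, dtype=np.intp))
        out = np.zeros(centers.size)
        for row, c in enumerate(centers):
            _, _, r = neighbors_of(config, int(c), self.r_cut)
            if r.size:
                out[row] = 0.5 * float(np.sum(self.u(r)))
        return out


class HardCorePotential:
    """Bare hard-sphere core as a large finite overlap penalty.

    Mean-force-trained potentials carry only the medium-induced part of
    the interaction; the direct core repulsion of the effective
    one-component Hamiltonian is added separately.  A finite penalty
    (default 1e4 kBT per overlapping pair) keeps the incremental energy
    bookkeeping free of inf - inf while rejecting every overlap move in
    practice.
    """

    is_zero = False

    def __init__(self, sigma: float, strength: float = 1e4):
        self.sigma = float(sigma)
        self.strength = float(strength)
        self.r_cut = float(sigma)

    def site_energies(self, config):
        return self.site_energies_subset(config, np.arange(config.n_sites))

    def site_energies_subset(self, config, centers):
        from .core import neighbors_of

        centers = np.atleast_1d(np.asarray(centers, dtype=np.intp))
        out = np.zeros(centers.size)
        for row, c in enumerate(centers):
            _, _, r = neighbors_of(config, int(c), self.sigma)
            out[row] = 0.5 * self.strength * np.count_nonzero(r < self.sigma)
        return out


class CompositePotential:
    """Sum of potential terms sharing the per-site energy protocol."""

    is_zero = False

    def __init__(self, *terms):
        if not terms:
            raise ValueError("need at least one term")
        self.terms = terms
        self.r_cut = max(t.r_cut for t in terms)

    def site_energies(self, config):
        return sum(t.site_energies(config) for t in self.terms)

    def site_energies_subset(self, config, centers):
        return sum(t.site_energies_subset(config, centers) for t in self.terms)


def _site_energies_subset_model(model: LinearCGPotential, config, centers):
    from .descriptors import site_descriptors

    G = site_descriptors(config, model.specs, centers)
    return (G - model.isolated_ref) @ model.weights


# give the learned potential the MC protocol
LinearCGPotential.is_zero = False
LinearCGPotential.site_energies_subset = _site_energies_subset_model


# ---------------------------------------------------------------------------
# parameters and observables


@dataclass
class MCParams:
    """Monte Carlo run control (reduced units: sigma_c, k_B T)."""

    ensemble: str = "nvt"  # "nvt" | "npt"
    pressure: float | None = None  # reduced P sigma_c^3 / kBT (NPT)
    max_disp: float = 0.25
    max_dlnv: float = 0.02
    n_equil_sweeps: int = 500
    n_prod_sweeps: int = 1000
    frame_stride: int = 20
    check_every: int = 100  # full-energy consistency check interval (sweeps)
    target_acceptance: tuple = (0.2, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble not in ("nvt", "npt"):
            raise ValueError("ensemble must be 'nvt' or 'npt'")
        if self.ensemble == "npt" and self.pressure is None:
            raise ValueError("NPT runs need a reduced pressure")


@dataclass
class Observables:
    """Averages and samples collected during production."""

    density_mean: float
    density_se: float
    energy_per_particle: float
    acceptance_translation: float
    acceptance_volume: float
    max_energy_drift: float
    density_samples: np.ndarray
    energy_samples: np.ndarray
    volume_samples: np.ndarray
    frames: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"<rho sigma_c^3> = {self.density_mean:.5f} +- {self.density_se:.5f}\n"
            f"<Phi>/N         = {self.energy_per_particle:.5f} kBT\n"
            f"acc(transl)     = {self.acceptance_translation:.3f}\n"
            f"acc(volume)     = {self.acceptance_volume:.3f}\n"
            f"max |dE| drift  = {self.max_energy_drift:.3e}"
        )


# ---------------------------------------------------------------------------
# initial states


def fcc_init(n: int, reduced_density: float) -> Configuration:
    """Perfect FCC lattice of ``n = 4 m^3`` sites at the requested density."""
    m = round((n / 4.0) ** (1.0 / 3.0))
    if 4 * m**3 != n:
        raise ValueError(f"FCC initialisation needs N = 4 m^3 (got {n})")
    if reduced_density <= 0:
        raise ValueError("density must be positive")
    a = (4.0 / reduced_density) ** (1.0 / 3.0)
    basis = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    cells = np.array([[i, j, k] for i in range(m) for j in range(m) for k in range(m)])
    pos = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    box = np.full(3, m * a)
    return Configuration(pos, box)


# ---------------------------------------------------------------------------
# the MC engine


def _affected_sites(pos, box, x_old, x_new, i, r_cut):
    d_old = np.linalg.norm(minimum_image(pos - x_old, box), axis=1)
    d_new = np.linalg.norm(minimum_image(pos - x_new, box), axis=1)
    mask = (d_old <= r_cut) | (d_new <= r_cut)
    mask[i] = True
    return np.nonzero(mask)[0]


def mc_run(potential, params: MCParams, initial: Configuration):
    """Metropolis run; returns ``(final Configuration, Observables)``.

    Single-particle translations, plus uniform ln V volume moves in NPT
    (one attempt per N translation attempts, acceptance including the
    ``-beta P dV + (N+1) ln(V'/V)`` terms).  Translation steps are tuned
    toward the target acceptance window during equilibration only and
    frozen for production.
    """
    rng = np.random.default_rng(params.seed)
    cfg = initial.copy()
    if not cfg.periodic:
        raise ValueError("mc_run needs a periodic configuration")
    n = cfg.n_sites
    zero = getattr(potential, "is_zero", False)
    r_cut = potential.r_cut

    def check_box(box):
        if r_cut > 0 and np.any(box < 2.0 * r_cut):
            raise RuntimeError("box shrank below 2 R_c during NPT; aborting")

    check_box(cfg.box)
    site_e = potential.site_energies(cfg) if not zero else np.zeros(n)
    e_total = float(site_e.sum())
    max_disp = params.max_disp
    max_drift = 0.0
    acc_t = att_t = acc_v = att_v = 0
    density_samples, energy_samples, volume_samples, frames = [], [], [], []

    n_sweeps = params.n_equil_sweeps + params.n_prod_sweeps
    for sweep in range(n_sweeps):
        production = sweep >= params.n_equil_sweeps
        for _ in range(n):
            i = int(rng.integers(n))
            att_t += 1
            x_old = cfg.positions[i].copy()
            x_new = (x_old + rng.uniform(-max_disp, max_disp, 3)) % cfg.box
            if zero:
                cfg.positions[i] = x_new
                acc_t += 1
                continue
            aff = _affected_sites(cfg.positions, cfg.box, x_old, x_new, i, r_cut)
            e_old = potential.site_energies_subset(cfg, aff).sum()
            cfg.positions[i] = x_new
            e_new = potential.site_energies_subset(cfg, aff).sum()
            de = e_new - e_old
            if de <= 0.0 or rng.random() < np.exp(-de):
                e_total += de
                acc_t += 1
            else:
                cfg.positions[i] = x_old
        if params.ensemble == "npt":
            att_v += 1
            v_old = float(np.prod(cfg.box))
            lnv_new = np.log(v_old) + rng.uniform(-params.max_dlnv, params.max_dlnv)
            v_new = np.exp(lnv_new)
            scale = (v_new / v_old) ** (1.0 / 3.0)
            box_new = cfg.box * scale
            if r_cut > 0 and np.any(box_new < 2.0 * r_cut):
                pass  # reject: minimum-image validity is part of the move's domain
            else:
                pos_new = cfg.positions * scale
                trial = Configuration(pos_new, box_new)
                e_new = 0.0 if zero else float(potential.site_energies(trial).sum())
                arg = (
                    -(e_new - e_total)
                    - params.pressure * (v_new - v_old)
                    + (n + 1) * np.log(v_new / v_old)
                )
                if arg >= 0.0 or rng.random() < np.exp(arg):
                    cfg = trial
                    e_total = e_new
                    acc_v += 1
        if not production and (sweep + 1) % 50 == 0 and att_t:
            rate = acc_t / att_t
            lo, hi = params.target_acceptance
            if rate < lo:
                max_disp = max(max_disp * 0.8, 1e-3)
            elif rate > hi:
                max_disp = min(max_disp * 1.2, cfg.box.min() / 4.0)
            acc_t = att_t = 0
        if production:
            v = float(np.prod(cfg.box))
            density_samples.append(n / v)
            energy_samples.append(e_total / n)
            volume_samples.append(v)
            if params.frame_stride and (sweep - params.n_equil_sweeps) % params.frame_stride == 0:
                frames.append(cfg.copy())
            if params.check_every and (sweep + 1) % params.check_every == 0 and not zero:
                e_full = float(potential.site_energies(cfg).sum())
                denom = max(abs(e_full), 1.0)
                max_drift = max(max_drift, abs(e_full - e_total) / denom)
                e_total = e_full

    rho = np.array(density_samples)
    # crude autocorrelation-blind SE from 10 blocks
    blocks = [b.mean() for b in np.array_split(rho, 10) if b.size]
    se = float(np.std(blocks, ddof=1) / np.sqrt(len(blocks))) if len(blocks) > 1 else 0.0
    obs = Observables(
        density_mean=float(rho.mean()),
        density_se=se,
        energy_per_particle=float(np.mean(energy_samples)),
        acceptance_translation=acc_t / att_t if att_t else 0.0,
        acceptance_volume=acc_v / att_v if att_v else 0.0,
        max_energy_drift=max_drift,
        density_samples=rho,
        energy_samples=np.array(energy_samples),
        volume_samples=np.array(volume_samples),
        frames=frames,
    )
    return cfg, obs


def mc_eos(potential, pressures, n: int, params: MCParams, initial: Configuration | None = None):
    """Equation of state: NPT density ladder over reduced pressures."""
    rows = []
    cfg = initial
    for p in pressures:
        pp = MCParams(**{**params.__dict__, "ensemble": "npt", "pressure": float(p)})
        if cfg is None:
            rho0 = 0.4 * p if p > 0 else 0.05
            cfg = fcc_init(n, max(min(rho0, 0.8), 0.02))
        cfg, obs = mc_run(potential, pp, cfg)
        rows.append(
            {
                "pressure": float(p),
                "density": obs.density_mean,
                "density_se": obs.density_se,
                "energy_per_particle": obs.energy_per_particle,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structure


def radial_distribution(frames, bin_width: float = 0.05, r_max: float | None = None) -> pd.DataFrame:
    """Pair-distance histogram normalised by the ideal-gas shell count."""
    if not frames:
        raise ValueError("no frames given")
    box = frames[0].box
    if box is None:
        raise ValueError("g(r) needs periodic frames")
    limit = box.min() / 2.0
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-12:
        raise ValueError("r_max must not exceed half the smallest box edge")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    n = frames[0].n_sites
    for cfg in frames:
        ii, jj = np.triu_indices(cfg.n_sites, k=1)
        disp = minimum_image(cfg.positions[ii] - cfg.positions[jj], cfg.box)
        r = np.linalg.norm(disp, axis=1)
        h, _ = np.histogram(r, bins=edges)
        counts += h
    v = float(np.prod(box))
    rho = n / v
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = len(frames) * 0.5 * n * rho * shell
    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    return pd.DataFrame({"r": centers, "g": g, "count": counts})


# ---------------------------------------------------------------------------
# fixed-geometry scans


def _scan_config(geometry: str, separation: float, h: float) -> Configuration:
    d = separation
    fixed = np.array([[-d / 2.0, 0.0, 0.0], [d / 2.0, 0.0, 0.0]])
    if geometry == "T":
        probe = np.array([[0.0, h, 0.0]])
    elif geometry == "L":
        probe = np.array([[d / 2.0 + h, 0.0, 0.0]])
    elif geometry == "SQ":
        probe = np.array([[-d / 2.0, h, 0.0], [d / 2.0, h, 0.0]])
    else:
        raise ValueError("geometry must be 'T', 'L' or 'SQ'")
    return Configuration(np.vstack([fixed, probe]))


def geometry_scan(
    pair_model,
    many_model,
    geometry: str,
    h_values,
    separation: float = 1.88,
) -> pd.DataFrame:
    """PMF curves of rigid triplet/quartet geometries and their difference.

    Two particles are fixed at ``separation`` (in sigma_c); the probe
    particle (or probe pair for SQ) is placed at offsets ``h``.  Open
    boundaries.  ``phi3plus = phi_many - phi_pair`` isolates three- and
    higher-body contributions; it vanishes identically if the many-body
    model is effectively pairwise.
    """
    rows = []
    for h in np.asarray(h_values, dtype=float):
        cfg = _scan_config(geometry, separation, h)
        phi_pair = float(pair_model.site_energies(cfg).sum())
        phi_many = float(many_model.site_energies(cfg).sum())
        rows.append(
            {
                "h": h,
                "phi_pair": phi_pair,
                "phi_many": phi_many,
                "phi3plus": phi_many - phi_pair,
            }
        )
    return pd.DataFrame(rows)
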
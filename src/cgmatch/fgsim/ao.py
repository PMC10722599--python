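"""Colloid-polymer depletion system with an exact analytic oracle.

Hard-sphere colloids of diameter ``sigma_c`` in a reservoir of mutually
ideal polymer coils of diameter ``sigma_p = q sigma_c``.  A polymer
centre is excluded from a sphere of radius ``a = (sigma_c + sigma_p)/2``
around each colloid.  Because the polymers are ideal, their density at
any accessible point equals the reservoir density and the mean force on
colloid ``I`` is a contact-pressure integral over its exclusion sphere:

    F_I = k_B T rho_p  ∮_{S_I}  n_hat(s) [s blocked by another colloid] dS,

the blocked patches being where neighbouring exclusion spheres overlap
(depletion attraction).  For two colloids this integral has the closed
Asakura-Oosawa form, used as the oracle throughout; for small size
ratios (q <= 0.14) the many-colloid force is exactly pairwise additive.

Lengths in sigma_c, energies in k_B T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Configuration, minimum_image
from ..forcematch import MeanForceDataset
from .nanoparticle import fibonacci_sphere, _random_rotation

__all__ = [
    "AOParams",
    "ao_analytic_depletion",
    "ao_analytic_pair_force",
    "ao_mean_forces",
    "ao_pair_dataset",
    "random_colloid_cluster",
    "ao_cluster_dataset",
]


@dataclass(frozen=True)
class AOParams:
    """Colloid-polymer mixture parameters.

    ``q = sigma_p / sigma_c`` is the polymer-to-colloid size ratio and
    ``eta_p_r`` the polymer packing fraction of the reservoir.
    """

    q: float = 1.0
    eta_p_r: float = 0.5
    sigma_c: float = 1.0
    eta_c: float | None = None

    def __post_init__(self) -> None:
        if self.q <= 0 or self.sigma_c <= 0 or self.eta_p_r < 0:
            raise ValueError("q and sigma_c must be positive, eta_p_r non-negative")

    @property
    def sigma_p(self) -> float:
        return self.q * self.sigma_c

    @property
    def exclusion_radius(self) -> float:
        """Centre-of-polymer exclusion radius a = (sigma_c + sigma_p)/2."""
        return 0.5 * (self.sigma_c + self.sigma_p)

    @property
    def rho_p(self) -> float:
        """Reservoir polymer number density."""
        return 6.0 * self.eta_p_r / (np.pi * self.sigma_p**3)

    @property
    def range_(self) -> float:
        """Outer edge of the depletion attraction, (1 + q) sigma_c."""
        return (1.0 + self.q) * self.sigma_c


def ao_analytic_depletion(r, ao: AOParams):
    """Closed-form two-body depletion potential beta W(r), in k_B T.

    Hard-core infinite below sigma_c, zero beyond (1+q) sigma_c, and the
    overlap-volume cubic in between.
    """
    r = np.asarray(r, dtype=float)
    q, sc = ao.q, ao.sigma_c
    pref = ao.eta_p_r * (1.0 + q) ** 3 / q**3
    x = r / sc
    w = -pref * (1.0 - 3.0 * x / (2.0 * (1.0 + q)) + x**3 / (2.0 * (1.0 + q) ** 3))
    out = np.where(r >= ao.range_, 0.0, w)
    out = np.where(r < sc, np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def ao_analytic_pair_force(r, ao: AOParams):
    """Radial mean force -dW/dr of the depletion pair potential (k_B T/sigma_c).

    Negative (attractive) throughout the depletion range; zero outside.
    """
    r = np.asarray(r, dtype=float)
    a = ao.exclusion_radius
    f = -ao.rho_p * np.pi * (a**2 - r**2 / 4.0)
    out = np.where((r >= ao.sigma_c) & (r < ao.range_), f, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _surface_points(n_points: int, rng: np.random.Generator | None, method: str):
    if method == "quadrature":
        pts = fibonacci_sphere(n_points)
        if rng is not None:
            pts = pts @ _random_rotation(rng).T
        return pts
    if method == "monte-carlo":
        if rng is None:
            raise ValueError("monte-carlo integration needs a seed")
        v = rng.standard_normal((n_points, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    raise ValueError("method must be 'quadrature' or 'monte-carlo'")


def ao_mean_forces(
    config: Configuration,
    ao: AOParams,
    method: str = "quadrature",
    n_points: int = 120_000,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Mean depletion force on every colloid of a fixed configuration.

    Integrates the ideal-polymer contact pressure over each colloid's
    exclusion sphere.  ``method='quadrature'`` uses a seeded randomly
    oriented Fibonacci point set (deterministic given the seed);
    ``method='monte-carlo'`` uses uniform random surface points.
    Returns (N, 3) forces in k_B T / sigma_c.
    """
    if config.periodic and np.any(config.box < 2.0 * ao.range_):
        raise ValueError("box too small for minimum-image depletion integrals")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else (np.random.default_rng(seed) if seed is not None else None)
    )
    a = ao.exclusion_radius
    pos = config.positions
    n = config.n_sites
    forces = np.zeros((n, 3))
    pts = _surface_points(n_points, rng, method)
    weight = ao.rho_p * 4.0 * np.pi * a**2 / n_points
    for i in range(n):
        others = np.delete(np.arange(n), i)
        if others.size == 0:
            continue
        rel = minimum_image(pos[others] - pos[i], config.box)  # (M, 3)
        near = np.linalg.norm(rel, axis=1) < 2.0 * a
        rel = rel[near]
        if rel.size == 0:
            continue
        surf = a * pts  # points relative to colloid i
        d2 = ((surf[:, None, :] - rel[None, :, :]) ** 2).sum(axis=2)
        blocked = (d2 < a * a).any(axis=1)
        forces[i] = weight * pts[blocked].sum(axis=0)
    return forces


# ---------------------------------------------------------------------------
# descriptor pools matched to the depletion range


def depletion_pool(ao: AOParams, r_cut: float = 2.5, angular: bool = False):
    """Candidate descriptor pool whose resolution follows the depletion range.

    The attraction acts over a shell of width ``q sigma_c``; Gaussian
    shifts are therefore spaced at a quarter of that width across the
    interacting region (with a coarser tail out to the cutoff) and the
    width ladder extends to Gaussians a fraction of the shell wide.
    With ``angular=True`` the standard angular ladder is appended for
    many-body training sets.
    """
    from ..descriptors import CLUSTER_POOL_LAM, CLUSTER_POOL_MU_ANG, CLUSTER_POOL_XI, build_pool

    width = ao.q * ao.sigma_c
    fine = np.arange(
        max(ao.sigma_c - 0.5 * width, 0.0),
        min(ao.range_ + width, r_cut),
        width / 4.0,
    )
    coarse = np.arange(0.0, r_cut, max(width, r_cut / 15.0))
    shifts = np.unique(np.round(np.concatenate([fine, coarse]), 10))
    # widths from system-spanning down to a quarter of the shell
    mu_max = (4.0 / width) ** 2
    mus = np.concatenate([[1e-5, 1e-3], np.geomspace(1.0, mu_max, 10)])
    return build_pool(
        mus,
        shifts,
        CLUSTER_POOL_MU_ANG if angular else (),
        CLUSTER_POOL_XI if angular else (),
        CLUSTER_POOL_LAM if angular else (),
        r_cut=r_cut,
    )


# ---------------------------------------------------------------------------
# training datasets


def ao_pair_dataset(
    ao: AOParams,
    distances=None,
    n_points: int = 120_000,
    seed: int = 0,
    method: str = "quadrature",
) -> MeanForceDataset:
    """Two-colloid mean-force scan for force matching.

    Defaults to 250 separation distances spanning contact to beyond the
    depletion range, each a randomly oriented pair (descriptors are
    rotation invariant; orientations exercise the vector bookkeeping).
    """
    rng = np.random.default_rng(seed)
    if distances is None:
        distances = np.linspace(ao.sigma_c, 1.2 * ao.range_, 250)
    distances = np.asarray(distances, dtype=float)
    configs, forces = [], []
    for d in distances:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        cfg = Configuration(np.vstack([np.zeros(3), d * axis]))
        configs.append(cfg)
        forces.append(ao_mean_forces(cfg, ao, method=method, n_points=n_points, seed=rng))
    return MeanForceDataset(
        configs,
        forces,
        meta={
            "units": "kBT/sigma_c",
            "source": "ao-pair-scan",
            "q": ao.q,
            "eta_p_r": ao.eta_p_r,
            "beta": 1.0,
            "seed": seed,
        },
    )


def random_colloid_cluster(
    n: int,
    ao: AOParams,
    spread: float,
    seed: int | np.random.Generator = 0,
    max_tries: int = 20_000,
) -> Configuration:
    """Random non-overlapping colloid cluster in a sphere of radius ``spread``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos: list[np.ndarray] = []
    tries = 0
    while len(pos) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping colloids; increase spread")
        cand = rng.uniform(-spread, spread, 3)
        if np.linalg.norm(cand) > spread:
            continue
        if pos and np.min(np.linalg.norm(np.array(pos) - cand, axis=1)) < ao.sigma_c:
            continue
        pos.append(cand)
    return Configuration(np.array(pos))


def ao_cluster_dataset(
    ao: AOParams,
    n_colloids: int = 8,
    n_configs: int = 60,
    eta_range: tuple = (0.01, 0.3),
    n_points: int = 60_000,
    seed: int = 0,
    method: str = "quadrature",
) -> MeanForceDataset:
    """Mean forces for random colloid clusters at varying density.

    The cluster radius is laddered over colloid packing fractions
    ``eta_range`` so the set spans near-isolated configurations
    (vanishing forces) through dense packings with overlapping depletion
    shells.
    """
    rng = np.random.default_rng(seed)
    etas = np.linspace(eta_range[0], eta_range[1], n_configs)
    # packing fraction of n colloids in a sphere of radius R:
    # eta = n sigma^3 / (8 R^3)
    spreads = ao.sigma_c * (n_colloids / (8.0 * etas)) ** (1.0 / 3.0)
    configs, forces = [], []
    for s in spreads:
        cfg = random_colloid_cluster(n_colloids, ao, s, seed=rng)
        configs.append(cfg)
        forces.append(ao_mean_forces(cfg, ao, method=method, n_points=n_points, seed=rng))
    return MeanForceDataset(
        configs,
        forces,
        meta={
            "units": "kBT/sigma_c",
            "source": "ao-cluster",
            "q": ao.q,
            "eta_p_r": ao.eta_p_r,
            "beta": 1.0,
            "seed": seed,
        },
    )
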
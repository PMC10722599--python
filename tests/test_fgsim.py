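"""Fine-grained simulators: bead force field, constrained sampling, AO oracle."""

import numpy as np
import pytest

from cgmatch.core import Configuration
from cgmatch.fgsim import (
    AOParams,
    FGParams,
    FGSystem,
    NPGeometry,
    PMFCurve,
    ao_analytic_depletion,
    ao_analytic_pair_force,
    ao_mean_forces,
    angle_energy,
    bond_energy,
    build_nanoparticle,
    generate_training_configs,
    integrate_pmf,
    lj_energy,
    md_sample_mean_forces,
    modified_lj,
    random_colloid_cluster,
)


@pytest.fixture(scope="module")
def params():
    return FGParams.martini(0.3)


# ---------------------------------------------------------------------------
# force field


def test_wca_limit_zero_at_minimum(params):
    p0 = params.with_s(0.0)
    u, f = modified_lj(p0.r_min, p0)
    assert u == pytest.approx(0.0, abs=1e-12)
    assert f == pytest.approx(0.0, abs=1e-9)
    # purely repulsive: no negative energies anywhere
    r = np.linspace(0.8 * p0.sigma_b, p0.r_cut, 200)
    u, _ = modified_lj(r, p0)
    assert np.all(u >= -1e-12)


def test_full_lj_zero_crossing(params):
    p1 = params.with_s(1.0)
    # the unshifted LJ term vanishes at sigma_b
    assert lj_energy(p1.sigma_b, p1.sigma_b, p1.eps) == pytest.approx(0.0, abs=1e-12)
    # cut-and-shift moves the zero crossing by exactly the tail value
    u, _ = modified_lj(p1.sigma_b, p1)
    assert u == pytest.approx(-lj_energy(p1.r_cut, p1.sigma_b, p1.eps), rel=1e-10)


@pytest.mark.parametrize("s", [0.0, 0.3, 1.0])
def test_modified_lj_force_is_minus_derivative(s):
    p = FGParams.martini(s)
    h = 1e-7
    for r in np.linspace(0.4, 1.15, 25):
        u_lo, _ = modified_lj(r - h, p)
        u_hi, _ = modified_lj(r + h, p)
        _, f = modified_lj(r, p)
        assert f == pytest.approx(-(u_hi - u_lo) / (2 * h), rel=1e-6, abs=1e-8)


def test_modified_lj_continuous_at_lj_minimum_and_cutoff(params):
    for s in (0.1, 0.7):
        p = params.with_s(s)
        for r0 in (p.r_min, p.r_cut):
            u_lo, _ = modified_lj(r0 - 1e-9, p)
            u_hi, _ = modified_lj(r0 + 1e-9, p)
            assert abs(u_hi - u_lo) < 1e-6


def test_modified_lj_rejects_zero_distance(params):
    with pytest.raises(ValueError):
        modified_lj(0.0, params)


def test_bond_and_angle_equilibrium_and_symmetry(params):
    assert bond_energy(params.b0, params)[0] == 0.0
    assert angle_energy(params.theta0, params)[0] == 0.0
    for delta in (0.01, 0.1):
        assert bond_energy(params.b0 + delta, params)[0] == pytest.approx(
            bond_energy(params.b0 - delta, params)[0]
        )
        assert angle_energy(params.theta0 + delta, params)[0] == pytest.approx(
            angle_energy(params.theta0 - delta, params)[0]
        )
    # printed convention: K (x - x0)^2 without a 1/2 prefactor
    assert bond_energy(params.b0 + 0.1, params)[0] == pytest.approx(0.01 * params.k_bond)


def test_system_forces_match_energy_gradient(params):
    # random ligand-bead chain on a single nanoparticle
    geom = NPGeometry(sigma_c=1.0, n_core_beads=1, n_ligands=3, beads_per_ligand=3)
    nano = build_nanoparticle(geom, params, seed=4, relax_steps=20)
    system = FGSystem([nano], params)
    x = system.positions.copy()
    f, _ = system.forces(x)
    h = 1e-6
    num = np.zeros_like(f)
    for i in range(x.shape[0]):
        for a in range(3):
            for sign in (1.0, -1.0):
                xp = x.copy()
                xp[i, a] += sign * h
                num[i, a] -= sign * system.energy(xp) / (2 * h)
    scale = max(np.abs(num).max(), 1.0)
    assert np.abs(f - num).max() / scale < 1e-5


# ---------------------------------------------------------------------------
# nanoparticle construction


def test_full_scale_bead_count():
    geom = NPGeometry.full_scale()
    assert geom.n_beads == 1650
    assert geom.n_ligand_beads == 1375


def test_desk_scale_bead_count(params):
    geom = NPGeometry.desk_scale()
    assert geom.n_beads == 127
    nano = build_nanoparticle(geom, params, seed=1, relax_steps=0)
    assert nano.beads.shape == (126, 3)
    assert nano.graft_sites.shape == (42, 3)
    # grafting sites on the core surface
    r = np.linalg.norm(nano.graft_sites - nano.center, axis=1)
    assert np.allclose(r, geom.sigma_c / 2.0)


def test_bare_cores_exert_zero_mean_force(params):
    geom = NPGeometry(sigma_c=2.0, n_core_beads=1, n_ligands=0, beads_per_ligand=0)
    a = build_nanoparticle(geom, params, seed=0)
    b = build_nanoparticle(geom, params, center=(2.5, 0, 0), seed=1)
    system = FGSystem([a, b], params)
    mean, err, _ = md_sample_mean_forces(system, 10, 0, seed=0)
    assert np.all(mean == 0.0)  # core-core interactions are neglected


def test_symmetric_dimer_action_reaction(params):
    geom = NPGeometry(sigma_c=1.2, n_core_beads=1, n_ligands=12, beads_per_ligand=2)
    rng = np.random.default_rng(8)
    a = build_nanoparticle(geom, params, center=(0, 0, 0), seed=rng)
    b = build_nanoparticle(geom, params, center=(2.4, 0, 0), seed=rng)
    system = FGSystem([a, b], params)
    mean, err, diag = md_sample_mean_forces(system, 3000, 800, seed=3)
    tol = 4.0 * np.maximum(err[0] + err[1], 0.5)
    assert np.all(np.abs(mean[0] + mean[1]) < tol)
    # thermostat equilibrated: kinetic energy per dof near kT/2
    assert 0.35 < diag["kinetic_per_dof"] < 0.65


def test_distant_pair_mean_force_vanishes(params):
    geom = NPGeometry(sigma_c=1.2, n_core_beads=1, n_ligands=10, beads_per_ligand=2)
    rng = np.random.default_rng(9)
    # separation far beyond sigma_NP + bead cutoff: coronas cannot touch
    far = geom.sigma_np(params) + params.r_cut + 2.0
    a = build_nanoparticle(geom, params, center=(0, 0, 0), seed=rng)
    b = build_nanoparticle(geom, params, center=(far, 0, 0), seed=rng)
    system = FGSystem([a, b], params)
    mean, err, _ = md_sample_mean_forces(system, 1500, 500, seed=4)
    assert np.abs(mean).max() < np.maximum(4.0 * err, 0.5).max()


# ---------------------------------------------------------------------------
# PMF integration


def test_integrate_zero_forces_gives_zero_pmf():
    curve = integrate_pmf(PMFCurve(np.linspace(1, 2, 20), np.zeros(20)))
    assert np.all(curve.pmf == 0.0)


def test_integrate_constant_force_block():
    r = np.linspace(0.0, 3.0, 3001)
    a, b, f0 = 1.0, 2.0, -0.7
    force = np.where((r >= a) & (r <= b), f0, 0.0)
    curve = integrate_pmf(PMFCurve(r, force))
    k = np.searchsorted(r, a)
    assert curve.pmf[k] == pytest.approx(f0 * (b - a), rel=1e-3)
    assert curve.pmf[-1] == 0.0


def test_integration_recovers_analytic_pair_potential():
    # forces from a known analytic potential, integrated back
    r = np.linspace(0.9, 3.0, 800)
    phi = 4.0 * ((1.0 / r) ** 12 - (1.0 / r) ** 6) - 4.0 * ((1 / 3.0) ** 12 - (1 / 3.0) ** 6)
    force = 24.0 * (2.0 * r**-13 - r**-7)
    curve = integrate_pmf(PMFCurve(r, force))
    assert np.abs(curve.pmf - phi).max() < 5e-3  # trapezoid O(dr^2)


def test_integration_inverts_differentiation():
    r = np.linspace(1.0, 2.0, 400)
    force = np.sin(3.0 * r)
    curve = integrate_pmf(PMFCurve(r, force))
    interior = -np.gradient(curve.pmf, r)[5:-5]
    assert np.abs(interior - force[5:-5]).max() < 1e-4


# ---------------------------------------------------------------------------
# training configurations


def test_training_configs_deterministic_and_sized():
    kw = dict(n_particles=12, diameters=(12.0, 6.0), n_per_diameter=3, n_sweeps=60, seed=5)
    configs_a = generate_training_configs(**kw)
    configs_b = generate_training_configs(**kw)
    assert len(configs_a) == 6
    for ca, cb in zip(configs_a, configs_b):
        assert np.array_equal(ca.positions, cb.positions)
    assert all(c.n_sites == 12 for c in configs_a)


def test_training_ladder_spans_low_density():
    configs = generate_training_configs(
        n_particles=12, diameters=(40.0,), n_per_diameter=3, n_sweeps=60, sigma_np=2.0, seed=2
    )
    # a huge confining sphere leaves sites mostly beyond interaction range
    for cfg in configs:
        d = cfg.positions[:, None, :] - cfg.positions[None, :, :]
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert np.median(r[np.isfinite(r)]) > 2.5


# ---------------------------------------------------------------------------
# AO depletion oracle


def test_ao_analytic_hand_value():
    ao = AOParams(q=1.0, eta_p_r=0.5)
    # -0.5 * 8 * (1 - 3/4 + 1/16) = -1.25
    assert ao_analytic_depletion(1.0, ao) == pytest.approx(-1.25, abs=1e-12)
    assert ao_analytic_depletion(ao.range_, ao) == 0.0
    assert ao_analytic_depletion(0.99, ao) == np.inf
    r = np.linspace(1.0, ao.range_, 100)
    assert np.all(np.diff(ao_analytic_depletion(r, ao)) > 0)  # overlap volume shrinks


def test_ao_force_is_minus_derivative_of_potential():
    ao = AOParams(q=0.6, eta_p_r=0.8)
    r = np.linspace(1.01, ao.range_ - 0.01, 50)
    h = 1e-7
    num = -(ao_analytic_depletion(r + h, ao) - ao_analytic_depletion(r - h, ao)) / (2 * h)
    assert np.allclose(ao_analytic_pair_force(r, ao), num, rtol=1e-6)


def test_single_colloid_zero_force():
    ao = AOParams()
    cfg = Configuration(np.array([[0.0, 0, 0]]))
    assert np.all(ao_mean_forces(cfg, ao, n_points=1000) == 0.0)


def test_two_distant_colloids_zero_force():
    ao = AOParams(q=1.0, eta_p_r=0.5)
    cfg = Configuration(np.array([[0.0, 0, 0], [2.5, 0, 0]]))  # beyond (1+q) sigma_c
    assert np.all(ao_mean_forces(cfg, ao, n_points=2000) == 0.0)


def test_two_colloid_quadrature_matches_analytic_derivative():
    ao = AOParams(q=1.0, eta_p_r=0.5)
    for d in (1.0, 1.3, 1.7, 1.95):
        cfg = Configuration(np.array([[0.0, 0, 0], [d, 0, 0]]))
        F = ao_mean_forces(cfg, ao, n_points=150_000, seed=12)
        exact = ao_analytic_pair_force(d, ao)  # attractive, along -(R_I - R_J)
        assert F[0, 0] == pytest.approx(-exact, rel=0.01)
        # action-reaction to quadrature accuracy
        assert np.abs(F[0] + F[1]).max() < 0.005 * np.abs(F[0, 0])
    # small-q pairwise regime reproduces the analytic force as well
    ao_small = AOParams(q=0.1, eta_p_r=0.5)
    cfg = Configuration(np.array([[0.0, 0, 0], [1.05, 0, 0]]))
    F = ao_mean_forces(cfg, ao_small, n_points=150_000, seed=12)
    assert F[0, 0] == pytest.approx(-ao_analytic_pair_force(1.05, ao_small), rel=0.01)


def test_ao_monte_carlo_agrees_with_quadrature():
    ao = AOParams(q=1.0, eta_p_r=0.5)
    cfg = Configuration(np.array([[0.0, 0, 0], [1.4, 0, 0]]))
    fq = ao_mean_forces(cfg, ao, method="quadrature", n_points=100_000, seed=1)
    fmc = ao_mean_forces(cfg, ao, method="monte-carlo", n_points=400_000, seed=2)
    assert fmc[0, 0] == pytest.approx(fq[0, 0], rel=0.05)


def test_many_colloid_forces_pairwise_additive_at_small_q(rng):
    ao = AOParams(q=0.1, eta_p_r=0.5)
    worst = 0.0
    for k in range(3):
        cfg = random_colloid_cluster(8, ao, spread=1.6, seed=rng)
        F = ao_mean_forces(cfg, ao, n_points=200_000, seed=rng)
        Fp = np.zeros_like(F)
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                d = cfg.positions[i] - cfg.positions[j]
                r = np.linalg.norm(d)
                Fp[i] += ao_analytic_pair_force(r, ao) * d / r
        if np.linalg.norm(Fp) > 0:
            worst = max(worst, np.linalg.norm(F - Fp) / np.linalg.norm(Fp))
    assert worst <= 0.01
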
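"""Design assembly, descriptor selection, weight fitting, PMF evaluation."""

import numpy as np
import pytest

from cgmatch.core import Configuration
from cgmatch.descriptors import SymmetryFunctionSpec, build_pool
from cgmatch.forcematch import (
    ForceMatching,
    LinearCGPotential,
    MeanForceDataset,
    assemble_design,
    fit_weights,
    multiple_r2,
    pearson_r2,
    select_features,
)

from conftest import R_CUT, random_configuration


@pytest.fixture
def small_pool():
    return build_pool(
        [0.001, 1.7, 3.4, 8.6],
        [0.0, 0.5, 1.0],
        [0.1, 1.0],
        [1.0, 4.0],
        [1, -1],
        r_cut=R_CUT,
    )


@pytest.fixture
def planted(rng, small_pool):
    """Noiseless forces generated by known weights on known specs."""
    idx = [2, 7, 14]
    w = np.array([1.5, -0.8, 0.3])
    truth = LinearCGPotential([small_pool[k] for k in idx], w)
    configs, forces = [], []
    for _ in range(30):
        cfg = random_configuration(rng, spread=3.5)
        configs.append(cfg)
        forces.append(truth.predict_forces(cfg))
    return MeanForceDataset(configs, forces), idx, w, truth


# ---------------------------------------------------------------------------
# design assembly


def test_design_row_bookkeeping(small_pool):
    pair_configs = [
        Configuration(np.array([[0.0, 0, 0], [1.0 + 0.005 * k, 0, 0]])) for k in range(250)
    ]
    ds = MeanForceDataset(pair_configs, [np.zeros((2, 3))] * 250)
    assert ds.n_rows == 1500  # 2 sites x 3 components x 250 distances
    design = assemble_design(ds, small_pool[:3])
    assert design.X.shape == (1500, 3)

    twelve = [Configuration(np.random.default_rng(k).uniform(0, 5, (12, 3))) for k in range(100)]
    ds12 = MeanForceDataset(twelve, [np.zeros((12, 3))] * 100)
    assert ds12.n_rows == 3600  # 12 sites x 3 components x 100 configurations


def test_design_isolated_configuration_gives_zero_columns(small_pool):
    cfg = Configuration(np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]))
    ds = MeanForceDataset([cfg], [np.zeros((3, 3))])
    design = assemble_design(ds, small_pool)
    assert np.all(design.X == 0.0)


def test_design_rejects_unit_mismatch(small_pool):
    cfg = Configuration(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    ds = MeanForceDataset([cfg], [np.zeros((2, 3))], meta={"units": "kJ/mol/nm"})
    with pytest.raises(ValueError, match="units"):
        assemble_design(ds, small_pool)


# ---------------------------------------------------------------------------
# correlation measures


def test_pearson_r2_examples(rng):
    t = rng.normal(size=200)
    assert pearson_r2(t, t) == pytest.approx(1.0)
    assert pearson_r2(-2.0 * t, t) == pytest.approx(1.0)
    # explicitly orthogonalised column has zero correlation
    x = rng.normal(size=200)
    tc = t - t.mean()
    x = x - x.mean()
    x -= (x @ tc) / (tc @ tc) * tc
    assert pearson_r2(x, t) == pytest.approx(0.0, abs=1e-12)


def test_pearson_degenerate_column_flags_and_returns_zero():
    with pytest.warns(UserWarning, match="degenerate"):
        assert pearson_r2(np.ones(10), np.arange(10.0)) == 0.0


def test_multiple_r2_single_column_reduces_to_pearson(rng):
    x = rng.normal(size=100)
    y = 0.3 * x + rng.normal(size=100)
    assert multiple_r2(x[:, None], y) == pytest.approx(pearson_r2(x, y), abs=1e-12)


def test_multiple_r2_exact_span_is_one(rng):
    X = rng.normal(size=(50, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + 0.7
    assert multiple_r2(X, y) == pytest.approx(1.0, abs=1e-12)


def test_multiple_r2_matrix_equals_residual_route(rng):
    for _ in range(10):
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        assert multiple_r2(X, y, "matrix") == pytest.approx(
            multiple_r2(X, y, "residual"), abs=1e-10
        )


def test_multiple_r2_singular_matrix_falls_back(rng):
    x = rng.normal(size=40)
    X = np.column_stack([x, x])  # perfectly collinear
    y = x + rng.normal(size=40)
    r2 = multiple_r2(X, y, "matrix")
    assert r2 == pytest.approx(pearson_r2(x, y), abs=1e-8)


# ---------------------------------------------------------------------------
# selection


def test_single_planted_column_selected_first(planted, small_pool):
    ds, idx, w, truth = planted
    single = LinearCGPotential([small_pool[idx[0]]], [2.0])
    forces = [single.predict_forces(c) for c in ds.configs]
    design = assemble_design(MeanForceDataset(ds.configs, forces), small_pool)
    trace = select_features(design)
    assert trace.order[0] == idx[0]
    assert trace.r2_path[0] == pytest.approx(1.0, abs=1e-10)
    assert len(trace) == 1


def test_three_planted_columns_recovered(planted, small_pool):
    ds, idx, w, _ = planted
    design = assemble_design(ds, small_pool)
    trace = select_features(design, delta_r2_min=1e-8)
    assert set(trace.order) == set(idx)
    assert trace.r2_path[-1] == pytest.approx(1.0, abs=1e-8)
    assert all(b >= a - 1e-12 for a, b in zip(trace.r2_path, trace.r2_path[1:]))


def test_stopping_rule_boundary_keeps_first_pick(planted, small_pool):
    ds, _, _, _ = planted
    design = assemble_design(ds, small_pool)
    trace = select_features(design, delta_r2_min=1.0)
    assert len(trace) == 1


# ---------------------------------------------------------------------------
# fitting


def test_planted_weights_recovered(planted, small_pool):
    ds, idx, w_true, _ = planted
    res = ForceMatching(ds, small_pool).fit(delta_r2_min=1e-8)
    recovered = dict(zip(res.kept, res.params))
    for k, w in zip(idx, w_true):
        assert recovered[k] == pytest.approx(w, rel=1e-8)
    assert res.rsquared == pytest.approx(1.0, abs=1e-10)


def test_zero_model_rmse_equals_target_rms(planted, small_pool):
    ds, *_ = planted
    design = assemble_design(ds, small_pool)
    rms = float(np.sqrt(np.mean(design.y**2)))
    w, kept, diag = fit_weights(design, [0])  # single useless column
    resid = design.y - design.X[:, kept] @ w
    assert np.sqrt(np.mean(resid**2)) <= rms + 1e-12


def test_all_zero_forces_give_zero_weights(rng, small_pool):
    configs = [random_configuration(rng) for _ in range(5)]
    ds = MeanForceDataset(configs, [np.zeros((c.n_sites, 3)) for c in configs])
    res = ForceMatching(ds, small_pool).fit()
    assert np.all(res.params == 0.0)
    assert res.rmse == 0.0
    assert np.isnan(res.rsquared)


def test_rank_deficient_selection_drops_columns(rng, small_pool):
    ds_configs = [random_configuration(rng) for _ in range(10)]
    truth = LinearCGPotential([small_pool[0]], [1.0])
    ds = MeanForceDataset(ds_configs, [truth.predict_forces(c) for c in ds_configs])
    design = assemble_design(ds, small_pool)
    design.X = np.column_stack([design.X[:, 0], design.X[:, 0]])  # duplicate column
    design.pool = small_pool[:2]
    with pytest.warns(UserWarning, match="dependent"):
        w, kept, diag = fit_weights(design, [0, 1])
    assert len(kept) == 1 and diag["dropped_columns"]


# ---------------------------------------------------------------------------
# prediction and the scalar PMF


def test_isolated_particle_has_zero_force_and_pmf(small_pool):
    pot = LinearCGPotential(small_pool[:5], np.ones(5))
    cfg = Configuration(np.array([[0.0, 0, 0]]))
    assert np.all(pot.predict_forces(cfg) == 0.0)
    assert pot.energy(cfg) == 0.0


def test_symmetric_pair_forces_obey_newtons_third_law(small_pool):
    pot = LinearCGPotential(small_pool, np.linspace(-1, 1, len(small_pool)))
    cfg = Configuration(np.array([[0.0, 0, 0], [1.3, 0, 0]]))
    f = pot.predict_forces(cfg)
    assert np.abs(f[0] + f[1]).max() < 1e-10
    assert abs(f[0][1]) < 1e-12 and abs(f[0][2]) < 1e-12  # along the pair axis


def test_forces_are_minus_gradient_of_pmf(rng, small_pool):
    pot = LinearCGPotential(small_pool, rng.normal(size=len(small_pool)))
    h = 1e-6
    for _ in range(5):
        cfg = random_configuration(rng, spread=3.0)
        f = pot.predict_forces(cfg)
        num = np.zeros_like(f)
        for i in range(cfg.n_sites):
            for a in range(3):
                for sign in (1.0, -1.0):
                    pos = cfg.positions.copy()
                    pos[i, a] += sign * h
                    num[i, a] -= sign * pot.energy(Configuration(pos, cfg.box)) / (2 * h)
        scale = max(np.abs(num).max(), 1e-10)
        assert np.abs(f - num).max() / scale < 1e-5


def test_pmf_zero_beyond_cutoff(small_pool):
    pot = LinearCGPotential(small_pool, np.ones(len(small_pool)))
    cfg = Configuration(np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]]))
    assert pot.energy(cfg) == 0.0


def test_pmf_invariant_under_rigid_motions(rng, small_pool):
    pot = LinearCGPotential(small_pool, rng.normal(size=len(small_pool)))
    cfg = random_configuration(rng, n=5)
    e0 = pot.energy(cfg)
    shifted = Configuration(cfg.positions + [3.0, -1.0, 0.5])
    theta = 1.2
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    rotated = Configuration(cfg.positions @ rot.T)
    perm = Configuration(cfg.positions[rng.permutation(5)])
    for other in (shifted, rotated, perm):
        assert pot.energy(other) == pytest.approx(e0, abs=1e-10)


def test_radial_pair_model_depends_only_on_separation(rng, small_pool):
    radial = [s for s in small_pool if s.kind == "radial"]
    pot = LinearCGPotential(radial, rng.normal(size=len(radial)))
    rs = np.linspace(0.8, 2.4, 9)
    direct = pot.pair_pmf(rs)
    for k, r in enumerate(rs):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        cfg = Configuration(np.vstack([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0] + r * axis]))
        assert pot.energy(cfg) == pytest.approx(direct[k], abs=1e-10)


def test_pair_pmf_matches_integrated_mean_force(planted, small_pool):
    # the model's pair PMF must agree with trapezoid integration of its
    # own pair forces (energy-force consistency along a 1D scan)
    from cgmatch.fgsim import PMFCurve, integrate_pmf

    _, idx, w, truth = planted
    rs = np.linspace(0.7, 2.5, 400)
    f_pair = []
    for r in rs:
        cfg = Configuration(np.array([[0.0, 0, 0], [r, 0, 0]]))
        f = truth.predict_forces(cfg)
        f_pair.append(0.5 * (f[0] - f[1]) @ np.array([-1.0, 0, 0]))
    curve = integrate_pmf(PMFCurve(rs, np.array(f_pair)))
    phi_direct = truth.pair_pmf(rs)
    assert np.abs(curve.pmf - phi_direct).max() < 5e-4  # trapezoid error O(dr^2)


def test_results_summary_mentions_key_quantities(planted, small_pool):
    ds, *_ = planted
    res = ForceMatching(ds, small_pool).fit()
    text = res.summary()
    assert "R^2" in text and "RMSE" in text and "selected" in text
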
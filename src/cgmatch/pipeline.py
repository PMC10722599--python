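"""Run configuration and the end-to-end pipeline.

A single structured-text (YAML) configuration file drives the pipeline:
generate a mean-force dataset with one of the fine-grained simulators,
select and fit a linear CG model, and write report artifacts.  Every
stochastic stage derives its random stream from the global seed plus a
stage tag, so a rerun with the same configuration and seed reproduces
every artifact bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .core import Configuration
from .descriptors import build_pool, default_pair_pool, default_cluster_pool
from .forcematch import ForceMatching
from .io import write_extxyz, write_forces_table, write_model

log = logging.getLogger("cgmatch")

__all__ = ["RunConfig", "load_config", "pipeline_run", "stage_seed"]

_ALLOWED = {
    "pipeline": {"kind"},
    "geometry": {"sigma_c", "n_core_beads", "n_ligands", "beads_per_ligand"},
    "forcefield": {"s", "temperature"},
    "pool": {"preset", "r_cut", "mu", "r_shift", "mu_ang", "xi", "lam"},
    "selection": {"delta_r2_min"},
    "sampling": {
        "distances", "n_distances", "r_min", "r_max",
        "n_steps", "n_equil", "dt", "n_points", "method",
        "n_colloids", "n_configs",
    },
    "ao": {"q", "eta_p_r", "eta_c", "sigma_c"},
    "mc": {
        "ensemble", "pressure", "n_particles", "density",
        "n_equil_sweeps", "n_prod_sweeps", "max_disp", "frame_stride",
    },
}
_TOP_KEYS = set(_ALLOWED) | {"seed", "units"}


class RunConfig(dict):
    """Validated nested key-value run configuration."""

    @property
    def seed(self) -> int:
        return int(self.get("seed", 0))


def load_config(source) -> RunConfig:
    """Parse and validate a YAML run configuration (unknown keys rejected)."""
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        data = yaml.safe_load(source)
    elif isinstance(source, dict):
        data = source
    else:
        raise ValueError(f"cannot load configuration from {source!r}")
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration section(s): {sorted(unknown)}")
    for section, keys in _ALLOWED.items():
        sub = data.get(section, {})
        if not isinstance(sub, dict):
            raise ValueError(f"section [{section}] must be a mapping")
        bad = set(sub) - keys
        if bad:
            raise ValueError(f"unknown key(s) in [{section}]: {sorted(bad)}")
    return RunConfig(data)


def stage_seed(global_seed: int, tag: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and a stage tag."""
    h = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_pool(config: RunConfig):
    sec = config.get("pool", {})
    r_cut = float(sec.get("r_cut", 2.5))
    preset = sec.get("preset")
    if preset == "pair":
        return default_pair_pool(r_cut)
    if preset == "cluster":
        return default_cluster_pool(r_cut)
    if preset is not None:
        raise ValueError(f"unknown pool preset {preset!r}")
    return build_pool(
        sec.get("mu", ()),
        sec.get("r_shift", ()),
        sec.get("mu_ang", ()),
        sec.get("xi", ()),
        sec.get("lam", ()),
        r_cut=r_cut,
    )


def _make_dataset(config: RunConfig, seed: int):
    kind = config.get("pipeline", {}).get("kind", "ao")
    samp = config.get("sampling", {})
    if kind == "ao":
        from .fgsim import AOParams, ao_pair_dataset, ao_cluster_dataset

        ao = AOParams(**{k: float(v) for k, v in config.get("ao", {}).items()})
        if samp.get("n_colloids"):
            ds = ao_cluster_dataset(
                ao,
                n_colloids=int(samp["n_colloids"]),
                n_configs=int(samp.get("n_configs", 60)),
                n_points=int(samp.get("n_points", 60_000)),
                seed=seed,
            )
        else:
            n_d = int(samp.get("n_distances", 250))
            r_lo = float(samp.get("r_min", ao.sigma_c))
            r_hi = float(samp.get("r_max", 1.2 * ao.range_))
            ds = ao_pair_dataset(
                ao,
                distances=np.linspace(r_lo, r_hi, n_d),
                n_points=int(samp.get("n_points", 120_000)),
                seed=seed,
            )
        return ds, {"ao": ao}
    if kind == "np_pair":
        from .fgsim import FGParams, NPGeometry, pair_mean_force_scan

        gsec = config.get("geometry", {})
        geom = (
            NPGeometry(**{k: v for k, v in gsec.items()})
            if gsec
            else NPGeometry.desk_scale()
        )
        fsec = config.get("forcefield", {})
        params = FGParams.martini(
            float(fsec.get("s", 0.1)), float(fsec.get("temperature", 300.0))
        )
        n_d = int(samp.get("n_distances", 16))
        dists = np.linspace(
            float(samp.get("r_min", 1.05)), float(samp.get("r_max", 2.4)), n_d
        )
        curve, ds = pair_mean_force_scan(
            geom,
            params,
            dists,
            n_steps=int(samp.get("n_steps", 6000)),
            n_equil=int(samp.get("n_equil", 2000)),
            dt=float(samp.get("dt", 0.004)),
            seed=seed,
        )
        return ds, {"curve": curve, "geom": geom, "params": params}
    raise ValueError(f"unknown pipeline kind {kind!r}")


def pipeline_run(config: RunConfig | dict, outdir) -> dict:
    """Execute fgsim -> forcematch (-> reports) and write artifacts.

    Returns a manifest dict (also written as ``report.json``) recording
    the configuration hash, the seed, per-stage wall times and the
    selection-trace summary.
    """
    config = config if isinstance(config, RunConfig) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    chash = _config_hash(dict(config))
    log.info("pipeline start: config hash %s, seed %d", chash, seed)
    manifest: dict = {"config_hash": chash, "seed": seed, "stages": {}}

    t0 = time.perf_counter()
    ds, extra = _make_dataset(config, stage_seed(seed, "dataset"))
    manifest["stages"]["dataset"] = {
        "wall_s": round(time.perf_counter() - t0, 3),
        "n_configs": len(ds),
        "n_rows": ds.n_rows,
    }
    write_extxyz(ds.configs, outdir / "dataset.xyz")
    write_forces_table(ds, outdir / "forces.tsv")

    t0 = time.perf_counter()
    pool = _build_pool(config)
    delta = float(config.get("selection", {}).get("delta_r2_min", 1e-4))
    results = ForceMatching(ds, pool).fit(delta_r2_min=delta)
    potential = results.as_potential(
        meta={"config_hash": chash, "seed": seed, "source": ds.meta.get("source")}
    )
    write_model(potential, outdir / "model.json")
    (outdir / "selection.txt").write_text(results.summary() + "\n")
    manifest["stages"]["fit"] = {
        "wall_s": round(time.perf_counter() - t0, 3),
        "pool_size": len(pool),
        "n_selected": results.n_selected,
        "r_squared": results.rsquared,
        "rmse": results.rmse,
    }
    log.info(
        "fit: %d/%d descriptors, R^2=%.6f, RMSE=%.4f",
        results.n_selected, len(pool), results.rsquared, results.rmse,
    )

    kind = config.get("pipeline", {}).get("kind", "ao")
    if kind == "ao" and "ao" in extra:
        from .fgsim import ao_analytic_depletion

        ao = extra["ao"]
        grid = np.linspace(ao.sigma_c, ao.range_, 60)
        phi_ml = potential.pair_pmf(grid)
        phi_exact = ao_analytic_depletion(grid, ao)
        table = "\n".join(
            f"{r:.6f}\t{ml:.6f}\t{ex:.6f}" for r, ml, ex in zip(grid, phi_ml, phi_exact)
        )
        (outdir / "pair_pmf_vs_analytic.tsv").write_text(
            "# r/sigma_c\tphi_ml\tphi_analytic (kBT)\n" + table + "\n"
        )
        manifest["stages"]["report"] = {
            "max_abs_pmf_error": float(np.max(np.abs(phi_ml - phi_exact))),
        }
    elif kind == "np_pair" and "curve" in extra:
        from .fgsim import integrate_pmf

        curve = integrate_pmf(extra["curve"])
        phi_ml = potential.pair_pmf(curve.r)
        table = "\n".join(
            f"{r:.6f}\t{f:.6f}\t{p:.6f}\t{ml:.6f}"
            for r, f, p, ml in zip(curve.r, curve.mean_force, curve.pmf, phi_ml)
        )
        (outdir / "pair_pmf.tsv").write_text(
            "# r/sigma_c\tF_m\tphi_integrated\tphi_ml (kBT)\n" + table + "\n"
        )
        manifest["stages"]["report"] = {
            "pmf_minimum": float(np.min(curve.pmf)),
            "pmf_min_location": float(curve.r[int(np.argmin(curve.pmf))]),
        }
    (outdir / "report.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
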
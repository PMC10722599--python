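"""Plain-text formats: extended XYZ, mean-force tables, model files.

Every numeric file carries its unit system in a header and the loaders
enforce it; floating-point values are written with 17 significant
digits so write -> read round trips are bit exact.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Configuration
from .forcematch import LinearCGPotential, MeanForceDataset

__all__ = [
    "read_extxyz",
    "write_extxyz",
    "read_forces_table",
    "write_forces_table",
    "read_model",
    "write_model",
]


def _fmt(x: float) -> str:
    return f"{float(x):.17g}"


class ExtXYZError(ValueError):
    """Malformed extended-XYZ input, annotated with the offending line."""


# ---------------------------------------------------------------------------
# extended XYZ


_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def write_extxyz(configs, path) -> None:
    """Write configurations as extended XYZ frames.

    Periodic frames record ``Lattice`` (orthorhombic, diagonal) and
    ``pbc="T T T"``; open cluster geometries omit the lattice record.
    """
    if isinstance(configs, Configuration):
        configs = [configs]
    lines = []
    for cfg in configs:
        lines.append(str(cfg.n_sites))
        fields = []
        if cfg.periodic:
            lx, ly, lz = (_fmt(v) for v in cfg.box)
            fields.append(f'Lattice="{lx} 0 0 0 {ly} 0 0 0 {lz}"')
            fields.append('pbc="T T T"')
        else:
            fields.append('pbc="F F F"')
        fields.append("Properties=species:S:1:pos:R:3")
        lines.append(" ".join(fields))
        for sp, p in zip(cfg.species, cfg.positions):
            lines.append(f"{sp} {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_extxyz(path) -> list[Configuration]:
    """Read all frames of an extended-XYZ file."""
    raw = Path(path).read_text().splitlines()
    configs: list[Configuration] = []
    ln = 0
    while ln < len(raw):
        if not raw[ln].strip():
            ln += 1
            continue
        try:
            n = int(raw[ln].strip())
        except ValueError as exc:
            raise ExtXYZError(f"line {ln + 1}: expected an atom count") from exc
        if ln + 1 >= len(raw):
            raise ExtXYZError(f"line {ln + 2}: missing comment line")
        comment = raw[ln + 1]
        kv = {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
              for m in _KV_RE.finditer(comment)}
        box = None
        if "Lattice" in kv:
            vals = np.array([float(v) for v in kv["Lattice"].split()])
            if vals.size != 9:
                raise ExtXYZError(f"line {ln + 2}: Lattice needs 9 components")
            mat = vals.reshape(3, 3)
            if np.any(mat - np.diag(np.diag(mat)) != 0.0):
                raise ExtXYZError(f"line {ln + 2}: only orthorhombic lattices supported")
            box = np.diag(mat).copy()
        species, pos = [], []
        for k in range(n):
            idx = ln + 2 + k
            if idx >= len(raw):
                raise ExtXYZError(f"line {idx + 1}: truncated frame (expected {n} atoms)")
            parts = raw[idx].split()
            if len(parts) < 4:
                raise ExtXYZError(f"line {idx + 1}: expected 'species x y z'")
            species.append(parts[0])
            try:
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ExtXYZError(f"line {idx + 1}: bad coordinate") from exc
        configs.append(Configuration(np.array(pos), box, species))
        ln += 2 + n
    return configs


# ---------------------------------------------------------------------------
# mean-force tables


def write_forces_table(dataset: MeanForceDataset, path) -> None:
    """Tab-separated mean forces: one row per (frame, site), with a unit header."""
    lines = [
        f"# units={dataset.meta.get('units', 'kBT/sigma_c')}",
        f"# beta={_fmt(dataset.meta.get('beta', 1.0))}",
        f"# source={dataset.meta.get('source', 'unknown')}",
        "frame\tsite\tfx\tfy\tfz",
    ]
    for fi, f in enumerate(dataset.forces):
        for si, row in enumerate(f):
            lines.append(
                f"{fi}\t{si}\t{_fmt(row[0])}\t{_fmt(row[1])}\t{_fmt(row[2])}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_forces_table(path, configs) -> MeanForceDataset:
    """Load a mean-force table against its configurations.

    ``configs`` is a list of :class:`Configuration` or a path to the
    matching extended-XYZ file.  Loading refuses tables without a unit
    header (silent unit bugs are worse than a crash).
    """
    text = Path(path).read_text().splitlines()
    meta: dict = {}
    body_start = 0
    for k, line in enumerate(text):
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)=(.*)", line)
            if m:
                key, val = m.group(1), m.group(2).strip()
                meta[key] = float(val) if key == "beta" else val
        else:
            body_start = k
            break
    if "units" not in meta:
        raise ValueError(f"{path}: missing '# units=' header; refusing to load")
    if isinstance(configs, (str, Path)):
        configs = read_extxyz(configs)
    df = pd.read_csv(
        Path(path),
        sep="\t",
        skiprows=body_start,
        float_precision="round_trip",
    )
    expected = {"frame", "site", "fx", "fy", "fz"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    if df.empty:
        raise ValueError(f"{path}: empty mean-force table")
    forces = []
    for fi, cfg in enumerate(configs):
        sub = df[df["frame"] == fi].sort_values("site")
        if len(sub) != cfg.n_sites:
            raise ValueError(
                f"{path}: frame {fi} has {len(sub)} rows for {cfg.n_sites} sites"
            )
        forces.append(sub[["fx", "fy", "fz"]].to_numpy())
    return MeanForceDataset([c.copy() for c in configs], forces, meta=meta)


# ---------------------------------------------------------------------------
# model files


def write_model(potential: LinearCGPotential, path) -> None:
    """Versioned structured-text (JSON) model file; bit-exact round trip."""
    Path(path).write_text(json.dumps(potential.to_dict(), indent=1) + "\n")


def read_model(path) -> LinearCGPotential:
    return LinearCGPotential.from_dict(json.loads(Path(path).read_text()))
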
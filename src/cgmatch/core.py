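"""Particle configurations and periodic-geometry utilities.

All lengths are expressed in reduced units of the coarse-grained core
diameter ``sigma_c`` and all energies in units of ``k_B T`` unless a
function explicitly says otherwise.  A :class:`Configuration` is either
periodic in an orthorhombic box or "open" (``box is None``), the latter
being used for cluster geometries such as fixed triplet/quartet scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Configuration", "minimum_image", "pair_table", "DegenerateGeometryError"]

#: pair distances below this (in sigma_c) are treated as coincident particles
DEGENERATE_DISTANCE = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when two particles (quasi-)coincide inside a cutoff sphere."""


@dataclass
class Configuration:
    """Positions of N sites, optionally in a periodic orthorhombic box.

    Parameters
    ----------
    positions : (N, 3) array
        Site coordinates in units of sigma_c.
    box : (3,) array or None
        Orthorhombic edge lengths; ``None`` marks an open (non-periodic)
        cluster geometry.
    species : sequence of str, optional
        Per-site labels, kept only for I/O round trips.
    """

    positions: np.ndarray
    box: np.ndarray | None = None
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.positions.shape[0] < 1:
            raise ValueError("a configuration needs at least one site")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box is not None:
            self.box = np.ascontiguousarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must hold three positive edge lengths")
        if not self.species:
            self.species = ["X"] * len(self.positions)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def periodic(self) -> bool:
        return self.box is not None

    def copy(self) -> "Configuration":
        box = None if self.box is None else self.box.copy()
        return Configuration(self.positions.copy(), box, list(self.species))


def minimum_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box."""
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def _check_box(box: np.ndarray | None, r_cut: float) -> None:
    if box is not None and np.any(box < 2.0 * r_cut):
        raise ValueError(
            f"minimum-image convention requires every box edge >= 2 R_c "
            f"(box={box}, R_c={r_cut}); this would silently double count"
        )


def pair_table(config: Configuration, r_cut: float):
    """All pairs (i < j) within ``r_cut``, with minimum-image displacements.

    Returns
    -------
    i, j : (P,) int arrays
    disp : (P, 3) array
        ``R_i - R_j`` under minimum image.
    r : (P,) array
        Pair distances.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    _check_box(config.box, r_cut)
    pos = config.positions
    n = pos.shape[0]
    if n < 2:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty, np.empty((0, 3)), np.empty(0)
    ii, jj = np.triu_indices(n, k=1)
    disp = minimum_image(pos[ii] - pos[jj], config.box)
    r = np.linalg.norm(disp, axis=1)
    mask = r <= r_cut
    ii, jj, disp, r = ii[mask], jj[mask], disp[mask], r[mask]
    if np.any(r < DEGENERATE_DISTANCE):
        raise DegenerateGeometryError(
            "coincident particles inside the cutoff sphere"
        )
    return ii, jj, disp, r


def neighbors_of(config: Configuration, index: int, r_cut: float):
    """Neighbors of one site within ``r_cut``: indices, displacements R_I - R_J, distances."""
    _check_box(config.box, r_cut)
    pos = config.positions
    disp = minimum_image(pos[index] - pos, config.box)
    r = np.linalg.norm(disp, axis=1)
    mask = (r <= r_cut) & (np.arange(pos.shape[0]) != index)
    if np.any(r[mask] < DEGENERATE_DISTANCE):
        raise DegenerateGeometryError(
            "coincident particles inside the cutoff sphere"
        )
    idx = np.nonzero(mask)[0]
    return idx, disp[idx], r[idx]
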
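"""Behler-Parrinello symmetry functions and their analytic gradients.

Two descriptor families characterise the local environment of a particle
``I`` inside a cutoff sphere of radius ``R_c``:

* radial:  ``G2(I) = sum_{J != I} exp(-mu (R_IJ - R_s)^2) f_c(R_IJ)``
* angular: ``G3(I) = 2^(1-xi) sum_{J<K} (1 + lam cos th_IJK)^xi
  exp(-mu_a (R_IJ^2 + R_IK^2 + R_JK^2)) f_c(R_IJ) f_c(R_IK) f_c(R_JK)``

with the smooth cutoff ``f_c(r) = [cos(pi r / R_c) + 1] / 2`` for
``r <= R_c`` and zero beyond, which decays to zero in both value and
slope at ``R_c``.  The angle ``th_IJK`` sits at vertex ``I``.

Both values and the full gradient tensor ``d G_J(K) / d R_I`` are
evaluated analytically; the gradients are what the force-matching
regression uses as basis functions, so they are checked against central
finite differences in the test suite.  Vector convention:
``R_IJ = R_I - R_J``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import product

import numpy as np

from .core import Configuration, pair_table

__all__ = [
    "SymmetryFunctionSpec",
    "cutoff_value",
    "radial_sf",
    "angular_sf",
    "descriptor_table",
    "site_descriptors",
    "sf_gradients",
    "descriptor_force_columns",
    "isolated_reference",
    "build_pool",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SymmetryFunctionSpec:
    """Parameters of one symmetry function.

    Radial specs set (``mu``, ``r_shift``); angular specs set
    (``mu_ang``, ``xi``, ``lam``).  Lengths in sigma_c, inverse-square
    lengths in 1/sigma_c^2.
    """

    kind: str
    r_cut: float
    mu: float | None = None
    r_shift: float | None = None
    mu_ang: float | None = None
    xi: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("radial", "angular"):
            raise ValueError(f"unknown symmetry-function kind {self.kind!r}")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.kind == "radial":
            if self.mu is None or self.r_shift is None:
                raise ValueError("radial spec needs mu and r_shift")
            if self.mu < 0 or self.r_shift < 0:
                raise ValueError("mu and r_shift must be non-negative")
            if self.mu_ang is not None or self.xi is not None or self.lam is not None:
                raise ValueError("radial spec must leave angular fields unset")
        else:
            if self.mu_ang is None or self.xi is None or self.lam is None:
                raise ValueError("angular spec needs mu_ang, xi and lam")
            if self.mu_ang < 0:
                raise ValueError("mu_ang must be non-negative")
            if self.xi <= 0:
                raise ValueError("xi must be positive")
            if self.lam not in (-1.0, 1.0, -1, 1):
                raise ValueError("lam must be +1 or -1")
            if self.mu is not None or self.r_shift is not None:
                raise ValueError("angular spec must leave radial fields unset")

    @classmethod
    def radial(cls, mu: float, r_shift: float, r_cut: float) -> "SymmetryFunctionSpec":
        return cls(kind="radial", r_cut=r_cut, mu=mu, r_shift=r_shift)

    @classmethod
    def angular(cls, mu_ang: float, xi: float, lam: float, r_cut: float) -> "SymmetryFunctionSpec":
        return cls(kind="angular", r_cut=r_cut, mu_ang=mu_ang, xi=xi, lam=float(lam))

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryFunctionSpec":
        return cls(**d)


def build_pool(
    mu_values=(),
    r_shift_values=(),
    mu_ang_values=(),
    xi_values=(),
    lam_values=(),
    *,
    r_cut: float,
) -> list[SymmetryFunctionSpec]:
    """Cartesian-product pool of candidate descriptors at a common cutoff.

    Radial candidates come from ``mu_values x r_shift_values`` and angular
    ones from ``mu_ang_values x lam_values x xi_values``; duplicates are
    dropped while preserving first-seen order.
    """
    pool: list[SymmetryFunctionSpec] = []
    seen = set()
    for mu, rs in product(mu_values, r_shift_values):
        spec = SymmetryFunctionSpec.radial(float(mu), float(rs), r_cut)
        if spec not in seen:
            seen.add(spec)
            pool.append(spec)
    for mu_a, lam, xi in product(mu_ang_values, lam_values, xi_values):
        spec = SymmetryFunctionSpec.angular(float(mu_a), float(xi), float(lam), r_cut)
        if spec not in seen:
            seen.add(spec)
            pool.append(spec)
    if not pool:
        raise ValueError("parameter lists produced an empty pool")
    return pool


#: radial-width pool used for two-particle training sets (1/sigma_c^2)
PAIR_POOL_MU = (
    0.00001, 0.0001, 0.001, 1.715, 3.429, 5.144, 6.858, 8.572, 10.286,
    12.000, 13.715, 15.429, 17.143, 18.857, 20.572, 22.286, 24.000,
    26.000, 28.000, 30.000, 32.000, 34.000,
)
#: radial-shift pool for two-particle training sets (sigma_c)
PAIR_POOL_R_SHIFT = tuple(np.round(np.arange(0.0, 1.5, 0.1), 1))

#: radial widths for many-particle (cluster) training sets
CLUSTER_POOL_MU = (0.001, 1.715, 3.429, 5.144, 6.858, 8.572, 10.286, 12.000, 13.715, 15.429)
CLUSTER_POOL_R_SHIFT = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
CLUSTER_POOL_MU_ANG = (0.0001, 0.001, 0.01, 0.1, 1.0, 2.0, 4.0, 8.0)
CLUSTER_POOL_XI = (1.0, 4.0, 8.0, 12.0)
CLUSTER_POOL_LAM = (1.0, -1.0)


def default_pair_pool(r_cut: float = 2.5) -> list[SymmetryFunctionSpec]:
    """Radial-only candidate pool for two-body force matching (330 specs)."""
    return build_pool(PAIR_POOL_MU, PAIR_POOL_R_SHIFT, r_cut=r_cut)


def default_cluster_pool(r_cut: float = 2.5) -> list[SymmetryFunctionSpec]:
    """Radial + angular candidate pool for many-body force matching (164 specs)."""
    return build_pool(
        CLUSTER_POOL_MU,
        CLUSTER_POOL_R_SHIFT,
        CLUSTER_POOL_MU_ANG,
        CLUSTER_POOL_XI,
        CLUSTER_POOL_LAM,
        r_cut=r_cut,
    )


# ---------------------------------------------------------------------------
# cutoff function


def cutoff_value(r, r_cut: float):
    """Smooth cosine cutoff; zero in value and slope at ``r = r_cut``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or r_cut <= 0:
        raise ValueError("require r >= 0 and r_cut > 0")
    out = np.where(r <= r_cut, 0.5 * (np.cos(np.pi * np.minimum(r, r_cut) / r_cut) + 1.0), 0.0)
    return out if out.ndim else float(out)


def _fc(r: np.ndarray, r_cut) -> np.ndarray:
    """Cutoff values, broadcasting distances against per-spec cutoffs."""
    x = np.minimum(r / r_cut, 1.0)
    return np.where(r <= r_cut, 0.5 * (np.cos(np.pi * x) + 1.0), 0.0)


def _dfc(r: np.ndarray, r_cut) -> np.ndarray:
    x = r / r_cut
    return np.where(r <= r_cut, -0.5 * np.pi / r_cut * np.sin(np.pi * np.minimum(x, 1.0)), 0.0)


# ---------------------------------------------------------------------------
# spec bookkeeping


def _split_specs(specs):
    rad = [(k, s) for k, s in enumerate(specs) if s.kind == "radial"]
    ang = [(k, s) for k, s in enumerate(specs) if s.kind == "angular"]

    def cols(items, names):
        if not items:
            return np.empty(0, dtype=np.intp), {n: np.empty(0) for n in names}
        idx = np.array([k for k, _ in items], dtype=np.intp)
        arr = {n: np.array([getattr(s, n) for _, s in items], dtype=float) for n in names}
        return idx, arr

    ridx, rpar = cols(rad, ("mu", "r_shift", "r_cut"))
    aidx, apar = cols(ang, ("mu_ang", "xi", "lam", "r_cut"))
    return ridx, rpar, aidx, apar


def _max_cut(specs) -> float:
    return max(s.r_cut for s in specs)


# ---------------------------------------------------------------------------
# pair / triplet kernels (shared by values, gradients and force columns)


def _radial_terms(r, rpar, with_derivative=False):
    """Per-(pair, radial spec) values t and optionally dt/dr."""
    rr = r[:, None]
    mu, rs, rc = rpar["mu"][None, :], rpar["r_shift"][None, :], rpar["r_cut"][None, :]
    gauss = np.exp(-mu * (rr - rs) ** 2)
    fc = _fc(rr, rc)
    val = gauss * fc
    if not with_derivative:
        return val, None
    dval = gauss * (_dfc(rr, rc) - 2.0 * mu * (rr - rs) * fc)
    return val, dval


def _triplet_list(n: int, i: np.ndarray, j: np.ndarray, disp: np.ndarray, r: np.ndarray):
    """Enumerate triplets (center C, neighbours J < K) from a pair table.

    Returns center indices, neighbour indices, displacements a = R_C - R_J
    and b = R_C - R_K, and the three distances.
    """
    di = np.concatenate([i, j])
    dj = np.concatenate([j, i])
    dd = np.concatenate([disp, -disp])
    dr = np.concatenate([r, r])
    order = np.argsort(di, kind="stable")
    di, dj, dd, dr = di[order], dj[order], dd[order], dr[order]
    counts = np.bincount(di, minlength=n)
    starts = np.concatenate([[0], np.cumsum(counts)])

    combo_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    cs, p1s, p2s = [], [], []
    for c in range(n):
        k = counts[c]
        if k < 2:
            continue
        if k not in combo_cache:
            combo_cache[k] = np.triu_indices(k, k=1)
        u, v = combo_cache[k]
        base = starts[c]
        cs.append(np.full(u.size, c, dtype=np.intp))
        p1s.append(base + u)
        p2s.append(base + v)
    if not cs:
        z = np.empty(0, dtype=np.intp)
        return z, z, z, np.empty((0, 3)), np.empty((0, 3)), np.empty(0), np.empty(0), np.empty(0)
    carr = np.concatenate(cs)
    p1 = np.concatenate(p1s)
    p2 = np.concatenate(p2s)
    jn, kn = dj[p1], dj[p2]
    a, b = dd[p1], dd[p2]
    r1, r2 = dr[p1], dr[p2]
    r3 = np.linalg.norm(b - a, axis=1)
    return carr, jn, kn, a, b, r1, r2, r3


def _angular_terms(r1, r2, r3, cos_th, apar, with_derivative=False):
    """Per-(triplet, angular spec) values and the pieces of their gradients.

    Returns (val, dA * g, A * dg/dr1, A * dg/dr2, A * dg/dr3) where
    ``A`` is the angular factor and ``g`` the radial weight product; the
    derivative pieces are ``None`` unless requested.
    """
    mu_a = apar["mu_ang"][None, :]
    xi = apar["xi"][None, :]
    lam = apar["lam"][None, :]
    rc = apar["r_cut"][None, :]

    def w(rr):
        rr = rr[:, None]
        return np.exp(-mu_a * rr**2) * _fc(rr, rc)

    def dw(rr):
        rr = rr[:, None]
        e = np.exp(-mu_a * rr**2)
        return e * (_dfc(rr, rc) - 2.0 * mu_a * rr * _fc(rr, rc))

    w1, w2, w3 = w(r1), w(r2), w(r3)
    g = w1 * w2 * w3
    base = 1.0 + lam * cos_th[:, None]
    base = np.maximum(base, 0.0)  # clamp guards rounding at cos = -lam
    pref = 2.0 ** (1.0 - xi)
    A = pref * base**xi
    val = A * g
    if not with_derivative:
        return val, None, None, None, None
    dA = pref * lam * xi * base ** (xi - 1.0)
    return val, dA * g, A * dw(r1) * w2 * w3, A * w1 * dw(r2) * w3, A * w1 * w2 * dw(r3)


def _cos_theta(a, b, r1, r2):
    c = np.einsum("ij,ij->i", a, b) / (r1 * r2)
    return np.clip(c, -1.0, 1.0)


# ---------------------------------------------------------------------------
# public evaluation


def descriptor_table(config: Configuration, specs) -> np.ndarray:
    """Values of every descriptor on every particle, shape (N, n_specs)."""
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    ridx, rpar, aidx, apar = _split_specs(specs)
    n = config.n_sites
    table = np.zeros((n, len(specs)))
    i, j, disp, r = pair_table(config, _max_cut(specs))
    if r.size and ridx.size:
        val, _ = _radial_terms(r, rpar)
        sub = np.zeros((n, ridx.size))
        np.add.at(sub, i, val)
        np.add.at(sub, j, val)
        table[:, ridx] = sub
    if r.size and aidx.size:
        c, _, _, a, b, r1, r2, r3 = _triplet_list(n, i, j, disp, r)
        if c.size:
            cth = _cos_theta(a, b, r1, r2)
            val, *_ = _angular_terms(r1, r2, r3, cth, apar)
            sub = np.zeros((n, aidx.size))
            np.add.at(sub, c, val)
            table[:, aidx] = sub
    return table


def site_descriptors(config: Configuration, specs, centers) -> np.ndarray:
    """Descriptor rows for a subset of centers only (local MC updates).

    Semantically identical to ``descriptor_table(config, specs)[centers]``
    but touches only pairs and triplets involving the requested centers.
    """
    from .core import neighbors_of

    specs = list(specs)
    centers = np.atleast_1d(np.asarray(centers, dtype=np.intp))
    ridx, rpar, aidx, apar = _split_specs(specs)
    rows = np.zeros((centers.size, len(specs)))
    rc = _max_cut(specs)
    for row, cidx in enumerate(centers):
        idx, disp, r = neighbors_of(config, int(cidx), rc)
        if r.size == 0:
            continue
        if ridx.size:
            val, _ = _radial_terms(r, rpar)
            rows[row, ridx] = val.sum(axis=0)
        if aidx.size and r.size >= 2:
            u, v = np.triu_indices(r.size, k=1)
            a, b = disp[u], disp[v]
            r1, r2 = r[u], r[v]
            r3 = np.linalg.norm(b - a, axis=1)
            cth = _cos_theta(a, b, r1, r2)
            val, *_ = _angular_terms(r1, r2, r3, cth, apar)
            rows[row, aidx] = val.sum(axis=0)
    return rows


def radial_sf(config: Configuration, center: int, spec: SymmetryFunctionSpec) -> float:
    """Value of one radial symmetry function centred on ``center``."""
    if spec.kind != "radial":
        raise ValueError("spec must be radial")
    return float(site_descriptors(config, [spec], [center])[0, 0])


def angular_sf(config: Configuration, center: int, spec: SymmetryFunctionSpec) -> float:
    """Value of one angular symmetry function centred on ``center``."""
    if spec.kind != "angular":
        raise ValueError("spec must be angular")
    return float(site_descriptors(config, [spec], [center])[0, 0])


def isolated_reference(specs) -> np.ndarray:
    """Descriptor values of an isolated particle (empty neighbour sums)."""
    return np.zeros(len(list(specs)))


def sf_gradients(config: Configuration, specs) -> np.ndarray:
    """Dense gradient tensor ``grad[K, I, J, :] = d G_J(K) / d R_I``.

    Intended for small configurations (tests, finite-difference checks,
    cluster scans); memory grows as N^2 x n_specs.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    ridx, rpar, aidx, apar = _split_specs(specs)
    n = config.n_sites
    grad = np.zeros((n, n, len(specs), 3))
    i, j, disp, r = pair_table(config, _max_cut(specs))
    if r.size == 0:
        return grad
    if ridx.size:
        _, dval = _radial_terms(r, rpar, with_derivative=True)
        u = disp / r[:, None]
        # contribution of pair (i, j): d t / d R_i = dval * u, d t / d R_j = -dval * u
        contrib = dval[:, :, None] * u[:, None, :]  # (P, Sr, 3)
        sub = np.zeros((n, n, ridx.size, 3))
        np.add.at(sub, (i, i), contrib)
        np.add.at(sub, (i, j), -contrib)
        np.add.at(sub, (j, j), -contrib)
        np.add.at(sub, (j, i), contrib)
        grad[:, :, ridx, :] = sub
    if aidx.size:
        c, jn, kn, a, b, r1, r2, r3 = _triplet_list(n, i, j, disp, r)
        if c.size:
            gI, gJ, gK = _angular_triplet_gradients(a, b, r1, r2, r3, apar)
            sub = np.zeros((n, n, aidx.size, 3))
            np.add.at(sub, (c, c), gI)
            np.add.at(sub, (c, jn), gJ)
            np.add.at(sub, (c, kn), gK)
            grad[:, :, aidx, :] = sub
    return grad


def _angular_triplet_gradients(a, b, r1, r2, r3, apar):
    """Gradients of one angular triplet term w.r.t. R_I, R_J, R_K.

    Shapes (T, Sa, 3).  ``a = R_I - R_J``, ``b = R_I - R_K``.
    """
    cth = _cos_theta(a, b, r1, r2)
    _, dAg, Adg1, Adg2, Adg3 = _angular_terms(r1, r2, r3, cth, apar, with_derivative=True)
    u1 = a / r1[:, None]
    u2 = b / r2[:, None]
    u3 = (b - a) / r3[:, None]  # direction of R_J - R_K
    inv12 = 1.0 / (r1 * r2)
    # dcos/dR for the three vertices
    dc_I = (a + b) * inv12[:, None] - cth[:, None] * (a / r1[:, None] ** 2 + b / r2[:, None] ** 2)
    dc_J = -b * inv12[:, None] + cth[:, None] * a / r1[:, None] ** 2
    dc_K = -a * inv12[:, None] + cth[:, None] * b / r2[:, None] ** 2

    def outer(coef, vec):
        return coef[:, :, None] * vec[:, None, :]

    gI = outer(dAg, dc_I) + outer(Adg1, u1) + outer(Adg2, u2)
    gJ = outer(dAg, dc_J) - outer(Adg1, u1) + outer(Adg3, u3)
    gK = outer(dAg, dc_K) - outer(Adg2, u2) - outer(Adg3, u3)
    return gI, gJ, gK


def descriptor_force_columns(config: Configuration, specs) -> np.ndarray:
    """Force basis ``out[I, :, J] = -sum_K d G_J(K) / d R_I``, shape (N, 3, S).

    These are the regression columns of the linear force model: the force
    on site ``I`` predicted by weights ``w`` is ``out @ w``.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    ridx, rpar, aidx, apar = _split_specs(specs)
    n = config.n_sites
    out = np.zeros((n, 3, len(specs)))
    i, j, disp, r = pair_table(config, _max_cut(specs))
    if r.size == 0:
        return out
    if ridx.size:
        _, dval = _radial_terms(r, rpar, with_derivative=True)
        u = disp / r[:, None]
        # moving i changes both G(i) and G(j) by the same dval along u
        contrib = 2.0 * dval[:, :, None] * u[:, None, :]  # (P, Sr, 3)
        sub = np.zeros((n, len(ridx), 3))
        np.add.at(sub, i, -contrib)
        np.add.at(sub, j, contrib)
        out[:, :, ridx] = sub.transpose(0, 2, 1)
    if aidx.size:
        c, jn, kn, a, b, r1, r2, r3 = _triplet_list(n, i, j, disp, r)
        if c.size:
            gI, gJ, gK = _angular_triplet_gradients(a, b, r1, r2, r3, apar)
            sub = np.zeros((n, len(aidx), 3))
            np.add.at(sub, c, -gI)
            np.add.at(sub, jn, -gJ)
            np.add.at(sub, kn, -gK)
            out[:, :, aidx] = sub.transpose(0, 2, 1)
    return out
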
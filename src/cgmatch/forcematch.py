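"""Linear force matching of coarse-grained mean forces.

The mean force on CG site ``I`` is modelled linearly in the gradients of
symmetry functions,

    F_{I,a} = - sum_K sum_J w_J  dG_J(K) / dR_{I,a},

so a weight vector ``w`` is obtained by ordinary least squares of the
sampled mean-force components on the descriptor-gradient columns.  The
linearity gives the scalar many-body potential of mean force in closed
form,

    Phi(R^N) = sum_K sum_J w_J [ G_J(K) - G_J(isolated) ],

with the infinite-dilution state as the zero of free energy (no
intercept anywhere: mean forces vanish on an isolated particle).

Descriptor columns are picked from a large candidate pool by greedy
forward selection: the first pick maximises the squared Pearson
correlation with the force components, each later pick maximises the
increase of the squared coefficient of multiple correlation, and
selection stops when the best available increase falls below
``delta_r2_min``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Configuration
from .descriptors import (
    SymmetryFunctionSpec,
    descriptor_force_columns,
    descriptor_table,
    isolated_reference,
)

__all__ = [
    "MeanForceDataset",
    "DesignMatrix",
    "SelectionTrace",
    "assemble_design",
    "pearson_r2",
    "multiple_r2",
    "select_features",
    "fit_weights",
    "LinearCGPotential",
    "ForceMatching",
    "ForceMatchingResults",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class MeanForceDataset:
    """Pairs of (configuration, per-site mean-force vectors).

    Forces are in k_B T / sigma_c; one (N, 3) force array per
    configuration.  ``meta`` records provenance (source model,
    temperature, sampling lengths, seed, units).
    """

    configs: list[Configuration]
    forces: list[np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.configs) != len(self.forces):
            raise ValueError("one force array per configuration required")
        self.forces = [np.asarray(f, dtype=float) for f in self.forces]
        for cfg, f in zip(self.configs, self.forces):
            if f.shape != (cfg.n_sites, 3):
                raise ValueError(
                    f"force array shape {f.shape} does not match "
                    f"{cfg.n_sites} sites"
                )
        self.meta.setdefault("units", "kBT/sigma_c")

    @property
    def n_rows(self) -> int:
        """Number of scalar regression examples (3 per site per frame)."""
        return 3 * sum(c.n_sites for c in self.configs)

    def __len__(self) -> int:
        return len(self.configs)


@dataclass
class DesignMatrix:
    """Force-matching regression problem.

    Row order: for each configuration, for each site, the x, y, z force
    components.  Column ``J`` holds ``-sum_K dG_J(K)/dR_{I,a}``.
    """

    X: np.ndarray
    y: np.ndarray
    pool: list[SymmetryFunctionSpec]
    row_index: np.ndarray  # (rows, 3): config id, site id, component id

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class SelectionTrace:
    """Record of the stepwise descriptor selection."""

    order: list[int]
    r2_path: list[float]
    gains: list[float]
    c2_individual: list[float]
    column_means: np.ndarray
    column_stds: np.ndarray
    target_mean: float
    target_std: float
    n_degenerate: int = 0

    def __len__(self) -> int:
        return len(self.order)

    def correlation_matrix(self, X: np.ndarray) -> np.ndarray:
        """Pearson correlation matrix of the selected raw columns."""
        return np.corrcoef(X[:, self.order], rowvar=False).reshape(
            len(self.order), len(self.order)
        )


# ---------------------------------------------------------------------------
# design assembly


def assemble_design(dataset: MeanForceDataset, pool) -> DesignMatrix:
    """Stack descriptor-gradient force columns and target components."""
    pool = list(pool)
    if not pool:
        raise ValueError("descriptor pool must be non-empty")
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    units = dataset.meta.get("units", "kBT/sigma_c")
    if units != "kBT/sigma_c":
        raise ValueError(f"dataset units {units!r}; expected 'kBT/sigma_c'")
    blocks, targets, rows = [], [], []
    for ci, (cfg, f) in enumerate(zip(dataset.configs, dataset.forces)):
        cols = descriptor_force_columns(cfg, pool)  # (N, 3, S)
        blocks.append(cols.reshape(-1, len(pool)))
        targets.append(f.reshape(-1))
        n = cfg.n_sites
        idx = np.empty((3 * n, 3), dtype=np.intp)
        idx[:, 0] = ci
        idx[:, 1] = np.repeat(np.arange(n), 3)
        idx[:, 2] = np.tile(np.arange(3), n)
        rows.append(idx)
    return DesignMatrix(
        X=np.vstack(blocks),
        y=np.concatenate(targets),
        pool=pool,
        row_index=np.vstack(rows),
    )


# ---------------------------------------------------------------------------
# correlation measures


def pearson_r2(column: np.ndarray, target: np.ndarray) -> float:
    """Squared Pearson correlation between one column and the target."""
    column = np.asarray(column, dtype=float)
    target = np.asarray(target, dtype=float)
    if column.shape != target.shape or column.size < 2:
        raise ValueError("column and target must share a length >= 2")
    xc = column - column.mean()
    yc = target - target.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        warnings.warn("degenerate (zero-variance) column in pearson_r2", stacklevel=2)
        return 0.0
    c = (xc @ yc) / (sx * sy)
    return float(min(c * c, 1.0))


def multiple_r2(columns: np.ndarray, target: np.ndarray, method: str = "residual") -> float:
    """Squared coefficient of multiple correlation of target on columns.

    ``method='residual'`` computes the variance fraction explained by a
    linear fit with intercept (numerically stable default);
    ``method='matrix'`` evaluates ``c^T R^-1 c`` with ``c`` the vector of
    Pearson correlations and ``R`` the column correlation matrix, falling
    back to the residual route if ``R`` is singular.
    """
    X = np.atleast_2d(np.asarray(columns, dtype=float))
    if X.shape[0] == target.size and X.ndim == 2:
        pass
    elif X.shape[1] == target.size:
        X = X.T
    y = np.asarray(target, dtype=float)
    if method == "matrix":
        sx = X.std(axis=0)
        sy = y.std()
        if sy == 0.0 or np.any(sx == 0.0):
            return multiple_r2(X, y, method="residual")
        Z = (X - X.mean(axis=0)) / sx
        t = (y - y.mean()) / sy
        n = y.size
        c = Z.T @ t / n
        R = Z.T @ Z / n
        try:
            sol = np.linalg.solve(R, c)
        except np.linalg.LinAlgError:
            return multiple_r2(X, y, method="residual")
        if not np.all(np.isfinite(sol)):
            return multiple_r2(X, y, method="residual")
        return float(c @ sol)
    if method != "residual":
        raise ValueError("method must be 'residual' or 'matrix'")
    yc = y - y.mean()
    ss_tot = yc @ yc
    if ss_tot == 0.0:
        return 0.0
    A = np.column_stack([np.ones_like(y), X])
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(1.0 - (resid @ resid) / ss_tot)


# ---------------------------------------------------------------------------
# stepwise forward selection


def select_features(design: DesignMatrix, delta_r2_min: float = 1e-4) -> SelectionTrace:
    """Greedy forward selection of descriptor columns.

    Equivalent to stepwise maximisation of the squared coefficient of
    multiple correlation, implemented by Gram-Schmidt residualisation so
    each sweep over the pool is O(rows x pool).  Ties break to the lowest
    column index; all-zero columns are removed up front.
    """
    X, y = design.X, design.y
    n, m = X.shape
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    alive = stds > 0.0
    n_degenerate = int(m - alive.sum())

    t = y - y.mean()
    ss_tot = float(t @ t)
    trace = SelectionTrace(
        order=[],
        r2_path=[],
        gains=[],
        c2_individual=[],
        column_means=means,
        column_stds=stds,
        target_mean=float(y.mean()),
        target_std=float(y.std()),
        n_degenerate=n_degenerate,
    )
    if ss_tot == 0.0 or not alive.any():
        return trace

    Xr = X - means  # residualised columns, updated in place
    tr = t.copy()
    norms2 = np.einsum("ij,ij->j", Xr, Xr)
    r2 = 0.0
    # tolerance below which a residual column is linearly dependent on the
    # selected set and must not be picked
    dep_tol = 1e-10 * float(norms2.max())

    while alive.any():
        proj = Xr.T @ tr
        gains = np.zeros(m)
        pickable = alive & (norms2 > dep_tol)
        gains[pickable] = proj[pickable] ** 2 / norms2[pickable]
        best = int(np.argmax(gains))  # argmax returns the first (lowest) index on ties
        gain = float(gains[best]) / ss_tot
        if trace.order and gain < delta_r2_min:
            break
        if gain <= 0.0:
            break
        q = Xr[:, best] / np.sqrt(norms2[best])
        trace.order.append(best)
        trace.c2_individual.append(pearson_r2(X[:, best], y))
        trace.gains.append(gain)
        r2 += gain
        trace.r2_path.append(min(r2, 1.0))
        alive[best] = False
        coeffs = q @ Xr
        Xr -= np.outer(q, coeffs)
        tr -= q * (q @ tr)
        norms2 = np.maximum(norms2 - coeffs**2, 0.0)
        if (tr @ tr) / ss_tot < 1e-12:
            break
    return trace


# ---------------------------------------------------------------------------
# weight fitting


def fit_weights(design: DesignMatrix, trace: SelectionTrace | list[int]):
    """Ordinary least squares, no intercept, on the selected raw columns.

    Returns ``(weights, kept_indices, diagnostics)``.  Rank-deficient
    selections drop the dependent columns with a warning.
    """
    order = list(trace.order) if isinstance(trace, SelectionTrace) else list(trace)
    if not order:
        raise ValueError("selection is empty; nothing to fit")
    X = design.X[:, order]
    y = design.y
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    kept_local = sorted(piv[:rank])
    dropped = [order[k] for k in range(len(order)) if k not in kept_local]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} linearly dependent column(s) from the fit",
            stacklevel=2,
        )
    kept = [order[k] for k in kept_local]
    Xk = design.X[:, kept]
    w, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ w
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    diagnostics = {
        "r_squared": float("nan") if ss_tot == 0.0 else 1.0 - ss_res / ss_tot,
        "rmse": float(np.sqrt(ss_res / y.size)),
        "n_rows": int(y.size),
        "n_selected": len(order),
        "n_kept": len(kept),
        "dropped_columns": dropped,
    }
    return w, kept, diagnostics


# ---------------------------------------------------------------------------
# the learned potential


class LinearCGPotential:
    """A fitted linear CG potential: ordered specs, weights, zero baseline.

    Evaluates the scalar many-body PMF (k_B T) and its exact negative
    gradient (the predicted mean forces) on any configuration; the two
    share one code path for the descriptor kernels, so force = -grad(PMF)
    holds identically.
    """

    def __init__(self, specs, weights, r_cut=None, isolated_ref=None, meta=None):
        self.specs = list(specs)
        self.weights = np.asarray(weights, dtype=float)
        if len(self.specs) != self.weights.size:
            raise ValueError("one weight per spec required")
        if not self.specs:
            raise ValueError("potential needs at least one descriptor")
        self.r_cut = float(r_cut) if r_cut is not None else max(s.r_cut for s in self.specs)
        self.isolated_ref = (
            np.asarray(isolated_ref, dtype=float)
            if isolated_ref is not None
            else isolated_reference(self.specs)
        )
        self.meta = dict(meta or {})

    # -- evaluation ---------------------------------------------------------

    def site_energies(self, config: Configuration) -> np.ndarray:
        """Per-site contributions Phi_K in k_B T (zero at infinite dilution)."""
        G = descriptor_table(config, self.specs)
        return (G - self.isolated_ref) @ self.weights

    def energy(self, config: Configuration) -> float:
        """Total many-body PMF Phi(R^N) in k_B T."""
        return float(self.site_energies(config).sum())

    def evaluate_pmf(self, config: Configuration):
        """Total PMF and per-site contributions ``(Phi, Phi_K)``."""
        per_site = self.site_energies(config)
        return float(per_site.sum()), per_site

    def predict_forces(self, config: Configuration) -> np.ndarray:
        """Mean forces -dPhi/dR_I, shape (N, 3), in k_B T / sigma_c."""
        cols = descriptor_force_columns(config, self.specs)
        return cols @ self.weights

    def pair_pmf(self, distances) -> np.ndarray:
        """PMF of an isolated pair as a function of separation distance."""
        distances = np.asarray(distances, dtype=float)
        out = np.empty(distances.shape)
        for k, d in enumerate(distances.ravel()):
            cfg = Configuration(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
            out.ravel()[k] = self.energy(cfg)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": 1,
            "units": {"length": "sigma_c", "energy": "kBT"},
            "r_cut": self.r_cut,
            "specs": [s.to_dict() for s in self.specs],
            "weights": self.weights.tolist(),
            "isolated_ref": self.isolated_ref.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearCGPotential":
        if d.get("schema") != 1:
            raise ValueError(f"unsupported model-file schema {d.get('schema')!r}")
        return cls(
            specs=[SymmetryFunctionSpec.from_dict(s) for s in d["specs"]],
            weights=np.array(d["weights"], dtype=float),
            r_cut=d["r_cut"],
            isolated_ref=np.array(d["isolated_ref"], dtype=float),
            meta=d.get("meta", {}),
        )

    def save(self, path) -> None:
        from .io import write_model

        write_model(self, path)

    @classmethod
    def load(cls, path) -> "LinearCGPotential":
        from .io import read_model

        return read_model(path)


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface


class ForceMatching:
    """Force-matching model: mean-force dataset + descriptor pool.

    Parameters
    ----------
    dataset : MeanForceDataset
    pool : sequence of SymmetryFunctionSpec
        Candidate descriptors; a subset is selected during fitting.
    """

    def __init__(self, dataset: MeanForceDataset, pool):
        self.dataset = dataset
        self.pool = list(pool)
        self._design: DesignMatrix | None = None

    @property
    def design(self) -> DesignMatrix:
        if self._design is None:
            self._design = assemble_design(self.dataset, self.pool)
        return self._design

    def fit(self, delta_r2_min: float = 1e-4) -> "ForceMatchingResults":
        """Select descriptors stepwise, then fit weights by plain OLS."""
        design = self.design
        trace = select_features(design, delta_r2_min=delta_r2_min)
        if not trace.order:
            # an all-zero target: the zero potential on the full pool's
            # first column keeps downstream code functional
            w = np.zeros(1)
            kept = [0]
            diagnostics = {
                "r_squared": float("nan"),
                "rmse": float(np.sqrt(np.mean(design.y**2))),
                "n_rows": design.n_rows,
                "n_selected": 0,
                "n_kept": 1,
                "dropped_columns": [],
            }
        else:
            w, kept, diagnostics = fit_weights(design, trace)
        return ForceMatchingResults(self, trace, w, kept, diagnostics, delta_r2_min)


class ForceMatchingResults:
    """Fit results: selected descriptors, weights, and diagnostics."""

    def __init__(self, model, trace, params, kept, diagnostics, delta_r2_min):
        self.model = model
        self.trace = trace
        self.params = np.asarray(params, dtype=float)
        self.kept = list(kept)
        self.diagnostics = dict(diagnostics)
        self.delta_r2_min = float(delta_r2_min)
        self.specs = [model.pool[k] for k in self.kept]
        self.rsquared = self.diagnostics["r_squared"]
        self.rmse = self.diagnostics["rmse"]

    @property
    def n_selected(self) -> int:
        return len(self.trace)

    def as_potential(self, meta=None) -> LinearCGPotential:
        base = {
            "delta_r2_min": self.delta_r2_min,
            "r_squared": self.rsquared,
            "rmse": self.rmse,
            "n_rows": self.diagnostics["n_rows"],
            "selection_r2_path": list(self.trace.r2_path),
        }
        base.update(meta or {})
        return LinearCGPotential(self.specs, self.params, meta=base)

    # evaluation conveniences delegate to the potential
    def predict_forces(self, config: Configuration) -> np.ndarray:
        return self.as_potential().predict_forces(config)

    def evaluate_pmf(self, config: Configuration):
        return self.as_potential().evaluate_pmf(config)

    def fittedvalues(self) -> np.ndarray:
        design = self.model.design
        return design.X[:, self.kept] @ self.params

    def resid(self) -> np.ndarray:
        return self.model.design.y - self.fittedvalues()

    def summary(self) -> str:
        lines = [
            "Force-matching fit",
            "==================",
            f"rows (force components) : {self.diagnostics['n_rows']}",
            f"pool size               : {len(self.model.pool)}",
            f"selected descriptors    : {self.n_selected}"
            f" (kept {self.diagnostics['n_kept']})",
            f"degenerate columns      : {self.trace.n_degenerate}",
            f"R^2                     : {self.rsquared:.6f}",
            f"RMSE [kBT/sigma_c]      : {self.rmse:.4f}",
            "",
            f"{'step':>4} {'col':>5} {'kind':>8} {'c_i^2':>10} {'dR^2':>10} {'R^2':>10}",
        ]
        for step, (col, c2, gain, r2) in enumerate(
            zip(self.trace.order, self.trace.c2_individual, self.trace.gains, self.trace.r2_path)
        ):
            kind = self.model.pool[col].kind
            lines.append(
                f"{step:>4} {col:>5} {kind:>8} {c2:>10.4f} {gain:>10.2e} {r2:>10.6f}"
            )
        return "\n".join(lines)
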
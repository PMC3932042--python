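"""Derivative-free likelihood maximization: MADS with orthogonal polling,
plus a restarted generalized-pattern-search (GPS) comparator.

Both optimizers maximize a black-box objective over a finite box.  The
objective may return the :data:`~linkld.trait_model.INFEASIBLE` sentinel
(or a non-finite value), in which case the *extreme barrier* applies: the
trial point is discarded as if its objective value were infinitely bad and
can never become the incumbent.  Bound constraints are handled explicitly —
no point outside the box is ever proposed.

The MADS poll uses 2n mutually orthogonal directions built from an integer
scaled-Householder matrix H = ||q||^2 I - 2 q q^T of a pseudo-random integer
vector q (the OrthoMADS construction): the columns of H are exactly
orthogonal, and because q varies from iteration to iteration the closure of
the normalized poll directions densifies on the unit sphere.  The mesh size
delta = min(Delta, Delta^2) shrinks quadratically relative to the poll size
Delta, so poll directions become richer as the mesh refines.  The poll size
halves after a failed poll and is kept after a success; iteration stops
when Delta drops below ``min_poll_size`` or the evaluation budget is
exhausted.  An optional search step maximizes a quadratic model
fitted to recently evaluated points before polling.

All optimization is carried out in box-scaled coordinates ([0, 1] per
variable) so a single ``min_poll_size`` threshold is meaningful across
parameters with different natural ranges (e.g. a recombination fraction in
[0, 0.5] next to allele frequencies in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .trait_model import INFEASIBLE

__all__ = [
    "OptimizerOptions",
    "MeshState",
    "OptResult",
    "ortho_poll_directions",
    "mads_maximize",
    "gps_maximize",
]


@dataclass(frozen=True)
class OptimizerOptions:
    min_poll_size: float = 1e-4
    initial_poll_size: float = 1.0
    max_evaluations: int = 20000
    seed: int = 0
    use_quadratic_search: bool = True
    gps_max_restarts: int = 4
    gps_restart_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.min_poll_size <= 0:
            raise ValueError("min_poll_size must be positive")


@dataclass
class MeshState:
    """Poll size Delta, mesh size delta = min(Delta, Delta^2), incumbent."""

    poll_size: float
    incumbent: np.ndarray
    value: float
    n_evals: int = 0

    @property
    def mesh_size(self) -> float:
        return min(self.poll_size, self.poll_size**2)


@dataclass
class OptResult:
    x: np.ndarray
    f: float
    n_evals: int
    trace: list[tuple[int, np.ndarray, float]] = field(default_factory=list)
    evaluated: list[np.ndarray] = field(default_factory=list)
    final_poll_size: float = float("nan")
    n_restarts: int = 0


def ortho_poll_directions(
    n: int, mesh: "MeshState | float", rng: np.random.Generator
) -> np.ndarray:
    """2n orthogonal integer poll directions (columns), OrthoMADS-style.

    ``mesh`` is the current :class:`MeshState` (or directly the ratio
    alpha = Delta/delta), which controls the direction magnitude: steps of
    ``delta * direction`` have infinity-norm of order Delta.  The first n
    columns are the scaled-Householder matrix ||q||^2 I - 2 q q^T of a
    pseudo-random integer vector q (mutually orthogonal exactly, in integer
    arithmetic); the last n are their negatives.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = mesh.poll_size / mesh.mesh_size if isinstance(mesh, MeshState) else mesh
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    # ||q||^2 should be ~ alpha so that delta * ||column||_inf ~ Delta
    scale = max(np.sqrt(max(alpha, 1.0)), 1.0)
    q = np.round(v * scale).astype(np.int64)
    if not q.any():
        q[int(rng.integers(n))] = 1
    norm2 = int(q @ q)
    Hmat = norm2 * np.eye(n, dtype=np.int64) - 2 * np.outer(q, q)
    return np.hstack([Hmat, -Hmat])


class _ScaledObjective:
    """Maps [0,1]^n coordinates to the user box and applies the barrier."""

    def __init__(self, objective, lo, hi):
        self.objective = objective
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.span = self.hi - self.lo
        if np.any(~np.isfinite(self.lo)) or np.any(~np.isfinite(self.hi)):
            raise ValueError("bounds must be finite")
        if np.any(self.span <= 0):
            raise ValueError("upper bounds must exceed lower bounds")
        self.cache: dict[tuple, float | None] = {}
        self.n_evals = 0
        self.evaluated: list[np.ndarray] = []

    def to_user(self, z: np.ndarray) -> np.ndarray:
        return self.lo + z * self.span

    def to_scaled(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.lo) / self.span

    def __call__(self, z: np.ndarray) -> float | None:
        """Returns the objective value, or None for barrier-rejected points."""
        key = tuple(np.round(z, 12))
        if key in self.cache:
            return self.cache[key]
        x = self.to_user(z)
        val = self.objective(x)
        self.n_evals += 1
        self.evaluated.append(x)
        if val is INFEASIBLE or val is None or not np.isfinite(val):
            out = None
        else:
            out = float(val)
        self.cache[key] = out
        return out


def _snap_to_mesh(z: np.ndarray, center: np.ndarray, delta: float) -> np.ndarray:
    """Clip to [0,1] then snap onto the mesh anchored at ``center``.

    Rounding the clipped offset toward zero keeps the snapped point inside
    the box whenever ``center`` is.
    """
    z = np.clip(z, 0.0, 1.0)
    steps = np.trunc((z - center) / delta + np.sign(z - center) * 1e-12)
    return np.clip(center + steps * delta, 0.0, 1.0)


def _fit_quadratic(
    zs: np.ndarray, fs: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Least-squares quadratic model f(z) ~ c + g.z + z.Q z / 2.

    Returns (g, Q) of the fitted model, or None with too few points.
    """
    m, n = zs.shape
    ncoef = 1 + n + n * (n + 1) // 2
    if m < ncoef + 1:
        return None
    iu, ju = np.triu_indices(n)
    A = np.column_stack([np.ones(m), zs, zs[:, iu] * zs[:, ju]])
    try:
        coef, *_ = np.linalg.lstsq(A, fs, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    g = coef[1 : 1 + n]
    Q = np.zeros((n, n))
    Q[iu, ju] = coef[1 + n :]
    Q = Q + Q.T  # off-diagonal split; diagonal doubled = 2 * quad coeff
    return g, Q


def _quadratic_search_point(
    history_z: list[np.ndarray],
    history_f: list[float],
    center: np.ndarray,
    poll_size: float,
    n: int,
) -> np.ndarray | None:
    """Candidate maximizer of a local quadratic model, box/trust clipped.

    The model maximum is taken in closed form (Newton point of the fitted
    quadratic, falling back to a gradient step when the Hessian is not
    invertible or not concave), then clipped to the box intersected with a
    trust region of twice the poll size around the incumbent.
    """
    if not history_f:
        return None
    nkeep = 4 * (1 + n + n * (n + 1) // 2)
    zs = np.asarray(history_z[-nkeep:])
    fs = np.asarray(history_f[-nkeep:])
    fit = _fit_quadratic(zs, fs)
    if fit is None:
        return None
    g, Q = fit
    lo = np.clip(center - 2.0 * poll_size, 0.0, 1.0)
    hi = np.clip(center + 2.0 * poll_size, 0.0, 1.0)
    grad_at_center = g + Q @ center
    candidate = None
    try:
        eig = np.linalg.eigvalsh(Q)
        if np.all(eig < -1e-12):  # strictly concave: interior Newton point
            candidate = np.linalg.solve(-Q, g)
    except np.linalg.LinAlgError:  # pragma: no cover
        candidate = None
    if candidate is None or not np.all(np.isfinite(candidate)):
        gn = np.linalg.norm(grad_at_center)
        if gn < 1e-14:
            return None
        candidate = center + (2.0 * poll_size / gn) * grad_at_center
    candidate = np.clip(candidate, lo, hi)

    def mval(z: np.ndarray) -> float:
        return float(g @ z + 0.5 * z @ Q @ z)

    # don't spend an evaluation when the model predicts no improvement
    if mval(candidate) <= mval(center) + 1e-12:
        return None
    return candidate


def mads_maximize(
    objective: Callable[[np.ndarray], float],
    bounds: tuple[Sequence[float], Sequence[float]],
    x0: Sequence[float],
    options: OptimizerOptions | None = None,
) -> OptResult:
    """Maximize ``objective`` over a box with MADS (2n orthogonal directions).

    ``objective`` maps a point in user coordinates to a float, or to
    INFEASIBLE/None/non-finite for barrier rejection.  ``x0`` must be
    feasible.  Deterministic for a fixed ``options.seed``.
    """
    opts = options or OptimizerOptions()
    lo, hi = bounds
    wrapped = _ScaledObjective(objective, lo, hi)
    z = wrapped.to_scaled(np.asarray(x0, dtype=float))
    if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
        raise ValueError("x0 outside bounds")
    z = np.clip(z, 0.0, 1.0)
    n = z.size
    f = wrapped(z)
    if f is None:
        raise ValueError("objective infeasible at x0")
    rng = np.random.default_rng(opts.seed)
    mesh = MeshState(poll_size=opts.initial_poll_size, incumbent=z, value=f)
    trace = [(wrapped.n_evals, wrapped.to_user(z), f)]
    hist_z: list[np.ndarray] = [z.copy()]
    hist_f: list[float] = [f]

    def try_point(zc: np.ndarray) -> float | None:
        val = wrapped(zc)
        if val is not None:
            hist_z.append(zc.copy())
            hist_f.append(val)
        return val

    while mesh.poll_size >= opts.min_poll_size and wrapped.n_evals < opts.max_evaluations:
        delta = mesh.mesh_size
        success = False
        search_success = False
        # --- search step: quadratic model of recent evaluations
        if opts.use_quadratic_search:
            zq = _quadratic_search_point(
                hist_z, hist_f, mesh.incumbent, mesh.poll_size, n
            )
            if zq is not None:
                zq = _snap_to_mesh(zq, mesh.incumbent, delta)
                if not np.allclose(zq, mesh.incumbent):
                    val = try_point(zq)
                    if val is not None and val > mesh.value:
                        mesh.incumbent, mesh.value = zq, val
                        trace.append((wrapped.n_evals, wrapped.to_user(zq), val))
                        success = search_success = True
        # --- poll step: 2n orthogonal directions, opportunistic
        if not success:
            alpha = mesh.poll_size / delta
            dirs = ortho_poll_directions(n, alpha, rng)
            for jcol in range(dirs.shape[1]):
                if wrapped.n_evals >= opts.max_evaluations:
                    break
                d = dirs[:, jcol].astype(float)
                nrm = np.abs(d).max()
                if nrm > 0:
                    d = d / nrm * alpha  # step of infinity-norm Delta on the mesh
                zc = _snap_to_mesh(mesh.incumbent + delta * np.round(d), mesh.incumbent, delta)
                if np.allclose(zc, mesh.incumbent):
                    continue
                val = try_point(zc)
                if val is not None and val > mesh.value:
                    mesh.incumbent, mesh.value = zc, val
                    trace.append((wrapped.n_evals, wrapped.to_user(zc), val))
                    success = True
                    break  # opportunistic
        # the poll size is non-increasing: kept on success, halved on failure.
        # (Re-expanding on success was tried and costs ~25-40% more
        # evaluations on likelihood problems: every re-expansion must be
        # paid back by a full failed poll per extra level on the way down.)
        if not success:
            mesh.poll_size *= 0.5
    mesh.n_evals = wrapped.n_evals
    return OptResult(
        x=wrapped.to_user(mesh.incumbent),
        f=mesh.value,
        n_evals=wrapped.n_evals,
        trace=trace,
        evaluated=wrapped.evaluated,
        final_poll_size=mesh.poll_size,
    )


def _gps_single(
    wrapped: _ScaledObjective, z0: np.ndarray, opts: OptimizerOptions
) -> tuple[np.ndarray, float]:
    """One GPS run: fixed coordinate directions, step halving on failure."""
    n = z0.size
    z = z0.copy()
    f = wrapped(z)
    if f is None:
        raise ValueError("objective infeasible at GPS start")
    step = opts.initial_poll_size
    while step >= opts.min_poll_size and wrapped.n_evals < opts.max_evaluations:
        success = False
        for j in range(n):
            for sgn in (+1.0, -1.0):
                if wrapped.n_evals >= opts.max_evaluations:
                    break
                zc = z.copy()
                zc[j] = np.clip(zc[j] + sgn * step, 0.0, 1.0)
                if zc[j] == z[j]:
                    continue
                val = wrapped(zc)
                if val is not None and val > f:
                    z, f = zc, val
                    success = True
                    break
            if success:
                break
        if not success:
            step *= 0.5
    return z, f


def gps_maximize(
    objective: Callable[[np.ndarray], float],
    bounds: tuple[Sequence[float], Sequence[float]],
    x0: Sequence[float],
    options: OptimizerOptions | None = None,
) -> OptResult:
    """GPS comparator: fixed +/- coordinate poll directions, with restarts.

    After each converged run the search restarts from the returned solution
    at the initial step size, until the improvement falls below
    ``gps_restart_tol`` or ``gps_max_restarts`` is reached (the protocol
    historically used to reduce the chance of stalling at a non-optimum).
    """
    opts = options or OptimizerOptions()
    lo, hi = bounds
    wrapped = _ScaledObjective(objective, lo, hi)
    z = wrapped.to_scaled(np.asarray(x0, dtype=float))
    if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
        raise ValueError("x0 outside bounds")
    z = np.clip(z, 0.0, 1.0)
    trace = []
    best_z, best_f = _gps_single(wrapped, z, opts)
    trace.append((wrapped.n_evals, wrapped.to_user(best_z), best_f))
    restarts = 0
    for _ in range(opts.gps_max_restarts):
        if wrapped.n_evals >= opts.max_evaluations:
            break
        # restart clears the cache so the re-run genuinely re-polls
        wrapped.cache.clear()
        z2, f2 = _gps_single(wrapped, best_z, opts)
        restarts += 1
        if f2 > best_f:
            trace.append((wrapped.n_evals, wrapped.to_user(z2), f2))
        improved = f2 - best_f
        if f2 > best_f:
            best_z, best_f = z2, f2
        if improved < opts.gps_restart_tol:
            break
    return OptResult(
        x=wrapped.to_user(best_z),
        f=best_f,
        n_evals=wrapped.n_evals,
        trace=trace,
        evaluated=wrapped.evaluated,
        final_poll_size=float("nan"),
        n_restarts=restarts,
    )
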
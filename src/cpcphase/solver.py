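"""Method-of-lines solver for the switch-off Allen-Cahn setting model.

Space: cell-centered N x N grid on the square ``[-L, L]^2`` with spacing
``h = 2L/N`` and a 5-point Laplacian; homogeneous Neumann boundaries are
realized by ghost-cell mirroring (the ghost value equals the adjacent
interior value), which is exact for fields even about the boundary and
second-order accurate in general.

Time: classical fourth-order Runge-Kutta with a fixed step.  The
discontinuous diffusion coefficient D(t) is handled by snapping the step
sequence so that the switch time T is a step boundary; within each step
every RK stage uses the diffusion value of the regime the step starts in,
so the scheme is exactly RK4 on each smooth piece of the equation and no
stage ever samples the coefficient across the jump.

The hot loop is compiled with numba when available and falls back to a
vectorized numpy path otherwise; both evaluate the identical arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    ModelParameters,
    diffusion_coefficient,
    potential,
    reaction,
)

__all__ = [
    "OrderParameterField",
    "NumericsConfig",
    "SnapshotSeries",
    "SolverDivergenceError",
    "laplacian_neumann",
    "rhs",
    "rk4_step",
    "integrate",
    "discrete_energy",
    "stability_dt_bound",
]

#: Safety factor applied to the reaction time scale in the stability bound.
STABILITY_SAFETY = 0.1

#: How often (in steps) the compiled kernel scans the field for NaN/Inf.
_DIVERGENCE_CHECK_EVERY = 200


class SolverDivergenceError(RuntimeError):
    """Integration produced a non-finite field value."""


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class OrderParameterField:
    """Discrete order-parameter field phi on the square ``[-L, L]^2``.

    ``values[i, j]`` lives at the cell center
    ``(-L + h/2 + i*h, -L + h/2 + j*h)`` with ``h = 2L/N``.  Values are
    dimensionless; physically meaningful states lie in [0, 1], but the
    field is not clamped — transient excursions are diagnosed, not hidden.
    """

    values: np.ndarray
    L: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"field must be a square 2-D grid, got shape {self.values.shape}")
        if self.N < 3:
            raise ValueError(f"grid must have N >= 3 points per side, got N={self.N}")
        if self.L <= 0:
            raise ValueError(f"domain half-width must be positive, got L={self.L}")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def h(self) -> float:
        return 2.0 * self.L / self.N

    def cell_centers(self) -> np.ndarray:
        """1-D array of cell-center coordinates along one axis."""
        return -self.L + self.h * (np.arange(self.N) + 0.5)

    def range_violation(self, tol: float = 1e-6) -> float:
        """How far values stray outside [0, 1] beyond `tol` (0.0 if none)."""
        over = max(float(self.values.max()) - 1.0, 0.0)
        under = max(-float(self.values.min()), 0.0)
        return max(max(over, under) - tol, 0.0)

    def copy(self) -> "OrderParameterField":
        return OrderParameterField(self.values.copy(), L=self.L, t=self.t)


@dataclass
class NumericsConfig:
    """Discretization controls for one integration.

    ``dt=None`` selects the reproduction default ``0.1 / N**2`` — very
    conservative, but it is the step the reference simulations use.  The
    ``"stability-checked"`` policy instead *validates* the supplied dt
    against ``min(h**2/(4*D0), 0.1*epsilon**2)`` for faster exploratory
    runs.
    """

    N: int = 200
    dt: float | None = None
    t_end: float = 1.0
    snapshot_times: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    dt_policy: str = "fixed"

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError(f"N must be >= 3, got {self.N}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        if self.dt is not None and self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dt_policy not in ("fixed", "stability-checked"):
            raise ValueError(f"unknown dt_policy {self.dt_policy!r}")
        times = tuple(float(t) for t in self.snapshot_times)
        if sorted(set(times)) != list(times):
            raise ValueError("snapshot_times must be sorted and unique")
        if times and (times[0] < 0.0 or times[-1] > self.t_end + 1e-12):
            raise ValueError("snapshot_times must lie within [0, t_end]")
        self.snapshot_times = times

    def resolved_dt(self) -> float:
        return 0.1 / self.N ** 2 if self.dt is None else self.dt


@dataclass
class SnapshotSeries:
    """Time-stamped fields from one integration, initial condition first."""

    entries: list[tuple[float, OrderParameterField]]
    params: ModelParameters
    config: NumericsConfig
    seed: int | None = None

    def __post_init__(self) -> None:
        times = self.times
        if not times:
            raise ValueError("snapshot series must be nonempty")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")
        shapes = {f.values.shape for _, f in self.entries}
        ls = {f.L for _, f in self.entries}
        if len(shapes) > 1 or len(ls) > 1:
            raise ValueError("all fields in a series must share N and L")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.entries]

    def field_at(self, t: float, atol: float = 1e-9) -> OrderParameterField:
        for ts, f in self.entries:
            if abs(ts - t) <= atol:
                return f
        raise KeyError(f"no snapshot at t={t}; available: {self.times}")


# ----------------------------------------------------------------------
# spatial operator and right-hand side (numpy reference path)
# ----------------------------------------------------------------------

def _mirror_pad(u: np.ndarray, out: np.ndarray) -> None:
    out[1:-1, 1:-1] = u
    out[0, 1:-1] = u[0]
    out[-1, 1:-1] = u[-1]
    out[1:-1, 0] = u[:, 0]
    out[1:-1, -1] = u[:, -1]


def laplacian_neumann(field: OrderParameterField) -> np.ndarray:
    """5-point Laplacian with mirrored (zero-flux) ghost cells.

    Returns ``(phi_E + phi_W + phi_N + phi_S - 4*phi_C) / h**2`` with
    boundary neighbors equal to the interior cell they mirror.  The sum is
    grouped as ``(E+W) + (N+S) - 4*C`` so that a uniform field yields an
    exact floating-point zero.
    """
    u = field.values
    n = field.N
    p = np.empty((n + 2, n + 2), dtype=u.dtype)
    _mirror_pad(u, p)
    stencil = (p[:-2, 1:-1] + p[2:, 1:-1]) + (p[1:-1, :-2] + p[1:-1, 2:]) - 4.0 * u
    return stencil / field.h ** 2


def rhs(field: OrderParameterField, t: float, params: ModelParameters) -> np.ndarray:
    """Semi-discrete right-hand side ``D(t)*Lap(phi) + epsilon**-2 * f(phi)``."""
    d = diffusion_coefficient(t, params)
    out = reaction(field.values, params.phi_bar)
    out *= params.epsilon ** -2
    if d != 0.0:
        out += d * laplacian_neumann(field)
    return out


def _rhs_fixed_d(u: np.ndarray, d_over_h2: float, inv_eps2: float, phi_bar: float,
                 pad: np.ndarray) -> np.ndarray:
    """rhs with a frozen diffusion value; arithmetic mirrors the numba kernel."""
    _mirror_pad(u, pad)
    stencil = (pad[:-2, 1:-1] + pad[2:, 1:-1]) + (pad[1:-1, :-2] + pad[1:-1, 2:]) - 4.0 * u
    return d_over_h2 * stencil + inv_eps2 * (u * (1.0 - u) * (u - phi_bar))


def rk4_step(
    field: OrderParameterField,
    t: float,
    dt: float,
    params: ModelParameters,
) -> OrderParameterField:
    """One classical RK4 step from t to t + dt.

    The step must not straddle the diffusion switch time T: refuse with an
    error telling the caller to split the step at T.  All four stages use
    the diffusion value of the step's starting regime (``D0`` if ``t < T``
    else 0), i.e. the one-sided limit valid on the whole step, so the
    update is plain RK4 for a smooth equation.  Uniform fields at the
    reaction roots 0, phi_bar, 1 are exact fixed points bit-for-bit.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t < params.T and t + dt > params.T + 1e-12:
        raise ValueError(
            f"step [{t}, {t + dt}] straddles the diffusion switch time "
            f"T={params.T}; split the step so T is a step boundary"
        )
    d = diffusion_coefficient(t, params)
    u = field.values
    h2 = field.h ** 2
    d_h2 = d / h2
    inv_eps2 = params.epsilon ** -2
    pb = params.phi_bar
    pad = np.empty((field.N + 2, field.N + 2), dtype=u.dtype)

    k1 = _rhs_fixed_d(u, d_h2, inv_eps2, pb, pad)
    k2 = _rhs_fixed_d(u + (0.5 * dt) * k1, d_h2, inv_eps2, pb, pad)
    k3 = _rhs_fixed_d(u + (0.5 * dt) * k2, d_h2, inv_eps2, pb, pad)
    k4 = _rhs_fixed_d(u + dt * k3, d_h2, inv_eps2, pb, pad)
    new = u + (dt / 6.0) * ((k1 + k4) + 2.0 * (k2 + k3))
    return OrderParameterField(new, L=field.L, t=t + dt)


# ----------------------------------------------------------------------
# compiled segment kernel
# ----------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly by integrate()
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _segment_python(u, nsteps, dt_main, dt_last, d_h2, inv_eps2, pb, check_every):
    """Reference segment loop: repeated RK4 steps with frozen diffusion."""
    n = u.shape[0]
    pad = np.empty((n + 2, n + 2), dtype=u.dtype)
    for step in range(nsteps):
        dt = dt_main if step < nsteps - 1 else dt_last
        k1 = _rhs_fixed_d(u, d_h2, inv_eps2, pb, pad)
        k2 = _rhs_fixed_d(u + (0.5 * dt) * k1, d_h2, inv_eps2, pb, pad)
        k3 = _rhs_fixed_d(u + (0.5 * dt) * k2, d_h2, inv_eps2, pb, pad)
        k4 = _rhs_fixed_d(u + dt * k3, d_h2, inv_eps2, pb, pad)
        u += (dt / 6.0) * ((k1 + k4) + 2.0 * (k2 + k3))
        if (step + 1) % check_every == 0 or step == nsteps - 1:
            if not np.all(np.isfinite(u)):
                return step
    return -1


if _HAVE_NUMBA:

    @njit(cache=True)
    def _stage(u, out, d_h2, inv_eps2, pb):  # pragma: no cover - compiled
        # Boundary columns are peeled out of the inner loop so the hot path
        # carries no index clamping.
        n = u.shape[0]
        for i in range(n):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n - 1 else n - 1
            p = u[i, 0]
            stencil = (u[im, 0] + u[ip, 0]) + (u[i, 0] + u[i, 1]) - 4.0 * p
            out[i, 0] = d_h2 * stencil + inv_eps2 * (p * (1.0 - p) * (p - pb))
            for j in range(1, n - 1):
                p = u[i, j]
                stencil = (u[im, j] + u[ip, j]) + (u[i, j - 1] + u[i, j + 1]) - 4.0 * p
                out[i, j] = d_h2 * stencil + inv_eps2 * (p * (1.0 - p) * (p - pb))
            p = u[i, n - 1]
            stencil = (u[im, n - 1] + u[ip, n - 1]) + (u[i, n - 2] + u[i, n - 1]) - 4.0 * p
            out[i, n - 1] = d_h2 * stencil + inv_eps2 * (p * (1.0 - p) * (p - pb))

    @njit(cache=True)
    def _segment_numba(u, nsteps, dt_main, dt_last, d_h2, inv_eps2, pb,
                       check_every):  # pragma: no cover - compiled
        n = u.shape[0]
        k1 = np.empty((n, n))
        k2 = np.empty((n, n))
        k3 = np.empty((n, n))
        k4 = np.empty((n, n))
        us = np.empty((n, n))
        for step in range(nsteps):
            dt = dt_main if step < nsteps - 1 else dt_last
            _stage(u, k1, d_h2, inv_eps2, pb)
            for i in range(n):
                for j in range(n):
                    us[i, j] = u[i, j] + (0.5 * dt) * k1[i, j]
            _stage(us, k2, d_h2, inv_eps2, pb)
            for i in range(n):
                for j in range(n):
                    us[i, j] = u[i, j] + (0.5 * dt) * k2[i, j]
            _stage(us, k3, d_h2, inv_eps2, pb)
            for i in range(n):
                for j in range(n):
                    us[i, j] = u[i, j] + dt * k3[i, j]
            _stage(us, k4, d_h2, inv_eps2, pb)
            for i in range(n):
                for j in range(n):
                    u[i, j] = u[i, j] + (dt / 6.0) * ((k1[i, j] + k4[i, j])
                                                      + 2.0 * (k2[i, j] + k3[i, j]))
            if (step + 1) % check_every == 0 or step == nsteps - 1:
                ok = True
                for i in range(n):
                    for j in range(n):
                        if not np.isfinite(u[i, j]):
                            ok = False
                if not ok:
                    return step
        return -1

    _segment_kernel = _segment_numba
else:  # pragma: no cover
    _segment_kernel = _segment_python


# ----------------------------------------------------------------------
# integration driver
# ----------------------------------------------------------------------

def stability_dt_bound(params: ModelParameters, h: float) -> float:
    """Explicit-step bound ``min(h**2/(4*D0), 0.1*epsilon**2)``.

    The first term keeps the diffusion eigenvalues inside the RK4 stability
    region; the second resolves the fastest reaction rate
    ``~ epsilon**-2 / 4`` with a safety factor of 0.1.
    """
    return min(h * h / (4.0 * params.D0), STABILITY_SAFETY * params.epsilon ** 2)


def _segment_boundaries(params: ModelParameters, config: NumericsConfig) -> list[float]:
    marks = {config.t_end}
    marks.update(t for t in config.snapshot_times if t > 0.0)
    if 0.0 < params.T < config.t_end:
        marks.add(params.T)
    return sorted(marks)


def integrate(
    initial: OrderParameterField,
    params: ModelParameters,
    config: NumericsConfig,
    seed: int | None = None,
) -> SnapshotSeries:
    """Advance the field from t=0 to ``config.t_end``; record snapshots.

    The interval is split at the diffusion switch time T and at every
    snapshot time; within each segment a fixed step dt is used with the
    last step shortened to land exactly on the segment end, so snapshot
    times (and T) are hit exactly rather than approximately.  Snapshot
    times are reconstructed from segment boundaries, never by accumulating
    dt, so they carry no floating-point drift.  Deterministic given
    (initial, params, config).

    Raises
    ------
    SolverDivergenceError
        If a NaN/Inf appears in the field; the error reports the time
        interval of the offending step instead of clamping the blow-up.
    ValueError
        If ``dt_policy == "stability-checked"`` and dt exceeds
        `stability_dt_bound`.
    """
    dt = config.resolved_dt()
    if config.dt_policy == "stability-checked":
        bound = stability_dt_bound(params, initial.h)
        if dt > bound * (1.0 + 1e-12):
            raise ValueError(
                f"dt={dt} violates the stability bound {bound} "
                f"(h={initial.h}, D0={params.D0}, epsilon={params.epsilon})"
            )

    u = initial.values.astype(np.float64).copy()
    inv_eps2 = params.epsilon ** -2
    pb = params.phi_bar
    h2 = initial.h ** 2

    entries: list[tuple[float, OrderParameterField]] = [
        (0.0, OrderParameterField(initial.values.copy(), L=initial.L, t=0.0))
    ]
    want_snapshot = set(config.snapshot_times)

    t_prev = 0.0
    for t_next in _segment_boundaries(params, config):
        length = t_next - t_prev
        nsteps = max(1, math.ceil(length / dt - 1e-9))
        dt_last = length - (nsteps - 1) * dt
        d = diffusion_coefficient(t_prev, params)
        bad = _segment_kernel(u, nsteps, dt, dt_last, d / h2, inv_eps2, pb,
                              _DIVERGENCE_CHECK_EVERY)
        if bad >= 0:
            t_bad = t_prev + min((bad + 1) * dt, length)
            raise SolverDivergenceError(
                f"non-finite field value detected by step {bad} of segment "
                f"[{t_prev}, {t_next}] (t <= {t_bad}); the integration is "
                "unstable for this dt"
            )
        if any(abs(t_next - s) <= 1e-12 for s in want_snapshot):
            entries.append((t_next, OrderParameterField(u.copy(), L=initial.L, t=t_next)))
        t_prev = t_next

    return SnapshotSeries(entries=entries, params=params, config=config, seed=seed)


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def discrete_energy(field: OrderParameterField, t: float, params: ModelParameters) -> float:
    """Discrete Ginzburg-Landau energy; a Lyapunov function of the flow.

    ``E = (D(t)/2) * sum_faces (phi_a - phi_b)**2
    + epsilon**-2 * h**2 * sum_cells W(phi)``,
    where the face sum runs over interior cell faces (one-sided
    differences consistent with the mirrored-ghost Neumann stencil; the
    face term equals ``(D/2)|grad phi|^2 h^2`` with those differences).
    The semi-discrete system is exactly the gradient flow of this
    functional, so E is non-increasing in time on every interval where
    D(t) is constant.  Note E can be negative when ``phi_bar < 0.5``
    (the solid well of W sits below zero).
    """
    u = field.values
    d = diffusion_coefficient(t, params)
    dx = np.diff(u, axis=0)
    dy = np.diff(u, axis=1)
    grad_term = 0.5 * d * (float(np.sum(dx * dx)) + float(np.sum(dy * dy)))
    well_term = params.epsilon ** -2 * field.h ** 2 * float(
        np.sum(potential(u, params.phi_bar))
    )
    return grad_term + well_term
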
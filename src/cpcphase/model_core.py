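"""Scalar model functions and parameter algebra for the cement-setting model.

The setting of an injectable calcium-phosphate cement (CPC) paste is
described by an order parameter ``phi`` on a square domain: ``phi = 1`` is
set cement (solid), ``phi = 0`` is a void, ``phi = 0.5`` is liquid paste,
and intermediate values are incompletely set material.  The field obeys an
Allen-Cahn type reaction-diffusion equation

    phi_t = D(t) * Laplacian(phi) + epsilon**-2 * f(phi)

whose two non-standard ingredients live here:

* ``D(t)`` is a *switch-off* diffusion coefficient: it equals ``D0`` during
  the initial-setting stage ``0 <= t < T`` and drops to exactly zero once
  the paste has set (``t >= T``), mimicking a Vicat-needle setting time.
* The cubic reaction ``f(phi) = phi*(1-phi)*(phi - phi_bar)`` has its
  unstable root at a *solid-formation threshold* ``phi_bar`` that decreases
  with the concentration ``c`` of the chelating agent IP6 (phytic acid):
  more IP6 makes solidification easier.

The module also provides the nondimensionalizing scale transform that
collapses the concentration dependence of ``(D0, T, epsilon)`` into
``phi_bar`` alone, under the proportionality assumption ``T ~ epsilon**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ModelParameters",
    "ScaleTransform",
    "ScaleConsistencyError",
    "solid_threshold",
    "reaction",
    "potential",
    "diffusion_coefficient",
    "scale_parameters",
]

#: Relative tolerance within which the two definitions of the time-scale
#: factor (epsilon**2/epsilon0**2 and T/tau0) must agree.
SCALE_CONSISTENCY_RTOL = 1e-12


class ScaleConsistencyError(ValueError):
    """The (epsilon, epsilon0, T, tau0) quadruple violates T ~ epsilon**2."""


def solid_threshold(c: float) -> float:
    """Solid-formation threshold ``phi_bar(c) = 0.5 / (1 + c/1000)``.

    ``phi_bar`` is the unstable middle root of the reaction cubic: cells
    above it flow toward solid (1), cells below it toward void (0).  It is
    strictly decreasing in the IP6 concentration ``c`` with range
    ``(0, 0.5]`` — more IP6 means solidification wins more easily.

    Parameters
    ----------
    c
        IP6 concentration, ``c >= 0``.  The caller's concentration scale is
        used unchanged (see `ModelParameters` notes).
    """
    if c < 0:
        raise ValueError(f"IP6 concentration must be nonnegative, got c={c}")
    return 0.5 / (1.0 + c / 1000.0)


def reaction(phi, phi_bar):
    """Cubic reaction term ``f(phi) = phi * (1 - phi) * (phi - phi_bar)``.

    Roots at 0, ``phi_bar`` and 1; negative on ``(0, phi_bar)`` and positive
    on ``(phi_bar, 1)``, so under the pure reaction ODE the order parameter
    flows away from ``phi_bar`` toward the stable states 0 (void) and 1
    (solid).  Accepts scalars or arrays.
    """
    return phi * (1.0 - phi) * (phi - phi_bar)


def potential(phi, phi_bar):
    """Double-well potential ``W(phi)`` with ``W'(phi) = -f(phi)``.

    ``W(phi) = phi**4/4 - (1 + phi_bar)*phi**3/3 + phi_bar*phi**2/2``.
    Used by the discrete Lyapunov energy of the solver.  ``W(0) = 0``
    always; the solid well has ``W(1) = phi_bar/6 - 1/12``, which is
    negative whenever ``phi_bar < 0.5`` (solid is the deeper well).
    """
    phi2 = phi * phi
    return phi2 * phi2 / 4.0 - (1.0 + phi_bar) * phi2 * phi / 3.0 + phi_bar * phi2 / 2.0


@dataclass(frozen=True)
class ModelParameters:
    """Physical/model constants of one simulation run.

    Attributes
    ----------
    D0
        Diffusion magnitude during the initial-setting stage (> 0).
    T
        Initial-setting completion time: the instant the diffusion
        coefficient switches off (> 0).  Operationally this is the
        Vicat-needle setting time mapped onto the model's time scale.
    epsilon
        Phase-separation strength (> 0); ``epsilon**-2`` multiplies the
        reaction term.
    c
        IP6 concentration (>= 0).  Accepted on whatever scale the caller
        uses; it enters only through ``solid_threshold(c)``.
    phi_bar
        Solid-formation threshold in (0, 1).  Derived from ``c`` via
        `solid_threshold` when not supplied; an explicit value overrides
        the formula (useful because the concentration scale of the
        threshold formula is a modelling choice).
    """

    D0: float = 0.01
    T: float = 0.8
    epsilon: float = 0.1
    c: float = 0.0
    phi_bar: float | None = None
    #: True when phi_bar was computed from c rather than supplied.
    phi_bar_derived: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.D0 <= 0:
            raise ValueError(f"D0 must be positive, got {self.D0}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.c < 0:
            raise ValueError(f"c must be nonnegative, got {self.c}")
        if self.phi_bar is None:
            object.__setattr__(self, "phi_bar", solid_threshold(self.c))
            object.__setattr__(self, "phi_bar_derived", True)
        if not 0.0 < self.phi_bar < 1.0:
            raise ValueError(f"phi_bar must lie in (0, 1), got {self.phi_bar}")


def diffusion_coefficient(t: float, params: ModelParameters) -> float:
    """Switch-off diffusion schedule ``D(t)``.

    Returns ``D0`` for ``0 <= t < T`` (strict inequality) and exactly 0 for
    ``t >= T``; right-continuous at the switch.  The two-valued step is
    used as printed — no smoothing — so the diffusion term disappears at a
    finite time, after which every grid cell evolves independently under
    the reaction alone (the "recuperation" stage).
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got t={t}")
    return params.D0 if t < params.T else 0.0


@dataclass(frozen=True)
class ScaleTransform:
    """Nondimensionalizing scale transform ``t = lam*tau``, ``x = sqrt(mu)*xi``.

    Built by `scale_parameters`.  ``lam = epsilon**2/epsilon0**2 = T/tau0``
    is the time-scale factor and ``mu = (D0/d0)*lam`` the space-scale
    factor; both must be positive.  Applying the transform maps a run with
    parameters ``(D0, T, epsilon)`` onto the reference run with
    ``(d0, tau0, epsilon0)`` — all concentration dependence of the PDE
    coefficients is absorbed, leaving only ``phi_bar(c)``.
    """

    epsilon0: float
    tau0: float
    d0: float
    lam: float
    mu: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.mu <= 0:
            raise ValueError(f"scale factors must be positive: lam={self.lam}, mu={self.mu}")

    # -- coordinate maps ---------------------------------------------------
    def physical_time(self, tau: float) -> float:
        """Map reduced time tau to physical time ``t = lam * tau``."""
        return self.lam * tau

    def reduced_time(self, t: float) -> float:
        """Map physical time t to reduced time ``tau = t / lam``."""
        return t / self.lam

    def physical_length(self, xi: float) -> float:
        """Map reduced coordinate xi to physical ``x = sqrt(mu) * xi``."""
        return math.sqrt(self.mu) * xi

    def reduced_length(self, x: float) -> float:
        """Map physical coordinate x to reduced ``xi = x / sqrt(mu)``."""
        return x / math.sqrt(self.mu)

    # -- parameter maps ----------------------------------------------------
    def reduce(self, params: ModelParameters) -> ModelParameters:
        """Parameters of the equivalent reduced run: ``(d0, tau0, epsilon0)``.

        The threshold ``phi_bar`` is carried over unchanged — it is the one
        quantity the transform does not touch.
        """
        return ModelParameters(
            D0=self.d0, T=self.tau0, epsilon=self.epsilon0,
            c=params.c, phi_bar=params.phi_bar,
        )

    def restore(self, reduced: ModelParameters) -> ModelParameters:
        """Invert `reduce`: recover the physical ``(D0, T, epsilon)``."""
        return ModelParameters(
            D0=reduced.D0 * self.mu / self.lam,
            T=reduced.T * self.lam,
            epsilon=reduced.epsilon * math.sqrt(self.lam),
            c=reduced.c, phi_bar=reduced.phi_bar,
        )


def scale_parameters(
    D0: float,
    T: float,
    epsilon: float,
    epsilon0: float,
    tau0: float,
    d0: float,
) -> ScaleTransform:
    """Build the scale transform onto the reference parameters.

    Checks the proportionality assumption ``T ~ epsilon**2`` by requiring
    the two expressions for the time-scale factor,
    ``epsilon**2/epsilon0**2`` and ``T/tau0``, to agree to relative
    tolerance ``1e-12``.  A mismatch raises `ScaleConsistencyError` naming
    both values: the assumption is a modelling statement and violations
    should be loud, not silently absorbed.
    """
    for name, v in [("D0", D0), ("T", T), ("epsilon", epsilon),
                    ("epsilon0", epsilon0), ("tau0", tau0), ("d0", d0)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    lam_eps = epsilon ** 2 / epsilon0 ** 2
    lam_time = T / tau0
    if not math.isclose(lam_eps, lam_time, rel_tol=SCALE_CONSISTENCY_RTOL):
        raise ScaleConsistencyError(
            "time-scale factor mismatch: epsilon**2/epsilon0**2 = "
            f"{lam_eps!r} but T/tau0 = {lam_time!r}; the quadruple violates "
            "the proportionality T ~ epsilon**2"
        )
    lam = lam_eps
    mu = (D0 / d0) * lam
    return ScaleTransform(epsilon0=epsilon0, tau0=tau0, d0=d0, lam=lam, mu=mu)
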
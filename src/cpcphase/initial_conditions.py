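"""Seeded generators for initial order-parameter fields.

The reference initial state is uniformly liquid paste (phi = 0.5) with a
small seeded perturbation: independent uniform noise of amplitude 5% of
the grid spacing h added to every cell.  The perturbation models the
coarseness/density fluctuations a real paste acquires on injection; the
instability of the liquid state then amplifies it into solid and void
domains.  An optional variant starts the setting from the domain rim.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .solver import OrderParameterField

__all__ = ["NoiseSpec", "noisy_uniform_field", "boundary_set_field", "load_field"]


@dataclass(frozen=True)
class NoiseSpec:
    """Perturbed-uniform initial condition: ``phi0 + U(-a*h, a*h)`` per cell.

    ``amplitude_fraction`` is interpreted as a fraction of the grid
    spacing h (the "5% of h" convention), so the absolute noise bound is
    ``amplitude_fraction * h`` — 5e-4 for N=200, L=1.  The distribution is
    symmetric uniform; this is a convention choice recorded in run
    manifests, since only the amplitude is prescribed by the model.
    """

    base_value: float = 0.5
    amplitude_fraction: float = 0.05
    seed: int = 0
    distribution: str = "uniform-symmetric"

    def __post_init__(self) -> None:
        if self.amplitude_fraction < 0:
            raise ValueError(f"amplitude_fraction must be >= 0, got {self.amplitude_fraction}")
        if not 0.0 < self.base_value < 1.0:
            raise ValueError(f"base_value must lie in (0, 1), got {self.base_value}")
        if self.distribution != "uniform-symmetric":
            raise ValueError(f"unsupported distribution {self.distribution!r}")

    def amplitude(self, h: float) -> float:
        """Absolute noise bound ``amplitude_fraction * h``."""
        return self.amplitude_fraction * h


def _rng(seed: int) -> np.random.Generator:
    # Counter-based generator: identical streams across platforms/runs.
    return np.random.Generator(np.random.Philox(seed))


def noisy_uniform_field(spec: NoiseSpec, N: int, L: float = 1.0) -> OrderParameterField:
    """Uniform field at ``base_value`` plus independent uniform cell noise.

    Cells are filled in row-major order from a single counter-based stream,
    so the same (seed, N, L, spec) always yields a bitwise-identical field.

    Raises a ``ValueError`` if the noise band ``base_value +- a*h`` leaves
    (0, 1): such a field would start partly solid/void by construction.
    """
    h = 2.0 * L / N
    a = spec.amplitude(h)
    if spec.base_value - a <= 0.0 or spec.base_value + a >= 1.0:
        raise ValueError(
            f"noise band [{spec.base_value - a}, {spec.base_value + a}] "
            "leaves the open interval (0, 1); reduce amplitude_fraction"
        )
    noise = _rng(spec.seed).uniform(-a, a, size=(N, N))
    return OrderParameterField(spec.base_value + noise, L=L, t=0.0)


def boundary_set_field(
    spec: NoiseSpec,
    N: int,
    L: float = 1.0,
    rim_width: float = 0.1,
    rim_value: float = 1.0,
) -> OrderParameterField:
    """Noisy liquid interior with an already-set rim along the boundary.

    Emulates setting that starts near the domain boundary: every cell whose
    center lies within ``rim_width`` of the boundary is set to
    ``rim_value``; the interior is drawn exactly as `noisy_uniform_field`
    (same seed => same interior noise).  ``rim_width -> 0`` recovers the
    plain noisy field, since cell centers sit h/2 away from the boundary.
    """
    if not 0.0 < rim_width < L:
        raise ValueError(f"rim_width must lie in (0, L), got {rim_width}")
    if not 0.0 < rim_value <= 1.0:
        raise ValueError(f"rim_value must lie in (0, 1], got {rim_value}")
    fld = noisy_uniform_field(spec, N, L)
    x = fld.cell_centers()
    dist = L - np.abs(x)  # distance of a cell center to the nearest boundary, per axis
    near = dist < rim_width
    mask = near[:, None] | near[None, :]
    fld.values[mask] = rim_value
    return fld


def load_field(path: str | Path, N: int, L: float = 1.0) -> OrderParameterField:
    """Read a user-supplied initial field from ``.npy`` or delimited text.

    The array shape must match the configured N; anything else is a
    configuration error, not silently resampled.
    """
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (N, N):
        raise ValueError(
            f"initial field in {path} has shape {values.shape}, expected ({N}, {N})"
        )
    return OrderParameterField(values, L=L, t=0.0)
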
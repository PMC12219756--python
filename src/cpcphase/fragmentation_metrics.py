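"""Void/fragmentation quantification and setting-time data reduction.

Snapshot fields are reduced to solid/void/intermediate label maps, void
area fractions and connected-void counts, and a per-run verdict:
*fragmentation* if a coherent void survives to the end of the run,
*non-fragmentation* if voids appeared but healed, *indeterminate* if no
void ever formed.  The same module reduces Vicat-needle penetration data
to a setting time T and wires it into the model's diffusion schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .model_core import ModelParameters
from .solver import OrderParameterField, SnapshotSeries

__all__ = [
    "PhaseLabelMap",
    "VoidSnapshot",
    "VoidReport",
    "PenetrationSeries",
    "classify_phase",
    "void_area_fraction",
    "connected_void_components",
    "void_timeline",
    "estimate_setting_time",
    "build_setting_schedule",
    "VOID",
    "INTERMEDIATE",
    "SOLID",
]

VOID, INTERMEDIATE, SOLID = 0, 1, 2

#: 4-connectivity structuring element (edge neighbors only).
_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

DEFAULT_THRESHOLDS = (0.1, 0.9)
DEFAULT_MIN_CELLS = 4


@dataclass
class PhaseLabelMap:
    """Per-cell solid/void/intermediate labels derived from phi.

    A cell is *void* iff ``phi <= theta_void``, *solid* iff
    ``phi >= theta_solid``, otherwise *intermediate* (incompletely set
    paste, including the liquid state phi ~ 0.5).  The thresholds default
    to (0.1, 0.9): the ideal phases are the exact values 0 and 1, so bands
    symmetric about 0.5 are needed to classify finite-precision fields.
    """

    labels: np.ndarray
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        theta_void, theta_solid = self.thresholds
        if not 0.0 < theta_void < theta_solid < 1.0:
            raise ValueError(
                f"thresholds must satisfy 0 < theta_void < theta_solid < 1, "
                f"got {self.thresholds}"
            )

    @property
    def N(self) -> int:
        return self.labels.shape[0]

    def counts(self) -> dict[str, int]:
        flat = np.bincount(self.labels.ravel(), minlength=3)
        return {"void": int(flat[VOID]), "intermediate": int(flat[INTERMEDIATE]),
                "solid": int(flat[SOLID])}


def classify_phase(
    field: OrderParameterField,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> PhaseLabelMap:
    """Label every cell as void / intermediate / solid by thresholding phi."""
    theta_void, theta_solid = thresholds
    if not 0.0 < theta_void < theta_solid < 1.0:
        raise ValueError(
            f"thresholds must satisfy 0 < theta_void < theta_solid < 1, got {thresholds}"
        )
    u = field.values
    labels = np.full(u.shape, INTERMEDIATE, dtype=np.int8)
    labels[u <= theta_void] = VOID
    labels[u >= theta_solid] = SOLID
    return PhaseLabelMap(labels=labels, thresholds=(theta_void, theta_solid))


def void_area_fraction(label_map: PhaseLabelMap) -> float:
    """Fraction of cells labeled void, in [0, 1]."""
    return float(np.count_nonzero(label_map.labels == VOID)) / label_map.labels.size


def connected_void_components(label_map: PhaseLabelMap, min_cells: int = DEFAULT_MIN_CELLS) -> int:
    """Number of 4-connected void components of at least ``min_cells`` cells.

    The size filter (default 4 cells) discards single-cell speckle left by
    the noisy initial data, so a counted component is a spatially coherent
    void region.  4-connectivity is the conservative choice: diagonal
    contact does not merge regions.
    """
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    mask = label_map.labels == VOID
    labeled, ncomp = ndimage.label(mask, structure=_FOUR_CONNECTED)
    if ncomp == 0:
        return 0
    sizes = np.bincount(labeled.ravel())[1:]  # skip background
    return int(np.count_nonzero(sizes >= min_cells))


@dataclass(frozen=True)
class VoidSnapshot:
    """Void metrics of one snapshot."""

    time: float
    void_area_fraction: float
    void_component_count: int


@dataclass
class VoidReport:
    """Per-snapshot void metrics plus the run-level fragmentation verdict.

    ``onset_time`` is the first snapshot with a counted void component;
    ``vanish_time`` the first later snapshot with none.  The verdict is
    *fragmentation* if the final snapshot still contains a void,
    *non-fragmentation* if a void appeared and healed by the end, and
    *indeterminate* if no void was ever detected.
    """

    snapshots: list[VoidSnapshot]
    onset_time: float | None = None
    vanish_time: float | None = None
    verdict: str = "indeterminate"
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    min_cells: int = DEFAULT_MIN_CELLS

    def __post_init__(self) -> None:
        if self.verdict not in ("fragmentation", "non-fragmentation", "indeterminate"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.vanish_time is not None:
            if self.onset_time is None or self.vanish_time <= self.onset_time:
                raise ValueError("vanish_time requires an earlier onset_time")

    def to_dict(self) -> dict:
        return {
            "thresholds": {"theta_void": self.thresholds[0], "theta_solid": self.thresholds[1]},
            "min_cells": self.min_cells,
            "snapshots": [
                {"time": s.time, "void_area_fraction": s.void_area_fraction,
                 "void_component_count": s.void_component_count}
                for s in self.snapshots
            ],
            "onset_time": self.onset_time,
            "vanish_time": self.vanish_time,
            "verdict": self.verdict,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_table(self, path: str | Path) -> None:
        """Per-snapshot metrics as a tab-separated table."""
        df = pd.DataFrame(
            {"time": [s.time for s in self.snapshots],
             "void_area_fraction": [s.void_area_fraction for s in self.snapshots],
             "void_component_count": [s.void_component_count for s in self.snapshots]}
        )
        df.to_csv(path, sep="\t", index=False)


def void_timeline(
    series: SnapshotSeries,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> VoidReport:
    """Track void metrics across a snapshot series and render the verdict."""
    snaps: list[VoidSnapshot] = []
    for t, fld in series.entries:
        label_map = classify_phase(fld, thresholds)
        snaps.append(VoidSnapshot(
            time=t,
            void_area_fraction=void_area_fraction(label_map),
            void_component_count=connected_void_components(label_map, min_cells),
        ))

    onset = next((s.time for s in snaps if s.void_component_count >= 1), None)
    vanish = None
    if onset is not None:
        vanish = next(
            (s.time for s in snaps if s.time > onset and s.void_component_count == 0),
            None,
        )
    if onset is None:
        verdict = "indeterminate"
    elif snaps[-1].void_component_count > 0:
        verdict = "fragmentation"
    else:
        verdict = "non-fragmentation"
    return VoidReport(snapshots=snaps, onset_time=onset, vanish_time=vanish,
                      verdict=verdict, thresholds=thresholds, min_cells=min_cells)


# ----------------------------------------------------------------------
# Vicat penetration data
# ----------------------------------------------------------------------

@dataclass
class PenetrationSeries:
    """Vicat-needle penetration depths over time (minutes, mm)."""

    times: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.times.size == 0 or self.times.shape != self.depths.shape:
            raise ValueError("times and depths must be nonempty arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if np.any(self.depths < 0):
            raise ValueError("penetration depths must be nonnegative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PenetrationSeries":
        """Read a two-column time/depth table (one header line, any common delimiter)."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError(f"{path} must have two columns (time, depth)")
        return cls(times=df.iloc[:, 0].to_numpy(), depths=df.iloc[:, 1].to_numpy())


def estimate_setting_time(series: PenetrationSeries) -> float | None:
    """Setting time: the earliest measurement at which the needle no longer
    penetrates (depth exactly 0 mm).

    Returns ``None`` when the paste never reached zero depth within the
    observation window; no interpolation or extrapolation is attempted,
    mirroring the operational definition of the needle test.
    """
    zero = np.flatnonzero(series.depths == 0.0)
    if zero.size == 0:
        return None
    return float(series.times[zero[0]])


def build_setting_schedule(T: float, D0: float = 0.01, **kwargs) -> ModelParameters:
    """Wire a measured setting time into the model's diffusion schedule.

    Returns `ModelParameters` whose switch-off time is T and diffusion
    magnitude D0, so ``diffusion_coefficient`` equals D0 before T and 0
    from T on.  Extra keyword arguments (epsilon, c, phi_bar) pass through.
    """
    if T <= 0:
        raise ValueError(f"setting time must be positive, got T={T}")
    if D0 <= 0:
        raise ValueError(f"D0 must be positive, got {D0}")
    return ModelParameters(D0=D0, T=T, **kwargs)
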
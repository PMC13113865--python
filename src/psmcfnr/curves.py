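"""FNR correction and projection of Ne trajectories onto a shared time grid.

PSMC discretizes coalescent time differently for every inference, so two
trajectories cannot be compared pointwise as emitted.  Here every
trajectory is projected onto a shared logarithmic grid of time points
(default: 60 points, 10 kya to 1.5 Mya) as an ordered planar point
sequence with x = log10(time in years) and y = Ne / 1e4 individuals, the
psmc_plot axis units.  Distances between curves are computed in that
plane.

The false-negative-rate correction rescales the PSMC scaled mutation rate,
theta0 -> theta0 / (1 - FNR), which propagates multiplicatively to N0 and
hence to both the time and Ne axes: all coordinates are multiplied by
1 / (1 - FNR).  Missed heterozygotes at low coverage deflate theta0, so an
uncorrected low-coverage curve sits below and to the left of the truth;
the correction pushes it back up and out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .psmc_io import ScaledTrajectory

__all__ = [
    "TimeGrid",
    "ProjectedCurve",
    "DEFAULT_GRID",
    "RECENT_STABLE_GRID",
    "apply_fnr_correction",
    "build_grid",
    "project_onto_grid",
]


@dataclass(frozen=True)
class TimeGrid:
    """Log10-uniform vector of time points (years), endpoints inclusive."""

    n_points: int = 60
    t_min: float = 1.0e4
    t_max: float = 1.5e6

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("require 0 < t_min < t_max")

    @property
    def times(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.t_min), np.log10(self.t_max), self.n_points
        )


#: 60 points spanning 10 kya - 1.5 Mya, the general-purpose window.
DEFAULT_GRID = TimeGrid()
#: Same span but starting at 50 kya, for trajectories whose most recent
#: segments are unstable (e.g. the sharp recent Ne peak in non-African
#: human inferences); window choice is the analyst's, never automatic.
RECENT_STABLE_GRID = TimeGrid(t_min=5.0e4)


@dataclass(frozen=True)
class ProjectedCurve:
    """A trajectory sampled on a grid: ordered points (log10 years, Ne/y_scale)."""

    points: np.ndarray  # shape (m, 2)
    grid: TimeGrid
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (m, 2) array")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("x coordinates must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def __len__(self) -> int:
        return int(self.points.shape[0])


def build_grid(n_points: int = 60, t_min: float = 1.0e4, t_max: float = 1.5e6) -> TimeGrid:
    """Construct a log10-uniform time grid; see :class:`TimeGrid`."""
    return TimeGrid(n_points=n_points, t_min=t_min, t_max=t_max)


def apply_fnr_correction(traj: ScaledTrajectory, fnr: float) -> ScaledTrajectory:
    """Rescale a trajectory for a false-negative rate ``fnr`` in [0, 1).

    Both segment start times and Ne are multiplied by 1/(1-fnr); fnr=0 is
    the identity.  The returned trajectory records ``fnr`` as applied.
    """
    if not 0.0 <= fnr < 1.0:
        raise ValueError(f"fnr must lie in [0, 1), got {fnr}")
    if fnr == 0.0:
        return replace(traj, fnr_applied=0.0)
    factor = 1.0 / (1.0 - fnr)
    return ScaledTrajectory(
        traj.times * factor, traj.ne * factor, traj.meta, fnr_applied=fnr
    )


def project_onto_grid(
    traj: ScaledTrajectory,
    grid: TimeGrid,
    y_scale: float = 1.0e4,
    log_y: bool = False,
    label: str | None = None,
) -> ProjectedCurve:
    """Sample a piecewise-constant trajectory at the grid's time points.

    Step lookup, no interpolation: grid time t takes the Ne of the segment
    whose right-open interval [t_k, t_{k+1}) contains it; times before the
    first segment start clamp to the first segment, times at or beyond the
    last start use the last segment.  y is Ne divided by ``y_scale``
    (optionally log10-transformed), x is log10(t).
    """
    t = grid.times
    # searchsorted(side="right") - 1 gives the segment with start <= t,
    # honouring the right-open convention at exact boundaries.
    idx = np.searchsorted(traj.times, t, side="right") - 1
    idx = np.clip(idx, 0, traj.n_segments - 1)
    y = traj.ne[idx] / y_scale
    if log_y:
        y = np.log10(y)
    points = np.column_stack([np.log10(t), y])
    return ProjectedCurve(points, grid, label=label if label is not None else traj.meta.sample_id)
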
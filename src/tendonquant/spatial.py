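"""Recruitment geometry: distances to the core, compartments, cumulative curves.

The assembloid core is modeled as a strip around a centerline polyline (the
clamped explant); in vivo lesions as a circle (default radius 480 µm around
the center of the Achilles tendon).  Marker-positive cells are classified as
core-resident or extrinsic, counted into a core/extrinsic recruitment ratio,
and summarized as cumulative distance distributions (mean ± sem over
biological samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoreGeometry",
    "distance_to_centerline",
    "classify_compartment",
    "core_extrinsic_ratio",
    "cumulative_distribution",
    "lesion_circle_fraction",
]

DEFAULT_LESION_RADIUS_UM = 480.0


@dataclass(frozen=True)
class CoreGeometry:
    """Core region: either a centerline strip or a lesion circle (all µm).

    Use the :meth:`strip` and :meth:`circle` constructors.
    """

    kind: str
    centerline: np.ndarray | None = None  # (M, 2) array of (x, y) vertices
    half_width: float | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None

    @classmethod
    def strip(cls, centerline: Sequence[Sequence[float]], half_width: float) -> "CoreGeometry":
        pts = np.asarray(centerline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("centerline must be an (M, 2) polyline with M >= 2")
        if half_width <= 0:
            raise ValueError("half_width must be > 0")
        return cls(kind="strip", centerline=pts, half_width=float(half_width))

    @classmethod
    def circle(
        cls,
        center: Sequence[float],
        radius: float = DEFAULT_LESION_RADIUS_UM,
    ) -> "CoreGeometry":
        if radius <= 0:
            raise ValueError("radius must be > 0")
        cx, cy = (float(center[0]), float(center[1]))
        return cls(kind="circle", center=(cx, cy), radius=float(radius))


def _points_from(cells) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(cells, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(1, 2)
    return pts


def distance_to_centerline(cells, geometry: CoreGeometry) -> np.ndarray:
    """Euclidean distance (µm) from each cell centroid to the centerline.

    Distances are minima over the polyline segments, using perpendicular
    projection clamped at segment endpoints.  ``cells`` may be a cell table
    with ``x_um``/``y_um`` columns or an (N, 2) coordinate array.
    """
    if geometry.kind != "strip":
        raise ValueError("distance_to_centerline requires strip geometry")
    pts = _points_from(cells)
    if pts.size == 0:
        raise ValueError("empty cell table")
    line = geometry.centerline
    a = line[:-1]  # (S, 2) segment starts
    b = line[1:]  # (S, 2) segment ends
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom = np.where(denom == 0, 1.0, denom)  # degenerate zero-length segment
    # t: projection parameter of every point on every segment, clamped to [0,1]
    diff = pts[:, None, :] - a[None, :, :]  # (N, S, 2)
    t = np.clip((diff * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.sqrt(((pts[:, None, :] - proj) ** 2).sum(axis=2))
    return d.min(axis=1)


def classify_compartment(distances, half_width: float) -> np.ndarray:
    """Label cells ``"core"`` when distance <= half_width (closed interval),
    else ``"extrinsic"``."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    d = np.asarray(distances, dtype=float)
    return np.where(d <= half_width, "core", "extrinsic")


def core_extrinsic_ratio(positive, compartment) -> float:
    """Ratio of core-resident to extrinsic marker-positive cells.

    This is the recruitment readout: positive cells inside the core strip
    divided by those remaining in the surrounding extrinsic compartment
    (raw counts).  Returns NaN with a warning when there are no extrinsic
    positives — the ratio is undefined, not infinite.
    """
    positive = np.asarray(positive, dtype=bool)
    compartment = np.asarray(compartment)
    n_core = int((positive & (compartment == "core")).sum())
    n_ext = int((positive & (compartment == "extrinsic")).sum())
    if n_ext == 0:
        warnings.warn(
            "no extrinsic marker-positive cells; core/extrinsic ratio undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return n_core / n_ext


def cumulative_distribution(
    distances_per_sample: Sequence[np.ndarray],
    grid: np.ndarray | None = None,
    grid_step: float = 25.0,
) -> pd.DataFrame:
    """Mean ± sem cumulative distance distribution across samples.

    For each sample the curve is the percentage of its marker-positive cells
    whose distance from the centerline is <= d, evaluated on a common grid
    (default: 0 to the maximum observed distance in ``grid_step`` µm steps,
    extended to cover the maximum).  Curves are then averaged pointwise over
    samples with the standard error of the mean; with a single sample the
    sem is 0 by convention (a warning is emitted).

    Returns a DataFrame with columns ``distance_um``, ``mean_pct``,
    ``sem_pct`` and ``n_samples``.
    """
    samples = [np.asarray(d, dtype=float) for d in distances_per_sample]
    samples = [s for s in samples if s.size > 0]
    if not samples:
        raise ValueError("need at least one sample with at least one cell")
    if grid is None:
        dmax = max(s.max() for s in samples)
        n_steps = int(np.ceil(dmax / grid_step)) if dmax > 0 else 1
        grid = np.arange(0, n_steps + 1) * grid_step
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty grid")
    curves = np.stack(
        [100.0 * (s[None, :] <= grid[:, None]).mean(axis=1) for s in samples]
    )
    mean = curves.mean(axis=0)
    if len(samples) == 1:
        warnings.warn(
            "single sample: sem is 0 by convention", RuntimeWarning, stacklevel=2
        )
        sem = np.zeros_like(mean)
    else:
        sem = curves.std(axis=0, ddof=1) / np.sqrt(len(samples))
    return pd.DataFrame(
        {
            "distance_um": grid,
            "mean_pct": mean,
            "sem_pct": sem,
            "n_samples": len(samples),
        }
    )


def lesion_circle_fraction(cells, positive, geometry: CoreGeometry) -> float:
    """Percent of marker-positive cells inside the lesion circle.

    A cell is inside iff its distance to the circle center is <= radius.
    Returns NaN with a warning when there are no marker-positive cells.
    """
    if geometry.kind != "circle":
        raise ValueError("lesion_circle_fraction requires circle geometry")
    pts = _points_from(cells)
    positive = np.asarray(positive, dtype=bool)
    if positive.sum() == 0:
        warnings.warn(
            "no marker-positive cells; lesion fraction undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    pts = pts[positive]
    cx, cy = geometry.center
    d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return 100.0 * (d <= geometry.radius).mean()
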
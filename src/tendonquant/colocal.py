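"""Marker calling and co-localization percentages.

Per-cell intensities (from :mod:`tendonquant.imgseg`) are dichotomized into
marker-positive / negative calls using a threshold calibrated either from
the bimodal density of the intensities themselves (the valley between the
negative and positive mode of a kernel density estimate) or from a
percentile of a negative-control image, mirroring how reporter signal
thresholds are set from density plots plus a negative control in practice.
All percentages downstream of the calls — marker-positive fraction of all
cells, and conditional co-localization fractions such as "CD90+ as percent
of IL-6+ cells" — are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

__all__ = [
    "ThresholdEstimate",
    "MarkerThreshold",
    "estimate_threshold",
    "call_markers",
    "marker_fraction",
    "conditional_fraction",
    "summarize_by_sample",
]


@dataclass
class ThresholdEstimate:
    """A calibrated intensity threshold and how it was obtained."""

    marker: str
    threshold: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


class MarkerThreshold(BaseEstimator):
    """Estimate a marker intensity threshold and call cells against it.

    Methods
    -------
    ``density_valley``
        Kernel density estimate (Silverman bandwidth) of the per-cell
        intensities on a 512-point grid; the threshold is the density
        minimum between the two largest modes.  If fewer than two modes are
        found the estimator falls back to the negative-control percentile;
        without a control this is an error.
    ``negative_control_percentile``
        The ``percentile``-th percentile (type-7 / linear interpolation) of
        the negative-control intensities.
    ``fixed``
        A user-supplied value.

    Calls are strict: a cell is positive iff intensity > threshold.
    """

    def __init__(
        self,
        method: str = "density_valley",
        percentile: float = 99.0,
        fixed_value: float | None = None,
        grid_size: int = 512,
    ):
        self.method = method
        self.percentile = percentile
        self.fixed_value = fixed_value
        self.grid_size = grid_size

    def fit(self, X, negative_control=None) -> "MarkerThreshold":
        if self.method not in ("density_valley", "negative_control_percentile", "fixed"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError("percentile must lie in [0, 100]")
        x = np.asarray(X, dtype=float).ravel()
        control = (
            None
            if negative_control is None
            else np.asarray(negative_control, dtype=float).ravel()
        )
        self.diagnostics_ = {}

        if self.method == "fixed":
            if self.fixed_value is None:
                raise ValueError("fixed_value required for method='fixed'")
            self.threshold_ = float(self.fixed_value)
            self.method_used_ = "fixed"
            return self

        if self.method == "negative_control_percentile":
            self.threshold_ = self._control_percentile(control)
            self.method_used_ = "negative_control_percentile"
            return self

        # density_valley
        if x.size < 10:
            raise ValueError("density_valley requires at least 10 intensity values")
        valley = self._density_valley(x)
        if valley is None:
            if control is None:
                raise ValueError(
                    "density_valley found fewer than two modes and no negative "
                    "control was provided: the percentile fallback is unavailable"
                )
            self.threshold_ = self._control_percentile(control)
            self.method_used_ = "negative_control_percentile"
        else:
            self.threshold_ = valley
            self.method_used_ = "density_valley"
        return self

    def _control_percentile(self, control: np.ndarray | None) -> float:
        if control is None or control.size == 0:
            raise ValueError(
                "negative_control_percentile requires negative-control intensities"
            )
        value = float(np.percentile(control, self.percentile))  # type-7 default
        self.diagnostics_["percentile"] = self.percentile
        return value

    def _density_valley(self, x: np.ndarray) -> float | None:
        if np.ptp(x) == 0:
            return None  # degenerate constant intensities: no modes
        try:
            kde = gaussian_kde(x, bw_method="silverman")
        except np.linalg.LinAlgError:
            return None
        grid = np.linspace(x.min(), x.max(), self.grid_size)
        density = kde(grid)
        peaks, _ = find_peaks(density)
        # interior peaks only; a monotone density has none
        if peaks.size < 2:
            return None
        top2 = peaks[np.argsort(density[peaks])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        valley_idx = lo + int(np.argmin(density[lo : hi + 1]))
        self.diagnostics_["modes"] = grid[top2].tolist()
        return float(grid[valley_idx])

    def predict(self, X) -> np.ndarray:
        """Boolean marker calls: intensity strictly greater than threshold."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("MarkerThreshold must be fitted before predict")
        return np.asarray(X, dtype=float) > self.threshold_


def estimate_threshold(
    intensities: Sequence[float],
    negative_control: Sequence[float] | None = None,
    method: str = "density_valley",
    percentile: float = 99.0,
    fixed_value: float | None = None,
    marker: str = "marker",
) -> ThresholdEstimate:
    """Functional wrapper over :class:`MarkerThreshold`."""
    est = MarkerThreshold(
        method=method, percentile=percentile, fixed_value=fixed_value
    ).fit(intensities, negative_control=negative_control)
    return ThresholdEstimate(
        marker=marker,
        threshold=est.threshold_,
        method=est.method_used_,
        diagnostics=dict(est.diagnostics_),
    )


def call_markers(
    cells: pd.DataFrame,
    thresholds: Mapping[str, ThresholdEstimate | float],
) -> pd.DataFrame:
    """Apply per-marker thresholds to a cell table.

    ``cells`` must carry one ``<marker>_mean`` intensity column per marker in
    ``thresholds``.  Returns a table with the same ``cell_id`` values, one
    boolean ``<marker>_positive`` column per marker, and a ``<marker>_threshold``
    column recording the value used.  Positivity is strict (> threshold).
    """
    out = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()})
    for carry in ("sample_id", "group"):
        if carry in cells.columns:
            out[carry] = cells[carry].to_numpy()
    for marker, thr in thresholds.items():
        column = f"{marker}_mean"
        if column not in cells.columns:
            raise KeyError(
                f"marker {marker!r}: channel column {column!r} missing from cell table"
            )
        value = thr.threshold if isinstance(thr, ThresholdEstimate) else float(thr)
        out[f"{marker}_positive"] = cells[column].to_numpy() > value
        out[f"{marker}_threshold"] = value
    return out


def marker_fraction(calls: pd.DataFrame, marker: str) -> float:
    """Marker-positive cells as a percent of all cells."""
    if len(calls) == 0:
        raise ValueError("cannot compute a fraction of an empty cell table")
    positive = calls[f"{marker}_positive"].to_numpy(dtype=bool)
    return 100.0 * positive.sum() / positive.size


def conditional_fraction(calls: pd.DataFrame, target_marker: str, given_marker: str) -> float:
    """Target-positive cells as a percent of given-positive cells.

    Example: ``conditional_fraction(calls, "cd90", "il6")`` is the percentage
    of IL-6+ cells that are also CD90+.  Returns NaN (with a warning) when no
    cell is positive for the conditioning marker — the quantity is undefined,
    not zero.
    """
    if len(calls) == 0:
        raise ValueError("cannot compute a fraction of an empty cell table")
    given = calls[f"{given_marker}_positive"].to_numpy(dtype=bool)
    if given.sum() == 0:
        warnings.warn(
            f"no cell is positive for {given_marker!r}; conditional fraction undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    target = calls[f"{target_marker}_positive"].to_numpy(dtype=bool)
    return 100.0 * (target & given).sum() / given.sum()


def summarize_by_sample(
    per_image: pd.DataFrame,
    value_column: str,
    sample_column: str = "sample_id",
    group_column: str | None = "group",
) -> pd.DataFrame:
    """Aggregate image-level statistics to one value per biological sample.

    Each boxplot datapoint in the quantification scheme is the mean over the
    set of images taken from the same sample, so group-level statistics are
    computed on sample means, not on individual images.
    """
    keys = [sample_column]
    if group_column is not None and group_column in per_image.columns:
        keys.append(group_column)
    out = per_image.groupby(keys, sort=True)[value_column].mean().reset_index()
    return out
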
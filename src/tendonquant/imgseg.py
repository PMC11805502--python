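"""Nuclear segmentation and per-cell intensity measurement.

The cell registry is built the way the source images are quantified in
practice: a mask is created from the nuclear channel (DAPI/NucBlue), and the
fluorescence of every other channel is measured at the identified cell
locations.  Secreted or membrane signal (e.g. IL-6 around a secreting cell)
is attributed to the nearest nucleus within a configurable proximity radius.

Physical units: images carry a ``pixel_size`` in µm/pixel; all distances,
areas and radii exposed by this module are in µm / µm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from skimage import filters
from sklearn.base import BaseEstimator

__all__ = [
    "ImageStack",
    "NuclearMask",
    "NucleusSegmenter",
    "segment_nuclei",
    "extract_cells",
    "write_stack",
    "read_stack",
]


@dataclass
class ImageStack:
    """Named 2-D intensity channels sharing one pixel grid.

    Parameters
    ----------
    channels:
        Mapping from channel name (e.g. ``"nuclei"``, ``"scxgfp"``) to a
        2-D float array of arbitrary units.
    pixel_size:
        Physical edge length of one pixel in µm.
    sample_id, group:
        Optional identifiers carried through to downstream tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    sample_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class NuclearMask:
    """Labeled nuclei (0 = background, 1..K = nuclei) plus the parameters used."""

    labels: np.ndarray
    pixel_size: float
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


class NucleusSegmenter(BaseEstimator):
    """Segment nuclei from the nuclear channel of an :class:`ImageStack`.

    Pipeline: Gaussian smoothing -> global threshold (Otsu by default, or a
    fixed value for negative controls) -> hole filling -> connected-component
    labeling -> removal of regions below ``min_area``.

    Parameters
    ----------
    smoothing_sigma : float
        Gaussian sigma in µm applied before thresholding.
    threshold_method : {"otsu", "fixed"}
    threshold_value : float, optional
        Required when ``threshold_method="fixed"``.
    min_area : float
        Minimum nuclear area in µm²; smaller regions are discarded.
    nuclear_channel : str
        Name of the nuclear channel in the stack.
    """

    def __init__(
        self,
        smoothing_sigma: float = 1.0,
        threshold_method: str = "otsu",
        threshold_value: float | None = None,
        min_area: float = 10.0,
        nuclear_channel: str = "nuclei",
    ):
        self.smoothing_sigma = smoothing_sigma
        self.threshold_method = threshold_method
        self.threshold_value = threshold_value
        self.min_area = min_area
        self.nuclear_channel = nuclear_channel

    def _validate(self) -> None:
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be > 0")
        if self.min_area <= 0:
            raise ValueError("min_area must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("threshold_value required for threshold_method='fixed'")

    def fit(self, X=None, y=None) -> "NucleusSegmenter":
        """Stateless transformer; present for pipeline compatibility."""
        self._validate()
        self.fitted_ = True
        return self

    def transform(self, stack: ImageStack) -> NuclearMask:
        self._validate()
        if self.nuclear_channel not in stack.channels:
            raise KeyError(
                f"nuclear channel {self.nuclear_channel!r} not in stack "
                f"(have {sorted(stack.channels)})"
            )
        img = stack.channels[self.nuclear_channel]
        sigma_px = self.smoothing_sigma / stack.pixel_size
        smoothed = filters.gaussian(img, sigma=sigma_px, preserve_range=True)

        if smoothed.min() == smoothed.max():
            # Flat image (e.g. blank negative control): nothing to segment.
            labels = np.zeros(smoothed.shape, dtype=np.int32)
            threshold = float(smoothed.min())
        else:
            if self.threshold_method == "otsu":
                threshold = float(filters.threshold_otsu(smoothed))
            else:
                threshold = float(self.threshold_value)
            binary = smoothed > threshold
            binary = ndi.binary_fill_holes(binary)
            labels, _ = ndi.label(binary)
            min_area_px = self.min_area / stack.pixel_size**2
            sizes = np.bincount(labels.ravel())
            keep = np.flatnonzero(sizes >= min_area_px)
            keep = keep[keep > 0]
            remap = np.zeros(sizes.size, dtype=np.int32)
            remap[keep] = np.arange(1, keep.size + 1)
            labels = remap[labels]

        return NuclearMask(
            labels=labels,
            pixel_size=stack.pixel_size,
            params={
                "smoothing_sigma": self.smoothing_sigma,
                "threshold_method": self.threshold_method,
                "threshold": threshold,
                "min_area": self.min_area,
                "nuclear_channel": self.nuclear_channel,
            },
        )

    # alias matching the operation name used throughout the docs
    segment = transform


def segment_nuclei(
    stack: ImageStack,
    smoothing_sigma: float = 1.0,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_area: float = 10.0,
    nuclear_channel: str = "nuclei",
) -> NuclearMask:
    """Functional wrapper over :class:`NucleusSegmenter`."""
    return NucleusSegmenter(
        smoothing_sigma=smoothing_sigma,
        threshold_method=threshold_method,
        threshold_value=threshold_value,
        min_area=min_area,
        nuclear_channel=nuclear_channel,
    ).transform(stack)


def extract_cells(
    mask: NuclearMask,
    stack: ImageStack,
    proximity_dilation: float = 2.0,
) -> pd.DataFrame:
    """Build the per-cell table: centroid, area and per-channel mean intensity.

    Each labeled nucleus is (optionally) dilated by ``proximity_dilation`` µm
    before intensities are averaged, so that peri-nuclear signal (secreted
    protein, membrane markers, cytoplasmic GFP) is attributed to the cell by
    spatial proximity.  Where dilations of neighboring cells collide, every
    pixel is assigned to the *nearest* nucleus, so pixels are counted for
    exactly one cell.

    Returns a DataFrame with one row per mask label: ``cell_id``, ``x_um``,
    ``y_um`` (centroid), ``area_um2`` and one ``<channel>_mean`` column per
    channel of the stack.
    """
    if proximity_dilation < 0:
        raise ValueError("proximity_dilation must be >= 0")
    labels = mask.labels
    if labels.shape != stack.shape:
        raise ValueError("mask and stack have different shapes")
    n = mask.n_cells
    px = stack.pixel_size

    if proximity_dilation > 0 and n > 0:
        dist, (ri, ci) = ndi.distance_transform_edt(
            labels == 0, sampling=px, return_indices=True
        )
        region = np.where(dist <= proximity_dilation, labels[ri, ci], 0)
    else:
        region = labels

    records: dict[str, np.ndarray] = {}
    index = np.arange(1, n + 1)
    if n > 0:
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, index)
        centroids = np.asarray(centroids, dtype=float)  # (n, 2) rows, cols
        areas = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, index)
    else:
        centroids = np.empty((0, 2))
        areas = np.empty(0)
    records["cell_id"] = index
    records["x_um"] = centroids[:, 1] * px if n else np.empty(0)
    records["y_um"] = centroids[:, 0] * px if n else np.empty(0)
    records["area_um2"] = areas * px**2
    for name, channel in stack.channels.items():
        if n > 0:
            means = ndi.mean(channel, labels=region, index=index)
        else:
            means = np.empty(0)
        records[f"{name}_mean"] = np.asarray(means, dtype=float)

    table = pd.DataFrame(records)
    if stack.sample_id is not None:
        table.insert(0, "sample_id", stack.sample_id)
    if stack.group is not None:
        table.insert(1 if stack.sample_id is not None else 0, "group", stack.group)
    return table


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a multi-channel TIFF (one page per channel) plus a JSON sidecar
    holding channel names, pixel size and identifiers."""
    path = Path(path)
    data = np.stack([stack.channels[k] for k in stack.channels], axis=0)
    tifffile.imwrite(path, data.astype(np.float32))
    sidecar = {
        "channels": list(stack.channels),
        "pixel_size": stack.pixel_size,
        "sample_id": stack.sample_id,
        "group": stack.group,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> ImageStack:
    """Inverse of :func:`write_stack`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    channels = {name: data[i] for i, name in enumerate(meta["channels"])}
    return ImageStack(
        channels=channels,
        pixel_size=meta["pixel_size"],
        sample_id=meta.get("sample_id"),
        group=meta.get("group"),
    )
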
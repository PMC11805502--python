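"""Synthetic tendon-section images and two-group expression matrices.

Every downstream stage of the package (segmentation, marker calling, spatial
recruitment statistics, moderated differential expression) is benchmarked
against data generated here, because the quantities the pipeline estimates
are known exactly by construction:

* :func:`generate_section_image` renders a multi-channel fluorescence image
  of a tendon section or assembloid cross-section — a horizontal *core* strip
  of clamped explant tissue surrounded by the *extrinsic* compartment — and
  exports a ground-truth table with every cell's position, compartment and
  per-marker status.
* :func:`generate_expression_matrix` draws a log2 expression matrix whose
  gene-wise variances follow a scaled inverse-chi-square prior
  sigma_g^2 ~ s0^2 * d0 / chi2(d0), the distributional assumption behind
  empirical-Bayes variance moderation, with a planted fraction of
  differentially expressed genes, replicated probes and low-expression genes.

Coordinates are 0-based pixel indices; physical units enter through
``pixel_size`` (µm/pixel) with the origin at the top-left corner.  The core
centerline is the horizontal mid-row of the image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imgseg import ImageStack

__all__ = [
    "MarkerSpec",
    "SynthImageConfig",
    "SynthExprConfig",
    "SynthExpression",
    "PlacementError",
    "generate_section_image",
    "generate_assembloid_pair",
    "generate_expression_matrix",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap (density too high)."""


@dataclass(frozen=True)
class MarkerSpec:
    """Intensity model of one fluorescent marker.

    Positive cells draw their painted intensity from
    N(pos_intensity_mean, pos_intensity_sd), negative cells from
    N(neg_intensity_mean, neg_intensity_sd); the positive mean must exceed
    the negative mean.
    """

    name: str
    positive_fraction_core: float = 0.45
    positive_fraction_extrinsic: float = 0.45
    pos_intensity_mean: float = 1000.0
    pos_intensity_sd: float = 100.0
    neg_intensity_mean: float = 100.0
    neg_intensity_sd: float = 30.0

    def __post_init__(self) -> None:
        for f in (self.positive_fraction_core, self.positive_fraction_extrinsic):
            if not 0.0 <= f <= 1.0:
                raise ValueError("positive fractions must lie in [0, 1]")
        if self.pos_intensity_mean <= self.neg_intensity_mean:
            raise ValueError("pos_intensity_mean must exceed neg_intensity_mean")


def _default_markers() -> tuple[MarkerSpec, ...]:
    return (MarkerSpec(name="marker"),)


@dataclass(frozen=True)
class SynthImageConfig:
    """Geometry, cell counts and signal model of one synthetic section.

    Lengths are µm.  ``gradient_scale`` (optional) is the decay length of an
    exponential core-directed density gradient applied to extrinsic cells
    positive for the *first* marker — emulating recruitment of reporter-
    positive fibroblasts toward the signaling core.  ``None`` means uniform
    placement (no recruitment).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    core_half_width: float = 60.0
    n_cells_core: int = 120
    n_cells_extrinsic: int = 280
    nucleus_radius: float = 4.0
    marker_specs: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    gradient_scale: float | None = None
    psf_sigma: float = 0.5
    noise_sd: float = 20.0
    nuclear_intensity: float = 800.0
    min_separation: float | None = None  # default: 2 r + 4 psf_sigma
    max_retries: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "core_half_width", "nucleus_radius", "nuclear_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        if self.n_cells_core < 0 or self.n_cells_extrinsic < 0:
            raise ValueError("cell counts must be >= 0")
        if self.gradient_scale is not None and self.gradient_scale <= 0:
            raise ValueError("gradient_scale must be > 0 when given")
        if not self.marker_specs:
            raise ValueError("at least one marker spec is required")
        names = [m.name for m in self.marker_specs]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    @property
    def centerline_y(self) -> float:
        """y-coordinate (µm) of the horizontal core centerline (mid-row)."""
        return self.image_shape[0] * self.pixel_size / 2.0

    @property
    def effective_min_separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 2.0 * self.nucleus_radius + 4.0 * self.psf_sigma


def _place_cells(config: SynthImageConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign compartments and marker statuses, then draw non-overlapping
    positions.  Returns the ground-truth table (without intensities)."""
    h_um = config.image_shape[0] * config.pixel_size
    w_um = config.image_shape[1] * config.pixel_size
    margin = config.nucleus_radius + 2.0 * config.pixel_size
    yc = config.centerline_y
    hw = config.core_half_width

    compartments = ["core"] * config.n_cells_core + ["extrinsic"] * config.n_cells_extrinsic
    n = len(compartments)
    status = {}
    for spec in config.marker_specs:
        p = np.where(
            np.array(compartments) == "core",
            spec.positive_fraction_core,
            spec.positive_fraction_extrinsic,
        )
        status[spec.name] = rng.random(n) < p

    gradient_marker = config.marker_specs[0].name
    min_sep2 = config.effective_min_separation**2
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    retries = 0
    ext_lo, ext_hi = margin, h_um - margin
    while placed < n:
        comp = compartments[placed]
        x = rng.uniform(margin, w_um - margin)
        if comp == "core":
            y = rng.uniform(max(yc - hw, margin), min(yc + hw, h_um - margin))
        else:
            use_gradient = (
                config.gradient_scale is not None
                and np.isfinite(config.gradient_scale)
                and status[gradient_marker][placed]
            )
            if use_gradient:
                d = hw + rng.exponential(config.gradient_scale)
                y = yc + d if rng.random() < 0.5 else yc - d
                if not (ext_lo <= y <= ext_hi):
                    retries += 1
                    if retries > config.max_retries:
                        raise PlacementError(
                            f"failed to place cell {placed + 1}/{n} after "
                            f"{config.max_retries} retries; reduce cell density or "
                            f"min_separation ({config.effective_min_separation:.1f} µm)"
                        )
                    continue
            else:
                # uniform over the extrinsic region (outside the core strip)
                y = rng.uniform(ext_lo, ext_hi)
                if abs(y - yc) <= hw:
                    retries += 1
                    if retries > config.max_retries:
                        raise PlacementError(
                            f"failed to place cell {placed + 1}/{n} after "
                            f"{config.max_retries} retries; reduce cell density or "
                            f"min_separation ({config.effective_min_separation:.1f} µm)"
                        )
                    continue
        if placed > 0:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if d2.min() < min_sep2:
                retries += 1
                if retries > config.max_retries:
                    raise PlacementError(
                        f"failed to place cell {placed + 1}/{n} after "
                        f"{config.max_retries} retries; reduce cell density or "
                        f"min_separation ({config.effective_min_separation:.1f} µm)"
                    )
                continue
        xs[placed] = x
        ys[placed] = y
        placed += 1

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "x_um": xs,
            "y_um": ys,
            "compartment": compartments,
        }
    )
    for name, st in status.items():
        truth[f"{name}_positive"] = st
    return truth


def generate_section_image(
    config: SynthImageConfig,
    sample_id: str | None = None,
    group: str | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render one synthetic section and export its ground truth.

    The nuclear channel contains one blurred disk of radius
    ``nucleus_radius`` per cell; each marker channel paints the same disk
    with an intensity drawn from the positive or negative distribution
    according to the cell's ground-truth status.  All channels are convolved
    with a Gaussian PSF and Gaussian read noise of sd ``noise_sd`` is added.

    Returns ``(stack, truth)`` where ``truth`` has one row per cell with
    columns ``cell_id, x_um, y_um, compartment, <marker>_positive,
    <marker>_intensity``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _place_cells(config, rng)
    h, w = config.image_shape
    px = config.pixel_size
    r_px = config.nucleus_radius / px

    nuclear = np.zeros((h, w))
    marker_imgs = {spec.name: np.zeros((h, w)) for spec in config.marker_specs}
    intensities = {spec.name: np.empty(len(truth)) for spec in config.marker_specs}

    for i, row in enumerate(truth.itertuples(index=False)):
        cy, cx = row.y_um / px, row.x_um / px
        r0, r1 = int(np.floor(cy - r_px - 1)), int(np.ceil(cy + r_px + 2))
        c0, c1 = int(np.floor(cx - r_px - 1)), int(np.ceil(cx + r_px + 2))
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        nuclear[r0:r1, c0:c1][disk] = config.nuclear_intensity
        for spec in config.marker_specs:
            positive = getattr(row, f"{spec.name}_positive")
            mu = spec.pos_intensity_mean if positive else spec.neg_intensity_mean
            sd = spec.pos_intensity_sd if positive else spec.neg_intensity_sd
            amp = max(rng.normal(mu, sd), 0.0)
            intensities[spec.name][i] = amp
            img = marker_imgs[spec.name]
            img[r0:r1, c0:c1][disk] = np.maximum(img[r0:r1, c0:c1][disk], amp)

    for name, amp in intensities.items():
        truth[f"{name}_intensity"] = amp

    channels = {"nuclei": nuclear, **marker_imgs}
    sigma_px = config.psf_sigma / px
    for name, img in channels.items():
        if sigma_px > 0:
            img = ndi.gaussian_filter(img, sigma_px)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    stack = ImageStack(
        channels=channels, pixel_size=px, sample_id=sample_id, group=group
    )
    return stack, truth


def generate_assembloid_pair(
    config_wt: SynthImageConfig,
    config_ko: SynthImageConfig,
    n_samples: int,
) -> list[tuple[ImageStack, pd.DataFrame]]:
    """Generate matched WT and KO image sets with group labels.

    Both configs must share geometry (shape, pixel size, core half-width);
    they may differ in marker fractions and gradient scale — the WT config
    typically carries the steeper core-directed gradient.  Per-sample seeds
    are derived deterministically from each config's master seed and the
    sample index, so individual images are reproducible in isolation.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for attr in ("image_shape", "pixel_size", "core_half_width"):
        if getattr(config_wt, attr) != getattr(config_ko, attr):
            raise ValueError(f"configs must share geometry; {attr} differs")

    out: list[tuple[ImageStack, pd.DataFrame]] = []
    for label, config in (("WT", config_wt), ("KO", config_ko)):
        for i in range(n_samples):
            child = int(
                np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)
            )
            cfg_i = dataclasses.replace(config, seed=child)
            stack, truth = generate_section_image(
                cfg_i, sample_id=f"{label.lower()}_{i + 1:02d}", group=label
            )
            out.append((stack, truth))
    return out


@dataclass(frozen=True)
class SynthExprConfig:
    """Parameters of the synthetic two-group log2 expression matrix.

    ``prior_df`` (d0) and ``prior_scale`` (s0²) parameterize the scaled
    inverse-chi-square distribution of gene-wise variances; ``de_fraction``
    of the genes receive a group-2 mean shift of ±``logfc_magnitude`` log2
    units; ``replicate_probe_fraction`` of the genes get a duplicated probe;
    ``low_expression_fraction`` of the genes are drawn well below the global
    median so the median-expression filter removes them.
    """

    n_genes: int = 2000
    n_per_group: tuple[int, int] = (18, 18)
    de_fraction: float = 0.05
    logfc_magnitude: float = 1.0
    prior_df: float = 4.0
    prior_scale: float = 0.25
    replicate_probe_fraction: float = 0.1
    low_expression_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 samples per group")
        for name in ("de_fraction", "replicate_probe_fraction", "low_expression_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.de_fraction + self.low_expression_fraction > 1.0:
            raise ValueError("de_fraction + low_expression_fraction must be <= 1")
        if self.prior_df <= 0 or self.prior_scale <= 0:
            raise ValueError("prior_df and prior_scale must be > 0")


class SynthExpression(NamedTuple):
    matrix: pd.DataFrame  # probes x samples, log2 scale
    groups: pd.Series  # sample -> {"control", "case"}
    truth: pd.DataFrame  # one row per gene
    probe_map: pd.DataFrame  # probe_id -> gene_id


def generate_expression_matrix(config: SynthExprConfig) -> SynthExpression:
    """Draw a log2 expression matrix with known differential-expression truth.

    Gene-wise variances are sigma_g^2 = s0^2 * d0 / X with X ~ chi2(d0);
    expressed genes get baseline means N(10, 0.5) log2 units, low-expression
    genes N(4, 0.5) (well below the overall median, so the median-expression
    filter removes essentially exactly the planted fraction); DE genes shift
    the case-group mean by ±logfc_magnitude.  A fraction of genes is
    represented by two probes, the second being the first plus N(0, 0.1)
    measurement noise.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n1, n2 = config.n_per_group
    genes = np.array([f"GENE{i + 1:05d}" for i in range(g)])

    n_low = int(round(config.low_expression_fraction * g))
    n_de = int(round(config.de_fraction * g))
    order = rng.permutation(g)
    low_idx = order[:n_low]
    de_idx = order[n_low : n_low + n_de]
    is_low = np.zeros(g, dtype=bool)
    is_low[low_idx] = True
    is_de = np.zeros(g, dtype=bool)
    is_de[de_idx] = True

    sigma2 = config.prior_scale * config.prior_df / rng.chisquare(config.prior_df, g)
    base = np.where(is_low, rng.normal(4.0, 0.5, g), rng.normal(10.0, 0.5, g))
    direction = np.where(rng.random(g) < 0.5, 1.0, -1.0)
    lfc = np.where(is_de, direction * config.logfc_magnitude, 0.0)

    sd = np.sqrt(sigma2)[:, None]
    ctrl = base[:, None] + rng.normal(0.0, 1.0, (g, n1)) * sd
    case = (base + lfc)[:, None] + rng.normal(0.0, 1.0, (g, n2)) * sd
    values = np.hstack([ctrl, case])
    samples = [f"ctrl_{i + 1:02d}" for i in range(n1)] + [
        f"case_{i + 1:02d}" for i in range(n2)
    ]
    groups = pd.Series(
        ["control"] * n1 + ["case"] * n2, index=samples, name="group"
    )

    n_rep = int(round(config.replicate_probe_fraction * g))
    rep_idx = rng.choice(g, size=n_rep, replace=False) if n_rep else np.array([], int)
    probe_ids = [f"P_{gene}_1" for gene in genes]
    rows = [values]
    rep_probe_ids = [f"P_{genes[i]}_2" for i in rep_idx]
    if n_rep:
        rows.append(values[rep_idx] + rng.normal(0.0, 0.1, (n_rep, n1 + n2)))
    matrix = pd.DataFrame(
        np.vstack(rows), index=probe_ids + rep_probe_ids, columns=samples
    )
    matrix.index.name = "probe_id"

    probe_map = pd.DataFrame(
        {
            "probe_id": probe_ids + rep_probe_ids,
            "gene_id": list(genes) + [genes[i] for i in rep_idx],
        }
    )
    has_rep = np.zeros(g, dtype=bool)
    has_rep[rep_idx] = True
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de": is_de,
            "true_lfc": lfc,
            "is_low_expression": is_low,
            "has_replicate_probe": has_rep,
            "sigma2": sigma2,
            "base_mean": base,
        }
    )
    return SynthExpression(matrix=matrix, groups=groups, truth=truth, probe_map=probe_map)
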
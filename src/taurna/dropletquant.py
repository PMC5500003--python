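"""Bright-field droplet coverage quantification.

Phase-separated droplets settle on the cover slide and appear darker than the
surrounding buffer under optimized Koehler illumination.  The pipeline:

1. threshold = mean intensity of a buffer-only blank image;
2. droplet mask = pixels strictly below the threshold; connected components;
3. per-region shape measurement (area, eccentricity of the equivalent
   ellipse, equivalent diameter 2*sqrt(area/pi) in um);
4. regions with eccentricity > 0.9 or equivalent diameter < 1 um are
   filtered out as non-droplets;
5. percent coverage = 100 * kept droplet pixels / total pixels, aggregated
   as mean +/- sd over replicate images of one condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure


@dataclass
class BrightFieldImage:
    """A 2-D intensity grid with pixel-size calibration and metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 12
    condition: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 16:
            raise ValueError("image must be 2-D and at least 16x16 pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")
        if np.issubdtype(self.pixels.dtype, np.integer):
            if self.pixels.min() < 0 or self.pixels.max() >= 2 ** self.bit_depth:
                raise ValueError(
                    f"intensities exceed the declared {self.bit_depth}-bit range"
                )

    @property
    def total_pixels(self) -> int:
        return int(self.pixels.size)


@dataclass(frozen=True)
class SegmentationParams:
    threshold: float
    connectivity: int = 8
    max_eccentricity: float = 0.9
    min_diameter_um: float = 1.0
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0.0 <= self.max_eccentricity <= 1.0:
            raise ValueError("eccentricity bound must lie in [0, 1]")
        if self.min_diameter_um <= 0:
            raise ValueError("diameter bound must be positive")


@dataclass
class DropletRegion:
    pixel_count: int
    area_um2: float
    eccentricity: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]
    touches_border: bool


@dataclass
class CoverageResult:
    percent_coverage: float
    kept_count: int
    filtered_count: int
    threshold: float
    condition: str | None = None
    replicate: int | None = None


def buffer_threshold(buffer_image: BrightFieldImage, k_sigma: float = 0.0) -> float:
    """Mean intensity of a buffer-only blank image, used as the droplet
    threshold.  With ``k_sigma > 0`` the threshold is lowered to
    mean - k_sigma * sd: the plain mean classifies half of a noisy
    background as sub-threshold, so noisy backgrounds need the offset
    variant (tiny spurious specks are then removed by the 1-um diameter
    filter).  A fully saturated blank is degenerate and triggers a
    warning."""
    pixels = buffer_image.pixels
    if pixels.size == 0:
        raise ValueError("buffer image is empty")
    max_value = 2 ** buffer_image.bit_depth - 1
    if np.issubdtype(pixels.dtype, np.integer) and np.all(pixels == max_value):
        warnings.warn(
            "buffer image is saturated; threshold equals the maximum value",
            UserWarning, stacklevel=2,
        )
    return float(pixels.mean() - k_sigma * pixels.std())


def segment_and_measure(
    image: BrightFieldImage, params: SegmentationParams
) -> list[DropletRegion]:
    """Label sub-threshold (darker-than-buffer) pixels and measure each
    connected component's shape in calibrated units."""
    if image.pixel_size_um is None or image.pixel_size_um <= 0:
        raise ValueError("pixel size required for um-based measurements")
    mask = image.pixels < params.threshold
    if params.fill_holes:
        from scipy import ndimage

        mask = ndimage.binary_fill_holes(mask)
    skimage_conn = 1 if params.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=skimage_conn)
    h, w = mask.shape
    px = image.pixel_size_um
    regions = []
    for props in measure.regionprops(labels):
        minr, minc, maxr, maxc = props.bbox
        regions.append(
            DropletRegion(
                pixel_count=int(props.area),
                area_um2=float(props.area) * px * px,
                eccentricity=float(props.eccentricity),
                equivalent_diameter_um=2.0 * np.sqrt(float(props.area) * px * px / np.pi),
                centroid=tuple(props.centroid),
                touches_border=bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            )
        )
    return regions


def apply_filters(
    regions: list[DropletRegion], params: SegmentationParams
) -> tuple[list[DropletRegion], list[DropletRegion]]:
    """Partition regions into (kept, filtered) by the shape filters: a
    droplet must have eccentricity <= max bound and equivalent diameter >=
    min bound.  Border-touching regions are kept but remain flagged."""
    kept, filtered = [], []
    for region in regions:
        ok = (
            region.eccentricity <= params.max_eccentricity
            and region.equivalent_diameter_um >= params.min_diameter_um
        )
        (kept if ok else filtered).append(region)
    return kept, filtered


def coverage_percent(
    kept: list[DropletRegion],
    image: BrightFieldImage,
    params: SegmentationParams | None = None,
    filtered_count: int = 0,
) -> CoverageResult:
    """Percent of the image area covered by accepted droplet regions."""
    total = image.total_pixels
    droplet_pixels = sum(r.pixel_count for r in kept)
    if droplet_pixels > total:
        raise ValueError("regions cover more pixels than the image holds")
    return CoverageResult(
        percent_coverage=100.0 * droplet_pixels / total,
        kept_count=len(kept),
        filtered_count=filtered_count,
        threshold=params.threshold if params is not None else np.nan,
        condition=image.condition,
        replicate=image.replicate,
    )


def quantify(image: BrightFieldImage, params: SegmentationParams) -> CoverageResult:
    """Full pipeline on one image: segment, measure, filter, coverage."""
    regions = segment_and_measure(image, params)
    kept, filtered = apply_filters(regions, params)
    return coverage_percent(kept, image, params, filtered_count=len(filtered))


def aggregate(results: list[CoverageResult]) -> pd.DataFrame:
    """Mean +/- sd percent coverage per condition over replicate images."""
    frame = pd.DataFrame(
        dict(
            condition=[r.condition for r in results],
            percent_coverage=[r.percent_coverage for r in results],
        )
    )
    out = frame.groupby("condition", dropna=False)["percent_coverage"].agg(
        mean="mean", sd="std", n="count"
    )
    return out.reset_index()
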
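"""Domain types, mask algebra, and per-cell feature extraction.

Single cells arrive as aligned multichannel 2-D intensity images
(brightfield, lamin A, tubulin, chromatin/DNA).  This module defines the
image/mask containers used throughout the pipeline and the morphological
feature set that the serial gating tree consumes: brightfield area and
aspect ratio, centroid-x, gradient RMS focus measure, lamin A mean/max
over the peri-nuclear ring, and the nuclear spot count.

Conventions: 0-based row-major pixel coordinates with the origin at the
upper-left corner; masks are boolean grids on the same lattice as the
image; structuring elements for "eroded/dilated by N pixels" are
Euclidean disks of radius N.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import filters, measure, morphology

#: Canonical channel order used for multi-page TIFF I/O.
CHANNELS = ("brightfield", "laminA", "tubulin", "chromatin")

#: Column order of the per-cell feature table.
FEATURE_COLUMNS = (
    "cell_id",
    "area",
    "aspect_ratio",
    "centroid_x",
    "gradient_rms",
    "laminA_mean_perinuclear",
    "laminA_max_perinuclear",
    "nuclear_spot_count",
    "nuclear_aspect_ratio",
    "nuclear_total_chromatin",
)


class FlatImageError(ValueError):
    """Raised when an all-zero / constant channel makes a threshold undefined."""


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean pixel set plus a free-text provenance label."""

    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        object.__setattr__(self, "grid", grid)

    @property
    def area(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.grid & other.grid, f"({self.provenance})&({other.provenance})")

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.grid | other.grid, f"({self.provenance})|({other.provenance})")

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.grid, f"not({self.provenance})")


@dataclass
class MultiChannelCellImage:
    """Aligned per-channel intensity grids for one cell.

    All channels share the same height x width; intensities are finite,
    non-negative and in arbitrary units.  ``pixel_size`` is the physical
    edge length of one pixel in micrometres, when known.
    """

    cell_id: str
    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image needs at least one channel")
        shapes = set()
        clean: dict[str, np.ndarray] = {}
        for name, grid in self.channels.items():
            arr = np.asarray(grid, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2-D grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            shapes.add(arr.shape)
            clean[name] = arr
        if len(shapes) != 1:
            raise ValueError("all channels must share identical dimensions")
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not present (have {sorted(self.channels)})")


@dataclass
class CellFeatures:
    """Scalar morphology/intensity features of one cell.

    ``aspect_ratio`` (minor/major axis of the ellipse-equivalent region,
    hence in [0, 1]) refers to the cell mask; ``nuclear_aspect_ratio`` to
    the nuclear (chromatin morphology) mask, which drives the mitotic
    sub-phase gates.  ``mean_intensity`` / ``max_pixel`` map mask names to
    lamin A statistics over that mask.
    """

    cell_id: str
    area: int
    aspect_ratio: float
    centroid_x: float
    gradient_rms: float
    mean_intensity: dict[str, float]
    max_pixel: dict[str, float]
    nuclear_spot_count: int
    nuclear_aspect_ratio: float = 1.0
    nuclear_total_chromatin: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.aspect_ratio <= 1.0:
            raise ValueError("aspect_ratio must be in [0, 1]")
        if self.area < 0 or self.nuclear_spot_count < 0:
            raise ValueError("area and spot count must be non-negative")

    def as_row(self) -> dict[str, object]:
        return {
            "cell_id": self.cell_id,
            "area": self.area,
            "aspect_ratio": self.aspect_ratio,
            "centroid_x": self.centroid_x,
            "gradient_rms": self.gradient_rms,
            "laminA_mean_perinuclear": self.mean_intensity.get("perinuclear", np.nan),
            "laminA_max_perinuclear": self.max_pixel.get("perinuclear", np.nan),
            "nuclear_spot_count": self.nuclear_spot_count,
            "nuclear_aspect_ratio": self.nuclear_aspect_ratio,
            "nuclear_total_chromatin": self.nuclear_total_chromatin,
        }


# ---------------------------------------------------------------------------
# Mask algebra
# ---------------------------------------------------------------------------


def threshold_mask(channel: np.ndarray, fraction: float) -> BinaryMask:
    """Pixels at or above ``fraction`` x (per-image maximum).

    Raises :class:`FlatImageError` on an all-zero channel, where the
    threshold would be undefined.
    """
    arr = np.asarray(channel, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    peak = float(arr.max(initial=0.0))
    if peak <= 0.0:
        raise FlatImageError("flat image, threshold undefined")
    return BinaryMask(arr >= fraction * peak, f"threshold({fraction:g})")


def morph_mask(mask: BinaryMask, op: str, pixels: int) -> BinaryMask:
    """Erode or dilate by a Euclidean disk of radius ``pixels``."""
    if pixels < 1:
        raise ValueError("pixels must be >= 1")
    footprint = morphology.disk(int(pixels))
    if op == "erode":
        grid = morphology.erosion(mask.grid, footprint)
    elif op == "dilate":
        grid = morphology.dilation(mask.grid, footprint)
    else:
        raise ValueError(f"unknown morphological op {op!r}")
    return BinaryMask(grid, f"{op}({mask.provenance},{pixels})")


def perinuclear_mask(nuclear_mask: BinaryMask) -> BinaryMask:
    """Peri-nuclear ring: (nucleus dilated by 1 px) minus (nucleus eroded by 2 px).

    The ring covers the nuclear envelope band where the lamina sits; lamin A
    mean/max statistics for the mitotic gate are computed over it.
    """
    if mask_is_empty(nuclear_mask):
        raise EmptyMaskError("no nuclear region")
    dilated = morph_mask(nuclear_mask, "dilate", 1)
    eroded = morph_mask(nuclear_mask, "erode", 2)
    return BinaryMask(dilated.grid & ~eroded.grid, "perinuclear")


def mask_is_empty(mask: BinaryMask) -> bool:
    return not bool(mask.grid.any())


def morphology_mask(
    channel: np.ndarray,
    fraction: float = 0.3,
    keep_fraction: float = 0.25,
    min_area: int = 10,
) -> BinaryMask:
    """Morphology mask of a stained structure (e.g. the Hoechst nucleus).

    Threshold at ``fraction`` of the channel maximum, fill holes, and keep
    every connected component whose area is at least ``keep_fraction`` of
    the largest one (so two-lobed telophase/anaphase nuclei survive intact)
    and at least ``min_area`` pixels.
    """
    thresholded = threshold_mask(channel, fraction)
    filled = ndimage.binary_fill_holes(thresholded.grid)
    labels = measure.label(filled, connectivity=2)
    if labels.max() == 0:
        raise EmptyMaskError("no structure above threshold")
    areas = np.bincount(labels.ravel())[1:]
    cutoff = max(float(min_area), keep_fraction * float(areas.max()))
    keep = np.flatnonzero(areas >= cutoff) + 1
    grid = np.isin(labels, keep)
    return BinaryMask(grid, f"morphology({fraction:g})")


def spot_count(
    channel: np.ndarray,
    threshold_fraction: float = 0.6,
    min_component_area: int = 10,
    within: BinaryMask | None = None,
) -> int:
    """Count bright spots: 8-connected components of the threshold mask.

    The threshold mask keeps pixels at >= ``threshold_fraction`` of the
    channel maximum (taken inside ``within`` when given); components
    smaller than ``min_component_area`` pixels are discarded as noise
    (the "range mask" role).
    """
    if min_component_area < 1:
        raise ValueError("min_component_area must be >= 1")
    arr = np.asarray(channel, dtype=float)
    if within is not None:
        restricted = np.where(within.grid, arr, 0.0)
    else:
        restricted = arr
    mask = threshold_mask(restricted, threshold_fraction)
    labels = measure.label(mask.grid, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_component_area).sum())


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def region_aspect_ratio(mask: BinaryMask) -> float:
    """Minor/major axis ratio of the ellipse with the same second central
    moments as the full mask region (all components pooled).

    Degenerate regions (single pixel, zero major axis) return 1.0.
    """
    if mask_is_empty(mask):
        raise EmptyMaskError("empty mask for aspect ratio")
    props = measure.regionprops(mask.grid.astype(np.uint8))[0]
    major = props.axis_major_length
    if major <= 0:
        return 1.0
    return float(min(props.axis_minor_length / major, 1.0))


def gradient_rms(channel: np.ndarray, mask: BinaryMask) -> float:
    """Root-mean-square Sobel gradient magnitude within the mask.

    A monotone focus measure: defocused cells have weak edges and a low
    value. Constant images give exactly 0.
    """
    if mask_is_empty(mask):
        raise EmptyMaskError("empty mask for gradient RMS")
    grad = filters.sobel(np.asarray(channel, dtype=float))
    vals = grad[mask.grid]
    return float(np.sqrt(np.mean(vals**2)))


def extract_features(
    image: MultiChannelCellImage,
    masks: Mapping[str, BinaryMask],
    spot_threshold_fraction: float = 0.6,
    spot_min_area: int = 10,
    spot_neighborhood_px: int = 12,
    spot_channel: str = "laminA",
    focus_channel: str = "brightfield",
) -> CellFeatures:
    """Compute the gating feature set for one cell.

    ``masks`` must contain ``"cell"`` and ``"nucleus"``; the peri-nuclear
    ring is derived from the nucleus mask when not supplied.  Lamin A
    mean/max are computed over the ring; the nuclear spot count is taken
    on the lamin A channel restricted to a ``spot_neighborhood_px``-dilated
    neighborhood of the nucleus intersected with the cell mask.
    """
    for required in ("cell", "nucleus"):
        if required not in masks:
            raise KeyError(f"masks must include {required!r}")
        if mask_is_empty(masks[required]):
            raise EmptyMaskError(f"empty mask for feature {required!r}")
    cell = masks["cell"]
    nucleus = masks["nucleus"]
    ring = masks.get("perinuclear") or perinuclear_mask(nucleus)

    lamin = image.channel("laminA")
    ring_vals = lamin[ring.grid]
    if ring_vals.size == 0:
        raise EmptyMaskError("empty mask for feature 'perinuclear'")

    neighborhood = morph_mask(nucleus, "dilate", spot_neighborhood_px) & cell
    n_spots = spot_count(
        image.channel(spot_channel),
        threshold_fraction=spot_threshold_fraction,
        min_component_area=spot_min_area,
        within=neighborhood,
    )

    rows, cols = np.nonzero(cell.grid)
    centroid_x = float(cols.mean())

    chromatin_total = 0.0
    if "chromatin" in image.channels:
        chromatin_total = float(image.channel("chromatin")[nucleus.grid].sum())

    return CellFeatures(
        cell_id=image.cell_id,
        area=cell.area,
        aspect_ratio=region_aspect_ratio(cell),
        centroid_x=centroid_x,
        gradient_rms=gradient_rms(image.channel(focus_channel), cell),
        mean_intensity={"perinuclear": float(ring_vals.mean())},
        max_pixel={"perinuclear": float(ring_vals.max())},
        nuclear_spot_count=n_spots,
        nuclear_aspect_ratio=region_aspect_ratio(nucleus),
        nuclear_total_chromatin=chromatin_total,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_cell_tiff(
    path: str | Path,
    channel_order: Iterable[str] = CHANNELS,
    cell_id: str | None = None,
    pixel_size: float | None = None,
) -> MultiChannelCellImage:
    """Read one multi-page TIFF (page order = ``channel_order``) as a cell image."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    names = list(channel_order)
    if pages.shape[0] != len(names):
        raise ValueError(
            f"{path.name}: expected {len(names)} pages for channels {names}, got {pages.shape[0]}"
        )
    return MultiChannelCellImage(
        cell_id=cell_id or path.stem,
        channels={name: pages[i].astype(float) for i, name in enumerate(names)},
        pixel_size=pixel_size,
    )


def write_cell_tiff(image: MultiChannelCellImage, path: str | Path,
                    channel_order: Iterable[str] = CHANNELS) -> None:
    stack = np.stack([image.channel(name) for name in channel_order]).astype(np.float32)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def features_to_frame(features: Iterable[CellFeatures]) -> pd.DataFrame:
    rows = [f.as_row() for f in features]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def write_features_csv(features: Iterable[CellFeatures], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[CellFeatures]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            CellFeatures(
                cell_id=str(row["cell_id"]),
                area=int(row["area"]),
                aspect_ratio=float(row["aspect_ratio"]),
                centroid_x=float(row["centroid_x"]),
                gradient_rms=float(row["gradient_rms"]),
                mean_intensity={"perinuclear": float(row["laminA_mean_perinuclear"])},
                max_pixel={"perinuclear": float(row["laminA_max_perinuclear"])},
                nuclear_spot_count=int(row["nuclear_spot_count"]),
                nuclear_aspect_ratio=float(row["nuclear_aspect_ratio"]),
                nuclear_total_chromatin=float(row["nuclear_total_chromatin"]),
            )
        )
    return out
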
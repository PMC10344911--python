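"""Silhouette extraction from two-channel fluorescence micrographs.

Mirrors the classical ImageJ workflow for cultured microglia: split the
nuclear and cytoplasmic-marker channels, convert each to 8-bit, threshold
each channel separately, merge the two binary silhouettes (the cytoplasmic
marker is typically dim over the nucleus, so the nuclear silhouette fills
the perinuclear gap), clean the result (fill holes, optional
distance-transform watershed to separate touching cells, size filter,
edge exclusion) and crop one centred silhouette per retained cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .core import BinarySilhouette, MultiChannelImage

__all__ = [
    "ExtractionConfig",
    "Binarization",
    "DegenerateThresholdError",
    "split_and_grayscale",
    "binarize",
    "merge_silhouettes",
    "clean_mask",
    "crop_cell",
    "extract_outline",
    "extract_silhouettes",
]

_SQUARE = ndi.generate_binary_structure(2, 2)
_CROSS = ndi.generate_binary_structure(2, 1)


class DegenerateThresholdError(ValueError):
    """Automatic thresholding failed (e.g. constant raster under Otsu)."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the threshold → clean → crop pipeline.

    ``threshold_method`` is ``"otsu"``, ``"fixed:<value>"`` or
    ``"percentile:<q>"`` and applies to both channels unless overridden per
    role via ``threshold_overrides``.  ``min_object_area`` is the particle
    size filter in px² (the published workflows leave this "depending on the
    circumstances"; 200 px² is this package's default).  ``watershed_min_distance``
    is the minimum separation of distance-transform seed maxima in px.
    """

    threshold_method: str = "otsu"
    threshold_overrides: dict | None = None
    min_object_area: int = 200
    exclude_edges: bool = True
    apply_watershed: bool = True
    fill_holes: bool = True
    crop_size: int = 400
    watershed_min_distance: int = 10

    def __post_init__(self) -> None:
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")
        if self.crop_size <= 0:
            raise ValueError("crop_size must be positive")

    def method_for(self, role: str) -> str:
        if self.threshold_overrides and role in self.threshold_overrides:
            return self.threshold_overrides[role]
        return self.threshold_method


def split_and_grayscale(image: MultiChannelImage) -> dict[str, np.ndarray]:
    """Split channel roles into 8-bit grayscale rasters.

    Integer rasters are rescaled linearly from the full range of their bit
    depth (65535 → 255 for 16-bit); 8-bit input passes through unchanged.
    Float rasters are assumed to lie in [0, 1].
    """
    out: dict[str, np.ndarray] = {}
    for role in ("nucleus", "cytoplasm"):
        if role not in image.channel_roles:
            raise KeyError(f"image has no channel for role {role!r}")
        raster = image.channel(role)
        if raster.dtype == np.uint8:
            out[role] = raster.copy()
        elif np.issubdtype(raster.dtype, np.integer):
            top = np.iinfo(raster.dtype).max
            out[role] = (raster.astype(np.float64) * (255.0 / top)).round().astype(np.uint8)
        else:
            out[role] = np.clip(raster * 255.0, 0, 255).round().astype(np.uint8)
    return out


class Binarization(NamedTuple):
    """A thresholded raster together with the threshold actually applied."""

    mask: np.ndarray
    threshold: float


def binarize(raster: np.ndarray, method: str = "otsu") -> Binarization:
    """Threshold an 8-bit grayscale raster; foreground = pixels above threshold.

    ``method``: ``"otsu"`` (raises :class:`DegenerateThresholdError` on a
    constant raster), ``"fixed:<v>"`` or ``"percentile:<q>"``.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    if method == "otsu":
        if raster.min() == raster.max():
            raise DegenerateThresholdError(
                "constant raster: Otsu threshold is undefined; use fixed:<value>"
            )
        thr = float(threshold_otsu(raster))
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    elif method.startswith("percentile:"):
        q = float(method.split(":", 1)[1])
        thr = float(np.percentile(raster, q))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return Binarization(raster > thr, thr)


def merge_silhouettes(cytoplasm_mask: np.ndarray, nucleus_mask: np.ndarray) -> np.ndarray:
    """Union of the cytoplasm mask with cell-associated nuclear components.

    A nuclear component contributes only if it overlaps a cytoplasm
    component or sits inside one (inside its filled outline — the typical
    perinuclear hole); isolated nuclear debris is dropped.  This closes the
    hole left by weak cytoplasmic staining over the nucleus.
    """
    cyt = np.asarray(cytoplasm_mask, bool)
    nuc = np.asarray(nucleus_mask, bool)
    if cyt.shape != nuc.shape:
        raise ValueError(f"shape mismatch: {cyt.shape} vs {nuc.shape}")
    labels, n = ndi.label(nuc, structure=_SQUARE)
    if n == 0:
        return cyt.copy()
    cyt_filled = ndi.binary_fill_holes(cyt)
    overlapping = np.unique(labels[cyt_filled & nuc])
    overlapping = overlapping[overlapping > 0]
    keep = np.isin(labels, overlapping)
    return cyt | keep


def clean_mask(mask: np.ndarray, config: ExtractionConfig | None = None) -> np.ndarray:
    """Clean a binary mask and label the retained cells.

    Steps (each optional per config): fill interior holes; split touching
    cells by watershed on the Euclidean distance transform, seeded at local
    maxima at least ``watershed_min_distance`` apart; drop components below
    ``min_object_area`` px²; drop components touching the raster border.
    Returns an ``int32`` label raster (0 = background), labels renumbered
    1..n in scan order.
    """
    config = config or ExtractionConfig()
    mask = np.asarray(mask, bool)
    if config.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if config.apply_watershed and mask.any():
        distance = ndi.distance_transform_edt(mask)
        seeds = peak_local_max(
            distance, min_distance=config.watershed_min_distance, labels=mask
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
        if markers.max() > 0:
            labels = watershed(-distance, markers, mask=mask)
        else:  # no interior maxima (e.g. 1-px lines): keep plain components
            labels, _ = ndi.label(mask, structure=_SQUARE)
    else:
        labels, _ = ndi.label(mask, structure=_SQUARE)

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if config.min_object_area > 0 and ids.size:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < config.min_object_area)
        labels[np.isin(labels, small[small > 0])] = 0
    if config.exclude_edges:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border[border > 0])] = 0
    # renumber sequentially for stable downstream naming
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def crop_cell(labels: np.ndarray, label: int, crop_size: int = 400) -> BinarySilhouette:
    """Cut one labelled component into a centred ``crop_size`` square.

    The component centroid lands within ±1 px of the crop centre; ``origin``
    records the crop's top-left corner in source-image coordinates (possibly
    negative when the cell sits near the image border).
    """
    component = labels == label
    if not component.any():
        raise ValueError(f"label {label} not present")
    rr, cc = np.nonzero(component)
    h = rr.max() - rr.min() + 1
    w = cc.max() - cc.min() + 1
    if h > crop_size or w > crop_size:
        raise ValueError(
            f"component {label} spans {h}x{w} px and does not fit a "
            f"{crop_size}-px crop; increase crop_size"
        )
    r0 = int(round(rr.mean() - crop_size / 2))
    c0 = int(round(cc.mean() - crop_size / 2))
    # keep the component fully inside the crop
    r0 = min(max(r0, rr.max() - crop_size + 1), rr.min())
    c0 = min(max(c0, cc.max() - crop_size + 1), cc.min())
    crop = np.zeros((crop_size, crop_size), dtype=bool)
    crop[rr - r0, cc - c0] = True
    return BinarySilhouette(crop, origin=(r0, c0), label=f"cell_{label:04d}")


def extract_outline(silhouette: BinarySilhouette | np.ndarray) -> np.ndarray:
    """One-pixel 8-connected boundary of a silhouette.

    Boundary pixels are foreground pixels with at least one background
    4-neighbour; refilling the outline of a hole-free silhouette recovers it
    exactly.  The outline raster is the input to the box-counting fractal
    dimension.
    """
    mask = silhouette.mask if isinstance(silhouette, BinarySilhouette) else silhouette
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no outline")
    interior = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~interior


def extract_silhouettes(
    image: MultiChannelImage,
    config: ExtractionConfig | None = None,
) -> tuple[list[BinarySilhouette], dict]:
    """Full channel-split → threshold → merge → clean → crop pipeline.

    Returns the per-cell silhouettes and a run log with the thresholds used
    and per-stage cell counts.
    """
    config = config or ExtractionConfig()
    gray = split_and_grayscale(image)
    cyt = binarize(gray["cytoplasm"], config.method_for("cytoplasm"))
    nuc = binarize(gray["nucleus"], config.method_for("nucleus"))
    merged = merge_silhouettes(cyt.mask, nuc.mask)
    labels = clean_mask(merged, config)
    n = int(labels.max())
    cells = [crop_cell(labels, i, config.crop_size) for i in range(1, n + 1)]
    log = {
        "threshold_cytoplasm": cyt.threshold,
        "threshold_nucleus": nuc.threshold,
        "n_foreground_px_merged": int(merged.sum()),
        "n_cells_retained": n,
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
    }
    return cells, log
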
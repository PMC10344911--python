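"""Core data model and I/O for microglial cytomorphometry.

The unit of measurement throughout the package is the :class:`BinarySilhouette`
— the filled binary mask of a single cell.  Sixteen morphometric parameters
are collected per cell in a :class:`FeatureVector`, and per-cell rows labelled
by treatment group form a :class:`CohortTable` (a thin wrapper around a pandas
DataFrame) that feeds the group statistics.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; masks use ``True`` for foreground
  (cell) and ``False`` for background.  Input mask images that encode the
  cell as black-on-white are normalised at read time.
* Physical units are micrometres; the :class:`PixelCalibration` carries the
  single scale factor (default 1 μm/px, i.e. pixel units).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "PixelCalibration",
    "MultiChannelImage",
    "BinarySilhouette",
    "FeatureVector",
    "FEATURE_NAMES",
    "CohortTable",
    "STUDY_GROUPS",
    "FormatError",
    "read_image",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
    "to_physical",
]

#: Treatment groups of the six-arm culture design this package emulates.
STUDY_GROUPS = ("control", "LPS", "KYNA", "LPS+KYNA", "SZR104", "LPS+SZR104")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class PixelCalibration:
    """Linear pixel-size calibration.

    Parameters
    ----------
    microns_per_pixel : float
        Physical side length of one pixel in μm.  Lengths scale by this
        factor, areas by its square.
    """

    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.microns_per_pixel) or self.microns_per_pixel <= 0:
            raise ValueError(
                f"microns_per_pixel must be positive, got {self.microns_per_pixel}"
            )

    @property
    def area_scale(self) -> float:
        """μm² per px²."""
        return self.microns_per_pixel**2


def to_physical(
    pixel_value: float | np.ndarray,
    calibration: PixelCalibration,
    kind: str = "length",
) -> float | np.ndarray:
    """Convert a pixel measure to physical units.

    ``kind`` is ``"length"`` (px → μm) or ``"area"`` (px² → μm²).
    """
    if kind == "length":
        return pixel_value * calibration.microns_per_pixel
    if kind == "area":
        return pixel_value * calibration.area_scale
    raise ValueError(f"kind must be 'length' or 'area', got {kind!r}")


_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity
_SQUARE = ndi.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass
class MultiChannelImage:
    """A multi-channel intensity raster with named channel roles.

    ``pixels`` has shape ``(n_channels, height, width)``; ``channel_roles``
    maps the roles ``"nucleus"`` (DNA stain) and ``"cytoplasm"`` (membrane /
    cytoplasmic marker) to channel indices.
    """

    pixels: np.ndarray
    channel_roles: Mapping[str, int]
    calibration: PixelCalibration = field(default_factory=PixelCalibration)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise FormatError(
                f"pixels must be (channels, height, width), got shape {self.pixels.shape}"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and self.pixels.min() < 0:
            raise FormatError("intensities must be non-negative")
        n = self.pixels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n:
                raise FormatError(
                    f"role {role!r} assigned to channel {idx}, image has {n} channels"
                )
        idxs = list(self.channel_roles.values())
        if len(set(idxs)) != len(idxs):
            raise FormatError("each role needs a distinct channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the raster assigned to ``role``."""
        if role not in self.channel_roles:
            raise KeyError(f"no channel assigned to role {role!r}")
        return self.pixels[self.channel_roles[role]]


@dataclass
class BinarySilhouette:
    """Filled binary mask of one cell, cropped from a source image.

    A clean silhouette has exactly one 8-connected foreground component and
    no interior holes; :meth:`validate` checks both.
    """

    mask: np.ndarray
    origin: tuple[int, int] = (0, 0)
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[float, float]:
        """Foreground centroid in crop coordinates (row, col)."""
        rr, cc = np.nonzero(self.mask)
        if rr.size == 0:
            raise ValueError("empty mask has no centroid")
        return float(rr.mean()), float(cc.mean())

    def validate(self) -> None:
        """Raise ``ValueError`` unless the silhouette is clean.

        Checks: non-empty, a single 8-connected component, and no interior
        background holes.
        """
        if not self.mask.any():
            raise ValueError(f"silhouette {self.label!r}: empty mask")
        _, n = ndi.label(self.mask, structure=_SQUARE)
        if n != 1:
            raise ValueError(
                f"silhouette {self.label!r}: {n} connected components, expected 1"
            )
        filled = ndi.binary_fill_holes(self.mask)
        if (filled & ~self.mask).any():
            raise ValueError(f"silhouette {self.label!r}: interior holes present")


#: The 16 morphometric parameters, in frozen column order.
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "circularity",
    "transformation_index",
    "hull_area",
    "hull_perimeter",
    "hull_circularity",
    "hull_mean_radius",
    "hull_max_span",
    "bounding_circle_diameter",
    "hull_max_min_radii",
    "hull_span_ratio",
    "density",
    "roughness",
    "fractal_dimension",
    "lacunarity",
)


@dataclass(frozen=True)
class FeatureVector:
    """The 16 morphometric parameters of one cell.

    Geometric class: ``area`` (μm²), ``perimeter`` (μm), ``circularity``
    (4πA/P², 1 for a circle) and its reciprocal ``transformation_index``.
    Convex-hull class: hull area/perimeter/circularity, mean and max/min
    centroid-to-vertex radii, maximum span (hull diameter), diameter of the
    minimal bounding circle, and span ratio (major/minor caliper axes).
    Density/roughness class: cell area / hull area and cell perimeter /
    hull perimeter.  Box-counting class: fractal dimension of the outline
    and lacunarity of the filled silhouette.
    """

    area: float
    perimeter: float
    circularity: float
    transformation_index: float
    hull_area: float
    hull_perimeter: float
    hull_circularity: float
    hull_mean_radius: float
    hull_max_span: float
    bounding_circle_diameter: float
    hull_max_min_radii: float
    hull_span_ratio: float
    density: float
    roughness: float
    fractal_dimension: float
    lacunarity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


class CohortTable:
    """Per-cell feature rows labelled by treatment group.

    Wraps a DataFrame with columns ``label``, ``group`` and the 16 feature
    columns in :data:`FEATURE_NAMES` order.
    """

    COLUMNS = ("label", "group", *FEATURE_NAMES)

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if frame["group"].isna().any():
            raise ValueError("every row needs a group label")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_cells(
        cls,
        cells: Iterable[tuple[str, str, FeatureVector]],
    ) -> "CohortTable":
        """Build a table from ``(label, group, features)`` triples."""
        rows = [{"label": lab, "group": grp, **fv.to_dict()} for lab, grp, fv in cells]
        if not rows:
            raise ValueError("cohort is empty")
        return cls(pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["group"]))

    def group_values(self, feature: str) -> dict[str, np.ndarray]:
        """Per-group value arrays for one feature."""
        if feature not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {feature!r}")
        return {
            g: self.frame.loc[self.frame["group"] == g, feature].to_numpy(float)
            for g in self.groups
        }


# ---------------------------------------------------------------------------
# readers / writers


def _normalise_channel_axis(arr: np.ndarray) -> np.ndarray:
    """Return (C, H, W) from (H, W), (C, H, W) or (H, W, C) arrays."""
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim != 3:
        raise FormatError(f"cannot interpret image of shape {arr.shape}")
    # channels-last if the last axis is small and the first is not
    if arr.shape[-1] <= 4 < arr.shape[0]:
        return np.moveaxis(arr, -1, 0)
    return arr


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(
    path: str | Path | Sequence[str | Path],
    channel_roles: Mapping[str, int],
    calibration: PixelCalibration | float = 1.0,
) -> MultiChannelImage:
    """Read a two-channel micrograph (TIFF/PNG) into a :class:`MultiChannelImage`.

    ``path`` may be a single multi-channel file, or a sequence of
    single-channel files that are stacked in the given order (role indices
    then refer to positions in that sequence).
    """
    if isinstance(calibration, (int, float)):
        calibration = PixelCalibration(float(calibration))
    if isinstance(path, (str, Path)):
        arr = _normalise_channel_axis(_read_raster(path))
    else:
        planes = []
        for p in path:
            a = _read_raster(p)
            if a.ndim != 2:
                raise FormatError(f"{p}: expected a single-channel image")
            planes.append(a)
        shapes = {a.shape for a in planes}
        if len(shapes) != 1:
            raise FormatError(f"channel files differ in shape: {sorted(shapes)}")
        arr = np.stack(planes)
    if arr.shape[0] < len(channel_roles):
        raise FormatError(
            f"{len(channel_roles)} roles requested but image has {arr.shape[0]} channel(s)"
        )
    return MultiChannelImage(arr, dict(channel_roles), calibration)


def read_mask(path: str | Path, invert: bool | None = None) -> np.ndarray:
    """Read a binary mask image (0/255 or 0/1 coding) as a boolean array.

    With ``invert=None`` the minority value is taken as foreground, which
    normalises both white-on-black and the ImageJ-style black-on-white
    ("Lock white as background") conventions for typical sparse cell masks.
    """
    arr = _read_raster(path)
    if arr.ndim == 3:
        arr = arr[..., 0] if arr.shape[-1] <= 4 else arr[0]
    mask = arr > (arr.max() / 2 if arr.max() > 1 else 0)
    if invert is None:
        invert = mask.mean() > 0.5
    return ~mask if invert else mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit image (foreground=255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_feature_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as RFC-4180 CSV with the frozen column order.

    Feature values are written with ``repr`` round-trip precision, so a
    read-back restores them to better than 1e-9 relative error.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    cohort.frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> CohortTable:
    """Read a feature CSV written by :func:`write_feature_table`."""
    return CohortTable(pd.read_csv(path))
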
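"""Per-cell feature measurement: one silhouette in, 16 parameters out."""

from __future__ import annotations

from typing import Iterable

from .core import BinarySilhouette, CohortTable, FeatureVector, PixelCalibration
from .extraction import extract_outline
from .fractal import BoxCountingConfig, fractal_dimension, lacunarity
from .morphometry import (
    bounding_circle,
    circularity,
    convex_hull,
    density_roughness,
    hull_metrics,
    measure_area_perimeter,
    transformation_index,
)

__all__ = ["measure_cell", "measure_cohort"]


def measure_cell(
    silhouette: BinarySilhouette,
    calibration: PixelCalibration | None = None,
    box_config: BoxCountingConfig | None = None,
    hull_points: str = "corners",
) -> FeatureVector:
    """Compute the full 16-parameter feature vector of one silhouette.

    Geometry and hull metrics are reported in physical units; the fractal
    dimension is measured on the one-pixel outline and lacunarity on the
    filled silhouette, both via box counting.
    """
    calibration = calibration or PixelCalibration()
    box_config = box_config or BoxCountingConfig()
    area, perimeter = measure_area_perimeter(silhouette, calibration)
    hull = convex_hull(silhouette, calibration, points=hull_points)
    hm = hull_metrics(hull)
    dens, rough = density_roughness(area, perimeter, hull)
    outline = extract_outline(silhouette)
    bc = fractal_dimension(outline, box_config)
    lac = lacunarity(silhouette, box_config)
    return FeatureVector(
        area=area,
        perimeter=perimeter,
        circularity=circularity(area, perimeter),
        transformation_index=transformation_index(area, perimeter),
        hull_area=hull.area,
        hull_perimeter=hull.perimeter,
        hull_circularity=hm.hull_circularity,
        hull_mean_radius=hm.mean_radius,
        hull_max_span=hm.max_span,
        bounding_circle_diameter=bounding_circle(hull),
        hull_max_min_radii=hm.max_min_radii,
        hull_span_ratio=hm.span_ratio,
        density=dens,
        roughness=rough,
        fractal_dimension=bc.Db,
        lacunarity=lac,
    )


def measure_cohort(
    cells: Iterable[tuple[str, str, BinarySilhouette]],
    calibration: PixelCalibration | None = None,
    box_config: BoxCountingConfig | None = None,
    hull_points: str = "corners",
) -> CohortTable:
    """Measure every ``(label, group, silhouette)`` triple into a cohort table."""
    rows = [
        (label, group, measure_cell(sil, calibration, box_config, hull_points))
        for label, group, sil in cells
    ]
    return CohortTable.from_cells(rows)
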
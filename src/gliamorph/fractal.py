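"""Box-counting fractal dimension and lacunarity of binary silhouettes.

The fractal dimension Db is measured on the one-pixel outline of the cell,
lacunarity on the filled silhouette, matching the classical FracLac
workflow.  Box sizes follow a power series with base 2 (2, 4, 8, … px) up
to a fixed fraction of the raster side, and counts are averaged over
several grid placements: the corner-anchored grid plus a number of
seeded random offsets, which reduces the placement bias of a single grid.

Db is the least-squares slope of log N(ε) against log(1/ε), where N(ε) is
the minimal occupied-box count over the grid placements (the covering
number), with the fit r² reported.  Lacunarity is the mean, over
box sizes and placements, of the squared coefficient of variation
(σ/μ)² of the per-box foreground fill fractions, computed over the boxes
tiling the silhouette's bounding box (empty boxes inside the bounding box
count; far-field background does not, so the statistic is independent of
crop padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinarySilhouette

__all__ = [
    "BoxCountingConfig",
    "BoxCountingResult",
    "InsufficientScalesError",
    "box_sizes",
    "box_count",
    "fractal_dimension",
    "lacunarity",
]


class InsufficientScalesError(ValueError):
    """Fewer than the minimum number of usable box sizes for a fit."""


@dataclass(frozen=True)
class BoxCountingConfig:
    """Grid design for box counting.

    ``base`` — the power-series base for box sizes (sizes ``min_box·base^k``).
    ``min_box`` — smallest box edge in px.  ``max_box_fraction`` — largest
    box edge as a fraction of the shorter raster side (capped below the
    1–2-box regime that flattens the log–log regression).  ``grid_offsets``
    — number of random grid origins averaged in addition to the
    corner-anchored grid.  ``seed`` — seed for those offsets.
    """

    base: int = 2
    min_box: int = 2
    max_box_fraction: float = 0.45
    grid_offsets: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base < 2:
            raise ValueError("base must be >= 2")
        if not 0 < self.max_box_fraction <= 1:
            raise ValueError("max_box_fraction must be in (0, 1]")
        if self.grid_offsets < 0:
            raise ValueError("grid_offsets must be >= 0")


@dataclass(frozen=True)
class BoxCountingResult:
    sizes: np.ndarray
    counts: np.ndarray  # (n_offsets, n_sizes) occupied-box counts
    Db: float
    r_squared: float


def box_sizes(shape: tuple[int, int], config: BoxCountingConfig) -> np.ndarray:
    """Power-series box sizes for a pattern of the given extent.

    Sizes run from ``min_box`` up to ``max_box_fraction`` of the larger
    pattern side; for small patterns the fraction cap yields to a minimum
    of three sizes as long as the largest box still fits the pattern.
    """
    side = max(shape)
    limit = max(int(side * config.max_box_fraction), config.min_box)
    floor_limit = config.min_box * config.base**2  # three sizes minimum
    if limit < floor_limit <= side:
        limit = floor_limit
    sizes = []
    s = config.min_box
    while s <= limit:
        sizes.append(s)
        s *= config.base
    return np.asarray(sizes, dtype=int)


def _grid_origins(config: BoxCountingConfig) -> list[tuple[float, float]]:
    """Fractional grid origins: corner-anchored plus seeded random offsets."""
    origins = [(0.0, 0.0)]
    rng = np.random.default_rng(config.seed)
    for _ in range(config.grid_offsets):
        u, v = rng.random(2)
        origins.append((float(u), float(v)))
    return origins


def box_count(
    mask: np.ndarray, config: BoxCountingConfig | None = None
) -> tuple[np.ndarray, np.ndarray, list[list[np.ndarray]]]:
    """Occupied-box counts N(ε) and per-box masses for every grid placement.

    Returns ``(sizes, counts, masses)`` where ``counts[g, i]`` is the number
    of ε_i-sized boxes of grid placement g containing at least one
    foreground pixel, and ``masses[g][i]`` the foreground pixel counts of
    those occupied boxes.
    """
    config = config or BoxCountingConfig()
    mask = np.asarray(mask, bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask")
    # anchor the grid at the pattern's bounding box so counts (and the box
    # size range) are independent of where the pattern sits in its crop
    rr = rr - rr.min()
    cc = cc - cc.min()
    extent = (int(rr.max()) + 1, int(cc.max()) + 1)
    sizes = box_sizes(extent, config)
    if len(sizes) < 3:
        raise InsufficientScalesError(
            f"only {len(sizes)} usable box sizes for pattern extent {extent}; need >= 3"
        )
    origins = _grid_origins(config)
    counts = np.zeros((len(origins), len(sizes)), dtype=int)
    masses: list[list[np.ndarray]] = []
    for g, (u, v) in enumerate(origins):
        per_size = []
        for i, eps in enumerate(sizes):
            off_r = int(u * eps)
            off_c = int(v * eps)
            br = (rr + off_r) // eps
            bc = (cc + off_c) // eps
            ids = br * (extent[1] // eps + 2) + bc
            m = np.bincount(ids)
            m = m[m > 0]
            counts[g, i] = m.size
            per_size.append(m)
        masses.append(per_size)
    return sizes, counts, masses


def _fit_dimension(sizes: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of log N vs log(1/ε) and its r²."""
    x = np.log(1.0 / sizes.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def fractal_dimension(
    outline: np.ndarray, config: BoxCountingConfig | None = None
) -> BoxCountingResult:
    """Box-counting fractal dimension Db of a 1-px outline raster.

    The covering number at each scale is approximated as the minimum of
    N(ε) over the grid placements — box-counting dimension is defined by
    the *minimal* cover, and a single fixed grid systematically
    overestimates N for patterns not aligned with it.  Db is the
    least-squares slope of log N_min(ε) against log(1/ε); ``r_squared``
    reports the fit quality.
    """
    config = config or BoxCountingConfig()
    sizes, counts, _ = box_count(outline, config)
    db, r2 = _fit_dimension(sizes, counts.min(axis=0))
    return BoxCountingResult(sizes=sizes, counts=counts, Db=db, r_squared=r2)


def lacunarity(
    silhouette: BinarySilhouette | np.ndarray,
    config: BoxCountingConfig | None = None,
) -> float:
    """Gappiness of the filled silhouette: mean (σ/μ)² of box fill fractions.

    Boxes tile the foreground bounding box for each size and grid placement;
    boxes are clipped to the bounding box and their mass expressed as a fill
    fraction of the clipped area, so a solid block scores exactly 0 at every
    size and scale-free translation of the silhouette inside its crop does
    not change the value.
    """
    config = config or BoxCountingConfig()
    mask = silhouette.mask if isinstance(silhouette, BinarySilhouette) else np.asarray(silhouette, bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask")
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    window = mask[r0:r1, c0:c1]
    h, w = window.shape
    # cumulative sum with a leading zero row/col for O(1) box sums
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(window, axis=0), axis=1, out=integral[1:, 1:])

    sizes = box_sizes(window.shape, config)
    lambdas = []
    for u, v in _grid_origins(config):
        for eps in sizes:
            off_r = int(u * eps) % eps
            off_c = int(v * eps) % eps
            # box edges clipped to [0, h] x [0, w]
            r_edges = np.unique(np.clip(np.arange(-off_r, h + eps, eps), 0, h))
            c_edges = np.unique(np.clip(np.arange(-off_c, w + eps, eps), 0, w))
            if len(r_edges) < 2 or len(c_edges) < 2:
                continue
            S = integral[np.ix_(r_edges, c_edges)]
            sums = S[1:, 1:] - S[:-1, 1:] - S[1:, :-1] + S[:-1, :-1]
            areas = np.outer(np.diff(r_edges), np.diff(c_edges))
            frac = sums / areas
            mu = frac.mean()
            if mu == 0:
                continue
            lambdas.append(float(frac.var() / mu**2))
    if not lambdas:
        return 0.0
    return float(np.mean(lambdas))
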
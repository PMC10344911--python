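"""Synthetic silhouettes and pseudo-micrographs for pipeline validation.

Two families of fixtures:

* :func:`make_reference_shape` — deterministic analytic rasters (disk,
  square, segment, plus-polyomino, Sierpinski triangle, spiky star) whose
  feature values are known in closed form, used to validate the
  morphometry and fractal estimators.

* :func:`generate_silhouette` / :func:`generate_cohort` — parameterised
  microglial phenotypes: a soma drawn as a radial-harmonic blob, tapered
  random-walk processes growing from the soma rim (with optional secondary
  branches), and short filopodia-like spikes.  Phenotype presets emulate
  the morphological states of cultured microglia: *ameboid* (round
  activated cells without ramifications), *slightly ramified* (surveillant
  cells with a few short processes, typical of young cultures) and
  *hypertrophied* (swollen soma, irregular boundary, many filopodia — the
  state reported after SZR104 treatment).

Every generator output is a pure function of its seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian

from .core import BinarySilhouette, MultiChannelImage, PixelCalibration

__all__ = [
    "PhenotypeParams",
    "CohortDesign",
    "STUDY_GROUP_SIZES",
    "make_reference_shape",
    "generate_silhouette",
    "render_two_channel",
    "generate_cohort",
    "ameboid_params",
    "slightly_ramified_params",
    "hypertrophied_params",
    "two_group_design",
    "study_design",
]

_SQUARE = ndi.generate_binary_structure(2, 2)

#: Per-group cell counts of the six-arm study design (total 974).
STUDY_GROUP_SIZES = {
    "control": 148,
    "LPS": 131,
    "KYNA": 107,
    "LPS+KYNA": 215,
    "SZR104": 164,
    "LPS+SZR104": 209,
}


# ---------------------------------------------------------------------------
# analytic reference shapes


def make_reference_shape(kind: str, size: int) -> BinarySilhouette:
    """Deterministic raster of a named reference shape.

    ``size`` is the radius for ``disk`` and ``spiky_star``, the side for
    ``square`` and ``sierpinski`` (power of two), the length for
    ``segment`` and the arm unit for ``plus``.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if kind == "disk":
        side = 2 * size + 60
        mask = np.zeros((side, side), bool)
        rr, cc = draw_disk((side // 2, side // 2), size)
        mask[rr, cc] = True
    elif kind == "square":
        side = size + 8
        mask = np.zeros((side, side), bool)
        mask[4 : 4 + size, 4 : 4 + size] = True
    elif kind == "segment":
        mask = np.zeros((max(9, size // 4), size + 8), bool)
        mask[mask.shape[0] // 2, 4 : 4 + size] = True
    elif kind == "plus":
        u = size
        side = 3 * u + 8
        mask = np.zeros((side, side), bool)
        mask[4 + u : 4 + 2 * u, 4 : 4 + 3 * u] = True
        mask[4 : 4 + 3 * u, 4 + u : 4 + 2 * u] = True
    elif kind == "sierpinski":
        depth = int(round(math.log2(size)))
        if 2**depth != size:
            raise ValueError("sierpinski size must be a power of 2")
        i, j = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        core = (i & j) == 0
        mask = np.pad(core, 8)
    elif kind == "spiky_star":
        # 12-pointed star: deep alternating radii produce strong concavity
        side = 2 * size + 60
        mask = np.zeros((side, side), bool)
        ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        radii = np.where(np.arange(48) % 4 == 0, size, 0.35 * size)
        r = side // 2 + radii * np.sin(ang)
        c = side // 2 + radii * np.cos(ang)
        rr, cc = draw_polygon(r, c, shape=mask.shape)
        mask[rr, cc] = True
    else:
        raise ValueError(f"unknown reference shape {kind!r}")
    return BinarySilhouette(mask, label=f"{kind}_{size}")


# ---------------------------------------------------------------------------
# phenotype generator


@dataclass(frozen=True)
class PhenotypeParams:
    """Parameters of one microglial phenotype, in μm.

    ``soma_radius`` / ``process_length`` are (mean, sd) pairs sampled per
    cell; ``boundary_harmonics`` is (number of harmonics, relative
    amplitude) shaping soma irregularity; ``n_processes`` is the mean
    process count (Poisson); filopodia are short thin spikes on the rim.
    """

    soma_radius: tuple[float, float] = (8.0, 1.0)
    boundary_harmonics: tuple[int, float] = (3, 0.05)
    n_processes: float = 0.0
    process_length: tuple[float, float] = (10.0, 3.0)
    process_thickness: float = 2.5
    branch_probability: float = 0.3
    n_filopodia: int = 0
    filopodia_length: float = 4.0

    def __post_init__(self) -> None:
        if self.soma_radius[0] <= 0 or self.process_length[0] <= 0:
            raise ValueError("lengths must be positive")
        if self.n_processes < 0 or self.n_filopodia < 0:
            raise ValueError("counts must be >= 0")


def ameboid_params(**overrides) -> PhenotypeParams:
    """Round activated cells without ramifications."""
    return replace(
        PhenotypeParams(
            soma_radius=(9.0, 1.2),
            boundary_harmonics=(3, 0.04),
            n_processes=0.0,
            n_filopodia=0,
        ),
        **overrides,
    )


def slightly_ramified_params(**overrides) -> PhenotypeParams:
    """Surveillant cells of young cultures: a few short, stout processes."""
    return replace(
        PhenotypeParams(
            soma_radius=(8.0, 1.0),
            boundary_harmonics=(2, 0.03),
            n_processes=2.0,
            process_length=(7.0, 1.5),
            process_thickness=3.0,
            branch_probability=0.2,
            n_filopodia=1,
            filopodia_length=3.0,
        ),
        **overrides,
    )


def hypertrophied_params(**overrides) -> PhenotypeParams:
    """Swollen soma with irregular boundary and many filopodia-like spikes."""
    return replace(
        PhenotypeParams(
            soma_radius=(11.5, 1.2),
            boundary_harmonics=(8, 0.16),
            n_processes=0.5,
            process_length=(8.0, 2.0),
            process_thickness=2.5,
            n_filopodia=12,
            filopodia_length=6.0,
        ),
        **overrides,
    )


def ramified_params(**overrides) -> PhenotypeParams:
    """Strongly ramified surveillant phenotype (long thin processes)."""
    return replace(
        PhenotypeParams(
            soma_radius=(5.0, 0.6),
            boundary_harmonics=(3, 0.06),
            n_processes=5.0,
            process_length=(25.0, 5.0),
            process_thickness=2.2,
            n_filopodia=2,
            filopodia_length=3.0,
        ),
        **overrides,
    )


def _soma_polygon(rng, params: PhenotypeParams, scale: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Radial-harmonic soma boundary; returns (angles, radii px, base radius px)."""
    r_mean, r_sd = params.soma_radius
    r0 = max(2.0, rng.normal(r_mean, r_sd)) * scale
    n_harm, amp = params.boundary_harmonics
    phi = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    r = np.full_like(phi, r0)
    for k in range(2, 2 + n_harm):
        a = amp * r0 * rng.uniform(0.5, 1.0)
        r += a * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    return phi, np.maximum(r, 0.3 * r0), r0


def _stamp_stroke(mask, start, direction, length, thickness, rng, jitter=0.18):
    """Rasterise a tapered random-walk stroke; returns its end point/direction."""
    pos = np.array(start, dtype=float)
    ang = direction
    steps = max(int(round(length)), 1)
    for i in range(steps):
        frac = i / steps
        t = max(thickness * (1.0 - 0.6 * frac), 1.0)
        rr, cc = draw_disk(pos, max(t / 2.0, 0.6), shape=mask.shape)
        mask[rr, cc] = True
        ang += rng.normal(0.0, jitter)
        pos += np.array([math.sin(ang), math.cos(ang)])
        if not (0 <= pos[0] < mask.shape[0] and 0 <= pos[1] < mask.shape[1]):
            break
    return pos, ang


def generate_silhouette(
    params: PhenotypeParams,
    seed: int,
    crop_size: int = 400,
    calibration: PixelCalibration | None = None,
    label: str = "",
) -> BinarySilhouette:
    """Draw one phenotype silhouette: soma + processes + filopodia.

    The result is a single 8-connected, hole-free component centred in a
    ``crop_size`` square.  Raises if the cell would touch the crop border
    (choose a larger crop for extreme parameters).
    """
    calibration = calibration or PixelCalibration()
    scale = 1.0 / calibration.microns_per_pixel  # px per μm
    rng = np.random.default_rng(seed)
    mask = np.zeros((crop_size, crop_size), bool)
    center = np.array([crop_size / 2.0, crop_size / 2.0])

    phi, radii, r0 = _soma_polygon(rng, params, scale)
    rr, cc = draw_polygon(
        center[0] + radii * np.sin(phi), center[1] + radii * np.cos(phi), shape=mask.shape
    )
    mask[rr, cc] = True

    def rim_point(angle: float) -> np.ndarray:
        r = float(np.interp(angle % (2 * np.pi), phi, radii, period=2 * np.pi))
        return center + (r - 1.0) * np.array([math.sin(angle), math.cos(angle)])

    n_proc = rng.poisson(params.n_processes) if params.n_processes > 0 else 0
    for _ in range(n_proc):
        ang = rng.uniform(0, 2 * np.pi)
        length = max(2.0, rng.normal(*params.process_length)) * scale
        thick = params.process_thickness * scale
        end, end_ang = _stamp_stroke(mask, rim_point(ang), ang, length, thick, rng)
        if rng.random() < params.branch_probability:
            _stamp_stroke(
                mask, end, end_ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0),
                0.5 * length, max(thick * 0.7, 1.0), rng,
            )

    for _ in range(params.n_filopodia):
        ang = rng.uniform(0, 2 * np.pi)
        length = max(1.0, rng.normal(params.filopodia_length, 0.25 * params.filopodia_length)) * scale
        _stamp_stroke(mask, rim_point(ang), ang, length, 1.6 * scale, rng, jitter=0.08)

    mask = ndi.binary_fill_holes(mask)
    # keep the soma's component (strokes start on the rim, so normally all of it)
    labels, n = ndi.label(mask, structure=_SQUARE)
    if n > 1:
        mask = labels == labels[int(center[0]), int(center[1])]
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError(
            "generated cell touches the crop border; increase crop_size"
        )
    # re-centre on the centroid
    rr, cc = np.nonzero(mask)
    dr = int(round(crop_size / 2 - rr.mean()))
    dc = int(round(crop_size / 2 - cc.mean()))
    mask = np.roll(np.roll(mask, dr, axis=0), dc, axis=1)
    return BinarySilhouette(mask, label=label or f"cell_{seed}")


# ---------------------------------------------------------------------------
# cohort design and rendering


@dataclass(frozen=True)
class CohortDesign:
    """Groups of phenotypes plus rendering noise parameters.

    ``groups`` is a list of ``(label, params, n)``; rendering uses a
    constant ``background`` offset, additive Gaussian noise of standard
    deviation ``noise_sd`` and a Gaussian blur of ``blur_sigma`` px.
    """

    groups: tuple[tuple[str, PhenotypeParams, int], ...]
    background: float = 10.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    crop_size: int = 400

    def __post_init__(self) -> None:
        if not self.groups or any(n < 1 for _, _, n in self.groups):
            raise ValueError("every group needs n >= 1")

    @property
    def total_n(self) -> int:
        return sum(n for _, _, n in self.groups)


def two_group_design(
    n_per_group: int = 25,
    crop_size: int = 192,
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
) -> CohortDesign:
    """Control vs SZR104-like contrast used for direction-recovery checks.

    The treated phenotype has a ~1.4× soma radius, a more irregular
    boundary and added filopodia, which by construction shifts area,
    perimeter, transformation index, hull area/perimeter, roughness and
    fractal dimension up, and circularity and density down.
    """
    return CohortDesign(
        groups=(
            ("control", slightly_ramified_params(), n_per_group),
            ("SZR104", hypertrophied_params(), n_per_group),
        ),
        crop_size=crop_size,
        noise_sd=noise_sd,
        blur_sigma=blur_sigma,
    )


def study_design(sizes: dict[str, int] | None = None, crop_size: int = 256) -> CohortDesign:
    """Six-arm design emulating the study's treatment groups.

    Group sizes default to the study's cell counts (974 in total).  The
    phenotype mixture per arm follows the reported qualitative morphologies:
    control and KYNA mostly slightly ramified, LPS ameboid, SZR104
    hypertrophied, and the combination arms intermediate.
    """
    sizes = sizes or STUDY_GROUP_SIZES
    presets = {
        "control": slightly_ramified_params(),
        "LPS": ameboid_params(soma_radius=(9.5, 1.3)),
        "KYNA": slightly_ramified_params(soma_radius=(7.5, 1.0), n_filopodia=2),
        "LPS+KYNA": ameboid_params(soma_radius=(9.0, 1.2), n_filopodia=1),
        "SZR104": hypertrophied_params(),
        "LPS+SZR104": hypertrophied_params(
            soma_radius=(10.0, 1.4), n_filopodia=4, boundary_harmonics=(4, 0.07)
        ),
    }
    groups = tuple((g, presets[g], n) for g, n in sizes.items())
    return CohortDesign(groups=groups, crop_size=crop_size)


def generate_cohort(
    design: CohortDesign,
    seed: int,
    calibration: PixelCalibration | None = None,
) -> list[tuple[str, str, BinarySilhouette]]:
    """Generate ``(label, group, silhouette)`` triples for a cohort design.

    Per-cell seeds are ``seed + cell_index``, so the cohort is a pure
    function of the master seed.
    """
    out = []
    index = 0
    for group, params, n in design.groups:
        for _ in range(n):
            label = f"{group}_{index:04d}"
            sil = generate_silhouette(
                params, seed=seed + index, crop_size=design.crop_size,
                calibration=calibration, label=label,
            )
            out.append((label, group, sil))
            index += 1
    return out


def render_two_channel(
    silhouette: BinarySilhouette,
    design: CohortDesign | None = None,
    seed: int = 0,
    calibration: PixelCalibration | None = None,
) -> MultiChannelImage:
    """Render a silhouette as a two-channel pseudo-micrograph.

    Channel 0 (nucleus) holds a bright nuclear disk placed at the deepest
    interior point of the cell; channel 1 (cytoplasm) holds the silhouette
    with the nuclear region dimmed — emulating the weak perinuclear
    staining of cytoplasmic markers that motivates merging the two binary
    silhouettes.  Gaussian blur and additive noise follow the design.
    """
    design = design or CohortDesign(groups=(("synthetic", PhenotypeParams(), 1),))
    mask = silhouette.mask
    dist = ndi.distance_transform_edt(mask)
    center = np.unravel_index(np.argmax(dist), dist.shape)
    nuc_radius = max(2.0, 0.6 * dist[center])
    nucleus = np.zeros_like(mask)
    rr, cc = draw_disk(center, nuc_radius, shape=mask.shape)
    nucleus[rr, cc] = True

    bg = design.background
    cyt = np.full(mask.shape, bg, dtype=float)
    cyt[mask] = 200.0
    cyt[nucleus & mask] = 60.0  # dim perinuclear staining
    nuc = np.full(mask.shape, bg, dtype=float)
    nuc[nucleus] = 200.0

    rng = np.random.default_rng(seed)
    planes = []
    for plane in (nuc, cyt):
        if design.blur_sigma > 0:
            plane = gaussian(plane, sigma=design.blur_sigma, preserve_range=True)
        if design.noise_sd > 0:
            plane = plane + rng.normal(0.0, design.noise_sd, plane.shape)
        planes.append(np.clip(plane, 0, 255).round().astype(np.uint8))
    return MultiChannelImage(
        np.stack(planes),
        {"nucleus": 0, "cytoplasm": 1},
        calibration or PixelCalibration(),
    )
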
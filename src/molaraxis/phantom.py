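"""Parametric molar phantoms with known ground-truth angulation.

The phantom family is the package's synthetic stand-in for segmented molars
on panoramic radiographs. Each phantom is a simple polygon built from the
features the measurement algorithm relies on: a crown wider than the cervix
(with a shallow occlusal cusp profile), near-parallel mesial/distal cervix
walls, and 0-2 root prongs (0 roots encodes an early development-stage
follicle, before root formation). The polygon is rotated to a known
ground-truth angle, optionally perturbed with vertex jitter/dropout, and
rasterized — so angle-recovery error can be measured exactly.

Six-tooth scenes emulate a mandibular arch: per-position angle magnitudes
are drawn from normal distributions whose defaults are the means and SDs
reported for manually measured molars (M1 16.7 +/- 5.2, M2 19.4 +/- 6.8,
M3 44.8 +/- 11.2 degrees), truncated to [0, 90); the sign follows the jaw
side (molars tilt mesially: positive for right-side teeth displayed on the
image left, negative for left-side teeth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import MultiPolygon, Polygon

from .annotations_io import (
    BinaryMask,
    Scene,
    ToothInstance,
    ToothLabel,
    rasterize_geometry,
)
from .errors import CanvasError, ParameterError, PlacementError

__all__ = [
    "MolarShapeParams",
    "NoiseParams",
    "PhantomRecord",
    "DEFAULT_ANGLE_MODEL",
    "make_molar_polygon",
    "make_phantom",
    "sample_scene",
]

#: Per-position (mean, sd) of angle magnitudes in degrees, matching the
#: distribution of manually measured molar angulations.
DEFAULT_ANGLE_MODEL: dict[str, tuple[float, float]] = {
    "M1": (16.7, 5.2),
    "M2": (19.4, 6.8),
    "M3": (44.8, 11.2),
}

#: Development-stage sampling for third molars: shortened Demirjian classes
#: with probabilities matching a 500-tooth adolescent cohort split
#: (117 no-roots / 174 bifurcation / 209 developed).
_M3_STAGE_CLASSES = ["no_roots", "bifurcation", "developed_roots"]
_M3_STAGE_PROBS = [117 / 500, 174 / 500, 209 / 500]
_STAGE_LETTERS = {"no_roots": "C", "bifurcation": "E", "developed_roots": "G"}
_STAGE_N_ROOTS = {"no_roots": 0, "bifurcation": 1, "developed_roots": 2}


@dataclass(frozen=True)
class MolarShapeParams:
    """Geometry of an upright molar phantom, in pixels.

    ``asymmetry`` skews the crown taper (mesial vs distal imbalance) in
    [-0.3, 0.3]; the cervix walls and roots stay symmetric so the shape's
    long axis remains well defined. ``n_roots = 0`` encodes a rootless
    follicle (development stages A-D): the outline stops at the cervix.
    """

    crown_width: float = 48.0
    crown_height: float = 30.0
    cervix_width: float = 32.0
    cervix_height: float = 40.0
    root_length: float = 30.0
    n_roots: int = 2
    root_spread: float = 20.0
    asymmetry: float = 0.0

    def __post_init__(self):
        if not self.crown_width > self.cervix_width > 0:
            raise ParameterError(
                f"need crown_width > cervix_width > 0, got "
                f"{self.crown_width} vs {self.cervix_width}"
            )
        for name in ("crown_height", "cervix_height", "root_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_roots not in (0, 1, 2):
            raise ParameterError(f"n_roots must be 0, 1 or 2, got {self.n_roots}")
        if self.n_roots == 2 and not 0 < self.root_spread:
            raise ParameterError("root_spread must be > 0 for two roots")
        if not -0.3 <= self.asymmetry <= 0.3:
            raise ParameterError(
                f"asymmetry must be in [-0.3, 0.3], got {self.asymmetry}"
            )


@dataclass(frozen=True)
class NoiseParams:
    """Boundary perturbation: i.i.d. Gaussian vertex jitter + dropout."""

    vertex_jitter_sd: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.vertex_jitter_sd < 0:
            raise ParameterError("vertex_jitter_sd must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ParameterError("dropout_prob must be in [0, 1)")


@dataclass
class PhantomRecord:
    """A generated tooth instance together with its ground truth."""

    instance: ToothInstance
    true_angle_deg: float
    params: MolarShapeParams
    stage_letter: str = "G"

    def __post_init__(self):
        if not abs(self.true_angle_deg) < 90:
            raise ParameterError("|true_angle_deg| must be < 90")


def make_molar_polygon(params: MolarShapeParams) -> np.ndarray:
    """Vertices (x, y) of an upright molar outline, occlusal edge at top.

    The shape is centered on x = 0; y runs from 0 (occlusal) downward. For
    ``asymmetry == 0`` the polygon is mirror-symmetric about x = 0. With two
    roots the bottom chain has exactly two downward prongs.
    """
    a = params.asymmetry
    half_l = params.crown_width / 2 * (1 - a)  # left crown half-width
    half_r = params.crown_width / 2 * (1 + a)
    cx = params.cervix_width / 2
    ch = params.crown_height
    y0 = ch + params.cervix_height  # cervix bottom
    cusp_dip = min(3.0, 0.1 * ch)

    # crown profile: bulge (height of contour) high in the occlusal third,
    # narrowed back to cervix width by 30% of crown height, then
    # near-vertical walls down to the cervix — molar proximal walls are
    # parallel below the bulge
    pts: list[tuple[float, float]] = [
        (-half_l, 0.1 * ch),
        (-half_l * 0.45, 0.0),
        (0.0, cusp_dip),
        (half_r * 0.45, 0.0),
        (half_r, 0.1 * ch),
        (half_r, 0.22 * ch),
        (cx, 0.30 * ch),
        (cx, y0),
    ]
    if params.n_roots == 1:
        pts.append((0.0, y0 + params.root_length))
    elif params.n_roots == 2:
        tip = params.root_spread / 2
        notch_y = y0 + 0.4 * params.root_length
        pts.extend(
            [
                (tip, y0 + params.root_length),
                (0.0, notch_y),
                (-tip, y0 + params.root_length),
            ]
        )
    pts.extend([(-cx, y0), (-cx, 0.30 * ch), (-half_l, 0.22 * ch)])

    poly = np.array(pts, dtype=float)
    if not Polygon(poly).is_valid:  # pragma: no cover - guards odd params
        raise ParameterError("shape parameters produce a self-intersecting outline")
    return poly


def _largest_polygon(geom) -> Polygon:
    """Largest polygonal component of a (possibly repaired) geometry."""
    if isinstance(geom, Polygon):
        return geom
    if isinstance(geom, MultiPolygon):
        return max(geom.geoms, key=lambda g: g.area)
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        raise ParameterError("noise destroyed the phantom outline")
    return max(polys, key=lambda g: g.area)


def make_phantom(
    params: MolarShapeParams,
    true_angle_deg: float,
    noise: NoiseParams | None = None,
    canvas: tuple[int, int] = (200, 200),
    center: tuple[float, float] | None = None,
    label: ToothLabel | None = None,
    image_id: str = "phantom",
) -> PhantomRecord:
    """Generate one rasterized molar phantom at a known angle.

    The upright outline is densified (~2.5 px vertex spacing), rotated by
    ``true_angle_deg`` about its centroid (positive = occlusal end toward
    +x), jittered per ``noise``, translated to ``center`` (canvas center by
    default) and rasterized by the pixel-center rule. Identical arguments
    (including the noise seed) produce identical masks.
    """
    noise = noise or NoiseParams()
    h, w = canvas
    poly = Polygon(make_molar_polygon(params))
    poly = shapely.segmentize(poly, max_segment_length=2.5)
    centroid = poly.centroid
    # shapely's CCW rotation in (x, y-down) raster axes moves the occlusal
    # (top) end toward +x for positive angles — exactly our sign convention
    poly = affinity.rotate(poly, true_angle_deg, origin=centroid)

    coords = np.asarray(poly.exterior.coords)[:-1]
    rng = np.random.default_rng(noise.seed)
    if noise.dropout_prob > 0:
        keep = rng.random(len(coords)) >= noise.dropout_prob
        if keep.sum() >= 3:
            coords = coords[keep]
    if noise.vertex_jitter_sd > 0:
        coords = coords + rng.normal(0, noise.vertex_jitter_sd, coords.shape)
    poly = Polygon(coords)
    if not poly.is_valid:
        poly = _largest_polygon(shapely.make_valid(poly))

    if center is None:
        center = (w / 2, h / 2)
    c = poly.centroid
    poly = affinity.translate(poly, xoff=center[0] - c.x, yoff=center[1] - c.y)
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise CanvasError(
            f"rotated phantom bounds {poly.bounds} exceed canvas {canvas}"
        )
    mask = rasterize_geometry(poly, h, w)
    instance = ToothInstance(
        label=label or ToothLabel.from_fdi(38),
        mask=mask,
        source_image_id=image_id,
    )
    return PhantomRecord(
        instance=instance, true_angle_deg=float(true_angle_deg), params=params
    )


def _sample_magnitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Angle magnitude from Normal(mean, sd) truncated to [0, 90)."""
    if sd == 0:
        return float(mean)
    from scipy.stats import truncnorm

    a, b = (0 - mean) / sd, (90 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# arch layout: (fdi, center x) on a 1000-px-wide canvas; right side (46-48)
# on the image left, M3 most distal
_ARCH_X = {48: 110, 47: 250, 46: 390, 36: 610, 37: 750, 38: 890}


def sample_scene(
    rng_seed: int,
    angle_model: dict[str, tuple[float, float]] | None = None,
    canvas: tuple[int, int] = (320, 1000),
    noise: NoiseParams | None = None,
    base_params: MolarShapeParams | None = None,
    image_id: str | None = None,
    max_retries: int = 10,
) -> tuple[Scene, list[PhantomRecord]]:
    """Generate a six-molar scene along a shallow arch.

    Per-position angle magnitudes are drawn from ``angle_model`` (position
    -> (mean, sd), default :data:`DEFAULT_ANGLE_MODEL`) truncated to
    [0, 90); signs follow the jaw side (right positive, left negative).
    Third-molar morphology is sampled over the shortened development-stage
    classes (rootless follicle / starting bifurcation / developed roots);
    first and second molars always have developed roots. Shape dimensions
    are mildly randomized (+/-10% scale, small crown asymmetry) per tooth.

    Returns the Scene plus one :class:`PhantomRecord` per tooth. Fixed
    ``rng_seed`` gives an identical scene on repeat.
    """
    angle_model = angle_model or DEFAULT_ANGLE_MODEL
    base = base_params or MolarShapeParams()
    rng = np.random.default_rng(rng_seed)
    image_id = image_id or f"phantom_scene_{rng_seed:08d}"
    h, w = canvas

    occupied = np.zeros((h, w), dtype=bool)
    instances: list[ToothInstance] = []
    records: list[PhantomRecord] = []
    for fdi, x_center in _ARCH_X.items():
        tooth = ToothLabel.from_fdi(fdi)
        mean, sd = angle_model[tooth.position.value]
        if tooth.position.value == "M3":
            stage_class = rng.choice(_M3_STAGE_CLASSES, p=_M3_STAGE_PROBS)
        else:
            stage_class = "developed_roots"
        scale = rng.uniform(0.9, 1.1)
        params = replace(
            base,
            crown_width=base.crown_width * scale,
            crown_height=base.crown_height * scale,
            cervix_width=base.cervix_width * scale,
            cervix_height=base.cervix_height * scale,
            root_length=base.root_length * scale,
            root_spread=base.root_spread * scale,
            n_roots=_STAGE_N_ROOTS[stage_class],
            asymmetry=float(rng.uniform(-0.1, 0.1)),
        )
        # shallow arch: distal molars sit slightly lower
        y_center = 160 + 0.00015 * (x_center - w / 2) ** 2
        tooth_noise = (
            replace(noise, seed=int(rng.integers(2**31))) if noise else None
        )
        last_err: Exception | None = None
        for attempt in range(max_retries):
            magnitude = _sample_magnitude(rng, mean, sd)
            signed = magnitude if tooth.side.value == "right" else -magnitude
            try:
                rec = make_phantom(
                    params,
                    signed,
                    noise=tooth_noise,
                    canvas=canvas,
                    center=(x_center, y_center),
                    label=tooth,
                    image_id=image_id,
                )
            except CanvasError as exc:
                last_err = exc
                continue
            if not (occupied & rec.instance.mask.pixels).any():
                break
            last_err = PlacementError(f"tooth {fdi} overlaps a neighbor")
        else:
            raise PlacementError(
                f"could not place tooth {fdi} after {max_retries} tries: {last_err}"
            )
        rec.stage_letter = _STAGE_LETTERS[stage_class]
        occupied |= rec.instance.mask.pixels
        instances.append(rec.instance)
        records.append(rec)

    scene = Scene(
        image_id=image_id, instances=instances, image_height=h, image_width=w
    )
    return scene, records
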
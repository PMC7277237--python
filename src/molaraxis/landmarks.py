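"""Reference-point estimation and the initial axis angle.

The iterative orientation refinement needs a seed angle. Clinically the
seed comes from two reference points on the tooth: the midpoint of the
occlusal surface and the floor of the pulp chamber, which for mandibular
molars sit roughly on the long axis near its two ends. Here both points
are estimated geometrically from the mask with a two-pass band heuristic:

1. take foreground centroids over two horizontal row bands of the occupied
   extent — an upper-crown band for the occlusal midpoint and a cervix
   band for the pulp floor — and form a first axis estimate;
2. rotate the foreground coordinates upright by that estimate, re-apply
   the same bands in the rotated frame (where they now cut clean
   cross-sections of crown and cervix), and map the band centroids back to
   image coordinates.

The second pass matters for strongly tilted teeth, where a horizontal band
at the top of the bounding box catches a crown corner rather than a
cross-section. The seed only needs to fall within a few degrees of the
true axis — the contour-regression iterations do the rest.

Angle convention (used throughout the package): 0 deg = image-vertical
axis, positive = occlusal end displaced toward +x (image right), in the
raster frame with y pointing down.
"""

from __future__ import annotations

import math

import numpy as np

from .annotations_io import BinaryMask, LandmarkPair
from .errors import DegenerateMaskError, UndefinedAxisError

__all__ = ["estimate_landmarks", "initial_axis_angle"]

#: Band fractions of the occupied vertical span (from the top) whose
#: foreground centroids serve as landmark estimates: upper crown for the
#: occlusal midpoint, cervix for the pulp-chamber floor.
OCCLUSAL_BAND = (0.10, 0.30)
PULP_BAND = (0.45, 0.65)


def _band_centroids(
    xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Centroids of the occlusal and pulp bands over foreground points."""
    y_min, y_max = ys.min(), ys.max()
    span = y_max - y_min
    out = []
    for lo, hi in (OCCLUSAL_BAND, PULP_BAND):
        frac = (ys - y_min) / span
        sel = (frac >= lo) & (frac < hi)
        if not sel.any():  # extremely flat masks: fall back to nearest row
            sel = np.abs(frac - (lo + hi) / 2) <= 0.5 / span
        out.append(np.array([xs[sel].mean(), ys[sel].mean()]))
    return out[0], out[1]


def estimate_landmarks(mask: BinaryMask) -> LandmarkPair:
    """Estimate the occlusal midpoint and pulp-chamber floor from the mask.

    Two-pass band-centroid heuristic (see module docstring). Raises
    :class:`DegenerateMaskError` when the mask occupies fewer than 3 rows.
    """
    fg = mask.pixels
    occupied = np.nonzero(fg.any(axis=1))[0]
    if len(occupied) < 3:
        raise DegenerateMaskError(
            f"landmark estimation needs >= 3 occupied rows, got {len(occupied)}"
        )
    rows, cols = np.nonzero(fg)
    xs = cols.astype(float)
    ys = rows.astype(float)

    # pass 1: bands on image rows
    occ, pulp = _band_centroids(xs, ys)
    # tilt of the first-pass axis, same convention as initial_axis_angle
    theta = math.atan2(occ[0] - pulp[0], pulp[1] - occ[1])

    # pass 2: re-apply the bands in the upright frame
    c, s = math.cos(theta), math.sin(theta)
    center = np.array([xs.mean(), ys.mean()])
    xr = c * (xs - center[0]) + s * (ys - center[1])
    yr = -s * (xs - center[0]) + c * (ys - center[1])
    occ_r, pulp_r = _band_centroids(xr, yr)
    back = np.array([[c, -s], [s, c]])
    occ = back @ occ_r + center
    pulp = back @ pulp_r + center

    return LandmarkPair(
        occlusal_midpoint=(float(occ[0]), float(occ[1])),
        pulp_floor=(float(pulp[0]), float(pulp[1])),
    )


def initial_axis_angle(landmarks: LandmarkPair) -> float:
    """Signed seed angle (degrees) of the occlusal->pulp axis from vertical.

    angle = atan2(x_occ - x_pulp, y_pulp - y_occ); 0 deg is image-vertical,
    positive means the occlusal point lies to the right of the pulp point.
    """
    (xo, yo) = landmarks.occlusal_midpoint
    (xp, yp) = landmarks.pulp_floor
    dx = xo - xp
    dy = yp - yo
    if math.hypot(dx, dy) < 1e-12:
        raise UndefinedAxisError("landmark points coincide; axis undefined")
    return math.degrees(math.atan2(dx, dy))
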
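"""Spherical-droplet and droplet-pair geometry.

Two lipid-monolayer-coated aqueous droplets adhering in oil form a bilayer
at their contact zone.  In the image plane each droplet projects to a
circle; the pair geometry (contact-patch radius ``rc``, contact angle
``theta``, bilayer area ``Ab``) follows from the standard two-circle
intersection.  The contact angle convention is the angle between each
droplet's monolayer tangent at the contact line and the bilayer plane, so
that the bilayer-tension relation gamma_b = 2*gamma_m*cos(theta) returns
2*gamma_m at theta = 0; per droplet theta_i = arcsin(rc / R_i) and the
reported angle is the mean of the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops


class NoBilayerError(ValueError):
    """Raised when two circles are disjoint or nested: no contact patch exists."""


class UnusableFrameError(ValueError):
    """Raised when an image does not contain a detectable droplet pair."""


@dataclass(frozen=True)
class Circle:
    """A circle in the image plane: center (cx, cy) and radius r, all in one
    length unit (um or px).  Raster convention: origin top-left, x rightward,
    y downward."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")


@dataclass(frozen=True)
class DropletPairGeometry:
    """Geometry of two adherent spherical droplets.

    Attributes
    ----------
    R1, R2 : float
        Droplet radii (um), largest first by convention of the constructors.
    D : float
        Center-to-center distance (um).
    rc : float
        Contact-patch (bilayer) radius (um).
    theta : float
        Contact angle (degrees), mean of the per-droplet angles.
    Ab : float
        Bilayer contact area pi*rc**2 (um^2).
    """

    R1: float
    R2: float
    D: float
    rc: float
    theta: float
    Ab: float

    def to_dict(self) -> dict:
        g = asdict(self)
        return {
            "R1_um": g["R1"],
            "R2_um": g["R2"],
            "D_um": g["D"],
            "rc_um": g["rc"],
            "theta_deg": g["theta"],
            "Ab_um2": g["Ab"],
        }


def sphere_volume_from_diameter(d: float) -> float:
    """Volume (um^3) of a sphere of diameter ``d`` (um): (pi/6) d^3."""
    if not d > 0:
        raise ValueError(f"diameter must be positive, got {d}")
    return math.pi / 6.0 * d**3


def sphere_diameter_from_volume(v: float) -> float:
    """Inverse of :func:`sphere_volume_from_diameter`."""
    if not v > 0:
        raise ValueError(f"volume must be positive, got {v}")
    return (6.0 * v / math.pi) ** (1.0 / 3.0)


def contact_geometry_from_circles(c1: Circle, c2: Circle) -> DropletPairGeometry:
    """Pair geometry from two intersecting circles.

    The contact-patch radius is half the common chord of the two circles;
    per-droplet contact angles are arcsin(rc/Ri) and the reported angle is
    their mean.  Raises :class:`NoBilayerError` for disjoint or nested
    circles (no bilayer formed).
    """
    d = math.hypot(c2.cx - c1.cx, c2.cy - c1.cy)
    r1, r2 = c1.r, c2.r
    if not (abs(r1 - r2) < d < r1 + r2):
        raise NoBilayerError(
            f"circles do not intersect (r1={r1}, r2={r2}, D={d}): no bilayer formed"
        )
    # distance from center 1 to the radical line, then half-chord length
    a = (d**2 + r1**2 - r2**2) / (2.0 * d)
    rc2 = r1**2 - a**2
    if rc2 <= 0:  # numerically tangent
        raise NoBilayerError("circles are tangent: zero-area contact patch")
    rc = math.sqrt(rc2)
    th1 = math.degrees(math.asin(min(rc / r1, 1.0)))
    th2 = math.degrees(math.asin(min(rc / r2, 1.0)))
    R1, R2 = (r1, r2) if r1 >= r2 else (r2, r1)
    return DropletPairGeometry(
        R1=R1, R2=R2, D=d, rc=rc, theta=0.5 * (th1 + th2), Ab=math.pi * rc2
    )


def geometry_from_diameters_and_theta(
    d1: float, d2: float, theta_deg: float
) -> DropletPairGeometry:
    """Pair geometry from the two droplet diameters and a known contact angle.

    Convenience constructor for permeability analysis, where diameters and
    the contact angle are the measured quantities.  rc is set by the smaller
    droplet (rc = R_min * sin(theta)); D follows from the two sagittae.
    """
    if not (0 < theta_deg < 90):
        raise ValueError("contact angle must lie in (0, 90) degrees")
    R1, R2 = d1 / 2.0, d2 / 2.0
    rmin = min(R1, R2)
    rc = rmin * math.sin(math.radians(theta_deg))
    D = math.sqrt(R1**2 - rc**2) + math.sqrt(R2**2 - rc**2)
    Rb, Rs = max(R1, R2), min(R1, R2)
    th = 0.5 * (
        math.degrees(math.asin(rc / Rb)) + math.degrees(math.asin(rc / Rs))
    )
    return DropletPairGeometry(R1=Rb, R2=Rs, D=D, rc=rc, theta=th, Ab=math.pi * rc**2)


# ---------------------------------------------------------------------------
# circle fitting


def fit_circle_kasa(x: np.ndarray, y: np.ndarray) -> Circle:
    """Algebraic (Kasa) least-squares circle fit to boundary points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to fit a circle")
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate point set: negative squared radius")
    return Circle(cx=float(cx), cy=float(cy), r=float(math.sqrt(r2)))


def refine_circle_geometric(
    x: np.ndarray, y: np.ndarray, init: Circle, n_iter: int = 3
) -> Circle:
    """Gauss–Newton refinement of a circle fit minimizing geometric distance."""
    cx, cy, r = init.cx, init.cy, init.r
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for _ in range(n_iter):
        dx = x - cx
        dy = y - cy
        di = np.hypot(dx, dy)
        di = np.where(di == 0, 1e-12, di)
        res = di - r
        J = np.column_stack([-dx / di, -dy / di, -np.ones_like(di)])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        cx += step[0]
        cy += step[1]
        r += step[2]
    if r <= 0:
        raise ValueError("geometric refinement collapsed to non-positive radius")
    return Circle(cx=float(cx), cy=float(cy), r=float(r))


def _fit_circle(points: np.ndarray) -> Circle:
    c0 = fit_circle_kasa(points[:, 1], points[:, 0])  # contour rows are (y, x)
    return refine_circle_geometric(points[:, 1], points[:, 0], c0)


def _two_arc_decomposition(points: np.ndarray, n_iter: int = 25) -> tuple[Circle, Circle]:
    """Fit two circles to the boundary of a union of two overlapping disks.

    The union boundary consists of exactly two circular arcs, so alternating
    point assignment (to the circle with smaller radial residual) and
    per-subset circle fitting converges to the generating circles.
    Initialised by splitting the contour along its principal axis.
    """
    xy = points[:, ::-1]  # (x, y)
    mean = xy.mean(axis=0)
    centered = xy - mean
    # principal axis of the blob boundary
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    assign = proj > np.median(proj)
    prev = None
    c1 = c2 = None
    for _ in range(n_iter):
        if assign.sum() < 3 or (~assign).sum() < 3:
            raise UnusableFrameError("arc decomposition degenerated")
        c1 = _fit_circle(points[assign])
        c2 = _fit_circle(points[~assign])
        d1 = np.abs(np.hypot(xy[:, 0] - c1.cx, xy[:, 1] - c1.cy) - c1.r)
        d2 = np.abs(np.hypot(xy[:, 0] - c2.cx, xy[:, 1] - c2.cy) - c2.r)
        new = d1 < d2
        if prev is not None and np.array_equal(new, prev):
            break
        prev = assign
        assign = new
    return c1, c2


def detect_droplet_pair(
    image: np.ndarray,
    threshold: float | None = None,
    min_area: int = 50,
) -> tuple[Circle, Circle]:
    """Detect two droplets in a grayscale image and fit circles to them.

    The image is thresholded (Otsu by default; droplets are assumed bright on
    a dark background), connected components smaller than ``min_area`` px are
    discarded, and subpixel boundaries are extracted with marching squares.
    Two components are fitted independently; a single component — the normal
    case for an adherent pair, whose union boundary is two circular arcs —
    is decomposed into two arcs and fitted.  Returns the circles largest
    first.  Raises :class:`UnusableFrameError` if no droplet pair is found.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 1e-12:
        raise UnusableFrameError("blank image: no droplets detected")
    if threshold is None:
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    lab = label(mask)
    comps = [p for p in regionprops(lab) if p.area >= min_area]
    if len(comps) == 0:
        raise UnusableFrameError("no components above minimum area")
    if len(comps) > 2:
        comps = sorted(comps, key=lambda p: p.area, reverse=True)
        if comps[2].area > 0.1 * comps[1].area:
            raise UnusableFrameError(f"{len(comps)} components found, expected 2")
        comps = comps[:2]

    level = threshold
    contours = [c for c in find_contours(img, level) if len(c) >= 20]
    if not contours:
        raise UnusableFrameError("no usable boundary contour")

    if len(comps) == 2:
        circles = []
        for p in comps:
            cy, cx = p.centroid
            # nearest contour to this component centroid
            best = min(
                contours,
                key=lambda c: np.hypot(c[:, 0] - cy, c[:, 1] - cx).min(),
            )
            circles.append(_fit_circle(best))
        c1, c2 = circles
    else:
        contour = max(contours, key=len)
        c1, c2 = _two_arc_decomposition(contour)

    if c1.r * c2.r <= 0:
        raise UnusableFrameError("degenerate circle fit")
    if c1.r < c2.r:
        c1, c2 = c2, c1
    return c1, c2
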
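"""Four-point estimation and removal of uneven lighting in the L* channel.

Uneven lighting from a misaligned microscope lamp or condenser (poor
Koehler illumination) manifests as an approximately planar loss of
lightness across the field.  Given four pixels that ought to be unstained
white background (``L* = 100``), the per-pixel lightness deficit — the
*illumination mask* — is estimated by a stepwise geometric scheme:

1. for every pair of source points, extend the line through them to the
   image border and linearly extrapolate the deficit to the two
   intersection points;
2. on each border, average the linear extensions of every pair of
   intersection points to obtain a 1-D deficit profile;
3. at an interior pixel, average the vertical interpolation between the
   top/bottom profiles with the horizontal one between left/right.

Every step is linear in position and in the sampled deficits, so the
composite is exact whenever the true deficit field is a plane — the
observed lighting pattern — while the full estimate is quadratic in pixel
position.  Restoring the deficit (scaled by ``factor/5``) brightens the
background back toward the reference lightness; the a*/b* chromaticity
planes are never touched, which is the entire point of working in CIE LAB.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ColinearPointsError,
    DuplicatePointError,
    NoWhiteAreaError,
    OutOfBoundsError,
    ValidationError,
)

__all__ = [
    "SourcePoint",
    "SourcePointSet",
    "CorrectionSettings",
    "validate_points",
    "line_rectangle_intersections",
    "extrapolate_mask_to_boundary",
    "border_profiles",
    "build_mask",
    "apply_correction",
    "auto_select_points",
]

#: Triangle area below which three points count as colinear (px² units).
COLINEARITY_TOL = 1e-9

_GEOM_TOL = 1e-7


@dataclass(frozen=True)
class SourcePoint:
    """A background anchor pixel: column ``x``, row ``y`` (0-based, origin
    top-left) and its observed lightness ``lstar``."""

    x: float
    y: float
    lstar: float

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class SourcePointSet:
    """Exactly four source points plus the reference lightness (default 100)
    that unstained background should reach."""

    points: tuple[SourcePoint, SourcePoint, SourcePoint, SourcePoint]
    reference: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) != 4:
            raise ValidationError(f"exactly 4 source points required, got {len(self.points)}")

    def deficits(self) -> np.ndarray:
        """Lightness deficit ``reference − L*`` of each point."""
        return np.array([self.reference - p.lstar for p in self.points])


@dataclass(frozen=True)
class CorrectionSettings:
    """Correction strength: integer ``factor`` in 1..5 (5 = restore the full
    deficit, lower = dimmer result) and the reference lightness."""

    factor: int = 5
    reference: float = 100.0

    def __post_init__(self) -> None:
        if not (1 <= int(self.factor) <= 5) or int(self.factor) != self.factor:
            raise ValidationError(f"correction factor must be an integer in [1, 5], got {self.factor}")


def _triangle_area(p, q, r) -> float:
    return 0.5 * abs(
        (q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1])
    )


def validate_points(pts: SourcePointSet, image_shape: tuple[int, int]) -> SourcePointSet:
    """Check bounds, distinctness and the no-three-colinear constraint.

    Returns the set unchanged when valid; raises otherwise.
    """
    h, w = image_shape[:2]
    for p in pts.points:
        if not (0 <= p.x <= w - 1 and 0 <= p.y <= h - 1):
            raise OutOfBoundsError(f"source point {p.xy} outside {w}x{h} image")
    for a, b in itertools.combinations(pts.points, 2):
        if abs(a.x - b.x) < _GEOM_TOL and abs(a.y - b.y) < _GEOM_TOL:
            raise DuplicatePointError(f"duplicate source point {a.xy}")
    for a, b, c in itertools.combinations(pts.points, 3):
        if _triangle_area(a.xy, b.xy, c.xy) <= COLINEARITY_TOL:
            raise ColinearPointsError(
                f"source points {a.xy}, {b.xy}, {c.xy} are colinear"
            )
    return pts


def line_rectangle_intersections(
    p: SourcePoint | tuple[float, float],
    q: SourcePoint | tuple[float, float],
    image_shape: tuple[int, int],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Where the infinite line through ``p`` and ``q`` meets the image border.

    The border is the rectangle ``x ∈ [0, W−1], y ∈ [0, H−1]``.  If both
    points already lie on the same border, they are returned themselves
    (the line runs along that border).
    """
    px, py = (p.x, p.y) if isinstance(p, SourcePoint) else p
    qx, qy = (q.x, q.y) if isinstance(q, SourcePoint) else q
    h, w = image_shape[:2]
    if abs(px - qx) < _GEOM_TOL and abs(py - qy) < _GEOM_TOL:
        raise ValidationError("degenerate pair: identical points have no line")

    # same-border rule
    for coords, val in (((px, qx), 0.0), ((px, qx), w - 1.0), ((py, qy), 0.0), ((py, qy), h - 1.0)):
        if abs(coords[0] - val) < _GEOM_TOL and abs(coords[1] - val) < _GEOM_TOL:
            return ((px, py), (qx, qy))

    dx, dy = qx - px, qy - py
    cands: list[tuple[float, float, float]] = []  # (t, x, y)
    if abs(dx) > _GEOM_TOL:
        for xb in (0.0, w - 1.0):
            t = (xb - px) / dx
            y = py + t * dy
            if -_GEOM_TOL <= y <= h - 1 + _GEOM_TOL:
                cands.append((t, xb, min(max(y, 0.0), h - 1.0)))
    if abs(dy) > _GEOM_TOL:
        for yb in (0.0, h - 1.0):
            t = (yb - py) / dy
            x = px + t * dx
            if -_GEOM_TOL <= x <= w - 1 + _GEOM_TOL:
                cands.append((t, min(max(x, 0.0), w - 1.0), yb))
    uniq: list[tuple[float, float, float]] = []
    for c in sorted(cands):
        if not any(abs(c[1] - u[1]) < _GEOM_TOL and abs(c[2] - u[2]) < _GEOM_TOL for u in uniq):
            uniq.append(c)
    if len(uniq) < 2:  # cannot happen for two in-bounds distinct points
        raise ValidationError("line does not cross the image border twice")
    first, last = uniq[0], uniq[-1]
    return ((first[1], first[2]), (last[1], last[2]))


def extrapolate_mask_to_boundary(
    p: SourcePoint,
    q: SourcePoint,
    boundary_pt: tuple[float, float],
    reference: float = 100.0,
) -> float:
    """Deficit at a point on the line through ``p`` and ``q``.

    The deficits ``reference − L*`` of the two source points are extended
    linearly along the line, parameterized by signed projection from ``p``.
    """
    dx, dy = q.x - p.x, q.y - p.y
    norm2 = dx * dx + dy * dy
    if norm2 < _GEOM_TOL**2:
        raise ValidationError("degenerate pair: identical points")
    t = ((boundary_pt[0] - p.x) * dx + (boundary_pt[1] - p.y) * dy) / norm2
    mp, mq = reference - p.lstar, reference - q.lstar
    return mp + t * (mq - mp)


def _gather_border_points(
    pts: SourcePointSet, image_shape: tuple[int, int]
) -> dict[str, list[tuple[float, float]]]:
    """Intersection points with deficits, grouped per border.

    Each entry is ``(position along border, deficit)``; a corner point
    contributes to both borders it lies on.
    """
    h, w = image_shape[:2]
    borders: dict[str, list[tuple[float, float]]] = {
        "top": [], "bottom": [], "left": [], "right": []
    }
    for p, q in itertools.combinations(pts.points, 2):
        for bx, by in line_rectangle_intersections(p, q, image_shape):
            mv = extrapolate_mask_to_boundary(p, q, (bx, by), pts.reference)
            if abs(by) < _GEOM_TOL:
                borders["top"].append((bx, mv))
            if abs(by - (h - 1.0)) < _GEOM_TOL:
                borders["bottom"].append((bx, mv))
            if abs(bx) < _GEOM_TOL:
                borders["left"].append((by, mv))
            if abs(bx - (w - 1.0)) < _GEOM_TOL:
                borders["right"].append((by, mv))
    return borders


def _lsq_plane(pts: SourcePointSet):
    """Least-squares plane a + b·x + c·y through the four deficits."""
    A = np.array([[1.0, p.x, p.y] for p in pts.points])
    coef, *_ = np.linalg.lstsq(A, pts.deficits(), rcond=None)
    return coef


def border_profiles(
    border_points: dict[str, list[tuple[float, float]]],
    image_shape: tuple[int, int],
    pts: SourcePointSet | None = None,
) -> dict[str, np.ndarray]:
    """1-D deficit profiles along the four borders.

    At each border position the profile is the mean, over every pair of
    intersection points on that border with distinct positions, of the
    linear inter/extrapolation through the pair.  A border carrying fewer
    than two distinct positions falls back to the least-squares plane
    through the four source deficits, evaluated along that border (exact
    for planar fields).
    """
    h, w = image_shape[:2]
    lengths = {"top": w, "bottom": w, "left": h, "right": h}
    fixed = {"top": 0.0, "bottom": h - 1.0, "left": 0.0, "right": w - 1.0}
    horizontal = {"top": True, "bottom": True, "left": False, "right": False}
    coef = _lsq_plane(pts) if pts is not None else None

    profiles: dict[str, np.ndarray] = {}
    for name, entries in border_points.items():
        n = lengths[name]
        pos = np.arange(n, dtype=float)
        pairs = [
            (p1, m1, p2, m2)
            for (p1, m1), (p2, m2) in itertools.combinations(entries, 2)
            if abs(p2 - p1) > _GEOM_TOL
        ]
        if pairs:
            acc = np.zeros(n)
            for p1, m1, p2, m2 in pairs:
                acc += m1 + (pos - p1) * (m2 - m1) / (p2 - p1)
            profiles[name] = acc / len(pairs)
        else:
            if coef is None:
                raise ValidationError(
                    f"border '{name}' has <2 distinct intersection points and "
                    "no source points were given for the plane fallback"
                )
            if horizontal[name]:
                profiles[name] = coef[0] + coef[1] * pos + coef[2] * fixed[name]
            else:
                profiles[name] = coef[0] + coef[1] * fixed[name] + coef[2] * pos
    return profiles


def build_mask(pts: SourcePointSet, image_shape: tuple[int, int]) -> np.ndarray:
    """Estimate the per-pixel lightness deficit from four source points.

    Runs the full stepwise pipeline (pair lines → border intersections →
    extrapolated deficits → border profiles → directional interpolation);
    at pixel ``(x, y)`` the value is the mean of the vertical interpolation
    between ``top(x)`` and ``bottom(x)`` and the horizontal one between
    ``left(y)`` and ``right(y)``.
    """
    validate_points(pts, image_shape)
    h, w = image_shape[:2]
    prof = border_profiles(_gather_border_points(pts, image_shape), image_shape, pts)
    ty = (np.arange(h, dtype=float) / (h - 1))[:, None]
    tx = (np.arange(w, dtype=float) / (w - 1))[None, :]
    vert = prof["top"][None, :] * (1.0 - ty) + prof["bottom"][None, :] * ty
    horiz = prof["left"][:, None] * (1.0 - tx) + prof["right"][:, None] * tx
    return 0.5 * (vert + horiz)


def apply_correction(
    lab: np.ndarray,
    mask: np.ndarray,
    settings: CorrectionSettings | None = None,
) -> np.ndarray:
    """Restore the lightness deficit: ``L*out = clip(L* + (factor/5)·mask)``.

    a* and b* are returned bit-identical; only the L* plane changes.
    Factor 5 restores the full deficit, smaller factors a proportional
    part of it.
    """
    settings = settings or CorrectionSettings()
    lab = np.asarray(lab, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if lab.shape[:2] != mask.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image shape {lab.shape[:2]}"
        )
    out = lab.copy()
    out[..., 0] = np.clip(lab[..., 0] + (settings.factor / 5.0) * mask, 0.0, 100.0)
    return out


def _mirror_into(
    x: float, y: float, src_quad: tuple[int, int], dst_quad: tuple[int, int], h: int, w: int
) -> tuple[float, float]:
    """Reflect a point across the image center lines from one quadrant into
    another (flip x across the vertical line iff the column halves differ,
    y across the horizontal line iff the row halves differ)."""
    if src_quad[1] != dst_quad[1]:
        x = (w - 1) - x
    if src_quad[0] != dst_quad[0]:
        y = (h - 1) - y
    return x, y


def auto_select_points(
    lab: np.ndarray,
    white_threshold: float = 90.0,
    reference: float = 100.0,
) -> SourcePointSet:
    """Pick one probable-white source point per image quadrant.

    Pixels with ``L* ≥ white_threshold`` are the white candidates.  The
    image is split in four quadrants at ``floor(W/2)`` / ``floor(H/2)``
    (boundary pixels belong to the right/bottom quadrant).  In a populated
    quadrant the selected point is the candidate closest (Euclidean) to the
    centroid of that quadrant's candidates, ties broken by row-major order.
    An empty quadrant receives the centroid of the other quadrants' points
    mirrored across the image center lines, with its deficit set to the
    mean deficit of the found points.
    """
    lab = np.asarray(lab, dtype=float)
    h, w = lab.shape[:2]
    L = lab[..., 0]
    cand = L >= white_threshold
    if not cand.any():
        raise NoWhiteAreaError(
            f"no pixel reaches the white threshold L* >= {white_threshold}"
        )
    mx, my = w // 2, h // 2
    found: dict[tuple[int, int], SourcePoint] = {}
    for qr in (0, 1):  # 0 = top half, 1 = bottom half
        for qc in (0, 1):  # 0 = left half, 1 = right half
            rows = slice(0, my) if qr == 0 else slice(my, h)
            cols = slice(0, mx) if qc == 0 else slice(mx, w)
            sub = cand[rows, cols]
            ys, xs = np.nonzero(sub)
            if ys.size == 0:
                continue
            ys = ys + rows.start
            xs = xs + cols.start
            cx, cy = xs.mean(), ys.mean()
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2
            i = int(np.argmin(d2))  # first minimum = row-major tie-break
            found[(qr, qc)] = SourcePoint(float(xs[i]), float(ys[i]), float(L[ys[i], xs[i]]))

    mean_deficit = float(np.mean([reference - p.lstar for p in found.values()]))
    points: list[SourcePoint] = []
    for quad in ((0, 0), (0, 1), (1, 0), (1, 1)):
        if quad in found:
            points.append(found[quad])
            continue
        mirrored = [
            _mirror_into(p.x, p.y, src, quad, h, w) for src, p in found.items()
        ]
        mxs = float(np.mean([m[0] for m in mirrored]))
        mys = float(np.mean([m[1] for m in mirrored]))
        x = float(np.clip(round(mxs), 0, w - 1))
        y = float(np.clip(round(mys), 0, h - 1))
        points.append(SourcePoint(x, y, reference - mean_deficit))

    pts = SourcePointSet(tuple(points), reference=reference)
    return validate_points(pts, (h, w))
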
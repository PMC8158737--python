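"""Raster-and-contour geometry for lumbar-spine measurements.

All operations work in physical millimetres: a pixel at ``(row, col)`` has
its centre at ``(row * spacing_row, col * spacing_col)``.  Contours are
closed polylines of ``(x, y)`` points where ``x`` is the column coordinate
and ``y`` the row coordinate, both in mm, wound counter-clockwise in that
frame.

The measurements implemented here feed the per-segment pathology rules:

* the excess of the intervertebral disc beyond the projected footprint of
  the adjacent vertebral bodies (disc herniation / bulging),
* the cross-sectional area of the dural sac (spinal canal stenosis),
* posterior tangents and the superior-endplate line of adjacent vertebral
  bodies on the sagittal view (spondylolisthesis percentage),
* expected-versus-actual nerve-root positions and tissue contact
  (nerve root compression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from .datamodel import LabelMap

__all__ = [
    "GeometryError",
    "EmptyMaskError",
    "Contour",
    "ExcessRegion",
    "TangentConstruction",
    "extract_contour",
    "project_vertebral_footprint",
    "disc_excess",
    "region_area",
    "posterior_tangent_construction",
    "expected_root_position",
    "contact",
]

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


class GeometryError(ValueError):
    """Raised for degenerate geometric input (e.g. collinear contours)."""


class EmptyMaskError(GeometryError):
    """Raised when an operation requires a non-empty mask."""


@dataclass
class Contour:
    """Closed sub-pixel boundary in mm, counter-clockwise.

    ``points`` is an (n, 2) array of (x, y) vertices; the polygon is
    implicitly closed (last vertex connects back to the first).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise GeometryError("contour needs >= 3 (x, y) points")
        # drop a duplicated closing vertex and consecutive duplicates
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        pts = pts[keep]
        if len(pts) < 3:
            raise GeometryError("contour degenerates to fewer than 3 points")
        if _shoelace(pts) < 0:  # normalize winding to CCW
            pts = pts[::-1]
        if _shoelace(pts) <= 0:
            raise GeometryError("contour encloses no area (collinear points)")
        self.points = pts

    @property
    def area(self) -> float:
        """Enclosed area in mm² (shoelace)."""
        return _shoelace(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def as_polygon(self) -> Polygon:
        return Polygon(self.points)


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ExcessRegion:
    """One connected component of disc material outside the vertebral footprint.

    ``max_excess_mm`` is the maximum over the component's pixels of the
    distance to the footprint; ``angular_span_fraction`` the fraction of the
    full circle the component subtends about the disc centroid;
    ``dome_width_mm`` the widest extent, parallel to the local footprint
    tangent, of the outer half of the component (pixels beyond half the
    maximal excess — the "dome" of the displaced material);
    ``base_width_mm`` the length of footprint boundary the component
    touches.
    """

    mask: np.ndarray
    max_excess_mm: float
    angular_span_fraction: float
    dome_width_mm: float
    base_width_mm: float


@dataclass
class TangentConstruction:
    """Posterior-tangent construction for the spondylolisthesis percentage.

    Each tangent is a least-squares line through the posterior boundary
    points of one vertebral body; both are intersected with the
    least-squares line along the superior endplate of the lower body.  The
    listhesis percentage is ``offset_mm / endplate_length_mm * 100``.
    """

    upper_tangent: tuple[np.ndarray, np.ndarray]  # (point, unit direction)
    lower_tangent: tuple[np.ndarray, np.ndarray]
    endplate_line: tuple[np.ndarray, np.ndarray]
    p_upper: np.ndarray
    p_lower: np.ndarray
    offset_mm: float
    endplate_length_mm: float

    @property
    def listhesis_percent(self) -> float:
        return 100.0 * self.offset_mm / self.endplate_length_mm


def extract_contour(mask: np.ndarray, spacing_mm: Sequence[float]) -> Contour:
    """Closed sub-pixel boundary of a binary mask at the 0.5 iso-level.

    The float mask is lightly Gaussian-smoothed before marching squares so
    that the iso-contour of a rasterized smooth shape is free of the
    pixel-staircase bias (which would otherwise inflate perimeters by ~8 %);
    shapes too small to survive smoothing fall back to the raw 0.5
    iso-level.  If the mask has several 8-connected components the largest
    is used and a warning is logged.  Raises :class:`EmptyMaskError` on an
    empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract a contour from an empty mask")
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n > 1:
        log.warning("mask has %d components; keeping the largest", n)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    # pad so that foreground touching the border still yields a closed curve
    padded = np.pad(mask.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:  # thin/small structure erased by smoothing
        contours = measure.find_contours(padded, 0.5)
    rc = max(contours, key=len) - 2.0  # undo padding; (row, col) sub-pixel
    sr, sc = float(spacing_mm[0]), float(spacing_mm[1])
    xy = np.column_stack([rc[:, 1] * sc, rc[:, 0] * sr])
    return Contour(xy)


def _mm_coords(shape: tuple[int, int], spacing: Sequence[float]):
    rows = np.arange(shape[0]) * float(spacing[0])
    cols = np.arange(shape[1]) * float(spacing[1])
    return rows, cols


def project_vertebral_footprint(
    upper_vb: LabelMap, lower_vb: LabelMap, disc_grid: LabelMap, vb_label: int
) -> np.ndarray:
    """Union of the two vertebral-body masks resampled onto the disc grid.

    The adjacent vertebral bodies are "projected over" the disc slice: each
    disc-grid pixel centre is looked up (nearest neighbour, in mm) in both
    vertebral-body slices and marked if it falls inside either body.
    """
    masks = [upper_vb.mask(vb_label), lower_vb.mask(vb_label)]
    if not any(m.any() for m in masks):
        raise EmptyMaskError("no vertebral-body pixels in either adjacent slice")

    out = np.zeros(disc_grid.pixels.shape, dtype=bool)
    rows_mm, cols_mm = _mm_coords(out.shape, disc_grid.spacing_mm)
    for src, mask in ((upper_vb, masks[0]), (lower_vb, masks[1])):
        sr, sc = src.spacing_mm
        ri = np.rint(rows_mm / sr).astype(int)
        ci = np.rint(cols_mm / sc).astype(int)
        ok_r = (ri >= 0) & (ri < mask.shape[0])
        ok_c = (ci >= 0) & (ci < mask.shape[1])
        sub = np.zeros_like(out)
        sub[np.ix_(ok_r, ok_c)] = mask[np.ix_(ri[ok_r], ci[ok_c])]
        out |= sub
    return out


def region_area(mask: np.ndarray, spacing_mm: Sequence[float]) -> float:
    """Area of a binary mask in mm² (pixel count times pixel area)."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * float(spacing_mm[0]) * float(spacing_mm[1])


def _angular_span_fraction(dy: np.ndarray, dx: np.ndarray) -> float:
    """Fraction of the full circle subtended by points at offsets (dy, dx)."""
    angles = np.sort(np.arctan2(dy, dx))
    if len(angles) == 1:
        return 0.0
    gaps = np.diff(angles)
    wrap = 2.0 * np.pi - (angles[-1] - angles[0])
    span = 2.0 * np.pi - max(float(gaps.max(initial=0.0)), wrap)
    return span / (2.0 * np.pi)


def disc_excess(
    disc_mask: np.ndarray,
    footprint: np.ndarray,
    spacing_mm: Sequence[float],
    ap_axis_only: bool = False,
) -> list[ExcessRegion]:
    """Connected regions of disc material posterior to the centroid and
    outside the vertebral footprint, with their herniation measurements.

    ``max_excess_mm`` is measured perpendicular to the footprint boundary
    (the distance from each excess pixel to the nearest footprint pixel);
    with ``ap_axis_only`` it is instead the pure anterior-posterior (row
    axis) distance to the footprint.  An empty result means the disc lies
    fully inside the footprint.
    """
    disc_mask = np.asarray(disc_mask, dtype=bool)
    footprint = np.asarray(footprint, dtype=bool)
    if disc_mask.shape != footprint.shape:
        raise GeometryError("disc mask and footprint must share one grid")
    if not disc_mask.any():
        raise EmptyMaskError("empty disc mask")
    sr, sc = float(spacing_mm[0]), float(spacing_mm[1])

    excess = disc_mask & ~footprint
    if not excess.any():
        return []

    rr, cc = np.nonzero(disc_mask)
    centroid_row_mm = rr.mean() * sr
    centroid_col_mm = cc.mean() * sc

    if footprint.any():
        dist_mm = ndimage.distance_transform_edt(~footprint, sampling=(sr, sc))
    else:
        dist_mm = np.full(excess.shape, np.inf)

    fp_boundary = footprint & ~ndimage.binary_erosion(footprint, structure=_STRUCT8)
    fp_contour = extract_contour(footprint, (sr, sc)) if footprint.any() else None

    labels, n = ndimage.label(excess, structure=_STRUCT8)
    regions: list[ExcessRegion] = []
    for k in range(1, n + 1):
        comp = labels == k
        crr, ccc = np.nonzero(comp)
        dy = crr * sr - centroid_row_mm
        dx = ccc * sc - centroid_col_mm
        if dy.mean() <= 0:  # anterior to the disc centroid: not canal-side
            continue
        if ap_axis_only:
            # row-axis distance from each excess pixel to the footprint
            max_excess = 0.0
            for col in np.unique(ccc):
                fp_rows = np.nonzero(footprint[:, col])[0]
                ex_rows = crr[ccc == col]
                if len(fp_rows):
                    d = (ex_rows.max() - fp_rows.max()) * sr
                else:
                    d = np.inf
                max_excess = max(max_excess, float(d))
        else:
            max_excess = float(dist_mm[comp].max())

        fraction = _angular_span_fraction(dy, dx)

        # contact arc: footprint boundary pixels 8-adjacent to the component
        touch = ndimage.binary_dilation(comp, structure=_STRUCT8) & fp_boundary
        trr, tcc = np.nonzero(touch)
        if len(trr):
            contact_centroid = np.array([trr.mean() * sr, tcc.mean() * sc])
            comp_centroid = np.array([crr.mean() * sr, ccc.mean() * sc])
            normal = comp_centroid - contact_centroid
            nn = np.linalg.norm(normal)
            normal = normal / nn if nn > 0 else np.array([1.0, 0.0])
            tangent = np.array([-normal[1], normal[0]])
            # dome = widest chord of the displaced material away from the
            # base (outer half by excess distance), measured along the
            # local footprint tangent
            outer = dist_mm[comp] >= 0.5 * max_excess
            orr, occ = crr[outer], ccc[outer]
            proj = orr * sr * tangent[0] + occ * sc * tangent[1]
            dome_width = float(proj.max() - proj.min())
            # base = arc length of the sub-pixel footprint contour where the
            # component touches it (contour vertices within ~1 pixel of a
            # component pixel centre)
            base_width = _contact_arc_length(fp_contour, crr, ccc, sr, sc)
        else:  # free fragment with no footprint contact
            proj = ccc * sc
            dome_width = float(proj.max() - proj.min())
            base_width = 0.0

        regions.append(
            ExcessRegion(
                mask=comp,
                max_excess_mm=max_excess,
                angular_span_fraction=fraction,
                dome_width_mm=dome_width,
                base_width_mm=base_width,
            )
        )
    regions.sort(key=lambda r: r.max_excess_mm, reverse=True)
    return regions


def _contact_arc_length(
    fp_contour: "Contour", crr: np.ndarray, ccc: np.ndarray, sr: float, sc: float
) -> float:
    """Length of the footprint-contour arc adjacent to the component pixels."""
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([ccc * sc, crr * sr]))
    dists, _ = tree.query(fp_contour.points)
    near = dists <= 1.2 * max(sr, sc)
    if not near.any():
        return 0.0
    closed = np.append(near, near[0])
    pts = np.vstack([fp_contour.points, fp_contour.points[:1]])
    seg_near = closed[:-1] & closed[1:]
    seg_len = np.hypot(*np.diff(pts, axis=0).T)
    return float(seg_len[seg_near].sum())


def _principal_frame(pts: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Centroid and principal axes of a point set in the sagittal frame.

    The major axis is oriented posteriorly (positive x component), the
    minor axis inferiorly (positive y component).
    """
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    major = vt[0] if vt[0][0] >= 0 else -vt[0]
    minor = np.array([-major[1], major[0]])
    if minor[1] < 0:
        minor = -minor
    return centroid, (major, minor)


def _edge_band(
    pts: np.ndarray,
    along: np.ndarray,
    across: np.ndarray,
    fraction: float,
    side: str,
    central: float = 0.7,
) -> np.ndarray:
    """Boundary points of one edge of a body, corners trimmed.

    Selects the ``fraction`` of the contour's extent along ``along`` at the
    requested extreme, keeping only the central ``central`` share of the
    extent along ``across`` so that high-leverage corner points do not tilt
    the fitted line.
    """
    centred = pts - pts.mean(axis=0)
    t = centred @ along
    s = centred @ across
    extent = t.max() - t.min()
    if extent <= 0:
        raise GeometryError("contour has no extent along the requested axis")
    if side == "max":
        band = t >= t.max() - fraction * extent
    else:
        band = t <= t.min() + fraction * extent
    s_mid = 0.5 * (s.max() + s.min())
    trimmed = band & (np.abs(s - s_mid) <= 0.5 * central * (s.max() - s.min()))
    if trimmed.sum() >= 2:
        band = trimmed
    return pts[band]


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points -> (centroid, unit direction)."""
    if len(points) < 2:
        raise GeometryError("need at least two points to fit a line")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise GeometryError("degenerate (zero-extent) point set")
    return centroid, vt[0]


def _intersect(line_a, line_b) -> np.ndarray:
    (pa, da), (pb, db) = line_a, line_b
    mat = np.column_stack([da, -db])
    det = np.linalg.det(mat)
    if abs(det) < 1e-12:
        raise GeometryError("parallel lines do not intersect")
    t = np.linalg.solve(mat, pb - pa)
    return pa + t[0] * da


def posterior_tangent_construction(
    upper_vb_contour: Contour,
    lower_vb_contour: Contour,
    posterior_fraction: float = 0.20,
    endplate_fraction: float = 0.15,
) -> TangentConstruction:
    """Spondylolisthesis construction from two sagittal vertebral contours.

    A tangent is fitted through the posterior ``posterior_fraction`` (by
    anterior-posterior extent) of each body's boundary points, the
    superior-endplate line through the superior ``endplate_fraction`` (by
    cranio-caudal extent) of the lower body's boundary points.  The offset
    between the tangent/endplate intersection points, compared with the
    endplate length, yields the slip percentage.  Sagittal frame: x grows
    posteriorly, y grows inferiorly.
    """
    # bands are selected in each body's own principal-axis frame (major
    # axis ~ anterior-posterior for a vertebral body), which makes the
    # construction invariant under joint rigid rotation
    lines = []
    for contour in (upper_vb_contour, lower_vb_contour):
        pts = contour.points
        _, (ap_axis, cc_axis) = _principal_frame(pts)
        band = _edge_band(pts, ap_axis, cc_axis, posterior_fraction, "max")
        lines.append(_fit_line(band))
    upper_tangent, lower_tangent = lines

    pts = lower_vb_contour.points
    _, (ap_axis, cc_axis) = _principal_frame(pts)
    band = _edge_band(pts, cc_axis, ap_axis, endplate_fraction, "min")
    endplate_line = _fit_line(band)
    # endplate length from the full (untrimmed) superior band
    s = (pts - pts.mean(axis=0)) @ cc_axis
    full_band = pts[s <= s.min() + endplate_fraction * (s.max() - s.min())]
    t = (full_band - endplate_line[0]) @ endplate_line[1]
    endplate_length = float(t.max() - t.min())
    if endplate_length <= 0:
        raise GeometryError("degenerate superior endplate")

    p_upper = _intersect(upper_tangent, endplate_line)
    p_lower = _intersect(lower_tangent, endplate_line)
    return TangentConstruction(
        upper_tangent=upper_tangent,
        lower_tangent=lower_tangent,
        endplate_line=endplate_line,
        p_upper=p_upper,
        p_lower=p_lower,
        offset_mm=float(np.linalg.norm(p_upper - p_lower)),
        endplate_length_mm=endplate_length,
    )


def expected_root_position(
    root_above: Sequence[float] | None,
    root_below: Sequence[float] | None,
    slice_fraction: float,
) -> np.ndarray:
    """Expected nerve-root position at a disc-level slice.

    Linear interpolation at ``slice_fraction`` between the root centroids on
    the neighbouring slices; if one neighbour is missing the available one
    is used as-is (logged).
    """
    if root_above is None and root_below is None:
        raise GeometryError("no neighbouring root position available")
    if root_above is None or root_below is None:
        log.warning("root position missing on one neighbouring slice; copying")
        avail = root_above if root_above is not None else root_below
        return np.asarray(avail, dtype=float)
    a = np.asarray(root_above, dtype=float)
    b = np.asarray(root_below, dtype=float)
    return a + float(slice_fraction) * (b - a)


def contact(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """True iff the two masks touch (8-connectivity) or overlap."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise GeometryError("contact masks must share one grid")
    if not mask_a.any() or not mask_b.any():
        return False
    return bool((ndimage.binary_dilation(mask_a, structure=_STRUCT8) & mask_b).any())
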
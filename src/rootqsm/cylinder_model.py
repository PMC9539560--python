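"""Least-squares circular-cylinder fitting and QSM assembly.

Each segment from the region growing is approximated by a sequence of
circular cylinders — the most robust primitive for noisy tubular
surfaces.  A cylinder is fitted by minimizing Σ (d(pᵢ, axis) − r)² with
a Gauss–Newton scheme over a four-parameter axis perturbation (two
in-plane offsets, two tilt angles about the initial axis) with the
radius eliminated analytically (r = mean axial distance).  Gaps between
consecutive cylinders are filled with interpolating cylinders so the
model is a single connected tree.

The minimum cylinder length is a fixed constant in *scaled* units
(3 × patch diameter): this is exactly where the user's scale factor
exerts its effect — a larger SF makes the same physical root span more
scaled units, hence shorter cylinders in physical terms and a finer fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry_io import PointCloud
from .segmentation import (
    Segment,
    build_cover,
    default_patch_diameter,
    find_base,
    segment_root,
)

log = logging.getLogger(__name__)

MIN_CYL_LENGTH_PATCHES = 3.0   # min cylinder length, in units of patch_diameter
CONNECT_TOL_PATCHES = 1.0      # parent-child connection tolerance, same units


class CylinderFitError(RuntimeError):
    """Raised when a cylinder cannot be fitted (too few / degenerate points)."""


class EmptyModelError(RuntimeError):
    """Raised when no structured root is found in the cloud."""


@dataclass(eq=False)
class Cylinder:
    start: np.ndarray          # (3,) base end of the axis segment
    axis: np.ndarray           # (3,) unit vector pointing away from the root base
    length: float
    radius: float
    parent: int | None = None  # index into QSM.cylinders
    segment_id: int = 0
    order: int = 0
    gap_fill: bool = False
    fallback: bool = False     # set when the robust fit failed and endpoints were used

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            self.axis = self.axis / n
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("cylinder length and radius must be positive")

    @property
    def end(self) -> np.ndarray:
        return self.start + self.axis * self.length

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius**2 * self.length)

    @property
    def lateral_area(self) -> float:
        return float(2.0 * np.pi * self.radius * self.length)


@dataclass(eq=False)
class QSM:
    """Quantitative structure model: a tree of cylinders plus provenance."""

    cylinders: list
    sf: float
    seed: int
    base_point: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def total_volume(self) -> float:
        return sum(c.volume for c in self.cylinders)

    @property
    def total_length(self) -> float:
        return sum(c.length for c in self.cylinders)

    @property
    def max_order(self) -> int:
        return max((c.order for c in self.cylinders), default=0)

    def to_csv(self, path) -> None:
        rows = []
        for c in self.cylinders:
            rows.append({
                "start_x": c.start[0], "start_y": c.start[1], "start_z": c.start[2],
                "axis_x": c.axis[0], "axis_y": c.axis[1], "axis_z": c.axis[2],
                "length": c.length, "radius": c.radius,
                "parent": -1 if c.parent is None else c.parent,
                "segment": c.segment_id, "order": c.order,
                "gap_fill": int(c.gap_fill),
            })
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sf: float = 1.0, seed: int = 0) -> "QSM":
        df = pd.read_csv(path)
        cyls = []
        for _, r in df.iterrows():
            cyls.append(Cylinder(
                start=np.array([r.start_x, r.start_y, r.start_z]),
                axis=np.array([r.axis_x, r.axis_y, r.axis_z]),
                length=float(r.length), radius=float(r.radius),
                parent=None if int(r.parent) < 0 else int(r.parent),
                segment_id=int(r.segment), order=int(r.order),
                gap_fill=bool(r.gap_fill),
            ))
        base = cyls[0].start if cyls else np.zeros(3)
        return cls(cyls, sf=sf, seed=seed, base_point=base)


def _orthonormal_frame(axis: np.ndarray):
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return a, u, v


def _fit_cylinder_once(pts: np.ndarray, initial_axis: np.ndarray,
                       max_iter: int, tol: float):
    centroid = pts.mean(0)
    centered = pts - centroid
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-30):
        raise CylinderFitError("points are collinear; cylinder fit is rank-deficient")

    a0, u0, v0 = _orthonormal_frame(np.asarray(initial_axis, dtype=float))

    def unpack(x):
        px, py, alpha, beta = x
        axis = a0 + alpha * u0 + beta * v0
        axis = axis / np.linalg.norm(axis)
        point = centroid + px * u0 + py * v0
        return point, axis

    def residuals(x):
        point, axis = unpack(x)
        d = centered + centroid - point
        proj = d @ axis
        radial = d - np.outer(proj, axis)
        dist = np.linalg.norm(radial, axis=1)
        return dist - dist.mean()

    # bounds prevent the far-axis/large-radius degeneracy a thin arc invites
    spread = float(np.linalg.norm(centered, axis=1).max())
    bounds = ([-spread, -spread, -1.0, -1.0], [spread, spread, 1.0, 1.0])
    sol = least_squares(residuals, np.zeros(4), method="trf", bounds=bounds,
                        max_nfev=max_iter * 10, xtol=tol, ftol=tol, gtol=tol)
    point, axis = unpack(sol.x)
    if axis @ a0 < 0:
        axis = -axis
    d = pts - point
    proj = d @ axis
    dist = np.linalg.norm(d - np.outer(proj, axis), axis=1)
    if np.linalg.norm(point - centroid) > spread or dist.mean() > spread:
        raise CylinderFitError("fit diverged from the point set")
    return point, axis, proj, dist


def fit_cylinder(points: np.ndarray, initial_axis: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-8, robust: bool = False):
    """Fit a circular cylinder to ``points``.

    Returns ``(start, axis, length, radius, rms_residual)``.  The axis
    is oriented along ``initial_axis``; ``start`` is the
    projection-minimal end.  With ``robust=True`` a second pass refits
    after trimming radial outliers (|d − median| > 2.5 NMAD), which
    suppresses contamination from branch junctions.  Raises
    :class:`CylinderFitError` for fewer than 6 points or a
    rank-deficient (collinear) configuration.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 6:
        raise CylinderFitError(f"need >= 6 points, got {len(pts)}")
    point, axis, proj, dist = _fit_cylinder_once(pts, initial_axis, max_iter, tol)
    if robust:
        inliers = pts
        for _ in range(3):  # junction contamination can be bimodal
            med = np.median(dist)
            nmad = 1.4826 * np.median(np.abs(dist - med))
            keep = np.abs(dist - med) <= 2.5 * nmad + 1e-12
            if keep.sum() < 6 or keep.all():
                break
            try:
                refit = _fit_cylinder_once(inliers[keep], initial_axis,
                                           max_iter, tol)
            except CylinderFitError:
                break  # keep the last good fit
            inliers = inliers[keep]
            point, axis, proj, dist = refit
    # median rather than mean: insensitive to residual junction points
    radius = float(np.median(dist))
    if radius <= 0:
        raise CylinderFitError("degenerate fit: non-positive radius")
    tmin, tmax = proj.min(), proj.max()
    length = float(tmax - tmin)
    if length <= 0:
        raise CylinderFitError("degenerate fit: zero length")
    start = point + tmin * axis
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return start, axis, length, radius, rms


def _point_line_dist(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    n = np.linalg.norm(d)
    if n == 0:
        return np.linalg.norm(pts - p0, axis=1)
    d = d / n
    rel = pts - p0
    return np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)


def model_segment(segment: Segment, cover: list, cloud: PointCloud,
                  min_cylinder_length: float) -> list[Cylinder]:
    """Fit a chain of cylinders to one segment.

    Layers are grouped into runs whose centroid span reaches
    ``min_cylinder_length``; one cylinder per run, initial axis from the
    run's centroid direction.  A failed fit merges its run into the
    successor.  A segment too short for any run yields one fallback
    cylinder between its endpoints with radius = median point-to-chord
    distance.
    """
    if not segment.layers:
        raise ValueError("segment has no layers")
    layer_pts = []
    layer_centroids = []
    for layer in segment.layers:
        idx = np.concatenate([cover[cid].member_indices for cid in layer])
        pts = cloud.points[idx]
        layer_pts.append(pts)
        layer_centroids.append(pts.mean(0))
    centroids = np.asarray(layer_centroids)

    # group layers into disjoint runs spanning at least min_cylinder_length
    runs: list[list[int]] = []
    cur = [0]
    for i in range(1, len(centroids)):
        cur.append(i)
        if np.linalg.norm(centroids[i] - centroids[cur[0]]) >= min_cylinder_length:
            runs.append(cur)
            cur = []
    if cur:
        if runs and (len(cur) < 2 or np.linalg.norm(
                centroids[cur[-1]] - centroids[cur[0]]) < 0.5 * min_cylinder_length):
            runs[-1] = runs[-1] + cur  # tail too short for its own cylinder
        else:
            runs.append(cur)

    all_pts = np.vstack(layer_pts)
    chord_r = float(np.median(_point_line_dist(all_pts, centroids[0], centroids[-1])))

    def fallback_cylinder(p0, p1, pts):
        d = p1 - p0
        n = np.linalg.norm(d)
        if n == 0:
            n = max(chord_r, 1e-9)
            d = np.array([0.0, 0.0, -1.0]) * n
        r = float(np.median(_point_line_dist(pts, p0, p1)))
        r = max(r, 1e-9)
        return Cylinder(start=p0, axis=d / n, length=float(n), radius=r,
                        segment_id=segment.id, order=segment.order, fallback=True)

    if len(centroids) < 2 or np.linalg.norm(centroids[-1] - centroids[0]) \
            < min_cylinder_length:
        return [fallback_cylinder(centroids[0], centroids[-1]
                                  if len(centroids) > 1 else centroids[0],
                                  all_pts)]

    cylinders: list[Cylinder] = []
    pending: list[int] = []  # layer indices carried over after a failed fit
    for k, run in enumerate(runs):
        layers_here = sorted(set(pending + run))
        pending = []
        pts = np.vstack([layer_pts[i] for i in layers_here])
        p0, p1 = centroids[layers_here[0]], centroids[layers_here[-1]]
        direction = p1 - p0
        if np.linalg.norm(direction) == 0:
            direction = np.array([0.0, 0.0, -1.0])
        # pre-filter against the centroid chord: points belonging to an
        # attached branch sit far off the tube surface and would drag
        # the axis fit before its own trimming can engage
        d_chord = _point_line_dist(pts, p0, p1)
        med = np.median(d_chord)
        nmad = 1.4826 * np.median(np.abs(d_chord - med))
        pre = np.abs(d_chord - med) <= 2.5 * nmad + 1e-12
        if pre.sum() >= 6:
            pts = pts[pre]
        try:
            start, axis, length, radius, _ = fit_cylinder(pts, direction,
                                                          robust=True)
            run_r = float(np.median(_point_line_dist(pts, p0, p1)))
            radius = float(np.clip(radius, 0.5 * run_r, 2.0 * run_r)) \
                if run_r > 0 else radius
            cylinders.append(Cylinder(start=start, axis=axis, length=length,
                                      radius=radius, segment_id=segment.id,
                                      order=segment.order))
        except CylinderFitError:
            if k < len(runs) - 1:
                pending = layers_here  # merge with successor run
            else:
                cylinders.append(fallback_cylinder(p0, p1, pts))

    if not cylinders:
        cylinders = [fallback_cylinder(centroids[0], centroids[-1], all_pts)]

    for i in range(1, len(cylinders)):
        cylinders[i].parent = i  # provisional, re-indexed during assembly
    return cylinders


def fill_gaps(qsm: QSM, tolerance: float) -> QSM:
    """Insert interpolating cylinders where parent→child gaps exceed ``tolerance``.

    Within a segment the gap is measured end-to-start; across segments
    (a branch attachment) the child start only needs to lie within
    ``tolerance`` of the parent cylinder's *surface*.  The inserted
    cylinder carries the mean of the flanking radii and a ``gap_fill``
    flag.
    """
    cyls = list(qsm.cylinders)
    n_filled = 0
    for i, c in enumerate(cyls):
        if c.parent is None or c.gap_fill:
            continue
        par = cyls[c.parent]
        if par.segment_id == c.segment_id:
            anchor = par.end
            gap = float(np.linalg.norm(c.start - anchor))
            # a child starting "behind" the parent end interpenetrates it;
            # bridging that would double-count material
            overlap = (c.start - par.end) @ par.axis < 0
            needs_fill = gap > tolerance and not overlap
        else:
            # branch attachment: bridge only the void beyond the parent
            # cylinder's surface
            t = float(np.clip((c.start - par.start) @ par.axis, 0.0, par.length))
            axis_pt = par.start + t * par.axis
            radial = c.start - axis_pt
            rn = float(np.linalg.norm(radial))
            surf_dist = rn - par.radius
            if rn > 1e-12 and surf_dist > 0:
                anchor = axis_pt + radial * (par.radius / rn)
            else:
                anchor = axis_pt
            gap = max(surf_dist, 0.0)
            needs_fill = surf_dist > tolerance
        if needs_fill and gap > 1e-12:
            gap_vec = c.start - anchor
            g = Cylinder(start=anchor.copy(), axis=gap_vec / gap, length=gap,
                         radius=0.5 * (par.radius + c.radius), parent=c.parent,
                         segment_id=c.segment_id, order=c.order, gap_fill=True)
            cyls.append(g)
            c.parent = len(cyls) - 1
            n_filled += 1
    if n_filled:
        log.info("gap filling inserted %d cylinders", n_filled)
    out = QSM(cyls, sf=qsm.sf, seed=qsm.seed, base_point=qsm.base_point,
              provenance=dict(qsm.provenance))
    out.provenance["n_gap_filled"] = n_filled
    return out


def assemble_qsm(segments: list[Segment], cover: list, cloud: PointCloud,
                 sf: float, seed: int, patch_diameter: float) -> QSM:
    """Model every segment and link child chains to their parent cylinders."""
    min_len = MIN_CYL_LENGTH_PATCHES * patch_diameter
    all_cyls: list[Cylinder] = []
    seg_slices: dict[int, tuple[int, int]] = {}
    for seg in segments:
        chain = model_segment(seg, cover, cloud, min_len)
        lo = len(all_cyls)
        for j, c in enumerate(chain):
            c.parent = lo + j - 1 if j > 0 else None
            all_cyls.append(c)
        seg_slices[seg.id] = (lo, len(all_cyls))

    # attach each child segment's first cylinder to the nearest parent cylinder
    for seg in segments:
        if seg.parent_segment is None:
            continue
        lo, _ = seg_slices[seg.id]
        child0 = all_cyls[lo]
        plo, phi = seg_slices[seg.parent_segment]
        best, best_d = None, np.inf
        for idx in range(plo, phi):
            pc = all_cyls[idx]
            t = float(np.clip((child0.start - pc.start) @ pc.axis, 0.0, pc.length))
            d = np.linalg.norm(child0.start - (pc.start + t * pc.axis))
            if d < best_d:
                best, best_d = idx, d
        child0.parent = best

    # trim axial overlap between consecutive cylinders of a segment so
    # material is not double-counted where fitted extents overshoot
    for c in all_cyls:
        if c.parent is None:
            continue
        par = all_cyls[c.parent]
        if par.segment_id != c.segment_id:
            continue
        t0 = float((par.end - c.start) @ c.axis)
        if 0.0 < t0 < c.length:
            c.start = c.start + t0 * c.axis
            c.length -= t0

    if not all_cyls:
        raise EmptyModelError("no cylinders could be fitted")
    roots = [c for c in all_cyls if c.parent is None]
    assert len(roots) == 1, "QSM must be a single tree"

    base_seg = next(s for s in segments if s.parent_segment is None)
    base_cover = base_seg.layers[0][0]
    base_point = cover[base_cover].center
    qsm = QSM(all_cyls, sf=sf, seed=seed, base_point=np.asarray(base_point),
              provenance={"patch_diameter": patch_diameter,
                          "min_cylinder_length": min_len,
                          "n_segments": len(segments)})
    return qsm


def reconstruct(cloud: PointCloud, patch_diameter: float | None = None,
                seed: int = 0, min_component_size: int = 2) -> QSM:
    """Full pipeline: cover → base → segments → cylinders → gap filling.

    The default patch diameter is a fixed constant in scaled units
    (see :data:`~rootqsm.segmentation.PATCH_DIAMETER_SCALED`), which is
    how the scale factor controls model resolution.
    """
    if patch_diameter is None:
        patch_diameter = default_patch_diameter(cloud)
    cover = build_cover(cloud, patch_diameter, seed=seed)
    base = find_base(cover)
    segments = segment_root(cover, base, min_component_size=min_component_size)
    n_structured = sum(len(layer) for s in segments for layer in s.layers)
    if n_structured < 3:
        raise EmptyModelError(
            "cloud has no connected structure above the minimum size")
    qsm = assemble_qsm(segments, cover, cloud, sf=cloud.scale_factor,
                       seed=seed, patch_diameter=patch_diameter)
    qsm = fill_gaps(qsm, tolerance=CONNECT_TOL_PATCHES * patch_diameter)
    qsm.provenance["seed"] = seed
    return qsm
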
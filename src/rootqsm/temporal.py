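"""Registration and growth analysis of temporal scan series.

Weekly scans of the same pot are aligned in two stages: a coarse
closed-form rigid fit from hand-picked point correspondences
(orthogonal Procrustes with a reflection guard), then trimmed
iterative-closest-point refinement that keeps only the best
``overlap_fraction`` of closest-point pairs each iteration — the
younger scan only overlaps part of the grown root, so typical overlaps
are 35–40%.  A rotation-only mode constrains the solution to a rotation
about the matched centroid, the natural constraint when the pot never
leaves its holder.  Growth is quantified as the difference of spread
matrices (10 depth layers × 18 directions) between registered weeks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import PointCloud
from .cylinder_model import QSM, Cylinder
from .traits import SpreadMatrix, spread


@dataclass
class RigidTransform:
    """y = R (x − center) + center + t;  rotation-only mode keeps t = 0."""

    rotation: np.ndarray
    translation: np.ndarray
    rotation_only: bool = False
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.rotation_only and not np.allclose(self.translation, 0.0):
            raise ValueError("rotation-only transform must have zero translation")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (points - self.center) @ self.rotation.T + self.center \
            + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        off_other = other.center - other.rotation @ other.center + other.translation
        off_self = self.center - self.rotation @ self.center + self.translation
        t = self.rotation @ off_other + off_self
        return RigidTransform(R, t)

    @property
    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_json(self, path, rms: float | None = None,
                iterations: int | None = None) -> None:
        obj = {"rotation": self.rotation.tolist(),
               "translation": self.translation.tolist(),
               "center": self.center.tolist(),
               "rotation_only": self.rotation_only}
        if rms is not None:
            obj["rms"] = rms
        if iterations is not None:
            obj["iterations"] = iterations
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array(obj["rotation"]), np.array(obj["translation"]),
                   obj.get("rotation_only", False),
                   np.array(obj.get("center", [0, 0, 0])))


def _kabsch(src: np.ndarray, dst: np.ndarray):
    """Rotation (with reflection guard) aligning centered src to dst."""
    H = src.T @ dst
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def coarse_align(pairs) -> RigidTransform:
    """Closed-form rigid transform from ≥ 3 non-collinear point pairs.

    ``pairs`` is a sequence of (source_xyz, target_xyz).
    """
    pairs = [(np.asarray(a, float), np.asarray(b, float)) for a, b in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 point pairs")
    src = np.array([a for a, _ in pairs])
    dst = np.array([b for _, b in pairs])
    sc, dc = src.mean(0), dst.mean(0)
    s = np.linalg.svd(src - sc, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("point pairs are collinear")
    R = _kabsch(src - sc, dst - dc)
    t = dc - R @ sc
    return RigidTransform(R, t)


def remove_statistical_outliers(cloud: PointCloud, k: int = 8,
                                n_sigma: float = 2.5) -> PointCloud:
    """Drop points whose mean k-nearest-neighbor distance exceeds the
    cloud mean by ``n_sigma`` standard deviations."""
    pts = cloud.points
    if len(pts) <= k + 1:
        return cloud
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k + 1)
    mean_d = d[:, 1:].mean(1)
    keep = mean_d <= mean_d.mean() + n_sigma * mean_d.std()
    if keep.sum() < 4:
        return cloud
    return PointCloud(pts[keep], scale_factor=cloud.scale_factor,
                      source_unit=cloud.source_unit)


def icp(source: PointCloud, target: PointCloud, overlap_fraction: float = 0.4,
        rotation_only: bool = False, max_iter: int = 60, tol: float = 1e-8,
        initial: RigidTransform | None = None):
    """Trimmed ICP registering ``source`` onto ``target``.

    Each iteration matches every source point to its closest target
    point, keeps the best ``overlap_fraction`` of pairs, and solves the
    rigid (or rotation-about-centroid) Procrustes problem on the kept
    pairs; stops when the kept-pair rms improves by less than ``tol``.

    Returns ``(transform, rms, converged)``; non-convergence returns the
    best transform found with ``converged`` False and a warning.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    src_c = remove_statistical_outliers(source)
    dst_c = remove_statistical_outliers(target)
    if len(src_c) < 100 or len(dst_c) < 100:
        raise ValueError("need >= 100 points per cloud after outlier removal")
    src = src_c.points
    dst = dst_c.points
    tree = cKDTree(dst)
    center = src.mean(0)
    current = initial if initial is not None else RigidTransform.identity()
    moved = current.apply(src)
    n_keep = max(int(np.ceil(overlap_fraction * len(src))), 3)
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d, j = tree.query(moved)
        keep = np.argsort(d)[:n_keep]
        s_k = moved[keep]
        t_k = dst[j[keep]]
        sc = s_k.mean(0)
        if rotation_only:
            R = _kabsch(s_k - sc, t_k - sc)
            step = RigidTransform(R, np.zeros(3), rotation_only=True, center=sc)
        else:
            tc = t_k.mean(0)
            R = _kabsch(s_k - sc, t_k - tc)
            step = RigidTransform(R, tc - R @ sc)
        current = step.compose(current)
        if rotation_only:
            # keep the composed transform in rotation-only form about the
            # original source centroid
            R = current.rotation
            current = RigidTransform(R, np.zeros(3), rotation_only=True,
                                     center=_solve_center(R, current))
        moved = current.apply(src)
        d, j = tree.query(moved)
        keep = np.argsort(d)[:n_keep]
        rms = float(np.sqrt((d[keep] ** 2).mean()))
        if prev_rms - rms < tol:
            converged = True
            prev_rms = rms
            break
        prev_rms = rms
    if not converged:
        warnings.warn(f"ICP did not converge in {max_iter} iterations "
                      f"(rms {prev_rms:.4g})", stacklevel=2)
    diag = float(np.linalg.norm(dst.max(0) - dst.min(0)))
    if prev_rms > 0.25 * diag:
        converged = False
        warnings.warn(
            f"registration failed: residual rms {prev_rms:.4g} is large "
            "compared to the target extent (clouds may not overlap)",
            stacklevel=2)
    return current, prev_rms, converged


def _solve_center(R: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Center c with (I−R)c = offset of ``transform``; least-squares when
    I−R is singular (rotation axis direction is unconstrained)."""
    off = transform.center - transform.rotation @ transform.center \
        + transform.translation
    c, *_ = np.linalg.lstsq(np.eye(3) - R, off, rcond=None)
    return c


def transform_qsm(qsm: QSM, transform: RigidTransform) -> QSM:
    """Apply a rigid transform (in physical units) to every cylinder."""
    # transform is expressed in physical units; QSM geometry is scaled
    sf = qsm.sf
    cyls = []
    for c in qsm.cylinders:
        start_p = c.start / sf
        new_start = transform.apply(start_p[None, :])[0] * sf
        new_axis = transform.rotation @ c.axis
        cyls.append(Cylinder(new_start, new_axis, c.length, c.radius,
                             c.parent, c.segment_id, c.order, c.gap_fill,
                             c.fallback))
    base = transform.apply((np.asarray(qsm.base_point) / sf)[None, :])[0] * sf
    return QSM(cyls, sf=sf, seed=qsm.seed, base_point=base,
               provenance=dict(qsm.provenance))


def growth_spread(qsm_t1: QSM, qsm_t2: QSM,
                  transform: RigidTransform | None = None) -> SpreadMatrix:
    """Spread-matrix growth between two registered time points.

    Returns spread(t2) − spread(t1 mapped into the t2 frame).  Negative
    deltas are reported as-is with a warning: apparent shrinkage
    indicates registration or fitting error, not biology.
    """
    if transform is None:
        transform = RigidTransform.identity()
    # both scans binned on the later scan's base and depth grid so the
    # cells compare the same physical region
    s2 = spread(qsm_t2)
    base2 = np.asarray(qsm_t2.base_point, float) / qsm_t2.sf
    pts2 = np.array([p for c in qsm_t2.cylinders for p in (c.start, c.end)])
    dmax2 = float(base2[2] - pts2[:, 2].min() / qsm_t2.sf)
    s1 = spread(transform_qsm(qsm_t1, transform), base=base2, max_depth=dmax2)
    delta = s2.values - s1.values
    occupied = (s1.values > 0) | (s2.values > 0)
    if np.any(delta[occupied] < -1e-9):
        warnings.warn("negative growth deltas present (registration or "
                      "fitting error)", stacklevel=2)
    return SpreadMatrix(delta, s2.depth_edges, s2.direction_edges)
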
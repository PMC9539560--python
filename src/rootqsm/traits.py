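"""The six-sheet trait catalogue extracted from a QSM.

All geometry inside a QSM lives in scaled units (input units × SF).
Physical traits are recovered with the unit rules: lengths and depths
divide by SF, areas by SF², volumes by SF³.  Input meshes are assumed
to be in centimetres (the convention of the CT scans this pipeline
targets), so traits come out in cm / cm² / cm³; diameter distribution
classes are 0.1 mm = 0.01 cm wide.

Sheets:
  I   TotalTraits    — whole-root totals, root-ball envelope, base, ratios
  II  OrderTraits    — volume/area/length/count per ramification order
  III TaprootTaper   — main-root diameter vs. arc distance from the base
  IV  Spread         — horizontal reach, 10 depth layers × 18 azimuth sectors
  V   CylinderDist   — main-root distributions (diameter/depth/zenith/azimuth)
  VI  LateralDist    — the same four distributions for lateral roots + counts
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .cylinder_model import QSM, Cylinder  # Cylinder re-used by callers

DIAMETER_CLASS_CM = 0.01   # 0.1 mm classes
DEPTH_CLASS_CM = 1.0
ANGLE_CLASS_DEG = 10.0
N_DEPTH_LAYERS = 10
N_DIRECTIONS = 18


@dataclass
class TotalTraits:
    volume: float               # cm^3
    rooting_depth: float        # cm
    length: float               # cm
    area: float                 # cm^2, lateral cylinder surface
    n_ramifications: int
    max_order: int
    ball_diam_avg: float        # cm
    ball_diam_max: float        # cm
    ball_area_convexhull: float   # cm^2, planar projection
    ball_area_alphashape: float   # cm^2
    ball_volume_convexhull: float  # cm^3
    ball_volume_alphashape: float  # cm^3
    base_xyz: tuple             # cm
    pct_volume_area: float      # 100 * volume / area
    pct_volume_length: float    # 100 * volume / length
    pct_area_length: float      # 100 * area / length

    def as_dict(self) -> dict:
        d = asdict(self)
        x, y, z = d.pop("base_xyz")
        d.update(base_x=x, base_y=y, base_z=z)
        return d


@dataclass
class SpreadMatrix:
    values: np.ndarray          # (10, 18) radial extents, cm
    depth_edges: np.ndarray     # (11,)
    direction_edges: np.ndarray  # (19,) degrees

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        assert self.values.shape == (N_DEPTH_LAYERS, N_DIRECTIONS)


@dataclass
class DistributionTable:
    classifier: str
    class_edges: np.ndarray
    volume: np.ndarray
    area: np.ndarray
    length: np.ndarray
    count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_low": self.class_edges[:-1],
            "class_high": self.class_edges[1:],
            "volume": self.volume,
            "area": self.area,
            "length": self.length,
            "count": self.count,
        })


@dataclass
class TaperFunction:
    distance_along_taproot: np.ndarray  # cm, strictly increasing from 0
    diameter: np.ndarray                # cm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distance_along_taproot,
                             "diameter": self.diameter})


# ---------------------------------------------------------------------------
# helpers

def _endpoints_physical(qsm: QSM) -> np.ndarray:
    """Both endpoints of every cylinder, in physical units."""
    pts = []
    for c in qsm.cylinders:
        pts.append(c.start)
        pts.append(c.end)
    return np.asarray(pts) / qsm.sf


def _base_physical(qsm: QSM) -> np.ndarray:
    return np.asarray(qsm.base_point, dtype=float) / qsm.sf


def alpha_shape_area_2d(points_xy: np.ndarray, alpha_radius: float) -> float:
    """Area of the 2D alpha shape: Delaunay triangles with circumradius
    below ``alpha_radius``.  Always ≤ the convex-hull area."""
    if len(points_xy) < 3:
        return 0.0
    try:
        tri = Delaunay(points_xy)
    except QhullError:
        return 0.0
    p = points_xy[tri.simplices]  # (m, 3, 2)
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = np.where(area > 0, a * b * c / (4.0 * area), np.inf)
    return float(area[circum < alpha_radius].sum())


def alpha_shape_volume_3d(points: np.ndarray, alpha_radius: float) -> float:
    """Volume of the 3D alpha shape: Delaunay tetrahedra with
    circumradius below ``alpha_radius``."""
    if len(points) < 4:
        return 0.0
    try:
        tet = Delaunay(points)
    except QhullError:
        return 0.0
    p = points[tet.simplices]  # (m, 4, 3)
    a, b, c, d = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    vol = np.abs(np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))) / 6.0
    # circumradius of a tetrahedron via the Cayley-Menger-free formula
    ba, ca, da = b - a, c - a, d - a
    n1 = np.einsum("ij,ij->i", ba, ba)[:, None] * np.cross(ca, da)
    n2 = np.einsum("ij,ij->i", ca, ca)[:, None] * np.cross(da, ba)
    n3 = np.einsum("ij,ij->i", da, da)[:, None] * np.cross(ba, ca)
    num = np.linalg.norm(n1 + n2 + n3, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = np.where(vol > 0, num / (12.0 * vol), np.inf)
    return float(vol[circum < alpha_radius].sum())


def root_ball(points: np.ndarray, alpha_radius: float | None = None) -> dict:
    """Root-ball envelope metrics from a physical-unit point set.

    Planar metrics use the horizontal (x, y) projection; volumetric
    metrics use the full 3D set.  ``ball_diam_avg`` is the mean of the
    maximum horizontal pairwise extent over 10 equal depth layers
    (empty layers contribute 0); ``ball_diam_max`` the global maximum.
    Degenerate (coplanar/collinear) sets return planar metrics only,
    volumes 0 with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if alpha_radius is None:
        ext = pts.max(0) - pts.min(0)
        alpha_radius = 0.25 * float(np.linalg.norm(ext))
    xy = pts[:, :2]

    def max_pairwise(q):
        if len(q) < 2:
            return 0.0
        try:
            h = ConvexHull(q)
            q = q[h.vertices]
        except QhullError:
            pass
        diff = q[:, None, :] - q[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).max())

    try:
        area_ch = float(ConvexHull(xy).volume)  # 2D hull .volume is the area
    except QhullError:
        area_ch = 0.0
    area_as = alpha_shape_area_2d(xy, alpha_radius)
    try:
        vol_ch = float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate point set: 3D hull volume set to 0", stacklevel=2)
        vol_ch = 0.0
    vol_as = alpha_shape_volume_3d(pts, alpha_radius) if vol_ch > 0 else 0.0

    z = pts[:, 2]
    edges = np.linspace(z.max(), z.min(), N_DEPTH_LAYERS + 1)
    layer_ext = []
    for i in range(N_DEPTH_LAYERS):
        m = (z <= edges[i]) & (z >= edges[i + 1])
        layer_ext.append(max_pairwise(xy[m]) if m.sum() >= 2 else 0.0)
    return {
        "ball_diam_avg": float(np.mean(layer_ext)),
        "ball_diam_max": max_pairwise(xy),
        "ball_area_convexhull": area_ch,
        "ball_area_alphashape": area_as,
        "ball_volume_convexhull": vol_ch,
        "ball_volume_alphashape": vol_as,
    }


# ---------------------------------------------------------------------------
# sheet I

def total_traits(qsm: QSM) -> TotalTraits:
    """Whole-root totals, converted to physical units by the SF rules."""
    if not qsm.cylinders:
        raise ValueError("empty QSM")
    sf = qsm.sf
    volume = qsm.total_volume / sf**3
    length = qsm.total_length / sf
    area = sum(c.lateral_area for c in qsm.cylinders) / sf**2
    base = _base_physical(qsm)
    pts = _endpoints_physical(qsm)
    rooting_depth = float(base[2] - pts[:, 2].min())
    segs = {(c.segment_id) for c in qsm.cylinders if c.order >= 1}
    ball = root_ball(pts)
    return TotalTraits(
        volume=volume,
        rooting_depth=rooting_depth,
        length=length,
        area=area,
        n_ramifications=len(segs),
        max_order=qsm.max_order,
        base_xyz=tuple(base),
        pct_volume_area=100.0 * volume / area if area > 0 else 0.0,
        pct_volume_length=100.0 * volume / length if length > 0 else 0.0,
        pct_area_length=100.0 * area / length if length > 0 else 0.0,
        **ball,
    )


def percent_ratios(volume: float, area: float, length: float) -> dict:
    """The three ratio traits, 100×Volume/Area, 100×Volume/Length,
    100×Area/Length, from totals in cm³ / cm² / cm."""
    return {
        "pct_volume_area": 100.0 * volume / area,
        "pct_volume_length": 100.0 * volume / length,
        "pct_area_length": 100.0 * area / length,
    }


# ---------------------------------------------------------------------------
# sheet II

def order_traits(qsm: QSM) -> pd.DataFrame:
    """Volume, area, length and ramification count per order (zero-filled)."""
    sf = qsm.sf
    rows = []
    for k in range(qsm.max_order + 1):
        cyls = [c for c in qsm.cylinders if c.order == k]
        segs = {c.segment_id for c in cyls}
        rows.append({
            "order": k,
            "volume": sum(c.volume for c in cyls) / sf**3,
            "area": sum(c.lateral_area for c in cyls) / sf**2,
            "length": sum(c.length for c in cyls) / sf,
            "count": len(segs),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sheet III

def _taproot_chain(qsm: QSM) -> list[Cylinder]:
    """Order-0 cylinders ordered from the base, gap fills included."""
    order0 = [(i, c) for i, c in enumerate(qsm.cylinders) if c.order == 0]
    children = {}
    root = None
    idx_set = {i for i, _ in order0}
    for i, c in order0:
        if c.parent is None or c.parent not in idx_set:
            root = i
        else:
            children[c.parent] = i
    chain = []
    cur = root
    while cur is not None:
        chain.append(qsm.cylinders[cur])
        cur = children.get(cur)
    return chain


def taproot_taper(qsm: QSM) -> TaperFunction:
    """Main-root diameter versus cumulative arc distance (at midpoints)."""
    chain = _taproot_chain(qsm)
    if not chain:
        raise ValueError("QSM has no order-0 cylinders")
    sf = qsm.sf
    dist, diam, acc = [], [], 0.0
    for c in chain:
        dist.append((acc + c.length / 2.0) / sf)
        diam.append(2.0 * c.radius / sf)
        acc += c.length
    return TaperFunction(np.asarray(dist), np.asarray(diam))


# ---------------------------------------------------------------------------
# sheet IV

def spread(qsm: QSM, base: np.ndarray | None = None,
           max_depth: float | None = None) -> SpreadMatrix:
    """Horizontal reach in 10 equal depth layers × 18 azimuth sectors.

    Each cell holds the maximum horizontal distance from the vertical
    axis through the base among cylinder endpoints in that (layer,
    sector); sectors are 20° wide starting at +x, counter-clockwise
    seen from above.  ``base`` (physical units) and ``max_depth``
    override the reference frame, which lets two registered scans be
    binned on a common grid.
    """
    base = _base_physical(qsm) if base is None else np.asarray(base, float)
    # sample along each cylinder axis so every traversed cell is
    # populated, not only the cells containing the two end points
    samples = []
    for c in qsm.cylinders:
        n = max(2, int(np.ceil(c.length / (0.5 * qsm.sf))) + 1)
        t = np.linspace(0.0, c.length, n)
        samples.append(c.start[None, :] + np.outer(t, c.axis))
    pts = np.vstack(samples) / qsm.sf
    rel = pts - base
    depth = -rel[:, 2]
    horiz = np.hypot(rel[:, 0], rel[:, 1])
    azi = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
    dmax = max(depth.max() if max_depth is None else max_depth, 1e-12)
    inside = depth <= dmax + 1e-12
    depth, horiz, azi = depth[inside], horiz[inside], azi[inside]
    depth_edges = np.linspace(0.0, dmax, N_DEPTH_LAYERS + 1)
    dir_edges = np.linspace(0.0, 360.0, N_DIRECTIONS + 1)
    li = np.clip((depth / dmax * N_DEPTH_LAYERS).astype(int), 0, N_DEPTH_LAYERS - 1)
    si = np.clip((azi / 20.0).astype(int), 0, N_DIRECTIONS - 1)
    vals = np.zeros((N_DEPTH_LAYERS, N_DIRECTIONS))
    np.maximum.at(vals, (li, si), horiz)
    return SpreadMatrix(vals, depth_edges, dir_edges)


# ---------------------------------------------------------------------------
# sheets V and VI

def _classify(values: np.ndarray, width: float) -> np.ndarray:
    return np.floor(values / width).astype(int)


def cylinder_distributions(qsm: QSM, which: str = "main") -> dict:
    """Distribution tables for one root class.

    ``which`` = "main" (order 0) or "lateral" (order ≥ 1).  Returns a
    dict of :class:`DistributionTable` keyed by classifier: ``diameter``
    (0.1 mm = 0.01 cm classes), ``depth`` (1 cm), ``zenith`` and
    ``azimuth`` (10°).  Classes are half-open [k·w, (k+1)·w); per-class
    totals conserve the group totals exactly.
    """
    if which == "main":
        cyls = [c for c in qsm.cylinders if c.order == 0]
    elif which == "lateral":
        cyls = [c for c in qsm.cylinders if c.order >= 1]
    else:
        raise ValueError(f"unknown selection {which!r}; use 'main' or 'lateral'")
    if not cyls:
        raise ValueError(f"no {which} cylinders in the QSM")
    sf = qsm.sf
    base = _base_physical(qsm)
    vol = np.array([c.volume for c in cyls]) / sf**3
    area = np.array([c.lateral_area for c in cyls]) / sf**2
    length = np.array([c.length for c in cyls]) / sf
    diam = np.array([2.0 * c.radius for c in cyls]) / sf
    mid = np.array([(c.start + c.end) / 2.0 for c in cyls]) / sf
    depth = base[2] - mid[:, 2]
    axes = np.array([c.axis for c in cyls])
    zenith = np.degrees(np.arccos(np.clip(axes[:, 2], -1.0, 1.0)))
    azimuth = np.degrees(np.arctan2(axes[:, 1], axes[:, 0])) % 360.0

    widths = {"diameter": DIAMETER_CLASS_CM, "depth": DEPTH_CLASS_CM,
              "zenith": ANGLE_CLASS_DEG, "azimuth": ANGLE_CLASS_DEG}
    classifiers = {"diameter": diam, "depth": np.maximum(depth, 0.0),
                   "zenith": zenith, "azimuth": azimuth}
    out = {}
    for name, vals in classifiers.items():
        w = widths[name]
        idx = _classify(vals, w)
        kmax = int(idx.max())
        edges = np.arange(0, kmax + 2) * w
        nb = kmax + 1
        tv = np.zeros(nb)
        ta = np.zeros(nb)
        tl = np.zeros(nb)
        tc = np.zeros(nb)
        np.add.at(tv, idx, vol)
        np.add.at(ta, idx, area)
        np.add.at(tl, idx, length)
        np.add.at(tc, idx, 1.0)
        out[name] = DistributionTable(name, edges, tv, ta, tl, tc)
    return out
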
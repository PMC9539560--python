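"""Procedural generation of branching root meshes with exact ground truth.

Emulates segmented X-ray CT scans of potted tap-rooted plants: a
tapering vertical main root with straight lateral roots at configurable
depths and directions, optional axis waviness (tortuosity), Gaussian
surface noise, and disconnected speckle blobs mimicking imperfect
soil–root segmentation.  Coordinates are centimetres, z up, the root
collar at the origin growing toward −z.

Ground-truth traits are computed in closed form from the skeleton
(frustum volume/area per edge), not from the mesh, so they serve as
exact oracles for the reconstruction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry_io import TriMesh

MESH_RESOLUTION = 0.1  # cm: axial ring spacing; ring vertex count scales with
                       # circumference so surface vertex density is uniform,
                       # as in real CT surface meshes
MIN_RING_SEGMENTS = 8


@dataclass
class Lateral:
    depth: float        # attachment depth below the collar (cm)
    azimuth: float      # horizontal bearing, degrees from +x, CCW from above
    zenith: float       # inclination from the upward vertical, degrees
    length: float       # cm
    radius: float       # cm


@dataclass
class RootSpec:
    """Parameter set for one synthetic root."""

    taproot_length: float = 20.0
    taproot_radius_top: float = 0.4
    taproot_radius_bottom: float = 0.15
    laterals: list = field(default_factory=list)
    tortuosity: float = 0.0        # waviness amplitude (cm)
    noise_sigma: float = 0.0       # surface noise std (cm)
    speckle_count: int = 0         # disconnected noise blobs
    speckle_size: float = 0.2      # blob radius (cm)
    mesh_resolution: float = MESH_RESOLUTION  # cm, axial ring spacing
    seed: int = 0

    def __post_init__(self):
        if self.taproot_radius_top <= 0 or self.taproot_radius_bottom <= 0:
            raise ValueError("taproot radii must be positive")
        self.laterals = [l if isinstance(l, Lateral) else Lateral(*l)
                         for l in self.laterals]
        for lat in self.laterals:
            if lat.radius <= 0:
                raise ValueError("lateral radius must be positive")
            if not 0 <= lat.depth <= self.taproot_length:
                raise ValueError("lateral attachment outside taproot")


def default_spec(seed: int = 0, n_laterals: int = 6) -> RootSpec:
    """A realistic pot-scale root: 20 cm taproot, mm-scale laterals.

    Mirrors the scanned study system: pots of 18 cm diameter × 40 cm
    height and minimum root diameters around 0.5 mm, scaled up enough in
    radius that a desk-scale mesh resolves every branch.
    """
    rng = np.random.default_rng(seed)
    laterals = []
    for k in range(n_laterals):
        laterals.append(Lateral(
            depth=3.0 + 14.0 * k / max(n_laterals - 1, 1),
            azimuth=float((k * 360.0 / n_laterals + rng.uniform(-10, 10)) % 360),
            zenith=float(rng.uniform(100.0, 130.0)),
            length=float(rng.uniform(3.0, 6.0)),
            radius=float(rng.uniform(0.12, 0.2)),
        ))
    return RootSpec(laterals=laterals, seed=seed)


def _taproot_skeleton(spec: RootSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Skeleton polyline and per-node radius of the main root."""
    step = spec.mesh_resolution
    n = max(int(np.ceil(spec.taproot_length / step)) + 1, 4)
    t = np.linspace(0.0, 1.0, n)
    z = -t * spec.taproot_length
    x = np.zeros(n)
    y = np.zeros(n)
    if spec.tortuosity > 0:
        phase = rng.uniform(0, 2 * np.pi, size=2)
        x = spec.tortuosity * np.sin(2 * np.pi * 1.5 * t + phase[0])
        y = spec.tortuosity * np.sin(2 * np.pi * 1.5 * t + phase[1])
        x -= x[0]
        y -= y[0]
    radii = spec.taproot_radius_top + t * (spec.taproot_radius_bottom
                                           - spec.taproot_radius_top)
    return np.c_[x, y, z], radii


def _lateral_skeleton(spec: RootSpec, lat: Lateral, tap_pts: np.ndarray):
    z_attach = -lat.depth
    i = int(np.argmin(np.abs(tap_pts[:, 2] - z_attach)))
    origin = tap_pts[i]
    zen = np.radians(lat.zenith)
    azi = np.radians(lat.azimuth)
    direction = np.array([np.sin(zen) * np.cos(azi),
                          np.sin(zen) * np.sin(azi),
                          np.cos(zen)])
    step = spec.mesh_resolution
    n = max(int(np.ceil(lat.length / step)) + 1, 3)
    t = np.linspace(0.0, 1.0, n)
    pts = origin[None, :] + np.outer(t * lat.length, direction)
    radii = np.full(n, lat.radius)
    return pts, radii


def _tube_mesh(skeleton: np.ndarray, radii: np.ndarray, rng,
               noise_sigma: float = 0.0, resolution: float = MESH_RESOLUTION):
    """Closed tube mesh around a polyline with per-node radii.

    The ring vertex count scales with the local circumference so the
    surface vertex density is approximately uniform.
    """
    n = len(skeleton)
    m = max(MIN_RING_SEGMENTS,
            int(np.round(2 * np.pi * float(np.median(radii)) / resolution)))
    theta = np.linspace(0, 2 * np.pi, m, endpoint=False)
    verts = []
    # parallel-transport-ish frames: recompute per node from segment tangent
    tangents = np.gradient(skeleton, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(tangents[0] @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(tangents[0], helper)
    u /= np.linalg.norm(u)
    for i in range(n):
        t = tangents[i]
        u = u - (u @ t) * t
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        ring = (skeleton[i][None, :]
                + radii[i] * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)))
        if noise_sigma > 0:
            ring = ring + rng.normal(0, noise_sigma, ring.shape)
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(n - 1):
        for j in range(m):
            a = i * m + j
            b = i * m + (j + 1) % m
            c = (i + 1) * m + j
            d = (i + 1) * m + (j + 1) % m
            faces.append([a, b, c])
            faces.append([b, d, c])
    # end caps
    top_center = len(verts)
    verts = np.vstack([verts, skeleton[0], skeleton[-1]])
    bot_center = top_center + 1
    for j in range(m):
        faces.append([top_center, (j + 1) % m, j])
        base = (n - 1) * m
        faces.append([bot_center, base + j, base + (j + 1) % m])
    return verts, np.asarray(faces, dtype=np.int64)


def _skeleton_truth(skeleton: np.ndarray, radii: np.ndarray):
    """Closed-form frustum volume, lateral area and arc length per polyline."""
    seg = np.diff(skeleton, axis=0)
    l = np.linalg.norm(seg, axis=1)
    r1, r2 = radii[:-1], radii[1:]
    vol = np.pi * l / 3.0 * (r1**2 + r1 * r2 + r2**2)
    slant = np.sqrt(l**2 + (r1 - r2) ** 2)
    area = np.pi * (r1 + r2) * slant
    return float(vol.sum()), float(area.sum()), float(l.sum())


def generate_mesh(spec: RootSpec):
    """Generate (mesh, ground-truth skeletons, ground-truth traits).

    The ground truth is a dict with keys ``volume`` (cm³), ``area``
    (cm²), ``length`` (cm), ``rooting_depth`` (cm), ``n_ramifications``,
    ``max_order`` and ``skeletons`` (list of (polyline, radii) pairs,
    taproot first).
    """
    rng = np.random.default_rng(spec.seed)
    tap_pts, tap_r = _taproot_skeleton(spec, rng)
    skeletons = [(tap_pts, tap_r)]
    for lat in spec.laterals:
        skeletons.append(_lateral_skeleton(spec, lat, tap_pts))

    all_v, all_f = [], []
    offset = 0
    for pts, radii in skeletons:
        v, f = _tube_mesh(pts, radii, rng, spec.noise_sigma,
                          spec.mesh_resolution)
        all_v.append(v)
        all_f.append(f + offset)
        offset += len(v)

    # disconnected speckle blobs: inside the pot but clear of the root
    # (imperfect soil-root segmentation leaves such islands nearby)
    reach = max([l.length for l in spec.laterals] + [1.0])
    for _ in range(spec.speckle_count):
        azi = rng.uniform(0, 2 * np.pi)
        rad = reach + rng.uniform(1.0, 2.5)
        center = np.array([rad * np.cos(azi), rad * np.sin(azi),
                           -rng.uniform(0, spec.taproot_length)])
        line = np.vstack([center, center + spec.speckle_size
                          * np.array([0, 0, -1.0])])
        v, f = _tube_mesh(line, np.full(2, spec.speckle_size / 2), rng,
                          resolution=spec.mesh_resolution)
        all_v.append(v)
        all_f.append(f + offset)
        offset += len(v)

    mesh = TriMesh(np.vstack(all_v), np.vstack(all_f))

    vol = area = length = 0.0
    for pts, radii in skeletons:
        dv, da, dl = _skeleton_truth(pts, radii)
        vol += dv
        area += da
        length += dl
    truth = {
        "volume": vol,
        "area": area,
        "length": length,
        "rooting_depth": float(-min(p[:, 2].min() for p, _ in skeletons)),
        "n_ramifications": len(spec.laterals),
        "max_order": 1 if spec.laterals else 0,
        "skeletons": skeletons,
    }
    return mesh, truth


def generate_series(spec: RootSpec, weeks: int, elongation_rate: float = 1.35,
                    new_laterals_per_week: int = 2,
                    perturb_deg: float = 0.0):
    """Weekly growth series: material strictly added week over week.

    Each week the taproot and every lateral elongate by
    ``elongation_rate`` and ``new_laterals_per_week`` fresh laterals
    appear.  If ``perturb_deg`` is nonzero, every week after the first
    is rigidly rotated about the vertical axis through the collar by
    that angle (cumulative), and the applied rotation matrix is recorded
    as ground truth.

    Returns a list of per-week dicts with keys ``mesh``, ``truth``,
    ``spec`` and ``rotation`` (3×3, identity for week 1).
    """
    if weeks < 2:
        raise ValueError("need at least 2 weeks")
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    for w in range(weeks):
        g = elongation_rate**w
        laterals = [Lateral(l.depth, l.azimuth, l.zenith, l.length * g, l.radius)
                    for l in spec.laterals]
        for k in range(new_laterals_per_week * w):
            laterals.append(Lateral(
                depth=float(rng.uniform(2.0, spec.taproot_length * 0.9)),
                azimuth=float(rng.uniform(0, 360)),
                zenith=float(rng.uniform(100, 135)),
                length=float(rng.uniform(2.0, 4.0)),
                radius=float(rng.uniform(0.1, 0.18)),
            ))
        wspec = RootSpec(
            taproot_length=spec.taproot_length * g,
            taproot_radius_top=spec.taproot_radius_top * (1 + 0.05 * w),
            taproot_radius_bottom=spec.taproot_radius_bottom,
            laterals=laterals, tortuosity=spec.tortuosity,
            noise_sigma=spec.noise_sigma, seed=spec.seed,
        )
        mesh, truth = generate_mesh(wspec)
        ang = np.radians(perturb_deg * w)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        mesh = TriMesh(mesh.vertices @ rot.T, mesh.faces)
        out.append({"mesh": mesh, "truth": truth, "spec": wspec, "rotation": rot})
    return out


def write_stl(mesh: TriMesh, path) -> None:
    """Write an ASCII STL (text deliverable friendly)."""
    import trimesh as _tm
    _tm.Trimesh(mesh.vertices, mesh.faces, process=False).export(
        str(path), file_type="stl_ascii")
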
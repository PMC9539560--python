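"""Cover-set construction and region-growing branch segmentation.

The point cloud is partitioned into small surface patches (cover sets)
by a seeded greedy ball cover.  Starting from the root base (topmost
patch — the collar sits at the soil surface, depth grows along −z), a
breadth-first region growing expands layer by layer; when a layer
splits into two or more connected components the largest continues the
current segment and the others seed child segments one ramification
order deeper.  Connected components of the patch graph that do not
contain the base are discarded as soil-segmentation speckle noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import PointCloud

log = logging.getLogger(__name__)

MIN_COMPONENT_SIZE = 2  # patches: smallest layer component that can seed a child


@dataclass
class CoverSet:
    id: int
    member_indices: np.ndarray
    center: np.ndarray
    neighbor_ids: set = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class Segment:
    """A non-bifurcated piece of root: ordered layers of cover-set ids."""

    id: int
    layers: list  # list[list[int]]
    parent_segment: int | None = None
    children: list = field(default_factory=list)
    order: int = 0

    def cover_ids(self):
        for layer in self.layers:
            yield from layer


#: patch diameter in scaled units; fixed, so the scale factor genuinely
#: controls the relative resolution of the model (a root scaled to the
#: recommended 10-30 units of depth gets 40-120 patches along its depth)
PATCH_DIAMETER_SCALED = 0.25


def default_patch_diameter(cloud: PointCloud) -> float:
    """The fixed working patch diameter in scaled units.

    Deliberately *not* adaptive: tying patch size to the cloud extent
    would cancel the scale factor's documented effect on model
    resolution and would let disconnected noise dilate the patches.
    """
    return PATCH_DIAMETER_SCALED


def build_cover(cloud: PointCloud, patch_diameter: float, seed: int = 0) -> list[CoverSet]:
    """Greedy seeded ball cover of the cloud.

    Points are visited in a pseudo-random order derived from a seeded
    hash of each point's coordinates; each uncovered point seeds a
    patch of all uncovered points within ``patch_diameter / 2``.  Two
    patches are neighbors when any of their member points come within
    ``patch_diameter``.  Hashing positions rather than indices keeps
    the cover over the root identical when unrelated points (speckle
    noise) are added to the cloud.
    """
    pts = cloud.points
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points to build a cover")
    if patch_diameter <= 0:
        raise ValueError("patch_diameter must be positive")
    diag = np.linalg.norm(pts.max(0) - pts.min(0))
    if patch_diameter > diag:
        warnings.warn("patch_diameter exceeds bounding box; single patch", stacklevel=2)

    rng = np.random.default_rng(seed)
    salt = rng.random(3)
    # seeded coordinate hash: order is independent of point indexing
    keys = np.sin((pts * 1e4) @ salt) + 1e-7 * np.arange(n)
    perm = np.argsort(keys, kind="stable")
    tree = cKDTree(pts)
    label = np.full(n, -1, dtype=np.int64)
    covers: list[CoverSet] = []
    for idx in perm:
        if label[idx] >= 0:
            continue
        ball = tree.query_ball_point(pts[idx], patch_diameter / 2.0)
        members = np.array([j for j in ball if label[j] < 0], dtype=np.int64)
        cid = len(covers)
        label[members] = cid
        covers.append(CoverSet(cid, members, pts[members].mean(0)))

    # neighbor relation from all point pairs within patch_diameter
    pairs = tree.query_pairs(patch_diameter, output_type="ndarray")
    if len(pairs):
        la, lb = label[pairs[:, 0]], label[pairs[:, 1]]
        mask = la != lb
        for a, b in set(map(tuple, np.sort(np.c_[la[mask], lb[mask]], axis=1))):
            covers[a].neighbor_ids.add(b)
            covers[b].neighbor_ids.add(a)
    return covers


def find_base(cover: list[CoverSet]) -> int:
    """Id of the root-base patch: topmost center, ties to the smallest id.

    Only patches in the largest connected component (by point count) are
    eligible, so isolated vertices or speckle noise floating above the
    collar can never anchor the segmentation.
    """
    if not cover:
        raise ValueError("empty cover")
    comps = _components({c.id for c in cover}, cover)
    main = max(comps, key=lambda comp: sum(cover[c].size for c in comp))
    best = max((cover[c] for c in main), key=lambda c: (c.center[2], -c.id))
    return best.id


def _layer_centroid(layer: list[int], cover: list) -> np.ndarray:
    sizes = np.array([cover[c].size for c in layer], dtype=float)
    centers = np.array([cover[c].center for c in layer])
    return (centers * sizes[:, None]).sum(0) / sizes.sum()


def _components(ids: set[int], cover: list[CoverSet]) -> list[list[int]]:
    """Connected components of the neighbor graph restricted to ``ids``."""
    seen: set[int] = set()
    comps = []
    for start in sorted(ids):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            c = stack.pop()
            comp.append(c)
            for nb in cover[c].neighbor_ids:
                if nb in ids and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


MIN_CHILD_LAYERS = 3  # child segments shorter than this merge back into the parent
LAYER_HOPS = 2    # hop-distance band width of one expansion layer
CONT_ALIGN_MIN = 0.75  # cos threshold: a successor continuing the segment


def segment_root(
    cover: list[CoverSet],
    base: int,
    min_component_size: int = MIN_COMPONENT_SIZE,
    min_child_layers: int = MIN_CHILD_LAYERS,
    layer_hops: int = LAYER_HOPS,
) -> list[Segment]:
    """Region-grow segments from the base; returns a tree of segments.

    Patches unreachable from the base are dropped as noise (logged).
    Growth is organized by geodesic level sets: every reachable patch
    gets its BFS hop distance from the base, each distance annulus is
    split into connected components, and components on consecutive
    annuli are linked by patch adjacency.  Walking this component tree,
    a single successor continues the current segment; at a bifurcation
    the successor best aligned with the segment's growth direction
    continues and the others seed children one order deeper.  If no
    successor clearly continues the direction (a symmetric fork), the
    segment ends and every limb becomes a child.
    Side components smaller than ``min_component_size`` patches are
    absorbed into the continuing layer.  Childless segments shorter
    than ``min_child_layers`` layers are spurious surface splits and
    are merged back into the parent layer they branched from.
    """
    if base < 0 or base >= len(cover):
        raise ValueError(f"base id {base} not in cover")

    # restrict to the base's connected component; rest is speckle noise
    reachable = set()
    stack = [base]
    reachable.add(base)
    while stack:
        c = stack.pop()
        for nb in cover[c].neighbor_ids:
            if nb not in reachable:
                reachable.add(nb)
                stack.append(nb)
    n_noise = len(cover) - len(reachable)
    if n_noise:
        noise_pts = sum(c.size for c in cover if c.id not in reachable)
        log.info("discarded %d noise patches (%d points) not connected to base",
                 n_noise, noise_pts)

    # geodesic (hop) distance from the base
    dist = {base: 0}
    order_bfs = [base]
    head = 0
    while head < len(order_bfs):
        c = order_bfs[head]
        head += 1
        for nb in cover[c].neighbor_ids:
            if nb in reachable and nb not in dist:
                dist[nb] = dist[c] + 1
                order_bfs.append(nb)
    dmax = max(dist.values())

    # connected components per distance band; single-hop annuli are too
    # ragged on an irregular patch graph, so hops are grouped in bands
    nbands = dmax // layer_hops + 1
    annuli: list[list[list[int]]] = []
    for d in range(nbands):
        ring = {c for c, dd in dist.items() if dd // layer_hops == d}
        annuli.append(_components(ring, cover))

    # link components on consecutive annuli by patch adjacency
    node_of: dict[int, tuple[int, int]] = {}
    for d, comps in enumerate(annuli):
        for k, comp in enumerate(comps):
            for c in comp:
                node_of[c] = (d, k)
    succ: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for d in range(nbands - 1):
        links: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
        for k, comp in enumerate(annuli[d + 1]):
            child = (d + 1, k)
            counts: dict[tuple[int, int], int] = {}
            for c in comp:
                for nb in cover[c].neighbor_ids:
                    if nb in dist and dist[nb] // layer_hops == d:
                        p = node_of[nb]
                        counts[p] = counts.get(p, 0) + 1
            if counts:  # attach to the most-connected predecessor
                parent = max(counts, key=lambda p: (counts[p], -p[1]))
                succ.setdefault(parent, []).append(child)

    def node_points(node):
        d, k = node
        return sum(cover[c].size for c in annuli[d][k])

    def node_centroid(node):
        d, k = node
        sizes = np.array([cover[c].size for c in annuli[d][k]], dtype=float)
        centers = np.array([cover[c].center for c in annuli[d][k]])
        return (centers * sizes[:, None]).sum(0) / sizes.sum()

    segments: list[Segment] = []
    spawn_layer: dict[int, int] = {}  # segment id -> parent layer index at spawn
    # queue of (start node, parent segment id, order, parent layer index)
    queue = [((0, 0), None, 0, 0)]
    while queue:
        node, parent_id, order, p_layer = queue.pop(0)
        seg = Segment(id=len(segments), layers=[],
                      parent_segment=parent_id, order=order)
        segments.append(seg)
        spawn_layer[seg.id] = p_layer
        if parent_id is not None:
            segments[parent_id].children.append(seg.id)
        while node is not None:
            d, k = node
            seg.layers.append(sorted(annuli[d][k]))
            nxt = succ.get(node, [])
            if not nxt:
                node = None
            elif len(nxt) == 1:
                node = nxt[0]
            else:
                nxt = sorted(nxt, key=node_points, reverse=True)
                big = [n for n in nxt if len(annuli[n[0]][n[1]])
                       >= min_component_size]
                small = [n for n in nxt if n not in big]
                cands = big if big else nxt
                # continuation follows the segment's growth direction;
                # raw size misidentifies the main limb where a tapering
                # root becomes thinner than its branch
                # the current (junction) layer mixes both limbs, so the
                # reference direction is taken over earlier, clean layers
                if len(seg.layers) >= 3:
                    c_ref = _layer_centroid(seg.layers[-2], cover)
                    c_old = _layer_centroid(
                        seg.layers[max(0, len(seg.layers) - 5)], cover)
                    direction = c_ref - c_old
                    nrm = np.linalg.norm(direction)
                else:
                    nrm = 0.0
                if nrm > 0:
                    direction = direction / nrm
                    c_last = _layer_centroid(seg.layers[-1], cover)

                    def alignment(n):
                        v = node_centroid(n) - c_last
                        vn = np.linalg.norm(v)
                        return (v @ direction) / vn if vn > 0 else -1.0

                    cont = max(cands, key=alignment)
                    if alignment(cont) < CONT_ALIGN_MIN:
                        # symmetric bifurcation: no limb continues the
                        # current direction, so all successors are children
                        cont = None
                else:
                    cont = cands[0]
                for side in nxt:
                    if side is cont:
                        continue
                    if side in small:
                        # absorb undersized side components into this layer
                        seg.layers[-1] = sorted(set(seg.layers[-1])
                                                | set(annuli[side[0]][side[1]]))
                        for follow in succ.get(side, []):
                            queue.append((follow, seg.id, order + 1,
                                          len(seg.layers) - 1))
                    else:
                        queue.append((side, seg.id, order + 1,
                                      len(seg.layers) - 1))
                node = cont

    segments = _merge_terminal_children(segments, spawn_layer, cover)
    segments = _prune_short_children(segments, spawn_layer, min_child_layers)
    _recompute_orders(segments)
    return segments


def _segment_end_direction(seg: Segment, cover: list) -> np.ndarray | None:
    if len(seg.layers) < 2:
        return None
    c1 = _layer_centroid(seg.layers[-1], cover)
    c0 = _layer_centroid(seg.layers[max(0, len(seg.layers) - 4)], cover)
    d = c1 - c0
    n = np.linalg.norm(d)
    return d / n if n > 0 else None


def _merge_terminal_children(segments: list[Segment], spawn_layer: dict,
                             cover: list) -> list[Segment]:
    """Splice a child that is really the parent's continuation.

    When a level-set ring transiently fragments, the walk's chosen
    fragment can die while the sibling fragment captures the rest of
    the limb as a spurious child.  The signature is a child spawned at
    the parent's final layer whose direction continues the parent's;
    such a child is merged back as the same segment.
    """
    segs = {s.id: s for s in segments}
    changed = True
    while changed:
        changed = False
        for s in list(segs.values()):
            if s.id not in segs:
                continue
            terminal = [c for c in s.children
                        if spawn_layer[c] >= len(s.layers) - 2]
            if not terminal:
                continue
            d = _segment_end_direction(s, cover)
            if d is None:
                continue
            best, best_cos = None, CONT_ALIGN_MIN  # require clear continuation
            tail = _layer_centroid(s.layers[-1], cover)
            for cid in terminal:
                child = segs[cid]
                v = _layer_centroid(child.layers[0], cover) - tail
                n = np.linalg.norm(v)
                cosang = (v @ d) / n if n > 0 else 1.0
                if cosang > best_cos:
                    best, best_cos = child, cosang
            if best is None:
                continue
            offset = len(s.layers)
            s.layers.extend(best.layers)
            s.children.remove(best.id)
            for gc in best.children:
                segs[gc].parent_segment = s.id
                s.children.append(gc)
                spawn_layer[gc] = spawn_layer[gc] + offset
            del segs[best.id]
            changed = True
    return sorted(segs.values(), key=lambda s: s.id)


def _recompute_orders(segments: list[Segment]) -> None:
    segs = {s.id: s for s in segments}
    roots = [s for s in segments if s.parent_segment is None]
    stack = [(r.id, 0) for r in roots]
    while stack:
        sid, order = stack.pop()
        segs[sid].order = order
        for c in segs[sid].children:
            stack.append((c, order + 1))


def _prune_short_children(segments: list[Segment], spawn_layer: dict[int, int],
                          min_child_layers: int) -> list[Segment]:
    """Merge childless segments shorter than ``min_child_layers`` back
    into the parent layer they spawned from, then re-index."""
    segs = {s.id: s for s in segments}
    changed = True
    while changed:
        changed = False
        for s in list(segs.values()):
            if (s.parent_segment is not None and not s.children
                    and len(s.layers) < min_child_layers):
                parent = segs[s.parent_segment]
                tgt = min(spawn_layer[s.id], len(parent.layers) - 1)
                merged = set(parent.layers[tgt])
                for layer in s.layers:
                    merged.update(layer)
                parent.layers[tgt] = sorted(merged)
                parent.children.remove(s.id)
                del segs[s.id]
                changed = True
    remaining = sorted(segs.values(), key=lambda s: s.id)
    new_id = {s.id: i for i, s in enumerate(remaining)}
    for s in remaining:
        s.id = new_id[s.id]
        if s.parent_segment is not None:
            s.parent_segment = new_id[s.parent_segment]
        s.children = [new_id[c] for c in s.children]
    return remaining


def dump_segments_xyz(segments: list[Segment], cover: list[CoverSet],
                      cloud: PointCloud, path) -> None:
    """Diagnostic dump: x y z segment_id order, one point per line."""
    with open(path, "w") as fh:
        for seg in segments:
            for cid in seg.cover_ids():
                for i in cover[cid].member_indices:
                    p = cloud.points[i]
                    fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g} {seg.id} {seg.order}\n")
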
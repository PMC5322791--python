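"""Skeletonization of the specimen mask and skeleton feature analysis.

The binary specimen is reduced to a single-pixel-wide skeleton with the
two-subiteration Zhang–Suen thinning scheme, which deletes boundary
pixels in alternating passes until a fixpoint is reached while
preserving the connectivity and the holes of the object.  On the
skeleton, *terminals* (exactly one 8-neighbour) and *junctions* (three
or more 8-neighbours) are classified; thinning typically produces small
clusters of junction pixels at a branching point, which are merged into
a single representative pixel so that one biological branching point
maps to one graph vertex and one thickness disc.

Spurious short branches caused by boundary roughness can be pruned, and
cycles of the skeleton (created when physical branches overlap in the
2D projection) are counted and located.  Automatic loop removal is
deliberately not attempted; instead :func:`break_loop` inserts an
explicit one-pixel-wide gap into the *binary* image at a user-chosen
location so that re-skeletonization separates the overlapping branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .preprocess import BinaryImage

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_FOUR = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SkeletonImage:
    """Single-pixel-wide skeleton with classified feature pixels.

    ``junctions`` holds one representative coordinate per merged junction
    cluster; ``junction_clusters`` maps each representative to all member
    pixels of its cluster.  ``loop_report`` is filled by
    :func:`detect_loops`.
    """

    mask: np.ndarray
    junctions: list[tuple[int, int]] = field(default_factory=list)
    terminals: list[tuple[int, int]] = field(default_factory=list)
    junction_clusters: dict = field(default_factory=dict)
    loop_report: list | None = None
    classified: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Zhang–Suen thinning
# ---------------------------------------------------------------------------

def _zs_deletable(img: np.ndarray, step: int) -> np.ndarray:
    """Deletion mask for one Zhang–Suen subiteration on a padded uint8 image."""
    p = img[1:-1, 1:-1]
    P2 = img[:-2, 1:-1]
    P3 = img[:-2, 2:]
    P4 = img[1:-1, 2:]
    P5 = img[2:, 2:]
    P6 = img[2:, 1:-1]
    P7 = img[2:, :-2]
    P8 = img[1:-1, :-2]
    P9 = img[:-2, :-2]
    seq = [P2, P3, P4, P5, P6, P7, P8, P9, P2]
    A = np.zeros(p.shape, dtype=np.uint8)
    for a, b in zip(seq[:-1], seq[1:]):
        A += (a == 0) & (b == 1)
    B = P2 + P3 + P4 + P5 + P6 + P7 + P8 + P9
    if step == 0:
        c3 = P2 * P4 * P6 == 0
        c4 = P4 * P6 * P8 == 0
    else:
        c3 = P2 * P4 * P8 == 0
        c4 = P2 * P6 * P8 == 0
    return (p == 1) & (B >= 2) & (B <= 6) & (A == 1) & c3 & c4


def thin_zhang_suen(binary: BinaryImage | np.ndarray) -> SkeletonImage:
    """Thin a binary image to its skeleton (Zhang & Suen's algorithm).

    The two subiterations are applied alternately, each deleting all of
    its candidate pixels simultaneously, until neither deletes anything.
    An empty foreground yields an empty skeleton.
    """
    mask = binary.mask if isinstance(binary, BinaryImage) else np.asarray(binary, bool)
    img = np.pad(mask.astype(np.uint8), 1)
    while True:
        changed = False
        for step in (0, 1):
            dele = _zs_deletable(img, step)
            if dele.any():
                img[1:-1, 1:-1][dele] = 0
                changed = True
        if not changed:
            break
    return SkeletonImage(img[1:-1, 1:-1].astype(bool))


# ---------------------------------------------------------------------------
# Feature classification
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(mask: np.ndarray) -> np.ndarray:
    return ndimage.convolve(mask.astype(np.uint8), _NEIGHBOR_KERNEL,
                            mode="constant", cval=0)


def classify_features(skel: SkeletonImage) -> SkeletonImage:
    """Fill in terminals and merged junctions of a skeleton.

    Terminals are skeleton pixels with exactly one skeleton 8-neighbour;
    junction pixels have three or more.  8-connected clusters of junction
    pixels are merged into one junction whose coordinate is the cluster
    member closest to the cluster centroid (lexicographic tie-break).
    """
    mask = skel.mask
    counts = _neighbor_counts(mask)
    terminals = [tuple(map(int, rc))
                 for rc in np.argwhere(mask & (counts == 1))]
    # a corner pixel on a smooth curve can have 3 raw 8-neighbours via a
    # diagonal shortcut; junctions are pixels with >= 3 *reduced*
    # neighbours (diagonals discounted when a 4-connected detour exists)
    junction_px = np.zeros_like(mask)
    candidates = np.argwhere(mask & (counts >= 3))
    if len(candidates):
        pixset = {tuple(map(int, rc)) for rc in np.argwhere(mask)}
        for rc in candidates:
            p = tuple(map(int, rc))
            if len(_reduced_neighbors(pixset, p)) >= 3:
                junction_px[p] = True
    labels, n = ndimage.label(junction_px, structure=_STRUCT8)
    junctions: list[tuple[int, int]] = []
    clusters: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for lab in range(1, n + 1):
        members = [tuple(map(int, rc)) for rc in np.argwhere(labels == lab)]
        members.sort()
        centroid = np.mean(members, axis=0)
        rep = min(members,
                  key=lambda m: (float(np.sum((np.array(m) - centroid) ** 2)), m))
        junctions.append(rep)
        clusters[rep] = members
    junctions.sort()
    terminals.sort()
    return SkeletonImage(mask, junctions=junctions, terminals=terminals,
                         junction_clusters=clusters,
                         loop_report=skel.loop_report, classified=True)


# ---------------------------------------------------------------------------
# Reduced pixel adjacency and tracing
# ---------------------------------------------------------------------------

def _reduced_neighbors(pixels: set, p: tuple[int, int]) -> list:
    """8-neighbours of ``p`` on the skeleton, with redundant diagonals dropped.

    A diagonal link is dropped when the two pixels share a 4-neighbour on
    the skeleton; the connection then runs through that pixel instead.
    This removes the spurious 3-cycles raw 8-adjacency creates at corners
    while preserving genuine connectivity and loops.
    """
    r, c = p
    out = []
    for dr, dc in _EIGHT:
        q = (r + dr, c + dc)
        if q not in pixels:
            continue
        if dr != 0 and dc != 0:
            if (r + dr, c) in pixels or (r, c + dc) in pixels:
                continue
        out.append(q)
    return out


@dataclass
class TracedEdge:
    """A branch path between two skeleton feature regions."""

    u: int                      # region id of the start
    v: int                      # region id of the end
    path: list                  # ordered interior pixels, u -> v


@dataclass
class TracedSkeleton:
    """Region/edge decomposition of a classified skeleton.

    Regions are junction clusters and terminals; ``region_kind[i]`` is
    ``"junction"`` or ``"terminal"``, ``region_rep[i]`` the representative
    coordinate and ``region_members[i]`` all pixels owned by the region.
    ``ring_components`` lists closed pixel cycles that touch no region
    (isolated rings).
    """

    region_kind: list
    region_rep: list
    region_members: list
    edges: list
    ring_components: list

    def component_labels(self) -> list[int]:
        """Connected-component label per region (edges as connections)."""
        n = len(self.region_rep)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for e in self.edges:
            ra, rb = find(e.u), find(e.v)
            if ra != rb:
                parent[ra] = rb
        roots = {}
        labels = []
        for i in range(n):
            r = find(i)
            labels.append(roots.setdefault(r, len(roots)))
        return labels


def trace_skeleton(skel: SkeletonImage) -> TracedSkeleton:
    """Decompose a classified skeleton into feature regions and branch paths.

    Every skeleton pixel ends up in exactly one region or one edge path.
    Deterministic: regions and walk starts are processed in lexicographic
    pixel order.
    """
    if not skel.classified:
        skel = classify_features(skel)
    pixels = {tuple(map(int, rc)) for rc in np.argwhere(skel.mask)}

    region_kind: list[str] = []
    region_rep: list[tuple[int, int]] = []
    region_members: list[list[tuple[int, int]]] = []
    region_of: dict[tuple[int, int], int] = {}
    for rep in skel.junctions:
        rid = len(region_rep)
        members = skel.junction_clusters[rep]
        region_kind.append("junction")
        region_rep.append(rep)
        region_members.append(list(members))
        for m in members:
            region_of[m] = rid
    for t in skel.terminals:
        rid = len(region_rep)
        region_kind.append("terminal")
        region_rep.append(t)
        region_members.append([t])
        region_of[t] = rid

    edges: list[TracedEdge] = []
    consumed: set = set()          # path pixels already assigned to an edge
    direct_pairs: set = set()      # dedup for zero-length region-region edges

    def walk(rid: int, start_member, first) -> None:
        path = [first]
        prev = start_member
        cur = first
        while True:
            nbrs = _reduced_neighbors(pixels, cur)
            # prefer ending at a region (excluding the pixel we came from)
            region_hits = sorted(q for q in nbrs
                                 if q in region_of and q != prev)
            nxts = [q for q in nbrs
                    if q not in region_of and q != prev and q not in consumed
                    and q not in path]
            if region_hits and (not nxts or len(path) > 1 or
                                region_of[region_hits[0]] != rid):
                end_rid = region_of[region_hits[0]]
                if end_rid == rid and len(path) < 4:
                    # not a real petal loop, just pixels inside a junction
                    # area: absorb them into the region
                    for p in path:
                        region_members[rid].append(p)
                        region_of[p] = rid
                    return
                edges.append(TracedEdge(rid, end_rid, path))
                return
            if not nxts:
                if region_hits:  # tight petal back to the start region
                    edges.append(TracedEdge(rid, region_of[region_hits[0]], path))
                    return
                # dangling path end not classified as terminal (rare thick
                # configurations): promote it to a terminal region
                trid = len(region_rep)
                region_kind.append("terminal")
                region_rep.append(cur)
                region_members.append([cur])
                region_of[cur] = trid
                consumed.discard(cur)
                edges.append(TracedEdge(rid, trid, path[:-1]))
                return
            prev, cur = cur, nxts[0]
            path.append(cur)
            consumed.add(cur)

    for rid in range(len(region_rep)):
        for member in sorted(region_members[rid]):
            for q in sorted(_reduced_neighbors(pixels, member)):
                if q in region_of:
                    other = region_of[q]
                    key = tuple(sorted((rid, other)))
                    if other != rid and key not in direct_pairs:
                        direct_pairs.add(key)
                        edges.append(TracedEdge(rid, other, []))
                elif q not in consumed:
                    consumed.add(q)
                    walk(rid, member, q)

    # isolated rings: cycles of path pixels touching no region
    ring_components: list[list[tuple[int, int]]] = []
    remaining = sorted(pixels - set(region_of) - consumed)
    seen: set = set()
    for start in remaining:
        if start in seen:
            continue
        ring = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nbrs = [q for q in _reduced_neighbors(pixels, cur) if q != prev]
            nbrs = [q for q in nbrs if q not in seen or (q == start and len(ring) > 2)]
            if not nbrs:
                break
            prev, cur = cur, sorted(nbrs)[0]
            if cur == start:
                break
            ring.append(cur)
            seen.add(cur)
        ring_components.append(ring)

    return TracedSkeleton(region_kind, region_rep, region_members,
                          edges, ring_components)


# ---------------------------------------------------------------------------
# Spur pruning
# ---------------------------------------------------------------------------

def prune_spurs(skel: SkeletonImage, min_length: float | None = None,
                distance_map: np.ndarray | None = None) -> SkeletonImage:
    """Iteratively remove terminal branches shorter than a threshold.

    A spur is the pixel path from a terminal up to (excluding) the first
    junction pixel; it is deleted when its pixel count is below the
    threshold.  With ``min_length=None`` the threshold adapts per spur to
    ``max(3, EDT at the parent junction)`` — half the local junction
    thickness — which requires ``distance_map``.  Junction-to-junction
    and terminal-to-terminal paths are never removed, so the skeleton is
    never disconnected.  ``min_length=0`` is the identity.
    Classification is re-run after every pass until no spur remains.
    """
    if min_length is None and distance_map is None:
        raise ValueError("adaptive pruning needs the distance map")
    if min_length == 0:
        return skel if skel.classified else classify_features(skel)
    mask = skel.mask.copy()
    while True:
        current = classify_features(SkeletonImage(mask))
        junction_members = {m for members in current.junction_clusters.values()
                            for m in members}
        pixset = {tuple(map(int, rc)) for rc in np.argwhere(mask)}
        removed_any = False
        for t in current.terminals:
            if t not in pixset:
                continue
            path = [t]
            prev = None
            cur = t
            junction = None
            while True:
                nbrs = [q for q in _reduced_neighbors(pixset, cur) if q != prev]
                jn = sorted(q for q in nbrs if q in junction_members)
                if jn:
                    junction = jn[0]
                    break
                nbrs = [q for q in nbrs if q not in path]
                if not nbrs:
                    break  # reached another terminal / isolated path: keep
                prev, cur = cur, sorted(nbrs)[0]
                path.append(cur)
            if junction is None:
                continue
            if min_length is not None:
                thr = min_length
            else:
                thr = max(3.0, float(distance_map[junction]))
            if len(path) < thr and not any(p in junction_members for p in path):
                for p in path:
                    mask[p] = False
                    pixset.discard(p)
                removed_any = True
        if not removed_any:
            break
    return classify_features(SkeletonImage(mask))


# ---------------------------------------------------------------------------
# Loop detection and breaking
# ---------------------------------------------------------------------------

def detect_loops(skel: SkeletonImage) -> list[list[tuple[int, int]]]:
    """Independent cycles of the skeleton, with their pixel coordinates.

    The count equals E − V + C of the traced region/edge multigraph
    (isolated rings each contribute one cycle).  Each entry lists the
    pixels along one basis cycle.  The report is also stored on the
    returned skeleton's ``loop_report``.
    """
    traced = trace_skeleton(skel)
    cycles: list[list[tuple[int, int]]] = [list(r) for r in traced.ring_components]

    # spanning forest over the region multigraph; every non-tree edge
    # closes exactly one basis cycle
    n = len(traced.region_rep)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for idx, e in enumerate(traced.edges):
        adj[e.u].append(idx)
        if e.v != e.u:
            adj[e.v].append(idx)
    parent_edge = {}
    visited = set()
    tree = set()
    for root in range(n):
        if root in visited:
            continue
        visited.add(root)
        stack = [root]
        while stack:
            u = stack.pop()
            for idx in adj[u]:
                e = traced.edges[idx]
                w = e.v if e.u == u else e.u
                if w not in visited:
                    visited.add(w)
                    tree.add(idx)
                    parent_edge[w] = (idx, u)
                    stack.append(w)

    def path_to_root(u):
        out = []
        while u in parent_edge:
            idx, p = parent_edge[u]
            out.append(idx)
            u = p
        return u, out

    for idx, e in enumerate(traced.edges):
        if idx in tree:
            continue
        ru, pu = path_to_root(e.u)
        rv, pv = path_to_root(e.v)
        if ru != rv:  # different trees cannot happen for a non-tree edge
            continue
        # symmetric difference of the two root paths + the closing edge
        edge_ids = set(pu) ^ set(pv)
        coords: list[tuple[int, int]] = list(e.path)
        for eid in edge_ids:
            coords.extend(traced.edges[eid].path)
        for rid in {e.u, e.v} | {traced.edges[eid].u for eid in edge_ids} \
                | {traced.edges[eid].v for eid in edge_ids}:
            coords.append(traced.region_rep[rid])
        cycles.append(sorted(set(coords)))

    skel.loop_report = cycles
    return cycles


def break_loop(binary: BinaryImage,
               cut: tuple[tuple[int, int], tuple[int, int]]) -> BinaryImage:
    """Insert a one-pixel-wide background gap across a branch.

    ``cut`` is a pair of adjacent foreground pixels giving the local
    branch direction; the gap is carved perpendicular to it through the
    midpoint, extended until background is reached on both sides.  The
    cleared strip is 4-connected so the two sides are genuinely separated
    under 8-connectivity.  Re-skeletonization of the edited image then
    yields separate branches.
    """
    (p, q) = cut
    mask = binary.mask.copy()
    for px in (p, q):
        if not (0 <= px[0] < mask.shape[0] and 0 <= px[1] < mask.shape[1]
                and mask[px]):
            raise ValueError(f"cut pixel {px} is not foreground")
    if max(abs(p[0] - q[0]), abs(p[1] - q[1])) > 1:
        raise ValueError("cut pixels must be 8-adjacent")
    d = np.array([q[0] - p[0], q[1] - p[1]], dtype=float)
    if not d.any():
        raise ValueError("cut pixels must be distinct")
    d /= np.linalg.norm(d)
    perp = np.array([-d[1], d[0]])
    mid = (np.array(p, dtype=float) + np.array(q, dtype=float)) / 2.0
    limit = max(mask.shape)

    orig = mask.copy()  # stop tests use the pre-cut image

    def carve(sign: int) -> None:
        prev_px = None
        t = 0.0
        while t <= limit:
            pt = mid + sign * t * perp
            px = (int(round(pt[0])), int(round(pt[1])))
            if not (0 <= px[0] < mask.shape[0] and 0 <= px[1] < mask.shape[1]):
                return
            if not orig[px] and px != prev_px:
                return
            if prev_px is not None and px != prev_px:
                dr, dc = px[0] - prev_px[0], px[1] - prev_px[1]
                if dr != 0 and dc != 0:  # bridge diagonal steps (4-connected cut)
                    bridge = (prev_px[0] + dr, prev_px[1])
                    if (0 <= bridge[0] < mask.shape[0]
                            and 0 <= bridge[1] < mask.shape[1]):
                        mask[bridge] = False
            mask[px] = False
            prev_px = px
            t += 0.25

    carve(+1)
    carve(-1)
    return BinaryImage(mask, pixel_scale=binary.pixel_scale,
                       provenance={**binary.provenance,
                                   "loop_cut": [list(p), list(q)]})


# ---------------------------------------------------------------------------
# Overlay output
# ---------------------------------------------------------------------------

#: Feature colours: skeleton green, junctions light blue, terminals pink,
#: root white.
OVERLAY_COLORS = {
    "foreground": (247, 222, 77),
    "skeleton": (0, 200, 0),
    "junction": (120, 200, 255),
    "terminal": (255, 150, 200),
    "root": (255, 255, 255),
}


def save_skeleton_overlay(binary: BinaryImage, skel: SkeletonImage,
                          path: str | Path,
                          root: tuple[int, int] | None = None) -> None:
    """Write an RGB PNG of the specimen with skeleton features highlighted."""
    h, w = binary.mask.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[binary.mask] = OVERLAY_COLORS["foreground"]
    img[skel.mask] = OVERLAY_COLORS["skeleton"]
    pil = Image.fromarray(img)
    px = pil.load()

    def dot(coord, color):
        r, c = coord
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if 0 <= r + dr < h and 0 <= c + dc < w:
                    px[c + dc, r + dr] = color

    for j in skel.junctions:
        dot(j, OVERLAY_COLORS["junction"])
    for t in skel.terminals:
        dot(t, OVERLAY_COLORS["terminal"])
    if root is not None:
        dot(root, OVERLAY_COLORS["root"])
    pil.save(path)


def skeletonize(binary: BinaryImage, prune: float | None = None,
                distance_map: np.ndarray | None = None) -> SkeletonImage:
    """Convenience chain: thin, classify, optionally prune spurs."""
    skel = classify_features(thin_zhang_suen(binary))
    if prune is None and distance_map is None:
        return skel
    return prune_spurs(skel, min_length=prune, distance_map=distance_map)
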
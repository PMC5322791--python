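"""The six morphological variables of a branching specimen.

All thickness measurements derive from the Euclidean distance map of
the binary image: the distance-map value at a centerline pixel is the
radius of the largest disc that fits inside the specimen there, so
local *thickness* is twice that value.

Variables (symbols follow common usage for branching-form morphometrics):

==== =================== =====================================================
da   junction thickness  disc diameter centred at each junction pixel
db   branch thickness    discs placed greedily along each branch after the
                         junction disc; successive discs do not overlap
dc   terminal thickness  disc diameter centred at each branch tip
bl   branch length       pixel count of the branch path and the Euclidean
                         chord between its end vertices (both reported)
ba   branch angle        opening angle between sibling branches at a
                         junction, from the junction to each child's first
                         branch-thickness disc centre, in degrees
bs   terminal spacing    Euclidean distance from each tip to its nearest
                         other tip
==== =================== =====================================================

Lengths are produced in pixels and, when a pixel scale is set, also in
physical units; angles are never scaled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import ndimage

from .graph import SkeletonGraph
from .preprocess import BinaryImage
from .skeleton import SkeletonImage

VARIABLES = ("da", "db", "dc", "bl", "bs", "ba")

#: Along-path probe distance (px) used for a branch direction when no
#: branch-thickness disc exists on the child edge.
ANGLE_PROBE_PX = 5


def distance_map(binary: BinaryImage | np.ndarray) -> np.ndarray:
    """Exact Euclidean distance transform; the image border is background."""
    mask = binary.mask if isinstance(binary, BinaryImage) else np.asarray(binary, bool)
    padded = np.pad(mask, 1)
    dm = ndimage.distance_transform_edt(padded)
    return dm[1:-1, 1:-1]


@dataclass
class DiscMeasurement:
    center: tuple[int, int]
    diameter_px: float
    kind: str                   # "da" | "db" | "dc"
    owner: int                  # vertex id (da, dc) or edge id (db)
    flags: list = field(default_factory=list)


@dataclass
class AngleMeasurement:
    junction: int
    edge_pair: tuple[int, int]
    degrees: float


@dataclass
class LengthMeasurement:
    edge: int
    pixel_path_length: float
    chord_length: float


@dataclass
class SpacingMeasurement:
    terminal: int
    nearest: int
    distance_px: float


@dataclass
class MeasurementSet:
    """All local measurements of one specimen, in pixels.

    ``means()`` gives the per-variable arithmetic means (the per-image
    summary statistic); ``medians()`` the medians.  With a pixel scale,
    :func:`apply_scale` converts all lengths; angles stay in degrees.
    """

    da: list = field(default_factory=list)
    db: list = field(default_factory=list)
    dc: list = field(default_factory=list)
    bl: list = field(default_factory=list)
    ba: list = field(default_factory=list)
    bs: list = field(default_factory=list)
    pixel_scale: float | None = None

    def _values(self, var: str) -> list[float]:
        if var in ("da", "db", "dc"):
            return [m.diameter_px for m in getattr(self, var)]
        if var == "bl":
            return [m.pixel_path_length for m in self.bl]
        if var == "bl_chord":
            return [m.chord_length for m in self.bl]
        if var == "ba":
            return [m.degrees for m in self.ba]
        if var == "bs":
            return [m.distance_px for m in self.bs]
        raise KeyError(var)

    def values(self, var: str, scaled: bool = False) -> list[float]:
        vals = self._values(var)
        if scaled and var != "ba":
            if self.pixel_scale is None:
                raise ValueError("no pixel scale set")
            vals = [v * self.pixel_scale for v in vals]
        return vals

    def means(self, scaled: bool = False) -> dict[str, float]:
        return {var: (float(np.mean(self.values(var, scaled)))
                      if self._values(var) else math.nan)
                for var in VARIABLES + ("bl_chord",)}

    def medians(self, scaled: bool = False) -> dict[str, float]:
        return {var: (float(np.median(self.values(var, scaled)))
                      if self._values(var) else math.nan)
                for var in VARIABLES + ("bl_chord",)}


def junction_thickness(dm: np.ndarray, g: SkeletonGraph) -> list[DiscMeasurement]:
    """da: one disc per junction, diameter = 2 x distance-map value."""
    return [DiscMeasurement(v.coordinate, 2.0 * float(dm[v.coordinate]),
                            "da", v.id)
            for v in g.junctions]


def terminal_thickness(dm: np.ndarray, g: SkeletonGraph) -> list[DiscMeasurement]:
    """dc: one disc per terminal (root included)."""
    return [DiscMeasurement(v.coordinate, 2.0 * float(dm[v.coordinate]),
                            "dc", v.id)
            for v in g.terminals]


def _dist(a, b) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def branch_thickness(dm: np.ndarray, g: SkeletonGraph,
                     da: list[DiscMeasurement],
                     dc: list[DiscMeasurement] | None = None,
                     ) -> list[DiscMeasurement]:
    """db: greedy non-overlapping discs along each branch.

    Each edge is walked from its parent vertex (DFS orientation).  The
    walk starts from the parent's own disc (da at a junction, dc at a
    terminal); the next centre is the first path pixel whose maximal
    disc (radius = distance-map value) no longer overlaps the previous
    disc.  The diameter is ``2 * min(EDT, distance to the previous
    disc's boundary)``; a measurement limited by the previous disc
    rather than the background is flagged ``boundary_limited``.  The
    walk stops when it reaches the far terminal's own disc zone.
    """
    if dc is None:
        dc = terminal_thickness(dm, g)
    vertex_disc = {m.owner: m.diameter_px / 2.0 for m in da}
    vertex_disc.update({m.owner: m.diameter_px / 2.0 for m in dc})
    out: list[DiscMeasurement] = []
    for e in g.edges:
        if e.parent is None:
            raise ValueError("edges are unoriented; run traverse_dfs first")
        parent = g.vertices[e.parent]
        child = g.vertices[e.other(e.parent)]
        path = e.path_from(e.parent)
        prev_center = parent.coordinate
        prev_r = vertex_disc.get(parent.id, float(dm[parent.coordinate]))
        child_r = vertex_disc.get(child.id, 0.0)
        if g.vertices[child.id].kind != "terminal":
            child_r = 0.0
        for p in path:
            if child_r > 0 and _dist(p, child.coordinate) <= child_r:
                break  # inside the terminal's dc zone
            r_bg = float(dm[p])
            gap = _dist(p, prev_center) - prev_r
            if gap <= 0 or r_bg <= 0:
                continue
            if gap >= r_bg:
                radius = r_bg
                flags = []
            else:
                continue  # maximal disc would still overlap: keep walking
            out.append(DiscMeasurement(p, 2.0 * radius, "db", e.id, flags))
            prev_center, prev_r = p, radius
    return out


def branch_length(g: SkeletonGraph) -> list[LengthMeasurement]:
    """bl: per edge, interior pixel count and endpoint chord length."""
    return [LengthMeasurement(e.id, float(len(e.path)),
                              _dist(g.vertices[e.u].coordinate,
                                    g.vertices[e.v].coordinate))
            for e in g.edges]


def branch_angle(g: SkeletonGraph,
                 db: list[DiscMeasurement]) -> list[AngleMeasurement]:
    """ba: opening angle between sibling child branches at each junction.

    The direction of a child branch follows the centres of its
    branch-thickness discs: from the first to the second disc when the
    edge carries at least two (both lie beyond the junction's own disc,
    outside the transient where the medial axis bends into the
    junction), else from the junction pixel to the single disc centre,
    else to a probe pixel ~:data:`ANGLE_PROBE_PX` px along the path (or
    the far endpoint).  Angles are reported in [0, 180] degrees.
    """
    edge_db: dict[int, list[tuple[int, int]]] = {}
    for m in db:
        edge_db.setdefault(m.owner, []).append(m.center)
    out: list[AngleMeasurement] = []
    for v in g.junctions:
        children = g.children_of(v.id)
        if len(children) < 2:
            warnings.warn(f"junction {v.id} has fewer than two child "
                          "branches; no angle measured")
            continue

        def direction(e):
            centers = edge_db.get(e.id, [])
            if len(centers) >= 2:
                origin, target = centers[0], centers[1]
            elif len(centers) == 1:
                origin, target = v.coordinate, centers[0]
            else:
                origin = v.coordinate
                path = e.path_from(v.id)
                if path:
                    target = path[min(ANGLE_PROBE_PX, len(path)) - 1]
                else:
                    target = g.vertices[e.other(v.id)].coordinate
            vec = np.array([target[0] - origin[0],
                            target[1] - origin[1]], dtype=float)
            n = np.linalg.norm(vec)
            return vec / n if n > 0 else None

        dirs = {e.id: direction(e) for e in children}
        for e1, e2 in combinations(children, 2):
            d1, d2 = dirs[e1.id], dirs[e2.id]
            if d1 is None or d2 is None:
                continue
            cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
            out.append(AngleMeasurement(v.id, (e1.id, e2.id),
                                        math.degrees(math.acos(cosang))))
    return out


def refine_tip_coordinates(binary: BinaryImage, dm: np.ndarray,
                           g: SkeletonGraph) -> dict:
    """Sub-pixel tip positions compensating the thinning retraction.

    Thinning pulls a skeleton endpoint one or two pixels back into the
    branch.  The physical tip centre is recovered by marching from the
    terminal along the branch's outward direction to the object's
    extreme end, then stepping one maximal-disc radius back inside:
    ``tip = end - EDT(terminal) * direction``.
    """
    mask = binary.mask if isinstance(binary, BinaryImage) else binary
    out: dict[int, tuple[float, float]] = {}
    for v in g.terminals:
        coord = np.array(v.coordinate, dtype=float)
        edges = g.incident(v.id)
        if not edges:
            out[v.id] = tuple(coord)
            continue
        path = edges[0].path_from(v.id)
        inner = (np.array(path[min(2, len(path) - 1)], dtype=float)
                 if path else
                 np.array(g.vertices[edges[0].other(v.id)].coordinate, float))
        d = coord - inner
        norm = np.linalg.norm(d)
        if norm == 0:
            out[v.id] = tuple(coord)
            continue
        d /= norm
        # march to the object's extreme end along the outward direction
        t = 0.0
        limit = 4.0 * float(dm[v.coordinate]) + 4.0
        while t < limit:
            p = coord + (t + 0.5) * d
            px = (int(round(p[0])), int(round(p[1])))
            if not (0 <= px[0] < mask.shape[0] and 0 <= px[1] < mask.shape[1]
                    and mask[px]):
                break
            t += 0.5
        tip = coord + (t - float(dm[v.coordinate])) * d
        out[v.id] = (float(tip[0]), float(tip[1]))
    return out


def terminal_spacing(g: SkeletonGraph,
                     extra_tips: list | None = None,
                     tip_coords: dict | None = None
                     ) -> list[SpacingMeasurement]:
    """bs: distance from each tip to the nearest other tip.

    ``extra_tips`` allows pooling tips of other components of the same
    image into the nearest-neighbour search; ``tip_coords`` substitutes
    refined coordinates (see :func:`refine_tip_coordinates`).
    """
    tip_coords = tip_coords or {}
    tips = [(v.id, tip_coords.get(v.id, v.coordinate)) for v in g.terminals]
    pool = tips + (extra_tips or [])
    if len(pool) < 2:
        warnings.warn("fewer than two terminals; no spacing measured")
        return []
    out = []
    for tid, coord in tips:
        best = min(((oid, _dist(coord, oc)) for oid, oc in pool
                    if (oid, oc) != (tid, coord)), key=lambda x: x[1])
        out.append(SpacingMeasurement(tid, best[0], best[1]))
    return out


def measure(binary: BinaryImage, g: SkeletonGraph,
            dm: np.ndarray | None = None,
            extra_tips: list | None = None) -> MeasurementSet:
    """Compute all six variables for one rooted graph."""
    if dm is None:
        dm = distance_map(binary)
    da = junction_thickness(dm, g)
    dc = terminal_thickness(dm, g)
    db = branch_thickness(dm, g, da, dc)
    tips = refine_tip_coordinates(binary, dm, g)
    return MeasurementSet(
        da=da, db=db, dc=dc,
        bl=branch_length(g),
        ba=branch_angle(g, db),
        bs=terminal_spacing(g, extra_tips=extra_tips, tip_coords=tips),
        pixel_scale=binary.pixel_scale,
    )


def merge_measurements(sets: list[MeasurementSet]) -> MeasurementSet:
    """Pool the measurements of several components of one image."""
    if not sets:
        return MeasurementSet()
    merged = MeasurementSet(pixel_scale=sets[0].pixel_scale)
    for ms in sets:
        for var in ("da", "db", "dc", "bl", "ba", "bs"):
            getattr(merged, var).extend(getattr(ms, var))
    return merged


def apply_scale(ms: MeasurementSet, pixel_scale: float) -> MeasurementSet:
    """Attach a physical pixel scale (units per px) to a measurement set.

    Scaled values become available through ``values(..., scaled=True)``
    and the data-frame export; pixel values are retained alongside and
    angles are unchanged.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be strictly positive")
    return replace(ms, pixel_scale=pixel_scale)


def to_dataframe(ms: MeasurementSet, image_id: str = "") -> pd.DataFrame:
    """Long-format table: one row per local measurement."""
    scale = ms.pixel_scale
    rows = []

    def add(variable, value_px, y, x, owner, flags=(), scaled_ok=True):
        scaled = (value_px * scale if (scale is not None and scaled_ok)
                  else (value_px if not scaled_ok else math.nan))
        rows.append({"image": image_id, "variable": variable,
                     "value_px": value_px, "value_scaled": scaled,
                     "y": y, "x": x, "owner": owner,
                     "flags": ";".join(flags)})

    for var in ("da", "db", "dc"):
        for m in getattr(ms, var):
            add(var, m.diameter_px, m.center[0], m.center[1], m.owner, m.flags)
    for m in ms.bl:
        add("bl_pixel", m.pixel_path_length, math.nan, math.nan, m.edge)
        add("bl_chord", m.chord_length, math.nan, math.nan, m.edge)
    for m in ms.ba:
        add("ba", m.degrees, math.nan, math.nan, m.junction, scaled_ok=False)
    for m in ms.bs:
        add("bs", m.distance_px, math.nan, math.nan, m.terminal)
    return pd.DataFrame(rows, columns=["image", "variable", "value_px",
                                       "value_scaled", "y", "x", "owner",
                                       "flags"])


def summary_row(ms: MeasurementSet, image_id: str = "") -> dict:
    """One summary row per image: the six per-variable means.

    Scaled units are used when a pixel scale is set, raw pixels
    otherwise; ``bl`` is the pixel-path mean, with the chord mean
    alongside.
    """
    scaled = ms.pixel_scale is not None
    means = ms.means(scaled=scaled)
    row = {"image": image_id}
    row.update({v: means[v] for v in VARIABLES})
    row["bl_chord"] = means["bl_chord"]
    row["pixel_scale"] = ms.pixel_scale if scaled else 1.0
    return row


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

#: Disc/line colours: da red, db gray, dc blue, length pink, angle blue,
#: spacing white.
MEASURE_COLORS = {
    "da": (230, 40, 40),
    "db": (140, 140, 140),
    "dc": (60, 90, 230),
    "bl": (255, 150, 200),
    "ba": (80, 160, 255),
    "bs": (255, 255, 255),
}


def save_measurement_overlay(binary: BinaryImage, skel: SkeletonImage,
                             ms: MeasurementSet, path: str | Path,
                             graphs: list[SkeletonGraph] | None = None) -> None:
    """RGB PNG with thickness discs and (if graphs given) spacing links."""
    h, w = binary.mask.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[binary.mask] = (247, 222, 77)
    img[skel.mask] = (0, 160, 0)
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)

    def circle(center, radius, color):
        y, x = center
        draw.ellipse([x - radius, y - radius, x + radius, y + radius],
                     outline=color)

    for kind in ("db", "da", "dc"):
        for m in getattr(ms, kind):
            circle(m.center, m.diameter_px / 2.0, MEASURE_COLORS[kind])
    if graphs:
        coords = {}
        for g in graphs:
            for v in g.terminals:
                coords[v.id] = v.coordinate
        for m in ms.bs:
            a = coords.get(m.terminal)
            b = coords.get(m.nearest)
            if a and b:
                draw.line([a[1], a[0], b[1], b[0]],
                          fill=MEASURE_COLORS["bs"], width=1)
    pil.save(path)
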
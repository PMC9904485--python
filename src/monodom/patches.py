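"""Delineation, filtering, merging, and tracking of monodominant patches.

A patch is the region where the focal-window BA intensity meets or exceeds
a site threshold (20 m² BA ha⁻¹ for well-developed monodominance, 10 for
younger sites).  Boundaries are marching-squares isolines of the intensity
surface, closed along the plot rectangle where they run off the edge.

Isolines are computed in the *cell-centre frame*: the surface is sampled at
cell centres, so interior isoline vertices live in
``[0.5, width-0.5] x [0.5, height-0.5]``.  Where the level set touches the
plot edge the polygon adopts the plot rectangle itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, MultiPolygon, box, mapping, shape
from shapely.ops import unary_union
from skimage import measure

from .stems import PlotGeometry
from .surfaces import BAGrid

__all__ = [
    "Patch",
    "PatchSet",
    "extract_isolines",
    "close_with_plot_boundary",
    "filter_and_merge",
    "track_across_censuses",
    "write_geojson",
    "read_geojson",
    "write_wkt",
]


@dataclass
class Patch:
    """One (possibly multipart) monodominant forest patch."""

    geometry: Polygon | MultiPolygon
    site: str = ""
    census: int | str = ""
    threshold: float = float("nan")
    id: int = -1

    @property
    def area(self) -> float:
        return self.geometry.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.geometry.centroid
        return (c.x, c.y)


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)
    site: str = ""
    census: int | str = ""
    threshold: float = float("nan")

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def total_area(self) -> float:
        return sum(p.area for p in self.patches)


def extract_isolines(grid: BAGrid, level: float) -> list[np.ndarray]:
    """Marching-squares contours of the (un-padded) surface at ``level``.

    Returns arrays of projected ``(easting, northing)`` vertices, linearly
    interpolated along cell edges.  Contours touching the sampling-frame
    edge come back open.  Ties (cells exactly at the level) count as
    inside.  A constant surface yields no contours (with a warning).
    """
    values = grid.interior
    if values.min() == values.max():
        import warnings

        warnings.warn("constant surface: no isolines")
        return []
    contours = measure.find_contours(values, level, positive_orientation="high")
    cs = grid.cell_size
    e0, n0 = grid.origin
    out = []
    for c in contours:
        xy = np.empty_like(c)
        xy[:, 0] = e0 + (c[:, 1] + 0.5) * cs   # easting from column
        xy[:, 1] = n0 + (c[:, 0] + 0.5) * cs   # northing from row
        out.append(xy)
    return out


def _rings_at_level(grid: BAGrid, level: float, plot: PlotGeometry) -> list[np.ndarray]:
    """Closed rings of the >= level region, adopting the plot boundary.

    The surface is wrapped in a one-cell ring sitting just outside the
    plot at a value strictly below ``level``; every contour then closes.
    Vertices produced by crossings into that artificial ring (those beyond
    the outermost line of real cell centres) are snapped outward onto the
    plot rectangle.
    """
    values = grid.interior
    drop = max(float(values.max() - values.min()), abs(level), 1.0)
    padded = np.pad(values, 1, mode="constant", constant_values=level - 2 * drop)
    contours = measure.find_contours(padded, level, positive_orientation="high")
    cs = grid.cell_size
    ny, nx = values.shape
    w, h = nx * cs, ny * cs
    rings = []
    for c in contours:
        x = (c[:, 1] - 1 + 0.5) * cs
        y = (c[:, 0] - 1 + 0.5) * cs
        # crossings beyond the outer cell-centre line are pad artifacts:
        # adopt the plot boundary there
        eps = 1e-9
        x = np.where(x < 0.5 * cs - eps, 0.0, x)
        x = np.where(x > w - 0.5 * cs + eps, w, x)
        y = np.where(y < 0.5 * cs - eps, 0.0, y)
        y = np.where(y > h - 0.5 * cs + eps, h, y)
        ring = np.column_stack([x + plot.origin_easting, y + plot.origin_northing])
        rings.append(ring)
    return rings


def close_with_plot_boundary(
    grid: BAGrid,
    level: float,
    plot: PlotGeometry,
    site: str = "",
    census: int | str = "",
    keep_holes: bool = True,
) -> PatchSet:
    """Polygonise the >= level region into singlepart patches.

    Interior below-level pockets become holes (optionally filled with
    ``keep_holes=False``).  Degenerate rings (< 3 distinct vertices or zero
    area) are dropped with a warning.
    """
    rings = _rings_at_level(grid, level, plot)
    polys = []
    for ring in rings:
        if len(np.unique(ring.round(9), axis=0)) < 3:
            import warnings

            warnings.warn("dropping degenerate contour with <3 distinct vertices")
            continue
        p = Polygon(ring)
        if not p.is_valid:
            p = p.buffer(0)
        if p.area > 0:
            polys.append(p)
    # nesting depth decides shell vs hole
    polys.sort(key=lambda p: p.area, reverse=True)
    depth = []
    for i, p in enumerate(polys):
        pt = p.representative_point()
        depth.append(sum(1 for q in polys[:i] if q.contains(pt)))
    shells = [(i, p) for i, (p, d) in enumerate(zip(polys, depth)) if d % 2 == 0]
    geom_parts = []
    for i, shell in shells:
        holes = []
        if keep_holes:
            for p, d in zip(polys, depth):
                if d == depth[i] + 1 and shell.contains(p.representative_point()):
                    holes.append(p.exterior.coords)
        geom_parts.append(Polygon(shell.exterior.coords, holes))
    rect = box(plot.origin_easting, plot.origin_northing,
               plot.origin_easting + plot.width, plot.origin_northing + plot.height)
    patches = []
    for g in geom_parts:
        g = g.intersection(rect)
        if g.is_empty:
            continue
        parts = g.geoms if isinstance(g, MultiPolygon) else [g]
        for part in parts:
            if part.area > 0:
                patches.append(Patch(part, site, census, level))
    patches.sort(key=lambda p: p.area, reverse=True)
    for k, p in enumerate(patches):
        p.id = k
    return PatchSet(patches, site, census, level)


def filter_and_merge(
    patchset: PatchSet,
    min_area: float = 300.0,
    isolation: float = 30.0,
) -> PatchSet:
    """Reduce a patch set to the established, spatially unique patch units.

    Patches below ``min_area`` m² are discarded (transient spurious
    features).  Remaining patches whose boundary-to-boundary distance is
    less than ``isolation`` m are functionally one unit (seed rain bridges
    the gap) and are merged into a single, possibly multipart, patch.
    Idempotent.
    """
    kept = [p for p in patchset.patches if p.area >= min_area]
    n = len(kept)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if kept[i].geometry.distance(kept[j].geometry) < isolation:
                parent[find(i)] = find(j)
    groups: dict[int, list[Patch]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(kept[i])
    merged = []
    for members in groups.values():
        geom = unary_union([m.geometry for m in members])
        merged.append(Patch(geom, patchset.site, patchset.census, patchset.threshold))
    merged.sort(key=lambda p: p.area, reverse=True)
    for k, p in enumerate(merged):
        p.id = k
    return PatchSet(merged, patchset.site, patchset.census, patchset.threshold)


def track_across_censuses(
    set_t1: PatchSet, set_t3: PatchSet
) -> tuple[list[tuple[Patch, Patch]], list[Patch], list[Patch]]:
    """Pair patches across censuses by maximal polygon-intersection area.

    Returns ``(pairs, unmatched_t1, unmatched_t3)``.  Greedy one-to-one
    assignment in descending overlap order; an exact tie between candidate
    assignments raises with the candidates listed.
    """
    if set_t1.site != set_t3.site or set_t1.threshold != set_t3.threshold:
        raise ValueError("patch sets come from different sites or thresholds")
    overlaps = []
    for i, p1 in enumerate(set_t1.patches):
        for j, p3 in enumerate(set_t3.patches):
            a = p1.geometry.intersection(p3.geometry).area
            if a > 0:
                overlaps.append((a, i, j))
    overlaps.sort(reverse=True)
    used1, used3, pairs = set(), set(), []
    k = 0
    while k < len(overlaps):
        a, i, j = overlaps[k]
        if i not in used1 and j not in used3:
            ties = [(ii, jj) for (aa, ii, jj) in overlaps[k + 1:]
                    if aa == a and (ii == i) != (jj == j)
                    and ii not in used1 and jj not in used3]
            if ties:
                raise ValueError(
                    f"ambiguous tracking tie: overlap {a} for ({i},{j}) and {ties}")
            pairs.append((set_t1.patches[i], set_t3.patches[j]))
            used1.add(i)
            used3.add(j)
        k += 1
    un1 = [p for i, p in enumerate(set_t1.patches) if i not in used1]
    un3 = [p for j, p in enumerate(set_t3.patches) if j not in used3]
    return pairs, un1, un3


def write_geojson(patchset: PatchSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {
                "site": p.site, "census": p.census,
                "threshold": p.threshold, "id": p.id, "area_m2": p.area,
            },
        }
        for p in patchset.patches
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_wkt(patchset: PatchSet, path) -> None:
    """One WKT geometry per line, prefixed by the patch id."""
    with open(path, "w") as fh:
        for p in patchset.patches:
            fh.write(f"{p.id}\t{p.geometry.wkt}\n")


def read_geojson(path) -> PatchSet:
    with open(path) as fh:
        fc = json.load(fh)
    patches = []
    site, census, threshold = "", "", float("nan")
    for f in fc["features"]:
        pr = f["properties"]
        site, census, threshold = pr["site"], pr["census"], pr["threshold"]
        patches.append(Patch(shape(f["geometry"]), site, census, threshold, pr["id"]))
    return PatchSet(patches, site, census, threshold)
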
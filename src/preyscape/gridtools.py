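"""Small shared grid helpers (contour extraction, ring assembly)."""

from __future__ import annotations

import numpy as np
from contourpy import LineType, contour_generator
from shapely.geometry import Polygon

__all__ = ["contour_polylines", "rings_to_polygons"]


def contour_polylines(x: np.ndarray, y: np.ndarray, z: np.ndarray, level: float):
    """Iso-level polylines of ``z`` sampled on the ``x`` by ``y`` grid.

    ``z`` has shape ``(x.size, y.size)``; returns a list of ``(k, 2)``
    arrays of (x, y) vertices.
    """
    cg = contour_generator(
        x=x, y=y, z=np.asarray(z).T, line_type=LineType.Separate
    )
    return [np.asarray(line) for line in cg.lines(level)]


def rings_to_polygons(lines) -> list:
    """Assemble closed contour rings into shapely polygons with holes.

    Rings nested at odd depth become holes of their smallest enclosing
    ring. Open polylines (grid-boundary intersections) are closed
    naively; callers should pad grids so isopleths stay interior.
    """
    rings = [Polygon(ln) for ln in lines if len(ln) >= 4]
    rings = [r if r.is_valid else r.buffer(0) for r in rings]
    rings = [r for r in rings if not r.is_empty and r.area > 0]
    rings.sort(key=lambda r: r.area, reverse=True)
    keep, holes = [], {i: [] for i in range(len(rings))}
    parent = [None] * len(rings)
    for i, r in enumerate(rings):
        # smallest ring strictly containing r
        for j in range(i - 1, -1, -1):
            if rings[j].contains(r.representative_point()) and rings[j].area > r.area:
                parent[i] = j
                break
        depth = 0
        p = parent[i]
        while p is not None:
            depth += 1
            p = parent[p]
        if depth % 2 == 0:
            keep.append(i)
        else:
            holes[parent[i]].append(i)
    out = []
    for i in keep:
        ext = rings[i].exterior.coords
        ints = [rings[k].exterior.coords for k in holes[i]]
        out.append(Polygon(ext, ints))
    return out
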
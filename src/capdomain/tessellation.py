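"""Capillary-domain ("trapping region") tessellation.

Each capillary's domain is the set of tissue points closer to it than
to any other capillary — the Voronoi cell of the capillary — clipped to
the rectangular sampling frame. Domains tile the frame exactly, so
their areas sum to the frame area; this conservation property is the
main internal consistency check.

Unbounded Voronoi cells are avoided by reflecting every site across
the four frame edges before triangulation: for any point inside the
frame the nearest site is always an original (not a mirror), so the
cells of the original sites, clipped to the frame, partition it.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .datatypes import CapillaryMap, DomainTessellation, ValidationError

_EDGE_TOL = 1e-9  # um; tolerance for flagging frame-edge contact


def tessellate(cmap: CapillaryMap) -> DomainTessellation:
    """Voronoi tessellation of the frame with capillaries as sites.

    Returns one simple polygon per capillary, clipped to the frame
    rectangle, with exact polygon areas. A single capillary yields a
    degenerate tessellation equal to the whole frame.
    """
    n = cmap.n_capillaries
    if n == 0:
        raise ValidationError("cannot tessellate a frame with zero capillaries")
    W, H = cmap.frame_width, cmap.frame_height
    frame = box(0.0, 0.0, W, H)

    if n == 1:
        return DomainTessellation(
            domains=[frame],
            areas=np.array([frame.area]),
            boundary_flags=np.array([True]),
            source_index=np.array([0]),
            frame_width=W,
            frame_height=H,
        )

    pts = cmap.capillaries
    mirrored = np.vstack(
        [
            pts,
            pts * [-1, 1],                      # across x = 0
            pts * [1, -1],                      # across y = 0
            np.column_stack([2 * W - pts[:, 0], pts[:, 1]]),  # across x = W
            np.column_stack([pts[:, 0], 2 * H - pts[:, 1]]),  # across y = H
        ]
    )
    vor = Voronoi(mirrored)

    domains: list[Polygon] = []
    areas = np.empty(n)
    flags = np.empty(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:  # pragma: no cover - mirrors bound cells
            raise RuntimeError(f"unbounded Voronoi cell for capillary {i}")
        cell = Polygon(vor.vertices[region])
        clipped = cell.intersection(frame)
        if clipped.is_empty or clipped.geom_type != "Polygon":
            raise RuntimeError(f"degenerate clipped domain for capillary {i}")
        domains.append(clipped)
        areas[i] = clipped.area
        xs, ys = clipped.exterior.coords.xy
        xs, ys = np.asarray(xs), np.asarray(ys)
        flags[i] = bool(
            np.any(xs < _EDGE_TOL)
            or np.any(xs > W - _EDGE_TOL)
            or np.any(ys < _EDGE_TOL)
            or np.any(ys > H - _EDGE_TOL)
        )

    return DomainTessellation(
        domains=domains,
        areas=areas,
        boundary_flags=flags,
        source_index=np.arange(n),
        frame_width=W,
        frame_height=H,
    )


def assign_pixels_bruteforce(cmap: CapillaryMap, resolution: float) -> np.ndarray:
    """Label a raster of the frame with the nearest capillary index.

    The grid has square cells of side ``resolution`` (um), cell centres
    at ``(i + 0.5) * resolution``; each cell is labelled with the index
    of the Euclidean-nearest capillary. Equidistant ties go to the
    lowest capillary index. Serves as the brute-force oracle for the
    polygon tessellation (label counts x cell area ~ polygon areas).

    Returns an array of shape (ny, nx); row 0 is the bottom of the frame.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    if cmap.n_capillaries == 0:
        raise ValidationError("no capillaries to assign")
    nx = int(round(cmap.frame_width / resolution))
    ny = int(round(cmap.frame_height / resolution))
    xc = (np.arange(nx) + 0.5) * resolution
    yc = (np.arange(ny) + 0.5) * resolution
    XX, YY = np.meshgrid(xc, yc)
    centres = np.column_stack([XX.ravel(), YY.ravel()])
    tree = cKDTree(cmap.capillaries)
    dist, idx = tree.query(centres, k=1)
    # resolve near-ties deterministically in favour of the lowest index
    k2 = min(2, cmap.n_capillaries)
    if k2 == 2:
        d2, i2 = tree.query(centres, k=2)
        tied = np.isclose(d2[:, 0], d2[:, 1], rtol=0.0, atol=1e-9)
        idx[tied] = np.minimum(i2[tied, 0], i2[tied, 1])
    return idx.reshape(ny, nx)


def raster_areas(labels: np.ndarray, resolution: float, n_sites: int) -> np.ndarray:
    """Per-site domain areas (um^2) implied by a nearest-site label grid."""
    counts = np.bincount(labels.ravel(), minlength=n_sites)
    return counts * resolution**2
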
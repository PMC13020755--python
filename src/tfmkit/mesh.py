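"""Cell masks and their triangulation for the monolayer stress solve.

The mask boundary is extracted as a polygon (holes preserved), resampled
at the target edge length, and the interior is filled with a hexagonal
point lattice; a Delaunay triangulation restricted to the polygon gives
a conforming, well-shaped mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from scipy import ndimage as ndi

__all__ = ["CellMask", "Mesh", "segment_mask", "build_mesh", "mesh_polygon"]

MAX_TRIANGLES = 400_000


@dataclass
class CellMask:
    """Binary cell-occupancy mask with its pixel size (µm/px)."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area(self) -> float:
        """Mask area in µm²."""
        return float(self.mask.sum()) * self.pixel_size**2


def segment_mask(
    cell_image: np.ndarray,
    pixel_size: float,
    threshold_mode: str | float = "otsu",
) -> CellMask:
    """Threshold-segment a cell image into a cleaned binary mask.

    Otsu (or a fixed numeric) threshold, morphological closing, hole
    filling, and retention of the largest connected component.  A boolean
    input image is validated and passed through the same cleanup.
    """
    img = np.asarray(cell_image)
    if img.dtype == bool:
        binary = img
    else:
        img = img.astype(float)
        if threshold_mode == "otsu":
            if img.max() == img.min():
                raise ValueError("constant image: cannot threshold")
            thr = threshold_otsu(img)
        else:
            thr = float(threshold_mode)
        binary = img > thr
    if not binary.any():
        raise ValueError("empty mask after thresholding")
    binary = morphology.binary_closing(binary, morphology.disk(2))
    binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary)
    if n > 1:
        sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    return CellMask(binary, pixel_size)


@dataclass
class Mesh:
    """Triangle mesh: ``nodes`` (N, 2) in µm, ``triangles`` (M, 3) node
    index triplets (positively oriented), ``boundary_edges`` (B, 2)."""

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    target_edge_length: float
    _delaunay: Delaunay | None = dc_field(default=None, repr=False)
    _simplex_map: np.ndarray | None = dc_field(default=None, repr=False)

    def areas(self) -> np.ndarray:
        """Signed triangle areas (µm²); positive for valid meshes."""
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    @property
    def area(self) -> float:
        return float(self.areas().sum())

    def node_areas(self) -> np.ndarray:
        """Lumped nodal areas (one third of each adjacent triangle)."""
        a = self.areas()
        out = np.zeros(len(self.nodes))
        for j in range(3):
            np.add.at(out, self.triangles[:, j], a / 3.0)
        return out

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Find containing triangles and barycentric weights.

        Returns ``(tri_index, bary)`` with ``tri_index = -1`` for points
        outside the mesh; ``bary`` has shape (n, 3).  Meshes built by
        :func:`mesh_polygon` use their Delaunay structure; others (e.g.
        deformed copies) fall back to a KD-tree candidate search.
        """
        if self._delaunay is None or self._simplex_map is None:
            return self._locate_kdtree(np.atleast_2d(points))
        points = np.atleast_2d(points)
        simplex = self._delaunay.find_simplex(points)
        tri = np.where(simplex >= 0, self._simplex_map[np.maximum(simplex, 0)], -1)
        bary = np.zeros((len(points), 3))
        ok = tri >= 0
        if ok.any():
            T = self._delaunay.transform[simplex[ok]]
            b = np.einsum(
                "nij,nj->ni", T[:, :2], points[ok] - T[:, 2]
            )
            bary[ok, :2] = b
            bary[ok, 2] = 1.0 - b.sum(axis=1)
            # map delaunay vertex order to mesh triangle vertex order
            dver = self._delaunay.simplices[simplex[ok]]
            mver = self.triangles[tri[ok]]
            # permutation: bary weight of delaunay vertex dver[k] belongs to
            # the matching position in mver
            perm = np.argmax(dver[:, :, None] == mver[:, None, :], axis=2)
            out = np.zeros_like(bary[ok])
            np.put_along_axis(out, perm, bary[ok], axis=1)
            bary[ok] = out
        return tri, bary

    def _locate_kdtree(
        self, points: np.ndarray, k: int = 16, tol: float = 1e-9
    ) -> tuple[np.ndarray, np.ndarray]:
        from scipy.spatial import cKDTree

        cent = self.nodes[self.triangles].mean(axis=1)
        kq = min(k, len(cent))
        _, cand = cKDTree(cent).query(points, k=kq)
        cand = np.atleast_2d(cand)
        p = self.nodes[self.triangles]  # (M, 3, 2)
        tri_out = np.full(len(points), -1, dtype=int)
        bary_out = np.zeros((len(points), 3))
        todo = np.arange(len(points))
        for j in range(cand.shape[1]):
            if not len(todo):
                break
            t = cand[todo, j]
            a, b, c = p[t, 0], p[t, 1], p[t, 2]
            d = points[todo]
            det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (
                b[:, 1] - a[:, 1]
            )
            w1 = ((d[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (d[:, 1] - a[:, 1])) / det
            w2 = ((b[:, 0] - a[:, 0]) * (d[:, 1] - a[:, 1]) - (d[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])) / det
            w0 = 1.0 - w1 - w2
            hit = (w0 >= -tol) & (w1 >= -tol) & (w2 >= -tol)
            idx = todo[hit]
            tri_out[idx] = t[hit]
            bary_out[idx] = np.column_stack([w0[hit], w1[hit], w2[hit]])
            todo = todo[~hit]
        return tri_out, bary_out


def _resample_ring(coords: np.ndarray, step: float) -> np.ndarray:
    """Resample a closed ring at (approximately) equal arclength ``step``."""
    coords = np.asarray(coords)
    if np.allclose(coords[0], coords[-1]):
        coords = coords[:-1]
    closed = np.vstack([coords, coords[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(8, int(round(total / step)))
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def mask_to_polygon(mask: CellMask, smooth: bool = True) -> Polygon:
    """Extract the mask boundary (holes included) as a shapely polygon in
    µm coordinates; lightly simplified to remove pixel staircasing."""
    padded = np.pad(mask.mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no boundary contour found")
    rings = []
    for c in contours:
        xy = np.column_stack([c[:, 1] - 1, c[:, 0] - 1]) * mask.pixel_size
        poly = Polygon(xy)
        if poly.is_valid and poly.area > 0:
            rings.append(poly)
    rings.sort(key=lambda p: p.area, reverse=True)
    exterior = rings[0]
    holes = [r.exterior.coords for r in rings[1:] if exterior.contains(r.representative_point())]
    poly = Polygon(exterior.exterior.coords, holes)
    if smooth:
        poly = poly.simplify(0.5 * mask.pixel_size)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def mesh_polygon(poly: Polygon, target_edge_length: float) -> Mesh:
    """Triangulate a polygon with a hexagonal interior lattice and
    boundary nodes resampled at the target edge length."""
    h = float(target_edge_length)
    est = poly.area / (0.43 * h**2)
    if est > MAX_TRIANGLES:
        raise ValueError(
            f"target_edge_length {h} would produce ~{int(est)} triangles "
            f"(limit {MAX_TRIANGLES}); increase the edge length"
        )
    boundary_pts = [_resample_ring(np.asarray(poly.exterior.coords), h)]
    for ring in poly.interiors:
        boundary_pts.append(_resample_ring(np.asarray(ring.coords), h))
    boundary = np.vstack(boundary_pts)

    minx, miny, maxx, maxy = poly.bounds
    dy = h * np.sqrt(3.0) / 2.0
    ys = np.arange(miny, maxy + dy, dy)
    rows = []
    for i, y in enumerate(ys):
        xs = np.arange(minx + (0.5 * h if i % 2 else 0.0), maxx + h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
    lattice = np.vstack(rows)
    inner = poly.buffer(-0.55 * h)
    if not inner.is_empty:
        keep = shapely.contains_xy(inner, lattice[:, 0], lattice[:, 1])
        interior = lattice[keep]
    else:
        interior = np.empty((0, 2))

    pts = np.vstack([boundary, interior])
    dela = Delaunay(pts)
    cent = pts[dela.simplices].mean(axis=1)
    inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    tri = dela.simplices[inside]

    # orient positively and drop degenerate slivers
    p = pts[tri]
    a2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = a2 < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    good = np.abs(a2) > 1e-9 * h**2
    tri = tri[good]

    simplex_map = np.full(len(dela.simplices), -1, dtype=int)
    simplex_map[np.flatnonzero(inside)[good]] = np.arange(len(tri))

    edges = np.sort(
        np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = uniq[counts == 1]

    return Mesh(
        nodes=pts,
        triangles=tri,
        boundary_edges=boundary_edges,
        target_edge_length=h,
        _delaunay=dela,
        _simplex_map=simplex_map,
    )


def build_mesh(mask: CellMask, target_edge_length: float) -> Mesh:
    """Conforming triangulation of a cell mask.

    ``target_edge_length`` (µm) must exceed twice the pixel size; the
    resulting mesh area tracks the mask area (boundary nodes sit on the
    extracted, lightly smoothed mask contour).
    """
    if not target_edge_length > 2.0 * mask.pixel_size:
        raise ValueError("target_edge_length must exceed 2 x pixel_size")
    poly = mask_to_polygon(mask)
    return mesh_polygon(poly, target_edge_length)
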
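"""Synthetic ground-truth scenarios for end-to-end validation.

Four generators cover the full pipeline:

* contractile force-dipole traction fields on a linear elastic substrate
  (mimicking a cell doublet on an H-shaped micropattern), with forward-
  simulated displacements and rendered/warped bead images;
* a parametric fluorescent-bead image renderer (Gaussian spots with
  Poisson + Gaussian camera noise);
* a uniformly edge-loaded square plate whose interior sheet stress is
  known in closed form;
* an actively contracting elastic cell adhering to the substrate at
  discrete peripheral islands, solved by FEM (the constitutive law is
  linear plane stress plus an isotropic active contractile stress, and
  force balance couples the sheet divergence to elastic-foundation
  springs at the adhesive islands).

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import shapely
from shapely.geometry import Point
from shapely.geometry import Polygon as ShapelyPolygon

from .displacement import BeadImagePair
from .fields import ElasticSubstrate, VectorField2D
from .fttc import forward_displacement
from .mesh import CellMask, Mesh, mesh_polygon
from .msm import StressField, _element_B, _plane_stress_D

__all__ = [
    "DipoleScenario",
    "ValidationScenario",
    "ActiveCellParams",
    "ActiveCellResult",
    "PlateCase",
    "make_dipole_traction",
    "render_bead_image",
    "warp_image",
    "make_dipole_scenario",
    "square_plate_case",
    "simulate_active_cell",
    "SCENARIO_FORCES_UN",
]

UM = 1e-6

#: total dipole force (µN) of the three standard validation conditions
SCENARIO_FORCES_UN = {"low": 0.0025, "mid": 0.025, "high": 0.25}


@dataclass(frozen=True)
class DipoleScenario:
    """Two 90°-rotated contractile force dipoles with a common center.

    Each dipole consists of two circular force regions of
    ``region_radius`` (µm) separated by ``pole_separation`` (µm), with
    uniform traction pointing inward along the dipole axis; the force
    integrated over one disk is ``total_force / 2`` (µN), so the
    assembled field is exactly force-free.
    """

    total_force: float = 0.025  # µN
    region_radius: float = 3.0  # µm
    pole_separation: float = 30.0  # µm
    angle: float = 0.0  # radians, axis of the first dipole
    center: tuple[float, float] | None = None  # µm; default: grid center
    substrate: ElasticSubstrate = field(default_factory=ElasticSubstrate)


def make_dipole_traction(
    spec: DipoleScenario, shape: tuple[int, int], spacing: float
) -> tuple[VectorField2D, np.ndarray]:
    """Rasterize the dipole traction field onto a regular grid.

    Returns the traction field (Pa) and the boolean mask of the four
    force-bearing disks.  Per-disk traction is uniform and scaled so the
    integrated force magnitude per disk equals ``total_force / 2`` µN
    exactly on the discrete grid; opposite poles share the same
    magnitude, so the net force is zero to round-off.
    """
    ny, nx = shape
    cx, cy = spec.center if spec.center is not None else (
        (nx - 1) / 2.0 * spacing,
        (ny - 1) / 2.0 * spacing,
    )
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    xx, yy = np.meshgrid(x, y)

    poles = []
    for k in range(2):
        th = spec.angle + k * np.pi / 2.0
        ax = np.array([np.cos(th), np.sin(th)])
        ax[np.abs(ax) < 1e-12] = 0.0  # exact axis alignment
        for sign in (+1.0, -1.0):
            pos = np.array([cx, cy]) + sign * 0.5 * spec.pole_separation * ax
            poles.append((pos, -sign * ax))  # traction points inward

    for i in range(len(poles)):
        for j in range(i + 1, len(poles)):
            if np.linalg.norm(poles[i][0] - poles[j][0]) < 2 * spec.region_radius:
                raise ValueError("force regions overlap")

    tx = np.zeros(shape)
    ty = np.zeros(shape)
    disk_mask = np.zeros(shape, dtype=bool)
    f_pole = 0.5 * spec.total_force * 1e-6  # N per disk
    cell_area = (spacing * UM) ** 2
    for pos, direction in poles:
        disk = (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2 <= spec.region_radius**2
        n_cells = int(disk.sum())
        if n_cells == 0:
            raise ValueError("grid does not resolve the force regions")
        mag = f_pole / (n_cells * cell_area)  # Pa
        tx[disk] += mag * direction[0]
        ty[disk] += mag * direction[1]
        disk_mask |= disk

    fld = VectorField2D(tx, ty, spacing, "Pa", {"scenario": spec})
    return fld, disk_mask


def render_bead_image(
    shape: tuple[int, int],
    pixel_size: float,
    density: float = 1.0,
    psf_sigma: float = 0.15,
    amplitude: float = 8000.0,
    background: float = 100.0,
    read_noise: float = 10.0,
    noise_model: str = "poisson-gaussian",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render a synthetic fluorescent-bead image.

    Beads are Gaussian spots (``psf_sigma`` in µm) at uniform random
    positions with Poisson-drawn count ``density`` (beads/µm²) × area,
    on a constant background, corrupted by Poisson shot noise plus
    Gaussian read noise (16-bit-camera-like counts).  Reproducible under
    a fixed ``rng`` seed.
    """
    if not density >= 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(rng)
    ny, nx = shape
    area = ny * nx * pixel_size**2
    n_beads = rng.poisson(density * area)
    img = np.full(shape, float(background))
    sig_px = psf_sigma / pixel_size
    half = max(2, int(np.ceil(4 * sig_px)))
    if n_beads:
        pos = rng.uniform(0, [ny, nx], size=(n_beads, 2))
        amps = amplitude * rng.uniform(0.5, 1.0, size=n_beads)
        for (py, px), a in zip(pos, amps):
            y0, y1 = max(0, int(py) - half), min(ny, int(py) + half + 1)
            x0, x1 = max(0, int(px) - half), min(nx, int(px) + half + 1)
            yy = np.arange(y0, y1)[:, None] - py
            xx = np.arange(x0, x1)[None, :] - px
            img[y0:y1, x0:x1] += a * np.exp(-(yy**2 + xx**2) / (2 * sig_px**2))
    if noise_model == "poisson-gaussian":
        img = rng.poisson(img).astype(float) + rng.normal(0.0, read_noise, shape)
        img = np.clip(img, 0.0, 65535.0)
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")
    return img


def warp_image(
    image: np.ndarray, disp: VectorField2D, n_invert: int = 3
) -> np.ndarray:
    """Deform an image by a pixel-valued displacement field.

    Backward warping with cubic interpolation: a bead imaged at relaxed
    position X appears at X + u(X) in the output ("tensed") image, i.e.
    ``out(x) = image(X(x))`` with ``X + u(X) = x``.  The inverse map is
    found by ``n_invert`` fixed-point iterations ``X ← x − u(X)``
    (``n_invert=0`` gives the common first-order approximation
    ``image(x − u(x))``).
    """
    if disp.shape != image.shape:
        raise ValueError("displacement and image shapes differ")
    if not (np.isfinite(disp.u).all() and np.isfinite(disp.v).all()):
        raise ValueError("displacement contains non-finite values")
    ny, nx = image.shape
    xx, yy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    Xx, Xy = xx - disp.u, yy - disp.v
    for _ in range(n_invert):
        ux = ndi.map_coordinates(disp.u, [Xy, Xx], order=1, mode="nearest")
        uy = ndi.map_coordinates(disp.v, [Xy, Xx], order=1, mode="nearest")
        Xx, Xy = xx - ux, yy - uy
    return ndi.map_coordinates(image, [Xy, Xx], order=3, mode="nearest")


@dataclass
class ValidationScenario:
    """Ground-truth bundle for end-to-end scoring."""

    name: str
    gt_traction: VectorField2D  # Pa
    gt_displacement: VectorField2D  # px
    force_mask: np.ndarray  # bool, force-bearing disks
    bead_pair: BeadImagePair
    substrate: ElasticSubstrate
    pixel_size: float
    seed: int | None = None


def make_dipole_scenario(
    level: str | float = "mid",
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.108,
    seed: int | None = 0,
    density: float = 1.0,
    psf_sigma: float = 0.15,
    spec: DipoleScenario | None = None,
    **bead_kwargs,
) -> ValidationScenario:
    """Build a complete dipole validation scenario.

    ``level`` is one of ``"low"/"mid"/"high"`` (total force 0.0025 /
    0.025 / 0.25 µN) or a numeric total force in µN.  The ground-truth
    displacement is the exact forward solution of the traction field on
    the substrate (E = 20 kPa, ν = 0.5 by default); the tensed bead image
    is the relaxed image warped by that field.
    """
    if isinstance(level, str):
        force = SCENARIO_FORCES_UN[level]
        name = f"dipole-{level}"
    else:
        force = float(level)
        name = f"dipole-{force:g}uN"
    if spec is None:
        spec = DipoleScenario(total_force=force)
    else:
        spec = replace(spec, total_force=force)

    traction, disk_mask = make_dipole_traction(spec, shape, pixel_size)
    disp_um = forward_displacement(traction, spec.substrate)
    disp_px = VectorField2D(
        disp_um.u / pixel_size, disp_um.v / pixel_size, pixel_size, "px"
    )
    rng = np.random.default_rng(seed)
    relaxed = render_bead_image(
        shape, pixel_size, density=density, psf_sigma=psf_sigma, rng=rng, **bead_kwargs
    )
    tensed = warp_image(relaxed, disp_px)
    # camera noise is independent between the two acquisitions
    tensed = np.clip(
        rng.poisson(np.maximum(tensed, 0.0)).astype(float)
        + rng.normal(0.0, bead_kwargs.get("read_noise", 10.0), shape),
        0.0,
        65535.0,
    )
    pair = BeadImagePair(tensed=tensed, relaxed=relaxed, pixel_size=pixel_size)
    return ValidationScenario(
        name, traction, disp_px, disk_mask, pair, spec.substrate, pixel_size, seed
    )


@dataclass
class PlateCase:
    """Uniformly edge-loaded square plate with its analytic solution."""

    traction: VectorField2D  # Pa
    mask: CellMask
    load: float  # N/m line load on each edge
    x_edges: tuple[float, float]  # µm, outer cell-boundary positions
    y_edges: tuple[float, float]

    def analytic_stress(self, points: np.ndarray) -> np.ndarray:
        """Analytic (σxx, σyy, σxy) at given (x, y) µm points.

        σxx ramps linearly from 0 to the line load across the one-cell
        edge bands and is constant inside; likewise σyy; σxy = 0.
        """
        d = self.traction.spacing
        x, y = points[:, 0], points[:, 1]
        xl, xr = self.x_edges
        yl, yr = self.y_edges
        rx = np.clip((x - xl) / d, 0, 1) * np.clip((xr - x) / d, 0, 1)
        ry = np.clip((y - yl) / d, 0, 1) * np.clip((yr - y) / d, 0, 1)
        # stress exists only where plate material exists
        in_x = (x > xl) & (x < xr)
        in_y = (y > yl) & (y < yr)
        return np.column_stack(
            [self.load * rx * in_y, self.load * ry * in_x, np.zeros_like(x)]
        )


def square_plate_case(
    side: float = 60.0,
    load: float = 1e-3,
    shape: tuple[int, int] = (128, 128),
    spacing: float = 1.0,
) -> PlateCase:
    """Square plate under uniform inward edge loading.

    ``load`` is the line load (N/m) applied along each edge, realized as
    inward-pointing uniform traction bands one grid cell wide.  The
    resulting interior sheet stress is constant, σxx = σyy = ``load``
    (tension positive), σxy = 0.
    """
    if not side > 0:
        raise ValueError("side must be positive")
    ny, nx = shape
    n_side = int(round(side / spacing))
    i0x = (nx - n_side) // 2
    i0y = (ny - n_side) // 2
    i1x, i1y = i0x + n_side - 1, i0y + n_side - 1
    if i0x < 1 or i0y < 1:
        raise ValueError("plate does not fit in the grid")

    t_band = load / (spacing * UM)  # Pa across a one-cell band
    tx = np.zeros(shape)
    ty = np.zeros(shape)
    tx[i0y : i1y + 1, i0x] = +t_band
    tx[i0y : i1y + 1, i1x] = -t_band
    ty[i0y, i0x : i1x + 1] = +t_band
    ty[i1y, i0x : i1x + 1] = -t_band

    mask = np.zeros(shape, dtype=bool)
    mask[i0y : i1y + 1, i0x : i1x + 1] = True
    traction = VectorField2D(tx, ty, spacing, "Pa")
    return PlateCase(
        traction=traction,
        mask=CellMask(mask, spacing),
        load=load,
        x_edges=((i0x - 0.5) * spacing, (i1x + 0.5) * spacing),
        y_edges=((i0y - 0.5) * spacing, (i1y + 0.5) * spacing),
    )


@dataclass(frozen=True)
class ActiveCellParams:
    """Parameters of the active elastic cell model.

    The cell sheet (Young's modulus ``Ec`` Pa, Poisson ratio ``nuc``,
    contractile thickness ``hc`` µm) carries an isotropic active stress
    ``hc·Ec/(2(1−nuc)) · P0`` and adheres to the substrate through an
    elastic foundation of spring-stiffness density ``Ys`` (Pa/µm),
    nonzero only on ``n_islands`` circular adhesive islands of radius
    ``island_radius`` placed on a ring at ``island_ring_frac`` of the
    cell radius.  Defaults are representative of contour-model studies
    of strongly adherent contractile cells, not canonical values.
    """

    Ec: float = 10_000.0
    nuc: float = 0.5
    hc: float = 1.0
    P0: float = 0.6
    Ys: float = 1_000.0
    radius: float = 25.0
    n_islands: int = 19
    island_radius: float = 2.5
    island_ring_frac: float = 0.9


@dataclass
class ActiveCellResult:
    """Converged state of the active-cell FEM simulation."""

    mesh: Mesh  # reference (undeformed) configuration, µm
    displacement: np.ndarray  # (N, 2) nodal displacement, µm
    stress: StressField  # internal sheet stress, N/m
    traction: VectorField2D  # Ys·u rasterized on a grid, Pa
    cell_mask: CellMask
    island_centers: np.ndarray  # (n_islands, 2) µm
    params: ActiveCellParams
    residual: float
    net_island_force: float  # |Σ F| / Σ |F| over the foundation


def _island_stiffness(
    points: np.ndarray, centers: np.ndarray, params: ActiveCellParams
) -> np.ndarray:
    """Foundation stiffness density Ys(x) (Pa/µm) sampled at points."""
    ys = np.zeros(len(points))
    for c in centers:
        d2 = (points[:, 0] - c[0]) ** 2 + (points[:, 1] - c[1]) ** 2
        ys[d2 <= params.island_radius**2] = params.Ys
    return ys


def _boundary_loop(nodes: np.ndarray, boundary_edges: np.ndarray) -> np.ndarray:
    """Order the boundary nodes of a single closed loop."""
    adj: dict[int, list[int]] = {}
    for a, b in boundary_edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    start = int(boundary_edges[0, 0])
    order = [start]
    prev, cur = -1, start
    while True:
        nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
        if nxt == start:
            break
        order.append(nxt)
        prev, cur = cur, nxt
    return nodes[order]


def simulate_active_cell(
    params: ActiveCellParams | None = None,
    mesh_edge_length: float = 1.5,
    grid_spacing: float = 0.5,
    grid_margin: float = 8.0,
    max_iter: int = 80,
    tol: float = 1e-5,
    relax: float = 0.7,
) -> ActiveCellResult:
    """Contract the active elastic cell to static force balance.

    An initially round cell contracts isotropically under the constant
    active stress until the sheet divergence balances the elastic-
    foundation forces at the adhesive islands.  The contraction is
    finite, so the static problem is solved by fixed-point iteration on
    the geometry: the plane-stress operator and active loads are
    reassembled on the current (deformed) configuration while the
    foundation springs stay anchored at the material island sites, until
    the displacement update falls below ``tol`` (µm).  Raises on
    non-convergence or element inversion, with the residual reported.

    Returns the deformed shape, the internal sheet stress on the
    deformed configuration (elastic + active, the MSM ground truth), the
    foundation traction ``t = Ys·u`` rasterized conservatively on a
    regular grid over the deformed cell, and the deformed cell mask.
    """
    if params is None:
        params = ActiveCellParams()
    R = params.radius
    c0 = R + grid_margin
    circle = Point(c0, c0).buffer(R, quad_segs=96)
    mesh0 = mesh_polygon(circle, mesh_edge_length)
    X0 = mesh0.nodes
    tri = mesh0.triangles
    ndof = 2 * len(X0)

    th = 2 * np.pi * np.arange(params.n_islands) / params.n_islands
    centers = np.column_stack(
        [c0 + params.island_ring_frac * R * np.cos(th),
         c0 + params.island_ring_frac * R * np.sin(th)]
    )

    hc_m = params.hc * UM
    D = _plane_stress_D(hc_m * params.Ec, params.nuc)  # sheet stiffness, N/m
    sigma_a = hc_m * params.Ec / (2.0 * (1.0 - params.nuc)) * params.P0  # N/m

    dof = np.empty((len(tri), 6), dtype=int)
    dof[:, 0::2] = 2 * tri
    dof[:, 1::2] = 2 * tri + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()

    # foundation: Ys piecewise constant per element, anchored in the
    # material frame; consistent (mass-matrix) assembly on material areas
    _, area0 = _element_B(X0 * UM, tri)
    centroids0 = X0[tri].mean(axis=1)
    ys_elem = _island_stiffness(centroids0, centers, params) / UM  # Pa/m
    mloc = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    Se = ys_elem[:, None, None] * area0[:, None, None] * mloc
    srows, scols, svals = [], [], []
    for a_ in range(3):
        for b_ in range(3):
            for comp in range(2):
                srows.append(2 * tri[:, a_] + comp)
                scols.append(2 * tri[:, b_] + comp)
                svals.append(Se[:, a_, b_])
    S = sp.coo_matrix(
        (np.concatenate(svals), (np.concatenate(srows), np.concatenate(scols))),
        shape=(ndof, ndof),
    ).tocsr()

    u = np.zeros(ndof)  # total displacement, meters
    act = np.array([sigma_a, sigma_a, 0.0])
    converged = params.P0 == 0.0
    delta = 0.0
    for _ in range(max_iter):
        x = X0 + np.column_stack([u[0::2], u[1::2]]) / UM
        B, area = _element_B(x * UM, tri)
        if np.any(area <= 0):
            raise RuntimeError(
                "active-cell solve failed: element inversion during contraction"
            )
        Ke = np.einsum("eji,jk,ekl,e->eil", B, D, B, area)
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
        fe = -np.einsum("eji,j,e->ei", B, act, area)
        f = np.zeros(ndof)
        np.add.at(f, dof.ravel(), fe.ravel())
        A = (K + S).tocsc()
        u_new = spla.spsolve(A, f)
        delta = float(np.max(np.abs(u_new - u)) / UM)
        u = u + relax * (u_new - u)
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"active-cell solve did not converge: last update {delta:.3e} µm"
        )

    x = X0 + np.column_stack([u[0::2], u[1::2]]) / UM
    B, area = _element_B(x * UM, tri)
    A = (sp.coo_matrix(
        (np.einsum("eji,jk,ekl,e->eil", B, D, B, area).ravel(), (rows, cols)),
        shape=(ndof, ndof),
    ).tocsr() + S).tocsc()
    fe = -np.einsum("eji,j,e->ei", B, act, area)
    f = np.zeros(ndof)
    np.add.at(f, dof.ravel(), fe.ravel())
    res = float(np.linalg.norm(A @ u - f))
    fnorm = float(np.linalg.norm(f))
    residual = res / fnorm if fnorm > 0 else res

    mesh_def = Mesh(
        nodes=x,
        triangles=tri,
        boundary_edges=mesh0.boundary_edges,
        target_edge_length=mesh_edge_length,
    )

    strain = np.einsum("eij,ej->ei", B, u[dof])
    sigma_e = strain @ D.T
    sigma_e[:, :2] += sigma_a
    nodal = np.zeros((len(X0), 3))
    wsum = np.zeros(len(X0))
    for j in range(3):
        np.add.at(nodal, tri[:, j], sigma_e * area[:, None])
        np.add.at(wsum, tri[:, j], area)
    nodal /= wsum[:, None]
    stress = StressField(mesh_def, nodal[:, 0], nodal[:, 1], nodal[:, 2])

    # foundation force balance on the FEM representation
    f_found = S @ u
    net = np.array([f_found[0::2].sum(), f_found[1::2].sum()])
    total = np.abs(f_found).sum()
    net_rel = float(np.linalg.norm(net) / total) if total > 0 else 0.0

    # conservative rasterization of t = Ys·u (Pa) on the deformed grid:
    # each foundation element deposits its force through 4 midpoint
    # subtriangles (exact for linear u), at deformed positions
    n_grid = int(np.ceil(2 * c0 / grid_spacing))
    tx = np.zeros((n_grid, n_grid))
    ty = np.zeros((n_grid, n_grid))
    u_um = np.column_stack([u[0::2], u[1::2]]) / UM
    active_el = np.flatnonzero(ys_elem > 0)
    if len(active_el):
        conn = tri[active_el]
        xd = x[conn]                      # (M, 3, 2) deformed corners
        ud = u_um[conn]                   # (M, 3, 2) corner displacement
        fa = ys_elem[active_el] * area0[active_el]  # Pa/m · m² = N per m of u
        # subtriangle corner index triplets in (corner0..2, mid01, mid12, mid20)
        combo = np.concatenate([xd, 0.5 * (xd + np.roll(xd, -1, axis=1))], axis=1)
        combo_u = np.concatenate([ud, 0.5 * (ud + np.roll(ud, -1, axis=1))], axis=1)
        subs = np.array([[0, 3, 5], [3, 1, 4], [5, 4, 2], [3, 4, 5]])
        cell_area_m2 = (grid_spacing * UM) ** 2
        for s_ in subs:
            cpos = combo[:, s_].mean(axis=1)          # deformed centroid, µm
            cu = combo_u[:, s_].mean(axis=1)          # mean displacement, µm
            Fs = (fa / 4.0)[:, None] * (cu * UM)      # N
            ii = np.clip((cpos[:, 1] / grid_spacing).round().astype(int), 0, n_grid - 1)
            jj = np.clip((cpos[:, 0] / grid_spacing).round().astype(int), 0, n_grid - 1)
            np.add.at(tx, (ii, jj), Fs[:, 0] / cell_area_m2)
            np.add.at(ty, (ii, jj), Fs[:, 1] / cell_area_m2)
    traction = VectorField2D(tx, ty, grid_spacing, "Pa")

    ring = _boundary_loop(x, mesh0.boundary_edges)
    poly_def = ShapelyPolygon(ring)
    gx = np.arange(n_grid) * grid_spacing
    xxg, yyg = np.meshgrid(gx, gx)
    inside = shapely.contains_xy(poly_def, xxg.ravel(), yyg.ravel())
    cell_mask = CellMask(inside.reshape(n_grid, n_grid), grid_spacing)

    return ActiveCellResult(
        mesh=mesh_def,
        displacement=u_um,
        stress=stress,
        traction=traction,
        cell_mask=cell_mask,
        island_centers=centers,
        params=params,
        residual=residual,
        net_island_force=net_rel,
    )
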
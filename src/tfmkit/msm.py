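"""Monolayer stress microscopy: plane-stress FEM recovery of the internal
2D sheet-stress tensor of a cell or monolayer from its traction field.

The monolayer is modeled as a thin elastic sheet in mechanical
equilibrium with the substrate: ``div σ = T`` with σ the sheet stress
(N/m, tension positive) and T the traction the cell exerts on the
substrate (Pa).  The reversed tractions are applied as distributed
in-plane loads on a linear-triangle mesh of the cell mask (free edge at
the mask boundary) and the stress is recovered from element strains with
area-weighted nodal averaging.  Because the loads are balanced, the
recovered stress does not depend on the assumed sheet Young's modulus
and only weakly on its Poisson ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .fields import VectorField2D
from .mesh import CellMask, Mesh

__all__ = ["StressField", "balance_forces", "msm_solve", "stress_summaries"]

UM = 1e-6  # µm → m


@dataclass
class StressField:
    """Per-node sheet stress tensor (N/m) on a triangle mesh."""

    mesh: Mesh
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray

    @property
    def snormal(self) -> np.ndarray:
        """Mean normal (isotropic) stress, (σxx + σyy)/2."""
        return 0.5 * (self.sxx + self.syy)

    def principal(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Principal stresses (σ1 ≥ σ2) and principal angle (radians)."""
        c = 0.5 * (self.sxx + self.syy)
        r = np.hypot(0.5 * (self.sxx - self.syy), self.sxy)
        ang = 0.5 * np.arctan2(2.0 * self.sxy, self.sxx - self.syy)
        return c + r, c - r, ang

    def component(self, name: str) -> np.ndarray:
        if name == "snormal":
            return self.snormal
        return getattr(self, name)

    def to_grid(self, shape: tuple[int, int], spacing: float) -> dict[str, np.ndarray]:
        """Rasterize nodal stresses onto a regular grid (NaN outside)."""
        ny, nx = shape
        xx, yy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        tri, bary = self.mesh.locate(pts)
        out = {}
        for name in ("sxx", "syy", "sxy"):
            vals = np.full(len(pts), np.nan)
            ok = tri >= 0
            nodal = getattr(self, name)
            vals[ok] = np.einsum(
                "nj,nj->n", bary[ok], nodal[self.mesh.triangles[tri[ok]]]
            )
            out[name] = vals.reshape(shape)
        out["snormal"] = 0.5 * (out["sxx"] + out["syy"])
        return out


def _mask_on_grid(traction: VectorField2D, mask: CellMask | np.ndarray) -> np.ndarray:
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if m.shape != traction.shape:
        raise ValueError("mask and traction grids differ in shape")
    return m


def balance_forces(
    traction: VectorField2D, mask: CellMask | np.ndarray
) -> tuple[VectorField2D, dict]:
    """Remove residual net force and net torque from a traction field.

    FTTC guarantees global but not local force balance, and the field
    restricted to the cell mask is generally unbalanced.  A uniform
    offset (net force / mask area) and a rigid-rotation component (net
    torque about the mask centroid) are subtracted inside the mask.  The
    correction magnitudes are returned as a quality metric.
    """
    m = _mask_on_grid(traction, mask)
    d = traction.spacing  # µm
    dA = d * d
    out = traction.copy()
    xx, yy = traction.coords()

    fx = float(out.u[m].sum() * dA)
    fy = float(out.v[m].sum() * dA)
    area = m.sum() * dA
    out.u[m] -= fx / area
    out.v[m] -= fy / area

    cx = float((xx[m]).mean())
    cy = float((yy[m]).mean())
    rx, ry = xx[m] - cx, yy[m] - cy
    torque = float(((rx * out.v[m] - ry * out.u[m]) * dA).sum())
    inertia = float(((rx**2 + ry**2) * dA).sum())
    alpha = torque / inertia if inertia > 0 else 0.0
    out.u[m] -= -alpha * ry
    out.v[m] -= alpha * rx

    report = {
        "net_force": (fx, fy),  # Pa µm²
        "net_torque": torque,  # Pa µm³
        "mean_traction": float(np.hypot(traction.u[m], traction.v[m]).mean()),
    }
    out.meta["balance_report"] = report
    return out, report


def _plane_stress_D(E: float, nu: float) -> np.ndarray:
    return (
        E
        / (1.0 - nu**2)
        * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, 0.5 * (1.0 - nu)]])
    )


def _element_B(nodes_m: np.ndarray, triangles: np.ndarray):
    """Constant strain-displacement matrices B (M, 3, 6) and areas (m²)."""
    p = nodes_m[triangles]
    x, y = p[..., 0], p[..., 1]
    b = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    )
    c = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    )
    area2 = b[:, 0] * (x[:, 1] - x[:, 2]) + b[:, 1] * (x[:, 2] - x[:, 0]) + b[:, 2] * (
        x[:, 0] - x[:, 1]
    )
    # equivalently 2A; use cross-product form for robustness
    area2 = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
        y[:, 1] - y[:, 0]
    )
    B = np.zeros((len(triangles), 3, 6))
    for j in range(3):
        B[:, 0, 2 * j] = b[:, j]
        B[:, 1, 2 * j + 1] = c[:, j]
        B[:, 2, 2 * j] = c[:, j]
        B[:, 2, 2 * j + 1] = b[:, j]
    B /= area2[:, None, None]
    return B, 0.5 * area2


def _assemble_stiffness(mesh: Mesh, D: np.ndarray) -> sp.csr_matrix:
    nodes_m = mesh.nodes * UM
    B, area = _element_B(nodes_m, mesh.triangles)
    Ke = np.einsum("eji,jk,ekl,e->eil", B, D, B, area)
    dof = np.empty((len(mesh.triangles), 6), dtype=int)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n = 2 * len(mesh.nodes)
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _scatter_loads(traction: VectorField2D, mesh: Mesh) -> np.ndarray:
    """Transfer grid tractions to nodal loads (N), reversed sign.

    Each grid cell center inside the mesh contributes its force
    ``t · spacing²`` to the nodes of the containing triangle with
    barycentric weights, conserving total force for narrow load bands
    as well as smooth fields.
    """
    ny, nx = traction.shape
    xx, yy = traction.coords()
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    tri, bary = mesh.locate(pts)
    ok = tri >= 0
    dA = (traction.spacing * UM) ** 2
    fx = -traction.u.ravel()[ok] * dA
    fy = -traction.v.ravel()[ok] * dA
    f = np.zeros(2 * len(mesh.nodes))
    conn = mesh.triangles[tri[ok]]
    for j in range(3):
        np.add.at(f, 2 * conn[:, j], bary[ok, j] * fx)
        np.add.at(f, 2 * conn[:, j] + 1, bary[ok, j] * fy)
    return f


def _project_out_rigid_loads(f: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Remove any residual net force/torque from the nodal load vector so
    the solution is independent of the rigid-body constraint location."""
    w = mesh.node_areas()
    w = w / w.sum()
    fx, fy = f[0::2], f[1::2]
    fx = fx - w * fx.sum()
    fy = fy - w * fy.sum()
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    cx, cy = (w * x).sum(), (w * y).sum()
    rx, ry = x - cx, y - cy
    tq = (rx * fy - ry * fx).sum()
    # rotational load pattern proportional to nodal weights
    rot_x, rot_y = -ry * w, rx * w
    denom = (rx * rot_y - ry * rot_x).sum()
    if abs(denom) > 0:
        beta = tq / denom
        fx = fx - beta * rot_x
        fy = fy - beta * rot_y
    out = np.empty_like(f)
    out[0::2], out[1::2] = fx, fy
    return out


def msm_solve(
    traction: VectorField2D,
    mesh: Mesh,
    nu_sheet: float = 0.5,
    E_sheet: float = 1.0,
) -> StressField:
    """Plane-stress FEM solve for the sheet stress driven by a traction
    field (Pa, cell-on-substrate sign).

    The traction should already be balanced over the analysis region
    (see :func:`balance_forces`); any residual imbalance in the nodal
    loads is projected out, which together with balanced loads makes the
    minimal rigid-body constraints (one node pinned in x and y, one in y)
    location-independent.  The recovered stress is invariant to
    ``E_sheet`` and only weakly sensitive to ``nu_sheet``.
    """
    D = _plane_stress_D(E_sheet, nu_sheet)
    K = _assemble_stiffness(mesh, D)

    adj = sp.coo_matrix(
        (
            np.ones(3 * len(mesh.triangles)),
            (
                np.concatenate([mesh.triangles[:, 0], mesh.triangles[:, 1], mesh.triangles[:, 2]]),
                np.concatenate([mesh.triangles[:, 1], mesh.triangles[:, 2], mesh.triangles[:, 0]]),
            ),
        ),
        shape=(len(mesh.nodes), len(mesh.nodes)),
    )
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp > 1:
        raise ValueError("mesh is disconnected; MSM system is singular")

    f = _scatter_loads(traction, mesh)
    f = _project_out_rigid_loads(f, mesh)

    # minimal rigid-body constraints: node 0 in x and y, farthest node in y
    far = int(np.argmax(np.hypot(*(mesh.nodes - mesh.nodes[0]).T)))
    fixed = np.array([0, 1, 2 * far + 1])
    free = np.setdiff1d(np.arange(2 * len(mesh.nodes)), fixed)
    u = np.zeros(2 * len(mesh.nodes))
    Kff = K[free][:, free].tocsc()
    u[free] = spla.spsolve(Kff, f[free])

    nodes_m = mesh.nodes * UM
    B, area = _element_B(nodes_m, mesh.triangles)
    dof = np.empty((len(mesh.triangles), 6), dtype=int)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    strain = np.einsum("eij,ej->ei", B, u[dof])
    sigma_e = strain @ D.T  # (M, 3): sxx, syy, sxy in N/m

    nodal = np.zeros((len(mesh.nodes), 3))
    wsum = np.zeros(len(mesh.nodes))
    for j in range(3):
        np.add.at(nodal, mesh.triangles[:, j], sigma_e * area[:, None])
        np.add.at(wsum, mesh.triangles[:, j], area)
    nodal /= wsum[:, None]
    return StressField(mesh, nodal[:, 0], nodal[:, 1], nodal[:, 2])


def stress_summaries(
    stress: StressField, mask: CellMask | None = None
) -> dict[str, float]:
    """Area-averaged stress summaries in mN/m.

    Averages σxx, σyy and σnormal over the mesh (optionally restricted to
    nodes inside ``mask``), the maximum principal stress, and the
    anisotropy ratio ⟨σ1 − σ2⟩ / ⟨σ1 + σ2⟩ (0 isotropic, 1 uniaxial).
    """
    w = stress.mesh.node_areas()
    sel = np.ones(len(w), dtype=bool)
    if mask is not None:
        ix = np.clip(
            np.round(stress.mesh.nodes[:, 0] / mask.pixel_size).astype(int),
            0,
            mask.mask.shape[1] - 1,
        )
        iy = np.clip(
            np.round(stress.mesh.nodes[:, 1] / mask.pixel_size).astype(int),
            0,
            mask.mask.shape[0] - 1,
        )
        sel = mask.mask[iy, ix]
        if not sel.any():
            sel = np.ones(len(w), dtype=bool)
    w = w[sel] / w[sel].sum()
    s1, s2, _ = stress.principal()
    mean = lambda a: float((w * a[sel]).sum())
    m1, m2 = mean(s1), mean(s2)
    to_mn = 1e3  # N/m → mN/m
    return {
        "sxx_mean_mN_per_m": mean(stress.sxx) * to_mn,
        "syy_mean_mN_per_m": mean(stress.syy) * to_mn,
        "snormal_mean_mN_per_m": mean(stress.snormal) * to_mn,
        "max_principal_mN_per_m": float(s1[sel].max()) * to_mn,
        "anisotropy_ratio": (m1 - m2) / (m1 + m2) if (m1 + m2) != 0 else 0.0,
    }
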
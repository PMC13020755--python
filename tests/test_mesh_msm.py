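"""Mask segmentation, triangulation, force balancing and the
plane-stress monolayer solve."""

import numpy as np
import pytest

from tfmkit import (
    CellMask,
    VectorField2D,
    balance_forces,
    build_mesh,
    msm_solve,
    segment_mask,
    square_plate_case,
    stress_summaries,
)
from tfmkit.validate import run_square_plate_validation


def disk_image(n=128, r=40, amp=1000.0):
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.full((n, n), 50.0)
    img[(xx - n / 2) ** 2 + (yy - n / 2) ** 2 < r**2] += amp
    return img


def disk_mask(n=128, r=40.0, pixel_size=1.0):
    yy, xx = np.mgrid[0:n, 0:n]
    return CellMask((xx - n / 2) ** 2 + (yy - n / 2) ** 2 < r**2, pixel_size)


class TestSegmentMask:
    def test_bright_disk_area_within_5pct(self):
        mask = segment_mask(disk_image(), 1.0)
        assert mask.area == pytest.approx(np.pi * 40**2, rel=0.05)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            segment_mask(np.full((64, 64), 7.0), 1.0)

    def test_boolean_passthrough_keeps_largest_component(self):
        m = np.zeros((64, 64), dtype=bool)
        m[10:40, 10:40] = True
        m[55:58, 55:58] = True  # small spurious blob
        out = segment_mask(m, 1.0)
        assert not out.mask[56, 56]
        assert out.mask[20, 20]


class TestBuildMesh:
    def test_square_mask_area_conserved(self):
        m = np.zeros((100, 100), dtype=bool)
        m[20:80, 20:80] = True
        mesh = build_mesh(CellMask(m, 1.0), 4.0)
        assert mesh.area == pytest.approx(60.0**2, rel=0.02)

    def test_halving_edge_length_quadruples_triangles(self):
        mask = disk_mask()
        n_coarse = len(build_mesh(mask, 8.0).triangles)
        n_fine = len(build_mesh(mask, 4.0).triangles)
        assert n_fine / n_coarse == pytest.approx(4.0, rel=0.3)

    def test_circle_boundary_nodes_on_contour(self):
        mask = disk_mask()
        mesh = build_mesh(mask, 5.0)
        bidx = np.unique(mesh.boundary_edges)
        r = np.hypot(*(mesh.nodes[bidx] - 64.0).T)
        assert np.abs(r - 40.0).max() < 1.0

    def test_triangles_positively_oriented(self):
        mesh = build_mesh(disk_mask(), 5.0)
        assert (mesh.areas() > 0).all()

    def test_boundary_edges_belong_to_one_triangle(self):
        mesh = build_mesh(disk_mask(), 6.0)
        edges = np.sort(
            np.vstack(
                [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]], mesh.triangles[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        once = {tuple(e) for e in uniq[counts == 1]}
        assert once == {tuple(e) for e in np.sort(mesh.boundary_edges, axis=1)}

    def test_excessive_resolution_raises(self, monkeypatch):
        import tfmkit.mesh as mesh_mod

        monkeypatch.setattr(mesh_mod, "MAX_TRIANGLES", 500)
        with pytest.raises(ValueError, match="triangles"):
            build_mesh(disk_mask(), 3.0)

    def test_mask_with_hole_preserved(self):
        m = np.zeros((100, 100), dtype=bool)
        m[10:90, 10:90] = True
        m[40:60, 40:60] = False
        mesh = build_mesh(CellMask(m, 1.0), 5.0)
        assert mesh.area == pytest.approx(80**2 - 20**2, rel=0.03)
        # no triangle centroid inside the hole
        cent = mesh.nodes[mesh.triangles].mean(axis=1)
        inside_hole = (
            (cent[:, 0] > 42) & (cent[:, 0] < 58) & (cent[:, 1] > 42) & (cent[:, 1] < 58)
        )
        assert not inside_hole.any()


class TestBalanceForces:
    def make_field(self, rng, n=64):
        u = rng.normal(size=(n, n))
        v = rng.normal(size=(n, n))
        return VectorField2D(u, v, 1.0, "Pa")

    def test_balanced_field_unchanged(self, rng):
        fld = self.make_field(rng)
        mask = np.ones(fld.shape, dtype=bool)
        bal1, _ = balance_forces(fld, mask)
        bal2, _ = balance_forces(bal1, mask)
        assert np.allclose(bal1.u, bal2.u, atol=1e-12)

    def test_uniform_offset_removed_exactly(self, rng):
        fld = self.make_field(rng)
        mask = np.ones(fld.shape, dtype=bool)
        bal, _ = balance_forces(fld, mask)
        shifted = fld.copy()
        shifted.u += 3.7
        bal2, rep = balance_forces(shifted, mask)
        assert np.allclose(bal.u, bal2.u, atol=1e-10)
        assert rep["net_force"][0] == pytest.approx(fld.u.sum() + 3.7 * fld.u.size, rel=1e-9)

    def test_net_force_and_torque_zeroed_to_machine_precision(self, rng):
        fld = self.make_field(rng)
        mask = np.ones(fld.shape, dtype=bool)
        bal, _ = balance_forces(fld, mask)
        scale = np.abs(bal.u).sum()
        assert abs(bal.u.sum()) < 1e-9 * scale
        assert abs(bal.v.sum()) < 1e-9 * scale
        xx, yy = bal.coords()
        cx, cy = xx[mask].mean(), yy[mask].mean()
        torque = ((xx - cx) * bal.v - (yy - cy) * bal.u)[mask].sum()
        assert abs(torque) < 1e-8 * scale

    def test_injected_torque_recovered(self, rng):
        n = 64
        xx, yy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        cx = cy = (n - 1) / 2.0
        alpha = 0.01
        fld = VectorField2D(-alpha * (yy - cy), alpha * (xx - cx), 1.0, "Pa")
        mask = np.ones((n, n), dtype=bool)
        inertia = (((xx - cx) ** 2 + (yy - cy) ** 2)).sum()
        bal, rep = balance_forces(fld, mask)
        assert rep["net_torque"] == pytest.approx(alpha * inertia, rel=1e-9)
        assert np.abs(bal.u).max() < 1e-12


class TestMsmSolve:
    def test_zero_traction_zero_stress(self):
        mask = disk_mask(n=64, r=24)
        mesh = build_mesh(mask, 4.0)
        t = VectorField2D(np.zeros((64, 64)), np.zeros((64, 64)), 1.0, "Pa")
        stress = msm_solve(t, mesh)
        assert np.abs(stress.sxx).max() < 1e-12
        assert np.abs(stress.sxy).max() < 1e-12

    def test_square_plate_benchmark(self):
        """Recovered stress correlates > 0.98 with the closed form and
        the interior magnitudes are within 5%."""
        v = run_square_plate_validation()
        assert v.min_corr > 0.98
        assert v.mean_rel_err_pct < 5.0

    def test_stress_independent_of_sheet_modulus(self):
        case = square_plate_case(shape=(96, 96), side=48.0)
        bal, _ = balance_forces(case.traction, case.mask.mask)
        mesh = build_mesh(case.mask, 3.0)
        s1 = msm_solve(bal, mesh, E_sheet=1.0)
        s2 = msm_solve(bal, mesh, E_sheet=10.0)
        scale = np.abs(s1.sxx).max()
        assert np.abs(s2.sxx - s1.sxx).max() < 1e-3 * scale

    def test_weak_poisson_dependence(self):
        case = square_plate_case(shape=(96, 96), side=48.0)
        bal, _ = balance_forces(case.traction, case.mask.mask)
        mesh = build_mesh(case.mask, 3.0)
        s1 = msm_solve(bal, mesh, nu_sheet=0.5)
        s2 = msm_solve(bal, mesh, nu_sheet=0.3)
        m1 = s1.snormal.mean()
        m2 = s2.snormal.mean()
        assert abs(m2 - m1) / abs(m1) < 0.02  # documented threshold

    def test_mesh_convergence_of_mean_stress(self):
        case = square_plate_case(shape=(192, 192), side=60.0, spacing=0.5)
        bal, _ = balance_forces(case.traction, case.mask.mask)
        means = []
        for h in (4.0, 2.0):
            mesh = build_mesh(case.mask, h)
            s = msm_solve(bal, mesh)
            w = mesh.node_areas()
            means.append((w * s.snormal).sum() / w.sum())
        assert abs(means[1] - means[0]) / abs(means[1]) < 0.01
        # and both sit at the analytic plate-average level
        assert means[1] == pytest.approx(case.load, rel=0.02)

    def test_constraint_location_independence(self):
        """Balanced loads + rigid-load projection make the pinned-node
        choice irrelevant."""
        case = square_plate_case(shape=(96, 96), side=48.0)
        bal, _ = balance_forces(case.traction, case.mask.mask)
        mesh = build_mesh(case.mask, 3.0)
        s1 = msm_solve(bal, mesh)
        # rotate node order by rebuilding with nodes re-indexed: emulate by
        # pinning different nodes via a shifted copy of the mesh object
        import copy

        mesh2 = copy.copy(mesh)
        perm = np.roll(np.arange(len(mesh.nodes)), 7)
        inv = np.argsort(perm)
        mesh2.nodes = mesh.nodes[perm]
        mesh2.triangles = inv[mesh.triangles]
        mesh2.boundary_edges = inv[mesh.boundary_edges]
        mesh2._delaunay = None
        mesh2._simplex_map = None
        s2 = msm_solve(bal, mesh2)
        assert np.allclose(s2.sxx[inv[0]], s1.sxx[0], rtol=1e-6, atol=1e-9)
        scale = np.abs(s1.sxx).max()
        assert np.abs(s2.sxx[inv] - s1.sxx).max() < 1e-6 * scale


class TestStressSummaries:
    def test_constant_field_averages(self):
        mesh = build_mesh(disk_mask(n=64, r=24), 4.0)
        from tfmkit.msm import StressField

        n = len(mesh.nodes)
        s = StressField(mesh, np.full(n, 2e-3), np.full(n, 2e-3), np.zeros(n))
        summ = stress_summaries(s)
        assert summ["sxx_mean_mN_per_m"] == pytest.approx(2.0)
        assert summ["snormal_mean_mN_per_m"] == pytest.approx(2.0)
        assert summ["anisotropy_ratio"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_uniaxial_maximal_anisotropy(self):
        mesh = build_mesh(disk_mask(n=64, r=24), 4.0)
        from tfmkit.msm import StressField

        n = len(mesh.nodes)
        s = StressField(mesh, np.full(n, 1e-3), np.zeros(n), np.zeros(n))
        summ = stress_summaries(s)
        assert summ["syy_mean_mN_per_m"] == pytest.approx(0.0, abs=1e-12)
        assert summ["anisotropy_ratio"] == pytest.approx(1.0)
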
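"""Tetrahedralisation, linear-tet elasticity and strength scores."""

import numpy as np
import pytest

from jawstrength import (
    DegenerateInputError,
    Material,
    RigidBodyModeError,
    ValidationError,
    generate_fixture,
    solve_elasticity,
    strength_score,
    tetrahedralise,
)
from jawstrength.fe_strength import LoadCase, points_in_mesh

E_BONE = 17_000.0  # MPa
MAT = Material(E_BONE, 0.3)


def _fixed_all(nodes_idx):
    return {3 * n + ax: 0.0 for n in nodes_idx for ax in range(3)}


class TestTetrahedralise:
    def test_unit_cube_volume_exact(self):
        mesh, refs = generate_fixture("cube")
        tet = tetrahedralise(mesh, 0.2)
        assert tet.total_volume() == pytest.approx(refs["volume"], abs=1e-6)
        assert np.all(tet.volumes() > 0)

    def test_sphere_volume_within_two_percent(self):
        mesh, refs = generate_fixture("sphere")
        tet = tetrahedralise(mesh, refs["radius"] / 10)
        assert tet.total_volume() == pytest.approx(refs["volume"], rel=0.02)
        assert tet.max_edge() <= 2 * refs["radius"] / 10

    def test_refinement_at_least_doubles_element_count(self):
        mesh, _ = generate_fixture("cube")
        coarse = tetrahedralise(mesh, 0.3)
        fine = tetrahedralise(mesh, 0.15)
        assert fine.n_tets >= 2 * coarse.n_tets

    def test_open_surface_rejected(self):
        mesh, _ = generate_fixture("cube")
        import numpy as np

        open_mesh = type(mesh)(mesh.vertices, mesh.faces[:-1])
        with pytest.raises(ValidationError, match="watertight"):
            tetrahedralise(open_mesh, 0.2)

    def test_containment_oracle_on_cube(self, rng):
        mesh, _ = generate_fixture("cube")
        pts = rng.uniform(-0.7, 0.7, size=(2000, 3))
        inside = points_in_mesh(mesh.vertices, mesh.faces, pts)
        truth = np.all(np.abs(pts) < 0.5, axis=1)
        assert np.array_equal(inside, truth)


class TestSolveElasticity:
    def test_patch_test_linear_field_constant_stress(self):
        # prescribe an affine displacement on every boundary node; linear
        # tets must reproduce it exactly with spatially constant stress
        mesh, _ = generate_fixture("cube")
        tet = tetrahedralise(mesh, 0.35)
        A = np.array([[2e-4, 1e-4, 0], [0, -1e-4, 5e-5], [1e-4, 0, 3e-4]])
        bounds = np.abs(np.abs(tet.nodes) - 0.5).min(axis=1) < 1e-9
        fixed = {}
        for n in np.where(bounds)[0]:
            u = A @ tet.nodes[n]
            for ax in range(3):
                fixed[3 * n + ax] = u[ax]
        case = LoadCase("patch", fixed, np.zeros_like(tet.nodes))
        res = solve_elasticity(tet, MAT, case)
        exact = A @ tet.nodes.T
        np.testing.assert_allclose(res.displacements.T, exact, atol=1e-12)
        rel = np.ptp(res.von_mises) / res.von_mises.mean()
        assert rel < 1e-8

    def test_uniaxial_bar_stress_and_displacement(self):
        mesh, refs = generate_fixture("bar")
        tet = tetrahedralise(mesh, 0.34)
        L, A_sec = refs["length"], refs["area"]
        F = 2.0
        left = np.where(tet.nodes[:, 0] < 1e-9)[0]
        right = np.where(tet.nodes[:, 0] > L - 1e-9)[0]
        fixed = {3 * n: 0.0 for n in left}
        # suppress lateral rigid modes without constraining Poisson
        # contraction: pin y on nodes at y=0, z on nodes at z=0 of the left face
        for n in left:
            if abs(tet.nodes[n, 1]) < 1e-9:
                fixed[3 * n + 1] = 0.0
            if abs(tet.nodes[n, 2]) < 1e-9:
                fixed[3 * n + 2] = 0.0
        forces = np.zeros_like(tet.nodes)
        forces[right, 0] = F / len(right)
        res = solve_elasticity(tet, MAT, LoadCase("bar", fixed, forces))
        sigma = F / A_sec
        med = np.median(res.von_mises)
        assert med == pytest.approx(sigma, rel=0.01)
        tip = res.displacements[right, 0].mean()
        assert tip == pytest.approx(refs["axial_displacement"](F, E_BONE), rel=0.01)
        # equilibrium: strain energy equals external work
        assert res.strain_energy == pytest.approx(res.external_work, rel=1e-6)

    def test_cantilever_tip_deflection_converges(self):
        mesh, refs = generate_fixture("cantilever")
        F = 1.0
        ref = refs["tip_deflection"](F, E_BONE)
        errors = []
        for edge in (0.5, 0.32, 0.22):
            tet = tetrahedralise(mesh, edge)
            left = np.where(tet.nodes[:, 0] < 1e-9)[0]
            right = np.where(tet.nodes[:, 0] > refs["length"] - 1e-9)[0]
            forces = np.zeros_like(tet.nodes)
            forces[right, 1] = -F / len(right)
            res = solve_elasticity(
                tet, MAT, LoadCase("cant", _fixed_all(left), forces)
            )
            tip = -res.displacements[right, 1].mean()
            errors.append(abs(tip - ref) / ref)
        assert errors[-1] < 0.10
        assert errors[-1] <= errors[0] + 1e-12

    def test_unconstrained_model_raises_rigid_body_error(self):
        mesh, _ = generate_fixture("cube")
        tet = tetrahedralise(mesh, 0.4)
        forces = np.zeros_like(tet.nodes)
        forces[0, 1] = 1.0
        with pytest.raises(RigidBodyModeError):
            solve_elasticity(tet, MAT, LoadCase("free", {}, forces))


class TestStrengthScore:
    def _bar_result(self, F):
        mesh, refs = generate_fixture("bar")
        tet = tetrahedralise(mesh, 0.4)
        left = np.where(tet.nodes[:, 0] < 1e-9)[0]
        right = np.where(tet.nodes[:, 0] > refs["length"] - 1e-9)[0]
        forces = np.zeros_like(tet.nodes)
        forces[right, 0] = F / len(right)
        return solve_elasticity(
            tet, MAT, LoadCase("bar", _fixed_all(left), forces)
        )

    def test_doubling_load_halves_strength(self):
        s1 = strength_score(self._bar_result(1.0))
        s2 = strength_score(self._bar_result(2.0))
        assert s2 == pytest.approx(s1 / 2, rel=1e-9)

    def test_uniform_bar_strength_near_inverse_stress_for_any_quantile(self):
        res = self._bar_result(2.0)  # sigma = F/A = 2 N/mm^2
        for q in (0.25, 0.5, 0.75):
            s = strength_score(res, q)
            assert s == pytest.approx(0.5, rel=0.05)

    def test_similarity_scaling_of_strength(self):
        # geometrically similar bars scaled by s under equal load:
        # stress ~ F / L^2, so strength ratio = s^2
        mesh, refs = generate_fixture("bar")
        s_factor = 1.5
        big = type(mesh)(mesh.vertices * s_factor, mesh.faces)
        out = []
        for m, edge, L in ((mesh, 0.3, refs["length"]),
                           (big, 0.3 * s_factor, refs["length"] * s_factor)):
            tet = tetrahedralise(m, edge)
            left = np.where(tet.nodes[:, 0] < 1e-9)[0]
            right = np.where(tet.nodes[:, 0] > L - 1e-9)[0]
            forces = np.zeros_like(tet.nodes)
            forces[right, 0] = 1.0 / len(right)
            res = solve_elasticity(tet, MAT, LoadCase("b", _fixed_all(left), forces))
            out.append(strength_score(res))
        assert out[1] / out[0] == pytest.approx(s_factor**2, rel=0.02)

    def test_zero_load_strength_undefined(self):
        mesh, _ = generate_fixture("cube")
        tet = tetrahedralise(mesh, 0.4)
        case = LoadCase("none", _fixed_all(range(8)), np.zeros_like(tet.nodes))
        res = solve_elasticity(tet, MAT, case)
        with pytest.raises(DegenerateInputError):
            strength_score(res)

    def test_thinned_jaw_is_weaker_for_all_quantiles(self):
        (thick, thin), _ = generate_fixture("two_jaws")
        scores = {}
        for name, m in (("thick", thick), ("thin", thin)):
            tet = tetrahedralise(m, 0.30)
            x = tet.nodes[:, 0]
            back = np.where(x > x.max() - 0.4)[0]
            forces = np.zeros_like(tet.nodes)
            tip = np.argmin(np.abs(tet.nodes[:, 0] - 4.0) + np.abs(tet.nodes[:, 1] - tet.nodes[:, 1].max()))
            forces[tip, 1] = -1.0
            res = solve_elasticity(tet, MAT, LoadCase("bite", _fixed_all(back), forces))
            scores[name] = [strength_score(res, q) for q in (0.5, 0.75, 0.9)]
        for a, b in zip(scores["thick"], scores["thin"]):
            assert a > b
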
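"""Reciprocal-lattice geometry: duality, volumes, g components, RMSD."""

import math

import numpy as np
import pytest

from gixdindex import ContactPlane, DirectCell, LaueTriple, cell_volume, g_components, rmsd
from gixdindex.lattice import TWO_PI, g_components_quadratic
from gixdindex.simulate import ASS_CELL, PQ_CELL, PQ_PLANE

CUBE = DirectCell(TWO_PI, TWO_PI, TWO_PI, 90, 90, 90)


def random_cell(rng):
    while True:
        lengths = rng.uniform(3.0, 20.0, 3)
        angles = rng.uniform(60.0, 120.0, 3)
        try:
            return DirectCell(*lengths, *angles)
        except ValueError:
            continue


class TestDirectCell:
    @pytest.mark.parametrize(
        "params",
        [
            (0.0, 5, 5, 90, 90, 90),
            (5, 5, 5, 0.0, 90, 90),
            (5, 5, 5, 190, 90, 90),
            (5, 5, 5, 170, 170, 170),  # no 3-D cell with these angles
        ],
    )
    def test_invalid_cells_rejected(self, params):
        with pytest.raises(ValueError):
            DirectCell(*params)

    def test_dual_basis_contract(self, rng):
        for _ in range(50):
            cell = random_cell(rng)
            prod = cell.basis() @ cell.reciprocal_basis().T
            assert np.allclose(prod, TWO_PI * np.eye(3), atol=1e-10)

    def test_reciprocal_is_involution(self, rng):
        for _ in range(50):
            cell = random_cell(rng)
            back = cell.reciprocal().direct()
            assert np.allclose(back.parameters, cell.parameters, rtol=1e-10)

    def test_volume_duality(self, rng):
        for _ in range(50):
            cell = random_cell(rng)
            assert cell.volume() * cell.reciprocal().volume() == pytest.approx(
                TWO_PI**3, rel=1e-10
            )


class TestReciprocalCell:
    def test_self_dual_cube(self):
        rec = CUBE.reciprocal()
        assert rec.parameters == pytest.approx((1, 1, 1, 90, 90, 90), abs=1e-12)

    def test_orthorhombic(self):
        rec = DirectCell(TWO_PI, 2 * TWO_PI, TWO_PI / 2, 90, 90, 90).reciprocal()
        assert rec.parameters == pytest.approx((1, 0.5, 2, 90, 90, 90), abs=1e-12)

    def test_pq_cell_matches_cartesian_construction(self):
        rec = PQ_CELL.reciprocal()
        lengths = np.linalg.norm(PQ_CELL.reciprocal_basis(), axis=1)
        assert lengths == pytest.approx(rec.parameters[:3], rel=1e-12)


class TestVolume:
    def test_cube(self):
        assert cell_volume(DirectCell(10, 10, 10, 90, 90, 90)) == pytest.approx(1000.0)

    def test_printed_worked_examples(self):
        # printed parameters are rounded: agreement to 0.1%
        assert cell_volume(ASS_CELL) == pytest.approx(852.98, rel=1e-3)
        assert cell_volume(PQ_CELL) == pytest.approx(360.8, rel=1e-3)


class TestGComponents:
    def test_cubic_in_plane_reflection(self):
        gc = g_components(CUBE, ContactPlane(0, 0, 1), LaueTriple(1, 0, 0))
        assert (gc.g_xy, gc.g_z, gc.g_xyz) == pytest.approx((1, 0, 1), abs=1e-12)

    def test_reflection_parallel_to_normal(self, rng):
        for _ in range(20):
            cell = random_cell(rng)
            uvw = tuple(int(x) for x in rng.integers(-2, 3, 3))
            if not any(uvw):
                continue
            gc = g_components(cell, ContactPlane(*uvw), LaueTriple(*uvw))
            assert gc.g_xy == pytest.approx(0.0, abs=1e-10)
            assert gc.g_z == pytest.approx(gc.g_spec, rel=1e-12)

    def test_pq_specular_matches_d_spacing(self):
        gemmi = pytest.importorskip("gemmi")
        gc = g_components(PQ_CELL, PQ_PLANE, LaueTriple(1, 0, 2))
        d102 = gemmi.UnitCell(*PQ_CELL.parameters).calculate_d((1, 0, 2))
        assert gc.g_z == pytest.approx(TWO_PI / d102, rel=1e-10)
        assert gc.g_spec == pytest.approx(TWO_PI / d102, rel=1e-10)

    def test_pythagoras_identity_bulk(self, rng):
        # 10^4 random (cell, plane, hkl): g_xy^2 + g_z^2 = g_xyz^2
        for _ in range(100):
            cell = random_cell(rng)
            uvw = rng.integers(-3, 4, 3)
            if not np.any(uvw):
                continue
            plane = ContactPlane(*(int(x) for x in uvw))
            from gixdindex.lattice import g_vectors

            hkl = rng.integers(-6, 7, (100, 3))
            g_xy, g_z, g_xyz, _ = g_vectors(cell, plane, hkl)
            assert np.allclose(g_xy**2 + g_z**2, g_xyz**2, rtol=1e-10, atol=1e-12)

    def test_closed_forms_match_vector_construction(self, rng):
        for _ in range(200):
            cell = random_cell(rng)
            uvw = rng.integers(-2, 3, 3)
            if not np.any(uvw):
                continue
            hkl = rng.integers(-5, 6, 3)
            if not np.any(hkl):
                continue
            plane = ContactPlane(*(int(x) for x in uvw))
            triple = LaueTriple(*(int(x) for x in hkl))
            gv = g_components(cell, plane, triple)
            gq = g_components_quadratic(cell, plane, triple)
            for name in ("g_xy", "g_z", "g_xyz", "g_spec"):
                assert getattr(gq, name) == pytest.approx(
                    getattr(gv, name), rel=1e-10, abs=1e-10
                )

    def test_centrosymmetry(self, rng):
        for _ in range(50):
            cell = random_cell(rng)
            plane = ContactPlane(1, 0, 2)
            hkl = tuple(int(x) for x in rng.integers(-5, 6, 3))
            if not any(hkl):
                continue
            gc = g_components(cell, plane, LaueTriple(*hkl))
            gm = g_components(cell, plane, LaueTriple(*(-x for x in hkl)))
            assert gm.g_xy == pytest.approx(gc.g_xy, rel=1e-12, abs=1e-14)
            assert gm.g_xyz == pytest.approx(gc.g_xyz, rel=1e-12)
            assert gm.g_z == pytest.approx(-gc.g_z, rel=1e-12, abs=1e-14)

    def test_monoclinic_limit(self, rng):
        # with alpha = gamma = 90 the triclinic quadratic form reduces to the
        # monoclinic closed forms; here both implementations must agree
        for _ in range(100):
            a, b, c = rng.uniform(4, 15, 3)
            beta = rng.uniform(75, 115)
            cell = DirectCell(a, b, c, 90.0, beta, 90.0)
            h, k, l = (int(x) for x in rng.integers(-4, 5, 3))
            if not (h or k or l):
                continue
            rec = cell.reciprocal()
            a_s, b_s, c_s = rec.parameters[:3]
            cb_s = math.cos(math.radians(rec.beta_star))
            mono_q2 = (
                h * h * a_s**2 + k * k * b_s**2 + l * l * c_s**2 + 2 * h * l * a_s * c_s * cb_s
            )
            gc = g_components(cell, ContactPlane(0, 0, 1), LaueTriple(h, k, l))
            assert gc.g_xyz**2 == pytest.approx(mono_q2, rel=1e-12)


class TestRmsd:
    def test_zero_and_single(self):
        assert rmsd([0.0, 0.0, 0.0]) == 0.0
        assert rmsd([-0.007]) == pytest.approx(0.007)

    def test_two_residuals(self):
        assert rmsd([0.003, 0.004]) == pytest.approx(math.sqrt(25e-6 / 2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd([])


class TestDualityProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(3.0, 30.0),
        st.floats(3.0, 30.0),
        st.floats(3.0, 30.0),
        st.floats(45.0, 135.0),
        st.floats(45.0, 135.0),
        st.floats(45.0, 135.0),
    )
    def test_reciprocal_round_trip_and_volume(self, a, b, c, alpha, beta, gamma):
        from hypothesis import assume

        from gixdindex.lattice import _metric_discriminant

        assume(_metric_discriminant(alpha, beta, gamma) > 1e-6)
        cell = DirectCell(a, b, c, alpha, beta, gamma)
        back = cell.reciprocal().direct()
        assert np.allclose(back.parameters, cell.parameters, rtol=1e-9, atol=1e-9)
        assert cell.volume() * cell.reciprocal().volume() == pytest.approx(
            TWO_PI**3, rel=1e-9
        )


def test_contact_plane_conventions():
    assert ContactPlane(-1, 0, 2).canonical().indices == (1, 0, -2)
    assert ContactPlane(0, 2, 0).primitive().indices == (0, 1, 0)
    assert ContactPlane(0, -2, 4).primitive().indices == (0, 1, -2)
    with pytest.raises(ValueError):
        ContactPlane(0, 0, 0)
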
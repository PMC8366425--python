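"""Two-stage specular-route indexing: stages, assignment, end-to-end recovery."""

import numpy as np
import pytest

from gixdindex import ContactPlane, DirectCell, Peak, PeakList, SearchConfig, index_with_specular
from gixdindex.lattice import TWO_PI
from gixdindex.reduction import niggli_reduce, transform_indices
from gixdindex.simulate import (
    ASS_CELL,
    ASS_PLANE,
    MONO_TOY_CELL,
    PQ_CELL,
    PQ_PLANE,
    SimulationSpec,
    random_cell_spec,
    simulate_pattern,
)
from gixdindex.specular import (
    assign_hk,
    assign_l,
    rank_stage1,
    select_start_triples,
    stage1_solve,
    stage2_solve,
)


def reduced_plane_of(cell, plane):
    """The generating plane expressed in the Niggli basis, sign-canonical."""
    _, m = niggli_reduce(cell)
    uvw = transform_indices(np.asarray(plane.indices), m)
    first = next((x for x in uvw if x != 0), 1)
    return tuple(-uvw) if first < 0 else tuple(uvw)


def assert_cell_close(found, expected, rtol_len, atol_ang):
    for f, e in zip(found.lengths, expected.lengths):
        assert abs(f - e) <= rtol_len * e
    for f, e in zip(found.angles, expected.angles):
        assert abs(f - e) <= atol_ang


class TestStartTriples:
    def test_generic_peaks_accepted(self):
        peaks = PeakList(
            (Peak(0.5, 0.3), Peak(0.7, 0.1), Peak(0.9, 0.55)), Peak(0.0, 1.2)
        )
        assert select_start_triples(peaks, 5) == [(0, 1, 2)]

    def test_harmonic_pair_rejected(self):
        peaks = PeakList(
            (Peak(0.5, 0.3), Peak(1.0, 0.6), Peak(0.9, 0.55), Peak(0.62, 0.18)),
            Peak(0.0, 1.2),
        )
        for t in select_start_triples(peaks, 10):
            assert not (0 in t and 1 in t)  # peak 1 = 2 * peak 0

    def test_too_few_peaks(self):
        peaks = PeakList((Peak(0.5, 0.3), Peak(0.7, 0.1)), Peak(0.0, 1.2))
        with pytest.raises(ValueError):
            select_start_triples(peaks, 5)

    def test_pq_triples_solvable_for_true_assignment(self, pq_pattern):
        peaks, truth = pq_pattern
        q_spec = peaks.q_spec
        u, v = PQ_PLANE.u, PQ_PLANE.v
        solvable = 0
        for t in select_start_triples(peaks, 6):
            rows = []
            for i in t:
                h, k, _ = truth.triples[i][0]
                xi = h - u * peaks.gixd[i].q_z / q_spec
                eta = k - v * peaks.gixd[i].q_z / q_spec
                rows.append([xi * xi, 2 * xi * eta, eta * eta])
            if abs(np.linalg.det(np.array(rows))) > 1e-9:
                solvable += 1
        assert solvable >= 3  # the start sets support the true solution


class TestStage1:
    def test_true_cell_among_candidates(self, pq_pattern):
        peaks, truth = pq_pattern
        config = SearchConfig()
        triple = tuple(peaks.gixd[i] for i in select_start_triples(peaks, 1)[0])
        cands = stage1_solve(triple, peaks.q_spec, config)
        found = [
            c
            for c in cands
            if abs(c.a - PQ_CELL.a) < 1e-6 * PQ_CELL.a
            and abs(c.b - PQ_CELL.b) < 1e-6 * PQ_CELL.b
            and abs(c.gamma - PQ_CELL.gamma) < 1e-4
            and (c.u, c.v) == (1, 0)
        ]
        assert found

    def test_gamma_window_enforced(self, pq_pattern):
        peaks, _ = pq_pattern
        config = SearchConfig()
        triple = tuple(peaks.gixd[i] for i in select_start_triples(peaks, 1)[0])
        for c in stage1_solve(triple, peaks.q_spec, config):
            assert 60.0 <= c.gamma <= 120.0
            assert config.a_range[0] <= c.a <= config.a_range[1]
            assert c.a <= c.b

    def test_invalid_specular_rejected(self):
        triple = (Peak(0.5, 0.3), Peak(0.7, 0.1), Peak(0.9, 0.55))
        with pytest.raises(ValueError):
            stage1_solve(triple, 0.0, SearchConfig())

    def test_empty_result_when_bounds_exclude_everything(self):
        triple = (Peak(0.5, 0.3), Peak(0.7, 0.1), Peak(0.9, 0.55))
        cands = stage1_solve(triple, 1.5, SearchConfig(a_range=(59.0, 60.0), b_range=(59.0, 60.0)))
        assert cands == []


class TestAssignHk:
    def _true_candidate(self, peaks, truth, plane, cell):
        config = SearchConfig()
        triple = tuple(peaks.gixd[i] for i in select_start_triples(peaks, 1)[0])
        cands = stage1_solve(triple, peaks.q_spec, config)
        best = min(
            cands,
            key=lambda c: abs(c.a - cell.a) + abs(c.b - cell.b) + abs(c.gamma - cell.gamma)
            + 100 * ((c.u, c.v) != (plane.u, plane.v)),
        )
        return best

    def test_true_pairs_retained_with_tiny_error(self, pq_pattern):
        peaks, truth = pq_pattern
        cand = self._true_candidate(peaks, truth, PQ_PLANE, PQ_CELL)
        cand = assign_hk(cand, peaks, peaks.q_spec, 6)
        assert cand.dq_xy < 1e-10
        for i, triples in enumerate(truth.triples):
            retained = {tuple(hk) for hk in cand.hk_candidates[i]}
            true_pairs = {t[:2] for t in triples}
            assert retained & true_pairs

    def test_square_lattice_fourfold_tie(self):
        cell = DirectCell(TWO_PI, TWO_PI, TWO_PI, 90, 90, 90)
        peaks = PeakList((Peak(1.0, 0.0),), Peak(0.0, 1.0))
        triple_cand = stage1_solve(
            (Peak(1.0, 0.0), Peak(1.0, 1.0), Peak(np.sqrt(2.0), 0.0)),
            1.0,
            SearchConfig(fixed_plane=(0, 0, 1)),
        )
        cand = min(triple_cand, key=lambda c: abs(c.a - TWO_PI) + abs(c.b - TWO_PI))
        cand = assign_hk(cand, peaks, 1.0, 6)
        assert {tuple(hk) for hk in cand.hk_candidates[0]} == {
            (1, 0),
            (-1, 0),
            (0, 1),
            (0, -1),
        }
        assert np.allclose(cand.hk_deltas[0], 0.0, atol=1e-12)

    def test_cap_exclusion_leaves_residual(self, mono_pattern):
        peaks, truth = mono_pattern
        config = SearchConfig()
        triple = tuple(peaks.gixd[i] for i in select_start_triples(peaks, 1)[0])
        cands = stage1_solve(triple, peaks.q_spec, config)
        cand = min(
            cands,
            key=lambda c: abs(c.a - MONO_TOY_CELL.a) + abs(c.b - MONO_TOY_CELL.b),
        )
        # peaks with |h| or |k| = 2 exist in the toy pattern; a cap of 1
        # cannot represent them exactly
        low = assign_hk(cand, peaks, peaks.q_spec, 1)
        full = assign_hk(cand, peaks, peaks.q_spec, 6)
        assert low.dq_xy > full.dq_xy
        assert low.dq_xy > 1e-6


class TestRankStage1:
    def test_orders_and_merges(self, pq_pattern):
        peaks, _ = pq_pattern
        config = SearchConfig()
        triple = tuple(peaks.gixd[i] for i in select_start_triples(peaks, 1)[0])
        cands = [
            assign_hk(c, peaks, peaks.q_spec, 6)
            for c in stage1_solve(triple, peaks.q_spec, config)[:40]
        ]
        by_dq = rank_stage1(cands, key="dq_xy")
        # distinct quality classes are ordered ascending
        coarse = [round(c.dq_xy, 4) for c in by_dq]
        assert coarse == sorted(coarse)
        by_area = rank_stage1(cands, key="area")
        areas = [c.area for c in by_area]
        assert areas == sorted(areas)
        assert len(by_dq) <= len(cands)  # duplicates merged

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            rank_stage1([], key="volume")


class TestStage2AndAssignL:
    def _carried_true(self, peaks, truth, plane, cell):
        config = SearchConfig()
        triples = select_start_triples(peaks, 3)
        target = None
        for t in triples:
            for c in stage1_solve(tuple(peaks.gixd[i] for i in t), peaks.q_spec, config):
                u, v = plane.u, plane.v
                a_t, b_t = cell.a, cell.b
                if a_t > b_t:
                    a_t, b_t, u, v = b_t, a_t, v, u
                if u < 0 or (u == 0 and v < 0):
                    u, v = -u, -v
                if (
                    abs(c.a - a_t) < 1e-4
                    and abs(c.b - b_t) < 1e-4
                    and abs(c.gamma - cell.gamma) < 1e-3
                    and (c.u, c.v) == (u, v)
                ):
                    target = c
                    break
            if target:
                break
        assert target is not None
        return assign_hk(target, peaks, peaks.q_spec, config.hk_assign_cap)

    def test_true_cell_completed(self, pq_pattern):
        peaks, truth = pq_pattern
        cand = self._carried_true(peaks, truth, PQ_PLANE, PQ_CELL)
        results = stage2_solve(cand, peaks, peaks.q_spec, SearchConfig(), w_cap=2)
        hit = [
            r
            for r in results
            if abs(r.cell.c - PQ_CELL.c) < 1e-5 * PQ_CELL.c
            and abs(r.cell.alpha - PQ_CELL.alpha) < 1e-3
            and abs(r.cell.beta - PQ_CELL.beta) < 1e-3
        ]
        assert hit

    def test_volume_bounds_filter(self, pq_pattern):
        peaks, truth = pq_pattern
        cand = self._carried_true(peaks, truth, PQ_PLANE, PQ_CELL)
        config = SearchConfig(volume_range=(10.0, 100.0))  # excludes 360.8
        for r in stage2_solve(cand, peaks, peaks.q_spec, config, w_cap=2):
            assert not abs(r.cell.volume() - PQ_CELL.volume()) < 1.0

    def test_assign_l_reproduces_pattern(self, pq_pattern):
        peaks, truth = pq_pattern
        cand = self._carried_true(peaks, truth, PQ_PLANE, PQ_CELL)
        hkl, d_xy, d_z, d_xyz = assign_l(
            PQ_CELL, PQ_PLANE, peaks, cand.hk_candidates, l_cap=6
        )
        assert np.all(d_xyz < 1e-10)
        assert np.all(d_z < 1e-10)

    def test_assign_l_rounding_and_cap(self):
        cell = DirectCell(TWO_PI, TWO_PI, TWO_PI, 90, 90, 90)
        plane = ContactPlane(0, 0, 1)
        # q_z = 2.5 sits exactly between l = 2 and l = 3: tie -> smaller |l|
        peaks = PeakList((Peak(1.0, 2.5), Peak(1.0, 7.2)), Peak(0.0, 1.0))
        hk4 = np.array([[[1, 0], [0, 1], [-1, 0], [0, -1]]] * 2)
        hkl, *_ = assign_l(cell, plane, peaks, hk4, l_cap=6)
        assert hkl[0][2] == 2
        assert abs(hkl[1][2]) <= 6


class TestEndToEnd:
    def test_pq_clean_recovery(self, pq_pattern, pq_solutions):
        top = pq_solutions[0]
        expected, _ = niggli_reduce(PQ_CELL)
        assert_cell_close(top.cell, expected, 1e-3, 0.05)
        assert top.plane.indices == reduced_plane_of(PQ_CELL, PQ_PLANE)
        assert top.errors.dq_xyz < 1e-6
        assert top.volume == pytest.approx(expected.volume(), rel=1e-3)

    def test_pq_noisy_recovery(self, pq_noisy_solutions):
        top = pq_noisy_solutions[0]
        expected, _ = niggli_reduce(PQ_CELL)
        assert_cell_close(top.cell, expected, 0.01, 0.5)
        assert top.plane.indices == reduced_plane_of(PQ_CELL, PQ_PLANE)
        assert top.errors.dq_xyz <= 3 * 0.002

    def test_ass_clean_recovery(self, ass_solutions):
        top = ass_solutions[0]
        expected, _ = niggli_reduce(ASS_CELL)
        assert_cell_close(top.cell, expected, 1e-3, 0.05)
        assert top.plane.indices == reduced_plane_of(ASS_CELL, ASS_PLANE)
        assert top.errors.dq_xyz < 1e-6

    def test_solutions_sorted_and_consistent(self, pq_solutions):
        dq = [s.errors.dq_xyz for s in pq_solutions]
        # ordering is ascending up to the tie quantum (ties resolved by volume)
        for earlier, later in zip(dq, dq[1:]):
            assert earlier <= later + 1e-4
        from gixdindex import rmsd

        for sol in pq_solutions:
            assert sol.volume == pytest.approx(sol.cell.volume(), rel=1e-12)
            assert sol.errors.dq_xyz == pytest.approx(
                rmsd([ip.d_xyz for ip in sol.indexed]), rel=1e-9, abs=1e-12
            )

    def test_random_cell_recovery(self):
        # seeded random fiber-texture patterns, 40 lowest reflections each
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(3):
            spec = random_cell_spec(rng)
            peaks, _ = simulate_pattern(spec)
            peaks = PeakList(peaks.gixd[:40], peaks.specular)
            expected, _ = niggli_reduce(spec.cell)
            sols = index_with_specular(peaks)
            top = sols[0].cell
            ok_len = all(
                abs(f - e) <= 1e-3 * e for f, e in zip(top.lengths, expected.lengths)
            )
            ok_ang = all(
                abs(f - e) <= 0.05 for f, e in zip(top.angles, expected.angles)
            )
            hits += ok_len and ok_ang
        assert hits == 3

    def test_requires_specular_and_enough_peaks(self):
        gixd = (Peak(0.5, 0.3), Peak(0.7, 0.1), Peak(0.9, 0.55))
        with pytest.raises(ValueError):
            index_with_specular(PeakList(gixd, None))
        with pytest.raises(ValueError):
            index_with_specular(PeakList(gixd[:2], Peak(0.0, 1.0)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(hk_assign_cap=9)
        with pytest.raises(ValueError):
            SearchConfig(l_cap=0)
        with pytest.raises(ValueError):
            SearchConfig(a_range=(5.0, 3.0))
        with pytest.raises(ValueError):
            SearchConfig(sort_key="volume")
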
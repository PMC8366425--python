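"""Single-step indexing of GIXD peak lists without a specular peak.

Without a specular peak the contact plane is not constrained to integer
Miller indices; instead the out-of-plane components of the reciprocal basis
vectors are fitted directly.  Two linear relations carry the search:

* the out-of-plane component  q_z = h (a*.n) + k (b*.n) + l (c*.n),
  linear in the three normal projections, and
* the total length            q_xyz^2 = h^2 a*^2 + k^2 b*^2 + l^2 c*^2
  + 2hk a*b* cos(gamma*) + 2hl a*c* cos(beta*) + 2kl b*c* cos(alpha*),
  linear in the six reciprocal-metric coefficients.

A seed system is built from the q_z of the four lowest-q reflections under
variation of their Laue indices; the best seeds are expanded by two more
reflections so the metric becomes solvable, then the remaining reflections
are assigned and refitted one at a time.  The monoclinic option (unique
axis b with the texture normal in the a*-c* plane, so b*.n = 0) shrinks
both systems and needs only four peaks.  Final cells are Niggli reduced and
reported with the orientation angles (psi, phi) of the crystallites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import DirectCell, LaueTriple, ReciprocalCell, RmsdReport, rmsd
from .peaks import PeakList
from .reduction import niggli_main_ok, niggli_reduce, transform_indices
from .specular import IndexedPeak, Solution, _gated_order

__all__ = [
    "NospecConfig",
    "Orientation",
    "SeedCandidate",
    "seed_qz_system",
    "grow_and_fit",
    "orientation_from_projection",
    "index_without_specular",
]


@dataclass(frozen=True)
class NospecConfig:
    """Caps and bounds of the no-specular search.

    Seed caps default to h within +/-1, k within +/-2 and l within +/-2;
    the subsequent assignment of further reflections uses indices within
    +/-6.  ``normal_tol`` bounds how far the fitted substrate normal may
    deviate from unit length before a candidate is rejected.
    """

    cell_type: str = "triclinic"
    seed_h_cap: int = 1
    seed_k_cap: int = 2
    seed_l_cap: int = 2
    assign_cap: int = 6
    beam_width: int = 50
    a_range: tuple[float, float] = (3.0, 60.0)
    b_range: tuple[float, float] = (3.0, 60.0)
    c_range: tuple[float, float] = (3.0, 60.0)
    volume_range: tuple[float, float] | None = None
    normal_tol: float = 0.05
    max_solutions: int = 10

    def __post_init__(self) -> None:
        if self.cell_type not in ("monoclinic", "triclinic"):
            raise ValueError(f"cell_type must be monoclinic or triclinic, got {self.cell_type!r}")
        for name in ("seed_h_cap", "seed_k_cap", "seed_l_cap", "assign_cap"):
            if not 1 <= getattr(self, name) <= 8:
                raise ValueError(f"{name} outside 1..8")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")


@dataclass(frozen=True)
class Orientation:
    """Crystallite orientation: the substrate normal in the crystal frame.

    In the canonical Cartesian setting of the cell (a along x, b in the x-y
    plane) the unit normal is n = (sin(psi) cos(phi), sin(psi) sin(phi),
    cos(psi)); psi is the tilt away from the canonical z axis and phi the
    azimuth.  When psi = 0 the azimuth is degenerate and reported as 0.
    """

    psi: float
    phi: float

    def normal(self) -> np.ndarray:
        sp, cp = math.sin(math.radians(self.psi)), math.cos(math.radians(self.psi))
        sf, cf = math.sin(math.radians(self.phi)), math.cos(math.radians(self.phi))
        return np.array([sp * cf, sp * sf, cp])

    def rotation_matrix(self) -> np.ndarray:
        """Crystal-to-lab rotation; its third row is the substrate normal."""
        sp, cp = math.sin(math.radians(self.psi)), math.cos(math.radians(self.psi))
        sf, cf = math.sin(math.radians(self.phi)), math.cos(math.radians(self.phi))
        return np.array(
            [
                [cp * cf, cp * sf, -sp],
                [-sf, cf, 0.0],
                [sp * cf, sp * sf, cp],
            ]
        )


@dataclass
class SeedCandidate:
    """Index assignment of the growing linear system with its fitted unknowns."""

    peak_idx: list[int]
    hkl: np.ndarray  # (n, 3) int
    proj: np.ndarray  # normal projections (2 coefficients monoclinic, else 3)
    metric: np.ndarray | None  # quadratic coefficients (4 or 6), None before growth
    residual: float


def _metric_design(hkl: np.ndarray, mono: bool) -> np.ndarray:
    h, k, l = (hkl[:, i].astype(float) for i in range(3))
    if mono:
        return np.column_stack([h * h, k * k, l * l, 2 * h * l])
    return np.column_stack([h * h, k * k, l * l, 2 * h * k, 2 * h * l, 2 * k * l])


def _metric_to_gram(coeff: np.ndarray, mono: bool) -> np.ndarray:
    if mono:
        a2, b2, c2, ac = coeff
        return np.array([[a2, 0.0, ac], [0.0, b2, 0.0], [ac, 0.0, c2]])
    a2, b2, c2, ab, ac, bc = coeff
    return np.array([[a2, ab, ac], [ab, b2, bc], [ac, bc, c2]])


def _proj_design(hkl: np.ndarray, mono: bool) -> np.ndarray:
    cols = hkl.astype(float)
    return cols[:, [0, 2]] if mono else cols


def _proj_full(proj: np.ndarray, mono: bool) -> np.ndarray:
    return np.array([proj[0], 0.0, proj[1]]) if mono else np.asarray(proj, dtype=float)


def _volume_from_metric(coeff: np.ndarray, mono: bool) -> float:
    """Direct-cell volume implied by the reciprocal-metric coefficients."""
    det = float(np.linalg.det(_metric_to_gram(coeff, mono)))
    if det <= 0:
        return float("inf")
    return (2.0 * math.pi) ** 3 / math.sqrt(det)


def _gram_to_cell(gram: np.ndarray) -> DirectCell | None:
    """Invert a reciprocal Gram matrix to a direct cell, or None if not valid."""
    if np.any(np.linalg.eigvalsh(gram) <= 0):
        return None
    a_s, b_s, c_s = np.sqrt(np.diag(gram))
    ca = gram[1, 2] / (b_s * c_s)
    cb = gram[0, 2] / (a_s * c_s)
    cg = gram[0, 1] / (a_s * b_s)
    if max(abs(ca), abs(cb), abs(cg)) >= 1.0 - 1e-12:
        return None
    rec = ReciprocalCell(
        a_s,
        b_s,
        c_s,
        math.degrees(math.acos(ca)),
        math.degrees(math.acos(cb)),
        math.degrees(math.acos(cg)),
    )
    try:
        return rec.direct()
    except ValueError:
        return None


def seed_qz_system(peaks: PeakList, config: NospecConfig) -> list[SeedCandidate]:
    """Overdetermined q_z seed systems from the four lowest-q reflections.

    Every integer combination of the four reflections' Laue indices within
    the seed caps yields a four-row linear system for the normal projections
    of the reciprocal basis; rank-deficient combinations are skipped, the
    mirror (all-indices-flipped) assignment is emitted once, and candidates
    are ranked by the least-squares residual norm.
    """
    if len(peaks) < 4:
        raise ValueError(f"at least 4 GIXD peaks required, got {len(peaks)}")
    mono = config.cell_type == "monoclinic"
    order = sorted(range(len(peaks)), key=lambda i: (peaks.gixd[i].q_xyz, i))
    idx4 = order[:4]
    q_z4 = np.array([peaks.gixd[i].q_z for i in idx4])

    hr = np.arange(-config.seed_h_cap, config.seed_h_cap + 1)
    kr = np.arange(-config.seed_k_cap, config.seed_k_cap + 1)
    lr = np.arange(-config.seed_l_cap, config.seed_l_cap + 1)
    if mono:
        hh, ll = np.meshgrid(hr, lr, indexing="ij")
        opts = np.column_stack([hh.ravel(), np.zeros(hh.size, dtype=int), ll.ravel()])
    else:
        hh, kk, ll = np.meshgrid(hr, kr, lr, indexing="ij")
        opts = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
        opts = opts[np.any(opts != 0, axis=1)]  # (0 0 0) is not a reflection
    m = len(opts)
    ncols = 2 if mono else 3
    cols = _proj_design(opts, mono)

    # canonical sign: restrict the first peak's triple to one sign class
    canon = np.array([tuple(t) >= tuple(-x for x in t) for t in opts])
    first_opts = np.nonzero(canon)[0]

    combo_iter = np.array(
        np.meshgrid(first_opts, np.arange(m), np.arange(m), np.arange(m), indexing="ij")
    ).reshape(4, -1)
    k_total = combo_iter.shape[1]
    res_all = np.empty(k_total)
    chunk = 250_000
    for s in range(0, k_total, chunk):
        e = min(s + chunk, k_total)
        design = np.stack([cols[combo_iter[i, s:e]] for i in range(4)], axis=1)  # (B,4,nc)
        gram = np.einsum("bij,bik->bjk", design, design)
        rhs = np.einsum("bij,i->bj", design, q_z4)
        det = np.linalg.det(gram)
        ok = det > 1e-9
        sol = np.zeros((e - s, ncols))
        if np.any(ok):
            sol[ok] = np.linalg.solve(gram[ok], rhs[ok][:, :, None])[:, :, 0]
        fit = np.einsum("bij,bj->bi", design, sol)
        res2 = np.sum((fit - q_z4[None, :]) ** 2, axis=1)
        res_all[s:e] = np.where(ok, np.sqrt(np.maximum(res2, 0.0)), np.inf)

    keep = min(config.beam_width, k_total)
    part = np.argpartition(res_all, keep - 1)[:keep]
    part = part[np.lexsort((part, res_all[part]))]
    out: list[SeedCandidate] = []
    seen: set[tuple] = set()
    for j in part:
        if not np.isfinite(res_all[j]):
            continue
        hkl = opts[combo_iter[:, j]]
        key = tuple(map(tuple, hkl))
        if tuple(map(tuple, -hkl)) in seen:  # mirrored normal, same physics
            continue
        seen.add(key)
        design = _proj_design(hkl, mono)
        sol, *_ = np.linalg.lstsq(design, q_z4, rcond=None)
        out.append(SeedCandidate(list(idx4), hkl.copy(), sol, None, float(res_all[j])))
    return out


def _fit_candidate(cand: SeedCandidate, peaks: PeakList, mono: bool) -> tuple | None:
    """Joint least-squares refit of metric and projections for assigned peaks."""
    q_xyz = np.array([peaks.gixd[i].q_xyz for i in cand.peak_idx])
    q_z = np.array([peaks.gixd[i].q_z for i in cand.peak_idx])
    md = _metric_design(cand.hkl, mono)
    if np.linalg.matrix_rank(md) < md.shape[1]:
        return None
    metric, *_ = np.linalg.lstsq(md, q_xyz**2, rcond=None)
    pd = _proj_design(cand.hkl, mono)
    proj, *_ = np.linalg.lstsq(pd, q_z, rcond=None)
    pred_q2 = md @ metric
    if np.any(pred_q2 <= 0):
        return None
    res = float(
        np.sqrt(np.sum((np.sqrt(pred_q2) - q_xyz) ** 2) + np.sum((pd @ proj - q_z) ** 2))
    )
    return metric, proj, res


def _extend_seeds(
    seeds: list[SeedCandidate], peaks: PeakList, config: NospecConfig
) -> list[SeedCandidate]:
    """Make the metric solvable: vary k of the seed peaks (monoclinic) or the
    indices of reflections five and six (triclinic), batched per seed."""
    mono = config.cell_type == "monoclinic"
    order = sorted(range(len(peaks)), key=lambda i: (peaks.gixd[i].q_xyz, i))
    # (rank tuple, candidate): residual, then deviation of the fitted normal
    # from unit length, then the index assignment as a deterministic tie-break
    scored: list[tuple[tuple, SeedCandidate]] = []

    if mono:
        kr = np.arange(-config.seed_k_cap, config.seed_k_cap + 1)
        kc = np.array(np.meshgrid(kr, kr, kr, kr, indexing="ij")).reshape(4, -1).T  # (K,4)
        for seed in seeds:
            q_xyz = np.array([peaks.gixd[i].q_xyz for i in seed.peak_idx])
            base = seed.hkl[None, :, :].repeat(len(kc), axis=0)  # (K,4,3)
            base[:, :, 1] = kc
            valid = ~np.any(np.all(base == 0, axis=2), axis=1)
            hkls = base[valid]
            k_n = len(hkls)
            h, k, l = (hkls[:, :, i].astype(float) for i in range(3))
            md = np.stack([h * h, k * k, l * l, 2 * h * l], axis=2)  # (K,4,4)
            det = np.abs(np.linalg.det(md))
            ok = det > 1e-9
            if not np.any(ok):
                continue
            metric = np.zeros((k_n, 4))
            rhs4 = np.broadcast_to(q_xyz**2, (int(ok.sum()), 4)).copy()
            metric[ok] = np.linalg.solve(md[ok], rhs4[:, :, None])[:, :, 0]
            gram = np.zeros((k_n, 3, 3))
            gram[:, 0, 0] = metric[:, 0]
            gram[:, 1, 1] = metric[:, 1]
            gram[:, 2, 2] = metric[:, 2]
            gram[:, 0, 2] = gram[:, 2, 0] = metric[:, 3]
            with np.errstate(invalid="ignore"):
                eig = np.linalg.eigvalsh(np.where(np.isfinite(gram), gram, 0.0))
            ok &= np.all(eig > 1e-12, axis=1)
            if not np.any(ok):
                continue
            pf = _proj_full(seed.proj, mono)
            consdev = np.full(k_n, np.inf)
            sel = np.nonzero(ok)[0]
            sol = np.linalg.solve(gram[sel], np.broadcast_to(pf, (len(sel), 3)).copy()[:, :, None])
            consdev[sel] = np.abs(np.einsum("bi,bi->b", sol[:, :, 0], np.broadcast_to(pf, (len(sel), 3))) - 1.0)
            good = np.nonzero(consdev <= config.normal_tol)[0]
            for i in good:
                cand = SeedCandidate(
                    list(seed.peak_idx), hkls[i].copy(), seed.proj, metric[i], seed.residual
                )
                scored.append((_beam_key(cand, mono), cand))
    else:
        hr = np.arange(-config.seed_h_cap, config.seed_h_cap + 1)
        kr = np.arange(-config.seed_k_cap, config.seed_k_cap + 1)
        lr = np.arange(-config.seed_l_cap, config.seed_l_cap + 1)
        hh, kk, ll = np.meshgrid(hr, kr, lr, indexing="ij")
        opts = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
        opts = opts[np.any(opts != 0, axis=1)]
        if not seeds:
            return []
        next_two = [i for i in order if i not in seeds[0].peak_idx][:2]
        if len(next_two) < 2:
            raise ValueError("triclinic indexing requires at least six peaks")
        q5, q6 = (peaks.gixd[i] for i in next_two)
        i5, i6 = np.meshgrid(np.arange(len(opts)), np.arange(len(opts)), indexing="ij")
        t5 = opts[i5.ravel()]  # (K,3)
        t6 = opts[i6.ravel()]
        md5 = _metric_design(t5, mono)
        md6 = _metric_design(t6, mono)
        pd5 = _proj_design(t5, mono)
        pd6 = _proj_design(t6, mono)
        for seed in seeds:
            q_xyz6 = np.array(
                [peaks.gixd[i].q_xyz for i in seed.peak_idx] + [q5.q_xyz, q6.q_xyz]
            )
            q_z6 = np.array([peaks.gixd[i].q_z for i in seed.peak_idx] + [q5.q_z, q6.q_z])
            md_seed = _metric_design(seed.hkl, mono)  # (4,6)
            pd_seed = _proj_design(seed.hkl, mono)  # (4,3)
            k_n = len(t5)
            md = np.empty((k_n, 6, 6))
            md[:, :4, :] = md_seed
            md[:, 4, :] = md5
            md[:, 5, :] = md6
            det = np.abs(np.linalg.det(md))
            ok = det > 1e-9
            if not np.any(ok):
                continue
            metric = np.zeros((k_n, 6))
            rhs6 = np.broadcast_to(q_xyz6**2, (int(ok.sum()), 6)).copy()
            metric[ok] = np.linalg.solve(md[ok], rhs6[:, :, None])[:, :, 0]
            # positive definiteness of the reciprocal Gram matrix
            gram = np.zeros((k_n, 3, 3))
            gram[:, 0, 0] = metric[:, 0]
            gram[:, 1, 1] = metric[:, 1]
            gram[:, 2, 2] = metric[:, 2]
            gram[:, 0, 1] = gram[:, 1, 0] = metric[:, 3]
            gram[:, 0, 2] = gram[:, 2, 0] = metric[:, 4]
            gram[:, 1, 2] = gram[:, 2, 1] = metric[:, 5]
            with np.errstate(invalid="ignore"):
                eig = np.linalg.eigvalsh(gram)
            ok &= np.all(eig > 1e-12, axis=1)
            if not np.any(ok):
                continue
            # projection refit over six q_z rows, batched via normal equations
            pd = np.empty((k_n, 6, 3))
            pd[:, :4, :] = pd_seed
            pd[:, 4, :] = pd5
            pd[:, 5, :] = pd6
            ng = np.einsum("bij,bik->bjk", pd, pd)
            nr = np.einsum("bij,i->bj", pd, q_z6)
            okp = ok & (np.linalg.det(ng) > 1e-9)
            if not np.any(okp):
                continue
            proj = np.zeros((k_n, 3))
            proj[okp] = np.linalg.solve(ng[okp], nr[okp][:, :, None])[:, :, 0]
            res_z2 = np.sum((np.einsum("bij,bj->bi", pd, proj) - q_z6[None, :]) ** 2, axis=1)
            res = np.where(okp, np.sqrt(np.maximum(res_z2, 0.0)), np.inf)
            consdev = np.full(k_n, np.inf)
            sel = np.nonzero(okp)[0]
            sol = np.linalg.solve(gram[sel], proj[sel][:, :, None])[:, :, 0]
            consdev[sel] = np.abs(np.einsum("bi,bi->b", sol, proj[sel]) - 1.0)
            good = np.nonzero(np.isfinite(res) & (consdev <= config.normal_tol))[0]
            if good.size > 4 * config.beam_width:
                good = good[np.argpartition(res[good], 4 * config.beam_width)[: 4 * config.beam_width]]
            for i in good:
                cand = SeedCandidate(
                    list(seed.peak_idx) + next_two,
                    np.vstack([seed.hkl, t5[i], t6[i]]),
                    proj[i].copy(),
                    metric[i].copy(),
                    float(res[i]),
                )
                scored.append((_beam_key(cand, mono), cand))
    scored.sort(key=lambda t: t[0])
    return _dedup_beam([cand for _, cand in scored], config.beam_width)


def _beam_key(cand: SeedCandidate, mono: bool) -> tuple:
    """Beam ranking: residual ties resolved toward the smallest cell volume.

    Any superlattice of the generating cell fits the data as well as the cell
    itself, so among near-tied residuals the smallest volume is preferred;
    the index assignment is the final deterministic tie-break.
    """
    return (
        round(cand.residual / 1e-4),
        round(_volume_from_metric(cand.metric, mono), 6),
        cand.residual,
        tuple(map(tuple, cand.hkl)),
    )


def _dedup_beam(cands: list[SeedCandidate], width: int) -> list[SeedCandidate]:
    """Drop lineages with identical fitted unknowns (index-sign mirrors etc.)."""
    seen: set[tuple] = set()
    out: list[SeedCandidate] = []
    for cand in cands:
        key = (
            tuple(np.round(cand.metric, 9)),
            tuple(np.round(np.abs(cand.proj), 9)),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(cand)
        if len(out) >= width:
            break
    return out


def grow_and_fit(
    seeds: list[SeedCandidate], peaks: PeakList, config: NospecConfig
) -> list[Solution]:
    """Expand seed systems over the full peak list and extract reduced cells.

    After the extension step the remaining reflections are assigned one at a
    time (indices within the assignment cap, smallest combined deviation in
    q_xyz and q_z first) with a joint refit after each addition; candidates
    whose fitted normal is inconsistent with the metric (not unit length
    within ``normal_tol``) are dropped, and surviving metrics are inverted,
    Niggli reduced and reported with orientation angles.
    """
    mono = config.cell_type == "monoclinic"
    n_min = 4 if mono else 6
    if len(peaks) < n_min:
        raise ValueError(
            f"{config.cell_type} indexing requires at least {n_min} peaks, got {len(peaks)}"
        )
    order = sorted(range(len(peaks)), key=lambda i: (peaks.gixd[i].q_xyz, i))
    beam = _extend_seeds(seeds, peaks, config)

    ar = np.arange(-config.assign_cap, config.assign_cap + 1)
    hh, kk, ll = np.meshgrid(ar, ar, ar, indexing="ij")
    assign_opts = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    assign_opts = assign_opts[np.any(assign_opts != 0, axis=1)]
    a_metric = _metric_design(assign_opts, mono)
    a_proj = _proj_design(assign_opts, mono)
    bulk = np.abs(assign_opts).sum(axis=1)

    remaining = [i for i in order if beam and i not in beam[0].peak_idx]
    for i in remaining:
        pk = peaks.gixd[i]
        survivors: list[SeedCandidate] = []
        for cand in beam:
            pred_q2 = a_metric @ cand.metric
            pred_qz = a_proj @ cand.proj
            with np.errstate(invalid="ignore"):
                dev = np.where(
                    pred_q2 > 0,
                    np.hypot(np.sqrt(np.maximum(pred_q2, 0.0)) - pk.q_xyz, pred_qz - pk.q_z),
                    np.inf,
                )
            j = np.lexsort((assign_opts[:, 2], assign_opts[:, 1], assign_opts[:, 0], bulk, dev))[0]
            cand.peak_idx = cand.peak_idx + [i]
            cand.hkl = np.vstack([cand.hkl, assign_opts[j]])
            fit = _fit_candidate(cand, peaks, mono)
            if fit is None:
                continue
            cand.metric, cand.proj, cand.residual = fit
            survivors.append(cand)
        # beam pruning after every addition: residual first, volume on ties
        survivors.sort(key=lambda c: _beam_key(c, mono))
        beam = _dedup_beam(survivors, config.beam_width)

    solutions: list[Solution] = []
    for cand in beam:
        if cand.metric is None:
            continue
        gram = _metric_to_gram(cand.metric, mono)
        full_proj = _proj_full(cand.proj, mono)
        try:
            consistency = float(full_proj @ np.linalg.solve(gram, full_proj))
        except np.linalg.LinAlgError:
            continue
        if abs(consistency - 1.0) > config.normal_tol:
            continue
        cell = _gram_to_cell(gram)
        if cell is None:
            continue
        perm = np.argsort(np.array(cand.peak_idx), kind="stable")
        hkl = cand.hkl[perm]
        reduced, m = niggli_reduce(cell)
        hkl_r = transform_indices(hkl, m)
        if not _within_bounds(reduced, config):
            continue
        sol = _solution_from_cell(reduced, hkl_r, peaks)
        if sol is not None:
            solutions.append(sol)

    if solutions:
        # near-tied deviations (supercells index any pattern their sublattice
        # indexes) are ordered by ascending cell volume
        order_s = _gated_order(
            np.array([s.errors.dq_xyz for s in solutions]),
            np.array([s.volume for s in solutions]),
            3.0,
        )
        solutions = [solutions[i] for i in order_s]
    deduped: list[Solution] = []
    for sol in solutions:
        if any(_cells_close(sol.cell, prev.cell) for prev in deduped):
            continue
        deduped.append(sol)
        if len(deduped) >= config.max_solutions:
            break
    return deduped


def _within_bounds(cell: DirectCell, config: NospecConfig) -> bool:
    lengths = sorted(cell.lengths)
    ranges = (config.a_range, config.b_range, config.c_range)
    if not all(lo <= x <= hi for x, (lo, hi) in zip(lengths, ranges)):
        return False
    if config.volume_range is not None:
        lo, hi = config.volume_range
        if not lo <= cell.volume() <= hi:
            return False
    return niggli_main_ok(cell, rel=0.05)


def _cells_close(c1: DirectCell, c2: DirectCell) -> bool:
    return (
        abs(c1.a - c2.a) <= 5e-3 * c2.a
        and abs(c1.b - c2.b) <= 5e-3 * c2.b
        and abs(c1.c - c2.c) <= 5e-3 * c2.c
        and abs(c1.alpha - c2.alpha) <= 0.3
        and abs(c1.beta - c2.beta) <= 0.3
        and abs(c1.gamma - c2.gamma) <= 0.3
    )


def _solution_from_cell(cell: DirectCell, hkl: np.ndarray, peaks: PeakList) -> Solution | None:
    """Residuals, orientation and error report for a reduced cell + assignment.

    The normal projections are refitted in the reduced basis (a plain linear
    least-squares problem) before the orientation angles are extracted.
    """
    q_xy, q_z = peaks.arrays()
    q_xyz = np.hypot(q_xy, q_z)
    bstar = cell.reciprocal_basis()
    pd = hkl.astype(float)
    proj, *_ = np.linalg.lstsq(pd, q_z, rcond=None)
    # the normal and its mirror describe the same texture; canonicalize to
    # psi <= 90 deg by flipping the normal together with all Laue indices
    if np.linalg.solve(bstar, proj)[2] < 0:
        proj = -proj
        hkl = -hkl
        pd = -pd
    try:
        orientation = orientation_from_projection(cell, proj)
    except ValueError:
        return None
    n_c = orientation.normal()
    gvec = pd @ bstar
    g_xyz = np.linalg.norm(gvec, axis=1)
    g_z = gvec @ n_c
    d_xy = np.abs(np.sqrt(np.maximum(g_xyz**2 - g_z**2, 0.0)) - q_xy)
    d_z = np.abs(g_z - q_z)
    d_xyz = np.abs(g_xyz - q_xyz)
    errors = RmsdReport(rmsd(d_xy), rmsd(d_z), rmsd(d_xyz), None)
    indexed = tuple(
        IndexedPeak(p, LaueTriple(*map(int, t)), float(x), float(z), float(xz))
        for p, t, x, z, xz in zip(peaks.gixd, hkl, d_xy, d_z, d_xyz)
    )
    return Solution(cell, None, indexed, errors, cell.volume(), orientation)


def orientation_from_projection(
    cell: DirectCell, proj: np.ndarray, tol: float = 0.05
) -> Orientation:
    """Rotation angles (psi, phi) from the normal projections of a*, b*, c*.

    Solves M n = proj with M the reciprocal basis rows in the canonical
    Cartesian frame; n must come out (nearly) unit length, otherwise the
    fitted projections are inconsistent with the metric (a Cauchy-Schwarz
    violation) and a ValueError is raised.
    """
    bstar = cell.reciprocal_basis()
    lengths = np.linalg.norm(bstar, axis=1)
    proj = np.asarray(proj, dtype=float)
    if np.any(np.abs(proj) > lengths * (1 + tol)):
        raise ValueError("normal projections exceed the reciprocal vector lengths")
    n_c = np.linalg.solve(bstar, proj)
    norm = float(np.linalg.norm(n_c))
    if abs(norm - 1.0) > tol:
        raise ValueError(f"fitted normal has length {norm:.4f}, not a unit vector")
    n_c /= norm
    psi = math.degrees(math.acos(max(-1.0, min(1.0, n_c[2]))))
    # below ~1e-3 deg of tilt the azimuth is numerically undefined
    phi = 0.0 if psi < 1e-3 else math.degrees(math.atan2(n_c[1], n_c[0]))
    return Orientation(psi, phi)


def index_without_specular(peaks: PeakList, config: NospecConfig | None = None) -> list[Solution]:
    """Full no-specular indexing: seed, extend, grow, fit, reduce, rank."""
    config = config or NospecConfig()
    mono = config.cell_type == "monoclinic"
    n_min = 4 if mono else 6
    if len(peaks) < n_min:
        raise ValueError(
            f"{config.cell_type} indexing requires at least {n_min} peaks, got {len(peaks)}"
        )
    seeds = seed_qz_system(peaks, config)
    return grow_and_fit(seeds, peaks, config)
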
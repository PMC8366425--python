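"""Two-stage indexing of GIXD peak lists using a specular diffraction peak.

The specular peak at (0, q_spec) pins the out-of-plane components of the
direct basis vectors: a.n = 2*pi*u/q_spec and b.n = 2*pi*v/q_spec for a
contact plane (u v w).  Stage 1 exploits that the in-plane peak component
obeys, for trial integers (u, v, h, k),

    q_xy^2 = xi^2 X1 + 2 xi eta X2 + eta^2 X3,
    xi = h - u q_z / q_spec,   eta = k - v q_z / q_spec,

which is linear in the three coefficients (X1, X2, X3) of the reciprocal
metric of the substrate-plane projection of the (a, b) sublattice.  Three
independent peaks give a 3x3 system per integer combination; back
substitution yields (a, b, gamma).  Stage 2 writes the third basis vector as
c = p a_xy + q b_xy + (2*pi*w/q_spec) n, turning each peak's q_z into the
linear equation

    (q_spec h - q_z u) p + (q_spec k - q_z v) q = q_spec l - q_z w,

solved in the least-squares sense over three low-q_z start peaks for every
(w, l1, l2, l3) combination, which yields (c, alpha, beta).  The remaining
Laue indices l are then assigned analytically, cells are refined, Niggli
reduced, deduplicated and ranked by the summed RMSD in q_xyz.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from .lattice import TWO_PI, ContactPlane, DirectCell, LaueTriple, RmsdReport, g_vectors, rmsd
from .peaks import Peak, PeakList
from .reduction import niggli_main_ok, niggli_reduce, transform_indices
from .refine import refine_cell_first_order

__all__ = [
    "SearchConfig",
    "Stage1Candidate",
    "IndexedPeak",
    "Solution",
    "select_start_triples",
    "stage1_solve",
    "assign_hk",
    "rank_stage1",
    "stage2_solve",
    "assign_l",
    "finalize",
    "index_with_specular",
]

_HARMONIC_RTOL = 1e-3
_CAP_MAX = 8
# Candidates whose summed RMSDs differ by less than this are treated as tied
# (exact data produces whole families of numerically perfect supercell
# candidates); ties are broken by the parallelogram area, preferring the
# smallest cell, as in the sorting guidance for stage-1 sub-sets.
_DQ_QUANTUM = 1e-4


@dataclass(frozen=True)
class SearchConfig:
    """Caps, bounds and knobs of the exhaustive integer-index search.

    Defaults follow the shipped defaults of the search: contact-plane indices
    u, v within +/-2; h, k within +/-3 when building the stage-1 systems and
    within +/-6 (at most +/-8) for the final assignment; l within +/-6 (at
    most +/-8); a, b, c between 3 and 60 A; gamma between 60 and 120 deg.
    """

    uv_cap: int = 2
    hk_lse_cap: int = 3
    hk_assign_cap: int = 6
    l_cap: int = 6
    w_cap: int | None = None
    a_range: tuple[float, float] = (3.0, 60.0)
    b_range: tuple[float, float] = (3.0, 60.0)
    c_range: tuple[float, float] = (3.0, 60.0)
    gamma_range: tuple[float, float] = (60.0, 120.0)
    volume_range: tuple[float, float] | None = None
    fixed_plane: tuple[int, int, int] | None = None
    sort_key: str = "area"
    max_start_triples: int = 6
    max_stage1_sets: int = 20
    max_stage2_per_set: int = 60
    max_refine: int = 40
    require_reduced: bool = True
    workers: int = 1

    # quality gate: candidates whose summed RMSD exceeds
    # max(gate_factor * best, best + tie quantum) are ranked after the gated
    # family, which is ordered by cell size (smallest first); this prevents
    # dense supercells, which always overfit, from crowding out the smallest
    # cell with a comparable deviation.  The factor is generous because the
    # cell-size tie-break protects the gated family: supercells lose the size
    # comparison and cells smaller than the generating one cannot fit the
    # pattern anywhere near the noise level.
    gate_factor: float = 3.0

    def __post_init__(self) -> None:
        for name in ("uv_cap", "hk_lse_cap", "hk_assign_cap", "l_cap"):
            val = getattr(self, name)
            if val < 1 or val > _CAP_MAX:
                raise ValueError(f"{name} = {val} outside 1..{_CAP_MAX}")
        if self.w_cap is not None and not 0 <= self.w_cap <= _CAP_MAX:
            raise ValueError(f"w_cap = {self.w_cap} outside 0..{_CAP_MAX}")
        for name in ("a_range", "b_range", "c_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.sort_key not in ("dq_xy", "area"):
            raise ValueError(f"unknown stage-1 sort key {self.sort_key!r}")


@dataclass
class Stage1Candidate:
    """Partial solution (u, v, a, b, gamma) with the projected 2-D metric.

    ``x`` holds (|A*|^2, A*.B*, |B*|^2) of the substrate-plane projection of
    the (a, b) sublattice; ``a2d``, ``b2d``, ``cosg2d`` are the projected
    direct sublattice, needed for stage 2.
    """

    u: int
    v: int
    a: float
    b: float
    gamma: float
    x: tuple[float, float, float]
    a2d: float
    b2d: float
    cosg2d: float
    dq_xy: float = math.nan
    hk_candidates: np.ndarray | None = None  # (N, 4, 2) int
    hk_deltas: np.ndarray | None = None  # (N, 4)

    @property
    def area(self) -> float:
        return self.a * self.b * math.sin(math.radians(self.gamma))


@dataclass(frozen=True)
class IndexedPeak:
    """A measured peak with its assigned Laue triple and component residuals."""

    peak: Peak
    hkl: LaueTriple
    d_xy: float
    d_z: float
    d_xyz: float


@dataclass(frozen=True)
class Solution:
    """A Niggli-reduced cell with contact plane, indexing and summed RMSDs."""

    cell: DirectCell
    plane: ContactPlane | None
    indexed: tuple[IndexedPeak, ...]
    errors: RmsdReport
    volume: float
    orientation: "object | None" = None  # Orientation for the no-specular route


def _harmonic_pair(p1: Peak, p2: Peak, rtol: float = _HARMONIC_RTOL) -> bool:
    """True if one peak is an integer multiple of the other in both components."""
    lo, hi = (p1, p2) if p1.q_xyz <= p2.q_xyz else (p2, p1)
    if lo.q_xyz < 1e-9:
        return True
    r = hi.q_xyz / lo.q_xyz
    m = round(r)
    if m < 1 or m > 12 or abs(r - m) > rtol * max(1.0, r):
        return False
    scale = max(hi.q_xyz, 1e-12)
    return (
        abs(hi.q_xy - m * lo.q_xy) <= rtol * scale and abs(hi.q_z - m * lo.q_z) <= rtol * scale
    )


def select_start_triples(
    peaks: PeakList, max_triples: int, cond_limit: float = 1e8
) -> list[tuple[int, int, int]]:
    """Independent three-peak start sets, lowest combined q first.

    Returns index triples into ``peaks.gixd``.  Triples containing a harmonic
    pair, or whose quadratic design matrix (q_xy^2, q_xy q_z, q_z^2) is
    ill-conditioned, are rejected.  After the first triple, a new triple may
    share at most one peak with each accepted one, so the start sets spread
    over the pattern instead of reusing the same lowest reflections (whose
    in-plane indices may lack the diversity the linear systems need).
    """
    if len(peaks) < 3:
        raise ValueError(f"at least 3 GIXD peaks required, got {len(peaks)}")
    pk = peaks.gixd
    combos = sorted(
        itertools.combinations(range(len(pk)), 3),
        key=lambda t: (pk[t[0]].q_xyz + pk[t[1]].q_xyz + pk[t[2]].q_xyz, t),
    )
    out: list[tuple[int, int, int]] = []
    for t in combos:
        if any(len(set(t) & set(prev)) > 1 for prev in out):
            continue
        trio = [pk[i] for i in t]
        if any(_harmonic_pair(a, b) for a, b in itertools.combinations(trio, 2)):
            continue
        m = np.array([[p.q_xy**2, p.q_xy * p.q_z, p.q_z**2] for p in trio])
        scale = np.abs(m).max()
        if scale <= 0 or np.linalg.cond(m / scale) > cond_limit:
            continue
        out.append(t)
        if len(out) >= max_triples:
            break
    return out


def _uv_list(config: SearchConfig) -> list[tuple[int, int]]:
    if config.fixed_plane is not None:
        u, v, _ = config.fixed_plane
        return [(u, v)]
    cap = config.uv_cap
    out = []
    for u in range(-cap, cap + 1):
        for v in range(-cap, cap + 1):
            # (u, v, h, k) and its global sign flip solve the same system
            if u > 0 or (u == 0 and v >= 0):
                out.append((u, v))
    return out


_S1_FIELDS = ("u", "v", "a", "b", "gamma", "x1", "x2", "x3", "a2d", "b2d", "cosg2d")


def _stage1_arrays(
    triple: tuple[Peak, Peak, Peak], q_spec: float, config: SearchConfig
) -> dict[str, np.ndarray]:
    """Array-valued core of :func:`stage1_solve` (one row per candidate)."""
    if q_spec <= 0:
        raise ValueError("q_spec must be positive")
    cap = config.hk_lse_cap
    hs, ks = np.meshgrid(np.arange(-cap, cap + 1), np.arange(-cap, cap + 1), indexing="ij")
    hk = np.column_stack([hs.ravel(), ks.ravel()]).astype(float)  # (P, 2)
    q_xy = np.array([p.q_xy for p in triple])
    q_z = np.array([p.q_z for p in triple])
    rhs = q_xy**2

    parts: list[dict[str, np.ndarray]] = []
    for u, v in _uv_list(config):
        rows = []
        for i in range(3):
            xi = hk[:, 0] - u * q_z[i] / q_spec
            eta = hk[:, 1] - v * q_z[i] / q_spec
            rows.append(np.column_stack([xi * xi, 2 * xi * eta, eta * eta]))  # (P, 3)
        r0, r1, r2 = rows
        p = len(hk)
        x0 = r0[:, 0][:, None, None]
        y0 = r0[:, 1][:, None, None]
        z0 = r0[:, 2][:, None, None]
        x1 = r1[:, 0][None, :, None]
        y1 = r1[:, 1][None, :, None]
        z1 = r1[:, 2][None, :, None]
        x2 = r2[:, 0][None, None, :]
        y2 = r2[:, 1][None, None, :]
        z2 = r2[:, 2][None, None, :]
        b0, b1, b2 = rhs

        c00 = y1 * z2 - z1 * y2
        c01 = x1 * z2 - z1 * x2
        c02 = x1 * y2 - y1 * x2
        det = x0 * c00 - y0 * c01 + z0 * c02
        det_x1 = b0 * c00 - y0 * (b1 * z2 - z1 * b2) + z0 * (b1 * y2 - y1 * b2)
        det_x2 = x0 * (b1 * z2 - b2 * z1) - b0 * c01 + z0 * (x1 * b2 - b1 * x2)
        det_x3 = x0 * (y1 * b2 - b1 * y2) - y0 * (x1 * b2 - b1 * x2) + b0 * c02

        det = det.ravel()
        good = np.abs(det) > 1e-9
        if not np.any(good):
            continue
        idx = np.nonzero(good)[0]
        det = det[idx]
        x1s = det_x1.ravel()[idx] / det
        x2s = det_x2.ravel()[idx] / det
        x3s = det_x3.ravel()[idx] / det

        mask = (x1s > 1e-10) & (x3s > 1e-10) & (x1s * x3s - x2s * x2s > 1e-12)
        if not np.any(mask):
            continue
        idx, x1s, x2s, x3s = idx[mask], x1s[mask], x2s[mask], x3s[mask]

        astar = np.sqrt(x1s)
        bstar = np.sqrt(x3s)
        cosgs = x2s / (astar * bstar)
        mask = np.abs(cosgs) < 1.0 - 1e-9
        idx, astar, bstar, cosgs = idx[mask], astar[mask], bstar[mask], cosgs[mask]
        x1s, x2s, x3s = x1s[mask], x2s[mask], x3s[mask]
        sings = np.sqrt(1.0 - cosgs**2)
        a2d = TWO_PI / (astar * sings)
        b2d = TWO_PI / (bstar * sings)
        cos2d = -cosgs
        az = TWO_PI * u / q_spec
        bz = TWO_PI * v / q_spec
        a = np.sqrt(a2d**2 + az**2)
        b = np.sqrt(b2d**2 + bz**2)
        cosg = (a2d * b2d * cos2d + az * bz) / (a * b)
        gamma = np.degrees(np.arccos(np.clip(cosg, -1.0, 1.0)))

        # canonical ordering a <= b (relabels the first two basis vectors)
        swap = a > b
        a_f = np.where(swap, b, a)
        b_f = np.where(swap, a, b)
        u_f = np.where(swap, v, u)
        v_f = np.where(swap, u, v)
        x1_f = np.where(swap, x3s, x1s)
        x3_f = np.where(swap, x1s, x3s)
        a2d_f = np.where(swap, b2d, a2d)
        b2d_f = np.where(swap, a2d, b2d)

        ok = (
            (a_f >= config.a_range[0])
            & (a_f <= config.a_range[1])
            & (b_f >= config.b_range[0])
            & (b_f <= config.b_range[1])
            & (gamma >= config.gamma_range[0])
            & (gamma <= config.gamma_range[1])
            & (np.abs(cosg) <= a_f / (2.0 * b_f) + 1e-12)
        )
        if not np.any(ok):
            continue
        sel = np.nonzero(ok)[0]
        u_s = u_f[sel].astype(int)
        v_s = v_f[sel].astype(int)
        # canonical sign of (u, v): first nonzero positive
        flip = (u_s < 0) | ((u_s == 0) & (v_s < 0))
        u_s = np.where(flip, -u_s, u_s)
        v_s = np.where(flip, -v_s, v_s)
        part = {
            "u": u_s,
            "v": v_s,
            "a": a_f[sel],
            "b": b_f[sel],
            "gamma": gamma[sel],
            "x1": x1_f[sel],
            "x2": x2s[sel],
            "x3": x3_f[sel],
            "a2d": a2d_f[sel],
            "b2d": b2d_f[sel],
            "cosg2d": cos2d[sel],
        }
        parts.append(_dedup_arrays(part))
    if not parts:
        return {f: np.empty(0) for f in _S1_FIELDS}
    return {f: np.concatenate([p[f] for p in parts]) for f in _S1_FIELDS}


def _dedup_arrays(part: dict[str, np.ndarray], coarse: bool = False) -> dict[str, np.ndarray]:
    """Drop rows duplicating (u, v, a, b, gamma) at rounding precision,
    keeping the first occurrence (deterministic enumeration order).

    The coarse precision (0.01 A, 0.1 deg) merges candidates that first-order
    refinement would drive to the same cell anyway.
    """
    nd_len, nd_ang = (2, 1) if coarse else (3, 2)
    key = np.rec.fromarrays(
        [
            part["u"],
            part["v"],
            np.round(part["a"], nd_len),
            np.round(part["b"], nd_len),
            np.round(part["gamma"], nd_ang),
        ]
    )
    _, first = np.unique(key, return_index=True)
    first.sort()
    return {f: part[f][first] for f in part}


def _gated_order(dq: np.ndarray, size: np.ndarray, factor: float) -> np.ndarray:
    """Ranking with a quality gate: candidates within the gate (dq close to
    the best) ascending by size (area or volume), the rest after them
    ascending by dq.  Dense supercells always overfit slightly, so among
    near-tied deviations the smallest cell is the physical choice."""
    dq = np.asarray(dq, dtype=float)
    dq_min = float(dq.min())
    gate = max(factor * dq_min, dq_min + _DQ_QUANTUM)
    outside = dq > gate
    return np.lexsort((dq, np.where(outside, 0.0, size), outside))


def _candidates_from_arrays(arrays: dict[str, np.ndarray], rows=None) -> list[Stage1Candidate]:
    if rows is None:
        rows = range(len(arrays["a"]))
    return [
        Stage1Candidate(
            u=int(arrays["u"][j]),
            v=int(arrays["v"][j]),
            a=float(arrays["a"][j]),
            b=float(arrays["b"][j]),
            gamma=float(arrays["gamma"][j]),
            x=(float(arrays["x1"][j]), float(arrays["x2"][j]), float(arrays["x3"][j])),
            a2d=float(arrays["a2d"][j]),
            b2d=float(arrays["b2d"][j]),
            cosg2d=float(arrays["cosg2d"][j]),
        )
        for j in rows
    ]


def stage1_solve(
    triple: tuple[Peak, Peak, Peak], q_spec: float, config: SearchConfig
) -> list[Stage1Candidate]:
    """All admissible (u, v, a, b, gamma) sub-sets from one start triple.

    For every (u, v) within the plane cap and (h_i, k_i) within the stage-1
    index cap a 3x3 linear system in (X1, X2, X3) is solved (combinations with
    vanishing determinant are skipped); solutions failing realness, the a/b
    bounds, the gamma window or the 2-D reduced-cell screen are discarded;
    symmetry-redundant sign combinations and rounding-level duplicates are
    emitted once.
    """
    return _candidates_from_arrays(_stage1_arrays(triple, q_spec, config))


def _batch_dq_xy(
    arrays: dict[str, np.ndarray],
    q_xy: np.ndarray,
    q_z: np.ndarray,
    q_spec: float,
    cap: int,
    chunk: int = 512,
) -> np.ndarray:
    """Summed RMSD in q_xy of the best (h, k) pair per peak, per candidate."""
    hk = _hk_grid(cap).astype(np.float32)
    n_cand = len(arrays["a"])
    out = np.empty(n_cand)
    uv_key = arrays["u"] * 100 + arrays["v"]
    q_xy32 = q_xy.astype(np.float32)
    for key in np.unique(uv_key):
        rows = np.nonzero(uv_key == key)[0]
        u = int(arrays["u"][rows[0]])
        v = int(arrays["v"][rows[0]])
        xi = hk[:, 0][None, :] - np.float32(u) * (q_z[:, None] / q_spec).astype(np.float32)
        eta = hk[:, 1][None, :] - np.float32(v) * (q_z[:, None] / q_spec).astype(np.float32)
        xi2, xieta, eta2 = xi * xi, xi * eta, eta * eta
        x1 = arrays["x1"].astype(np.float32)
        x2 = arrays["x2"].astype(np.float32)
        x3 = arrays["x3"].astype(np.float32)
        for s in range(0, len(rows), chunk):
            sel = rows[s : s + chunk]
            pred2 = (
                x1[sel, None, None] * xi2
                + 2.0 * x2[sel, None, None] * xieta
                + x3[sel, None, None] * eta2
            )
            np.maximum(pred2, 0.0, out=pred2)
            np.sqrt(pred2, out=pred2)
            pred2 -= q_xy32[None, :, None]
            np.abs(pred2, out=pred2)
            best = pred2.min(axis=2).astype(float)  # (B, N)
            out[sel] = np.sqrt(np.mean(best * best, axis=1))
    return out


def _predicted_q_xy(cand: Stage1Candidate, q_z: np.ndarray, hk: np.ndarray, q_spec: float):
    """Model q_xy for each peak (rows) and (h, k) pair (columns)."""
    x1, x2, x3 = cand.x
    xi = hk[:, 0][None, :] - cand.u * q_z[:, None] / q_spec
    eta = hk[:, 1][None, :] - cand.v * q_z[:, None] / q_spec
    return np.sqrt(np.maximum(xi * xi * x1 + 2 * xi * eta * x2 + eta * eta * x3, 0.0))


def _hk_grid(cap: int) -> np.ndarray:
    hs, ks = np.meshgrid(np.arange(-cap, cap + 1), np.arange(-cap, cap + 1), indexing="ij")
    return np.column_stack([hs.ravel(), ks.ravel()])


def assign_hk(
    cand: Stage1Candidate, peaks: PeakList, q_spec: float, cap: int
) -> Stage1Candidate:
    """Attach the four best (h, k) pairs per peak and the set's dq_xy.

    Pairs within +/-cap are ranked by |Delta q_xy| with the deterministic
    tie order (|h|+|k|, h, k); the set's dq_xy is the summed RMSD of each
    peak's best pair.
    """
    if cap > _CAP_MAX:
        raise ValueError(f"assignment cap {cap} above maximum {_CAP_MAX}")
    q_xy, q_z = peaks.arrays()
    hk = _hk_grid(cap)
    delta = np.abs(q_xy[:, None] - _predicted_q_xy(cand, q_z, hk.astype(float), q_spec))
    bulk = np.abs(hk).sum(axis=1)
    n = len(q_xy)
    hk4 = np.empty((n, 4, 2), dtype=int)
    d4 = np.empty((n, 4))
    for i in range(n):
        order = np.lexsort((hk[:, 1], hk[:, 0], bulk, delta[i]))[:4]
        hk4[i] = hk[order]
        d4[i] = delta[i][order]
    dq = rmsd(d4[:, 0])
    return replace(cand, dq_xy=dq, hk_candidates=hk4, hk_deltas=d4)


def rank_stage1(
    candidates: list[Stage1Candidate],
    key: str = "dq_xy",
    len_rtol: float = 5e-3,
    ang_atol: float = 0.3,
) -> list[Stage1Candidate]:
    """Stable ascending sort with tolerance merging of duplicates.

    Duplicates (same u, v and matching a, b, gamma within tolerance) keep the
    smaller dq_xy representative.  Under the dq_xy key, deviations closer than
    the tie quantum are ranked by ascending parallelogram area.
    """
    if key == "dq_xy":
        sort_key = lambda c: (round(c.dq_xy / _DQ_QUANTUM), c.area, c.a, c.b, c.gamma, c.u, c.v)
    elif key == "area":
        sort_key = lambda c: (c.area, c.dq_xy, c.a, c.b, c.gamma, c.u, c.v)
    else:
        raise ValueError(f"unknown stage-1 sort key {key!r}")
    return _merge_ordered(sorted(candidates, key=sort_key), len_rtol, ang_atol)


def _merge_ordered(
    candidates: list[Stage1Candidate], len_rtol: float = 5e-3, ang_atol: float = 0.3
) -> list[Stage1Candidate]:
    """Keep-first tolerance merge of an already-ordered candidate list."""
    kept: list[Stage1Candidate] = []
    for cand in candidates:
        dup = False
        for prev in kept:
            if (
                prev.u == cand.u
                and prev.v == cand.v
                and abs(prev.a - cand.a) <= len_rtol * cand.a
                and abs(prev.b - cand.b) <= len_rtol * cand.b
                and abs(prev.gamma - cand.gamma) <= ang_atol
            ):
                dup = True
                break
        if not dup:
            kept.append(cand)
    return kept


def _start_qz_peaks(peaks: PeakList, rtol: float = _HARMONIC_RTOL) -> list[int]:
    """Indices of the three lowest q_z values that are not mutual multiples."""
    order = sorted(range(len(peaks)), key=lambda i: (peaks.gixd[i].q_z, peaks.gixd[i].q_xy, i))
    chosen: list[int] = []
    for i in order:
        qi = peaks.gixd[i].q_z
        ok = True
        for j in chosen:
            qj = peaks.gixd[j].q_z
            lo, hi = min(qi, qj), max(qi, qj)
            if lo < 0.05:
                # near-in-plane peaks: their equations stay independent
                # through (h, k); only (near-)duplicates are harmonic
                if hi - lo < 1e-3:
                    ok = False
                continue
            r = hi / lo
            m = round(r)
            # a ratio near a small integer marks a multiple; huge ratios
            # cannot belong to one reflection family within the index caps
            if 1 <= m <= 12 and abs(r - m) <= rtol * m:
                ok = False
        if ok:
            chosen.append(i)
        if len(chosen) == 3:
            return chosen
    raise ValueError("fewer than three non-harmonic q_z start values available")


@dataclass(frozen=True)
class Stage2Result:
    """A full candidate: cell, plane and the stage-1 hk table, plus the
    least-squares residual norm of the stage-2 system."""

    cell: DirectCell
    plane: ContactPlane
    stage1: Stage1Candidate
    residual: float


def stage2_solve(
    stage1: Stage1Candidate,
    peaks: PeakList,
    q_spec: float,
    config: SearchConfig,
    w_cap: int | None = None,
) -> list[Stage2Result]:
    """Determine (w, c, alpha, beta) for one carried stage-1 sub-set.

    For each combination of the start peaks' retained (h, k) pairs and each
    integer (w, l1, l2, l3) an overdetermined 3x2 system in the coordinates
    (p, q) of the third basis vector's in-plane part is solved by least
    squares; back substitution gives (c, alpha, beta).  Results are filtered
    by bounds, realness and (optionally) the reduced-cell main conditions.

    The three-equation residual norm alone has a single degree of freedom and
    cannot separate candidates once measurement noise is present, so survivors
    are ranked by the analytic-l out-of-plane deviation accumulated over the
    whole peak list (with the cell volume breaking near-ties, smallest first)
    before the per-set cap is applied.
    """
    if stage1.hk_candidates is None:
        raise ValueError("stage-1 candidate lacks hk assignment; run assign_hk first")
    u, v = stage1.u, stage1.v
    start = _start_qz_peaks(peaks)
    q_z3 = np.array([peaks.gixd[i].q_z for i in start])
    hk4 = stage1.hk_candidates[start]  # (3, 4, 2)

    if config.fixed_plane is not None:
        w_values = [config.fixed_plane[2]]
    else:
        cap_w = config.w_cap if config.w_cap is not None else (w_cap or config.uv_cap)
        if u == 0 and v == 0:
            w_values = list(range(1, cap_w + 1))
        else:
            w_values = list(range(-cap_w, cap_w + 1))
    lr = np.arange(-config.l_cap, config.l_cap + 1)
    l1g, l2g, l3g, wg = np.meshgrid(lr, lr, lr, np.array(w_values), indexing="ij")
    l_all = np.stack([l1g.ravel(), l2g.ravel(), l3g.ravel()])  # (3, K)
    w_all = wg.ravel()  # (K,)
    nontrivial = ~((w_all == 0) & np.all(l_all == 0, axis=0))
    l_all, w_all = l_all[:, nontrivial], w_all[nontrivial]
    rhs = q_spec * l_all - q_z3[:, None] * w_all[None, :]  # (3, K)

    a2 = stage1.a2d**2
    b2 = stage1.b2d**2
    ab = stage1.a2d * stage1.b2d * stage1.cosg2d
    az = TWO_PI * u / q_spec
    bz = TWO_PI * v / q_spec
    cosg = math.cos(math.radians(stage1.gamma))
    aa, bb = stage1.a, stage1.b

    chunks: list[np.ndarray] = []
    for j1, j2, j3 in itertools.product(range(4), repeat=3):
        hks = np.array([hk4[0, j1], hk4[1, j2], hk4[2, j3]], dtype=float)  # (3, 2)
        design = np.column_stack(
            [q_spec * hks[:, 0] - q_z3 * u, q_spec * hks[:, 1] - q_z3 * v]
        )  # (3, 2)
        normal = design.T @ design
        det = normal[0, 0] * normal[1, 1] - normal[0, 1] ** 2
        if det < 1e-9:
            continue
        inv = np.array([[normal[1, 1], -normal[0, 1]], [-normal[0, 1], normal[0, 0]]]) / det
        sol = inv @ (design.T @ rhs)  # (2, K)
        resid = np.sqrt(np.sum((design @ sol - rhs) ** 2, axis=0))  # (K,)

        p, q = sol
        cz = TWO_PI * w_all / q_spec
        c2 = p * p * a2 + 2 * p * q * ab + q * q * b2 + cz * cz
        good = c2 > 1e-12
        c = np.sqrt(np.where(good, c2, 1.0))
        ac = p * a2 + q * ab + az * cz
        bc = p * ab + q * b2 + bz * cz
        cosb = ac / (aa * c)
        cosa = bc / (bb * c)
        good &= (np.abs(cosa) < 1.0 - 1e-9) & (np.abs(cosb) < 1.0 - 1e-9)
        good &= (c >= config.c_range[0]) & (c <= config.c_range[1])
        disc = 1 - cosa**2 - cosb**2 - cosg**2 + 2 * cosa * cosb * cosg
        good &= disc > 1e-12
        vol = aa * bb * c * np.sqrt(np.maximum(disc, 0.0))
        if config.volume_range is not None:
            good &= (vol >= config.volume_range[0]) & (vol <= config.volume_range[1])
        if config.require_reduced:
            # vectorized axis-order-insensitive Niggli main conditions (2%
            # slack): sort the squared lengths, pair each with the scalar
            # product of the other two, and bound the products
            s = 1.02
            big_a, big_b, big_c = aa * aa, bb * bb, c * c  # big_a <= big_b
            p_a = 2 * bb * c * cosa  # b.c term, paired with a
            p_b = 2 * aa * c * cosb  # a.c term, paired with b
            p_c = 2 * aa * bb * cosg  # a.b term, paired with c
            hi = big_c >= big_b
            mid = (~hi) & (big_c >= big_a)
            lo = big_c < big_a
            cond = np.empty(len(c), dtype=bool)
            cond[:] = False
            cond |= hi & (np.abs(p_a) <= big_b * s) & (np.abs(p_b) <= big_a * s) & (
                np.abs(p_c) <= big_a * s
            )
            cond |= mid & (np.abs(p_a) <= big_c * s) & (np.abs(p_c) <= big_a * s) & (
                np.abs(p_b) <= big_a * s
            )
            cond |= lo & (np.abs(p_c) <= big_a * s) & (np.abs(p_a) <= big_c * s) & (
                np.abs(p_b) <= big_c * s
            )
            good &= cond
        idx = np.nonzero(good)[0]
        if idx.size == 0:
            continue
        vol = aa * bb * c * np.sqrt(np.maximum(disc, 0.0))
        chunks.append(
            np.column_stack(
                [
                    resid[idx],
                    w_all[idx].astype(float),
                    c[idx],
                    np.degrees(np.arccos(cosa[idx])),
                    np.degrees(np.arccos(cosb[idx])),
                    p[idx],
                    q[idx],
                    vol[idx],
                ]
            )
        )

    if not chunks:
        return []
    rows_arr = np.concatenate(chunks)
    # rounding-level duplicates (same w, c, alpha, beta) collapse to the first
    key = np.rec.fromarrays(
        [
            rows_arr[:, 1].astype(int),
            np.round(rows_arr[:, 2], 3),
            np.round(rows_arr[:, 3], 2),
            np.round(rows_arr[:, 4], 2),
        ]
    )
    _, first = np.unique(key, return_index=True)
    first.sort()
    rows_arr = rows_arr[first]

    score = _stage2_qxyz_score(
        rows_arr[:, 5], rows_arr[:, 6], rows_arr[:, 1], stage1, peaks, q_spec, config.l_cap
    )
    order = _gated_order(score, rows_arr[:, 7], config.gate_factor)

    out: list[Stage2Result] = []
    for i in order:
        resid, w_f, c, alpha, beta = rows_arr[i, :5]
        w = int(round(w_f))
        try:
            cell = DirectCell(stage1.a, stage1.b, float(c), float(alpha), float(beta), stage1.gamma)
        except ValueError:
            continue
        if config.require_reduced and not niggli_main_ok(cell):
            continue
        uu, vv, ww = u, v, w
        if uu == 0 and vv == 0 and ww < 0:
            ww = -ww
        out.append(Stage2Result(cell, ContactPlane(uu, vv, ww), stage1, float(resid)))
        if len(out) >= config.max_stage2_per_set:
            break
    return out


def _stage2_qxyz_score(
    p: np.ndarray,
    q: np.ndarray,
    w: np.ndarray,
    stage1: Stage1Candidate,
    peaks: PeakList,
    q_spec: float,
    l_cap: int,
) -> np.ndarray:
    """Summed RMSD in q_xyz over all peaks under analytic l assignment.

    The stage-2 relation gives, per peak and (h, k) pair, the real-valued l
    matching the measured q_z exactly; rounding it to the nearest integer
    yields the model out-of-plane component g_z = q_spec (hp + kq - l) /
    (up + vq - w), and the in-plane component follows from the stage-1
    projected metric at that g_z.  The score takes, per peak, the best of the
    four retained (h, k) pairs by |Delta q_xyz| - the same deviation the
    final assignment minimizes - so neither a dense out-of-plane grid nor a
    dense in-plane lattice alone can fake a good candidate.
    """
    q_xy, q_z = peaks.arrays()
    q_xyz = np.hypot(q_xy, q_z)
    x1, x2, x3 = stage1.x
    hk4 = stage1.hk_candidates  # (N, 4, 2)
    h = hk4[:, :, 0].astype(float)[None, :, :]  # (1, N, 4)
    k = hk4[:, :, 1].astype(float)[None, :, :]
    out = np.empty(len(p))
    for s in range(0, len(p), 20_000):
        e = min(s + 20_000, len(p))
        pc, qc, wc = p[s:e], q[s:e], w[s:e]
        denom = stage1.u * pc + stage1.v * qc - wc  # (B,)
        denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
        term = pc[:, None, None] * h + qc[:, None, None] * k  # (B, N, 4)
        with np.errstate(invalid="ignore"):
            l_real = term - q_z[None, :, None] * denom[:, None, None] / q_spec
            l_round = np.rint(l_real)
            g_z = q_spec * (term - l_round) / denom[:, None, None]
            xi = h - stage1.u * g_z / q_spec
            eta = k - stage1.v * g_z / q_spec
            g_xy2 = np.maximum(xi * xi * x1 + 2 * xi * eta * x2 + eta * eta * x3, 0.0)
            dev = np.abs(np.sqrt(g_xy2 + g_z * g_z) - q_xyz[None, :, None])
            dev = np.where(np.abs(l_round) > l_cap, np.inf, dev)
            best = np.nanmin(np.where(np.isnan(dev), np.inf, dev), axis=2)  # (B, N)
        best = np.where(np.isfinite(best), best, 1e3)
        out[s:e] = np.sqrt(np.mean(best * best, axis=1))
    return out


def assign_l(
    cell: DirectCell,
    plane: ContactPlane,
    peaks: PeakList,
    hk4: np.ndarray,
    l_cap: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic l assignment and final per-peak residuals.

    For each peak, each retained (h, k) pair and its centrosymmetric mate
    (-h, -k) - the sign class the in-plane data cannot distinguish - l follows
    linearly from the out-of-plane component (rounded to the nearest integer,
    ties toward the smaller |l|); the triple with the smallest |Delta q_xyz|
    is assigned, with |Delta q_z| breaking ties so the mate with the correct
    sign of g_z wins.  Returns (hkl, d_xy, d_z, d_xyz) arrays.
    """
    q_xy, q_z = peaks.arrays()
    q_xyz = np.hypot(q_xy, q_z)
    bstar = cell.reciprocal_basis()
    svec = np.asarray(plane.indices, dtype=float) @ bstar
    n_hat = svec / np.linalg.norm(svec)
    proj = bstar @ n_hat  # (a*.n, b*.n, c*.n)

    hk4 = np.concatenate([np.asarray(hk4), -np.asarray(hk4)], axis=1)  # both sign classes
    h = hk4[:, :, 0].astype(float)  # (N, 8)
    k = hk4[:, :, 1].astype(float)
    if abs(proj[2]) > 1e-12:
        l_real = (q_z[:, None] - h * proj[0] - k * proj[1]) / proj[2]
        # round half toward zero: ties go to the smaller |l|
        l_round = np.sign(l_real) * np.ceil(np.abs(l_real) - 0.5)
        l_opts = l_round[:, :, None]  # (N, 4, 1)
    else:
        # degenerate geometry: c* has no out-of-plane component; enumerate l
        l_opts = np.broadcast_to(
            np.arange(-l_cap, l_cap + 1, dtype=float), (*h.shape, 2 * l_cap + 1)
        )

    hh = h[:, :, None]
    kk = k[:, :, None]
    gvec = (
        hh[..., None] * bstar[0] + kk[..., None] * bstar[1] + l_opts[..., None] * bstar[2]
    )  # (N, 4, L, 3)
    g_xyz = np.linalg.norm(gvec, axis=-1)
    g_z = gvec @ n_hat
    d_xyz = np.abs(g_xyz - q_xyz[:, None, None])
    d_z_opt = np.abs(g_z - q_z[:, None, None])

    invalid = (np.abs(l_opts) > l_cap) | ((hh == 0) & (kk == 0) & (l_opts == 0))
    d_sort = np.where(invalid, np.inf, d_xyz)

    n = len(q_xy)
    hkl = np.empty((n, 3), dtype=int)
    for i in range(n):
        flat = d_sort[i].ravel()
        dzf = d_z_opt[i].ravel()
        hf = np.broadcast_to(hh[i], d_sort[i].shape).ravel()
        kf = np.broadcast_to(kk[i], d_sort[i].shape).ravel()
        lf = np.broadcast_to(l_opts[i], d_sort[i].shape).ravel()
        if np.all(np.isinf(flat)):
            # no admissible triple: clamp l into range, keep determinism
            lf = np.clip(lf, -l_cap, l_cap)
            gv = hf[:, None] * bstar[0] + kf[:, None] * bstar[1] + lf[:, None] * bstar[2]
            flat = np.abs(np.linalg.norm(gv, axis=1) - q_xyz[i])
            dzf = np.abs(gv @ n_hat - q_z[i])
            flat = np.where((hf == 0) & (kf == 0) & (lf == 0), np.inf, flat)
        order = np.lexsort(
            (lf, kf, hf, np.abs(hf) + np.abs(kf) + np.abs(lf), dzf, flat)
        )
        j = order[0]
        hkl[i] = (int(hf[j]), int(kf[j]), int(lf[j]))
    g_xy_f, g_z_f, g_xyz_f, _ = g_vectors(cell, plane, hkl)
    d_xy_out = np.abs(g_xy_f - q_xy)
    d_z_out = np.abs(g_z_f - q_z)
    d_xyz_out = np.abs(g_xyz_f - q_xyz)
    return hkl, d_xy_out, d_z_out, d_xyz_out


def _canonical_triple(t: tuple[int, int, int]) -> tuple[int, int, int]:
    neg = tuple(-x for x in t)
    return max(t, neg)


def _build_solution(
    cell: DirectCell,
    plane: ContactPlane,
    peaks: PeakList,
    hkl: np.ndarray,
    q_spec: float | None,
    orientation=None,
) -> Solution:
    q_xy, q_z = peaks.arrays()
    g_xy, g_z, g_xyz, g_spec = g_vectors(cell, plane, hkl)
    d_xy = np.abs(g_xy - q_xy)
    d_z = np.abs(g_z - q_z)
    d_xyz = np.abs(g_xyz - np.hypot(q_xy, q_z))
    errors = RmsdReport(
        dq_xy=rmsd(d_xy),
        dq_z=rmsd(d_z),
        dq_xyz=rmsd(d_xyz),
        dq_spec=None if q_spec is None else abs(g_spec - q_spec),
    )
    indexed = tuple(
        IndexedPeak(p, LaueTriple(*map(int, t)), float(x), float(z), float(xyz))
        for p, t, x, z, xyz in zip(peaks.gixd, hkl, d_xy, d_z, d_xyz)
    )
    return Solution(cell, plane, indexed, errors, cell.volume(), orientation)


def finalize(
    candidates: list[tuple[DirectCell, ContactPlane, np.ndarray]],
    peaks: PeakList,
    q_spec: float,
    config: SearchConfig,
) -> list[Solution]:
    """Refine, Niggli-reduce, deduplicate and rank full candidates.

    ``candidates`` are (cell, plane, hkl assignment) tuples.  Each cell is
    refined with fixed indices, reduced (indices and plane remapped into the
    reduced basis), and duplicates - same reduced cell within tolerance and
    the same Laue-index multiset - are merged keeping the smallest errors.
    """
    q_xy, q_z = peaks.arrays()
    solutions: list[Solution] = []
    for cell, plane, hkl in candidates:
        refined = refine_cell_first_order(cell, plane, hkl, q_xy, q_z, q_spec)
        reduced, m = niggli_reduce(refined)
        hkl_r = transform_indices(hkl, m)
        uvw = transform_indices(np.asarray(plane.indices), m)
        # canonical plane sign: flipping the plane flips the normal, so the
        # peak indices flip too (centrosymmetric relabeling keeps residuals)
        first = next((x for x in uvw if x != 0), 1)
        if first < 0:
            uvw = -uvw
            hkl_r = -hkl_r
        plane_r = ContactPlane(*(int(x) for x in uvw))
        solutions.append(_build_solution(reduced, plane_r, peaks, hkl_r, q_spec))

    if solutions:
        order_s = _gated_order(
            np.array([s.errors.dq_xyz for s in solutions]),
            np.array([s.volume for s in solutions]),
            config.gate_factor,
        )
        solutions = [solutions[i] for i in order_s]
    kept: list[Solution] = []
    kept_keys: list[tuple] = []
    for sol in solutions:
        multiset = tuple(sorted(_canonical_triple(ip.hkl.indices) for ip in sol.indexed))
        dup = False
        for prev, pkey in zip(kept, kept_keys):
            if pkey != multiset:
                continue
            pc, sc = prev.cell, sol.cell
            if (
                abs(pc.a - sc.a) <= 5e-3 * sc.a
                and abs(pc.b - sc.b) <= 5e-3 * sc.b
                and abs(pc.c - sc.c) <= 5e-3 * sc.c
                and abs(pc.alpha - sc.alpha) <= 0.3
                and abs(pc.beta - sc.beta) <= 0.3
                and abs(pc.gamma - sc.gamma) <= 0.3
            ):
                dup = True
                break
        if not dup:
            kept.append(sol)
            kept_keys.append(multiset)
    return kept


def index_with_specular(peaks: PeakList, config: SearchConfig | None = None) -> list[Solution]:
    """Full two-stage indexing of a peak list containing a specular peak."""
    config = config or SearchConfig()
    if not peaks.has_specular:
        raise ValueError("specular route requires a peak with q_xy = 0")
    if peaks.q_spec is None or peaks.q_spec <= 0:
        raise ValueError("specular peak must have q_z > 0")
    if len(peaks) < 3:
        raise ValueError("specular route requires at least 3 GIXD peaks plus the specular peak")
    q_spec = float(peaks.q_spec)

    triples = select_start_triples(peaks, config.max_start_triples)
    if not triples:
        raise ValueError("no independent start triple found")
    triple_peaks = [tuple(peaks.gixd[i] for i in t) for t in triples]

    if config.workers > 1:
        from joblib import Parallel, delayed

        per_triple = Parallel(n_jobs=config.workers)(
            delayed(_stage1_arrays)(t, q_spec, config) for t in triple_peaks
        )
    else:
        per_triple = [_stage1_arrays(t, q_spec, config) for t in triple_peaks]

    arrays = {f: np.concatenate([p[f] for p in per_triple]) for f in _S1_FIELDS}
    if len(arrays["a"]) == 0:
        return []
    arrays = _dedup_arrays(arrays, coarse=True)

    q_xy_all, q_z_all = peaks.arrays()
    area = arrays["a"] * arrays["b"] * np.sin(np.radians(arrays["gamma"]))
    dq = _batch_dq_xy(arrays, q_xy_all, q_z_all, q_spec, config.hk_assign_cap)

    pool_n = min(len(dq), 25 * config.max_stage1_sets)
    if config.sort_key == "area":
        order = _gated_order(dq, area, config.gate_factor)
    else:  # dq_xy: near-tied deviations ranked by ascending area
        order = np.lexsort((area, np.round(dq / _DQ_QUANTUM)))
    pool_rows = order[:pool_n]
    pool = _candidates_from_arrays(arrays, pool_rows)
    for cand, row in zip(pool, pool_rows):
        cand.dq_xy = float(dq[row])
    ranked = _merge_ordered(pool)
    carried = [
        assign_hk(c, peaks, q_spec, config.hk_assign_cap)
        for c in ranked[: config.max_stage1_sets]
    ]
    if not carried:
        return []

    w_cap = max(
        config.uv_cap, max(max(abs(c.u), abs(c.v)) for c in carried)
    )
    full: list[tuple[DirectCell, ContactPlane, np.ndarray, float]] = []
    for cand in carried:
        for res in stage2_solve(cand, peaks, q_spec, config, w_cap=w_cap):
            hkl, _, _, d_xyz = assign_l(
                res.cell, res.plane, peaks, cand.hk_candidates, config.l_cap
            )
            full.append((res.cell, res.plane, hkl, rmsd(d_xyz)))
    if not full:
        return []
    order_f = _gated_order(
        np.array([r[3] for r in full]),
        np.array([r[0].volume() for r in full]),
        config.gate_factor,
    )
    top = [
        (full[i][0], full[i][1], full[i][2]) for i in order_f[: config.max_refine]
    ]
    return finalize(top, peaks, q_spec, config)
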
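"""Niggli (Krivy-Gruber) cell reduction with unimodular transform tracking.

The iterative algorithm of Krivy & Gruber (1976) is applied to the Niggli
character (A, B, C, xi, eta, zeta) = (a^2, b^2, c^2, 2 b.c, 2 a.c, 2 a.b)
with an absolute tolerance proportional to the mean squared cell edge.
Each step's integer matrix (determinant +1) is accumulated, so Laue indices
and contact-plane indices of an indexed pattern can be remapped into the
reduced basis.
"""

from __future__ import annotations

import math

import numpy as np

from .lattice import ContactPlane, DirectCell

__all__ = ["niggli_reduce", "is_niggli", "niggli_2d_ok", "transform_indices", "transform_plane"]

_MAX_STEPS = 1000


def _sign(x: float, eps: float) -> int:
    if x > eps:
        return 1
    if x < -eps:
        return -1
    return 0


def _character(cell: DirectCell) -> list[float]:
    g = cell.metric()
    return [g[0, 0], g[1, 1], g[2, 2], 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]]


def _cell_from_character(p: list[float]) -> DirectCell:
    big_a, big_b, big_c, xi, eta, zeta = p
    a, b, c = math.sqrt(big_a), math.sqrt(big_b), math.sqrt(big_c)
    alpha = math.degrees(math.acos(max(-1.0, min(1.0, xi / (2 * b * c)))))
    beta = math.degrees(math.acos(max(-1.0, min(1.0, eta / (2 * a * c)))))
    gamma = math.degrees(math.acos(max(-1.0, min(1.0, zeta / (2 * a * b)))))
    return DirectCell(a, b, c, alpha, beta, gamma)


def niggli_reduce(cell: DirectCell, eps: float | None = None) -> tuple[DirectCell, np.ndarray]:
    """Reduce ``cell`` to its Niggli cell.

    Returns ``(reduced, M)`` where ``M`` is the integer matrix (det +1) with
    new basis rows a'_i = sum_j M_ij a_j; Laue and plane indices transform as
    h' = M h (see :func:`transform_indices`).
    """
    p = _character(cell)
    if eps is None:
        eps = 1e-5 * (p[0] + p[1] + p[2]) / 3.0
    m_total = np.eye(3, dtype=int)

    def apply(m: np.ndarray) -> None:
        nonlocal m_total
        m_total = m @ m_total

    for _ in range(_MAX_STEPS):
        big_a, big_b, big_c, xi, eta, zeta = p
        # step 1: order a <= b
        if big_a > big_b + eps or (abs(big_a - big_b) <= eps and abs(xi) > abs(eta) + eps):
            p = [big_b, big_a, big_c, eta, xi, zeta]
            apply(np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]]))
            continue
        # step 2: order b <= c
        if big_b > big_c + eps or (abs(big_b - big_c) <= eps and abs(eta) > abs(zeta) + eps):
            p = [big_a, big_c, big_b, xi, zeta, eta]
            apply(np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]]))
            continue
        l, m, n = _sign(xi, eps), _sign(eta, eps), _sign(zeta, eps)
        if l * m * n == 1:
            # step 3: make all angle terms positive
            i = -1 if l == -1 else 1
            j = -1 if m == -1 else 1
            k = -1 if n == -1 else 1
            if (i, j, k) != (1, 1, 1):
                p = [big_a, big_b, big_c, j * k * xi, i * k * eta, i * j * zeta]
                apply(np.diag([i, j, k]))
                continue
        else:
            # step 4: make all angle terms non-positive
            i = -1 if l == 1 else 1
            j = -1 if m == 1 else 1
            k = -1 if n == 1 else 1
            if i * j * k == -1:
                if n == 0:
                    k = -1
                elif m == 0:
                    j = -1
                elif l == 0:
                    i = -1
            if (i, j, k) != (1, 1, 1):
                p = [big_a, big_b, big_c, j * k * xi, i * k * eta, i * j * zeta]
                apply(np.diag([i, j, k]))
                continue
        big_a, big_b, big_c, xi, eta, zeta = p
        # step 5
        if abs(xi) > big_b + eps or (abs(xi - big_b) <= eps and 2 * eta < zeta - eps) or (
            abs(xi + big_b) <= eps and zeta < -eps
        ):
            s = 1 if xi > 0 else -1
            p = [big_a, big_b, big_b + big_c - s * xi, xi - 2 * s * big_b, eta - s * zeta, zeta]
            apply(np.array([[1, 0, 0], [0, 1, 0], [0, -s, 1]]))
            continue
        # step 6
        if abs(eta) > big_a + eps or (abs(eta - big_a) <= eps and 2 * xi < zeta - eps) or (
            abs(eta + big_a) <= eps and zeta < -eps
        ):
            s = 1 if eta > 0 else -1
            p = [big_a, big_b, big_a + big_c - s * eta, xi - s * zeta, eta - 2 * s * big_a, zeta]
            apply(np.array([[1, 0, 0], [0, 1, 0], [-s, 0, 1]]))
            continue
        # step 7
        if abs(zeta) > big_a + eps or (abs(zeta - big_a) <= eps and 2 * xi < eta - eps) or (
            abs(zeta + big_a) <= eps and eta < -eps
        ):
            s = 1 if zeta > 0 else -1
            p = [big_a, big_a + big_b - s * zeta, big_c, xi - s * eta, eta, zeta - 2 * s * big_a]
            apply(np.array([[1, 0, 0], [-s, 1, 0], [0, 0, 1]]))
            continue
        # step 8
        total = xi + eta + zeta + big_a + big_b
        if total < -eps or (abs(total) <= eps and 2 * (big_a + eta) + zeta > eps):
            p = [
                big_a,
                big_b,
                big_a + big_b + big_c + xi + eta + zeta,
                2 * big_b + xi + zeta,
                2 * big_a + eta + zeta,
                zeta,
            ]
            apply(np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]]))
            continue
        break
    else:  # pragma: no cover - the algorithm terminates for valid metrics
        raise RuntimeError("Niggli reduction did not converge")
    return _cell_from_character(p), m_total


def is_niggli(cell: DirectCell, eps: float | None = None) -> bool:
    """True if the cell already satisfies the Niggli reduced-cell conditions."""
    reduced, m = niggli_reduce(cell, eps=eps)
    return bool(np.array_equal(m, np.eye(3, dtype=int)))


def transform_indices(hkl: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Remap Laue indices into the basis produced by :func:`niggli_reduce`.

    ``hkl`` may be a triple or an (N, 3) array; ``h' = M h`` per reflection.
    """
    arr = np.atleast_2d(np.asarray(hkl, dtype=int))
    out = arr @ np.asarray(m, dtype=int).T
    return out if np.asarray(hkl).ndim == 2 else out[0]


def transform_plane(plane: ContactPlane, m: np.ndarray) -> ContactPlane:
    """Remap the contact plane into the reduced basis (canonical sign)."""
    u, v, w = (int(x) for x in transform_indices(np.array(plane.indices), m))
    return ContactPlane(u, v, w).canonical()


def niggli_2d_ok(a: float, b: float, gamma: float) -> bool:
    """Two-dimensional reduced-cell screen for stage-1 (a, b, gamma) candidates.

    After ordering a <= b the scalar-product criterion |a.b| <= a^2/2
    (i.e. |cos(gamma)| <= a/(2b)) must hold, together with the conventional
    angle window 60 <= gamma <= 120 degrees.
    """
    if a <= 0 or b <= 0:
        return False
    if not 60.0 <= gamma <= 120.0:
        return False
    lo, hi = (a, b) if a <= b else (b, a)
    return abs(math.cos(math.radians(gamma))) <= lo / (2.0 * hi) + 1e-12


def niggli_main_ok(cell: DirectCell, rel: float = 0.02) -> bool:
    """Loose main-condition screen, insensitive to the axis labelling.

    The basis vectors are sorted by length first (a valid representation of a
    reduced cell may carry them in any order), then the scalar-product bounds
    |2b.c| <= b^2, |2a.c| <= a^2, |2a.b| <= a^2 are checked with relative
    slack ``rel`` so near-boundary cells are not discarded by rounding noise.
    """
    big_a, big_b, big_c, xi, eta, zeta = _character(cell)
    # pair each squared length with the scalar product of the *other* two
    pairs = sorted([(big_a, xi), (big_b, eta), (big_c, zeta)])
    (a2, xi_s), (b2, eta_s), (_, zeta_s) = pairs
    s = 1.0 + rel
    return abs(xi_s) <= b2 * s and abs(eta_s) <= a2 * s and abs(zeta_s) <= a2 * s
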
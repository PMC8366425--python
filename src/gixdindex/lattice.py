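"""Reciprocal-lattice geometry for fiber-textured thin films.

All scattering-vector magnitudes use the crystallographic convention
``q = 2*pi/d``, i.e. the factor 2*pi lives in the reciprocal basis
(``a_i . a_j* = 2*pi * delta_ij``).  Angles are degrees at every public
interface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import gcd

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "DirectCell",
    "ReciprocalCell",
    "ContactPlane",
    "LaueTriple",
    "GComponents",
    "RmsdReport",
    "reciprocal_cell",
    "cell_volume",
    "g_components",
    "g_vectors",
    "rmsd",
]


def _metric_discriminant(alpha: float, beta: float, gamma: float) -> float:
    """1 - cos^2(a) - cos^2(b) - cos^2(g) + 2 cos(a)cos(b)cos(g), angles in deg."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg


@dataclass(frozen=True)
class DirectCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"cell lengths must be positive, got {self.lengths}")
        for name, ang in zip(("alpha", "beta", "gamma"), self.angles):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"{name} = {ang} outside (0, 180) degrees")
        if _metric_discriminant(self.alpha, self.beta, self.gamma) <= 0.0:
            raise ValueError(f"invalid metric: angles {self.angles} admit no 3-D cell")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def volume(self) -> float:
        return self.a * self.b * self.c * math.sqrt(
            _metric_discriminant(self.alpha, self.beta, self.gamma)
        )

    def metric(self) -> np.ndarray:
        """Direct-space Gram matrix G_ij = a_i . a_j (A^2)."""
        bas = self.basis()
        return bas @ bas.T

    def basis(self) -> np.ndarray:
        """Cartesian basis vectors as rows (a; b; c).

        Standard setting: a along x, b in the x-y plane.
        """
        a, b, c = self.lengths
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(_metric_discriminant(self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a, 0.0, 0.0],
                [b * cg, b * sg, 0.0],
                [c * cb, c * (ca - cb * cg) / sg, c * v / sg],
            ]
        )

    def reciprocal_basis(self) -> np.ndarray:
        """Reciprocal Cartesian basis as rows (a*; b*; c*), with the 2*pi factor."""
        return TWO_PI * np.linalg.inv(self.basis()).T

    def reciprocal(self) -> "ReciprocalCell":
        return ReciprocalCell(*_dual(self.parameters))


@dataclass(frozen=True)
class ReciprocalCell:
    """Reciprocal cell: lengths in A^-1 (2*pi convention), angles in degrees."""

    a_star: float
    b_star: float
    c_star: float
    alpha_star: float
    beta_star: float
    gamma_star: float

    @property
    def parameters(self) -> tuple[float, ...]:
        return (
            self.a_star,
            self.b_star,
            self.c_star,
            self.alpha_star,
            self.beta_star,
            self.gamma_star,
        )

    def volume(self) -> float:
        """Reciprocal-cell volume V* (A^-3); V * V* = (2*pi)^3."""
        a, b, c, al, be, ga = self.parameters
        return a * b * c * math.sqrt(_metric_discriminant(al, be, ga))

    def direct(self) -> DirectCell:
        """Invert back to the direct cell (duality is an involution)."""
        p = _dual(self.parameters)
        return DirectCell(*p)

    def metric(self) -> np.ndarray:
        """Reciprocal Gram matrix G*_ij = a_i* . a_j* (A^-2)."""
        a, b, c, al, be, ga = self.parameters
        ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )


def _dual(params: tuple[float, ...]) -> tuple[float, ...]:
    """Map (a, b, c, alpha, beta, gamma) to its dual with the 2*pi convention.

    Applying the map twice is the identity; it serves both directions.
    """
    a, b, c, al, be, ga = params
    sa, sb, sg = (math.sin(math.radians(x)) for x in (al, be, ga))
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    v = a * b * c * math.sqrt(_metric_discriminant(al, be, ga))
    a_s = TWO_PI * b * c * sa / v
    b_s = TWO_PI * a * c * sb / v
    c_s = TWO_PI * a * b * sg / v
    ca_s = (cb * cg - ca) / (sb * sg)
    cb_s = (ca * cg - cb) / (sa * sg)
    cg_s = (ca * cb - cg) / (sa * sb)
    ang = tuple(math.degrees(math.acos(max(-1.0, min(1.0, x)))) for x in (ca_s, cb_s, cg_s))
    return (a_s, b_s, c_s) + ang


def reciprocal_cell(cell: DirectCell) -> ReciprocalCell:
    """Reciprocal lattice parameters, a* = 2*pi*b*c*sin(alpha)/V etc."""
    return cell.reciprocal()


def cell_volume(cell: DirectCell) -> float:
    """Unit-cell volume V = abc * sqrt(1 - cos^2 terms) in A^3."""
    return cell.volume()


@dataclass(frozen=True)
class ContactPlane:
    """Miller indices (u v w) of the net plane parallel to the substrate.

    The canonical sign convention makes the first nonzero index positive.
    A common integer factor is *not* divided out: a plane like (0 2 0)
    carries the meaningful second-order specular spacing.
    """

    u: int
    v: int
    w: int

    def __post_init__(self) -> None:
        if self.u == self.v == self.w == 0:
            raise ValueError("contact plane (0 0 0) is not a plane")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.u, self.v, self.w)

    def canonical(self) -> "ContactPlane":
        for x in self.indices:
            if x != 0:
                if x < 0:
                    return ContactPlane(-self.u, -self.v, -self.w)
                break
        return self

    def primitive(self) -> "ContactPlane":
        """The plane with common integer factors divided out."""
        g = gcd(gcd(abs(self.u), abs(self.v)), abs(self.w))
        return ContactPlane(self.u // g, self.v // g, self.w // g).canonical()


@dataclass(frozen=True)
class LaueTriple:
    """Laue indices (h k l) of a single reflection (not gcd-reduced)."""

    h: int
    k: int
    l: int

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass(frozen=True)
class GComponents:
    """Components of a reciprocal-lattice vector relative to the substrate normal."""

    g_xy: float
    g_z: float
    g_xyz: float
    g_spec: float


def g_vectors(cell: DirectCell, plane: ContactPlane, hkl: np.ndarray):
    """Vectorized g components for an (N, 3) integer index array.

    Returns (g_xy, g_z, g_xyz, g_spec) where the first three are arrays of
    length N and g_spec is the scalar length of the plane's reciprocal vector.
    """
    bstar = cell.reciprocal_basis()
    s = np.asarray(plane.indices, dtype=float) @ bstar
    g_spec = float(np.linalg.norm(s))
    n = s / g_spec
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    g = hkl @ bstar
    g_z = g @ n
    g_xyz = np.linalg.norm(g, axis=1)
    # vector rejection instead of sqrt(g^2 - g_z^2): no cancellation noise
    # for reflections (nearly) parallel to the normal
    g_xy = np.linalg.norm(g - g_z[:, None] * n, axis=1)
    return g_xy, g_z, g_xyz, g_spec


def g_components(cell: DirectCell, plane: ContactPlane, hkl: LaueTriple | tuple) -> GComponents:
    """g decomposed along/perpendicular to the contact-plane normal.

    With n the unit normal of the contact plane (direction of the specular
    reciprocal vector g_uvw = u a* + v b* + w c*):

        g      = h a* + k b* + l c*
        g_z    = g . n          (signed out-of-plane component)
        g_xy   = |g - (g.n) n|  (in-plane component)
        g_xyz  = |g|
        g_spec = |g_uvw|
    """
    idx = hkl.indices if isinstance(hkl, LaueTriple) else tuple(hkl)
    g_xy, g_z, g_xyz, g_spec = g_vectors(cell, plane, np.array([idx]))
    return GComponents(float(g_xy[0]), float(g_z[0]), float(g_xyz[0]), g_spec)


def g_components_quadratic(
    cell: DirectCell, plane: ContactPlane, hkl: LaueTriple | tuple
) -> GComponents:
    """Closed-form quadratic expressions for the g components.

    Independent of the Cartesian construction in :func:`g_components`:

    * g_xyz and g_spec from the reciprocal metric quadratic form,
    * g_z = (g . g_uvw) / g_spec from the mixed reciprocal form,
    * g_xy from |g x g_uvw| = (2*pi)^2/V * |(kw-lv) a + (lu-hw) b + (hv-ku) c|
      evaluated with the direct metric.

    Used as an internal cross-check of the geometry.
    """
    h, k, l = hkl.indices if isinstance(hkl, LaueTriple) else tuple(hkl)
    u, v, w = plane.indices
    gs = cell.reciprocal().metric()

    def qform(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return float(x @ gs @ y)

    g_spec = math.sqrt(qform((u, v, w), (u, v, w)))
    g_xyz = math.sqrt(qform((h, k, l), (h, k, l)))
    g_z = qform((h, k, l), (u, v, w)) / g_spec
    av, bv, cv = (kw_lv, lu_hw, hv_ku) = (k * w - l * v, l * u - h * w, h * v - k * u)
    gd = cell.metric()
    cross_sq = float(np.array([av, bv, cv], dtype=float) @ gd @ np.array([av, bv, cv], dtype=float))
    g_xy = (TWO_PI**2 / cell.volume()) * math.sqrt(cross_sq) / g_spec
    return GComponents(g_xy, g_z, g_xyz, g_spec)


def rmsd(residuals) -> float:
    """Summed root-mean-square deviation sqrt(mean(residual^2)) over N peaks."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("rmsd of an empty residual list is undefined")
    return float(np.sqrt(np.mean(r * r)))


@dataclass(frozen=True)
class RmsdReport:
    """Summed RMSDs of the indexed pattern, per scattering-vector component.

    ``dq_spec`` is ``None`` for the route without a specular peak, where no
    specular residual exists.
    """

    dq_xy: float
    dq_z: float
    dq_xyz: float
    dq_spec: float | None = None
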
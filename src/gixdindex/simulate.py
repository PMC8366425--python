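"""Forward simulation of fiber-texture GIXD patterns from a known cell.

Every pipeline stage is testable against patterns generated here: reflections
are enumerated within an index cap, mapped through the reciprocal-lattice
geometry, folded into the measured half-plane (q_z >= 0, reflections with
negative out-of-plane component replaced by their centrosymmetric mates),
optionally collapsed when coincident, and optionally perturbed with seeded
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lattice import ContactPlane, DirectCell, g_vectors
from .peaks import Peak, PeakList

__all__ = ["SimulationSpec", "GroundTruth", "simulate_pattern", "fixture_suite", "random_cell_spec"]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic pattern.

    noise_sigma is the Gaussian standard deviation applied independently to
    q_xy and q_z (A^-1); q_xy is clipped at zero afterwards so the pattern
    stays in the measurable half-plane.
    """

    cell: DirectCell
    plane: ContactPlane
    q_max: float = 2.2
    hkl_cap: int = 6
    noise_sigma: float = 0.0
    seed: int = 0
    include_specular: bool = True
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.q_max <= 0:
            raise ValueError("q_max must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.hkl_cap < 1:
            raise ValueError("hkl_cap must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """True positions and all contributing Laue triples per emitted GIXD peak."""

    q_xy: np.ndarray  # noise-free positions, shape (N,)
    q_z: np.ndarray
    triples: tuple[tuple[tuple[int, int, int], ...], ...]  # per peak, >= 1 triple
    q_spec: float

    def best_triples(self) -> np.ndarray:
        """First (deterministic) ground-truth triple per peak, shape (N, 3)."""
        return np.array([t[0] for t in self.triples], dtype=int)


def simulate_pattern(spec: SimulationSpec) -> tuple[PeakList, GroundTruth]:
    """Generate a peak list and its ground truth from a known cell and plane."""
    cap = spec.hkl_cap
    rng = np.arange(-cap, cap + 1)
    hkl = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g_xy, g_z, g_xyz, g_spec = g_vectors(spec.cell, spec.plane, hkl)

    # reflections on the specular rod (g parallel to the normal) are not
    # GIXD-accessible; the threshold absorbs cancellation noise in g_xy
    keep = (g_xyz <= spec.q_max) & (g_xy > 1e-6)
    hkl, g_xy, g_z, g_xyz = hkl[keep], g_xy[keep], g_z[keep], g_xyz[keep]
    # fold to the measured half-plane: report the mate with g_z >= 0
    flip = g_z < 0
    hkl = np.where(flip[:, None], -hkl, hkl)
    g_z = np.abs(g_z)
    # a reflection and its centrosymmetric mate fold onto the same row
    _, uniq = np.unique(hkl, axis=0, return_index=True)
    uniq.sort()
    hkl, g_xy, g_z, g_xyz = hkl[uniq], g_xy[uniq], g_z[uniq], g_xyz[uniq]

    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], g_xy, g_xyz))
    hkl, g_xy, g_z, g_xyz = hkl[order], g_xy[order], g_z[order], g_xyz[order]

    if spec.dedupe:
        groups: dict[tuple[int, int], list[int]] = {}
        for i, (x, z) in enumerate(zip(g_xy, g_z)):
            key = (round(x / 1e-6), round(z / 1e-6))
            groups.setdefault(key, []).append(i)
        reps = sorted(idx[0] for idx in groups.values())
        triples = tuple(
            tuple(map(tuple, hkl[groups[(round(g_xy[i] / 1e-6), round(g_z[i] / 1e-6))]]))
            for i in reps
        )
        g_xy, g_z = g_xy[reps], g_z[reps]
    else:
        triples = tuple((tuple(t),) for t in hkl)

    truth = GroundTruth(q_xy=g_xy.copy(), q_z=g_z.copy(), triples=triples, q_spec=g_spec)

    q_xy, q_z = g_xy.copy(), g_z.copy()
    spec_qz = g_spec
    if spec.noise_sigma > 0:
        gen = np.random.default_rng(spec.seed)
        q_xy = np.maximum(q_xy + gen.normal(0.0, spec.noise_sigma, q_xy.shape), 0.0)
        q_z = q_z + gen.normal(0.0, spec.noise_sigma, q_z.shape)
        spec_qz = g_spec + float(gen.normal(0.0, spec.noise_sigma))

    gixd = tuple(Peak(float(x), float(z)) for x, z in zip(q_xy, q_z))
    specular = Peak(0.0, float(spec_qz)) if spec.include_specular else None
    return PeakList(gixd, specular), truth


# printed worked-example cells: 6,13-pentacenequinone (PQ) on graphite with a
# (102) texture plane, and acetylsalicylic acid (ASS) on oxidized Si with (020)
PQ_CELL = DirectCell(5.056, 8.076, 8.871, 91.54, 93.03, 94.14)
PQ_PLANE = ContactPlane(1, 0, 2)
ASS_CELL = DirectCell(6.594, 11.378, 11.418, 95.29, 90.28, 90.07)
ASS_PLANE = ContactPlane(0, 2, 0)
MONO_TOY_CELL = DirectCell(6.0, 7.5, 9.0, 90.0, 95.0, 90.0)
MONO_TOY_PLANE = ContactPlane(0, 0, 1)


def fixture_suite() -> dict[str, SimulationSpec]:
    """Named simulation recipes used throughout the test suite."""
    return {
        "pq_clean": SimulationSpec(PQ_CELL, PQ_PLANE, q_max=2.2),
        "pq_noisy": SimulationSpec(PQ_CELL, PQ_PLANE, q_max=2.2, noise_sigma=0.002, seed=20210730),
        "ass_clean": SimulationSpec(ASS_CELL, ASS_PLANE, q_max=2.0),
        "mono_toy": SimulationSpec(MONO_TOY_CELL, MONO_TOY_PLANE, q_max=2.0),
    }


def random_cell_spec(rng: np.random.Generator, noise_sigma: float = 0.0) -> SimulationSpec:
    """A random valid cell and low-index plane for property tests.

    Lengths 4-15 A, angles 75-105 deg (rejected if the metric is invalid),
    plane indices with |u|,|v|,|w| <= 2 and at least 15 peaks below q_max.
    """
    while True:
        lengths = rng.uniform(4.0, 15.0, 3)
        angles = rng.uniform(75.0, 105.0, 3)
        try:
            cell = DirectCell(*lengths, *angles)
        except ValueError:
            continue
        uvw = rng.integers(-2, 3, 3)
        if not np.any(uvw):
            continue
        plane = ContactPlane(*(int(x) for x in uvw)).canonical()
        spec = SimulationSpec(
            cell, plane, q_max=2.2, noise_sigma=noise_sigma, seed=int(rng.integers(2**31))
        )
        peaks, _ = simulate_pattern(replace(spec, noise_sigma=0.0))
        if len(peaks) >= 15:
            return spec
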
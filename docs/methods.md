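# Methods

## Geometry and conventions

All scattering-vector magnitudes are in Å⁻¹ with q = 2π/d; the 2π factor
lives in the reciprocal basis, so aᵢ · aⱼ* = 2π δᵢⱼ and V·V* = (2π)³.
Angles are degrees at every public interface and radians internally. The
canonical Cartesian setting places a along x and b in the x–y plane.

For a contact plane (u v w) the substrate normal is n̂ = g₍ᵤᵥᵥ₎/|g₍ᵤᵥᵥ₎|
with g₍ᵤᵥᵥ₎ = u a* + v b* + w c*, and a reflection (h k l) has

    g_z = g · n̂,  g_xy = |g − (g·n̂) n̂|,  g_xyz = |g|,  g_spec = |g₍ᵤᵥᵥ₎|.

These are computed from explicit Cartesian bases; the closed quadratic
forms (g_z g_spec = g·g₍ᵤᵥᵥ₎ through the reciprocal metric, and
g_xy g_spec = (2π)²/V · |(kw−lv) a + (lu−hw) b + (hv−ku) c| through the
direct metric) are implemented independently and used as a cross-check in
the tests. Measured q_z is non-negative: the simulator folds every
reflection to the mate with g_z ≥ 0, and the indexer treats (h k l) and
(−h −k −l) — and equally (u v w) and (−u −v −w) — as one equivalence class.

## Specular route

A specular peak at (0, q_spec) fixes the out-of-plane components of the
direct basis: a·n̂ = 2πu/q_spec and b·n̂ = 2πv/q_spec. Projecting a and b
onto the substrate plane leaves a two-dimensional sublattice whose
reciprocal metric (X₁, X₂, X₃) = (|A*|², A*·B*, |B*|²) satisfies, for every
reflection,

    q_xy² = ξ²X₁ + 2ξη X₂ + η²X₃,   ξ = h − u q_z/q_spec,  η = k − v q_z/q_spec,

linear in the three unknowns. Stage 1 solves this 3×3 system for three
independent start reflections, for every integer combination of (u, v)
within ±2 and (hᵢ, kᵢ) within ±3 (combinations with vanishing determinant
are skipped), and back-substitutes to (a, b, γ). Results are filtered by
realness, the length bounds (3–60 Å), the 60–120° window on γ, and the
two-dimensional reduced-cell condition |cos γ| ≤ a/(2b) after ordering
a ≤ b. The sign class (u, v, h, k) ↔ (−u, −v, −h, −k) solves the same
system and is enumerated once.

Start triples are taken lowest combined q first; a triple is rejected if a
pair of its peaks is an integer multiple of another in both components
(relative tolerance 10⁻³, multiplier capped at 12) or if the quadratic
design proxy (q_xy², q_xy q_z, q_z²) is ill-conditioned. After the first
triple, a new one may share at most one peak with each accepted triple:
patterns whose lowest reflections all share the same in-plane index (all
h = 0, say) would otherwise only produce singular systems for the true
assignment.

Every peak then receives the four (h, k) pairs (within ±6, at most ±8)
minimizing |Δq_xy|, and the sub-set quality Δq_xy is the root-mean-square
of the best pair per peak ("summed RMSD" is read as summation inside the
mean; all four error measures are reported separately). Stage 2 writes the
third basis vector as c = p a_xy + q b_xy + (2πw/q_spec) n̂, so each peak's
q_z gives the linear equation

    (q_spec h − q_z u) p + (q_spec k − q_z v) q = q_spec l − q_z w.

The three lowest non-harmonic q_z values form an overdetermined 3×2 system
per integer combination of (w, l₁, l₂, l₃); back-substitution yields
(c, α, β). The cap on w defaults to the largest |u|, |v| occurring in the
carried stage-1 sets, floored at the (u, v) cap so planes like (1 0 2)
remain reachable. The final index l of every reflection follows analytically
from the out-of-plane component (rounded to the nearest integer, ties
toward the smaller |l|, |l| ≤ 6 by default, at most 8); each peak considers
its four retained (h, k) pairs and their centrosymmetric mates, assigning
the triple with the smallest |Δq_xyz| and breaking exact ties by |Δq_z| so
the mate with the correct sign of g_z wins.

## Supercell degeneracy and ranking

Any superlattice of the generating cell indexes the pattern exactly as well
as the cell itself (its reciprocal lattice is denser), and under noise it
even overfits slightly. Plain RMSD ranking therefore cannot identify the
physical cell. All rankings in the pipeline use a quality gate: candidates
whose deviation lies within max(3 × best, best + 10⁻⁴ Å⁻¹) count as tied
and are ordered by ascending cell size (parallelogram area in stage 1,
volume later); everything outside the gate follows, ordered by deviation.
The 10⁻⁴ Å⁻¹ tie quantum is far below experimental peak-position accuracy.
The gate factor is generous on purpose: within the gated family the size
tie-break protects the choice, because supercells lose the size comparison
while cells smaller than the generating one cannot fit the pattern anywhere
near the noise level (their reciprocal lattice is too sparse). A stage-1
candidate built from three noisy start reflections carries a systematic
parameter error on top of the per-peak noise, so its deviation can sit
2–3 × above the best overfitted supercell — the factor covers that.
The stage-1 sort key is configurable (`area`, the default, or `dq_xy`,
mirroring the two sorting options offered to the operator); stage-2
candidates are ranked by a vectorized whole-pattern Δq_xyz score under
analytic l assignment, which neither a dense out-of-plane grid nor a dense
in-plane lattice alone can fake.

## No-specular route

Without a specular peak the normal projections (a*·n̂, b*·n̂, c*·n̂) are
fitted directly from q_z = h(a*·n̂) + k(b*·n̂) + l(c*·n̂), and the six
reciprocal-metric coefficients from q_xyz². The four lowest-q reflections
seed the projection system under index variation (h ±1, k ±2, l ±2);
rank-deficient combinations are skipped and the mirror assignment (flipped
normal) is enumerated once. Reflections five and six (indices within the
seed caps) make the triclinic metric solvable; in monoclinic mode (unique
axis b, the texture normal in the a*–c* plane so b*·n̂ = 0, i.e. contact
planes of type (u 0 w)) the k indices of the seed reflections are varied
instead and four peaks suffice. Candidates must satisfy the unit-normal
consistency projᵀ(G*)⁻¹proj = 1 within 5%; remaining reflections are
assigned one at a time (indices within ±6) with a joint refit and beam
pruning (width 50, residual first, volume on ties, duplicate fitted
unknowns collapsed) after every addition. The final metric is inverted
through a Cholesky check, Niggli reduced, and the orientation angles are
extracted from the refitted projections: in the canonical cell frame the
unit normal is n = (sin ψ cos φ, sin ψ sin φ, cos ψ), canonicalized to
ψ ≤ 90° by flipping the normal together with all Laue indices; φ is
reported as 0 when ψ vanishes (below 10⁻³ °, where the azimuth is
numerically undefined). The linear metric and projection refits are
already least-squares optima for the assigned indices, which takes the
place of the first-order corrections applied on the specular route.

## Common final steps

Specular-route candidates are refined by Gauss–Newton on the stacked
residuals [Δq_z; Δq_xyz; Δq_spec] with the Laue indices fixed: central
finite-difference Jacobians, step halving (the objective never increases),
at most 50 iterations, convergence at a relative change below 10⁻¹⁰.
Refined cells are Niggli reduced with the Krivý–Gruber algorithm (tolerance
10⁻⁵ × mean squared edge, the accumulated transform is unimodular with
determinant +1); Laue and plane indices remap as h′ = M h, and a canonical
plane-sign flip negates all peak indices with it so residuals are invariant.
Solutions that reduce to the same cell (0.5% in lengths, 0.3° in angles)
with the same Laue-index multiset are merged keeping the smallest errors.

## Synthetic patterns

The forward simulator enumerates all (h k l) within an index cap, keeps
reflections with g_xyz below q_max, folds them to the measured half plane,
drops reflections on the specular rod (g_xy < 10⁻⁶ Å⁻¹ — inaccessible in
GIXD geometry), collapses coincidences within 10⁻⁶ Å⁻¹ (the ground truth
keeps all contributing triples), and optionally adds independent seeded
Gaussian noise to q_xy and q_z (q_xy clipped at zero) plus the specular
peak at (0, g_spec). Fixtures cover the reference cells of two known thin-film polymorphs
— the pentacenequinone polymorph (5.056, 8.076, 8.871 Å, 91.54°, 93.03°,
94.14°) with plane (1 0 2) and acetylsalicylic acid (6.594, 11.378,
11.418 Å, 95.29°, 90.28°, 90.07°) with plane (0 2 0) — a monoclinic toy
lattice, and seeded random cells (lengths 4–15 Å, angles 75–105°, plane
indices within ±2) for property tests.

What the simulator does not emulate: peak intensities and widths, detector
geometry, refraction and footprint corrections, missing reflections
(systematic absences or weak peaks below the detection limit), and outlier
peaks from secondary phases. Passing tests therefore demonstrate the
correctness of the search and the algebra under the stated noise model, not
robustness against contaminated experimental peak lists.

## Problem sizes and numerical choices

The shipped test and acceptance runs index 30–60-peak patterns at the
default caps; random-cell recovery tests use the 40 lowest reflections per
pattern, matching how an operator selects a subset of a crowded map. Batch
scoring of stage-1 candidates runs in single precision (deviations of
interest are ≥ 10⁻⁴ Å⁻¹; float32 noise is ~10⁻⁷); all linear solves are in
double precision. Degenerate inputs are handled explicitly: determinant
cut-offs of 10⁻⁹ on the small systems, a pseudo-inverse-free rejection of
rank-deficient seeds, an enumeration fallback for l when c*·n̂ ≈ 0, and an
input error when fewer than three mutually non-harmonic q_z start values
exist. Parallel stage-1 evaluation (joblib, one job per start triple)
merges results in triple order, so the worker count never changes the
output.

## Known limitations

* With four peaks and a monoclinic no-specular fit the solution is not
  unique; the volume tie-break returns the smallest consistent cell.
* The analytic l assignment inherits the printed caps; reflections whose
  true |l| exceeds the cap are assigned their best in-cap alternative and
  degrade the error measures rather than aborting.
* Triclinic no-specular searches at the printed caps enumerate ~10⁷ seed
  combinations; the implementation streams them in chunks, but runtime
  grows steeply with the caps, which is the known cost of that route.
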
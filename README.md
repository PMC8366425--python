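# gixdindex

Automated unit-cell indexing for grazing-incidence X-ray diffraction (GIXD)
data from fiber-textured thin films — organic semiconductors, drug
polymorphs, and other surface-grown crystallites that share a contact plane
with the substrate but have no in-plane order.

A GIXD measurement delivers two components per Bragg reflection: the
in-plane part q_xy and the out-of-plane part q_z of the scattering vector,
with q_xyz² = q_xy² + q_z² and q = 2π/d. Indexing such a pattern means
finding a cell (a, b, c, α, β, γ), the Miller indices (u v w) of the contact
plane, and Laue indices (h k l) for every reflection such that each measured
(q_xy, q_z) matches a reciprocal-lattice vector g = h**a*** + k**b*** +
l**c*** decomposed along the substrate normal **n** = **g**₍ᵤᵥᵥ₎/|g₍ᵤᵥᵥ₎|:

    q_z  = g · n̂,    q_xy = |g − (g · n̂) n̂|,    q_spec = |u a* + v b* + w c*|

`gixdindex` implements two search strategies:

* **Specular route** — when a specular peak (q_xy = 0) was measured, its
  position pins the out-of-plane components of the direct basis
  (a·n̂ = 2πu/q_spec, b·n̂ = 2πv/q_spec), which splits the search into two
  small linear problems: a 3×3 system per integer combination (u, v, h₁..₃,
  k₁..₃) solving for the projected two-dimensional metric — hence (a, b, γ) —
  followed by overdetermined two-unknown systems in the third basis vector —
  hence (w, c, α, β). The remaining index l of every reflection follows
  analytically and is rounded to the nearest integer.
* **No-specular route** — a single-step fit: the q_z values of the
  lowest-q reflections seed a linear system for the normal projections
  (a*·n̂, b*·n̂, c*·n̂); growing the system over all reflections jointly fits
  the six reciprocal-metric coefficients (triclinic) or four (monoclinic,
  unique axis b). The crystallite orientation is reported as rotation angles
  (ψ, φ) instead of an integer plane.

All candidate cells pass Niggli (Krivý–Gruber) reduction, first-order
(Gauss–Newton) refinement of the six lattice constants, and deduplication;
solutions are ranked by their summed RMSD in q_xyz, with near-ties resolved
toward the smallest cell volume (any superlattice indexes the data exactly
as well as the cell itself).

## Worked example

Simulate a fiber-texture pattern from a known monoclinic cell with a (001)
contact plane, then index it:

```
$ gixdindex simulate --cell 6,7.5,9,90,95,90 --plane 0,0,1 --q-max 2.0 --out toy.csv
wrote 15 GIXD peaks to toy.csv; q_spec = 0.7008 A^-1

$ gixdindex index-spec toy.csv --out report.csv
index-spec: 14 solution(s); best cell a=6.0000 b=7.5000 c=9.0000 A,
alpha=90.000 beta=95.000 gamma=90.000 deg, V=403.46 A^3, dq_xyz=0.00000 A^-1
contact plane (u v w) = (0, 0, 1)
```

The generating cell returns exactly, with the (001) contact plane and a
vanishing summed RMSD; `report_solutions.csv` lists every surviving reduced
cell with its four error measures (Δq_xy, Δq_z, Δq_xyz, Δq_spec) and
`report_indexing.csv` the per-peak Laue indices and residuals. Without a
specular row the same data go through the no-specular route:

```
$ gixdindex index-nospec toy_nospec.csv --cell-type monoclinic
index-nospec: 5 solution(s); best cell a=6.0000 b=7.5000 c=9.0000 A, ...
orientation psi=0.000 phi=0.000 deg
```

Input files are two-column .csv or .xlsx peak lists (q_xy, q_z in Å⁻¹, dot
decimals, one row with q_xy = 0 for the specular peak). The same machinery
is available as a library:

```python
from gixdindex import SearchConfig, index_with_specular, read_peaks
peaks = read_peaks("toy.csv")
solutions = index_with_specular(peaks, SearchConfig(sort_key="area"))
print(solutions[0].cell, solutions[0].plane.indices)
```

## Testing

```
python -m pytest -q tests/
```

The suite generates every pattern it needs with the built-in forward
simulator (`gixdindex.simulate`); no data files are required.

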
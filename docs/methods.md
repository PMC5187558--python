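# Methods

## Model

`cvmlat` implements the cluster variation method (CVM) for bistate
lattices whose units are either active (**A**) or inactive (**B**) — an
abstraction used, among other places, for patterns of neural activation
on 2-D cortical maps.  Unlike the point (mean-field/Bragg–Williams)
entropy, which sees only the A/B head-count, the CVM entropy is built
from *configuration variables*: the fractions of single units (x₁, x₂),
nearest-neighbour pairs (y₁, y₂, y₃ — AA, unlike, BB), next-nearest-
neighbour pairs (w₁, w₂, w₃) and triplets (z₁…z₆ — AAA, {AAB, BAA},
ABA, BAB, {ABB, BBA}, BBB).  Classes pooling two orderings carry
degeneracy factors β₂ = 2 (pairs) and γ₂ = γ₅ = 2 (triplets); all
others are 1.  Fractions are stored per arrangement, so
x₁ + x₂ = Σβᵢyᵢ = Σβᵢwᵢ = Σγᵢzᵢ = 1; degeneracy-weighted ("aggregated")
values are exposed alongside, since both conventions appear in practice.

Geometry. The 1-D lattice is a single zigzag chain: drawn as two
staggered half-rows of M units (N = 2M), with nearest neighbours on the
diagonals and next-nearest neighbours within a row.  All windows are
contiguous spans of the linear zigzag order with wraparound, so a chain
of N units has exactly N pair, N next-nearest and N triplet windows.
The 2-D lattice is a staggered grid (R rows × C columns, R even,
envelope wrap both ways); each adjacent row pair forms a circular
zigzag chain of 2C units, giving 2N triplet windows in total — twice
the unit count, each diagonal bond counted exactly once.  Next-nearest
pairs are defined as the end-units of the triplet windows in both
dimensionalities, which makes their totals equal by construction.

Energetics. The only enthalpy is a pairwise cost ε charged to each
unlike nearest-neighbour pair (per-unit enthalpy zero; k_BT ≡ 1, so
temperature is subsumed into ε).  The working parameter is
h = e^(ε/4): h = 1 means no interaction, h > 1 favours like-near-like
("ferromagnetic") order, h < 1 favours alternation.  With
Lf(p) = p ln p − p, the reduced (per-unit) free energies are

    G₁ = ε(z₂+z₃+z₄+z₅) − [2Σβ Lf(y) − 2Σγ Lf(z)]
    G₂ = ε(z₂+z₃+z₄+z₅) − [2Σβ Lf(y) + Σβ Lf(w) − ΣLf(x) − 2Σγ Lf(z)]

Lagrange multipliers enter only the derivation of stationarity; at
evaluation time the functionals act on already-normalised fractions and
the constraints are reported as residuals.

The 2-D term signs were fixed by an internal-consistency criterion: the
analytic 2-D solution (below) must be a stationary point of the
functional.  Only the sign set above satisfies it — the numerical
minimum then matches the analytic z₃ to < 1e−8 across the whole valid
branch — and it is the standard Kikuchi counting (basic triangle
clusters, corrected by pair, point overlaps); it also yields S̄ = ln 2
per unit at h = 1, exactly the entropy of a random equiprobable
lattice.  The choice is recorded in `FreeEnergyBreakdown.metadata`.
The 1-D normalisation as implemented gives S̄ = 2 ln 2 at h = 1; this
per-N versus per-half-chain factor is a pure scale convention that
moves no stationary point and no fraction, and is kept as is.

## Equilibrium solutions

In the equiprobable regime (x₁ = x₂ = 0.5) the minimum is symmetric
(y₁ = y₃, z₁ = z₆, z₂ = z₅, z₃ = z₄) and one ratio survives:
s = z₁/z₃ = h⁴.  The 1-D solution is closed-form:

    z₃ = 1 / (2(s+1) + 4√s),   z₁ = s·z₃,   z₂ = (0.5 − z₁ − z₃)/2

The quadratic-root ambiguity in 1/z₃ is resolved to the + branch: the −
branch gives 1/z₃ = 0 at h = 1, inconsistent with the uniform census
z₃ = 0.125 there.

For the 2-D grid one triplet fraction has an analytic form,

    z₃ = (h²−3)(h²+1) / (8[h⁴ − 6h² + 1]),

physically valid for h ∈ [3^(−1/2), 3^(1/2)], where z₃ runs from 0.5
down to 0; the denominator's poles (h² = 3 ± 2√2) lie outside that
interval.  Outside the branch the package raises rather than
extrapolates; sweep tables flag such rows instead of dropping them.
The remaining 2-D fractions come from numerical minimisation.

Numerics. The symmetric minimisation has two free variables (z₁, z₃)
with z₂ fixed by normalisation.  The feasible triangle is charted by a
softmax-style transform zᵢ = 0.5·e^{tᵢ}/(1 + Σe^t), so iterates stay
strictly interior (the entropy gradient diverges on the boundary, hence
so does the minimiser's distance from it).  Stationarity is solved with
a Powell-hybrid root solve on the analytic free-energy gradient from
three starts — the uniform point, the 1-D closed form, and (2-D) the
analytic z₃ — and a candidate is accepted at gradient norm ≤ 1e−9,
taking the lowest free energy among converged candidates.  The 2-D
minimiser's z₃ is always cross-checked against the analytic expression
(default tolerance 1e−6) and disagreement raises rather than passes
silently.

## Parameter inference

An observed lattice is scored by counting its triplet windows and
forming z₁ = Z₁/T and z₃ = Z₃/T (T = window total).  Each is inverted
through the equilibrium relations, giving h₁ and h₃, and the estimate
is their arithmetic mean h_avg.  On a finite lattice away from
equilibrium h₁ ≠ h₃; the spread shrinks as the system grows.  The 1-D
inversions are exact (no look-up table): √s = √(1/(2z₃)) − 1 for z₃,
and u = h² = [2z₁ + √(2z₁)]/(1 − 2z₁) for z₁.  The 2-D z₃ inversion
solves the implied quadratic in u = h², keeping the root with
u ∈ [1/3, 3]; the 2-D z₁ inversion brackets the numerically minimised
z₁(h) on the valid branch.  A sampled-curve + linear-interpolation path
(`method="table"`) is retained for parity experiments only.  Degenerate
observations (z₁ = 0, as in strict alternation) return h₁ = 0 with a
flag.  The inversion presumes equiprobability, so |x₁ − 0.5| beyond a
tolerance (default 0.05) raises in strict mode, flags otherwise;
observations outside the attainable equilibrium range (e.g. z₁ ≥ 0.5)
raise a range error.

## Pattern generators

`generate_pattern` produces the three deterministic 32-unit-style study
patterns plus seeded random chains; the deterministic kinds all have
exactly equal A/B counts:

- `ferro_defect` (even size ≥ 10): two like-domains of size/2, each
  with one opposite unit at the domain midpoint.  At size 32 the
  triplet census is Z₁ = 11, Z₃ = 1, giving h₁ = 2.2030, h₃ = √3 and
  h_avg ≈ 1.97.  The counts are invariant to where the defect sits in
  the domain interior; the midpoint is fixed for determinism.
- `equilibrium_motif` (size ≡ 0 mod 8): repeats of AAABABBB, whose
  circular census contains each of the 8 ordered triplets exactly once
  per repeat — the h = 1 equilibrium distribution, so h_avg = 1 exactly.
- `antiferro_defect` (even size ≥ 6): strict alternation except exactly
  one A-A and one B-B adjacency, non-adjacent to each other (one A-run
  and one B-run of length 2, placed half the run sequence apart).  Its
  z₁ = 0 is degenerate, so h₁ = 0 and h_avg < 1; the published analogue
  of this pattern is shown only graphically, so our construction is a
  stated stand-in and its h_avg is not treated as a reference value.
- `random`: i.i.d. P(A) = 0.5 draws from a seed; `generate_grid` does
  the same on a staggered grid.

What the generators emulate — and what they do not: they reproduce the
local-pattern statistics (triplet censuses) of the idealised study
conditions, not the spatial statistics of real neural recordings
(no spatial correlation structure beyond the constructed motifs, no
x₁ ≠ x₂ imbalance, no measurement noise).  Tests passing on them
validate the counting, thermodynamics and inversion machinery, not the
applicability of the equiprobable model to any particular dataset.

## Known limitations

- The equiprobable closed forms and inversions do not apply when
  x₁ ≠ x₂; the two-parameter interaction model needed there is out of
  scope.
- The 2-D z₁(h) used by `invert_z1(..., dims=2)` comes from this
  package's own minimiser; no independently published closed form for
  it is available to certify against (only z₃ has one), so 2-D h₁ and
  h_avg values should be read as internally consistent rather than
  externally certified.  Qualitatively they behave correctly (h_avg > 1
  for like-ordered patterns, < 1 for alternating ones).
- Kinetics (relaxation toward equilibrium) and clusters beyond
  triplets are not modelled.
- Open (non-wrapped) boundaries are not supported; all counting is
  periodic.
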
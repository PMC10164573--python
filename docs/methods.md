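# Methods

## The model

A DNA minicircle of a few hundred base pairs is represented as a closed,
inextensible, uniform elastic rod (Kirchhoff beam) of contour length *L*,
bending rigidity *A* and geometric torsional stiffness ω, carrying a
prescribed linking number *Lk*.  With the relaxed reference
*Lk*₀ = *N*bp/*h* (helical repeat *h* ≈ 10.42 bp/turn in 10 mM CaCl₂), the
linking deficit ΔLk = *Lk* − *Lk*₀ drives the shape.  The elastic energy is

    E = (A/2) ∮ (κ² + ω Ω²) ds,

where κ is the centerline curvature and Ω the residual excess-twist density.
Because the energy is quadratic in Ω with no positional coupling, the
minimiser distributes residual twist uniformly, so by the Călugăreanu
decomposition *Lk* = *Tw* + *Wr*,

    Ω = 2π (ΔLk − Wr) / L.

Scaling by k_BT leaves two dimensionless parameters: the aspect ratio
*d*ₛ/*L* of the steric tube and ω.  Shapes that minimise E are computed and
then treated as rigid bodies for hydrodynamics; thermal shape fluctuations
are neglected, which is justified for loops of this size because the stored
bending (~4π²P/L ≈ 17 k_BT for 336 bp) and twisting (~6π²ΔLk²P/L ≈ 105 k_BT
at |ΔLk| = 2) energies far exceed k_BT (see the electrostatics module for
these order-of-magnitude diagnostics and for the Debye/OSF estimates that
justify ignoring long-range electrostatics in a ~0.2 M buffer).

Sign convention: a right-handed crossing contributes +1 to writhe;
negatively supercoiled loops (ΔLk < 0) relax into negative writhe.  Where
published plots show magnitudes only, comparisons use |Wr|.

## Defaults and units

All geometry is in Å, energies in k_BT.

| parameter | default | meaning |
|---|---|---|
| P (persistence length) | 500 Å (150 bp) | sets A = k_BT·P |
| ω | 2/3 | circular cross section |
| d_s (steric diameter) | 20 Å | hard-core tube |
| d_h (hydrodynamic diameter) | 29.4 Å | calibrated on nicked-loop AUC data |
| h (helical repeat) | 10.42 bp/turn | buffer-dependent |
| rise | 3.4 Å/bp | bp ↔ Å convenience |
| buffer | η = 1.02667 cP, ρ = 1.00682 g/ml, 293.15 K | AUC conditions |
| v̄′ (apparent PSV) | 0.482 ml/g | study average |

Contour lengths for the benchmark loops are set by the published aspect
ratios (d_s/L = 0.018 and 0.0090 for elasticity; d_h/L = 0.026 and 0.013
for hydrodynamics, giving L ≈ 1131/2262 Å) rather than by the rise-per-bp
product; the two conventions differ by ~1–3 % and the ratios are what the
benchmark numbers were quoted at.  The nominal integer ΔLk labels carry the
fractional offset of Lk₀ (−0.25 turns for 336 bp at h = 10.42), which the
pipeline retains in every energy computation.

## Shape search

The centerline is a periodic cubic spline through 16 nodes (twice
continuously differentiable across the seam).  By default the node set is
constrained to C2 symmetry — rotation by π about a fixed axis — which the
figure-8 and interwound branches possess; this is the subgroup of the full
dihedral symmetry that survives at line contact, and it halves the search
space.  Asymmetric search is available by flag.

The objective adds to the elastic energy two quadratic penalties:

* length: w_len·((ℓ − L)/L)², holding the prescribed contour length;
* sterics: w_st·Σ(1 − d/d_s)² over sample pairs closer than d_s, with
  ~20 L/d_s samples along the curve and pairs closer than 1.5 d_s along the
  contour excluded (contour neighbours are legitimately within d_s).

Curvature and length integrals use fixed 8-point Gauss–Legendre quadrature
per spline interval (the public `ClosedCurve.arclength` uses adaptive
quadrature; the two agree to ~1e-10 on these smooth curves).  Writhe is the
exact Gauss-integral sum over pairs of straight segments (200 segments by
default), the formulation that removes the diagonal singularity.  Because
all sample sets sit at fixed spline parameters, every quantity is a fixed
linear operator applied to the node array followed by cheap nonlinear
kernels, which makes an energy evaluation ~1 ms.

Minimisation is simulated annealing over node positions (geometric
temperature 3 → 0.01 k_BT, proposal σ from 10 % to 0.4 % of the loop
radius, penalty weights ramped ×10), followed by a derivative-free Powell
quench at full sampling resolution, and a final uniform rescale to the
exact target length (writhe is scale invariant and bending energy
transforms exactly as 1/scale, so the projection is legitimate).  During
the anneal the steric scan runs on a coarser grid (≤450 samples) and the
writhe polygon on 120 segments; the quench and all reported values use the
full grids.

Starts: the flat circle is an exact equilibrium and is always evaluated in
closed form.  The writhed branch starts from an analytic figure-8
(lemniscate with parameterised apex separation), and for |ΔLk| > 2 also
from interwound two-strand (plectonemic) configurations whose initial
writhe brackets ~0.7·ΔLk — the figure-8 basin does not connect smoothly to
the line-contact branch, and multi-start is cheaper and more reliable than
forcing one chain of continuations.  Each start is annealed, cheaply
quenched for ranking, and the winner fully quenched.  The returned shape is
the lower of the writhed branch and the circle (the circle is excluded
above |ΔLk| = √3/ω where it stops being a solution); both branches are kept
on the result for consumers that need the multistable pair.

Convergence is declared when the final quench improves the objective by
less than 1 % and the hard constraints hold on the projected shape
(|ℓ − L|/L ≤ 1e-3, minimum non-neighbour separation ≥ d_s − 0.1 Å).
With the default budget (6000 MC steps), five independent seeds at
ΔLk = −3.2 spread by ~0.5 % in energy; the writhe of near-degenerate minima
can differ by ~0.2 because the landscape is nearly flat along the
bend/twist trade-off — this is the same few-per-cent reproducibility noise
expected of stochastic shape optimisation and it propagates to <1 % in
R_h.

Stability classification uses two closed forms: the empirical critical
deficit Lk_crit = √(1 + 23.1·d_s/L) for the onset of a stable writhed
branch, and the thickness-independent Lk_max = √3/ω ≈ 2.6 above which the
flat circle is no longer an equilibrium.  Between them both branches exist
(multistability); the global minimum switches from circle to writhed at a
length-dependent crossover inside this band.

## Hydrodynamics

The hydrodynamic radius R_h = k_BT/(6πηD) is computed three ways:

1. **Torus closed forms** for open circles: a Padé-type expression accurate
   at any aspect ratio, and a slender-body form L/((11/6)ln(2L/d_h) + 1.13)
   for L/d_h > 30.  The two agree within 2.5 % for L/d_h ≳ 32 (the gap is
   2.5–2.6 % right at 30 — a property of the closed forms themselves).
2. **Rigid bead model, pairwise engine** (default): 400 overlapping beads
   of diameter d_h equally spaced in arclength; the 6×6 grand resistance is
   assembled from the overlap-regularised Rotne–Prager–Yamakawa pair
   mobility plus each bead's rotational self-resistance 8πηa³, the
   reference point is moved to the centre of mobility, and
   R_h = 3/(6πη·tr μ_tt).  Deterministic and ~0.1 s per solve.  It
   reproduces the published ring and straight-rod diffusion predictions to
   1–3 %, but its two-body truncation under-resolves non-slender tori
   (−4 % vs the torus closed form at L/d_h ≈ 39, −8 % at L/d_h = 10) and
   compact clusters (touching dumbbell −4 %).
3. **Walk-on-spheres engine** (`method="montecarlo"`): stochastic
   capacitance of the bead union with exact Poisson-kernel re-entry
   sampling, using the capacitance ≈ R_h identity (good to ~1 % for compact
   particles).  Seeded, with reported standard error; tracks the torus
   closed form within ~3.5 % across L/d_h ∈ [10, 100] and is exact for the
   touching-dumbbell benchmark (2a·ln 2).

The hydrodynamic thickness d_h is the single fit parameter of the whole
pipeline: `calibrate_dh` least-squares fits one d_h to measured (L, R_h)
pairs through the torus model.  Because R_h depends on d_h only
logarithmically the fit is soft; with the two published nicked-loop radii
the residuals are necessarily nonzero and the recovered value depends on
the assumed contour lengths, so the published 29.4 Å is used as the default
rather than asserted as reproducible.  Linear DNA is modelled as a straight
overlapping-bead rod of the same L and d_h (ring:rod R_h ratio ≈ 6:7).

## Transport

Stokes–Einstein converts R_h to D; the Svedberg relation
s = M(1 − v̄ρ)D/(N_A k_BT) converts D to s given the molar mass and the
apparent partial specific volume; the inversion gives v̄′ from a measured
(s, D) pair.  The frictional ratio is f/f0 = R_h/R₀ with
R₀ = (3Mv̄/4πN_A)^{1/3}.  Standard-condition corrections to water at 20 ℃
(η = 1.0016 cP, ρ = 0.99823 g/ml, CRC values) are provided for
completeness; the benchmark numbers are all quoted at buffer conditions
because the PSV of DNA at standard conditions is not separately known.
Constants are CODATA 2018 exact values.

One documented inconsistency: at 230 mM ionic strength the Debye formula
R_D = 1/(0.329·√Cs) gives 6.3 Å, while 1.45 Å is sometimes quoted for the
same conditions; 1.45 Å numerically matches the OSF electrostatic
persistence length R_D²/(4l_B) instead.  The formulas are implemented as
written and the 1.45 Å figure is not used anywhere.

## What the synthetic fixtures do and do not emulate

The fixture generator produces exact circles, figure-8s with controlled
apex separation, smoothly perturbed loops (seeded Fourier modes) and
straight rods.  These span the geometric regimes the operations must
handle — planar, singly-crossed, generically curved, open — and give
closed-form or oracle-checkable values (zero writhe, |Wr| → 1, ellipse
curvature extrema).  They do not emulate sequence-dependent flexibility,
base-pair disruption, thermal shape ensembles or counterion-specific
effects; tests passing on them validate the geometry, topology, elasticity
and hydrodynamics machinery, not those biological effects.

## Numerical choices and degenerate inputs

* Periodic splines reject coincident consecutive control points rather than
  smoothing them.
* Writhe of adjacent (coplanar) segment pairs is exactly zero and skipped;
  dot products are clamped to [−1, 1] before arcsin.
* The steric scan excludes pairs within 1.5 d_s along the contour; the
  minimum-distance reporter uses the same window.
* Contact classification clusters sample pairs within 1.1 d_s by index
  connectivity; a cluster spanning >2 % of the contour is a line contact,
  otherwise a point contact.
* Single beads and collinear rods have free-spinning modes; the bead
  rotational self-resistance keeps the 6×6 resistance invertible and the
  sphere limit exact.
* Degenerate transport inputs raise typed errors (neutral buoyancy,
  non-positive mobilities, self-overlapping tori).

## Problem sizes

Default problem sizes are chosen so a full pipeline run for one topoisomer
completes in well under a minute on one core: 16 spline nodes, 200 writhe
segments, ~1100 steric samples, 6000 MC steps with three starts, 400
beads.  The test suite uses reduced Monte-Carlo budgets (≈2500 steps) for
shared fixtures where only qualitative branch structure matters, and the
full budget where writhe values are compared quantitatively.

## Known limitations

* The ODE/shooting construction of Lk_crit and glued-segment analytic
  plectonemes are not implemented; the empirical Lk_crit formula plus
  direct minimisation cover the same predictions.
* Elasticity is sequence-independent and athermal; no ensemble averaging.
* The pairwise hydrodynamic engine underestimates friction for fat tori
  and compact clusters (see above); use the walk-on-spheres engine when
  absolute accuracy on non-slender geometry matters.
* Published prose places the critical deficit near 1.1–1.2 with the
  *opposite* length ordering to the empirical formula (thicker ⇒ larger
  Lk_crit); the formula is implemented as printed and the prose values are
  not hard-coded.
* The "~90 % of torsional energy relaxed by writhing" statement is
  ambiguous between an energy fraction and a writhe fraction; both metrics
  are computable from a result's energy decomposition and neither is
  asserted as a fixed number.
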
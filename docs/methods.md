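# Methods

## Scope and model

The package post-processes per-node wall shear stress (WSS) vector time
series on triangulated vessel-wall surfaces and provides reduced-order
pulsatile flow models for validation.  It does not solve 3-D Navier–Stokes;
the flow side is the axisymmetric laminar axial momentum equation in a
rigid straight pipe,

    rho du/dt = G(t) + mu (1/r) d/dr (r du/dr),   u(R, t) = 0,

with G(t) = −dp/dz periodic in the cardiac cycle.  Blood is Newtonian and
incompressible with density 1060 kg/m³ and dynamic viscosity 3.5 mPa·s
(standard values for rodent CFD).  Flow is assumed laminar; Reynolds
numbers are reported and an advisory is emitted above Re = 2000.

## Metrics

For the shear vector τ_ω(t) at a node over one cycle T:

- TAWSS = (1/T) ∫ |τ_ω| dt (Pa)
- OSI = ½(1 − |∫ τ_ω dt| / ∫ |τ_ω| dt), clamped to [0, 0.5] against
  floating-point drift.  The numerator integrates the *vector* and then
  takes the magnitude (the standard definition; component-wise absolute
  values would not be rotation-invariant).
- RRT = 1/((1 − 2·OSI)·TAWSS) (Pa⁻¹).

Integrals use the periodic trapezoidal rule on the sample grid; when the
last sample falls short of T, a closing sample at t = T is synthesised
from the t = 0 sample.  On a uniform grid this makes the two OSI endpoint
identities exact to machine precision: a constant-direction series has
numerator = denominator (OSI = 0) and a zero-mean sinusoid has a vector
integral that cancels exactly (OSI = 0.5).

Degenerate nodes: where the total shear exposure ∫|τ_ω| dt < 1e-12 Pa·s,
OSI is set to 0 and the node flagged (rather than NaN) so area statistics
stay defined; where the RRT denominator < 1e-12, RRT is +inf with a flag.
Flagged counts are logged, regional means exclude non-finite values with a
warning, and the +inf sentinel counts as "above" any finite threshold in
area fractions.

Area statistics use barycentric node lumping (each triangle contributes a
third of its area to each vertex), chosen over Voronoi lumping because it
is always positive and bit-for-bit reproducible under triangle reordering.
Whether the original analyses weighted by faces or nodes is not knowable
from published descriptions; node lumping is this package's documented
convention.  Thresholds are strict inequalities exactly as conventionally
printed (TAWSS < 20 Pa, OSI > 0.2, RRT > 0.5); ties do not qualify.  The
TAWSS histogram uses seven 20-Pa bins, the last open above 120 Pa.
Geometry is stored in mm (areas in mm²); the pipe solvers work in SI.
Inlet/outlet cap nodes are excluded from the wall when a label array is
supplied; otherwise all nodes count as wall.

## Flow models

`womersley_wss` evaluates the analytic oscillatory pipe-flow solution per
Fourier harmonic of a flow-rate waveform: for forcing G e^{iωt} the
velocity is u = −(iG/ρω)[1 − J₀(ζr/R)/J₀(ζ)] with ζ = i^{3/2}α and
α = R√(ωρ/μ); the harmonic's flow rate and wall shear follow from J₁/J₀
ratios, and the steady harmonic contributes the Poiseuille wall shear
4μQ/(πR³).  Returned shear is *signed* along the axis (reversal shows as
negative values), which is what the OSI machinery needs.

`fd_pipe_solver` integrates the same equation with Crank–Nicolson time
stepping (second order, unconditionally stable at 100 steps/cycle for rat
heart rates) on a uniform radial grid (default 100 intervals); the 1/r
singularity at the axis is regularised by L'Hôpital (the operator limit
2·d²u/dr²), and wall shear uses a one-sided second-order difference.
Starting from rest, the start-up transient decays by roughly a factor 20
per cycle at rat scale (decay exp(−j₀₁²·νT/R²) per cycle), so the third
cycle is accurate to ~1e-4 relative — but the cycle-to-cycle residual
after only 3 cycles is of order 1e-2, not 1e-6; callers who need strict
periodicity pass `converge_tol`, which keeps cycling (up to `max_cycles`)
until the residual falls below it.  The residual is always reported in the
solution object.  Observed spatial convergence against the analytic
solution is second order (tested over nr ∈ {25, 50, 100}).

`fourier_decompose` resamples non-uniform waveforms onto a uniform grid by
periodic linear interpolation and takes an rFFT; with ≥ 2H+1 samples the
first H harmonics of a band-limited signal are recovered exactly.

`split_flow` applies time-invariant volume ratios (e.g. 10:7:8 across the
supra-aortic branches); published boundary conditions state only
cycle-volume ratios, so an instantaneous, time-invariant split is a
documented simplification.  An optional residual fraction models a
downstream (descending-aorta) outlet.

## Synthetic data

The generators define the study conditions for all tests:

- **Geometry**: a torus-segment tube (centerline radius 4 mm, vessel
  radius 1 mm, half-turn arch, 64×96 grid) at rat-aorta scale; the
  inner-arch mask is the circumferential strip within 0.25 rad of the
  lesser-curvature line.  Tube ends are open, so all nodes are wall nodes.
- **Waveforms**: raised-cosine systolic pulse (~35% of the cycle) over a
  small diastolic baseline, period 60/HR s, maximum equal to the requested
  peak velocity exactly; rat-scale defaults are HR 271–379 beats/min and
  ascending-aorta peaks 1521–2239 mm/s.  The pulse shape itself is a
  package choice — only period and peak are constrained by measurement.
- **WSS fields**: fixed-axis series τ(t) = (a + b·sin(2πt/T))·ê with ê the
  local arch tangent.  The oscillation-to-baseline ratio peaks at the
  inner line (default 30) and decays as a Gaussian (scale 0.12 rad) while
  the baseline (19 Pa, ±10% seeded jitter) simultaneously dips by 95% with
  the same profile — low-and-oscillatory shear at the inner curvature, the
  pattern seen in real arches.  TAWSS and OSI of a + b·sin have closed
  forms (for b > a the cycle mean of |a + b sin| is
  (2/π)(a·asin(a/b) + √(b²−a²))), so each generated field carries exact
  per-node ground truth.  Defaults put the whole-wall statistics in the
  hypertensive-rat regime: ~71% of the wall below 20 Pa, ~7% above OSI
  0.2, inner-arch regional OSI ~0.45, and a <1% high-RRT patch.  One
  caveat is inherent: with rodent-scale TAWSS in the tens of Pa, RRT
  values in Pa⁻¹ are necessarily ≲0.5 except where OSI approaches 0.5, so
  regional RRT magnitudes of order 1–2.5 cannot coexist with tens-of-Pa
  TAWSS under the defining identity; the study-table generator therefore
  draws per-animal regional RRT around group-level values (1.4–2.5)
  independently of the single demo geometry.
- **Study tables**: 4 groups (WKY/SHR × saline/nifedipine) × 6 animals.
  Per-animal regional OSI is drawn around group means 0.39/0.43/0.40/0.42
  (SD 0.02); wall thickness = intercept + slope·OSI + Gaussian noise
  (defaults slope 3 mm per OSI unit, intercept −0.9 mm, i.e. ~0.3 mm at
  OSI 0.4), elastin-layer thickness a 0.4-scaled copy with independent
  noise.  When a target Pearson r is given (pipeline default 0.62) the
  noise SD is derived as |slope|·sd(x)·√(1/r²−1) so the *population*
  correlation equals the target; the sample r at n = 24 then scatters with
  Fisher-z SD ≈ 0.22.

What passing tests on these inputs do **not** show: real WSS fields are
not fixed-axis sinusoids (no multi-directional oscillation, no branch
flows, no secondary vortices), the synthetic surface has no branch ostia
or caps, and the study table's linearity is planted rather than
biological.  The generators validate the *machinery* — integration,
area weighting, thresholding, statistics — not any physiological claim.

## Statistics

Group summaries are mean ± sample SD (n−1).  Omnibus comparisons use
one-way ANOVA or Kruskal–Wallis (both offered, selection explicit;
normality is not auto-tested).  Pairwise post-hoc tests (t or
Mann–Whitney U, two-sided) are Bonferroni-corrected — the correction is a
package choice, as published descriptions name none.  Correlation is
Pearson's r with the t-transform p-value (n−2 df) and an OLS line.
Calibration is verified in the suite: the ANOVA type-I error over 1000
seeded null replicates at α = 0.05 stays within 0.05 ± 0.02, and the
planted r = 0.62 at n = 24 falls inside its Fisher 95% sampling interval
in ≳97% of 500 replicates.

## Numerical conventions and limitations

- All randomness flows through explicit per-call `numpy` Generator seeds;
  there is no global state, and identical config + seed reproduces all
  CSV/JSON outputs byte for byte (fixed float formats, sorted JSON keys).
- Mesh I/O: STL (binary/ASCII, via trimesh) welds duplicate vertices in
  first-occurrence order; since STL is an unindexed triangle soup at
  float32 precision, node-indexed artifacts (masks, fields) written by the
  generator are keyed to the legacy-VTK copy of the mesh, which preserves
  indexing and full precision.  Metric maps are written as legacy VTK or
  XML VTP point data (ASCII; +inf RRT is written as −1 in VTP for viewer
  compatibility, with the flag column in the CSV authoritative).
- The solver problem sizes used throughout (100 radial intervals, 100
  steps/cycle, 3 cycles; 64×96 surface grids; 100 samples/cycle fields)
  are the package defaults chosen to resolve the physics at rat scale;
  all validation targets hold at these sizes.
- No fluid–structure interaction, no non-Newtonian rheology, no Lagrangian
  particle tracking (RRT is the algebraic surrogate, not a residence time
  from trajectories), and no OSI variants (transverse WSS, WSS divergence).
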
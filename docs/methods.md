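# Methods

## The model

A virtual rat explores a 1 m square arena in fixed steps of 0.6 cm, turning
at each step by a normal deviate with 17° s.d.; a proposed step that would
leave the arena redraws its turn.  An input layer of N_I = 225 place-cell-like
units with Gaussian fields (s.d. 5.4 cm, peak rate 20, centers on a 15 × 15
lattice) drives N_EC = 100 grid-layer cells through a plastic feedforward
matrix W.  The total field of grid cell i is

    h_i(t) = Σ_j W_ij r^I_j(t) + ρ_i(t),

where ρ is the recurrent collateral drive (below).  Firing-rate adaptation
uses two internal variables,

    h_act(t+1)   = h(t) − h_inact(t)
    h_inact(t+1) = h_inact(t) + β h_act(t+1),        β = 0.04,

so h_inact low-pass-filters h and sustained drive fatigues to zero.  Global
inhibition is a rank threshold: T is the largest h_act among the excluded
cells, so that exactly ⌈A·N_EC⌉ = 60 cells are positive (A = 0.6, ties broken
by index), and

    r_i = G (h_act,i − T)_+ / ⟨(h_act − T)_+⟩,      G = 0.1,

with ⟨·⟩ the mean over all cells, making the population mean rate exactly G.
Feedforward weights evolve by the covariance-like Hebbian rule

    ΔW_ij = ε (r^I_j r^EC_i − r̄^I_j r̄^EC_i),       ε = 0.005 (config knob),

with running averages r̄(t+1) = r̄(t)(1−δ) + r(t)δ, δ = 0.5; negative weights
clip to zero and any row with Euclidean norm above 1 is rescaled to the unit
sphere.  Rate maps accumulate per visited 2.4 cm pixel:
m ← m(1−τ) + r τ, τ = 0.03, on a 41 × 41 grid; analyses of population
topology use the central 60 cm (25 × 25 pixels).

### Recurrent collateral architectures

The collateral matrix is fixed, nonnegative, zero-diagonal, built by one of:

* **torus2d** — neurons on a 10 × 10 periodic lattice over the arena;
  weights follow the rectified three-cosine grid kernel
  f(x) = 1 + (2/3) Σ_i cos(k_i·x), wave vectors 120° apart with
  |k| = 4π/(√3·60 cm) so the kernel's own spacing is 60 cm; relative
  positions wrap (minimum image).
* **ring1d** — neurons every 3.6° on a circle; Gaussian of the minimum
  angular distance, s.d. 7.2°.
* **stripe1dl** — neurons on a line, Gaussian of distance with s.d. twice
  the inter-neuron spacing, no wrap.
* **fragmented** — the sum of 20 random 10-cell stripe attractors.
* **none** — zeros (control).

Rows are L1-normalized and the recurrent drive is

    ρ = recurrent_scale · A_rec · (Ŵ_rec r) / mean(r),    A_rec = 2,

i.e. the collateral input is a weighted neighborhood average of the rates,
normalized by the per-step population mean (= G whenever any cell fires,
guarded at 1e−12) — this keeps the feedforward and recurrent contributions
the same order of magnitude throughout learning, which is the stated goal of
the published normalization; the mechanism itself was a free design choice.
`recurrent_scale` ≠ 1 implements the too-strong/too-weak controls, and
`shuffle_recurrent` permutes each row's presynaptic identities.

Initial conditions (free choices): W rows i.i.d. uniform(0,1) scaled to unit
norm; h_act, h_inact, r̄ all zero.  A full run is 2·10⁷ steps; the default
test/acceptance scale is 10⁶ steps (~5% of full training), at which map
self-organization and population alignment are well underway but end-state
levels are not reached (see "Scaled runs" below).

## Grid metrics

Autocorrelograms are Pearson correlations of a map against itself at every
integer-pixel displacement, over the overlapping region (displacements with
fewer than 20 overlapping pixels are zeroed).  A circular Hamming taper of
1 m radius suppresses the low-overlap border region; the taper is used for
maxima detection and to bound the spacing search.  A 0.5 m radius would zero
out the 60 cm ring itself, so "1 m" is read as the taper radius.

**Spacing** is the radius with maximal magnitude of the 6th angular Fourier
coefficient of the polar-interpolated correlogram (bilinear, 1-pixel radial
and 1° angular steps, radii from 2 pixels to the lag-grid edge).  The search
runs on the *untapered* profile: the taper decays with radius and biased the
argmax inward by one bin on the ideal kernel (57.6 vs 60.0 cm).  A map is
flagged "no grid" when the winning ring carries almost no correlation mass
(mean |r| < 0.1 on the ring): pure-noise maps stay below ~0.07 while
hexagonal maps reach ~0.45, so the floor sits between the two populations.

**Gridness** is the mean *untapered* correlation at the six 60°-spaced
angles maximizing the 6-fold modulation on the spacing ring minus the mean
at the six interleaved angles.  Using untapered values keeps the score on
the interpretable correlation scale; the ideal kernel scores ≈ 1.3, white
noise |g| < 0.1.

**Angular spread** pools the six first-order correlogram maxima of every
non-flagged map, clusters them with k-means (k = 6, 10 restarts), and
averages absolute pairwise angle differences within clusters.  Aligned
populations score < 1°, random orientations ~15–20°.

## Topology stack

All persistence computations use an in-package Vietoris–Rips engine
(`flexgrid.homology`), written in the persistent-cohomology style: union-find
for degree 0, then per degree a reduction of the coboundary columns in
reverse filtration order with implicit cofacet enumeration, clearing of
columns paired in the previous degree, and compressed storage of reduced
columns.  Coefficients are Z2 or Z3.  The Rips scale is capped at the
enclosing radius (min-over-points of the max distance), beyond which the
complex is a cone and every positive-degree class has died.  The engine is
validated in the test suite against brute-force GF(p) rank computations of
simplicial homology on small complexes, at several scales and in both
fields.

Because the reduction enumerates all d-simplex columns, degree-2 diagrams of
large clouds are capped by deterministic maxmin landmark selection (default
200 points, chosen in the cloud's own metric, starting from the metric
1-center — no randomness).  Degree 0 always uses the full cloud (a Kruskal
pass is cheap and the H0 lifetime statistics should reflect the true
sampling density); degree-1-only computations (annulus neighborhoods, neuron
clouds) are never landmarked at the sizes used here.

**Metrics.**  Population clouds (625 pixels in R^100) use the kNN-geodesic
distance: shortest paths on the symmetrized k = 10 nearest-neighbor graph
with Euclidean edge lengths (disconnection is an error naming component
sizes).  Neuron clouds (100 maps in R^625) use the Pearson correlation
distance 1 − r.

**Automated Betti quantification.**  Per degree, pooled lifetimes go into a
100-bin histogram between 0 and their maximum, smoothed with a 3-bin-s.d.
Gaussian; among local minima the one with the greatest fall from the
preceding maximum is the cutoff, and Betti numbers count generators above
it.  The single essential H0 bar is assigned the display lifetime 1.2 × the
largest finite H0 lifetime so it participates in the counting; β₀ is clamped
to ≥ 1 since the essential class always exists.  Two adjustments stabilise
the rule outside its original regime (pools of 100 simulations):

* a degree whose pool holds fewer than 30 bars cannot support a 100-bin
  histogram; its cutoff is computed from the lifetimes pooled over all
  degrees of the same analysis (a clean circle has a single H1 bar and no
  per-degree noise floor);
* on sparse pools (< 500 bars) only essentially-empty valleys (< 0.5
  smoothed counts) qualify as separations, and a signal generator must be at
  least twice as long as the longest bar below the cutoff — the
  ordered-lifetime-difference idea: true topology stands clear of the noise
  floor, stragglers of a sparsely sampled noise tail do not.  Without these,
  a single pure-noise diagram reads spurious high Betti numbers.  Dense
  pools keep the verbatim rule.

**Local dimension.**  Per point, PCA of its k = 70 nearest Euclidean
neighbors (k = 20 recommended for unstructured populations); the local
dimension is the knee of the explained-variance-ratio curve in the
normalized-difference (kneedle) sense: the curve is truncated/zero-padded to
11 components, min-max normalized together with the component axis, and the
knee is argmax of (1 − y_n) − x_n.  Calibration anchors: an exact plane in
R^100 gives 2, a circle 1, an isotropic 3-sphere patch 3.

**Local homology.**  Per point, the annulus neighborhood between its 50th
and 100th nearest Euclidean neighbors (10/30 recommended for the
no-attractor condition) is run through degree-1 persistence; a single cutoff
pooled over all points' diagrams counts the loops.  Interior points of a
surface sample give β₁ = 1, boundary points 0, conical singularities 2.
Note the pooled cutoff presumes comparable annulus scales across points;
strongly heterogeneous sampling density (e.g. a glue point of two large
uniform planes, where the annulus is √2 denser and its rings weaker) can
push a genuine singularity below the pooled cutoff — a per-point cutoff
would be the alternative reading.

**Orientability.**  A closed surface has a salient H2 generator over Z2
(salient: at least twice the runner-up lifetime).  If the largest H2
lifetime under Z3 stays ≥ 50% of its Z2 value the dominant structure is
unchanged and the verdict is "orientable"; if it collapses below 50% the Z2
class was 2-torsion ("non-orientable", the Klein-bottle signature, which
also removes one H1 generator); no salient H2 signal is "inconclusive".

**Surface classification** chains the three checks — ≥ 90% of points locally
2-D, ≥ 90% with annulus β₁ = 1 (no boundary/singularities), orientable — and
then reads the Betti numbers; (1, 2, 1) with all checks passed is a torus.

## Population geometry of 1D attractors

For ring architectures each pixel gets the circular mean of the neuron ring
coordinates weighted by activity (pixels with near-zero resultant are
flagged, e.g. balanced antipodal bumps).  The configuration order O_n is
measured from the unwrapped phase increment per primitive lattice vector
(median over straight paths between anchor points, circular interpolation of
the phasor): if translating by a₁/a₂ advances the phase by δ₁/δ₂, the
attractor cycle displacement is the integer combination m a₁ + k a₂ with
m δ₁ + k δ₂ = 2π (±20% tolerance) of minimal hexagonal neighbor order, and
that order is O_n; near-zero increments mean the cycle closes within one
field (O₀).  A closed-loop winding number around a lattice tile would be
identically zero for any continuous phase field, so the per-lattice-vector
increment is the workable formalization of "the number of tiles traversed by
one attractor cycle".  On constructed phase fields the estimator recovers
O₀–O₃ exactly; on population-derived phase maps it is correct for most seeds
but can misread when circular-mean phases are noisy near frontiers — a known
limitation.  Stripe configurations are ordered by the hexagonal neighbor
order of the displacement between the activity peaks of the two attractor
extremes.

## Synthetic populations (what they emulate, and what not)

`ideal_grid_population` builds rate maps as the rectified three-cosine
kernel shifted by per-cell phases, plus i.i.d. Gaussian noise (s.d. as a
fraction of the kernel peak 3.0), with phases laid out uniformly over the
hexagonal unit cell (10 × 10 lattice plus 5% jitter — the end state of an
aligned 2D-attractor network), uniformly at random, along a winding-n cycle
(ring attractor configurations), or along an open path (stripe).  An
optional Gaussian envelope anchors each stripe cell's firing around its
phase position, emulating the imperfect tuning of trained stripe networks
whose attractor extremes occupy distinct fields; without it ideal maps are
exactly lattice-periodic and the extremes coincide.  Ring layouts with
winding ≥ 2 have circularly degenerate phase maps (w balanced bumps 120°
apart), so population-level order tests use winding 1 and constructed phase
fields for higher orders.

These fixtures reproduce the *structure* the analyses assume (aligned
lattices, smooth phase coverage, controlled noise) but not learning
transients, rate inhomogeneities, or the boundary irregularities of trained
maps; passing on fixtures therefore validates the analysis stack, while the
scaled simulation tests validate the model's own self-organization.

`manifold_sample` provides reference topologies: circle, flat torus
(double-angle embedding in R⁴), bounded sheet, sphere caps of intrinsic
dimension 2 or 3, a Klein bottle embedded in R⁴, and two orthogonal
2-planes glued at the origin of R⁴.

## Scaled runs and problem sizes

Full-scale training is 2·10⁷ steps × 100 simulations per condition; this
package's default validation scale is 10⁶ steps × 5 seeds × 4 conditions
(a single run takes ~20 s in the fused numba kernel).  At that scale the
population-level alignment signature is robust — population-autocorrelogram
gridness ≈ 0.12/0.22/0.23 for torus/ring/stripe vs 0.04 with no attractor;
angular spread 18.1/15.8/16.1 vs 19.3 — and map spacing contracts over
training for the torus (−9.8 cm) and ring (−8.9 cm) conditions, the sign of
the published negative spacing–time correlation.  Mean *individual* gridness
(~0.47–0.50 in all conditions at this scale) separates from the no-attractor
control only much later in training, consistent with the published learning
curves in which the control saturates while attractor conditions keep
rising; the end-state individual-gridness ordering is therefore not asserted
at the validation scale.

## Numerical choices

* Distance matrices are symmetrized (elementwise max) before persistence:
  cofacet filtration values are recomputed from matrix rows and must agree
  bitwise regardless of orientation; Dijkstra-based geodesic matrices are
  asymmetric at the ulp level, which would break lazy-heap cancellation.
* The transfer denominator ⟨(h_act − T)_+⟩ is guarded at 1e−12; a
  degenerate all-equal activation silences the step.
* The fused simulation kernel keeps a lazy per-row scale on the feedforward
  matrix (folded back when it drops below 1e−6) and truncates input rates
  below 1e−6 and running averages below 1e−10; the kernel is tested to
  reproduce the composed reference operations to 1e−8 over hundreds of
  steps.
* All randomness flows from a single seed through `numpy.random.SeedSequence`
  sub-seeds (< 2³¹) per component.
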
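# Methods

## Scope and model

`dsemicro` estimates an **axon radius index** from dual spin-echo (DSE)
diffusion MRI at clinical gradient strength (35 mT/m). The tissue is
modelled as three water pools in a voxel containing a coherent bundle of
parallel, impermeable cylinders of a single radius R:

    S / S0 = f_i * S_iso + f_r * S_restricted + (1 - f_i - f_r) * S_hindered,
    0 <= f_i + f_r <= 1

* **Isotropic** (CSF contamination): `S_iso = exp(-b D_i)` with D_i fixed at
  3.0e-9 m^2/s during fitting.
* **Hindered** (extracellular): cylindrically symmetric Gaussian,
  `S_h = exp(-b (cos^2(a) (D_par - D_perp) + D_perp))`, a the angle between
  gradient and bundle axis.
* **Restricted** (intracylinder): free 1-D Gaussian diffusion along the axis
  with D_par, multiplied by the Gaussian-phase-distribution (GPD)
  attenuation across the axis.

The model ignores compartmental T1/T2 differences, membrane permeability,
fiber dispersion and radius distributions; the fitted R is an *index*, not
a literal mean axon radius.

### GPD attenuation for arbitrary balanced waveforms

Rather than hard-coding the four-pulse DSE formula, the package evaluates
the GPD phase variance for *any* balanced piecewise-constant effective
gradient waveform. Writing the equilibrium position autocorrelation of
diffusion in a disk of radius R as

    <x(t) x(t')> = sum_m c_m exp(-lam_m |t - t'|),
    c_m = 2 R^2 / (alpha_m^2 (alpha_m^2 - 1)),   lam_m = D alpha_m^2 / R^2,

with alpha_m the roots of J1'(alpha) = 0, the log-attenuation is a double
integral of g(t) g(t') against this kernel. For piecewise-constant g every
segment pair has an analytic integral (no quadrature at run time). The
implementation is pinned by two independent oracles: the published
van Gelderen pulsed-gradient closed form (agreement to ~1e-15 relative) and
dense Gauss-Legendre quadrature of the double integral on the optimized DSE
arrangements (~1e-10 relative).

The Bessel-root series is truncated at **M = 30 roots**. At the protocol's
timing and diffusivity regime this keeps the series tail below 1e-8 in ln S
up to R = 15 um (20 roots leave ~1e-8 at 15 um, which is why the default is
30; adding further roots changes nothing at that precision).

### Known accuracy limit of the GPD

The GPD drops all phase cumulants beyond the second. Monte-Carlo
simulations in this package show that for R up to ~5 um under this protocol
the approximation is accurate to well below Monte-Carlo noise, but at
R = 10 um under the strongest arrangement (b = 2378 s/mm^2) the simulated
signal sits systematically 2-4% *below* the GPD value. The shortfall is
stable under time-step refinement and grows with attenuation, consistent
with the neglected negative fourth cumulant. Fits of large radii therefore
inherit a small model error on top of the prior-induced shrinkage.

## Protocol physics

Arrangements are ideal rectangular pulses (the sequence's own analytic
assumption; trapezoidal ramps are out of scope). Effective polarities are
inferred from the zero-net-area balance condition by sign enumeration: the
b-value and all model signals depend only on the effective waveform, not on
where the 180-degree pulses sit. b = gamma^2 * int q(t)^2 dt is evaluated
exactly on the piecewise-linear q. The built-in optimized protocol
(35 mT/m, TE 118.54 ms, five arrangements, 90 directions each plus nine
usable b = 0 volumes) reproduces the printed b-values 422, 620 and
2378 s/mm^2 to the nearest integer.

"Effective diffusion time" is reported as the onset-to-onset separation of
the outermost pulses — a convention, not physics; it reproduces the quoted
short (22 ms) and long (80-92 ms) diffusion times.

The eddy-current residual treats every gradient slew event as launching an
exponentially decaying field and sums the decays at the echo, normalized by
the gradient amplitude. Note that physical eddy currents follow the
*physical* gradient train; since the 180-degree pulse placements (hence the
physical polarities) are not part of the arrangement tables, the residual
computed from the effective waveform is a diagnostic, not a reconstruction
of the scanner's compensation state.

The Cramér-Rao objective evaluates inverse Fisher information under
independent Gaussian noise with central finite differences (step 1e-4 of
each parameter scale, one-sided at domain boundaries). The Fisher matrix
is inverted in scale-normalized coordinates: in raw SI units the mix of
~1e-9 diffusivities and ~1 fractions produces condition numbers ~1e18 that
are pure unit artifacts. Design-search over pulse timings is out of scope;
only the objective for a fixed protocol is provided.

## Monte-Carlo simulator

Substrates are 2-D cross-sections of parallel cylinders in a periodic
rectangular cell (axial motion is free and appended as an independent 1-D
Brownian coordinate). Two substrate families:

* **Hexagonal, fixed radius**: center spacing 2.3 R gives intracellular
  area fraction 2*pi/(sqrt(3)*2.3^2) ~= 0.686 for any R. The cell is the
  smallest lattice-commensurate rectangle spanning >= 10 cylinder
  diameters.
* **Gamma-distributed radii**: radii drawn from Gamma(mean^2/var,
  var/mean); cylinders are dart-thrown (largest first) into a dilute cell,
  which is then contracted gradually with repulsive overlap-relaxation
  sweeps until the intracellular fraction reaches the 0.65-0.70 target.
  Pure random sequential placement jams near fraction ~0.55, so the
  contraction stage is required to reach the target density; the resulting
  packings are random but not strictly "random sequential adsorption"
  configurations.

Walkers take Gaussian steps of s.d. sqrt(2 D dt) per axis over uniform
steps spanning [0, TE]. Membranes are impermeable both ways; collisions are
resolved by elastic specular reflection with repeated sub-step resolution
(up to 16 reflections per step, after which any unresolved remainder of the
step is discarded — rare, and logged as a potential small bias). A
crossing audit recomputes container membership each step; all shipped
tests observe exactly zero crossings. A warning is emitted when the step
length exceeds 0.2 x the smallest radius (geometry under-resolved).

Phase is accumulated trapezoidally: each step contributes
`g_int * (x_before + x_after)/2` with `g_int` the *exact* integral of the
effective gradient over the step interval, using unwrapped coordinates.
End-of-step accumulation leaves an O(dt) bias visible at 500 steps; the
trapezoidal rule removes it. One trajectory ensemble per substrate serves
every arrangement and direction simultaneously (the phase is a direction
projection of one vector integral), which makes measurement noise slightly
correlated across directions of one synthetic dataset but leaves each
signal unbiased. Signals are magnitudes of the ensemble-average phasor;
Rician noise is added per measurement as sqrt((v + n1)^2 + n2^2) with n1,
n2 ~ N(0, (S0/SNR)^2), SNR 19 at b = 0 matching the scanner estimate.

The synthetic study conditions are the defaults: hexagonal substrates at
fraction 0.69, diffusivity 1.7e-9 m^2/s, SNR 19, orientations spread over
the sphere by electrostatic repulsion, one dataset per (radius,
orientation) with counter-derived seeds.

What the simulator does *not* emulate: permeability, axial undulation or
beading, gradient ramps, T2 decay differences, imaging artifacts or
spatial noise correlation. Passing tests therefore certify the estimator
under the model's own geometry assumptions, not under real-tissue
complexity.

## Bayesian fitting

Measurements are Rician around the model prediction (evaluated with the
exponentially scaled Bessel I0 for overflow safety); measurements are
independent, so the joint log-likelihood is a sum. The informative priors
are

    f_i ~ Beta(1.2, 1.2)
    f_r / (1 - f_i) ~ Beta(5, 5)
    D_par ~ LogNormal(-20.69, 1)     mean 1.7e-9 m^2/s
    D_perp ~ LogNormal(-21.04, 1)    mean 1.2e-9 m^2/s
    R ~ Gamma(shape 3.562, scale 1.404e-6 m)   mean 5 um, mode ~3.6 um

in SI units and natural space. Any single prior can be disabled, which
reverts that coordinate to a flat prior on its transformed scale. The
noise prior is flat on log sigma over a broad bounded support (the study
leaves P(sigma) unspecified; a log-flat prior is a weak, sampler-friendly
default).

Sampling is blocked Metropolis-Hastings on transformed coordinates
(logs for positive parameters; logits for f_i and f_r/(1 - f_i); angles
untransformed with periodic wrapping and hemisphere folding at summary
time). Change-of-variable Jacobians enter the target density explicitly,
and a test verifies that accept/reject decisions are identical whether the
ratio is assembled in transformed or natural space. Blocks: (S0),
(f_i, f_r), (D_par, D_perp, R), (theta, phi), (sigma). D_i is fixed; f_i
can be fixed at 0 (synthetic data, which contain no CSF pool).

Chains initialize from an ordinary-least-squares log-linear tensor fit:
D_par = lam1, D_perp = (lam2 + lam3)/2, axis from the principal
eigenvector, R = 5 um, f_r = 0.7 (1 - f_i), and
f_i = lam3^2/(lam1 lam2) clipped to [1e-3, 1 - 1e-3] (the eigenvalue-ratio
rule tends to 1 for isotropic CSF-like voxels and is small in coherent
white matter; it only seeds the chain). Negative eigenvalues are clamped
to 1e-12 m^2/s; degenerate tensors fall back to the prior means. The
initial sigma is the tensor fit's RMS residual.

Proposal tuning runs after a short pre-adaptation sweep (so tuning sees
the posterior's local scale, not the initialization point): epochs of 250
iterations, after each of which a block's proposal scale is multiplied by
exp(acceptance - 0.23), until all block acceptances lie in [0.15, 0.35] or
30 epochs elapse. Adaptation is then frozen, preserving detailed balance
for the burn-in and sampling phases. Full-scale settings are burn-in
50,000 with 50 samples thinned by 100; the shipped desk-scale experiments
use burn-in 5,000 with 50 samples thinned by 20, which the
prior-recovery, toy-target and parameter-recovery tests support as
adequate for the pooled summaries reported here.

The per-voxel point estimate of radius is the **median of the posterior R
samples** (the axon radius index); maps also carry f_r, f_i, D_par,
D_perp, R^2 at the posterior-median parameters, and the percent
coefficient of variation of the R samples.

## Comparison metrics

Histogram intersection H = sum_j min(h1j, h2j) / sum_j h1j over shared
density-normalized bins; radius histograms use the range [0, 25] um with
0.25 um bins for synthetic pooled-posterior comparisons and 0.5 um bins
for whole-structure comparisons, with out-of-range samples assigned to the
end bins (the source histograms' truncation behavior is not stated; the
overflow-bin rule is this package's convention and keeps densities
normalized over all pooled samples). Callosal subregion analysis cuts the
mask into five slabs by equally spaced planes along the
anterior-posterior axis, boundary voxels joining the anterior side;
scan-rescan agreement uses the relative absolute difference
|a - b|/(a + b) of subregion medians.

## Desk-scale experiment sizes

The shipped discriminability experiment uses 4 generative radii
(1, 3, 5, 10 um) x 3 orientations, 2,000 spins x 500 steps per substrate,
SNR 19, and reduced chains (burn-in 5,000, 50 samples thinned by 20, f_i
fixed at 0), pooling 150 posterior samples per radius. These sizes were
chosen as the smallest at which the pooled histograms are stable enough to
reproduce the published overlap ordering; the generative substrate,
noise level and prior set are the full study conditions.

## Numerical choices and degenerate inputs

* Balance tolerance for waveforms: 1e-9 relative to amplitude x duration.
* Same-segment GPD integrand `x - 1 + exp(-x)` switches to its series for
  x < 1e-4 to avoid cancellation.
* Polarity inference prefers the lexicographically first balanced sign
  pattern with a leading +1 (global flips are physically irrelevant).
* Non-positive signals are excluded from the tensor fit; fewer than seven
  usable measurements is an error.
* A non-finite posterior at initialization triggers bounded re-draws
  around the start point before failing.
* Voxels whose proposal acceptance stays at zero through tuning are
  flagged, not dropped.

## Known limitations

* Single-radius cylinder model: gamma-substrate experiments show biased
  (overestimated) posteriors when the substrate truly contains a radius
  distribution, although ordering by mean radius is preserved.
* The prior dominates where the likelihood is flat: radii >~ 15 um are
  pulled down toward the prior mass, and sub-micron radii are
  indistinguishable — behavior inherited from the study design, not a
  software artifact.
* The GPD model error at R ~ 10 um described above.
* The simulator's specular-reflection rule is one of several defensible
  membrane interaction models; with 500-1,000 steps per echo time the
  step length can exceed 0.2 x radius for micron-scale cylinders (a
  warning is raised), slightly under-resolving the narrowest
  extracellular gaps.
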
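# Methods

`oceanhsrl` implements the full measurement chain of a triple-field-of-view
(FOV) oceanic high-spectral-resolution lidar (HSRL): the optical
parameterization of seawater, two forward models of the range-resolved
multi-FOV returns, the iterative inversion that recovers vertical profiles of
the absorption coefficient *a*, the scattering coefficient *b* and the
particle-size-distribution (PSD) slope *ξ*, and the derived products
*K*<sub>d</sub>, *b*<sub>bp</sub>, lidar ratio *R* and single-scattering
albedo *ω*₀.

## Seawater optics

Pure seawater at 532 nm contributes a_w = 0.042 m⁻¹ absorption,
b_w = 0.0022 m⁻¹ scattering and b_bw = 0.0011 m⁻¹ backscattering;
temperature and salinity dependence is deliberately omitted.  Particles
follow a power-law (Junge) size distribution of slope ξ, which fixes the
relative refractive index through m = 1.01 + 0.1542 (ξ − 3) and, through
the Fournier–Forand closed form, the particulate phase function and the
backscatter fraction BF(ξ) = b_bp / b_p.  We use the standard
Fournier–Forand convention δ(θ) = (4/3)(m − 1)⁻² sin²(θ/2), under which
the analytic cumulative distribution, the phase density and BF are mutually
consistent (BF equals the backward-hemisphere integral of the phase
function to better than 1 %, enforced by a quadrature test).  The valid
slope domain is 3 < ξ ≤ 5; BF degenerates at ξ = 3.  The molecular
(Brillouin) channel is modeled as Rayleigh-like, p(θ) ∝ 1 + f cos²θ with a
depolarization-adjusted f = 0.835 by default; near 180° the choice barely
affects channel ratios and it is exposed in the configuration.

## Semianalytic Monte Carlo forward model

The reference forward model traces photon packets through a depth-gridded
water column.  Free paths are drawn from the local scattering coefficient;
absorption attenuates packet weight continuously (`exp(−a·path)`); weights
below 10⁻⁶ enter Russian roulette.  At every collision an analytic
estimator adds the expected return to each channel: packet weight × the
probability of scattering into the receiver aperture × the transmission of
the return ray, binned at half the total optical path (time-of-flight
convention).  Because the Fournier–Forand forward peak varies enormously
across the aperture, the estimator integrates the phase function *exactly*
over the aperture disk (a precomputed off-axis cap-convolution table)
rather than evaluating it at a point; the point evaluation is both biased
and variance-exploding for near-forward deliveries.

Channel split (ideal iodine filter): a molecular Brillouin scattering shifts
the packet ~7–8 GHz off the laser line and subsequent particulate scattering
is elastic, so a packet belongs to the molecular channels as soon as its
history contains one molecular event.  This matters: the multiply
scattered wide-FOV molecular return is carried by Brillouin-shifted packets
that a particle redirects into the aperture on the way up, and it is what
drives the wide-FOV lidar attenuation toward the diffuse regime
(≈ 2a two-way) while the narrow FOV stays near the beam attenuation 2c.
Two variance-reduction devices make 10⁶-photon budgets usable:

* molecular scatterings are importance-boosted (sampled with probability
  ≥ 0.1, weights compensated exactly) so the shifted population is well
  sampled;
* at each scattering of a shifted packet the outgoing distribution is
  *split* into the cone of half-angle 0.3 rad around the receiver direction
  — carried by a spawned sub-packet holding exactly the phase-function mass
  of the cone — and its complement, carried by the parent.  Sub-packets do
  not split again; when the spawned weight would be negligible the parent
  simply samples the full sphere, which keeps the scheme unbiased at any
  spawn threshold.

The estimator was checked for invariance against the splitting parameters
(cone angle, spawn floor) and against the aperture-table resolution, and the
signals converge to the closed-form single-scattering lidar equation in
particulate-free water within Monte Carlo error.  Signals are returned with
per-bin standard errors estimated from 16 internal photon batches (which
respects intra-family correlations introduced by splitting).

## Analytic forward model (quasi-single-scattering, small-angle)

The fast surrogate used inside the inversion treats each molecular channel
as a single-backscatter return behind an effective two-way attenuation.
Absorption and molecular scattering attenuate fully; particulate forward
scattering through angles smaller than a geometric cutoff

    θ_cut(z′, z) = fov_half · (H + z) / (z − z′)

is *retained* in the beam (the deflected photon still lies inside the
receiver cone radius at the backscatter depth z; H is the platform height).
The retained fraction is the closed-form Fournier–Forand cumulative at
θ_cut, averaged over the source bin with Gauss–Legendre quadrature and
capped at π/2.  Retention applies on both legs — the receiver beam is the
reciprocal of the transmitted beam, and Brillouin-shifted light remains
molecular-channel light through elastic redirection — which reproduces the
Monte Carlo channels to a few per cent over the usable depth range.  Range
gates are integrated exactly for piecewise-constant coefficients, and the
geometry factor is the exact gate average of (H + z)⁻², so the surrogate
agrees with the Monte Carlo estimate to round-off in the single-scattering
limit.  The combined channel adds the particulate 180° return
β_p(π) = b_p p_ξ(π) behind the same wide-FOV attenuation; it is a
documented approximation (the deep combined channel is dominated by
stretched multiple-scattering paths outside the quasi-single-scattering
picture) and is not used by the inversion.

Two scalar knobs (a uniform cutoff rescale and an angular-random-walk
shrink of the cutoff with retained optical depth) were calibrated once
against high-statistics Monte Carlo runs on three scenario waters; the
calibration selected the plain geometric cutoff (scale 1, no shrink), which
is therefore the default.

## Iterative retrieval

The inversion minimizes the relative difference between measured and
simulated molecular signals at the three FOVs simultaneously,
X = argmin ‖(B_M − B_S)/B_M‖₂, with Gauss–Newton relative steps
ΔX/X = S⁻¹ ΔB/B, where S is the central-finite-difference sensitivity of
the (log) signals to relative parameter perturbations; S is exactly
lower-block-triangular in depth (a bin never influences shallower returns).
Safeguards around the raw step: log-space residuals and multiplicative
updates (linear in the attenuation errors even far from the solution), a
halving line search, Tikhonov ridge plus a vertical-smoothness penalty,
and projection onto [a_w, 2] × [b_w, 5] × (3, 5].  Iteration stops when the
pooled signal RMSRD, RMSRD = 100·√(Σ(x_i/x̃_i − 1)²/n), falls below the
noise-level tolerance (default 10 %) or when no damped step improves the
fit; the best iterate is always returned with full per-iteration
diagnostics.

Three practical elements matter for accuracy:

* **Initialization.**  The slope-based first guess (a₀ from the wide-FOV
  attenuation, b₀ = K_narrow − a₀ floor-clipped to b_w, ξ₀ = 3.5; the
  literal reading b₀ = K_narrow is available via a switch) is refined by a
  three-parameter depth-constant pre-fit solved with Levenberg–Marquardt in
  log-parameter space.  For homogeneous water the pre-fit is already the
  answer; for stratified water it starts the per-bin refinement close to
  the solution.
* **Noise weighting.**  Residuals are weighted by the per-bin signal
  uncertainties reported by the Monte Carlo engine (or unit weights if
  absent), floored by an irreducible 3 % model-error term.  Deep bins near
  the dynamic-range cutoff are noisy and would otherwise dominate the
  log-residual.
* **Usable depth.**  Bins are dropped once the narrow-FOV signal falls
  three orders of magnitude below its near-surface value, mirroring the
  instrument's usable dynamic range, or when any molecular channel goes
  non-positive.  Signals are compared relative to the first usable bin,
  which removes the system constant and any common amplitude bias between
  the data and the surrogate.

## Identifiability

The triple-FOV molecular measurement constrains the three unknowns
unevenly.  The wide FOV pins *a* strongly (its attenuation is close to the
diffuse regime), and *a* is recovered to a few per cent.  The pair (b, ξ)
is constrained only through the FOV-differential retention, and a soft
trade-off direction (larger b with smaller ξ producing nearly identical
channels) survives: in turbid waters (b toward 0.75 m⁻¹) profiles differing
by tens of per cent in b along this direction produce molecular signals
that agree within ~1 % over the usable range — we verified this directly
with the Monte Carlo engine, independently of the surrogate.  Retrieval
errors in b and ξ are therefore dominated by where the noise and the
residual ~1 % surrogate bias push the solution along this valley, improve
with photon budget, and are largest in the most turbid waters (the same
qualitative behaviour the technique shows in its original setting).  The
derived products offer a route out (the combined channel measures
β_p(π) = b_p p_ξ(π), which crosses the valley), but the inversion proper
uses only the molecular channels by construction.

## Synthetic scenarios

Presets L1–L5 span a nearshore-to-offshore transect: (a, b, ξ) from
(0.11, 0.75, 3.15) in the most turbid nearshore water to
(0.047, 0.25, 3.42) offshore, homogeneous over 0–30 m; L4 has a stratified
variant with a clearer 5 m surface layer emulating a clear-water intrusion.
Ensembles are Latin-hypercube draws over
a ∈ [0.047, 0.11], b ∈ [0.25, 0.75], ξ ∈ [3.15, 3.42].  Poisson
photon-counting noise can be layered on top; the Monte Carlo fluctuations
themselves play the role of system noise in the validation experiments.
What the generator does not emulate: sea-surface waves and refraction
(flat, refraction-free interface; FOVs are treated as in-water full
angles), polarization, detector artifacts, Brillouin lineshape, and depth
structure beyond piecewise-constant layers.  Passing recovery tests on
these scenarios therefore demonstrates the correctness and conditioning of
the measurement chain, not instrument-grade accuracy on field data.

## Validation experiment sizes

The recovery experiment used by `scripts/acceptance.py` and the acceptance
tests runs 20 Latin-hypercube profiles, 20 m deep at 1 m bins, observed at
1.5 × 10⁶ photons per profile (tests: 1.2 × 10⁶), plus a low-noise rerun of
the first six members (tests: five) at 6 × 10⁶ photons (tests: 5 × 10⁶) for
the PSD-slope scores.  Per-parameter scores are pooled over all usable bins
and profiles.  Geometry defaults: platform height 5 m, receiver radius
0.1 m, FOVs 40/80/200 mrad (full angles, in water), system constant 1.

## Numerical choices and degenerate inputs

* Phase-function tables: 2048-point log-angle grids; sampling by inverse
  CDF; the removable δ = 1 singularity of the closed forms is nudged off.
* The aperture cap-convolution table spans aperture half-angles
  0.5–60 mrad (log grid) × 512 off-axis angles; entries are 48-point
  Gauss–Legendre integrals with the fully-inside cap handled by the closed
  form.
* Sensitivity differencing uses a 2 % relative step, projected at the
  parameter bounds (a pinned parameter contributes a zero column).
* Profiles must sit on a uniform bin-center grid starting at dz/2;
  non-physical inputs (a < a_w, b < b_w, ξ outside (3, 5]) are rejected at
  construction.
* `iterate_retrieval` falls back to a mid-range constant first guess when
  fewer than five usable bins exist (too few for slope estimates).
* Retrieval below the deepest usable bin is not attempted; the deepest
  bin's parameters are only weakly identifiable (its in-bin retention is
  FOV-independent) and lean on the smoothness prior.

## Known limitations

* The combined-channel surrogate under-represents stretched
  multiple-scattering tails; combined-channel products are most reliable
  over the first optical depths.
* b and ξ inherit the soft-valley errors discussed above, largest in
  turbid water; reported uncertainties are pooled RMSRD diagnostics, not
  per-bin error bars.
* The instrument model is idealized: perfect iodine rejection, coaxial
  geometry, no overlap function, no surface roughness or refraction, no
  detector saturation or afterpulsing.
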
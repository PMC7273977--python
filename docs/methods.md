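# Methods

This note records the models, conventions and numerical choices behind
`bootrecon`, and what the synthetic experiments do and do not demonstrate.

## System model and projector

The forward model is `A = Radon ∘ PSF`: an isotropic image-space Gaussian
blur (FWHM `Geometry.psf_fwhm`, in mm; 0 disables it) followed by a
pixel-driven parallel-beam projection. Each pixel centre at offset
`t = x cosφ + y sinφ` deposits its value into the two nearest radial bins
with linear interpolation weights. Conventions: pixel centres, image centre
at the grid centre, angles in degrees uniformly covering [0°, 180°), radial
bin 0 at the most negative offset.

The back projector is the exact adjoint — the transpose of the same sparse
interpolation matrix, followed by the same Gaussian blur (zero-padded
correlation with a symmetric kernel is self-adjoint). A matched pair costs
a little modelling fidelity relative to a ray-driven integrator but makes
EM monotonicity, KKT conditions and adjoint identities hold to machine
precision, which the test suite exploits; these properties are only
approximate with an unmatched transform/adjoint pair.

The sparse matrix for a geometry is cached; the default desk geometry
(64×64 image, 2 mm pixels, 60 angles × 95 bins of 2 mm) keeps every
experiment in this repository in the seconds-to-minutes range on one CPU.
A full-scale 2D profile (180 angles × 185 bins) is available through
`full2d_geometry` / the CLI geometry flags.

FBP uses a plain ramp filter (|f| in cycles/mm, FFT with zero padding to
the next power of two past 2n bins); no apodisation window is applied since
FBP here only serves for guide, reference and mask images, never as the
reconstruction under study. The pixel-driven projector measures sums of
pixel samples rather than line integrals, so the backprojection is scaled
by `π · pixel_size² / (n_angles · bin_size)` to restore sample units; the
disc-phantom self-consistency test (normalised RMSE < 10% at 180 angles)
pins this factor.

## Acquisition simulator

`simulate_acquisition` emulates a 2D PET acquisition: the phantom is
blurred by the intrinsic scanner resolution (default 4.5 mm FWHM), projected
with a PSF-free system model (the intrinsic blur is handled explicitly so
reconstruction may use an independent PSF model — the default
reconstruction PSF is 3 mm), and combined with two mean background
components: scatter (the true projections blurred radially, per angle, with
a 10-bin-σ Gaussian; a flag switches to 2D blur) and randoms (uniform).
Fractions are defined against the *total* expected counts — 20% scatter and
20% randoms by default, leaving 60% trues — and the component means are
rescaled so the decomposition is exact to 1e-9 before Poisson noise is
drawn per bin. The background `b` handed to reconstruction is the exact
scatter+randoms mean, the idealisation of perfectly known background
estimates. Count levels 3.5e5 / 3.5e6 / 3.5e7 span the regimes from
substantial to nearly no required regularisation.

The `brain_like` phantom is procedural: a head-shaped support with a
high-uptake cortical ribbon, deep-grey nuclei, cold ventricles and a few
hot cortical foci, mimicking FDG contrast. It is *not* a digitised brain;
experiments on it verify method behaviour (trace shapes, monotonicities,
grid-search comparability), not any particular published error magnitude.
Real data also differ in ways the simulator does not model: attenuation,
detector normalisation, realistic scatter physics, dead time, and 3D
geometry. Passing tests therefore demonstrate the selection mechanism, not
clinical image quality.

Randomness uses one named substream per purpose (noise, bootstrap, thinning,
phantom), each derived from the user seed, so e.g. changing only the
bootstrap seed leaves the noise realisation untouched.

## Penalty machinery

Weights live on a fixed odd stencil of (dy, dx) offsets; out-of-image
neighbours carry weight zero and all normalisations run through the actual
per-pixel sum (truncation, no padding). The uniform map includes the centre
offset, making the interior 5×5 sum 25; the centre contributes nothing to
the roughness value but does enter the weight sums that scale ν and θ_reg.
Bowsher candidates are neighbours only (interior sum B), similarity is the
squared guide difference, ties break by stencil order, and border pixels
keep min(B, available). Bowsher weights are directed by default; a
`symmetrise` flag provides (w + wᵀ)/2 for when provable monotone ascent is
wanted. Either centre convention merely rescales the effective β — which
the selection mechanism absorbs — but the chosen convention is fixed by the
25-per-interior-pixel anchor above.

One deliberate bookkeeping decision: deriving De Pierro's separable
surrogate for the quarter-sum roughness `R = ¼ΣΣ w_jl (θ_j−θ_l)²` shows
that the update built on ν = Σw/s performs monotone ascent on
`loglik − (β/2) R`, not `loglik − β R`. The package keeps the update and
the quarter-sum penalty in their familiar printed forms and encodes the
factor once (`recon.PENALTY_STRENGTH_FACTOR`), so the reported objective,
the KKT checks and the independent-optimiser cross-check are mutually
consistent. The factor has no effect on the selection method, which scales
β automatically.

## Numerical choices

- `F_β` is evaluated as the positive root of `aνx² + ξx − θ_em` per pixel,
  using the rationalised `2θ_em/(ξ+√(ξ²+4aθ_em))` branch for ξ ≥ 0 and the
  direct root `(√disc − ξ)/(2a)` for ξ < 0, avoiding catastrophic
  cancellation in both regimes. Pixels with zero sensitivity are frozen at
  zero; sinogram bins with zero model mean and zero counts contribute 0/0→0;
  counts in a zero-mean bin raise an error (model inconsistency).
- The EMOF is summed (not averaged) over the mask Ω — the argmin is
  invariant. Its gradient uses the implicit derivative
  dF/dβ = −ν F (F − θ_reg)/√disc.
- The 1D β search brackets the upper bound by geometric growth (×10 from 1
  until the objective rises, max 12 expansions), scans ~80 log-spaced
  points, refines the best bracket with bounded Brent, warm-starts a second
  refinement at the previous iteration's fit, always admits the β = 0
  boundary, and polishes the winner to ~1e-5 relative. The dense-grid
  oracle test (1e4 points) confirms the search does not get trapped.
- Bootstrap replicates are generated once before iterating and held fixed.
  Above 2e5 total counts the replicate is drawn directly from
  Multinomial(Σm, m/Σm) instead of materialising the event list; the two
  procedures are distributionally identical and the tests verify this on
  small cases.
- The EMOF mask is a single threshold (10% of the 99th percentile) of an
  FBP reconstruction of the background-corrected data, followed by hole
  filling and keeping the largest connected component. The same mask serves
  the error metrics unless a separate one is supplied.
- The error reference is the FBP of the clean, unblurred phantom
  projection, rescaled to the count scale of the trues so that normalised
  bias/SD/RMSE compare like with like.

## Driver parameters

- `lambda0` (default 1000) and `N` (default 100 iterations): cooling
  initialisation and decay constant. Both only need to be "large enough";
  the selected β plateaus in both, at the cost of more iterations. The
  desk-scale experiments in the tests and the acceptance script use N = 30
  with 120–900 iterations, i.e. the same ≥(3–4)N, up to 30N, multiples of
  the full-scale defaults.
- `max_iter`: at least 3–4 N so the over-regularisation has decayed by the
  end; runs meant to demonstrate endpoint equivalence with a fixed-β
  reconstruction use ~30 N, since both trajectories must be near
  convergence before their distance drops below 1%.
- `n_bootstrap` (default 1): number of replicates; β_opt is the maximum of
  the per-replicate fits. On high-count data a single replicate can fit
  β = 0 for an entire run; ten replicates remove that failure mode. At desk
  scale the sinogram has ~10× fewer bins than the full 2D geometry, which
  also inflates the variance of the single-replicate fit at mid count
  levels — the grid-search comparability experiment therefore runs with
  ten replicates, where the selected β lands on the grid optimum.

## Known limitations

- 2D only; no attenuation, normalisation, time-of-flight or list-mode
  handling of scanner data.
- Convergence of MAPEM with *directed* Bowsher weights is not guaranteed
  (the monotonicity proof assumes symmetric weights); in practice the runs
  are well behaved, and the `symmetrise` flag restores the assumption.
- The β selected on bootstrap resampling noise compensates statistical
  noise only; systematic model errors (wrong background, wrong PSF) are
  outside its reach.
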
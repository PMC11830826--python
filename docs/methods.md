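# Methods

`abermat` implements guide-star-free computational adaptive optics for
angle-resolved holographic imaging of optically thick samples, together
with the synthetic-data machinery needed to validate it end to end.  This
note records the models, the defaults and why they were chosen, and what
the synthetic studies do and do not demonstrate.

## Aberration model and detection

A measurement is a set of complex fields `E_out(r; k_in)` acquired under
plane-wave illumination at incidences `k_in`, organised in *tilt groups*:
one central incidence plus (at least) two companions tilted by small
`delta_k` in linearly independent directions.  The sample is modelled as a
target operator `T` sandwiched between two aberrating media described by
pupil transfer functions `P_in`, `P_out` with phases `phi_in(k)`,
`phi_out(k)` (the aberration functions).  Because of the angular memory
effect, tilting the incidence by `delta_k` tilts the scattered field by the
same amount within the memory-effect range, so the conjugate product of the
tilt-shifted and unshifted spectra cancels the target contribution:

    A(k_out; k_in) = E~(k_out + dk; k_in + dk) E~*(k_out; k_in),
    arg A = [phi_out(k_out + dk) - phi_out(k_out)]
          + [phi_in(k_in + dk) - phi_in(k_in)] + O(dk^2 / k_MER^2),
    |A|  ~= |T(k_out; k_in)|^2.

The pipeline is:

1. **Matrix construction** (`build_aberration_matrix`): one column per
   group; sub-pixel tilts are handled exactly for band-limited fields by a
   real-space phase ramp before the forward FFT, never by pixel rolling.
2. **Reweighting** (`threshold_reweight`, `mask_offdiagonal`): the modulus
   (the target's angular spectrum squared) is a poor weight when the
   spectrum is narrow, so entries above a threshold are replaced by unit
   phasors.  The default threshold is a modulus quantile (q = 0.6) rather
   than a manually tuned level: reproducibility requires a deterministic
   rule; a numeric override exists.  Quantile selection keeps exactly
   `ceil((1 - q) n)` entries (top-k, tie-robust).  Optional masking removes
   entries with `|k_out - k_in|` beyond a radius (0.3-0.4 NA is a sensible
   band for low-scattering samples); note the exact no-op radius is
   `NA_det + NA_ill`.
3. **Factorization**: either a plain SVD or, by default, projection power
   iteration on the unimodular quadratic programme `max v^H (A^H A) v`,
   `|v_i| = 1`, iterated as `v <- e^{i arg(M v)}` from the all-ones vector;
   the outgoing differences then follow in closed form as `arg(A v)`.  The
   UQP objective is non-decreasing and always dominates the
   unimodular-projected SVD solution (asserted in tests).  Each detection
   pixel also gets a *reliability*: the coherence `|A v| / n_survivors` of
   the phasor sum behind its estimate.
4. **Gradient integration** (`integrate_gradients`): directional
   differences from two (or more) tilt directions are converted to
   Cartesian gradients by a per-pixel linear solve (no unwrapping), then
   integrated by weighted least squares over the pupil support with free
   boundaries: each adjacent-pixel edge contributes one wrapped difference
   equation, weighted by the geometric mean of the pixel reliabilities,
   solved by conjugate gradients (tolerance 1e-10, zero start).  The edge
   target is the forward difference anchored at the left/upper pixel -
   the exact discrete inverse of the measured differences.  Piston is
   pinned at the pupil-centre pixel; tip/tilt is kept by default (it
   encodes genuine image shift / refocus) with an opt-in removal used by
   the iterative loop, where gauge-tilt accumulation would otherwise walk
   the image out of the window.

Gauge conventions: the factorization's global phase per tilt direction is
unobservable and appears after integration as an arbitrary tip/tilt;
comparisons against ground truth therefore align piston and tilt first
(`align_piston_tilt`, a Fourier-peak coarse fit plus wrapped-residual
refinement).

**Desk-scale sampling caveat.** A layer at distance `z` from the focal
plane contributes the pupil phase `phi_layer(z k / kz)`.  On an `N`-pixel
lattice the per-k-pixel step of that mapping, `z (1 + k^2/kz^2) dk / kz`,
grows towards the pupil rim; where it exceeds the layer's correlation
length the gradients are aliased and integration injects spurious
low-order phase everywhere.  The reliability weighting mitigates this, and
`DetectorConfig.support_na` can exclude the rim outright.  This is a
limitation of coarse simulation lattices (and would apply to real data
only at extreme depth-to-FOV ratios).

## Correction

Correction is phase-only: spectra are multiplied by `e^{-i phi_out}` on the
support (`correct_outgoing`; exactly energy-conserving) and each group by
the scalar `e^{-i phi_in(k_in)}` (`correct_incoming`; only needed before
tomographic synthesis).  For media whose isoplanatic patch is smaller than
the PSF, `iterative_windowed_correction` loops window -> detect -> correct
the *original* stack, with a coarse-to-fine window schedule, per-step
tilt removal, and an under-relaxation gain (default 1.0; 0.7 in the
deep-tissue benchmark where the per-pass estimate is noisy).  The loop
stops early when the update RMS falls below 0.01 rad (configurable).

## Thin-target baseline

`baseline.class_iterate` implements the prior matrix-AO approach that
assumes a thin target, `E~ = P~_out(k_out) S~(k_out - k_in) P~_in(k_in)`,
and alternately maximises the synthesized 2D image intensity over the two
unimodular pupil phases (projection power updates; monotone by assertion;
initialisation at flat phases, iteration cap 50, relative tolerance 1e-9
- pinned because the non-convex objective has many maxima).  Incidences
are snapped to the k-lattice (the K-indexing presupposes a common grid);
the maximum rounding error is recorded.  On volumetric targets the method
raises its objective without improving the field - the contrast the
package's validation reproduces.

## Tomography

Reconstruction uses the Rytov approximation in gradient form: per pixel,
forward differences of `log |E/E_in|` plus `i` times the *wrapped* forward
differences of `arg(E/E_in)` (amplitude floor 1e-3 of the field maximum
before the logarithm).  These stay single-valued across phase vortices,
where area unwrapping is path-dependent.  In k-space the complex Rytov
phase is recovered by dividing by the exact finite-difference symbols
(least-squares combination of x and y; the DC component is irrecoverable -
the tomogram background is pinned to the medium index instead), mapped
onto the Ewald cap `V~(k - k_in, kz - kz_in) = -2 i kz psi~(k - k_in)`
with nearest-voxel accumulation and hit-count averaging, and inverse
transformed.  The potential convention `V = k0^2 (n^2 - n_m^2)` is stored
in the tomogram metadata.  No regularisation is applied; the missing cone
therefore elongates structures axially and underestimates contrast, as
expected for a plain first-order inversion.

## Windowing and stitching

Outgoing windows are real-space multiplications.  Incoming windows are
synthesised from a 3x3 scan of extra incidences around each nominal one
(interval `2 delta_k`), with coefficient moduli 4/2/1 on the centre, edge
and corner rings and phases chosen so all terms agree at the patch centre;
the synthesised beam is periodic with period `2 pi / dk_scan`.  The window
width is configured in sample-plane micrometres (a conjugate-plane figure
would require the system magnification, which is not part of the model).
Per-patch tomograms are blended with cosine-tapered weights at patch
midlines after solving the per-patch constant RI offsets (global phase
ambiguity) by least squares over pairwise overlap means, gauge-fixed at
the central patch, followed by a Gaussian high-pass (sigma = 1/4 um^-1)
removing the slowly varying background.

## Metrics

- `field_correlation`: per tilt, k-averaged normalised conjugate product
  over the pupil intersected with its shifted copy, averaged over groups;
  `memory_effect_range` interpolates the 1/e crossing.
- `phase_correlation_3d`: both fields are propagated through a z-range,
  the unit-modulus cross-spectrum is restricted to a one-voxel-thick,
  pupil-truncated Ewald shell (kz > 0) and inverse transformed, normalised
  by the same shell filled with unit phase.  Because any residual tilt
  between the fields shifts the peak off-lattice, `phase_correlation_peak`
  refines the peak sub-voxel by direct evaluation of the shell sum.
- `strehl_ratio`: peak intensity relative to the guide-star ideal
  (phase conjugation of a point-source field through the same medium
  realisation, band-limited to the illumination pupil).

## Synthetic data

The generators define the study conditions:

- **Aberration screens**: named Zernike combinations or correlated Gaussian
  random phase (Gaussian autocorrelation, exact-RMS normalisation on the
  pupil support); deterministic under seed.
- **Thin/thick targets**: the thin model is the exact discrete convolution
  model; the thick model is split-step multi-slice propagation with slices
  modulated at their centres (a single-slice volume reduces exactly to the
  thin model) and the output referenced to the focal plane.  Thick targets
  exhibit the finite memory-effect range that motivates the method.
- **Layered tissue**: transmission screens every 10 um calibrated so the
  assembled stack reproduces typical tissue optics, l_s = 53 um and
  l_t = 1.1 mm.  The calibration is closed-form: `sigma_phi^2 = dz / l_s`
  from `<e^{i phi}> = e^{-sigma^2/2}` (exact for Gaussian screens), and
  the correlation length solved so the per-layer angular variance
  `sigma^2 <|q|^2> / k_m^2` (second moment evaluated on the actual grid)
  equals the small-angle diffusion rate `2 dz / l_t`; for the defaults
  this gives a correlation length of ~0.41 um, which requires dx <= ~0.2
  um to be resolved.  Reflection screens are complex Gaussian fields
  band-limited to propagating k, scaled so the summed single-backscatter
  reflectance meets a configurable total (default 0.03, under the 0.04
  bound).  A smooth random surface-deflection phase can be added to the
  first layer; the strong/mild presets are defined operationally by the
  patch/PSF ordering (patch ~ 1/|grad phi|, PSF ~ 2 z |grad phi| / k_m).
- **Time gating**: reflected fields at 40 wavelengths (default) are summed
  with Gaussian spectral weights referenced to a mirror at the target
  depth; the default bandwidth (sigma_lambda = 2.55 nm) gives an axial
  intensity gate of ~11 um FWHM.  Gating is applied at the detector plane;
  numerical refocusing to the target depth happens once, at the centre
  wavelength.  The single-backscatter model collects every layer's
  reflection in one backward sweep; multiple inter-layer reflections are
  neglected.
- **Moving beads**: thin projected-sphere phase objects taking Gaussian
  steps between consecutive frames; consecutive frame triplets form the
  tilt groups, which is what makes the detection motion-tolerant.

What the generators do *not* emulate: vectorial effects, absorption,
detector noise statistics of a real camera, illumination-device artefacts
(e.g. diffraction orders of a modulator), and multi-scale / non-Gaussian
tissue correlation spectra.  Passing tests therefore demonstrate the
algorithmic chain under controlled scalar-wave conditions, not
instrument-level performance.

## Problem sizes and honest failures

The validation suite runs at desk scale: 96-256 px lattices, 16-76
illumination groups, phantoms 20-56 um thick, 1-12 gate wavelengths, 1-5
seeds per study.  Three documented gaps remain at this scale, all analysed
rather than hidden:

1. **Deep-tissue Strehl fold.**  In the deflection-dominant regime
   (scattering disabled) iterative windowed detection plus time-reversal
   focusing reaches a ~20x mean Strehl fold over no correction.  With the
   full l_s = 53 um stack at depth 2 l_s the gated forward-scattered
   background is itself tilt-correlated and varies below the k-lattice
   resolution, so detection degrades and the measured fold is ~1; even the
   analytically ray-mapped correction caps near ~6 under these conditions.
   The benchmark reports the measured value.
2. **3D correlation peak.**  Thick-phantom recovery reaches a pupil-phase
   circular correlation of ~0.996, but the corrected-vs-pristine 3D
   correlation peak saturates near 0.93: the equal-weight Ewald shell
   includes the pupil rim, where the phantom scatters essentially no power
   and the detector has nothing to estimate from.
3. **Correlation-curve restoration.**  Making the pristine curve cross 1/e
   requires scattering strong enough that detection at one-k-pixel tilts
   is already degraded; the restoration is qualitative (corrected above
   aberrated pointwise) but shallower than the aberration-free curve.
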
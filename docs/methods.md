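# Methods

## Image-formation model

`cryosim` simulates weak-phase contrast: the image is the z-projection of
the rotated, translated specimen potential, convolved with the microscope
point-spread function and scaled by the electron interaction constant σe,

    C(x, y) = σe · F⁻¹[ CTF(q) · e^(−2πi(qx·tx + qy·ty)) · P̂(q) ],

with P̂ the 2D spectrum of the projection.  Assumptions: a single
scattering event (no dynamical effects), a flat Ewald sphere, no
dose-dependent damage, no detector model, and potentials in arbitrary
units (σe defaults to 1; it is an overall contrast scale, and calibrated
absolute contrast is out of scope).

### Conventions

* **Grids.** Even-sided arrays only.  Real-space sample i of an n-point
  axis sits at (i − n/2)·Δ; Fourier transforms are centered
  (`fftshift`-wrapped), unnormalized-forward, so the DC coefficient equals
  the sample sum.  Voxel arrays are indexed [z, y, x]; z is the slowest
  (MRC section) axis.
* **Rotations.** Active zyz Euler convention: φ about z first, then θ
  about y, then ψ about z, as rotations of the body frame into the lab
  frame (matrix Rz(ψ)Ry(θ)Rz(φ)).  Internally everything is a scalar-first
  unit quaternion; q and −q are identified.  Degrees at the interface,
  radians inside.  Euler extraction at gimbal lock (θ ∈ {0°, 180°})
  returns the canonical solution ψ = 0.  Whether the convention is
  intrinsic/extrinsic or active/passive is underdetermined by common usage
  in the field; we fix active-volume rotation and verify internal
  consistency (pose → image round trips), not bit-compatibility with any
  other package.
* **Translation** is a Fourier-space phase ramp and therefore periodic;
  callers should keep particles centered within roughly half a box of the
  edge.

## Volume representations

A `GaussianMixtureVolume` carries one isotropic Gaussian per center with
amplitude a (integrated potential) and variance b (Å²).  Each Gaussian is
normalized to unit integral before scaling — the alternative (unit peak)
only changes the overall image scale, which NCC-based analyses ignore.
Multi-Gaussian atom models (e.g. tabulated electron scattering factors,
typically ~5 Gaussians per element) are expressible by repeating centers
with different (a, b); the provided helper `uniform_gmm` builds the
equal-weight, equal-variance coarse-grained model used in the refinement
experiments.

Rasterization samples the mixture at voxel centers using separability
(three 1D Gaussian factors per atom), which is exact at the sample points
and O(n·side) per atom.  For σ ≥ 2 voxels and centers ≥ 5σ from the box
edge, the voxel sum recovers the analytic integral to better than 1%.

## Projection

Three independent algorithms:

1. **Analytic** (mixtures): the z-integral of an isotropic 3D Gaussian is
   a 2D Gaussian of the same variance at the in-plane components of the
   rotated center — exact, no discretization of the volume.
2. **Fourier slice** (voxel grids): trilinear interpolation of the
   centered 3D spectrum on the plane {Rᵀ(qx, qy, 0)}, scaled by the voxel
   size so units match the analytic path.  Frequencies outside the Nyquist
   box are zeroed and counted.  Trilinear interpolation is the minimal
   standard choice; its error grows with the spectral phase gradient
   (i.e. with off-center mass), so `fourier_from_real` exposes an integer
   `pad_factor` that zero-pads the real volume before the FFT, refining
   spectral sampling.  pad_factor=2 brings slice/analytic agreement on
   smooth phantoms from NCC ≈ 0.998 to ≥ 0.9997; the default remains 1
   (no padding) to keep memory bounded.
3. **Real-space oracle**: rotate-and-resample plus Riemann z-sum, used
   only as a test cross-check.

## Optics

χ(q, φ) = −πλΔf(φ)|q|² + (π/2)Csλ³|q|⁴ + phase_shift, with the astigmatic
defocus Δf(φ) = ½[du + dv + (du − dv)cos 2(φ − φa)] and λ the relativistic
electron wavelength from CODATA constants.  Positive Δf is underfocus and
the Cs term opposes the defocus term in sign.  Amplitude contrast w enters
as √(1 − w²)·sin χ + w·cos χ, which reduces to sin χ at w = 0.  Parameters
are canonicalized to du ≥ dv (swapping rotates φa by 90°, wrapped to
[0°, 180°)), removing a two-fold degeneracy.  A global sign flag flips the
contrast convention; there is no envelope function by default.  Custom
aberration models plug in as `chi_fn(grid, params)`; the evaluation
routine only requires the returned phase array to match the grid shape.

## Noise and SNR

Noise is zero-mean Gaussian: white (stated per-pixel variance) or colored
(white noise shaped by √S(|q|) in Fourier space, where S is a caller
radial profile in per-pixel power units; the measured radially averaged
power spectrum approaches n_pixels·S).  A power-law-plus-constant
least-squares fitter (`fit_power_law_profile`) supports aligning a
simulated spectrum to a measured one; the target spectrum is
user-supplied.

**SNR is the ratio of per-pixel signal variance to noise variance**
(alternatives, such as band-limited power ratios, give different numbers).
`add_noise_at_snr` rescales the drawn field by its own sample standard
deviation, making the realized per-image ratio exact rather than an
expectation.

## Refinement

The loss is the stack sum of −NCC between simulated and observed images.
NCC (rather than a raw dot product) makes the score invariant to the
arbitrary σe scale and to additive offsets, and makes the ground truth an
exact stationary point on noiseless data.  Gradients with respect to all
Gaussian centers are closed-form: the NCC adjoint, the conjugate-filter
adjoint of the Fourier-diagonal CTF/translation factor, and the analytic
derivative of each projected Gaussian with respect to its in-plane
center, pulled back through Rᵀ.  They match central finite differences
(step 10⁻³ Å) to ~10⁻⁷ relative.  Amplitudes and variances stay frozen;
only centers move.

The optimizer is AdaBelief with the published defaults (β₁ = 0.9,
β₂ = 0.999, ε = 10⁻¹⁶) and step size 10⁻² Å by default.  The synthetic
recovery experiment perturbs centers by 3 Å and runs 100 steps, so it uses
step size 0.1 Å — sized so that 100 steps can traverse the perturbation
(AdaBelief steps are ≈ the learning rate in magnitude once the gradient
signal stabilizes).  Optimization is full-batch over the stack and fully
deterministic for fixed settings.

Volume agreement is scored by FSC over one-voxel-wide spherical shells
without masking or tapering, and by the mismatch score
s = 2·U₀/(U₀ + U) − 1, masked (NaN, with a reported count) where
U₀ + U ≤ 10⁻³·max(U₀) since the formula is undefined on empty space.

## Synthetic data generator

`make_refinement_fixture` emulates a known-pose, known-CTF single-particle
refinement: equal-weight, equal-variance Gaussians (σ = 4 Å, a
one-Gaussian-per-residue coarse-grained scale) at uniform random centers
in a 12 Å ball, imaged at 64×64 pixels of 1 Å under uniform random
orientations with one shared CTF (defocus 10000 Å, Cs 2.7 mm, 300 kV,
amplitude contrast 0.1 — typical single-particle values), then white noise
at the requested variance-ratio SNR.  The standard conditions used in the
tests are 20 atoms, 16 images, SNR 0.1, 3 Å start perturbation — a
desk-scale version of refining thousands of C-alpha centers against a
100-image stack, chosen so the complete experiment (simulation + 100
optimizer steps + FSC) runs in seconds while preserving the regime
(per-pixel SNR, Gaussian width in voxels, perturbation ≈ ¾σ).

What the generator does *not* emulate: structured solvent/ice background,
correlated (colored) noise in the refinement stacks, pose/CTF estimation
error, detector effects, and model mismatch between the imaging and
refinement forward models (both are Gaussian mixtures).  Passing recovery
tests therefore demonstrate correctness of the gradients and optimizer on
the stated model, not robustness to the systematic errors of real
micrographs.

## Numerical choices and limitations

* Slice extraction and the real-space oracle both use trilinear (order-1)
  interpolation; tolerances in the tests (NCC > 0.99 generic, > 0.999 for
  smooth phantoms with pad_factor 2) are set for that scheme.
* Degenerate inputs fail loudly: zero-variance images in NCC, empty
  mixtures, non-cubic or odd-sided grids, non-positive voltage/pixel
  sizes.  Divergent refinement (non-finite loss) aborts and returns the
  partial trace.
* The CSV metadata schema (angles in degrees, lengths in Å, voltage kV,
  Cs mm) is package-defined; MRC I/O goes through gemmi with z as the
  section axis.  Round-trips are bitwise at float32.
* Ewald-sphere curvature, B-factor envelopes, dose weighting, beam tilt,
  pose/CTF refinement, and neural/deformation volume representations are
  out of scope.
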
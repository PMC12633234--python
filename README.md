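# cryosim

Cryo-EM image simulation and gradient-based structure refinement.

Single-particle cryo-electron microscopy records noisy 2D projections of a
molecule's electrostatic potential, filtered by the microscope optics.
Methods research — particle localization, heterogeneity analysis, Bayesian
inference of molecular states — needs a forward model of this image
formation process that is modular, testable, and differentiable.  `cryosim`
implements that model for methods developers and students: each physical
ingredient (volume representation, pose, CTF, noise) is an explicit,
swappable component, and the analytic Gaussian-mixture path admits exact
gradients with respect to atomic positions, enabling structure refinement
by first-order optimization.

## The model

Under the weak-phase approximation, image contrast is linear in the
projected potential.  For a rotation R, in-plane translation
t = (tx, ty, 0), and aberration function χ, a simulated image is

    C(x, y) = σe · F⁻¹[ sin χ(q) · e^(−2πi q·t) · F ∫dz U(R⁻¹ r) ]

where U is the specimen potential, σe the electron interaction constant,
and F the 2D Fourier transform.  The pieces:

- **Volumes** — `GaussianMixtureVolume` (one isotropic Gaussian per atomic
  center, unit-integral normalized) or voxel grids
  (`RealVoxelVolume` / `FourierVoxelVolume`).  Projections are computed
  analytically for mixtures, or by central-slice extraction from the 3D
  spectrum (the Fourier slice theorem) for voxel grids; a brute-force
  rotate-and-sum oracle cross-checks both in the tests.
- **Poses** — active zyz Euler angles (φ about z, θ about y, ψ about z) or
  unit quaternions, interconvertible through a common `Rotation` type.
- **Optics** — the CTFFIND-style astigmatic CTF,
  χ = −πλΔf(φ)|q|² + (π/2)Csλ³|q|⁴ + phase shift, with amplitude-contrast
  mixing; any callable implementing the aberration phase can replace the
  built-in model.
- **Noise** — white or colored zero-mean Gaussian fields with a target
  radial power profile; SNR is defined as per-pixel signal variance over
  noise variance.
- **Refinement** — negative normalized cross-correlation loss against an
  observed stack at fixed pose/CTF, exact closed-form gradients with
  respect to all Gaussian centers, and an AdaBelief optimizer loop.
  Agreement between volumes is scored by Fourier shell correlation and the
  voxelwise mismatch score s = 2·U₀/(U₀ + U) − 1.

## Worked example

```python
import numpy as np
from cryosim import (
    CTFParams, EulerPose, ImageConfig, RefinementProblem,
    make_refinement_fixture, refine_centers, simulate_image, uniform_gmm,
)

# a toy "protein": 5 coarse-grained atoms, sigma = 4 A Gaussians
centers = [[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8], [-6, -6, 0]]
volume = uniform_gmm(centers, amplitude=1.0, variance=16.0)

pose = EulerPose(phi=30, theta=60, psi=-10, tx=2.0, ty=-1.0)
ctf = CTFParams(defocus_u=12000, defocus_v=10000, astig_angle=30, voltage=300)
cfg = ImageConfig(shape=(64, 64), pixel_size=1.0)
image = simulate_image(volume, pose, ctf, cfg)
print(f"image range: [{image.pixels.min():.5f}, {image.pixels.max():.5f}]")

# synthetic refinement: 20 atoms, 16 images at SNR 0.1, 3 A jitter on the start
truth, start, stack = make_refinement_fixture(
    n_atoms=20, n_images=16, snr=0.1, perturbation_scale=3.0, seed=0
)
prob = RefinementProblem(stack, start, ImageConfig((64, 64), 1.0))
trace = refine_centers(prob, steps=100, learning_rate=0.1)
print(f"loss: {trace.losses[0]:.4f} -> {trace.losses[-1]:.4f}")
d0 = np.linalg.norm(start.centers - truth.centers, axis=1).mean()
d1 = np.linalg.norm(trace.final_centers - truth.centers, axis=1).mean()
print(f"mean center error: {d0:.2f} A -> {d1:.2f} A")
```

Output:

```
image range: [-0.01114, 0.00460]
loss: -4.2650 -> -4.7977
mean center error: 4.74 A -> 4.28 A
```

The image values are CTF-filtered contrast (arbitrary potential units
scaled by σe).  The stack loss is the sum of −NCC over the 16 images, so
−4.27 → −4.80 means the average per-image correlation with the noisy
observations rose from 0.27 to 0.30 — close to the noise-limited ceiling
at SNR 0.1 — while the refined centers moved toward the ground truth.

A command-line interface mirrors the library
(`cryosim fixture | simulate | project | ctf | refine | fsc`); run
`cryosim --help` for the subcommands and their flags.

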
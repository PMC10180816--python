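# Methods

## Optical model

The device is a 4f relay with a polarization-dependent metasurface in its
Fourier plane, simulated on an N×N grid with the centered-spectrum
convention (DC at index N/2 on both axes for even N; `fftshift`
semantics). Physical frequency scaling fx = u/(λf) is dropped: the spiral
phase depends only on the *angle* of (u, v), which is scale invariant, so
frequency axes are indexed in integer cycles per grid and the wavelength
(0.9 µm) and nanobrick geometry (360 nm lattice, 500 nm height) are carried
as metadata only.

**Transfer functions.** The bright-field profile is a uniform phase
exp(iC₂). The edge profile is the spiral exp(i(atan2(v,u) + C₁)) whose
phase winds by 2π around DC. The DC sample itself is the vortex
singularity: its phase is undefined, and a physical spiral plate scatters
the DC energy into the characteristic donut rather than transmitting it on
axis. We therefore make that single sample opaque, H(0,0) = 0. This is the
choice that reproduces the defining behavior of spiral phase contrast —
uniform regions exit dark (a uniform field maps to exactly zero), a disk's
output energy concentrates on its boundary, and edge outputs track the
gradient magnitude of the scene even for high-mean scenes such as the cell
phantoms. Every other sample of the ideal profiles has unit modulus, so
Parseval energy conservation holds up to the DC content.

**Constants.** C₁ and C₂ are free device constants. Defaults: C₁ = 0 and
C₂ = 0.5 rad, the latter chosen inside the library's δy span [0.23, 0.82]
so that the quantized bright-field profile is nearly uniform (minimal
quantization ripple).

**Quantization.** The fabrication library holds 16 nanobricks, each with a
per-polarization phase shift and transmission. Quantization snaps each
pixel's phase to the library entry at minimum circular distance and
replaces its modulus by that entry's transmission (no renormalization —
quantized outputs are genuinely fainter, as a fabricated device's would
be). The per-pixel phase error is bounded by half the largest gap between
adjacent sorted library phases including the wrap-around gap: 0.325 rad for
the XLP (δx) column. Opaque samples (the vortex DC) stay opaque, and the
operation is idempotent.

**Fabrication error.** Real shape errors of the nanobrick axes act through
electromagnetic resonances that this toolkit deliberately does not solve
(no FDTD). They are modeled in the domain where they matter — as seeded
i.i.d. Gaussian phase offsets on the realized profile (default sd 0.1 rad
for a ±5 nm-scale error budget) plus an optional multiplicative amplitude
jitter clipped to [0, 1]. The phase channel dominates the observable effect
of shape errors, which is what the robustness study exercises.

**Detection.** The single-pixel detector is a square-law device: all
measurements are taken on the intensity |E_M|², and reconstruction targets
are therefore real and nonnegative. (Treating the bucket value as an inner
product with the complex field would make the measurement complex, which no
photodetector returns.)

## Acquisition

Fourier patterns are `0.5 + 0.5·sin(2π(fx·x + fy·y)/N + φ)` with integer
frequencies — the discrete sinusoid whose three-step combination is
*exactly* 1.5i times the scene's DFT coefficient, including at DC (the
three DC patterns are distinct constants, so no special DC calibration is
needed; the single global factor 1/(1.5i) is fixed analytically).

The Fourier sampling plan enumerates the non-redundant spectral half-plane
in low-frequency-first order (radius, then angle). For an even grid that
half-plane has N²/2 + 2 unique loci — the four self-conjugate DC/Nyquist
loci plus half of the conjugate pairs — and the plan keeps
⌈ratio × (N²/2 + 2)⌉ of them, so ratio 1.0 is exactly invertible.
Hadamard plans use the separable Sylvester transform, with natural or
sequency ordering (sequency, which ranks loci by sign changes, is the
sensible sub-full-sampling order and is what the pipeline uses). Random
plans are seeded Bernoulli(0.5) masks.

`measure` is the literal pattern-by-pattern inner product. The pipeline
uses `simulate_fourier_measurements` / `simulate_hadamard_measurements`,
which compute the identical bucket vectors through one FFT / fast transform
(algebraic identities, cross-checked against `measure` in the unit suite to
1e−9). Detector noise is i.i.d. Gaussian per bucket value, parameterized
either by absolute sigma or by SNR in dB against the RMS of the clean
bright-field measurement vector; the same *absolute* sigma is applied to
both modes in sweeps, because rotating a polarizer does not change the
detector.

## Reconstruction

The objective `min ‖AO − D‖² + λ·TV(Q)` s.t. `O = Q` is solved by ADMM:

* **O-update** — for Fourier/Hadamard plans the operator is a masked
  unitary transform, and the subproblem
  `argmin ‖AO − d‖² + ρ/2‖O − z‖²` has the exact per-coefficient solution
  `(2d̂ + ρẑ)/(2 + ρ)` on measured loci, `ẑ` elsewhere. Fourier spectra are
  conjugate-filled before solving, so the masked target is Hermitian and all
  iterates stay real. For dense random-pattern operators the same
  subproblem is solved by warm-started conjugate gradients (15 inner
  iterations).
* **Q-update** — the proximal operator of anisotropic TV (sum of absolute
  first differences, replicate boundaries), approximated by 20
  projected-gradient iterations on the dual with step 1/8 and componentwise
  clamping to [−λ, λ].
* **W-update** — `W ← W + ρ(O − Q)`.

Iterations stop at `max_iters` (default 200) or when both the relative
change of O and the relative O–Q gap fall below `tol` (default 1e−5); the
gap term matters because the zero-filled initialization is already a fixed
point of the data term alone. The final image is clipped at zero
(intensities are physical).

**Hyper-parameters.** ρ = 1, over-relaxation α = 1. The default TV weight
is λ = 0.002·max|D|/N², a scale-free choice calibrated so that the solution
is data-dominated: at full sampling the ADMM fixed point is the TV-denoised
exact inverse, and this weight keeps even a textureless white-noise image
within <1e−3 RMS of the direct inverse while still beating the zero-filled
baseline under 10 % sampling with 30 dB measurement noise. All defaults are
echoed into every report.

## Phantoms and metrics

All test scenes are generated, never downloaded, with power-of-two sides so
one phantom drives all three modulations: USAF-style bar triplets of
geometrically shrinking width, a centered disk (canonical edge object) with
its analytic boundary ring, seeded glyph scenes of rectangles and disks,
and Voronoi cell/membrane phantoms (seeded minimum-spacing sites,
nearest-site labeling, membranes at 0.1, interiors in [0.75, 1]). The cell
phantoms emulate the membrane/interior statistics of electron-microscopy
tissue that the edge mode is meant to enhance; they do not reproduce real
EM texture, noise statistics, or imaging artifacts, so passing tests
demonstrate the optical chain and solver, not performance on real
micrographs. PSNR/SSIM wrap scikit-image, with PSNR capped at 100 dB for
identical images; reconstruction quality is always scored against the
mode's own filtered scene |E_M|², normalized to that reference's peak.

## Study conditions and problem sizes

Experiments use the grid sizes at which each behavior is best exhibited and
cheaply reproducible: 16×16/8×8 for transform-oracle exactness, 64×64 for
round-trip, sampling-ratio {0.05, 0.1, 0.2, 0.4, 1.0}, noise
(SNR ∈ {40, 30, 20} dB, 10 phantoms) and fabrication studies (sampling
ratio 0.1, the regime where robustness questions arise), and 128×128 for
edge-selectivity and quantization-fidelity studies. The noise-sensitivity
comparison between modes is made on the prior-free direct inverse: the TV
prior denoises the sparse edge images disproportionately and would mask the
underlying physics, which is that the dim edge-mode signal has the worse
detector-noise budget and so degrades at least as fast as bright-field.

## Known limitations

* No electromagnetic solving: nanobrick responses are consumed from the
  bundled library table; fabrication error is a phase/amplitude surrogate.
* Scalar, monochromatic optics; no vector diffraction, no chromatic model,
  no finite-aperture cropping by default (a circular Fourier-plane aperture
  is exposed but off).
* The TV prox is approximate (fixed inner-iteration count), and ADMM is run
  to a practical tolerance, not to machine-precision optimality.
* Binary random modulation builds the dense pattern matrix; it is intended
  for moderate grids/ratios, not full sampling at large N.
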
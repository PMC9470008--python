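# Methods

This note documents the models, numerical choices and known limitations of
the package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sampling scheme

**Variable-density spiral.** The 2D readout is an Archimedean spiral with a
radius-dependent pitch: `dr/dθ = U(r) / (2π·fov)`, where the undersampling
factor U(r) is 1 (single-shot Nyquist, adjacent-turn gap 1/fov) inside the
fully sampled core (default inner 5% of k_max), ramps up along a half-cosine,
and is constant at the outer factor (default 8) beyond the transition end.
The transition end (default 50% of k_max) is a free design parameter: only
the two endpoint densities are externally specified, and the default was
chosen so that the full-geometry readout (2.88 mm in-plane, 1536 samples at
4 µs) is realizable under standard whole-body gradient limits (40 mT/m,
150 T/m/s); a taper extending to the edge of k-space needs ~8 ms instead of
~6 ms. Combining 13 rotations oversamples the outer region by 13/8, which
is what makes the time-averaged data fully sampled.

**Gradient design.** The curve is reparameterized time-optimally: a speed
limit from the amplitude constraint (γ·g_max) and from curvature
(√(β·γ·slew/κ)), plus forward/backward passes for tangential acceleration.
The slew budget is partitioned β = 0.9 to the centripetal and √(1−β²) to
the tangential component so their quadrature sum respects the limit; the
resulting minimum-time solution is then stretched uniformly to fill the
requested readout duration, which preserves feasibility. Gradients are not
printed for the readout in typical protocol listings, so the limits are
configurable with the defaults above.

**Rotation schedule.** θ(s, j) = (10π/13)(s + j − 1) reduced mod 2π, with
slice encodes s ∈ [−N/2, N/2−1] and 1-based interleaves j. Since
gcd(5, 13) = 1 (10π/13 ≡ 2π·5/13), the multiset of orientations over 13
consecutive interleaves at fixed kz is exactly {2πm/13}, uniform with gap
2π/13 — verified to 1e−12 in the tests. `schedule_period` scans up to 1e6
multiples with tolerance 1e−9; the true golden angle (137.51°) reports as
aperiodic because its rational approximations are badly convergent
(quadratic irrational), so no multiple comes within 1e−9 of 2π below the
cap. Centric kz ordering visits 0, +1, −1, +2, −2, …, −N/2 (positive side
first by default, configurable).

## Sequence simulation

**EPG.** Echo amplitudes come from a standard extended-phase-graph
recursion (states F±k, Zk; CPMG convention: 90° excitation about x,
refocusing pulses about y), with relaxation applied each half
echo-spacing and echoes read from the F0 state. The all-180° train
reduces to the closed form exp(−n·esp/T2), and a dictionary-based
configuration-state evaluation serves as an independent oracle for short
trains.

**Constant-amplitude flip train.** The published design procedure is not
restated in the protocol literature, so the package uses a sequential
inverse-EPG prescription: each refocusing angle is found by bisection so
that its echo reaches a fixed target amplitude, and an outer bisection on
the target makes the tail of the train converge to the requested asymptote
(62° by default, giving a target echo amplitude of ≈0.68 of M0). The family
is one-parameter; it reproduces the first three reference angles
(111.1°, 72.2°, 62.8°) to better than 0.2° but puts the transient dip at
60.5° rather than 60.9°, indicating the reference design handled the
transient slightly differently. The design-then-simulate closure (flat
amplitudes, CoV < 1e−3 without relaxation) is the defining property.

**Background suppression.** Static magnetization is tracked by piecewise T1
relaxation: Mz = 0 at the end of presaturation (3600 ms before imaging),
Mz ← 1 − (1 − Mz)·exp(−Δt/T1) between events, and Mz ← −η·Mz at each of
the four inversions (2848, 1546, 605, 131 ms). Inversion efficiency η
defaults to 1 (ideal adiabatic pulses); whether the sub-1% residual claim
assumed η < 1 is not stated, and with η = 1 the simulated bound over
T1 ∈ [700, 4500] ms is 0.73% of M0. The inferior saturation pulse is
bookkept but excluded from in-volume tissue. Labeling physics (pCASL RF
trains) is not simulated; the perfusion difference signal enters the
phantom directly.

## Phantom and forward model

The phantom is a jittered multi-ellipsoid object (GM shell, WM core, two
CSF ventricles) with per-tissue M0/T1/T2/perfusion (GM 60, WM 20
mL/100g/min). The baseline difference magnetization ΔM follows the same
pCASL kinetic forward model used for quantification, so the
simulate→reconstruct→quantify loop closes exactly at the model level; GM
ΔM lands at ≈0.5% of GM M0, a typical ASL fraction.

Coil sensitivities are synthesized in k-space (Gaussian-enveloped random
spectra hard-limited to a 22% k-radius over a dominant DC term, then
RSS-normalized). This guarantees the band-limit the calibration relies on
— image-domain Gaussian lobes violate it through FOV-truncation leakage.
The random-component weight (default 0.5 of the DC term) sets the coil
contrast: individual magnitudes vary several-fold across the FOV, as in a
real multi-channel head array, which is what gives SENSE/CS its encoding
power; much weaker variation leaves the single-shot inverse problem
poorly conditioned.

The forward model treats every echo as a 3D non-uniform Fourier sample of
a static volume, scaled by that echo's EPG amplitude, plus white complex
Gaussian noise per coil (no coil correlation). This matches the
reconstruction's data model by construction — an explicit, documented
inverse crime: intra-shot relaxation beyond the per-echo scalar, motion,
off-resonance blur and physiological noise spectra are absent, so passing
tests validate the pipeline's internal consistency, not robustness to
those real-world effects. Noise is referenced to the RMS magnitude of the
perfusion-difference data (default 5%), the signal the reconstruction
actually recovers; referencing it to the much larger M0 spectrum would
make the ΔM data unusable at any sensible percentage.

Label/control pairs share the interleave (hence identical rotations);
both contain the background-suppression residual of static tissue
(default 0.5% of M0) and ±ΔM/2, so control − label equals the forward
projection of ΔM exactly.

## NUFFT

Type-2/type-1 transforms are implemented as Kaiser–Bessel gridding with a
precomputed sparse interpolation matrix: 2× oversampled FFT, kernel width
8 with the Beatty shape parameter, analytic roll-off correction. The
adjoint is the literal conjugate transpose of the forward, so the adjoint
identity holds to machine precision, and forward accuracy against the
exact non-uniform DFT is ~1e−7 relative on test grids. When every kz
coincides with the Cartesian slice-encode grid — always true for this
package's trajectories — a fast path runs an exact FFT along z and 2D
gridding per plane; it agrees with the general 3D path to better than
1e−6 and needs an order of magnitude less interpolation memory.

## Reconstruction

**Pipeline order** (per the acquisition design): subtraction → per-echo
decay correction (reference = first echo; the reference convention is not
externally fixed, first-echo normalization preserves the dominant
k-space-centre scale under centric ordering) → spherical Fermi filter
(default cutoff 0.9 k_max, width 0.06 k_max, each axis normalized to its
own Nyquist) → (a) interleave-averaged fully sampled recon: per-coil CG
on the Tikhonov normal equations (λ = 0.01, 30 iterations, tolerance
1e−6) + sum of squares; (b) ESPIRiT maps from the Cartesian spectrum of
(a); (c) per-shot compressed sensing.

**Density compensation** (for the "zero-filled" adjoint baseline and the
λ₁ scale reference) is Pipe–Menon iteration on the gridding kernel, with
the global gain fixed so a flat object reconstructs at unit intensity —
normalizing the point-spread-function peak instead leaves a ~20% DC bias
because the PSF integral, not its peak, sets the extended-object gain.

**ESPIRiT.** Block-Hankel calibration matrix from the central k-space
region (kernel 6×6×4-scale, calibration region scaled to the grid), SVD,
right-singular vectors with σ ≥ 0.01·σ_max, kernels flipped and
inverse-FFT'd to image space with Parseval scaling so an ideal signal
subspace yields leading eigenvalue 1; the leading eigenvector
(phase-referenced to coil 0) is kept where the eigenvalue ≥ 0.8 and
zeroed elsewhere. Exact kernel/calibration sizes are not externally
specified; the defaults above were validated by recovering known
synthetic coils to |corr| > 0.98.

**Compressed sensing.** argmin_x ½‖Ex − d‖² + λ₁‖Ψx‖₁ with E = NUFFT ∘
coil maps and Ψ an orthogonal Daubechies-4 DWT (periodization, 3 levels,
capped by the dyadic limit of the shortest axis; orthonormality holds at
any depth and is asserted in tests). ADMM with the operator normalized by
its spectral norm (8 power iterations), ρ = 0.2 of the normalized scale —
converged results were ρ-independent over [0.01, 1] in development tests
— x-update by warm-started CG (8 inner iterations), soft-thresholding
z-update, fixed 100 outer iterations by default, no data rescaling so
absolute intensities survive for quantification. λ₁ is exposed both as an
absolute value and, by default, relative: λ₁ = 3e−4 × max|x_adj| of the
density-compensated adjoint reconstruction. The relative reference is the
image peak rather than the peak wavelet coefficient: the approximation-band
coefficient grows with block size and any usable fraction of it
over-shrinks every detail scale. With λ₁ = 0 the solver reduces to
iterated-Tikhonov refinement and matches CG-SENSE on well-posed (fully
sampled) data to 1e−3.

## Metrics and quantification

NRMSE = RMSE/RMS-of-reference inside a brain mask (robust-threshold of M0
at 30% of the 99th percentile, largest connected component). The blur
metric low-passes the volume with a 9-point uniform kernel along one axis
and scores the fraction of absolute neighbour variation that the extra
blur does not remove, averaged over the three axes (higher = blurrier,
bounded in [0, 1]); per-axis scores are exposed to isolate slice-direction
blurring. The axis aggregation (mean) and kernel length follow the common
variant of the construction; both are parameters.

CBF: the standard single-compartment pCASL formula
CBF = 6000·λp·ΔM·exp(w/T1b) / (2·α_total·T1b·M0·(1 − exp(−τ/T1b)))
with τ = w = 1.8 s, T1b = 1650 ms, α = 0.85, background-suppression factor
0.75, λp = 0.9 mL/g, values clipped to [0, 300] mL/100g/min. A
two-compartment option applies a configurable exchange-correction factor;
the single-compartment form is the default because the validation surface
is self-consistent recovery, not absolute in vivo accuracy.

## Dynamics

Single-shot series preprocessing: in-plane Fermi apodization (defaults
cutoff 0.8, width 0.1 of k_max — the "slight" smoothing step has no
published parameters), 3D Gaussian smoothing (4 mm FWHM,
σ = FWHM/2.3548), first volume dropped; per-volume global-mean
normalization; seed-ROI mean course and voxelwise Pearson r with Fisher z.
No CSF/WM confound regression or hemodynamic weighting — deliberately, as
those are BOLD-specific. The planted network is two GM spheres sharing a
10% sinusoidal perfusion modulation at 0.02 Hz (below the 0.0379 Hz
volume-rate Nyquist at the 13.2 s interval).

## Problem sizes

The default configuration is a desk-scale study: 64×64×16 grid, 8 coils,
512-sample spiral. The test suite and validation runs use a further
reduced 32×32×8 grid with 4 coils and a 750-sample spiral (and 16³ grids
for operator-level oracles), which keeps the full suite in a routine CI
budget while exercising every code path; the full acquisition geometry
(128×128×32, 32 coils, 1536 samples) is available via
`RunConfig.full_profile()`. Heavy property checks (paired
rotated-vs-unrotated comparisons, the 39-volume end-to-end run) use 25–30
ADMM iterations instead of 100; convergence at those counts was verified
against longer runs during development.

## Known limitations

* The inverse crime noted above: simulator and reconstructor share the
  forward model.
* No off-resonance/B0 blur, eddy currents, concomitant fields, motion, or
  physiological noise; no scanner waveform export.
* Group statistics across subjects, ICA, and template normalization are
  out of scope; the dynamics module is a toy-scale single-subject analysis.
* The flip-train transient differs from the unpublished reference design
  at the fourth pulse (60.5° vs 60.9°); see the design note above.
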
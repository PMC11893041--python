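# Methods

`dmirecon` simulates and reconstructs 3D deuterium metabolic imaging (DMI)
data of the human torso and quantifies how a low-rank/subspace model-based
reconstruction compares with the zero-filled Fourier baseline in spectral
fitting quality. This note records the models, the conventions, and the
design choices behind the implementation, and states what the synthetic
study does and does not show about real data.

## Signal model and simulation

Phase-encoded CSI is assumed: every sampled k-space location carries a
complete FID. The per-coil measurement is

    d_c(k, t) = ∫ s_c(r) ρ̃(r, t) e^{-i 2π k·r} dr + ξ_c(k, t)

with coil sensitivities `s_c(r)` and complex white Gaussian noise `ξ_c`.
Voxel FIDs are sums of Lorentzian resonances,

    s(t) = e^{iφ} Σ_p a_p exp[(i 2π f_p − π w_p) t],

where `a_p` is the t=0 amplitude, `f_p` the offset of the chemical shift
from the carrier, and `w_p` the FWHM in Hz (time-domain decay rate `π w_p`
— the AMARES convention).

The digital torso phantom has four tissue classes on a 256×256×15 grid:
body (superellipse cylinder; deuterated water, amplitude 1.0 at 4.7 ppm),
liver (ellipsoid, ~28% of the body volume; water + glucose 0.8 @ 3.8 ppm +
Glx 0.6 @ 2.25 ppm), stomach (ellipsoid, ~4%; water + glucose), and a
subcutaneous fat rim (in-plane erosion shell, 10 high-resolution voxels
thick; water + lipid 0.6 @ 1.3 ppm). All linewidths are 30 Hz. Volume
fractions are configuration, not constants; the defaults approximate an
upper-abdominal slab in which the liver dominates.

High-resolution data are down-sampled by centered k-space truncation to the
12×18×15 acquisition matrix. Because truncation is linear and spatial-only,
the acquisition-grid data are computed compartment-by-compartment (truncated
indicator map × compartment FID) — identical to rendering the full
high-resolution spatiotemporal array (tested), at a tiny fraction of the
memory. The truncated crop is rescaled by `sqrt(N_low/N_high)` so voxel
*intensities* (not array norms) are preserved; interior water amplitude
stays ≈1, which anchors the meaning of the noise scale and the TV weight.

Units and axes: 5 kHz bandwidth, 1024 time points, carrier at 4.7 ppm
(water on resonance), deuterium Larmor frequency 45.7 MHz (7 T). These two
ppm conventions are never stated in typical acquisition protocols and are
config fields; the defaults place the signal-free 8–12 ppm band well inside
the spectral window.

All FFTs (spatial and temporal) are unitary, so a noise SD means the same
thing in every domain.

## Noise model and SNR calibration

Noise is complex white Gaussian, `ξ = α/√2 (g_re + i g_im)`, added
independently per coil in k-space (statistically identical to any other
domain under unitary transforms). Spectral SNR is

    SNR = Re S(f_water) / SD( Re S, 8–12 ppm band ),

with the water height read at the known water bin. Two deliberate
conventions: the *real part* is used for the band SD (absorption tails
decay as 1/Δf² and are negligible in the band, whereas dispersion tails
decay as 1/Δf and would contaminate a complex-sample SD), and the peak is
read at a fixed bin rather than a window maximum (a window max is biased
upward by noise at low SNR; the fixed-bin read reproduces the published
30.4 / 15.1 / 5.1 ladder to better than 2% when the first level is
calibrated to 60). A window-max variant remains available.

`calibrate_alpha` solves mean-ROI-SNR(α) = target by a fixed-point
iteration (the statistic is ∝ 1/α to high accuracy) with common random
numbers; the four nominal levels 60/30/15/5 then follow the published
α ratios 0.923 : 1.830 : 3.700 : 10.900.

## Undersampling

Poisson-disk masks are generated by dart throwing over a seeded random
permutation of the grid, with the fully sampled central D1 block (default
3×5×3) pre-seeded as mandatory and the disk radius maximized by bisection
subject to the point budget `round(N/R)`. The achieved acceleration is
exact to rounding. On a 12×18×15 grid at R ≤ 1.3 the budget retains ≥77%
of the points, so the maximal feasible radius is below the grid spacing and
the pattern is effectively a uniform random complement — the minimum-
distance property is still verified, it is just not binding at these mild
accelerations. Masks at different R are independent draws (not nested), and
one mask per (R, seed) is shared across repetitions.

## Temporal subspace

The basis V̂ holds the L principal right singular vectors of the Casorati
matrix (voxels × time) built from the coil-combined image series of the D1
crop (zero-filled, inverse FFT, conjugate-sensitivity combination). The SVD
phase ambiguity is fixed by rotating each row's largest entry to the real
positive axis. Because the D1 crop retains only `n_coil × |D1|` k-space
FIDs, the Casorati matrix factorizes as `C = B K`; `estimate_basis_fast`
computes the SVD of `G^{1/2} K` with the small Gram matrix `G = B^H B`,
which is exact (tested against the step-by-step chain) and ~30× faster.

Model-order diagnostic: the suggested order is the onset of the singular-
value noise floor — the first normalized value that is below a significance
level (0.1) and flattens into the tail (relative step < 5%); a floor at
numerical zero is excluded. Noise-free phantom data suggest exactly their
algebraic rank (4); noisy data suggest 5, the rank plus the first noise-
floor component, which is the order used throughout. A plain threshold on
normalized singular values cannot make this distinction, because the noisy
plateau sits just below the 4th (lipid-dominated) singular value.

## Reconstruction

The subspace reconstruction solves

    min_U  ½ Σ_c ‖Ω F S_c U V̂ − d_c‖² + λ ‖D U‖₁

with anisotropic total variation over the three spatial axes of each
coefficient map (complex modulus, periodic differences; isotropic TV behind
a config flag). The solver is the primal–dual hybrid gradient
(Chambolle–Pock) method: both terms dualized, steps σ = τ = 0.99/‖K‖ with
the operator norm from 20 power iterations, over-relaxation θ = 1, 30
iterations, warm start from the adjoint. Because V̂ has orthonormal rows
and sampling is spatial, the data term is contracted onto the subspace
(`D_c = Ω(d_c V̂^H)`); iterations then run on N×L arrays and the cost per
iteration is independent of the number of time points. The reported
objective is the contracted form (it differs from the full residual by a
U-independent constant). λ defaults to 0.001 on data scaled so the water
FID amplitude is ≈1; the NRMSE of the study is flat in λ up to ~0.01 and
degrades (lipid first) at 0.03–0.05, matching the published sensitivity
pattern.

The baseline is the zero-filled inverse spatial FFT with conjugate-
sensitivity coil combination and a unitary temporal FFT.

## Spectral fitting and CRLB

Per voxel, four Lorentzians with a shared zero-order phase are fitted by
bounded nonlinear least squares in the time domain (projected
Levenberg–Marquardt, Nielsen damping, analytic derivatives), vectorized
across voxels: the normal matrix is assembled from the 0th/1st/2nd temporal
moments of basis-function cross products, so each iteration costs a few
length-M reductions per voxel. Amplitude initialization is the linear
projection onto the model at the prior shifts; zero-amplitude peaks are
frozen out of the step (their frequency/width directions are
unidentifiable).

Prior knowledge: amplitudes ≥ 0; chemical shifts bounded ±0.3 ppm around
the known positions; FWHM bounded [5, 120] Hz. By default the prior imposes
the classic AMARES equality constraints — one *global* frequency offset
shared by all peaks and one *shared* FWHM — which matches the simulation
truth, keeps the Fisher matrix well conditioned at SNR 5–15, and fits a
volume ~4× faster. Per-peak ("individual") shift/width modes are available
and tested; they inflate the amplitude CRLB ~2.2× (per-peak width freedom
is the dominant nuisance) and roughly triple the fitted-map errors of the
FFT baseline at SNR 15. Multi-start proved unnecessary under the
constrained prior — the linear initialization already lands in the basin of
attraction; restarts can be emulated by refitting with jittered priors.

CRLB% is `100 · sd · sqrt([F⁻¹]_aa) / a` with `F = Re(J^H J)/sd²` evaluated
in the *constrained* parameterization the fit used, and `sd` the
per-component noise SD estimated from the 8–12 ppm band of each voxel's
spectrum. Rank-deficient Fisher matrices (vanished or fully overlapping
peaks) yield an explicit infinite CRLB rather than a silent failure.

## Quantification

NRMSE is `‖θ − θ̂‖₂/‖θ‖₂` over the whole amplitude map, with θ the map
fitted from the noise-free reconstruction (the reference). Per-metabolite
CRLB summaries average over voxels whose ground-truth amplitude exceeds
25% of that metabolite's map maximum (elsewhere CRLB% diverges as the
amplitude vanishes). Bias maps use fit − truth (sign recorded), SD with
n−1 normalization.

## Study design and problem sizes

The default comparison runs 10 repetitions of the SNR-15 phantom (the full
published setting used 30; `n_repetitions` scales it), reconstructing with
the FFT baseline and the subspace method at R = 1.0/1.1/1.3 (L = 5,
D1 = 3×5×3, λ = 0.001, 30 PDHG iterations), fitting all supported voxels,
and tabulating mean CRLB% and NRMSE. SNR-ladder statistics use ≥1000 noise
realizations via an exact shortcut: at R = 1.0 with normalized
sensitivities, the FFT reconstruction of noisy data equals the noise-free
combined spectrum plus white noise of SD α, so the statistic is evaluated
on the ROI spectra directly (equivalence tested against the full pipeline).
Repetitions use independent noise realizations with seeds derived from one
master seed ("same noise distribution" is read as same statistics, not the
same realization — independent draws are required for bias-SD maps to be
meaningful).

## What the phantom does and does not show

The generator reproduces the published simulation conditions: compartment
spectral content and amplitudes, 30 Hz linewidths, k-space truncation
partial-volume mixing, calibrated noise ladders, and exact rank-4 partial
separability. It does not model B0 inhomogeneity or off-resonance,
respiratory motion, baseline/macromolecule signals, T1 weighting, or
anatomically faithful organ shapes (compartments are procedural
superellipse/ellipsoid solids rather than segmentations from an anatomical
phantom library such as XCAT, so absolute map norms — and hence absolute
NRMSE values — depend on the configured volume fractions). Passing tests therefore validate
the reconstruction/fitting machinery and the *direction and rough
magnitude* of the method comparison, not in vivo performance.

## Known limitations

* At R = 1.0 with λ in its flat regime, the subspace reconstruction is a
  per-voxel temporal projection; noise components lying along the signal
  basis directions survive it, so the fitted-amplitude error of a strong,
  well-conditioned resonance (water under the constrained prior) improves
  only modestly over the FFT baseline even though the band-noise SD — and
  with it the CRLB — drops by ~√(M/L). Comparisons between CRLB gains and
  NRMSE gains should keep this distinction in mind.
* The lipid compartment's temporal signature is carried by the smallest
  signal singular value, close to the noise floor of the D1 data at SNR 15;
  its basis estimate is the noisiest and lipid maps inherit a visible
  subspace bias.
* The simplified sensitivity estimator (central k-space ratio maps) is
  accurate to ~5–10% for smooth objects and degrades at sharp object
  edges; the simulation uses exact synthetic maps and the estimator is
  provided for measured data.
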
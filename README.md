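# dmirecon

Low-rank and subspace model-based reconstruction for 3D deuterium metabolic
imaging (DMI), with an end-to-end simulation study comparing it against the
conventional Fourier (zero-filled FFT) reconstruction.

DMI maps deuterated water, glucose and downstream metabolites (Glx, lipid /
lactate) by ²H MR spectroscopic imaging after intake of deuterium-labeled
glucose. The ²H signal is weak, so acquisitions are low-resolution and noisy.
This package is for MR physicists and methods researchers who want a fully
reproducible, data-free testbed for the subspace reconstruction idea: every
voxel's FID is (to good approximation) a combination of a handful of
metabolite decay patterns, so the Casorati matrix **C** (voxels × time) of
the spatiotemporal signal ρ̃(r,t) = Σ_ℓ u_ℓ(r) v_ℓ(t) is low rank. A temporal
basis V̂ estimated from the fully sampled central k-space (the D1 region) by
SVD reduces the reconstruction to the spatial coefficient maps **U**:

    Û = argmin_U  ½ Σ_c ‖Ω F S_c U V̂ − d_c‖₂² + λ‖D U‖₁

(Ω sampling mask with Poisson-disk undersampling and a fully sampled D1
core, F spatial Fourier encoding, S_c coil sensitivities, D spatial finite
differences), solved with a primal–dual hybrid gradient (Chambolle–Pock)
algorithm. Metabolite maps come from AMARES-style time-domain Lorentzian
fitting with prior knowledge, with Cramér–Rao lower bounds (CRLB%) as the
precision metric and overall NRMSE (‖θ−θ̂‖₂/‖θ‖₂) as the accuracy metric.

Everything is synthetic and self-contained: a procedural three-compartment
torso phantom (liver / stomach / body with a subcutaneous fat rim) rendered
at 256×256×15, truncated in k-space to the 12×18×15 acquisition matrix
(4 Lorentzian resonances, 5 kHz bandwidth, 1024 time points), with
calibrated complex Gaussian noise at nominal SNR 60/30/15/5.

## Worked example

```python
from dmirecon import (
    ExperimentConfig, prepare_inputs, calibrate_alpha, alphas_from_ratios,
    NoiseLevel, add_complex_noise, generate_poisson_disk_mask, apply_sampling,
    estimate_basis_fast, model_order_report, solve_subspace_recon,
    compose_spatiospectral, fft_reconstruction, fit_volume, compute_nrmse,
)

cfg = ExperimentConfig(master_seed=1)
inp = prepare_inputs(cfg)                       # phantom + coils + k-space
alpha = alphas_from_ratios(calibrate_alpha(60.0, inp, seed=1))[15]
noisy = add_complex_noise(inp.coil_kspace, NoiseLevel(alpha, 15, seed=7))

mask = generate_poisson_disk_mask(inp.grid.shape, 1.3, (3, 5, 3), seed=1)
print(f"achieved R = {mask.achieved_R:.3f}")    # achieved R = 1.300

sampled = apply_sampling(noisy, mask)
basis = estimate_basis_fast(sampled, inp.csm, (3, 5, 3), 5, mask=mask.mask)
print("suggested L =", model_order_report(basis)["suggested_L"])  # 5

coeffs = solve_subspace_recon(sampled, basis, inp.csm, mask, cfg.recon)
spectra = compose_spatiospectral(coeffs, basis, inp.grid)
fit = fit_volume(spectra, inp.prior, support=inp.support)
print("mean water CRLB% =", float(
    fit.crlb_map("water")[inp.liver_roi].mean()))  # 0.274
```

The noisy data are reconstructed at acceleration R = 1.3 with a rank-5
temporal basis estimated from the 3×5×3 central k-space; the fitted water
amplitudes in the liver carry a CRLB of 0.27% of the amplitude, twelve
times below the FFT baseline at the same noise level (3.3%) — the core
advantage of the subspace model.

The full comparison study (both methods, R = 1.0/1.1/1.3, repeated noise
realizations, CRLB and NRMSE tables) is one call:

```bash
dmirecon experiment --seed 1 --reps 10 --out study.csv
```

A `dmirecon` command-line interface with `phantom`, `mask`,
`estimate-basis`, `recon`, `fit`, `metrics` and `experiment` subcommands
wraps the same library functions; every run writes a JSON provenance record.

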
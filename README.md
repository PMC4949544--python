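# relb1map

Relative B1+ transmit-field mapping for parallel-transmit (PTx) MRI in the
presence of **large dynamic range** — the regime of local transmit arrays at
ultrahigh field, where the field directly adjacent to a transmit element can
be tens of times stronger than in the rest of the object.

## Who this is for

PTx pulse design needs per-channel maps of the transmit field B1+. The
standard relative-mapping approach — acquire one low-flip-angle spoiled
gradient-echo (SPGR) image per channel and take image ratios — breaks down
with local arrays: a drive low enough to stay linear next to the coil leaves
the rest of the object noise-dominated, while a drive high enough for remote
signal saturates near the coil. This package implements an acquisition and
reconstruction scheme that resolves the conflict: acquire SPGR images at
**multiple RF drive levels** per channel and combine them voxel by voxel with
a maximum-likelihood estimator that automatically rejects saturated
measurements.

## Method

The steady-state SPGR signal in a voxel is

    S_j = M0 R (1 − E1) e^{−TE/T2*} e^{iφ} sin(θ_j) / (1 − E1 cos(θ_j)) + ε(σ),

with E1 = exp(−TR/T1), flip angle θ_j = f·d_j·θ_ref (f the unitless transmit
sensitivity, d_j ∈ (0, 1] the RF drive of the j-th of N acquisitions, drives
ascending), and ε complex Gaussian noise with standard deviation σ per
real/imaginary channel. At low flip angle S_j ≈ ρ f d_j, so the *normalized*
signal S'_j = S_j/d_j is drive-independent with noise σ'_j = σ/d_j — until
saturation depresses the higher drives.

The reconstruction assumes the first k measurements are unsaturated. Under a
2D Normal noise model the maximum-likelihood estimate of the common mean and
its log-likelihood are

    γ̂_k = Σ_{j≤k} d_j² S'_j / Σ_{j≤k} d_j² ,
    L_k  = −k ln 2π − Σ_{j≤k} [ 2 ln σ'_j + |S'_j − γ̂_k|² / 2σ'_j² ] ,

and the reported estimate is γ̂ = γ̂_{k_max} with k_max = argmax_k L_k(γ̂_k).
Unsaturated low-noise measurements are rewarded through the ln σ'_j terms;
saturated ones pay a residual penalty and are rejected. γ̂ is complex, so both
magnitude and phase maps follow. Relative maps are formed per voxel as
rT_j = I_j / Σ_c |I_c|, which cancels the receive field and proton density;
the lowest drive is designed by root-finding so that the largest expected
sensitivity stays linear to a prescribed tolerance, and drives are spaced
linearly or logarithmically up to full drive.

The package contains the signal model and drive design (`signal_model`), the
voxelwise MLE (`mle`), relative-map formation (`relative`), a synthetic
multi-channel phantom with ground truth (`phantom`), a Monte Carlo error
study (`monte_carlo`), NIfTI/JSON I/O (`io`) and a CLI (`cli`).

## Worked example

```python
import numpy as np
import relb1map as rb

# design the acquisition: 4 logarithmic drives, lowest drive from a 1%
# linearity tolerance at the maximum expected sensitivity
params = rb.SPGRParams(TR=10.0, T1=1000.0, TE=4.0, T2star=100.0,
                       theta_ref=np.deg2rad(273.0))
d_min = rb.min_drive(params, f_max=1.0, tol=0.01)
drives = rb.make_drive_scheme(d_min, N=4, kind="logarithmic")
print(f"d_min = {d_min:.5f}")
print("drives =", np.round(drives.as_array(), 5))

# reconstruct one voxel whose full-drive measurement is saturated
series = rb.VoxelSeries(signals=(0.1, 0.5), drives=rb.DriveScheme((0.1, 1.0)),
                        sigma=0.01)
est = rb.reconstruct_voxel(series)
print(f"k_max = {est.k_max}, gamma_hat = {est.gamma_hat:.4f}, "
      f"log-likelihoods = {np.round(est.loglik, 3)}")

# end-to-end synthetic phantom: 8 channels, 4 drives, SNR 5300
config = rb.default_config(seed=0)
truth, stack, sigma, gamma, k_max, maps = rb.reconstruct_phantom(config)
report = rb.recovery_report(truth, maps)
print(report[["channel", "mag_err_median", "mag_err_p95"]].round(5).to_string(index=False))
```

Output:

```
d_min = 0.00299
drives = [0.00299 0.02073 0.14399 1.     ]
k_max = 1, gamma_hat = 1.0000+0.0000j, log-likelihoods = [ 2.767 -2.236]
 channel  mag_err_median  mag_err_p95
       0         0.00024      0.00121
       1         0.00034      0.00144
...
```

The single-voxel example shows the saturation rejection at work: the
normalized measurements are {1.0, 0.5}, the second (full-drive) value is
depressed by 50 noise standard deviations, the one-measurement model wins the
likelihood comparison (2.767 > −2.236), and the estimate 1.0 uses only the
unsaturated drive. The phantom report shows that the relative-map magnitudes
(which sum to 1 over the 8 channels at every voxel) are recovered with a
median absolute error of a few 10⁻⁴ despite a ~30:1 range of transmit-field
strength across the object.

The same pipeline is available from the shell:

```sh
relb1map phantom --out acq --seed 4
relb1map reconstruct --images acq --out recon
relb1map relmap --images recon --out maps --phase-ref 0
relb1map simulate --out study.csv --seed 1
```

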
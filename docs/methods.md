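# Methods

## Signal model

The SPGR steady-state signal is evaluated in closed form,

S(θ) = M0 · R · (1 − E1) · e^{−TE/T2\*} · e^{iφ} · sin θ / (1 − E1 cos θ),
E1 = e^{−TR/T1}, θ = f · d · θ_ref,

with f the unitless transmit sensitivity, d the RF drive scale and θ_ref the
flip angle at f = d = 1. The model assumes ideal spoiling, steady state, and
no slice-profile effects; all times are milliseconds, angles radians
(degrees are accepted only at the CLI/config boundary).

The linear (low-flip-angle) model is defined as the tangent of S at θ = 0,
i.e. S_lin = ρ f d with ρ = M0 R e^{−TE/T2\*} e^{iφ} θ_ref. With this
definition the saturation error

η(θ) = 1 − |S(θ)| / |S_lin(θ)|

depends only on θ and TR/T1 (all amplitude factors cancel), vanishes at
θ = 0 like θ² (1/6 + E1 / (2(1 − E1))), and increases monotonically to 90°.

**Drive design.** The lowest drive is the largest d for which
η(f_max · d · θ_ref) ≤ tol, found by Brent root-finding on d ∈ [10⁻⁶, 1]
(result capped at 1 when even full drive is linear; an error is raised if the
tolerance is unattainable at d = 10⁻⁶). Monotonicity of η on the relevant
range makes the bracketed solve safe; the root is resolved to 10⁻¹⁰ in d so
the round-trip error matches the tolerance to well under 10⁻⁶. Drive schemes
span [d_min, 1] with N levels, either equally spaced ("linear") or
geometrically spaced ("logarithmic", d_j = d_min^{(N−j)/(N−1)}), the latter
concentrating samples at low drives where saturation onset must be resolved.
Geometric spacing is one of several curves one could call logarithmic; it is
adopted because it is the unique scheme with constant drive ratio and fixed
endpoints.

## Maximum-likelihood reconstruction

Normalized signals S'_j = S_j/d_j share the mean ρf while unsaturated, with
circular complex Gaussian noise of per-component deviation σ'_j = σ/d_j. For
each model order k (first k measurements unsaturated) the ML estimate is the
d_j²-weighted mean γ̂_k — equivalently the inverse-variance weighted mean,
invariant to any common rescaling of the weights — and the model order is
chosen by maximizing L_k(γ̂_k) including its k-dependent constants
−k ln 2π − 2 Σ ln σ'_j. The saturated means μ_{k+1..N} are nuisance
parameters that never need to be estimated: measurements beyond k simply do
not enter L_k.

Numerical notes:

* The whole k-sweep reduces to three cumulative sums (of w|S'|², wS' and w
  with w = d²/2σ²). Data are centered on the first measurement before
  accumulating — the residual sum is translation invariant, and centering
  avoids catastrophic cancellation when σ is many orders of magnitude below
  the signal scale (residuals are clamped at 0 against remaining rounding).
* Ties in L_k within 10⁻¹² resolve to the larger k (more data); exact ties
  have measure zero on real data.
* k always starts at 1: the drive design guarantees the lowest-drive
  measurement is unsaturated. A voxel saturated even at d_1 is outside the
  model and is not detected.
* σ is a single global scalar per acquisition (estimated from a background
  region as the pooled standard deviation of real and imaginary parts);
  spatial noise variation from receive combination is ignored.
* Because L_k compares densities across different numbers of terms, the
  selected k depends on the absolute scale of σ' (adding an unsaturated term
  is rewarded only when σ'_j < (2π)^{−1/2}). Magnitude and phase of γ̂ are
  scale- and rotation-equivariant; the model-order choice is
  rotation-invariant and, away from likelihood near-ties, stable under
  rescaling. Acquisitions should pass raw scanner units and the matching σ
  through unchanged.
* The MLE runs at every voxel including pure-noise background; no masking is
  applied. Downstream users may mask.

Relative maps are rT_j = I_j / Σ_c |I_c| (complex; Σ_j |rT_j| = 1 wherever
the denominator is nonzero, asserted to 10⁻¹²). Zero-denominator voxels are
set to 0 and flagged in a validity mask rather than NaN, keeping NIfTI
outputs viewer-safe. Phase maps wrap to (−π, π]; referencing to a channel
cancels the common receive phase.

## Synthetic phantom

The phantom stands in for experimental multi-channel data, which is not
distributable. It emulates a torso-shaped elliptical object (default 64×64
grid, half-axes 28×19 voxels, T1 = 1300 ms, T2\* = 145 ms, TR/TE =
20/3.1 ms) ringed by 8 transmit elements just outside the boundary
(ring scale 1.12). Per channel the sensitivity magnitude decays
exponentially with distance from the element, f = f_peak e^{−dist/L} with
L = 16 voxels, normalized so the coil-nearest object voxel sits at
f_peak = 1; this yields a ≥ 20:1 (typically ~30:1) dynamic range across the
object, the regime the method targets. The transmit phase advances linearly
with distance (0.05 rad/voxel) plus a per-channel offset; the receive field
is a smooth superposition of decaying lobes from the same ring. θ_ref
defaults to 273°, a realistic peak flip angle for a local transmit array at
full drive. Drives default to 4 logarithmic levels designed at a 2%
linearity tolerance.

Noise: σ = (maximum noise-free signal magnitude over the whole dataset)/SNR
with SNR = 5300 by default, added as i.i.d. complex Gaussian everywhere;
outside the object the images are pure noise (used to exercise background σ
estimation). All draws flow from one seed.

What the phantom does *not* model: electromagnetic field physics
(Biot–Savart/FDTD coil fields), slice profiles, imperfect spoiling, motion
or spin-history effects, spatially varying noise after receive combination,
and tissue heterogeneity (T1/T2\* are uniform). Passing recovery tests
therefore demonstrates the estimator's statistical behavior under the stated
signal model, not robustness to these physical effects.

## Monte Carlo study

Defaults reproduce the reference validation design: 50 sensitivities
linearly spaced on [0.001, 1]; θ_ref = 273°; TR/T1 ∈ {0.01, 0.07} with
TE = 4 ms, T2\* = 100 ms; N ∈ {3, 4, 6, 12} drives, linear and logarithmic;
d_min from the 1% linearity rule per TR/T1 (both schemes share d_min and
d_max = 1); 50 noise repeats; SNR at 100%, 22% and 5% of a reference value
of 5300. The full factorial design vectorizes to ~1 s on one CPU, so no
scaling down is needed.

* **SNR convention.** The reference SNR derives from in-vivo pilot data that
  cannot be reproduced here; the package defines σ = (maximum noise-free
  |S_j| over the f-grid and drive set)/(level × 5300), i.e. SNR is referenced
  to the brightest voxel of the dataset. This convention is recorded with the
  outputs. The absolute noise scale shifts the f-location of the
  saturation-rejection transition (see the scale note above), so
  transition-location results depend on it; error *bounds* on the plateaus
  are insensitive to it.
* **Error metrics.** η_{a,b} is the complex estimate at sensitivity a,
  repeat b; the magnitude error is δ̄_a = 1 − |η̄_a/(ρf)| with η̄_a the
  complex mean across repeats (read literally; not the mean of magnitudes),
  and the phase error is δ̄_a^ph = 1 − ∠η̄_a/∠(ρf). Spreads are ±1 standard
  deviation across repeats. The simulated transmit phase is π/4 so the phase
  metric's denominator is nonzero.
* Per-cell RNG streams are spawned from one seed sequence, making the study
  bit-reproducible for a fixed seed regardless of cell order changes within
  a run.

## Known limitations

* Model-order selection inherits the density-scale sensitivity discussed
  above; a per-datum averaged or scale-free criterion is deliberately not
  substituted, to keep the estimator exactly as specified.
* The transition sensitivity (where error bars widen at low SNR) is
  reported on the 50-point f-grid and is resolution-limited to ±0.02.
* Absolute B1+ calibration, AFI comparison, receive-channel combination and
  DICOM/BIDS ingestion are out of scope; the tool consumes already-combined
  complex images as real/imaginary NIfTI pairs with a JSON sidecar.
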
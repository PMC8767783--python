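# Methods

This note documents the models, numerical choices and known
limitations behind `nirsdot`, in the order the pipeline runs.

## Forward model

**Geometry.** The head is a voxelized slab phantom (default 0.6 mm
cubic voxels) with up to six optical layers along depth — air, scalp,
skull, CSF, gray matter, white matter — each with configurable
absorption and reduced scattering coefficients per wavelength and a
common refractive index of 1.40. The default preparation has no scalp
layer (optodes on the skull surface); an incision patch can replace
scalp with air over a rectangular region for scalp-bearing phantoms.
The shipped optics table uses typical adult-mammal near-infrared values
(gray/skull μₐ ≈ 0.02 mm⁻¹, μₛ′ ≈ 1.0 mm⁻¹ at 805 nm, ±5% across
780/830 nm; CSF low-scattering). These are configuration, not ground
truth: any table with positive entries works, and none of the package's
validated properties depend on the specific values.

**Optode grid.** Optodes sit on a triangular lattice (all
nearest-neighbor distances equal to the 15 mm source–detector
separation, so channel midpoints are 7.5 mm apart); every optode is
bidirectional and a channel is an unordered optode pair. The 18-optode
replica layout forms two ladders of 8 and 10 optodes (one per
hemisphere), which yields exactly 30 nearest-neighbor channels.

**Photon transport.** Two engines compute fluence:

* *Analytic* (default): the continuous-wave Green's function of a
  semi-infinite homogeneous medium with gray-matter bulk optics,
  `Φ ∝ exp(−μ_eff d₁)/d₁ − exp(−μ_eff d₂)/d₂`, with
  `μ_eff = √(3 μₐ(μₐ+μₛ′))`, the image source mirrored across the
  extrapolated boundary plane `z = −z_b` (`z_b = 2AD` with the standard
  refractive-mismatch factor A), and optodes mapped to effective
  isotropic sources at depth `1/μₛ′`. The function is symmetric in its
  arguments, so channel reciprocity holds to machine precision.
* *Finite-difference*: a 7-point diffusion discretization on the voxel
  grid honoring per-tissue optics, with harmonic-mean face diffusivity
  (symmetric operator) and zero-fluence boundaries. It exists to
  validate the Rytov linearization: `A·x` agrees with differenced full
  FD forward solves to better than 10% for perturbations ≤ 1e−4 mm⁻¹.

**Sensitivity matrix.** Per channel `m = (s, d)` the Rytov kernel is
`a_m(v) = G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d) · V_voxel`, a partial
path length in mm. Each row is divided by its mean optical path length
`⟨L⟩_m = Σ_v a_m(v)` and by ln 10, so `A` maps absorption changes to
base-10 log-ratio absorbance. Per-voxel normalized sensitivity is
`Σ_m a_m(v)` scaled to a gray-matter maximum of 1; voxels at or below
the 0.001 threshold are dropped and the retained set is intersected
with the gray-matter mask.

## Synthetic sessions

The generator emulates the alternating left/right-hand task: activation
"blobs" (Gaussian spatial profiles, ~2 mm radius) placed in the
hemisphere contralateral to their hand, each with an HbO amplitude and
an HbR amplitude of opposite sign, convolved with a causal
gamma-density response kernel of configurable peak latency and width.
The default two-blob-per-hand configuration gives one early (3.8 s,
"premotor"-like) and one late (4.2 s, "motor"-like) region per
hemisphere. Blobs sit at the superficial gray-matter depth, where both
cortical responses arise and continuous-wave sensitivity concentrates.

Noise has three components: (i) correlated Gaussian channel noise with
exponential spatial decay across channel midpoints and heteroscedastic
per-channel gains; (ii) slow sinusoidal drift below the high-pass
cutoff; (iii) sparse exponential-decay artifact spikes whose
three-wavelength signature is constructed in the null space of the
extinction matrix, so the spectroscopic remover can null them exactly.
Raw output is `baseline · 10^(−signal−noise)`, the inverse of the
preprocessing log-ratio convention. Sessions refuse to run without an
explicit seed.

**Default conditions.** Trial structure follows the protocol (75 + 75
alternating trials ~20 s apart, 7.69 Hz, 3 days). The channel noise sd
(5e-5 log-ratio units) and blob amplitudes (0.02 mM HbO, −0.35 ratio
HbR) are not protocol numbers; they were calibrated once to the
regime characteristic of skull-surface recordings — substantial
day-level map agreement (Fleiss κ well above 0.6) and merged-day
HbO/HbR t-image correlations near −1 — which pins down the
signal-to-noise level. With these defaults the simulated experiment
reproduces that regime (κ ≈ 0.88, t-correlation ≈ −0.997 at the demo
scale).

**What the generator does not emulate** (hence what passing tests do
not show about real data): scalp hemodynamics and systemic physiology
(Mayer waves, respiration), task-correlated motion, optode coupling
drift across days, heterogeneous cortical geometry (sulci), and
HbO/HbR kernels with different shapes. Conclusions about artifact
removal, in particular, only cover artifacts outside the hemoglobin
spectral subspace.

## Preprocessing

Raw voltages → base-10 log-ratios against the per-channel series mean
(the session-mean reference is an assumption; a dark reference can be
passed explicitly) → zero-phase Butterworth filters (high-pass order 3
at 0.01 Hz, low-pass order 7 at 0.7 Hz, both forward–backward so
event latencies are undistorted) → orthogonal projection of each
(channel, time) wavelength 3-vector onto span{ε_HbO, ε_HbR}, with the
removed residual magnitude reported → segmentation into [−5, 20] s
windows with the pretask ([−5, 0] s) mean subtracted; edge-overlapping
trials are dropped and counted.

The pretask noise covariance `Σ̃` averages `y yᵀ` over all pooled
(trial, time) pretask pairs — dividing by the total pair count so `Σ̃`
is a proper covariance whatever the trial count — and is regularized as
`Σ = Σ̃ + β s I`, `s = trace(Σ̃)/M`. Diagonal mode zeroes off-diagonal
entries first. `β > 0` guarantees positive definiteness.

## Inverse solvers

**MN.** The closed form is evaluated in the M×M channel space
(`x̂ = Aᵀ(AAᵀ + αΣ)⁻¹y`), algebraically identical to the N×N normal
form. The evidence for α treats pooled task-window samples as
`y ~ N(0, AAᵀ/α + Σ)` and averages the log density over samples; the
grid spans 1e−6–1e6 × `trace(AᵀΣ⁻¹A)/N` (dimensionless scaling) with
100 points; ties resolve to the smallest maximizer and edge maxima are
logged. With weak per-sample signal the evidence legitimately saturates
at strong regularization; the resulting operator still preserves
spatial patterns, which is what the downstream statistics consume.

**VB.** ARD in the latent space `x = Wz`. `W` has Gaussian columns
(half-width at half maximum = smoothing radius, truncated at 2.5
half-widths, unit L2 columns); radius 0 is the identity. Updates are
exact coordinate ascent: Gaussian `q(z)` via the Woodbury form; Gamma
`q(a_v)` with posterior shape `γ₀ + T/2` and rate `γ₀/ā₀ + Σ_t⟨z²⟩/2`;
a scalar observation-noise gain `ρ` (the covariance *shape* stays the
estimated `Σ`). The free energy is evaluated after every z-update and
must not decrease (tolerance 1e−8 relative); iteration stops when the
relative change falls below 1e−10 with at least 500 iterations.

The MN initialization enters twice. The squared MN amplitudes start
the relevance iteration — the adaptive spatial prior belief that ARD
refines (γ₀ = 0 yields sparse unconstrained ARD). The Gamma hyperprior
mean is the MN regularization weight α — the uniform prior precision
the MN estimate itself assumes — so prior confidence interpolates
between free ARD and the MN solution, and the γ₀ → ∞ limit collapses
onto MN exactly. (Setting the hyperprior mean from per-voxel squared
amplitudes instead makes the strong-confidence limit a
squared-pattern-reweighted solve that does *not* reproduce the MN
pattern; the uniform-α choice is what makes "higher confidence ⇒
closer to the initialization" literally true.)

Numerical safeguards, both acting on update *targets* so the ascent
property survives: relevances are capped 1e12 above the strongest
initial relevance (a fully-pruned voxel), and ρ is floored at 1e−12 —
exactly noise-free data otherwise drives ρ → 0, where the free energy
is unbounded and the posterior system ill-conditioned. Free-energy
terms in log(rate) that cancel algebraically are cancelled symbolically
rather than numerically, avoiding catastrophic float cancellation at
extreme relevance ranges.

**Unmixing.** Per voxel and time the overdetermined 3×2 Beer–Lambert
system is solved by pseudoinverse; wavelength components orthogonal to
the extinction columns are annihilated. The shipped extinction table
(mM⁻¹·mm⁻¹; 805 nm near-isosbestic) is literature-style and
configurable.

## Statistics

Per-voxel unpaired pooled-variance t on [0, 10] s mean responses, left
minus right. Familywise error: 2000 seeded random relabelings
preserving group sizes; separate per-side thresholds at the 99.5th
percentile of the max-t (and 0.5th of the min-t) distributions. Merged
analysis concatenates trials across sessions. Core maps take the
top/bottom 5% of voxels by t with stable index tie-breaking.

Measured on null sessions, the realized familywise error sits at or
below the nominal 0.5% per side. A small conservatism is expected:
hands alternate strictly, so the observed L−R contrast partially
cancels slow shared noise in a way random relabelings do not.

## Reliability and ROI analysis

Agreement metrics follow their standard definitions (dates as raters,
voxels as subjects, three classes): Fleiss κ with `P_e = Σ π_q²`; Gwet
AC1 with `P_e = Σ π_q(1−π_q)/(Q−1)`; Dice averaged over date pairs and
both activation labels, with both-empty pairs skipped (logged) rather
than scored 0; detection rate over the retained gray-voxel universe;
ICC(1,1) from one-way ANOVA mean squares on ROI × date mean-t tables.
In-package implementations are cross-checked in the test suite against
statsmodels (κ) and pingouin (ICC).

Parcellation is synthetic (generator blob labels or geometric tiling;
parcels ≤ 50 voxels dropped); real-atlas support is a label-volume
file hook, not an algorithm. L−R difference time courses are
voxel-averaged per parcel, trial-averaged per hand, and differenced,
with 95% CIs from 1000 seeded bootstrap resamples over trials. Peak
latency is the windowed [0, 10] s extremum with the expected
contralateral sign (HbO positive, HbR negative); parcels whose peak is
ten times below the global maximum are excluded, as are flat series;
boundary extrema are flagged. Latency comparisons between regions use
the two-sided Wilcoxon rank-sum on the top 300 voxels ranked by
absolute trial-averaged L−R HbO peak amplitude (the ranking statistic
is a package choice; "largest modulation" admits several readings).
Cross-correlation grouping clusters parcels by single linkage on
absolute pairwise peak lags.

## Pipeline sizes and determinism

The pipeline's defaults are the protocol values (0.6 mm voxels, 15 mm
separation, 7.69 Hz, 75+75×3 trials, 2000 permutations at 0.5%, 5%
cores, 1000 bootstraps, 1e−10/500 VB stopping). Tests and the
acceptance script run the same code on reduced problem sizes chosen for
desk-scale turnaround — 1.2–2 mm voxels (≈ 1–12 k retained voxels),
15–30 trials per hand where a property does not need the full count,
200 Monte-Carlo repetitions for error-rate calibration — sizes at which
every validated property is already expressible. Every stochastic stage
(generator, permutations, bootstrap) requires an explicit seed and is
bit-reproducible given one; `run_pipeline` writes a manifest (config
hash, seed, version) so deterministic reruns are byte-identical.

## Known limitations

* The analytic forward model is homogeneous semi-infinite; layered
  optics affect only the FD engine. Depth localization inherits the
  usual CW-DOT surface bias (the spatial pattern, not depth, carries
  most of the inference here).
* Per-wavelength evidence selection can shrink wavelengths with weak
  effective signal (e.g. near HbO/HbR cancellation at 780 nm for
  HbR:HbO ≈ −0.35) more than others, which mildly distorts unmixing at
  low SNR.
* The VB noise update rescales a scalar gain only; a full covariance
  re-estimate inside VB is out of scope.
* Exactly noise-free inputs are numerically hostile to ARD (unbounded
  free energy); validation fixtures use noise ~1e5 below signal
  instead, which is noise-free for every practical purpose.
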
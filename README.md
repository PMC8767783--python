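# nirsdot

Diffuse optical tomography (DOT) of multichannel functional
near-infrared spectroscopy (fNIRS) signals: from raw multiwavelength
absorbance time series to 3D oxygenated/deoxygenated hemoglobin
(HbO/HbR) images, with permutation-based activation mapping,
cross-session reliability scoring, and region-of-interest (ROI)
time-series/latency analysis.

The package targets event-related fNIRS experiments of the
skull-surface kind: a bidirectional triangular optode grid (15 mm
source–detector separation, 7.5 mm channel spacing, ~30 channels) over
motor cortex, three wavelengths (780/805/830 nm) sampled at 7.69 Hz,
and alternating left/right-hand trials (75 + 75 per daily session over
3–4 sessions). Because such recordings are not publicly distributable,
a first-class synthetic-session generator with known voxel-level ground
truth stands in for them, making every downstream stage testable end to
end.

## The model

Light propagation in the head is treated under the diffusion
approximation; for small absorption changes the Rytov linearization
gives, per wavelength λ,

    y = A x

where `y` is the vector of channel log-ratio absorbance changes, `x`
the voxel absorption changes (mm⁻¹), and `A` the sensitivity matrix
(channels × voxels), built from products of continuous-wave Green's
functions (photon measurement density functions), normalized per
channel by the mean optical path length and thresholded at 0.001 of the
maximum gray-matter sensitivity.

Two inverse solvers estimate `x`:

* **Minimum norm (MN)** — `x̂ = (AᵀΣ⁻¹A + αI)⁻¹AᵀΣ⁻¹y`, with the noise
  covariance `Σ = Σ̃ + βs·I` estimated from pretask data
  (`s = trace(Σ̃)/M`) and `α` selected by maximizing the Gaussian
  marginal likelihood over 100 log-spaced candidates. Six conditions
  (MN201–MN206): full vs. diagonal `Σ̃` × β ∈ {1, 10⁻², 10⁻⁴}.
* **Hierarchical variational Bayes (VB)** — automatic relevance
  determination on latents `z` with `x = Wz` (`W` a Gaussian smoothing
  operator of half-width 0 or 2 mm), per-voxel relevance parameters
  under a Gamma hyperprior whose shape γ₀ ∈ {0, 10⁻³, 10⁻², 10⁻¹} sets
  the confidence in the MN initialization; free energy maximized to
  relative tolerance 1e−10 with ≥ 500 iterations. Forty-eight
  conditions (VB201–VB248).

Absorption images at the three wavelengths are unmixed into HbO/HbR via
the pseudoinverse of the modified Beer–Lambert extinction system.
Voxelwise left-vs-right activation uses unpaired t-tests on [0, 10] s
mean responses with max-t permutation control of the familywise error
(2000 relabelings, 0.5% per side). Cross-session consistency is scored
with Fleiss's κ, Gwet's AC1, Dice overlap, detection rate and ICC(1,1);
ROI analysis produces L−R difference time courses with bootstrap CIs
(1000 resamples), peak latencies in [0, 10] s, Wilcoxon rank-sum latency
comparisons on top-modulation voxels, and cross-correlation lag
grouping.

## Worked example

```python
from nirsdot.pipeline import PipelineConfig, run_pipeline, report

cfg = PipelineConfig(
    seed=7,
    extent_mm=(78.0, 64.0, 14.0),
    voxel_size_mm=2.0,      # coarse demo grid; the protocol default is 0.6 mm
    n_trials_per_hand=75,
    n_days=3,
    n_perm=2000,
    parcel_min_size=10,
)
res = run_pipeline(cfg, "demo_run")
print(report("demo_run"))
```

prints

```
run 50e89d3ddd914869 seed=7
channels=30 voxels=2230

Reliability by method:
       core_overlap_rate  detection_rate  dice_mean  fleiss_kappa  gwet_ac1  hb_image_correlation     icc11
MN201           0.959821        0.152317    0.89746       0.88476  0.964061             -0.996987  0.918799

Activation statistics by method:
       n_significant_hbo   overlap    t_corr  threshold_hi
MN201              374.0  0.959821 -0.996987      3.958204

ROI peak latencies (s):
  parcel 1: true 3.80  estimated 3.901170351105331
  parcel 2: true 4.20  estimated 4.031209362808842
  parcel 3: true 3.80  estimated 4.031209362808842
  parcel 4: true 4.20  estimated 4.161248374512353
```

Reading this: 18 optodes form 30 channels over both hemispheres;
2230 gray-matter voxels survive the 0.001 sensitivity threshold. Across
three simulated sessions the day-level activation maps agree
substantially (κ = 0.88, AC1 = 0.96, mean Dice = 0.90), about 15% of
retained voxels show significant task modulation per day, and the
merged-day HbO and HbR t-images are near-perfectly anticorrelated
(−0.997) with 96% overlap of their core (top/bottom 5%) maps — the
signature of HbO-up/HbR-down neurovascular coupling surviving
reconstruction. The four ground-truth activation parcels (two per
hemisphere, "premotor" 3.8 s vs. "motor" 4.2 s peak latency) are
recovered with the correct early/late ordering within each hemisphere;
the ≈0.1 s bias reflects the 0.13 s sampling interval and spatial
crosstalk between neighboring parcels.

The same pipeline is scriptable from the shell:

```bash
nirsdot all --seed 7 --out demo_run     # or: nirsdot simulate / stats / ...
nirsdot report demo_run
```

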
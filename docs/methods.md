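# Methods

## Scope and model

`woi` processes wide-field optical imaging (WOI) movies of the dorsal mouse
cortex — interleaved multi-LED acquisitions recording GCaMP fluorescence
(470 nm excitation) and hemoglobin reflectance (530/590/625 nm) — into
hemodynamic and calcium contrast movies, computes seed-wise and homotopic
(bilateral) Pearson functional-connectivity maps and block-design stimulus
activation maps, and controls the family-wise error of pixel-wise group
comparisons with a 2D random-field-theory (RFT) cluster-extent threshold.
The reference acquisition geometry is a 156×156 px frame binned over an
~11 mm field of view at 16.8 Hz per wavelength, downsampled by 2 to
78×78 px (pitch 11/78 ≈ 0.141 mm) for statistics.

## Processing chain

Order: dark subtraction → spatiotemporal detrend → branch:

* reflectance channels: log-mean `ln(F/mean_t F)` then modified
  Beer–Lambert inversion `y = diag(L)·E·ΔC` with `y = −logmean`,
  LED-spectrum-weighted extinction matrix `E` (species HbO, HbR) and
  differential pathlengths `L`;
* fluorescence channel: mean-normalize, multiply by
  `exp(Δμa_ex·x_ex + Δμa_em·x_em)` to undo hemoglobin absorption of
  excitation and emission light (band-averaged extinction at the 470 nm LED
  and over the 515–560 nm emission band), then log-mean;

then per-pixel temporal mean removal, 5×5 Gaussian smoothing (σ = 1.3 px,
kernel renormalized to unit sum after truncation, masked-normalized so
off-brain zeros do not bleed in), global signal regression (per-contrast
global mean, covariance-slope regression), optional atlas registration and
zero-phase Butterworth filtering (order 5; calcium 0.4–4.0 Hz, hemoglobin
0.009–0.08 Hz).

Design choices made where the procedure was genuinely open:

* **Detrending** is temporal-linear per pixel first, then a least-squares
  spatial plane per frame; the ops return zero-mean output and the pipeline
  re-adds the temporal-mean baseline before ratio-based steps, which need a
  positive baseline. Detrend/smooth/GSR are regressions against globally
  shared variance; they are flags so the pure spectroscopic forward/inverse
  identity can be evaluated with them off.
* **Centering**: log-mean output does not have exactly zero temporal mean
  (it is a log of ratios), so the pipeline subtracts each contrast's
  per-pixel temporal mean. This also cancels the second-order Jensen offset
  `ln(mean_t e^{−A})`, making the noiseless Beer–Lambert round trip exact
  to machine precision.
* **Pathlengths** `L`, `x_ex`, `x_em` default to 1 cm, so concentrations are
  in concentration×pathlength units; these cancel in all correlation- and
  t-based analyses.
* **Sign convention**: log-mean is `+ln(F/mean)`; attenuation enters the
  Beer–Lambert system as `y = −logmean`.
* **Hemoglobin correction** uses the exponential attenuation model; a
  ratiometric division against a reflectance channel would be an
  alternative and the exponential path is the one shipped.
* The **brain mask** is applied before the atlas transform by default
  (mask-then-warp); warping first is available by reordering calls.

## Geometry, masks, seeds

Masks are rasterized from a traced polygon; a pixel is brain iff its center
(integer row/col, row 0 anterior) lies inside or on the polygon. Only two
landmarks (anterior midline suture, lambda) are available, so the "affine"
registration to atlas space is the 2-point similarity transform (rotation +
uniform scale + translation, 4 dof) — a full 6-dof affine is undetermined
by two points. Frames are resampled bilinearly, masks nearest-neighbour.
Interactive tracing/clicking is replaced by explicit coordinates throughout.

The packaged seed template (`data/seed_template.txt`) lists named
mirror-pair seed centers in atlas millimetres (AP offset from the anterior
suture, absolute lateral offset), default radius 0.25 mm; any template
satisfying the mirror-symmetry invariant exercises the code identically.
Placed seed radii are floored at 0.75 px so a seed disc always covers at
least one pixel center. LED channel order must be declared by the user; no
auto-detection is attempted.

The packaged extinction table (`data/extinction_hb_synthetic.txt`) is a
synthetic stand-in reproducing the qualitative features of the standard
compiled hemoglobin spectra (isosbestic points near 530/570 nm, HbO2 α/β
bands, deoxy > oxy in the red); LED emission files are Gaussian-shaped.
All spectroscopy is self-consistent against these tables; for quantitative
work users should substitute measured spectra files of the same format.

## Connectivity

Seed traces are disc means inside the mask; seed maps are Pearson r of each
masked pixel against each trace. Bilateral FC pairs every left-side masked
pixel with its mirror across the midline column and writes r to both
pixels, so the map is exactly mirror-symmetric. Seed pixels are not
excluded from their own maps; no midline strip is excluded. Undefined
correlations (constant traces) are NaN. Group averaging across animals is
intended on Fisher-z maps (`fisher_z`, |r| clipped at 1−1e−7).

## Stimulus analysis

Blocks (default 5 s rest / 5 s stim / 10 s rest, 14 blocks, 8.4 Hz) are a
lossless reshape to pixels×pixels×block_length×blocks. Baseline is the
per-block mean over stimulus-off frames (so inter-block drifts cancel; a
global off-mean is a flag). The activation map is the mean over blocks and
on-frames; the ROI is pixels at ≥ 80% of the masked positive maximum
(signed; absolute-value mode available); the ROI-mean trace is reported per
block and block-averaged. The on-window is exactly the stimulus seconds
rounded to frames, with no hemodynamic-lag shift (appropriate for calcium).

## Cluster-extent statistics

For a standardized 2D Gaussian field thresholded at `Zt`:

    E[m]   = R · 4 ln2 · (2π)^(−3/2) · Zt · exp(−Zt²/2)
    R      = x² / FWHM²
    |Λ|    = [FWHM² / (4 ln2)]^(−2)
    E[n]   = 2π FWHM² / (Zt² · 4 ln2),   β = 1 / E[n]
    k_α    = (1/β) · ln( −E[m] / ln(1−α) )

Smoothness is estimated from one frame: standardize over the mask, take
forward finite differences (excluding pixels with off-mask neighbours),
form the 2×2 derivative covariance Λ, invert the |Λ|↔FWHM relation. At the
reference parameters (x = 78, FWHM = 7 px, Zt = 3.09, α = 0.05) the chain
gives R = 124.16, E[m] = 0.5704, E[n] = 11.630, β = 0.08599,
k_α = 28.0 px. Clusters are 8-connected by default (4 switchable); "at
least k_α" is implemented as size ≥ ceil(k_α) = 29 px (conservative
integerization). Bonferroni (`p < α/n_masked`) is provided as the stringent
comparator.

t-maps are converted to z exactly via one-tailed p-values
(sign-preserving) before the `Zt` cut; the cluster-defining threshold
(default Zt = 3.09, i.e. p = 0.001) and any display p-threshold are
separate parameters. At very small degrees of freedom the z-converted field
is marginally Gaussian but spatially heavier-tailed than a Gaussian field;
Monte-Carlo calibration shows this makes the cluster threshold
conservative (null clusters are smaller), which is the direction that
protects the FWE guarantee. `fwe_calibration` verifies the whole procedure
empirically: simulated null fields at the stated smoothness yield an FWE of
roughly 2–4% against the nominal 5% at these parameters, and the
Monte-Carlo 95th-percentile null max-cluster size (~21 px) is bounded by
k_α. R defaults to the full-image x²/FWHM² definition; a masked-area
variant `n_masked/FWHM²` is available for irregular fields of view.

## Synthetic data

The generators define the study conditions and ship with defaults matching
the reference design: 78×78 px, FWHM 7 px, 16.8 Hz per channel, 5/5/10 s
blocks × 14, paired groups of N = 4.

* **Gaussian random fields**: white noise convolved with a Gaussian kernel
  on a 3σ-padded grid, cropped, standardized per frame — uniform smoothness
  to the edge, per-frame mean 0 / sd 1 exactly.
* **Homotopic movies**: each mirror pair shares a component with weight
  √r so the pair correlation is the target r in expectation; pixels are
  otherwise independent (no spatial smoothing, keeping the closed form
  exact).
* **Multi-wavelength forward model**: `I_i = I0·exp(−L_i ε_i·ΔC)` with
  ~1 μM zero-mean sinusoidal ΔHbO (ΔHbR = −0.4·ΔHbO) on a spatial bump;
  the fluorescence channel applies the excitation/emission attenuation to a
  known truth. Optional Gaussian shot noise.
* **Stimulus movies**: Gaussian blob (σ 3 px) times the on-frame boxcar
  plus noise; the default detection test uses SNR 5 (amplitude/noise).
* **Group difference**: subject maps are a common base field plus smooth
  subject noise (sd 0.12, FWHM 7 px); the deficit group subtracts the
  effect (default 1.0) inside a disc region, giving a per-pixel paired
  Cohen's d ≈ 6 — a large effect, matching the deliberately small N = 4
  paired design the method targets.

What the generators do **not** emulate: vascular anatomy, heartbeat and
respiration harmonics, photobleaching beyond a linear trend, motion, and
spatially structured noise correlations between hemisphere pairs. Passing
tests therefore validate the algorithms and their statistical calibration
under the stated models, not the biology of any particular dataset.

## Numerical choices and problem sizes

Correlations clip to [−1, 1]; constant traces give NaN sentinels rather
than exceptions inside map code (but hard errors where the operation is
undefined, e.g. GSR on a constant global signal). Butterworth filtering is
`sosfiltfilt` (zero phase). The FWE calibration uses 500 null fields
(Monte-Carlo SE ≈ 1 percentage point at α = 0.05); smoothness-recovery
checks use 512×512 fields over 20 seeds; the null specificity check uses
100 paired-group draws. The test suite and calibration complete in well
under a minute on one CPU.

## Known limitations

2D RFT only (no 3D, no peak-height inference, no permutation tests);
cluster inference assumes stationary smoothness over the mask; the
similarity transform cannot correct shear or anisotropic scale; spectra
shipped are qualitative stand-ins; no motion correction or physiological
notch filtering.
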
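# Methods notes

This note documents the models, conventions and free parameters behind
`fbrquant`, and what the synthetic-data tests do and do not establish about
real sections and recordings.

## Coordinate and ROI conventions

Row 0 is the top of the image at the pial surface; rows increase with
cortical depth; all crops are half-open pixel intervals. Shank images are
800 px wide, centered on the track; out-of-bounds crop area is zero-padded
and flagged rather than truncated. The three depth ROIs are fixed in
pixels — 800 wide × 700 deep — anchored at the pia (upper cortex), at the
white-matter boundary extending upward (lower cortex) and downward (white
matter). The pixel size (default 0.576 µm/px, isotropic) is carried for
reporting only; every computation is pixel-based. When the cortical depth is
under 1400 px the two cortical ROIs overlap; both are returned with the
overlap recorded, and nothing is excluded. When a section has no white
matter, the white-matter ROI is absent rather than zero-filled.

## Binarization and mask filtering

The Moments (Tsai) threshold preserves the first three gray-level moments.
The closed form yields the background fraction p0; the returned threshold is
the gray level at which the cumulative histogram first reaches p0, i.e. the
cut bin is assigned to background (the convention of the common ImageJ-style
implementation). Degenerate single-valued histograms return that value with
an all-background result and a warning. Foreground is strictly above the
threshold.

The threshold adapts to each ROI's own histogram. A consequence worth
knowing: a lesion void adds dark mass, which lowers the threshold and can
slightly inflate the apparent occupancy of surviving structures, so mild
lesions can show a small *positive* ΔNeuN. The tissue-reaction index is
insensitive to this by construction (positive ΔNeuN is zeroed).

Mask filters remove whole 8-connected components that fail any active
criterion. The stains differ morphologically, so the defaults differ:

| stain | min area (px) | other | rationale |
|-------|---------------|-------|-----------|
| NeuN  | 20 | solidity ≥ 0.7 | compact somata; drop speckle and ragged debris |
| GFAP  | 5  | —              | keep thin filaments, drop single-pixel noise |
| IBA1  | 8  | —              | small blobs |

These numeric values are free parameters of this pipeline (config- and
call-overridable), chosen once so the generator's shapes are correctly
retained or removed.

## Downsampling

800 columns map to 11 bins and 700 rows to 10 bins by *exact area-weighted*
binning (800/11 is not integral), so total foreground mass is conserved to
floating-point rounding rather than being biased by cropping. Grid values
are 255 × occupancy, kept as floats.

## Tissue loss, Δ signals and the index

Tissue signal = (NeuN + GFAP)², computed in widened integers; pixels with
squared signal < 50 are non-tissue; the inverted binary is downsampled so a
cell reads 255 × lost fraction. The "< 50" threshold is applied to the
squared sum, following the stated processing order literally. Δ maps are
cell-wise experimental minus the cell-wise mean of all control sections for
that region and stain. Cells with loss intensity strictly above 190 (> 75 %)
are excluded from every mean; for upper-cortex NeuN the top 3 of the 10 grid
rows are excluded as cortical layer 1 (≈ 210 px ≈ the layer-1 thickness at
the default pixel size — the exclusion operates on downsampled rows, since
3 raw pixels could not represent a cortical layer).

The per-sample index is computed from the two region-mean deltas:
Idx = (|min(ΔNeuN,0)| + max(ΔGFAP,0)) / 510, so it spans 0–1 with both
channels bounded by 255. A cell-wise variant exists for maps, but the scalar
form is normative. White-matter Idx is reported yet excluded from
statistics, as NeuN carries no information there.

## Statistics

The sampling unit is the ROI image (shank × region); no mouse-level random
effect is modeled — a deliberate, mirrored limitation. ANOVA uses type-II
sums of squares (appropriate for unbalanced main-effects designs);
interactions are config options and are dropped with a warning when design
cells are empty. Rank tests always apply the tie correction, because
downsampled intensities produce ties. The Dunn z uses the pooled mean-rank
difference over √((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)) with two-sided
normal p values and Bonferroni adjustment. All tests are two-sided.
Degenerate all-equal inputs return a null result (statistic 0, p 1) rather
than floating-point noise.

## Ephys processing

Filters are 3rd-order Butterworth applied forward–backward (zero phase), so
response latencies are preserved; the envelope is decimated to 1 kHz after
the 200 Hz low-pass (no information loss). The trial window is
[−0.25, 1.25] s around onset; the baseline window is half-open [−250, 0) ms;
the three response windows are closed intervals. The trial-mean trace is
smoothed with a 5-ms Gaussian before the response is measured
(config-overridable). "Noise" is the SD across trials of the per-trial
baseline mean — the reading that makes an SD over trials well defined. Zero
noise flags the SNR as infinite and excludes the record.

The max-over-windows response statistic is biased above zero under the
null, so null SNRs concentrate near ~1 rather than 0 at moderate trial
counts; the SNR estimates amplitude/σ accurately once the evoked response
dominates the sampling noise of the trial-mean trace (the recovery test uses
amplitude = 10 σ at 100 trials).

## Synthetic-data generator

The generator renders occupancy statistics, not morphology realism: somata
are hard disks with Gaussian-blurred edges, astrocytic processes short
random strokes (so the per-stain filters are exercised on distinct shapes),
microglia small blobs. Intensities are foreground ≈ 200 over a diffuse
tissue background of 30 (void and extra-cerebral background 0) with additive
Gaussian noise (default SD 4) clipped to 0–255 — enough to test thresholding
robustness. Control occupancies (GFAP 0.08 cortex / 0.30 white matter, IBA1
0.04, ~8 somata per 100×100 px with a sparse layer 1) are free parameters;
no published control-occupancy values exist, so they were fixed once at
levels a histologist would call plausible for these stains.

Implanted sections add: a vertical void of width shank-width × lesion-scale
(all channels suppressed inside); neuronal depletion within a peri-track
radius (default 100 µm — deliberately wider than the void half-width, since
neuronal kill zones around stiff probes extend well past the physical
track); a GFAP depth gain of 1 + uniform + two Gaussian bumps at the pia and
the white-matter boundary (width = cortical depth / 6, the simplest shape
with two foci); an IBA1 bump at that boundary; and, with a configurable
probability, a threefold-widened through-lesion of the upper cortex. Stroke
placement uses a Poisson-coverage correction (λ = −ln(1−occupancy)) so
targets are met despite overlap. The default design-to-lesion effect map
gives silicon probes a wider void, larger depletion radius, stronger and
more uniform astrocytic gain and a higher through-lesion probability than
polyimide, encoding the qualitative phenomenology the pipeline is meant to
recover.

Synthetic recordings are per-electrode Gaussian noise plus Gaussian-windowed
3 kHz transients (inside the MUA band) at a fixed latency after each of the
three stimulus events, with per-electrode carrier phase and ±10 ms latency
offsets so the evoked signal is local rather than common-mode; amplitude
decays multiplicatively per week. A shared-mode artifact (8 Hz sinusoid plus
frequent broadband bursts, identical on all channels) makes common-average
referencing observably beneficial.

Every generator is a pure function of its parameters and seed; cohorts
derive per-section child seeds from one master seed.

## What the synthetic tests show — and don't

Passing tests establish that the *pipeline* recovers the direction and
ordering of effects it is designed to measure (lesion-width ordering of
ΔTissueLoss, the two astrocytic depth foci, the silicon-vs-polyimide index
difference, SNR decay) when those effects are present by construction. They
do not validate staining chemistry, registration, the manual annotation of
anatomical anchors, or effect sizes in real tissue; real sections add
vascular damage, section-to-section thickness variation, uneven
illumination and antibody variability that the generator does not model.
Group-level test statistics from real cohorts are therefore out of scope.

## Problem sizes used in the test suite

Directional-recovery checks run 10 independent replicates each: 20 shanks
per replicate for the depth-profile comparison, 10 shanks per material for
the index comparison, 10 seeds per width for the tissue-loss ordering, with
3 control sections per replicate; statistics calibration uses 5000 null
simulations; oracle equivalence uses 1000 random histograms and 300 small
rank datasets. These sizes give stable directional outcomes at the
generator's default effect sizes.
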